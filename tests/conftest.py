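import numpy as np
import pytest

from rewardscape import (
    Landscape,
    ModelParams,
    Segment,
    TrialSchedule,
    make_exp1_landscape,
    make_exp2_landscape,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def steep_cw():
    return make_exp1_landscape("steep", "CW")


@pytest.fixture(scope="session")
def shallow_cw():
    return make_exp1_landscape("shallow", "CW")


@pytest.fixture(scope="session")
def exp2_cw():
    return make_exp2_landscape("CW")


@pytest.fixture(scope="session")
def default_params():
    return ModelParams()


@pytest.fixture(scope="session")
def flat_zero_landscape():
    """R == 0 everywhere reachable: every feedback trial is a failure."""
    return Landscape((Segment(-50.0, 50.0, 0.0, 0.0),), "CW", 0.0, name="flat0")


@pytest.fixture(scope="session")
def flat_one_landscape():
    """R == 1 over a wide support: every feedback trial is a success."""
    return Landscape((Segment(-50.0, 50.0, 0.0, 1.0),), "CW", 1.0, name="flat1")


@pytest.fixture(scope="session")
def steep_cohort(steep_cw, default_params):
    """Shared small steep-landscape cohort (n=200) with per-individual series."""
    return simulate_cohort(default_params, steep_cw, TrialSchedule(),
                           n_individuals=200, seed=11)


@pytest.fixture(scope="session")
def shallow_cohort(shallow_cw, default_params):
    return simulate_cohort(default_params, shallow_cw, TrialSchedule(),
                           n_individuals=200, seed=12)


@pytest.fixture(scope="session")
def exp2_cohort(exp2_cw, default_params):
    """Valley-landscape cohort, n=2000, used by classification analyses."""
    return simulate_cohort(default_params, exp2_cw, TrialSchedule(),
                           n_individuals=2000, seed=13)
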