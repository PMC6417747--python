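"""Learning-curve fits, bootstrap inference, classification and exact tests."""

import math

import numpy as np
import pytest

from rewardscape import (
    ModelParams,
    TrialSchedule,
    bootstrap_lambda,
    classify_final,
    contingency_test,
    fit_exponential,
    nth_success_prediction,
    simulate_cohort,
    simulate_participant,
    variability_by_history,
)
from rewardscape.model import TrialSeries


# ---------------------------------------------------------------------------
# Exponential fit
# ---------------------------------------------------------------------------

def test_exponential_exact_recovery():
    i = np.arange(1, 351)
    curve = 4.0 * (1 - np.exp(-i / 30.0))
    fit = fit_exponential(curve)
    assert fit.a == pytest.approx(4.0, rel=1e-6)
    assert fit.lam == pytest.approx(30.0, rel=1e-6)
    assert fit.rss < 1e-12
    assert fit.identifiable


def test_exponential_degenerate_curve_flagged():
    fit = fit_exponential(np.zeros(350))
    assert abs(fit.a) < 1e-6
    assert not fit.identifiable


def test_exponential_too_short_raises():
    with pytest.raises(ValueError):
        fit_exponential(np.array([0.1, 0.2]))


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _noisy_group(lam, n_participants, n_trials, seed):
    rng = np.random.default_rng(seed)
    i = np.arange(1, n_trials + 1)
    base = 3.5 * (1 - np.exp(-i / lam))
    return [base + rng.normal(0, 0.8, size=n_trials) for _ in range(n_participants)]


def test_bootstrap_identical_groups_symmetric():
    """Two groups drawn from the same generating curve: the one-tailed p for
    lambda_a < lambda_b is ~0.5 by symmetry of the difference distribution."""
    a = _noisy_group(30.0, 12, 120, seed=1)
    res = bootstrap_lambda(a, [c.copy() for c in a], n_resamples=10_000, seed=3)
    assert res.p_value == pytest.approx(0.5, abs=0.05)
    assert res.ci95_a[0] < res.ci95_a[1]
    assert 0.0 <= res.p_value <= 1.0


def test_bootstrap_detects_faster_group():
    fast = _noisy_group(15.0, 14, 200, seed=4)
    slow = _noisy_group(60.0, 14, 200, seed=5)
    res = bootstrap_lambda(fast, slow, n_resamples=2_000, seed=6)
    assert res.p_value < 0.05
    # point fits are covered by their own percentile intervals
    lam_point = fit_exponential(np.mean(fast, axis=0)).lam
    assert res.ci95_a[0] <= lam_point <= res.ci95_a[1]


def test_bootstrap_requires_two_participants():
    g = _noisy_group(30.0, 1, 100, seed=7)
    with pytest.raises(ValueError):
        bootstrap_lambda(g, g)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "final_mean,scheme,cutoff,label,direction",
    [
        (3.5, "exp1", 1.0, "learner", None),
        (0.0, "exp1", 1.0, "non_learner", None),
        (0.99, "exp1", 1.0, "non_learner", None),
        (1.0, "exp1", 1.0, "learner", None),
        (-2.0, "exp2", 1.0, "shallow_learner", "CCW"),
        (2.0, "exp2", 1.0, "steep_learner", "CW"),
        (0.0, "exp2", 1.0, "non_learner", "center"),
        (0.7, "exp2", 0.5, "steep_learner", "CW"),
        (1.2, "exp2", 1.5, "non_learner", "center"),
    ],
)
def test_classify_final_cutoffs(final_mean, scheme, cutoff, label, direction):
    c = classify_final(final_mean, cutoff=cutoff, scheme=scheme)
    assert c.label == label
    assert c.direction == direction


def test_classify_invariant_under_sign_flip(exp2_cohort):
    """Pool-flipping a series mirrors its direction label but preserves the
    steep/shallow/non partition sizes."""
    from rewardscape import pool_sign_flip

    labels = [classify_final(s, scheme="exp2").label for s in exp2_cohort.series[:300]]
    flipped = [
        classify_final(pool_sign_flip(s, "steepCCW"), scheme="exp2").label
        for s in exp2_cohort.series[:300]
    ]
    swap = {"steep_learner": "shallow_learner", "shallow_learner": "steep_learner",
            "non_learner": "non_learner"}
    assert flipped == [swap[lab] for lab in labels]


# ---------------------------------------------------------------------------
# Nth-success prediction
# ---------------------------------------------------------------------------

def _series_from(theta_reward_pairs, n_last=4):
    """Tiny hand-built valley-cohort member: experimental trials only."""
    theta = np.array([t for t, _ in theta_reward_pairs], float)
    reward = np.array([r for _, r in theta_reward_pairs], float)
    phase = np.array(["experimental"] * len(theta))
    return TrialSeries("p", phase, theta, reward,
                       TrialSchedule(0, len(theta), 0))


def test_nth_success_hand_counted_fixture():
    """Three hand-built individuals; conditional frequencies by brute count.

    A: successes at +2 (steep), +3 (steep); final mean +3 -> steep learner.
    B: successes at -2 (shallow), -2.5; final mean -2.5 -> shallow learner.
    C: first success at +1 (steep), then drifts; final mean 0 -> non learner.
    """
    a = _series_from([(2, 1), (3, 1), (3, 1), (3, 1)])
    b = _series_from([(-2, 1), (-2.5, 1), (-2.5, 1), (-2.5, 1)])
    c = _series_from([(1, 1), (0, 0), (0, 0), (0, 0)])
    table = nth_success_prediction([a, b, c], max_n=2, n_last=4)

    row = table[(table.n == 1) & (table.slope == "steep")].iloc[0]
    assert row.n_individuals == 2  # A and C
    assert row.p_steep_learner == pytest.approx(0.5)
    assert row.p_non_learner == pytest.approx(0.5)
    row = table[(table.n == 1) & (table.slope == "shallow")].iloc[0]
    assert row.n_individuals == 1  # B only
    assert row.p_shallow_learner == pytest.approx(1.0)
    row = table[(table.n == 2) & (table.slope == "steep")].iloc[0]
    assert row.n_individuals == 1  # only A has a 2nd success, on steep
    assert row.p_steep_learner == pytest.approx(1.0)


def test_nth_success_empty_condition_is_nan():
    a = _series_from([(2, 1), (3, 1), (3, 1), (3, 1)])
    table = nth_success_prediction([a], max_n=3, n_last=4)
    shallow1 = table[(table.n == 1) & (table.slope == "shallow")].iloc[0]
    assert shallow1.n_individuals == 0
    assert math.isnan(shallow1.p_steep_learner)


# ---------------------------------------------------------------------------
# Variability by reinforcement history
# ---------------------------------------------------------------------------

def test_variability_closed_forms(flat_zero_landscape, flat_one_landscape):
    """alpha=0 oracle: differences of iid Normals give SD(dtheta) = sqrt(2)*SD."""
    sched = TrialSchedule(50, 10_000, 50)
    params = ModelParams(alpha=0.0, sigma_m=0.81, sigma_e=0.90)
    fail = simulate_participant(params, flat_zero_landscape, sched, seed=31)
    sds = variability_by_history(fail)
    expect_fail = np.sqrt(2.0) * np.sqrt(0.81**2 + 0.9**2)
    se3 = 3 * expect_fail / np.sqrt(2 * 10_000)  # ~3 Monte-Carlo SEs
    assert abs(sds["after_failure"] - expect_fail) < se3
    assert math.isnan(sds["after_success"])

    succ = simulate_participant(params, flat_one_landscape, sched, seed=32)
    sds = variability_by_history(succ)
    expect_succ = np.sqrt(2.0) * 0.81
    assert abs(sds["after_success"] - expect_succ) < 3 * expect_succ / np.sqrt(2 * 10_000)
    # baseline/washout reaches carry motor noise only
    assert sds["baseline"] == pytest.approx(expect_succ, rel=0.5)
    assert sds["washout"] == pytest.approx(expect_succ, rel=0.5)


def test_variability_failure_exceeds_success(steep_cohort):
    sds = variability_by_history(steep_cohort.series)
    assert sds["after_failure"] > sds["after_success"]


def test_variability_two_back_bins(steep_cohort):
    sds = variability_by_history(steep_cohort.series, two_back=True)
    assert set(sds) >= {"after_00", "after_01", "after_10", "after_11"}
    # the one-back bins are mixtures of the matching two-back bins
    assert min(sds["after_01"], sds["after_11"]) <= sds["after_success"] * 1.05
    assert sds["after_00"] > sds["after_11"]


# ---------------------------------------------------------------------------
# Exact contingency test
# ---------------------------------------------------------------------------

def fisher_two_sided_enumeration(table) -> float:
    """Brute-force two-sided exact test: enumerate all tables with the
    observed margins and sum the probabilities of those no more likely than
    the observed table (hypergeometric point masses via factorials)."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def point_prob(x):  # table [[x, r1-x], [c1-x, r2-c1+x]]
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = point_prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(point_prob(x) for x in range(lo, hi + 1) if point_prob(x) <= p_obs * (1 + 1e-9))


def test_contingency_matches_enumeration_oracle():
    tables = [
        [[37, 3], [29, 11]],
        [[5, 5], [5, 5]],
        [[8, 2], [3, 9]],
        [[1, 9], [9, 1]],
        [[10, 0], [0, 10]],
    ]
    for t in tables:
        assert contingency_test(t) == pytest.approx(
            fisher_two_sided_enumeration(t), abs=1e-10
        )


def test_contingency_known_values():
    # learner/non-learner counts by landscape gradient
    assert contingency_test([[37, 3], [29, 11]]) == pytest.approx(0.036, abs=0.001)
    assert contingency_test([[5, 5], [5, 5]]) == pytest.approx(1.0)


def test_contingency_validation():
    with pytest.raises(ValueError):
        contingency_test([[1, 2, 3], [4, 5, 6]])
    with pytest.raises(ValueError):
        contingency_test([[0, 0], [3, 4]])
    with pytest.raises(ValueError):
        contingency_test([[1.5, 2], [3, 4]])
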