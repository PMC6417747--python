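"""Trial-by-trial reinforcement learning model of reach adaptation.

The learner keeps a single cached action: the intended reach aim.  Each trial
the executed angle is the aim plus Normal noise whose variance depends on the
outcome of the previous trial — motor variance σm² after a success, motor
plus exploration variance σm² + σe² after a failure.  After a rewarded reach
the aim moves a fixed proportion α toward the executed angle; after an
unrewarded reach the aim is unchanged:

    θ_n ~ N(aim_n, σ_n²)
    aim_{n+1} = aim_n + α (θ_n − aim_n),  σ_{n+1}² = σm²            if r_n = 1
    aim_{n+1} = aim_n,                     σ_{n+1}² = σm² + σe²      if r_n = 0

No-feedback trials (baseline and washout) neither update the aim nor add
exploration variance: absence of feedback is not a failure signal, so the
learner reaches with motor noise only and the adapted aim is retained through
washout.  The best-fit parameters are α = 0.40, σm = 0.81 and σe = 0.90
(z-score units).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .landscape import Landscape

__all__ = [
    "ModelParams",
    "ModelState",
    "ModelState2D",
    "TrialSchedule",
    "TrialSeries",
    "CohortResult",
    "RectTarget",
    "trial_variance",
    "step",
    "step_2d",
    "simulate_participant",
    "simulate_cohort",
]

PHASES = ("baseline", "experimental", "washout")

SUCCESS = "success"
FAILURE = "failure"
NO_FEEDBACK = "no_feedback"


@dataclass(frozen=True)
class ModelParams:
    """Free parameters of the learner.

    alpha : proportion of the aim-to-reach difference applied after a success
        (unitless, in [0, 1]).
    sigma_m : motor (execution) SD, present on every trial.
    sigma_e : exploration SD, added after unsuccessful reaches.

    Units are z-scores for the normalized experiments; native units (degrees,
    mm) for the replication scenarios.
    """

    alpha: float = 0.40
    sigma_m: float = 0.81
    sigma_e: float = 0.90

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.sigma_m <= 0:
            raise ValueError("sigma_m must be positive")
        if self.sigma_e < 0:
            raise ValueError("sigma_e must be nonnegative")


@dataclass
class ModelState:
    """Current intended aim and the outcome of the previous trial."""

    aim: float = 0.0
    last_outcome: str = NO_FEEDBACK


@dataclass
class ModelState2D:
    """2D aim vector and last outcome, for rectangle-target simulations."""

    aim: np.ndarray = field(default_factory=lambda: np.zeros(2))
    last_outcome: str = NO_FEEDBACK


@dataclass(frozen=True)
class TrialSchedule:
    """Counts of baseline / experimental / washout trials (default 50/350/50)."""

    n_baseline: int = 50
    n_experimental: int = 350
    n_washout: int = 50

    def __post_init__(self) -> None:
        for name in ("n_baseline", "n_experimental", "n_washout"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.n_baseline + self.n_experimental + self.n_washout

    def phases(self) -> np.ndarray:
        """Phase label per trial, length ``total``."""
        return np.asarray(
            ["baseline"] * self.n_baseline
            + ["experimental"] * self.n_experimental
            + ["washout"] * self.n_washout
        )

    @property
    def experimental_slice(self) -> slice:
        return slice(self.n_baseline, self.n_baseline + self.n_experimental)

    @property
    def washout_slice(self) -> slice:
        return slice(self.n_baseline + self.n_experimental, self.total)


@dataclass
class TrialSeries:
    """One simulated or recorded participant: ordered trials with outcomes.

    ``reward`` is NaN on no-feedback (baseline/washout) trials, 0/1 elsewhere.
    """

    participant: str
    phase: np.ndarray
    theta: np.ndarray
    reward: np.ndarray
    schedule: TrialSchedule | None = None

    def __post_init__(self) -> None:
        n = len(self.theta)
        if not (len(self.phase) == len(self.reward) == n):
            raise ValueError("phase, theta and reward must have equal length")

    def __len__(self) -> int:
        return len(self.theta)

    @property
    def trial(self) -> np.ndarray:
        """1-based trial index over the session."""
        return np.arange(1, len(self) + 1)

    def phase_mask(self, phase: str) -> np.ndarray:
        return self.phase == phase

    @property
    def experimental_theta(self) -> np.ndarray:
        return self.theta[self.phase_mask("experimental")]

    @property
    def experimental_reward(self) -> np.ndarray:
        return self.reward[self.phase_mask("experimental")]

    def final_mean(self, n_last: int = 100) -> float:
        """Mean z of the last ``n_last`` experimental trials."""
        th = self.experimental_theta
        if len(th) < n_last:
            raise ValueError(f"need >= {n_last} experimental trials, have {len(th)}")
        return float(np.mean(th[-n_last:]))

    def replace_theta(self, theta: np.ndarray) -> "TrialSeries":
        return TrialSeries(self.participant, self.phase, np.asarray(theta, float),
                           self.reward, self.schedule)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant": self.participant,
                "trial": self.trial,
                "phase": self.phase,
                "theta": self.theta,
                "reward": self.reward,
            }
        )


@dataclass
class CohortResult:
    """Cohort simulation output: mean curve with SE, plus optional series."""

    mean_curve: np.ndarray
    se_curve: np.ndarray
    n_individuals: int
    schedule: TrialSchedule
    params: ModelParams
    seed: int | None = None
    series: list[TrialSeries] | None = None

    @property
    def mean_experimental_curve(self) -> np.ndarray:
        return self.mean_curve[self.schedule.experimental_slice]


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def trial_variance(params: ModelParams, last_outcome: str) -> float:
    """Variance of the upcoming reach given the previous trial's outcome.

    σm² after a success or a no-feedback trial; σm² + σe² after a failure.
    """
    if last_outcome == FAILURE:
        return params.sigma_m**2 + params.sigma_e**2
    if last_outcome in (SUCCESS, NO_FEEDBACK):
        return params.sigma_m**2
    raise ValueError(f"unknown outcome {last_outcome!r}")


def step(
    state: ModelState,
    params: ModelParams,
    landscape: Landscape,
    rng: np.random.Generator,
) -> tuple[ModelState, tuple[float, int]]:
    """One feedback trial: reach, sample reward, update the aim on success.

    Returns the new state and ``(theta, reward)`` for the executed trial.
    """
    sd = np.sqrt(trial_variance(params, state.last_outcome))
    theta = state.aim + sd * rng.standard_normal()
    r = int(rng.random() < landscape.probability(theta))
    if r == 1:
        new_aim = state.aim + params.alpha * (theta - state.aim)
        outcome = SUCCESS
    else:
        new_aim = state.aim
        outcome = FAILURE
    return ModelState(aim=new_aim, last_outcome=outcome), (theta, r)


def step_2d(
    state: ModelState2D,
    params: ModelParams,
    target: "RectTarget",
    rng: np.random.Generator,
) -> tuple[ModelState2D, tuple[np.ndarray, int]]:
    """One 2D trial against a rectangular target.

    Noise is isotropic (the same σm, σe on each axis, independent draws);
    reward is 1 iff the endpoint falls inside the rectangle; the aim vector is
    updated componentwise by the same α rule on success.
    """
    sd = np.sqrt(trial_variance(params, state.last_outcome))
    endpoint = state.aim + sd * rng.standard_normal(2)
    r = int(target.contains(endpoint))
    if r == 1:
        new_aim = state.aim + params.alpha * (endpoint - state.aim)
        outcome = SUCCESS
    else:
        new_aim = state.aim.copy()
        outcome = FAILURE
    return ModelState2D(aim=new_aim, last_outcome=outcome), (endpoint, r)


@dataclass(frozen=True)
class RectTarget:
    """Axis-aligned rectangular target centred at ``center``.

    ``width`` is the task-relevant extent (axis 0), ``length`` the
    task-irrelevant extent (axis 1).
    """

    width: float
    length: float
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.length <= 0:
            raise ValueError("target width and length must be positive")

    def contains(self, point: np.ndarray) -> bool:
        dx = abs(point[0] - self.center[0])
        dy = abs(point[1] - self.center[1])
        return bool(dx <= self.width / 2 and dy <= self.length / 2)


# ---------------------------------------------------------------------------
# Session simulation
# ---------------------------------------------------------------------------

def _simulate_block(
    params: ModelParams,
    landscape: Landscape,
    schedule: TrialSchedule,
    rngs: Sequence[np.random.Generator],
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``len(rngs)`` individuals with per-individual generators.

    Each individual's noise is pre-drawn from its own generator (two draws:
    standard normals then uniforms, ``total`` each), and the trial loop is
    vectorized across individuals.  Returns (thetas, rewards) of shape
    (n, total); rewards are NaN on no-feedback trials.
    """
    n = len(rngs)
    total = schedule.total
    z = np.empty((n, total))
    u = np.empty((n, total))
    for i, rng in enumerate(rngs):
        z[i] = rng.standard_normal(total)
        u[i] = rng.random(total)

    thetas = np.empty((n, total))
    rewards = np.full((n, total), np.nan)

    aim = np.zeros(n)
    sm2 = params.sigma_m**2
    se2 = params.sigma_e**2
    # Previous outcome enters through the per-individual variance; starts at
    # sigma_m^2 (previous trial absent / no feedback).
    var = np.full(n, sm2)

    exp_lo = schedule.n_baseline
    exp_hi = schedule.n_baseline + schedule.n_experimental
    for t in range(total):
        feedback = exp_lo <= t < exp_hi
        sd = np.sqrt(var) if feedback else params.sigma_m
        theta = aim + sd * z[:, t]
        thetas[:, t] = theta
        if feedback:
            p = landscape.probability(theta)
            r = u[:, t] < p
            rewards[:, t] = r
            aim = np.where(r, aim + params.alpha * (theta - aim), aim)
            var = np.where(r, sm2, sm2 + se2)
        # No-feedback trials (baseline/washout) leave both aim and var
        # untouched; they reach at sigma_m regardless of var.
    return thetas, rewards


def simulate_participant(
    params: ModelParams,
    landscape: Landscape,
    schedule: TrialSchedule | None = None,
    seed: int | np.random.SeedSequence | None = None,
    participant: str = "sim_0",
) -> TrialSeries:
    """Simulate one individual's full session (deterministic under ``seed``).

    The aim starts at 0 (the baseline mean in z-score units).  Baseline and
    washout reaches carry motor noise only and never update the aim.
    """
    schedule = schedule or TrialSchedule()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    thetas, rewards = _simulate_block(params, landscape, schedule, [np.random.default_rng(ss)])
    return TrialSeries(participant, schedule.phases(), thetas[0], rewards[0], schedule)


def simulate_cohort(
    params: ModelParams,
    landscape: Landscape,
    schedule: TrialSchedule | None = None,
    n_individuals: int = 40,
    seed: int | np.random.SeedSequence | None = None,
    keep_series: bool = True,
    chunk_size: int = 5000,
) -> CohortResult:
    """Simulate ``n_individuals`` independent learners and average them.

    A master :class:`numpy.random.SeedSequence` spawns one independent
    substream per individual, so the cohort is reproducible and individuals
    are statistically independent.  For large cohorts set
    ``keep_series=False`` to retain only the mean and standard-error curves
    (individuals are processed in chunks, memory stays bounded).
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    schedule = schedule or TrialSchedule()
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = master.spawn(n_individuals)

    total = schedule.total
    sum_theta = np.zeros(total)
    sumsq_theta = np.zeros(total)
    series: list[TrialSeries] | None = [] if keep_series else None
    phases = schedule.phases()

    for start in range(0, n_individuals, chunk_size):
        chunk = children[start : start + chunk_size]
        rngs = [np.random.default_rng(c) for c in chunk]
        thetas, rewards = _simulate_block(params, landscape, schedule, rngs)
        sum_theta += thetas.sum(axis=0)
        sumsq_theta += (thetas**2).sum(axis=0)
        if series is not None:
            for j in range(len(chunk)):
                series.append(
                    TrialSeries(f"sim_{start + j}", phases, thetas[j], rewards[j], schedule)
                )

    mean = sum_theta / n_individuals
    if n_individuals > 1:
        var = (sumsq_theta - n_individuals * mean**2) / (n_individuals - 1)
        se = np.sqrt(np.maximum(var, 0.0) / n_individuals)
    else:
        se = np.zeros(total)
    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    return CohortResult(mean, se, n_individuals, schedule, params,
                        seed=seed_int, series=series)
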