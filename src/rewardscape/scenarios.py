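"""Replication scenarios and parameter sweeps beyond the two main experiments.

These exercise the same learner in other task geometries: a target window
that is gradually rotated away from the visual target (binary feedback only),
a laterally shifted cursor drawn from a skewed distribution, a 2D rectangular
target probing random-walk drift along the task-irrelevant axis, and grids
over the noise parameters or the shallow landscape's baseline reward rate.

Scenario schedules for the replicated paradigms are configurable; their
defaults are representative rather than bit-faithful to the original
studies, and the scenario results are assessed as properties (linearity,
suboptimality, autocorrelation ordering) rather than numeric reproduction.
Scenario units are native (degrees or mm); z-normalization is bypassed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .analysis import fit_exponential
from .landscape import Landscape, Segment, make_exp1_landscape, M_SHALLOW
from .model import (
    ModelParams,
    ModelState2D,
    RectTarget,
    TrialSchedule,
    simulate_cohort,
    step_2d,
)

__all__ = [
    "GradualRotationConfig",
    "ShiftedCursorConfig",
    "RectTarget2DConfig",
    "run_gradual_rotation",
    "run_shifted_cursor",
    "run_rect_target_2d",
    "run_variability_sweep",
    "run_initial_reward_sweep",
    "lag1_autocorrelation",
    "shifted_shallow_landscape",
]


def lag1_autocorrelation(x: np.ndarray) -> float:
    """Lag-1 autocorrelation AFC(1) of a trial sequence."""
    x = np.asarray(x, float)
    if len(x) < 3:
        raise ValueError("sequence too short for autocorrelation")
    d = x - x.mean()
    denom = np.sum(d**2)
    if denom == 0:
        return 0.0
    return float(np.sum(d[:-1] * d[1:]) / denom)


# ---------------------------------------------------------------------------
# Gradual rotation of a rewarded target window (binary feedback)
# ---------------------------------------------------------------------------

@dataclass
class GradualRotationConfig:
    """Rotation schedule in degrees: the rewarded window steps away from the
    visual target by ``step_deg`` every ``trials_per_step`` trials up to
    ``total_rotation_deg``, then holds."""

    step_deg: float = 1.0
    trials_per_step: int = 40
    total_rotation_deg: float = 8.0
    window_deg: float = 3.0
    n_trials: int = 500
    n_individuals: int = 18
    params: ModelParams = field(default_factory=lambda: ModelParams(sigma_m=1.62, sigma_e=1.8))
    seed: int = 0

    def rotation_schedule(self) -> np.ndarray:
        steps = np.arange(self.n_trials) // self.trials_per_step
        return np.minimum(steps * self.step_deg, self.total_rotation_deg)


@dataclass
class ScenarioCohort:
    """Cohort output in native units: per-individual angle matrix + rewards."""

    thetas: np.ndarray  # (n, trials)
    rewards: np.ndarray
    config: object

    @property
    def mean_curve(self) -> np.ndarray:
        return self.thetas.mean(axis=0)

    @property
    def se_curve(self) -> np.ndarray:
        return self.thetas.std(axis=0, ddof=1) / np.sqrt(len(self.thetas))


def run_gradual_rotation(config: GradualRotationConfig) -> ScenarioCohort:
    """Simulate learners rewarded within a gradually rotating target window."""
    if config.window_deg <= 0:
        raise ValueError("window_deg must be positive")
    rot = config.rotation_schedule()
    n, t_total = config.n_individuals, config.n_trials
    master = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(c) for c in master.spawn(n)]
    z = np.vstack([r.standard_normal(t_total) for r in rngs])

    p = config.params
    sm2, se2 = p.sigma_m**2, p.sigma_e**2
    aim = np.zeros(n)
    var = np.full(n, sm2)
    thetas = np.empty((n, t_total))
    rewards = np.empty((n, t_total))
    half = config.window_deg / 2.0
    for t in range(t_total):
        theta = aim + np.sqrt(var) * z[:, t]
        # Binary feedback only: the model never sees the rotation itself.
        r = np.abs(theta - rot[t]) <= half
        aim = np.where(r, aim + p.alpha * (theta - aim), aim)
        var = np.where(r, sm2, sm2 + se2)
        thetas[:, t] = theta
        rewards[:, t] = r
    return ScenarioCohort(thetas, rewards, config)


# ---------------------------------------------------------------------------
# Laterally shifted cursor from a skewed distribution (mm)
# ---------------------------------------------------------------------------

@dataclass
class ShiftedCursorConfig:
    """Cursor shift drawn per trial from a skew-normal distribution (mm).

    Reward iff the shifted cursor lands inside the target of width
    ``target_width_mm`` centred at 0.  With positive skew, hits are maximized
    by aiming at the (negated) mode-side of the shift distribution.
    """

    shift_loc: float = 0.0
    shift_scale: float = 10.0
    shift_skew: float = 4.0
    target_width_mm: float = 20.0
    n_trials: int = 500
    n_individuals: int = 30
    params: ModelParams = field(default_factory=lambda: ModelParams(sigma_m=4.0, sigma_e=4.5))
    seed: int = 0

    def validate(self) -> None:
        if self.shift_scale < 0 or self.target_width_mm <= 0:
            raise ValueError("invalid shift distribution or target width")


def run_shifted_cursor(config: ShiftedCursorConfig) -> ScenarioCohort:
    """Simulate reaching with a stochastically shifted cursor."""
    config.validate()
    n, t_total = config.n_individuals, config.n_trials
    master = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(c) for c in master.spawn(n)]
    z = np.vstack([r.standard_normal(t_total) for r in rngs])
    if config.shift_scale == 0:
        shifts = np.full((n, t_total), config.shift_loc)
    else:
        shifts = stats.skewnorm.ppf(
            np.vstack([r.random(t_total) for r in rngs]),
            config.shift_skew, loc=config.shift_loc, scale=config.shift_scale,
        )

    p = config.params
    sm2, se2 = p.sigma_m**2, p.sigma_e**2
    aim = np.zeros(n)
    var = np.full(n, sm2)
    thetas = np.empty((n, t_total))
    rewards = np.empty((n, t_total))
    half = config.target_width_mm / 2.0
    for t in range(t_total):
        pos = aim + np.sqrt(var) * z[:, t]
        cursor = pos + shifts[:, t]
        r = np.abs(cursor) <= half
        aim = np.where(r, aim + p.alpha * (pos - aim), aim)
        var = np.where(r, sm2, sm2 + se2)
        thetas[:, t] = pos
        rewards[:, t] = r
    return ScenarioCohort(thetas, rewards, config)


def hit_maximizing_position(config: ShiftedCursorConfig, grid=None) -> float:
    """Position maximizing hit probability under the shift distribution."""
    if grid is None:
        grid = np.linspace(-60, 60, 4801)
    half = config.target_width_mm / 2.0
    p_hit = stats.skewnorm.cdf(
        half - grid, config.shift_skew, loc=config.shift_loc, scale=config.shift_scale
    ) - stats.skewnorm.cdf(
        -half - grid, config.shift_skew, loc=config.shift_loc, scale=config.shift_scale
    )
    return float(grid[np.argmax(p_hit)])


# ---------------------------------------------------------------------------
# 2D rectangular target: task-irrelevant random walk
# ---------------------------------------------------------------------------

@dataclass
class RectTarget2DConfig:
    """Long/thin rectangular target (units arbitrary; mm in the source task)."""

    width: float = 1.5    # task-relevant extent
    length: float = 30.0  # task-irrelevant extent
    n_trials: int = 300
    n_subjects: int = 6
    params: ModelParams = field(default_factory=lambda: ModelParams(sigma_m=0.81, sigma_e=0.90))
    seed: int = 0


@dataclass
class RectTarget2DResult:
    endpoints: np.ndarray        # (subjects, trials, 2)
    afc1_relevant: np.ndarray    # per subject
    afc1_irrelevant: np.ndarray

    @property
    def mean_afc1(self) -> tuple[float, float]:
        return float(self.afc1_relevant.mean()), float(self.afc1_irrelevant.mean())

    @property
    def se_afc1(self) -> tuple[float, float]:
        n = len(self.afc1_relevant)
        return (
            float(self.afc1_relevant.std(ddof=1) / np.sqrt(n)),
            float(self.afc1_irrelevant.std(ddof=1) / np.sqrt(n)),
        )


def run_rect_target_2d(config: RectTarget2DConfig) -> RectTarget2DResult:
    """Reinforcement-only reaching at a rectangle; AFC(1) per axis per subject.

    Axis 0 is task-relevant (short), axis 1 task-irrelevant (long).  Aim
    updates on success produce random-walk drift along the axis where almost
    every endpoint is rewarded.
    """
    target = RectTarget(config.width, config.length)
    master = np.random.SeedSequence(config.seed)
    endpoints = np.empty((config.n_subjects, config.n_trials, 2))
    for s, child in enumerate(master.spawn(config.n_subjects)):
        rng = np.random.default_rng(child)
        state = ModelState2D()
        for t in range(config.n_trials):
            state, (pt, _r) = step_2d(state, config.params, target, rng)
            endpoints[s, t] = pt
    rel = np.array([lag1_autocorrelation(endpoints[s, :, 0]) for s in range(config.n_subjects)])
    irr = np.array([lag1_autocorrelation(endpoints[s, :, 1]) for s in range(config.n_subjects)])
    return RectTarget2DResult(endpoints, rel, irr)


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------

def run_variability_sweep(
    sigma_m_values,
    sigma_e_values,
    landscapes: dict | None = None,
    n_per_cell: int = 10_000,
    alpha: float = 0.40,
    schedule: TrialSchedule | None = None,
    seed: int = 0,
):
    """λ of the cohort mean curve over a σm × σe grid, per landscape.

    Returns a pandas DataFrame with columns landscape, sigma_m, sigma_e,
    lam, a, fit_ok.  A cell whose exponential fit fails is marked
    ``fit_ok=False`` with NaN λ rather than aborting the sweep.
    """
    import pandas as pd

    if landscapes is None:
        landscapes = {
            "steep": make_exp1_landscape("steep", "CW"),
            "shallow": make_exp1_landscape("shallow", "CW"),
        }
    schedule = schedule or TrialSchedule()
    rows = []
    for k, (name, L) in enumerate(landscapes.items()):
        for i, sm in enumerate(sigma_m_values):
            for j, se in enumerate(sigma_e_values):
                params = ModelParams(alpha=alpha, sigma_m=float(sm), sigma_e=float(se))
                res = simulate_cohort(
                    params, L, schedule, n_individuals=n_per_cell,
                    seed=np.random.SeedSequence([seed, k, i, j]),
                    keep_series=False,
                )
                try:
                    fit = fit_exponential(res.mean_experimental_curve)
                    rows.append((name, sm, se, fit.lam, fit.a, fit.identifiable))
                except RuntimeError:
                    rows.append((name, sm, se, np.nan, np.nan, False))
    return pd.DataFrame(rows, columns=["landscape", "sigma_m", "sigma_e", "lam", "a", "fit_ok"])


def shifted_shallow_landscape(intercept: float) -> Landscape:
    """Shallow single-slope landscape with a shifted baseline reward rate.

    Keeps the 1/9-per-z-score slope and the plateau geometry; the line value
    at θ = 0 becomes ``intercept`` and the plateau at 3-6 z becomes
    ``1/3 + intercept`` capped into [0, 1].  ``intercept = 1/3`` reproduces
    the standard shallow landscape.
    """
    slope = 1.0 / 9.0
    plateau = slope * 3.0 + intercept
    if not (0.0 <= intercept <= 1.0) or not (0.0 <= plateau <= 1.0):
        raise ValueError("intercept leaves probabilities outside [0, 1]")
    x0 = -intercept / slope  # line's zero crossing
    return Landscape(
        segments=(
            Segment(x0, 3.0, slope, intercept),
            Segment(3.0, 6.0, 0.0, plateau, include_lo=False),
        ),
        direction_label="CW",
        max_rate=plateau,
        name=f"shallow_intercept_{intercept:.3f}",
    )


def run_initial_reward_sweep(
    intercepts,
    n_per_cell: int = 10_000,
    params: ModelParams | None = None,
    schedule: TrialSchedule | None = None,
    seed: int = 0,
):
    """λ of the shallow-landscape mean curve as the baseline reward rate varies."""
    import pandas as pd

    params = params or ModelParams()
    schedule = schedule or TrialSchedule()
    rows = []
    for i, c in enumerate(intercepts):
        L = shifted_shallow_landscape(float(c))
        res = simulate_cohort(
            params, L, schedule, n_individuals=n_per_cell,
            seed=np.random.SeedSequence([seed, i]), keep_series=False,
        )
        try:
            fit = fit_exponential(res.mean_experimental_curve)
            rows.append((float(c), fit.lam, fit.a, fit.identifiable))
        except RuntimeError:
            rows.append((float(c), np.nan, np.nan, False))
    return pd.DataFrame(rows, columns=["intercept", "lam", "a", "fit_ok"])
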