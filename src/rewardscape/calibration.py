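"""Simulation-based fitting of the learner's parameters (α, σm, σe).

The objective compares simulated cohort mean learning curves against target
mean curves for both single-slope gradients jointly (steep and shallow), by
summed squared error over experimental trials.  The objective is stochastic;
common random numbers (the same simulation seed at every evaluation) make it
smooth enough for a derivative-free optimizer: a coarse grid pass followed by
Nelder-Mead refinement.

Initial guesses for the noise parameters come from a trial-to-trial
difference analysis: for independent reaches at a fixed aim,
SD(Δθ) = √2 · SD(θ), so

    σm ≈ SD(Δθ | after success) / √2
    σe ≈ sqrt( SD(Δθ | after failure)² / 2 − σm² ) .
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .analysis import variability_by_history
from .landscape import Landscape, make_exp1_landscape
from .model import ModelParams, TrialSchedule, simulate_cohort

__all__ = ["FitSpec", "CalibrationResult", "initial_guess_sigmas", "fit_parameters"]


@dataclass
class FitSpec:
    """Specification for simulation-based parameter fitting.

    target_curves : mapping of condition name to mean experimental curve
        (z-score per experimental trial).
    landscapes : mapping of the same condition names to landscapes; defaults
        to the steep/shallow clockwise single-slope pair.
    bounds : (lo, hi) box per parameter, in order (alpha, sigma_m, sigma_e).
    n_sim : individuals simulated per objective evaluation (>= 100).
    n_boot : bootstrap refits on resampled per-participant targets (0 = off;
        requires ``target_participants``).
    """

    target_curves: dict
    landscapes: dict | None = None
    schedule: TrialSchedule = field(default_factory=TrialSchedule)
    bounds: tuple = ((0.05, 0.95), (0.2, 2.0), (0.0, 2.5))
    n_sim: int = 2000
    n_boot: int = 0
    seed: int = 0
    target_participants: dict | None = None

    def __post_init__(self) -> None:
        if self.n_sim < 100:
            raise ValueError("n_sim must be >= 100")
        if self.landscapes is None:
            self.landscapes = {
                "steep": make_exp1_landscape("steep", "CW"),
                "shallow": make_exp1_landscape("shallow", "CW"),
            }
        missing = set(self.target_curves) - set(self.landscapes)
        if missing:
            raise ValueError(f"no landscape for conditions {sorted(missing)}")


@dataclass
class CalibrationResult:
    """Best-fit parameters with the optimizer trace and bootstrap spread."""

    params: ModelParams
    objective: float
    trace: list
    converged: bool
    identifiable: bool = True
    boot_params: np.ndarray | None = None

    def boot_percentiles(self, q=(2.5, 97.5)) -> np.ndarray | None:
        if self.boot_params is None or len(self.boot_params) == 0:
            return None
        return np.percentile(self.boot_params, q, axis=0)


def initial_guess_sigmas(series_list) -> tuple[float, float]:
    """Difference-analysis starting values for (σm, σe).

    Raises when the post-success or post-failure bin is empty (e.g. an
    all-success series gives no information about exploration noise).
    """
    sds = variability_by_history(series_list)
    sd_s, sd_f = sds["after_success"], sds["after_failure"]
    if np.isnan(sd_s):
        raise ValueError("no post-success trial pairs: sigma_m guess undefined")
    if np.isnan(sd_f):
        raise ValueError("no post-failure trial pairs: sigma_e guess undefined")
    sm = sd_s / np.sqrt(2.0)
    se = float(np.sqrt(max(0.0, sd_f**2 / 2.0 - sm**2)))
    return float(sm), se


def _objective_factory(spec: FitSpec, targets: dict):
    conditions = sorted(targets)

    def objective(x: np.ndarray) -> float:
        alpha, sm, se = x
        (alo, ahi), (mlo, mhi), (elo, ehi) = spec.bounds
        # Penalty outside the box keeps Nelder-Mead inside without clipping.
        if not (alo <= alpha <= ahi and mlo <= sm <= mhi and elo <= se <= ehi):
            return 1e6 + float(np.sum(np.square(x)))
        params = ModelParams(alpha=float(alpha), sigma_m=float(sm), sigma_e=float(se))
        sse = 0.0
        for k, cond in enumerate(conditions):
            res = simulate_cohort(
                params,
                spec.landscapes[cond],
                spec.schedule,
                n_individuals=spec.n_sim,
                # Common random numbers: identical seeds at every evaluation.
                seed=np.random.SeedSequence([spec.seed, k]),
                keep_series=False,
            )
            sse += float(np.sum((res.mean_experimental_curve - targets[cond]) ** 2))
        return sse

    return objective


def _fit_once(spec: FitSpec, targets: dict, trace: list | None = None):
    objective = _objective_factory(spec, targets)
    (alo, ahi), (mlo, mhi), (elo, ehi) = spec.bounds

    # Coarse grid pass.
    alphas = np.linspace(alo + 0.05, min(ahi, 0.8), 4)
    sms = np.linspace(max(mlo, 0.4), min(mhi, 1.4), 4)
    ses = np.linspace(max(elo, 0.3), min(ehi, 1.5), 4)
    best_x, best_f = None, np.inf
    for a in alphas:
        for m in sms:
            for e in ses:
                f = objective(np.array([a, m, e]))
                if trace is not None:
                    trace.append(((float(a), float(m), float(e)), f))
                if f < best_f:
                    best_x, best_f = np.array([a, m, e]), f

    def traced(x):
        f = objective(x)
        if trace is not None:
            trace.append((tuple(map(float, x)), f))
        return f

    res = minimize(
        traced, best_x, method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-4, "maxfev": 400},
    )
    x = res.x if res.fun <= best_f else best_x
    f = min(res.fun, best_f)
    return x, float(f), bool(res.success)


def fit_parameters(spec: FitSpec) -> CalibrationResult:
    """Best-fit (α, σm, σe) against the target mean curves.

    Non-convergence of the refinement is reported via ``converged`` with the
    best-so-far parameters.  A degenerate target (essentially flat at zero)
    leaves α unidentifiable and is flagged via ``identifiable``.
    """
    targets = {k: np.asarray(v, float) for k, v in spec.target_curves.items()}
    for cond, curve in targets.items():
        if len(curve) != spec.schedule.n_experimental:
            raise ValueError(
                f"target curve {cond!r} has {len(curve)} trials; schedule expects "
                f"{spec.schedule.n_experimental}"
            )
    identifiable = any(np.max(np.abs(c)) > 0.25 for c in targets.values())

    trace: list = []
    x, f, ok = _fit_once(spec, targets, trace)

    boot = None
    if spec.n_boot > 0:
        if not spec.target_participants:
            raise ValueError("bootstrap refitting needs target_participants")
        rng = np.random.default_rng(spec.seed)
        mats = {k: np.asarray(v, float) for k, v in spec.target_participants.items()}
        samples = []
        for _ in range(spec.n_boot):
            resampled = {}
            for cond, mat in mats.items():
                idx = rng.integers(0, len(mat), size=len(mat))
                resampled[cond] = mat[idx].mean(axis=0)
            xb, _, _ = _fit_once(spec, resampled)
            samples.append(xb)
        boot = np.asarray(samples)

    params = ModelParams(alpha=float(x[0]), sigma_m=float(x[1]), sigma_e=float(x[2]))
    return CalibrationResult(params, f, trace, ok, identifiable, boot)
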