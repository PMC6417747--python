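"""Statistical analyses of trial series, applied to simulated or recorded data.

Covers the learning-curve statistics used to compare landscape gradients:
exponential fits of the mean experimental curve, participant-level bootstrap
posteriors of the time constant λ, learner/direction classification from
asymptotic reach angle, prediction of final classification from the slope of
the N-th success, trial-to-trial variability conditioned on reinforcement
history, and exact contingency tests on learner counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .model import TrialSchedule, TrialSeries

__all__ = [
    "ExpFit",
    "BootstrapResult",
    "Classification",
    "fit_exponential",
    "bootstrap_lambda",
    "classify_final",
    "nth_success_prediction",
    "variability_by_history",
    "contingency_test",
]

#: Multi-start initial values for the time constant (experimental trials).
LAMBDA_STARTS = (5.0, 20.0, 50.0, 100.0, 200.0)

EXP2_LABELS = ("steep_learner", "shallow_learner", "non_learner")


@dataclass
class ExpFit:
    """Least-squares fit of ``theta_i = a (1 - exp(-i / lam))``.

    ``i`` counts experimental trials starting at 1 (session trial 51 is
    i = 1), so ``lam`` is in units of experimental trials.  ``identifiable``
    is False for degenerate curves (asymptote indistinguishable from 0, where
    lam carries no information).
    """

    a: float
    lam: float
    rss: float
    identifiable: bool = True

    def predict(self, i: np.ndarray) -> np.ndarray:
        return self.a * (1.0 - np.exp(-np.asarray(i, float) / self.lam))


@dataclass
class BootstrapResult:
    """Participant-level bootstrap posteriors of λ for two groups.

    ``diff_samples`` is λ_b − λ_a per resample; ``p_value`` is the one-tailed
    probability for the hypothesis λ_a < λ_b (fraction of resamples with a
    non-positive difference).
    """

    lam_a: np.ndarray
    lam_b: np.ndarray
    diff_samples: np.ndarray
    p_value: float
    ci95_a: tuple[float, float]
    ci95_b: tuple[float, float]
    n_dropped: int = 0


@dataclass
class Classification:
    """Asymptotic-behaviour label from the mean of the last trials.

    Single-slope (Experiment 1) scheme: ``learner`` iff final mean >= cutoff.
    Valley (Experiment 2) scheme: direction is CW (>= +cutoff), CCW
    (<= −cutoff) or center; after sign-flip pooling the steep slope is
    positive, so the labels map to steep/shallow/non learner.
    """

    label: str
    final_mean: float
    cutoff: float
    direction: str | None = None


def _model(i, a, lam):
    return a * (1.0 - np.exp(-i / lam))


def _curve(curve_or_series) -> np.ndarray:
    if isinstance(curve_or_series, TrialSeries):
        return curve_or_series.experimental_theta
    return np.asarray(curve_or_series, dtype=float)


def fit_exponential(
    mean_curve,
    lambda_starts=LAMBDA_STARTS,
    p0: tuple[float, float] | None = None,
) -> ExpFit:
    """Fit the saturating exponential to a mean experimental-trial curve.

    Nonlinear least squares over (a, λ) with a multi-start over λ (lowest
    residual sum of squares wins).  When ``p0`` is given (bootstrap refits
    warm-starting from the point fit) only that start is tried, with the
    full multi-start as fallback on failure.  Raises if no start converges.
    """
    y = _curve(mean_curve)
    if len(y) < 3:
        raise ValueError("curve too short to fit")
    i = np.arange(1, len(y) + 1, dtype=float)
    a0 = float(np.mean(y[-max(len(y) // 7, 1):]))

    starts = [p0] if p0 is not None else [(a0, lam) for lam in lambda_starts]
    best = None
    for start in starts:
        try:
            popt, _ = curve_fit(
                _model, i, y, p0=start,
                bounds=([-np.inf, 1e-6], [np.inf, 1e6]), maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((y - _model(i, *popt)) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        if p0 is not None:
            return fit_exponential(y, lambda_starts, p0=None)
        raise RuntimeError("exponential fit failed to converge from all starts")
    (a, lam), rss = best
    identifiable = bool(abs(a) > 1e-6 and np.std(y) > 1e-12)
    return ExpFit(float(a), float(lam), rss, identifiable)


def _participant_curves(group) -> np.ndarray:
    """(n_participants, n_experimental) matrix from series or curves."""
    rows = [_curve(g) for g in group]
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError("participants have unequal experimental-trial counts")
    return np.vstack(rows)


def bootstrap_lambda(
    group_a,
    group_b,
    n_resamples: int = 10_000,
    seed: int | None = None,
) -> BootstrapResult:
    """Bootstrap posterior of λ per group and a one-tailed test λ_a < λ_b.

    Participants (not trials) are resampled with replacement within each
    group; each resample's mean curve is refit.  Refits warm-start from the
    group point fit and fall back to the full multi-start; a resample whose
    fit still fails is dropped and counted.
    """
    a = _participant_curves(group_a)
    b = _participant_curves(group_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("bootstrap needs >= 2 participants per group")
    rng = np.random.default_rng(seed)

    lam = {"a": [], "b": []}
    dropped = 0
    for key, mat in (("a", a), ("b", b)):
        point = fit_exponential(mat.mean(axis=0))
        warm = (point.a, point.lam)
        n = len(mat)
        for _ in range(n_resamples):
            idx = rng.integers(0, n, size=n)
            curve = mat[idx].mean(axis=0)
            try:
                fit = fit_exponential(curve, p0=warm)
            except RuntimeError:
                dropped += 1
                continue
            lam[key].append(fit.lam)

    lam_a = np.asarray(lam["a"])
    lam_b = np.asarray(lam["b"])
    m = min(len(lam_a), len(lam_b))
    diff = lam_b[:m] - lam_a[:m]
    p = float(np.mean(diff <= 0.0))
    ci = lambda x: tuple(np.percentile(x, [2.5, 97.5]))  # noqa: E731
    return BootstrapResult(lam_a, lam_b, diff, p, ci(lam_a), ci(lam_b), dropped)


def classify_final(
    series: TrialSeries | float,
    cutoff: float = 1.0,
    scheme: str = "exp1",
    n_last: int = 100,
) -> Classification:
    """Classify asymptotic behaviour from the mean of the last trials.

    ``series`` may be a TrialSeries (the mean of its last ``n_last``
    experimental trials is used) or a precomputed final mean.  ``cutoff``
    supports the robustness values 0.5 and 1.5 as well as the standard 1.0.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if isinstance(series, TrialSeries):
        fm = series.final_mean(n_last)
    else:
        fm = float(series)

    if scheme == "exp1":
        label = "learner" if fm >= cutoff else "non_learner"
        return Classification(label, fm, cutoff)
    if scheme == "exp2":
        if fm >= cutoff:
            direction, label = "CW", "steep_learner"
        elif fm <= -cutoff:
            direction, label = "CCW", "shallow_learner"
        else:
            direction, label = "center", "non_learner"
        return Classification(label, fm, cutoff, direction)
    raise ValueError(f"unknown scheme {scheme!r}")


def _success_slopes(series: TrialSeries) -> np.ndarray:
    """Sign labels (+1 steep, −1 shallow) of each success, in trial order.

    Assumes sign-flip pooling so that the steep slope lies at positive θ.
    Successes at exactly θ = 0 belong to neither slope and are skipped.
    """
    th = series.experimental_theta
    r = series.experimental_reward
    hit = (r == 1) & (th != 0.0)
    return np.sign(th[hit])


def nth_success_prediction(
    cohort,
    max_n: int = 30,
    cutoff: float = 1.0,
    n_last: int = 100,
):
    """P(final class | slope of the N-th success), over a valley-landscape cohort.

    For each N and slope s (steep: rewarded reach at θ > 0; shallow: θ < 0),
    conditions on the individuals whose N-th success overall lay on slope s
    and tabulates their final classifications.  Returns a pandas DataFrame
    with columns ``n``, ``slope``, ``n_individuals`` and one probability
    column per class; rows with an empty conditioning set carry NaN
    probabilities.
    """
    import pandas as pd

    labels = [classify_final(s, cutoff, scheme="exp2", n_last=n_last).label for s in cohort]
    slopes = [_success_slopes(s) for s in cohort]

    rows = []
    for n in range(1, max_n + 1):
        for slope_name, sign in (("steep", 1.0), ("shallow", -1.0)):
            sel = [
                lab
                for lab, sl in zip(labels, slopes)
                if len(sl) >= n and sl[n - 1] == sign
            ]
            row = {"n": n, "slope": slope_name, "n_individuals": len(sel)}
            for cls in EXP2_LABELS:
                row[f"p_{cls}"] = (
                    sum(lab == cls for lab in sel) / len(sel) if sel else np.nan
                )
            rows.append(row)
    return pd.DataFrame(rows)


def variability_by_history(
    series_list,
    two_back: bool = False,
    min_count: int = 2,
) -> dict:
    """SD of the trial-to-trial change Δθ = θ_{n+1} − θ_n by reinforcement history.

    Pools trial pairs across the given series.  Bins: ``after_success`` and
    ``after_failure`` (experimental pairs keyed by the reward on trial n),
    ``baseline`` (pairs within session trials 25-50) and ``washout`` (pairs
    within the washout block).  With ``two_back=True``, additional bins key on
    (r_{n−1}, r_n), e.g. ``after_01``.  Bins with fewer than ``min_count``
    observations map to NaN.
    """
    if isinstance(series_list, TrialSeries):
        series_list = [series_list]
    bins: dict[str, list] = {
        "after_success": [], "after_failure": [], "baseline": [], "washout": [],
    }
    if two_back:
        for h in ("00", "01", "10", "11"):
            bins[f"after_{h}"] = []

    for s in series_list:
        sched = s.schedule or TrialSchedule(
            n_baseline=int(np.sum(s.phase == "baseline")),
            n_experimental=int(np.sum(s.phase == "experimental")),
            n_washout=int(np.sum(s.phase == "washout")),
        )
        th, r = s.theta, s.reward
        dth = np.diff(th)

        exp_lo = sched.n_baseline
        exp_hi = sched.n_baseline + sched.n_experimental
        # Pair n -> n+1 is "experimental" when trial n has feedback and the
        # pair stays within the feedback block.
        for n in range(exp_lo, exp_hi - 1):
            key = "after_success" if r[n] == 1 else "after_failure"
            bins[key].append(dth[n])
            if two_back and n - 1 >= exp_lo:
                h = f"{int(r[n - 1])}{int(r[n])}"
                bins[f"after_{h}"].append(dth[n])
        # Late-baseline pairs (session trials 25-50, 1-based).
        lo = min(24, max(exp_lo - 1, 0))
        for n in range(lo, exp_lo - 1):
            bins["baseline"].append(dth[n])
        for n in range(exp_hi, sched.total - 1):
            bins["washout"].append(dth[n])

    out = {}
    for key, vals in bins.items():
        out[key] = float(np.std(vals, ddof=1)) if len(vals) >= min_count else float("nan")
    return out


def contingency_test(table) -> float:
    """Two-tailed exact probability for a 2x2 frequency table.

    Sums the hypergeometric probabilities of all tables with the observed
    margins that are no more likely than the observed one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table must contain nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has an empty margin")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])
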