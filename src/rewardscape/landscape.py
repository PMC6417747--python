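"""Reinforcement landscapes: reward probability as a function of reach angle.

A landscape maps normalized reach angle (z-score units, relative to each
participant's baseline mean and SD) to the probability of binary reward.
All landscapes used in the reaching experiments are piecewise linear with a
bounded support; outside the listed segments the reward probability is 0.

Experiment 1 landscapes rise in one direction (clockwise or counterclockwise)
toward a plateau of maximal success rate ``m`` located 3-6 z-scores from
baseline.  Experiment 2 landscapes place baseline behaviour in a 'valley'
between a steep slope rising one way and a shallow slope rising the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "Segment",
    "Landscape",
    "BaselineStats",
    "make_exp1_landscape",
    "make_exp2_landscape",
    "reward_probability",
    "sample_reward",
    "to_zscore",
    "from_zscore",
    "pool_sign_flip",
    "M_STEEP",
    "M_SHALLOW",
]

#: Maximal success rates of the steep and shallow gradients.
M_STEEP = 1.0
M_SHALLOW = 2.0 / 3.0

_CCW_LABELS = frozenset({"CCW", "steepCCW"})


@dataclass(frozen=True)
class Segment:
    """One affine piece ``p(theta) = slope * theta + intercept`` on an interval.

    ``include_lo`` / ``include_hi`` record which endpoints belong to the
    segment, matching the half-open conventions of the landscape definitions.
    Where the function is continuous the choice is observationally irrelevant.
    """

    lo: float
    hi: float
    slope: float
    intercept: float
    include_lo: bool = True
    include_hi: bool = True

    def contains(self, theta: np.ndarray) -> np.ndarray:
        lo_ok = theta >= self.lo if self.include_lo else theta > self.lo
        hi_ok = theta <= self.hi if self.include_hi else theta < self.hi
        return lo_ok & hi_ok

    def value(self, theta: np.ndarray) -> np.ndarray:
        return self.slope * theta + self.intercept


@dataclass(frozen=True)
class Landscape:
    """Piecewise-linear reward-probability landscape on the z-score axis.

    Only segments with (potentially) nonzero probability are stored; the
    probability is 0 everywhere else.  ``direction_label`` is one of
    ``CW``/``CCW`` (Experiment 1) or ``steepCW``/``steepCCW`` (Experiment 2)
    and drives the sign-flip pooling convention.
    """

    segments: tuple[Segment, ...]
    direction_label: str
    max_rate: float
    name: str = field(default="custom")

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_rate <= 1.0:
            raise ValueError(f"max_rate must lie in [0, 1], got {self.max_rate}")

    # -- evaluation ---------------------------------------------------------
    def probability(self, theta) -> np.ndarray | float:
        """Reward probability at reach angle ``theta`` (z-score), vectorized."""
        th = np.asarray(theta, dtype=float)
        if not np.all(np.isfinite(th)):
            raise ValueError("theta must be finite")
        out = np.zeros_like(th)
        for seg in self.segments:
            mask = seg.contains(th)
            out = np.where(mask, seg.value(th), out)
        out = np.clip(out, 0.0, 1.0)
        return float(out) if np.isscalar(theta) else out

    def sample(self, theta, rng: np.random.Generator) -> np.ndarray | int:
        """Bernoulli reward draw(s) with success probability ``probability``."""
        p = self.probability(theta)
        draw = rng.random(np.shape(theta)) < p
        return int(draw) if np.isscalar(theta) else draw.astype(np.int8)

    # -- geometry -----------------------------------------------------------
    @property
    def breakpoints(self) -> np.ndarray:
        """Sorted endpoints of the nonzero region."""
        pts = sorted({seg.lo for seg in self.segments} | {seg.hi for seg in self.segments})
        return np.asarray(pts)

    @property
    def support(self) -> tuple[float, float]:
        bp = self.breakpoints
        return float(bp[0]), float(bp[-1])

    def mirror(self) -> "Landscape":
        """Reflection about θ = 0: ``mirror(L)(θ) = L(−θ)`` exactly."""
        flipped = tuple(
            Segment(
                lo=-s.hi,
                hi=-s.lo,
                slope=-s.slope,
                intercept=s.intercept,
                include_lo=s.include_hi,
                include_hi=s.include_lo,
            )
            for s in reversed(self.segments)
        )
        label = _mirror_label(self.direction_label)
        return Landscape(flipped, label, self.max_rate, name=f"mirror({self.name})")

    # -- serialization ------------------------------------------------------
    def to_config(self) -> dict:
        return {
            "name": self.name,
            "direction_label": self.direction_label,
            "max_rate": self.max_rate,
            "segments": [
                {
                    "lo": s.lo,
                    "hi": s.hi,
                    "slope": s.slope,
                    "intercept": s.intercept,
                    "include_lo": s.include_lo,
                    "include_hi": s.include_hi,
                }
                for s in self.segments
            ],
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "Landscape":
        segs = tuple(Segment(**s) for s in cfg["segments"])
        return cls(segs, cfg["direction_label"], cfg["max_rate"], name=cfg.get("name", "custom"))


def _mirror_label(label: str) -> str:
    table = {"CW": "CCW", "CCW": "CW", "steepCW": "steepCCW", "steepCCW": "steepCW"}
    return table.get(label, label)


# ---------------------------------------------------------------------------
# Constructors for the experimentally imposed landscapes
# ---------------------------------------------------------------------------

def make_exp1_landscape(gradient: str, direction: str) -> Landscape:
    """Experiment 1 landscape: one slope rising toward a 3-6 z-score plateau.

    Parameters
    ----------
    gradient : {"steep", "shallow"}
        Steep has maximal success rate m = 1.0 (slope 2/9 per z-score, 22.2%);
        shallow has m = 2/3 (slope 1/9 per z-score, 11.1%).  Both pass through
        probability 1/3 at θ = 0 (average baseline reach angle).
    direction : {"CW", "CCW"}
        Direction in which reward probability rises.  The counterclockwise
        landscape is the exact mirror of the clockwise one about θ = 0.
    """
    rates = {"steep": M_STEEP, "shallow": M_SHALLOW}
    if gradient not in rates:
        raise ValueError(f"unknown gradient {gradient!r}; expected 'steep' or 'shallow'")
    if direction not in ("CW", "CCW"):
        raise ValueError(f"unknown direction {direction!r}; expected 'CW' or 'CCW'")

    m = rates[gradient]
    slope = m / 3.0 - 1.0 / 9.0
    # Lower support bound: where the rising line crosses zero probability,
    # -3/(3m - 1).  Steep: -1.5; shallow: -3.0.
    x0 = -3.0 / (3.0 * m - 1.0)
    cw = Landscape(
        segments=(
            Segment(x0, 3.0, slope, 1.0 / 3.0),
            Segment(3.0, 6.0, 0.0, m, include_lo=False),
        ),
        direction_label="CW",
        max_rate=m,
        name=f"exp1_{gradient}_CW",
    )
    if direction == "CW":
        return cw
    ccw = cw.mirror()
    return Landscape(ccw.segments, "CCW", m, name=f"exp1_{gradient}_CCW")


def make_exp2_landscape(steep_direction: str) -> Landscape:
    """Experiment 2 'valley' landscape: steep and shallow slopes rising in
    opposite directions from a minimum of 1/3 at θ = 0.

    With the steep slope clockwise: probability is 2/3 on [−6, −3) (shallow
    plateau), falls as −θ/9 + 1/3 on [−3, 0), rises as 2θ/9 + 1/3 on [0, 3],
    plateaus at 1 on (3, 6], and is 0 elsewhere.  The steep-counterclockwise
    landscape is the mirror image about θ = 0.
    """
    if steep_direction not in ("CW", "CCW"):
        raise ValueError(
            f"unknown steep_direction {steep_direction!r}; expected 'CW' or 'CCW'"
        )
    st_cw = Landscape(
        segments=(
            Segment(-6.0, -3.0, 0.0, M_SHALLOW, include_hi=False),
            Segment(-3.0, 0.0, -1.0 / 9.0, 1.0 / 3.0, include_hi=False),
            Segment(0.0, 3.0, 2.0 / 9.0, 1.0 / 3.0),
            Segment(3.0, 6.0, 0.0, 1.0, include_lo=False),
        ),
        direction_label="steepCW",
        max_rate=1.0,
        name="exp2_steepCW",
    )
    if steep_direction == "CW":
        return st_cw
    mirrored = st_cw.mirror()
    return Landscape(mirrored.segments, "steepCCW", 1.0, name="exp2_steepCCW")


# ---------------------------------------------------------------------------
# Functional conveniences
# ---------------------------------------------------------------------------

def reward_probability(landscape: Landscape, theta) -> np.ndarray | float:
    """Probability of reward at reach angle ``theta`` (z-score)."""
    return landscape.probability(theta)


def sample_reward(landscape: Landscape, theta, rng: np.random.Generator):
    """Binary reward draw(s) at ``theta`` from a seeded generator."""
    return landscape.sample(theta, rng)


# ---------------------------------------------------------------------------
# Baseline normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BaselineStats:
    """Baseline reach statistics used to express angles as z-scores.

    The mean and SD come from a participant's late-baseline reaches; a reach
    at ``mean_angle`` is z = 0 and one SD clockwise of it is z = +1.
    """

    mean_angle: float
    sd_angle: float
    n_trials: int = 25

    def __post_init__(self) -> None:
        if self.sd_angle <= 0:
            raise ValueError("sd_angle must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


def to_zscore(angle, baseline: BaselineStats):
    """Convert native reach angle (degrees) to baseline-normalized z-score."""
    return (np.asarray(angle, dtype=float) - baseline.mean_angle) / baseline.sd_angle


def from_zscore(z, baseline: BaselineStats):
    """Inverse of :func:`to_zscore`."""
    return np.asarray(z, dtype=float) * baseline.sd_angle + baseline.mean_angle


def pool_sign_flip(series, landscape_direction: str):
    """Pool across landscape directions by negating counterclockwise angles.

    Angles of participants who experienced a landscape rising counterclockwise
    (Experiment 1 ``CCW``) or the steep-counterclockwise Experiment 2 variant
    are multiplied by −1 so that 'toward the (steep) slope' is positive for
    everyone.  Rewards and phases are unchanged.  Accepts a TrialSeries (from
    :mod:`rewardscape.model`) or a plain array of angles.
    """
    flip = landscape_direction in _CCW_LABELS
    if hasattr(series, "theta") and hasattr(series, "replace_theta"):
        return series.replace_theta(-series.theta) if flip else series
    arr = np.asarray(series, dtype=float)
    return -arr if flip else arr
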