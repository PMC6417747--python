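"""Trial-series serialization, run configuration, and fixture generation.

The on-disk format is a delimited text table with header columns
``participant, trial, phase, theta, reward`` (tab-separated by default);
no-feedback trials carry an explicit ``NA`` reward token, preserving the
three-way outcome semantics.  A cohort fixture is such a table plus a JSON
sidecar recording the parameters, landscape, seed and software version.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .landscape import Landscape, make_exp1_landscape, make_exp2_landscape
from .model import ModelParams, TrialSchedule, TrialSeries, simulate_cohort

__all__ = [
    "RunConfig",
    "read_trials",
    "write_trials",
    "generate_fixture",
    "resolve_landscape",
]

NA_TOKEN = "NA"
COLUMNS = ["participant", "trial", "phase", "theta", "reward"]
VALID_PHASES = {"baseline", "experimental", "washout"}


def write_trials(series_list, path, sep: str = "\t") -> None:
    """Write a collection of trial series as one delimited text table."""
    if isinstance(series_list, TrialSeries):
        series_list = [series_list]
    frames = [s.to_frame() for s in series_list]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=COLUMNS)
    out = df.copy()
    out["reward"] = [
        NA_TOKEN if np.isnan(r) else str(int(r)) for r in df["reward"]
    ] if len(df) else []
    out.to_csv(path, sep=sep, index=False, float_format="%.10g")


def read_trials(path, sep: str = "\t") -> list[TrialSeries]:
    """Read a trial table back into per-participant series.

    Malformed rows (unknown phase, non-binary reward) raise with the
    offending line number; an empty table returns an empty list with a
    warning.
    """
    import warnings

    try:
        df = pd.read_csv(path, sep=sep, dtype={"participant": str, "phase": str},
                         keep_default_na=False, na_values=[NA_TOKEN])
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty trial table", stacklevel=2)
        return []
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df.empty:
        warnings.warn(f"{path}: empty trial table", stacklevel=2)
        return []

    bad_phase = ~df["phase"].isin(VALID_PHASES)
    if bad_phase.any():
        row = int(np.flatnonzero(bad_phase.to_numpy())[0])
        raise ValueError(
            f"{path}, line {row + 2}: unknown phase {df['phase'].iloc[row]!r}"
        )
    reward = pd.to_numeric(df["reward"], errors="coerce")
    bad_reward = (~reward.isin([0.0, 1.0])) & df["reward"].notna()
    if bad_reward.any():
        row = int(np.flatnonzero(bad_reward.to_numpy())[0])
        raise ValueError(
            f"{path}, line {row + 2}: reward must be 0, 1 or {NA_TOKEN}"
        )

    out = []
    for pid, g in df.groupby("participant", sort=False):
        g = g.sort_values("trial")
        out.append(
            TrialSeries(
                participant=str(pid),
                phase=g["phase"].to_numpy(),
                theta=g["theta"].to_numpy(dtype=float),
                reward=pd.to_numeric(g["reward"], errors="coerce").to_numpy(dtype=float),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_LANDSCAPE_NAMES = {
    "exp1_steep_CW": lambda: make_exp1_landscape("steep", "CW"),
    "exp1_steep_CCW": lambda: make_exp1_landscape("steep", "CCW"),
    "exp1_shallow_CW": lambda: make_exp1_landscape("shallow", "CW"),
    "exp1_shallow_CCW": lambda: make_exp1_landscape("shallow", "CCW"),
    "exp2_steepCW": lambda: make_exp2_landscape("CW"),
    "exp2_steepCCW": lambda: make_exp2_landscape("CCW"),
}


def resolve_landscape(name: str) -> Landscape:
    """Landscape from its canonical name (e.g. ``exp1_steep_CW``)."""
    try:
        return _LANDSCAPE_NAMES[name]()
    except KeyError:
        raise ValueError(
            f"unknown landscape {name!r}; known: {sorted(_LANDSCAPE_NAMES)}"
        ) from None


@dataclass
class RunConfig:
    """Flat configuration of one simulation run.

    Unknown keys in a config mapping are errors (fail-fast), so typos do not
    silently fall back to defaults.
    """

    landscape: str = "exp1_steep_CW"
    alpha: float = 0.40
    sigma_m: float = 0.81
    sigma_e: float = 0.90
    n_baseline: int = 50
    n_experimental: int = 350
    n_washout: int = 50
    n_individuals: int = 40
    seed: int = 0

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    @property
    def params(self) -> ModelParams:
        return ModelParams(self.alpha, self.sigma_m, self.sigma_e)

    @property
    def schedule(self) -> TrialSchedule:
        return TrialSchedule(self.n_baseline, self.n_experimental, self.n_washout)


def generate_fixture(config: RunConfig, out_dir) -> tuple[Path, Path]:
    """Write a synthetic cohort fixture (trials table + JSON metadata sidecar).

    Deterministic under the config's seed: the same config writes
    byte-identical files.  Returns (trials_path, sidecar_path).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    L = resolve_landscape(config.landscape)
    res = simulate_cohort(
        config.params, L, config.schedule,
        n_individuals=config.n_individuals, seed=config.seed,
    )
    trials_path = out_dir / "trials.tsv"
    write_trials(res.series, trials_path)
    sidecar = {
        "config": asdict(config),
        "landscape": L.to_config(),
        "software_version": __version__,
    }
    sidecar_path = out_dir / "meta.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return trials_path, sidecar_path
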