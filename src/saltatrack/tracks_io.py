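"""Trajectory tables, run configuration and provenance.

The universal input record is a :class:`Track`: one cell's time-stamped 2-D
positions (μm) with a group label, as exported by any tracking tool into a
plain CSV with columns ``cell_id,frame,t_min,x_um,y_um,group`` (``t_min``
optional — it is reconstructed from ``frame`` and the frame interval).
All internal units are μm and minutes; conversions happen only at I/O
boundaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "Track",
    "RunConfig",
    "TrackFormatError",
    "ValidationError",
    "ConfigError",
    "read_tracks",
    "write_tracks",
    "load_config",
    "write_provenance",
]


class TrackFormatError(ValueError):
    """The input table is structurally malformed (e.g. a missing column)."""


class ValidationError(ValueError):
    """The input values violate an invariant (duplicates, bad bounds...)."""


class ConfigError(ValueError):
    """The configuration file contains unknown or ill-typed keys."""


@dataclass(frozen=True)
class Track:
    """One cell's trajectory: strictly increasing times (min), 2-D positions (μm)."""

    cell_id: str
    group: str
    times: np.ndarray        # (n,) minutes, strictly increasing
    positions: np.ndarray    # (n, 2) μm

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        positions = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "positions", positions)
        if times.ndim != 1 or positions.ndim != 2 or positions.shape[1] != 2:
            raise ValidationError(
                f"track {self.cell_id!r}: times must be 1-D and positions (n, 2)"
            )
        if len(times) != len(positions):
            raise ValidationError(
                f"track {self.cell_id!r}: {len(times)} times vs {len(positions)} positions"
            )
        if len(times) < 2:
            raise ValidationError(f"track {self.cell_id!r}: needs at least 2 points")
        if not np.all(np.diff(times) > 0):
            raise ValidationError(f"track {self.cell_id!r}: times not strictly increasing")
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(positions))):
            raise ValidationError(f"track {self.cell_id!r}: non-finite coordinates")

    def __len__(self) -> int:
        return len(self.times)


# The defaults below are the fixed constants of the study design: 5-min
# frames, 5 μm nucleokinesis threshold, 100 surrogates x 20 realizations
# simulated for 10 h, 10 displacement thresholds, 75% frontier, 10,000
# permutations swept over 19 percentage levels.
@dataclass
class RunConfig:
    frame_interval_min: float = 5.0
    nk_threshold_um: float = 5.0
    pause_eps_um: float = 0.5
    n_surrogates: int = 100
    n_realizations: int = 20
    sim_duration_min: float = 600.0
    n_thresholds: int = 10
    frontier_q: float = 0.75
    n_perm: int = 10_000
    perm_levels: int = 19
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_surrogates", "n_realizations", "n_thresholds", "n_perm",
                     "perm_levels"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool) or v < 1:
                raise ValidationError(f"{name} must be a count >= 1, got {v!r}")
        for name in ("frame_interval_min", "nk_threshold_um", "sim_duration_min"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if not 0 < self.frontier_q < 1:
            raise ValidationError(f"frontier_q must lie in (0, 1), got {self.frontier_q}")
        if not 0 <= self.pause_eps_um < self.nk_threshold_um:
            raise ValidationError(
                "pause_eps_um must satisfy 0 <= pause_eps_um < nk_threshold_um"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_REQUIRED_COLUMNS = ("cell_id", "x_um", "y_um", "group")


def read_tracks(path: str | Path, frame_interval_min: float = 5.0) -> list[Track]:
    """Read a tracks CSV into one :class:`Track` per cell.

    Requires columns ``cell_id, x_um, y_um, group`` and either ``t_min`` or
    ``frame`` (times then become ``frame * frame_interval_min``). Rows are
    sorted by time within each cell; cells with fewer than 2 rows are dropped
    with a warning; a ``z`` column, if present, is ignored with a warning
    (analysis is planar).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise TrackFormatError(f"missing required column {col!r} in {path}")
    if "t_min" not in df.columns and "frame" not in df.columns:
        raise TrackFormatError(f"need a 't_min' or 'frame' column in {path}")
    for zcol in ("z", "z_um"):
        if zcol in df.columns:
            logger.warning("ignoring %r column in %s: analysis is planar (x, y)", zcol, path)
    if "t_min" in df.columns and df["t_min"].notna().all():
        df = df.assign(_t=df["t_min"].astype(float))
    else:
        df = df.assign(_t=df["frame"].astype(float) * float(frame_interval_min))
    if df.duplicated(subset=["cell_id", "_t"]).any():
        dup = df[df.duplicated(subset=["cell_id", "_t"])].iloc[0]
        raise ValidationError(
            f"duplicated (cell_id, time) row: cell {dup['cell_id']!r} at t={dup['_t']} min"
        )

    tracks: list[Track] = []
    for cell_id, sub in df.groupby("cell_id", sort=True):
        if len(sub) < 2:
            logger.warning("dropping cell %r: fewer than 2 rows", cell_id)
            continue
        sub = sub.sort_values("_t")
        groups = sub["group"].unique()
        if len(groups) > 1:
            raise ValidationError(f"cell {cell_id!r} carries multiple group labels: {groups}")
        tracks.append(
            Track(
                cell_id=str(cell_id),
                group=str(groups[0]),
                times=sub["_t"].to_numpy(dtype=float),
                positions=sub[["x_um", "y_um"]].to_numpy(dtype=float),
            )
        )
    return tracks


def write_tracks(tracks: Iterable[Track], path: str | Path,
                 frame_interval_min: float = 5.0) -> None:
    """Write tracks to the canonical CSV layout (full float precision)."""
    rows = []
    for tr in tracks:
        frames = np.round(tr.times / frame_interval_min).astype(int)
        for f, t, (x, y) in zip(frames, tr.times, tr.positions):
            rows.append((tr.cell_id, f, t, x, y, tr.group))
    df = pd.DataFrame(rows, columns=["cell_id", "frame", "t_min", "x_um", "y_um", "group"])
    df.to_csv(path, index=False, float_format="%.12g")


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a flat YAML config; omitted keys take the study-design defaults.

    Unknown keys are rejected so a typo cannot silently fall back to a
    default. Keyword overrides are applied after the file.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config {path} must be a flat mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def write_provenance(path: str | Path, *, seed: int, config: RunConfig,
                     inputs: Sequence[str] = (), extra: dict | None = None) -> None:
    """Write the JSON sidecar that makes every stochastic output replayable."""
    from saltatrack import __version__

    payload = {
        "package": "saltatrack",
        "version": __version__,
        "seed": int(seed),
        "config": config.to_dict(),
        "inputs": list(inputs),
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
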