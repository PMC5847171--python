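"""Per-cell kinematic features of saltatory migration.

Saltatory (two-stroke) neuronal migration alternates nuclear pauses with
discrete forward jumps of the nucleus (nucleokinesis). Operationally, on a
trajectory sampled every ``dt`` minutes:

* the per-interval displacement is the Euclidean distance between
  consecutive positions;
* an interval is a **pause** when that displacement is at most
  ``pause_eps_um`` (a small tolerance standing in for "no displacement"
  under tracking noise);
* it is a **nucleokinesis step** when the displacement exceeds
  ``nk_threshold_um`` (5 μm by default);
* anything in between is **sliding** — continuous sub-threshold movement.

A nucleokinesis *event* is a maximal run of consecutive supra-threshold
intervals; its amplitude is the summed displacement of the run (a jump can
span more than one frame at 5-min sampling). Per-cell features (average
speed, pausing-time fraction, event amplitudes and frequency, instantaneous
speeds, directionality) feed group-level empirical distributions
(:class:`GroupModel`) which in turn drive the surrogate simulator.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .tracks_io import RunConfig, Track, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "IntervalSeries",
    "NkEvent",
    "KinematicProfile",
    "GroupModel",
    "interval_series",
    "detect_nucleokinesis",
    "average_speed",
    "pausing_stats",
    "instantaneous_speeds",
    "directionality",
    "compute_profile",
    "build_group_model",
]

PAUSE, SLIDE, NK_STEP = 0, 1, 2
_LABEL_NAMES = {PAUSE: "pause", SLIDE: "slide", NK_STEP: "nk_step"}


@dataclass(frozen=True)
class IntervalSeries:
    """Per consecutive-frame-pair displacement series with phase labels."""

    t_start: np.ndarray      # (m,) minutes, interval start times
    dt: np.ndarray           # (m,) minutes
    displacement: np.ndarray  # (m,) μm, >= 0
    labels: np.ndarray       # (m,) int codes PAUSE/SLIDE/NK_STEP

    @property
    def total_time(self) -> float:
        return float(self.dt.sum())

    def label_names(self) -> list[str]:
        return [_LABEL_NAMES[int(c)] for c in self.labels]


@dataclass(frozen=True)
class NkEvent:
    """One nucleokinesis event: a maximal run of supra-threshold intervals."""

    t_start: float   # min
    t_end: float     # min
    amplitude: float  # μm, summed displacement of the run
    n_intervals: int


@dataclass
class KinematicProfile:
    cell_id: str
    group: str
    average_speed: float                 # μm/min, path length / elapsed time
    pausing_time_fraction: float         # in [0, 1]
    nk_events: list[NkEvent]
    nk_frequency: float                  # events / hr
    mean_nk_amplitude: float             # μm (nan if no events)
    instantaneous_speeds: np.ndarray     # μm/min over non-pause intervals
    pause_durations: np.ndarray          # min, maximal pause-run lengths
    directionality: float                # net / path, in [0, 1]


def interval_series(track: Track, cfg: RunConfig) -> IntervalSeries:
    """Label each frame-to-frame displacement as pause / slide / nk_step."""
    dt = np.diff(track.times)
    if np.any(dt <= 0):
        raise ValidationError(f"track {track.cell_id!r}: non-positive frame interval")
    if not np.allclose(dt, dt[0]):
        logger.info("track %r: non-uniform frame intervals", track.cell_id)
    disp = np.linalg.norm(np.diff(track.positions, axis=0), axis=1)
    labels = np.full(disp.shape, SLIDE, dtype=np.int8)
    labels[disp <= cfg.pause_eps_um] = PAUSE
    labels[disp > cfg.nk_threshold_um] = NK_STEP
    return IntervalSeries(
        t_start=track.times[:-1], dt=dt, displacement=disp, labels=labels
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean array, as [start, stop) index pairs."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def detect_nucleokinesis(series: IntervalSeries,
                         merge_runs: bool = True) -> list[NkEvent]:
    """Extract nucleokinesis events from a labelled series.

    With ``merge_runs`` (default) each maximal run of consecutive
    supra-threshold intervals forms one event whose amplitude is the summed
    displacement; with ``merge_runs=False`` every supra-threshold interval is
    its own event (sensitivity-analysis mode).
    """
    mask = series.labels == NK_STEP
    if merge_runs:
        spans = _runs(mask)
    else:
        spans = [(i, i + 1) for i in np.flatnonzero(mask)]
    events = []
    for i, j in spans:
        events.append(
            NkEvent(
                t_start=float(series.t_start[i]),
                t_end=float(series.t_start[j - 1] + series.dt[j - 1]),
                amplitude=float(series.displacement[i:j].sum()),
                n_intervals=int(j - i),
            )
        )
    return events


def average_speed(track: Track) -> float:
    """Total path length divided by elapsed time (μm/min)."""
    elapsed = track.times[-1] - track.times[0]
    if elapsed <= 0:
        raise ValidationError(f"track {track.cell_id!r}: zero elapsed time")
    path = float(np.linalg.norm(np.diff(track.positions, axis=0), axis=1).sum())
    return path / float(elapsed)


def pausing_stats(series: IntervalSeries) -> tuple[float, np.ndarray]:
    """Pausing-time fraction and the durations (min) of maximal pause runs."""
    pause_mask = series.labels == PAUSE
    durations = np.array(
        [series.dt[i:j].sum() for i, j in _runs(pause_mask)], dtype=float
    )
    fraction = float(series.dt[pause_mask].sum() / series.total_time)
    return fraction, durations


def instantaneous_speeds(series: IntervalSeries,
                         include_pauses: bool = False) -> np.ndarray:
    """Per-interval speeds (μm/min), by default over non-pause intervals only.

    The surrogate simulator samples pauses and moving speeds from separate
    distributions, so including the (near-)zero pause intervals here would
    double-count pausing; ``include_pauses=True`` gives the alternative.
    """
    if include_pauses:
        sel = slice(None)
    else:
        sel = series.labels != PAUSE
    return series.displacement[sel] / series.dt[sel]


def directionality(track: Track) -> float:
    """Net start-to-end displacement over total path length; 0/0 -> 0."""
    steps = np.linalg.norm(np.diff(track.positions, axis=0), axis=1)
    path = float(steps.sum())
    net = float(np.linalg.norm(track.positions[-1] - track.positions[0]))
    if path == 0.0:
        return 0.0
    return net / path


def compute_profile(track: Track, cfg: RunConfig) -> KinematicProfile:
    """All per-cell features in one pass."""
    series = interval_series(track, cfg)
    events = detect_nucleokinesis(series)
    fraction, pause_durations = pausing_stats(series)
    amplitudes = np.array([e.amplitude for e in events])
    return KinematicProfile(
        cell_id=track.cell_id,
        group=track.group,
        average_speed=average_speed(track),
        pausing_time_fraction=fraction,
        nk_events=events,
        nk_frequency=60.0 * len(events) / series.total_time,
        mean_nk_amplitude=float(amplitudes.mean()) if len(amplitudes) else float("nan"),
        instantaneous_speeds=instantaneous_speeds(series),
        pause_durations=pause_durations,
        directionality=directionality(track),
    )


@dataclass
class GroupModel:
    """Empirical pause-duration and moving-speed distributions of one group.

    Histograms use fixed-width, left-closed/right-open bins; masses sum to 1.
    ``pause_fraction_target`` is the population mean pausing-time fraction the
    surrogate simulator must preserve.
    """

    pause_edges: np.ndarray    # (kp+1,) min
    pause_masses: np.ndarray   # (kp,)
    speed_edges: np.ndarray    # (ks+1,) μm/min
    speed_masses: np.ndarray   # (ks,)
    pause_fraction_target: float

    def __post_init__(self) -> None:
        for name in ("pause", "speed"):
            edges = np.asarray(getattr(self, f"{name}_edges"), dtype=float)
            masses = np.asarray(getattr(self, f"{name}_masses"), dtype=float)
            setattr(self, f"{name}_edges", edges)
            setattr(self, f"{name}_masses", masses)
            if len(edges) != len(masses) + 1:
                raise ValidationError(f"{name} histogram: edges/masses length mismatch")
            if np.any(masses < 0) or not np.isclose(masses.sum(), 1.0, atol=1e-9):
                raise ValidationError(f"{name} histogram masses must sum to 1")
        if not 0 < self.pause_fraction_target < 1:
            raise ValidationError("pause_fraction_target must lie in (0, 1)")

    # -- moments ----------------------------------------------------------
    def mean_pause(self) -> float:
        """Mean pause duration (min) under uniform-within-bin density."""
        mids = 0.5 * (self.pause_edges[:-1] + self.pause_edges[1:])
        return float(np.dot(mids, self.pause_masses))

    def mean_speed(self) -> float:
        mids = 0.5 * (self.speed_edges[:-1] + self.speed_edges[1:])
        return float(np.dot(mids, self.speed_masses))

    # -- sampling ----------------------------------------------------------
    def _sample_hist(self, edges: np.ndarray, masses: np.ndarray, n: int,
                     rng: np.random.Generator) -> np.ndarray:
        idx = rng.choice(len(masses), size=n, p=masses)
        lo, hi = edges[idx], edges[idx + 1]
        return lo + (hi - lo) * rng.random(n)

    def sample_pauses(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Pause durations (min): bin by mass, uniform within the bin."""
        return self._sample_hist(self.pause_edges, self.pause_masses, n, rng)

    def sample_speeds(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Moving-phase instantaneous speeds (μm/min), i.i.d. from the histogram."""
        return self._sample_hist(self.speed_edges, self.speed_masses, n, rng)

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "pause_edges": self.pause_edges.tolist(),
            "pause_masses": self.pause_masses.tolist(),
            "speed_edges": self.speed_edges.tolist(),
            "speed_masses": self.speed_masses.tolist(),
            "pause_fraction_target": self.pause_fraction_target,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroupModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            pause_edges=np.asarray(payload["pause_edges"]),
            pause_masses=np.asarray(payload["pause_masses"]),
            speed_edges=np.asarray(payload["speed_edges"]),
            speed_masses=np.asarray(payload["speed_masses"]),
            pause_fraction_target=float(payload["pause_fraction_target"]),
        )


def _pooled_hist(values: np.ndarray, bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil((values.max() + 1e-12) / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    return edges, counts / counts.sum()


def build_group_model(profiles: Iterable[KinematicProfile],
                      bin_width_pause_min: float = 5.0,
                      bin_width_speed: float = 0.2) -> GroupModel:
    """Pool per-cell pauses and moving speeds into normalized histograms.

    Default bin widths: 5 min (one frame) for pause durations, 0.2 μm/min
    for instantaneous speeds. The pause-fraction target is the mean of the
    per-cell pausing-time fractions.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValidationError("cannot build a group model from zero profiles")
    pauses = np.concatenate([p.pause_durations for p in profiles]) if any(
        len(p.pause_durations) for p in profiles) else np.array([])
    speeds = np.concatenate([p.instantaneous_speeds for p in profiles]) if any(
        len(p.instantaneous_speeds) for p in profiles) else np.array([])
    if pauses.size == 0 or speeds.size == 0:
        raise ValidationError(
            "need at least one pause and one moving interval in the pool"
        )
    pause_edges, pause_masses = _pooled_hist(pauses, bin_width_pause_min)
    speed_edges, speed_masses = _pooled_hist(speeds, bin_width_speed)
    target = float(np.mean([p.pausing_time_fraction for p in profiles]))
    return GroupModel(
        pause_edges=pause_edges,
        pause_masses=pause_masses,
        speed_edges=speed_edges,
        speed_masses=speed_masses,
        pause_fraction_target=target,
    )
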