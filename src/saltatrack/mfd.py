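"""Microfluidic-device "race" analysis of two tracked populations.

Cells migrating in device corridors do not move along a straight line, so a
least-squares motion axis is fitted to each cell's positions (total least
squares: the principal axis of the centered position cloud, which minimizes
summed squared *perpendicular* distances). Each trajectory is decomposed
into displacements along and perpendicular to its axis; the along-axis
displacement at the end of recording is the cell's final displacement.

Population comparison uses the q-frontier (the largest displacement reached
by at least a fraction q of cells, default q = 0.75) over the common time
grid, and a permutation test on the frontier difference of the final
displacements: pooled final values are reshuffled between the two groups
(10,000 times by default) to build the null distribution of the frontier
difference, and the p value places the observed difference in that null.
The test is repeated over a sweep of percentage levels (19 levels, 5%-95%).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .surrogate import frontier_level
from .tracks_io import Track, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "MotionAxis",
    "ProjectedTrack",
    "PermResult",
    "fit_motion_axis",
    "project_track",
    "population_frontier",
    "permutation_test",
    "percentage_sweep",
]


@dataclass(frozen=True)
class MotionAxis:
    """Per-cell motion axis: origin at the first position, unit direction.

    The direction is oriented so the track's net displacement projects
    positively.
    """

    origin: np.ndarray     # (2,) μm
    direction: np.ndarray  # (2,) unit vector

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if not math.isclose(float(np.linalg.norm(d)), 1.0, abs_tol=1e-9):
            raise ValidationError("axis direction must be a unit vector")


@dataclass(frozen=True)
class ProjectedTrack:
    """Signed along/perpendicular displacements relative to a motion axis."""

    cell_id: str
    group: str
    times: np.ndarray  # (n,) min
    along: np.ndarray  # (n,) μm, 0 at the first frame when the axis is own-fitted
    perp: np.ndarray   # (n,) μm


def fit_motion_axis(track: Track, method: str = "tls") -> MotionAxis:
    """Fit the least-squares motion axis of a track.

    ``method="tls"`` (default): total least squares — the principal axis of
    the centered position cloud, minimizing summed squared perpendicular
    residuals. ``method="ols"``: ordinary y-on-x regression slope
    (sensitivity-analysis mode). A degenerate isotropic cloud falls back to
    the net-displacement direction, or +x if the net displacement is zero.
    """
    pos = track.positions
    centered = pos - pos.mean(axis=0)
    if np.allclose(centered, 0.0):
        raise ValidationError(f"track {track.cell_id!r}: all positions identical")
    net = pos[-1] - pos[0]

    if method == "tls":
        # principal axis via SVD of the centered cloud
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        if s[0] > 0 and np.isclose(s[0], s[-1], rtol=1e-12):
            logger.info("track %r: isotropic cloud, using net-displacement axis",
                        track.cell_id)
            d = net if np.linalg.norm(net) > 0 else np.array([1.0, 0.0])
        else:
            d = vt[0]
    elif method == "ols":
        x, y = centered[:, 0], centered[:, 1]
        sxx = float(np.dot(x, x))
        if sxx == 0.0:
            d = np.array([0.0, 1.0])
        else:
            d = np.array([1.0, float(np.dot(x, y)) / sxx])
    else:
        raise ValueError(f"unknown axis-fit method {method!r}")

    d = np.asarray(d, dtype=float)
    d = d / np.linalg.norm(d)
    sign = float(np.dot(net, d))
    if sign < 0:
        d = -d
    elif sign == 0.0:
        logger.info("track %r: zero net displacement, axis orientation arbitrary",
                    track.cell_id)
    return MotionAxis(origin=pos[0].copy(), direction=d)


def project_track(track: Track, axis: MotionAxis | None = None) -> ProjectedTrack:
    """Decompose a track into along/perpendicular displacements.

    With ``axis=None`` the track's own total-least-squares axis is fitted
    first. Along and perpendicular components reconstruct the positions
    exactly: ``p_t = origin + along_t * d + perp_t * d_perp``.
    """
    if axis is None:
        axis = fit_motion_axis(track)
    d = axis.direction
    d_perp = np.array([-d[1], d[0]])
    rel = track.positions - axis.origin
    return ProjectedTrack(
        cell_id=track.cell_id,
        group=track.group,
        times=track.times.copy(),
        along=rel @ d,
        perp=rel @ d_perp,
    )


def population_frontier(
    projected_by_group: Mapping[str, Sequence[ProjectedTrack]],
    q: float = 0.75,
    time_grid: np.ndarray | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Per-time q-frontier of along-axis displacements for each group.

    The default time grid is the frame set of the longest tracks; shorter
    tracks (cells leaving the field early) are excluded with a log message.
    Returns ``(time_grid, {group: frontier_series})``.
    """
    if not 0 < q < 1:
        raise ValidationError("q must lie in (0, 1)")
    all_tracks = [p for group in projected_by_group.values() for p in group]
    if not all_tracks:
        raise ValidationError("no projected tracks supplied")
    if time_grid is None:
        t_end = max(p.times[-1] for p in all_tracks)
        ref = next(p for p in all_tracks if p.times[-1] == t_end)
        time_grid = ref.times
    time_grid = np.asarray(time_grid, dtype=float)

    frontiers: dict[str, np.ndarray] = {}
    for label, projections in projected_by_group.items():
        rows = []
        for p in projections:
            idx = np.searchsorted(p.times, time_grid)
            in_range = np.all(idx < len(p.times))
            if not (in_range and np.allclose(
                    p.times[np.minimum(idx, len(p.times) - 1)], time_grid)):
                logger.info("excluding cell %r: does not cover the time grid",
                            p.cell_id)
                continue
            rows.append(p.along[idx])
        if not rows:
            raise ValidationError(f"group {label!r}: no track covers the time grid")
        mat = np.vstack(rows)  # (cells, times)
        n = mat.shape[0]
        k = math.ceil(q * n)
        if k < 1 or k > n:
            raise ValidationError(
                f"group {label!r}: frontier level q={q} infeasible for n={n}")
        frontiers[label] = np.sort(mat, axis=0)[n - k, :]
    return time_grid, frontiers


@dataclass(frozen=True)
class PermResult:
    """Permutation test on the q-frontier difference of final displacements."""

    q: float
    observed: float        # frontier(B) - frontier(A), μm
    null: np.ndarray       # (n_perm,) surrogate differences
    p_value: float
    n_a: int
    n_b: int
    alternative: str


def permutation_test(
    final_a: np.ndarray,
    final_b: np.ndarray,
    q: float = 0.75,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
    alternative: str = "greater",
) -> PermResult:
    """Permutation test: is group B's q-frontier higher than group A's?

    Pooled final displacements are reshuffled ``n_perm`` times; each shuffle
    reassigns ``n_a`` values to A and ``n_b`` to B and records the frontier
    difference B - A. The p value uses the add-one correction
    ``(#{null >= observed} + 1) / (n_perm + 1)`` (one-sided toward B > A;
    ``alternative="two-sided"`` compares absolute values,
    ``alternative="less"`` the lower tail).
    """
    final_a = np.asarray(final_a, dtype=float).ravel()
    final_b = np.asarray(final_b, dtype=float).ravel()
    n_a, n_b = len(final_a), len(final_b)
    if n_a < 1 or n_b < 1:
        raise ValidationError("both groups need at least one cell")
    if not 0 < q < 1:
        raise ValidationError("q must lie in (0, 1)")
    if math.ceil(q * min(n_a, n_b)) < 1:
        raise ValidationError("q too small for the group sizes")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng()

    observed = frontier_level(final_b, q) - frontier_level(final_a, q)

    pooled = np.concatenate([final_a, final_b])
    n = n_a + n_b
    k_a, k_b = math.ceil(q * n_a), math.ceil(q * n_b)
    perms = rng.permuted(np.broadcast_to(pooled, (n_perm, n)).copy(), axis=1)
    a_star, b_star = perms[:, :n_a], perms[:, n_a:]
    fa = np.partition(a_star, n_a - k_a, axis=1)[:, n_a - k_a]
    fb = np.partition(b_star, n_b - k_b, axis=1)[:, n_b - k_b]
    null = fb - fa

    if alternative == "greater":
        hits = np.sum(null >= observed)
    elif alternative == "less":
        hits = np.sum(null <= observed)
    elif alternative == "two-sided":
        hits = np.sum(np.abs(null) >= abs(observed))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (int(hits) + 1) / (n_perm + 1)
    return PermResult(q=q, observed=float(observed), null=null, p_value=float(p),
                      n_a=n_a, n_b=n_b, alternative=alternative)


def percentage_sweep(
    final_a: np.ndarray,
    final_b: np.ndarray,
    levels: int = 19,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
    alternative: str = "greater",
) -> list[PermResult]:
    """Repeat the permutation test over a sweep of percentage levels.

    The grid is the ``levels`` equally spaced interior percentages
    ``i / (levels + 1)``: 19 levels give 5%, 10%, ..., 95%; a single level
    gives the median frontier (50%).
    """
    if levels < 1:
        raise ValidationError("levels must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    n_min = min(len(np.ravel(final_a)), len(np.ravel(final_b)))
    results = []
    for i in range(1, levels + 1):
        q = i / (levels + 1)
        if math.ceil(q * n_min) < 1 or math.ceil(q * n_min) > n_min:
            logger.info("skipping level q=%.3f: infeasible for n=%d", q, n_min)
            continue
        results.append(
            permutation_test(final_a, final_b, q=q, n_perm=n_perm, rng=rng,
                             alternative=alternative)
        )
    return results
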