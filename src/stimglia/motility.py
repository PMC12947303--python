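"""Microglial process motility, directionality indices and angular polarity.

Three families of per-cell measures:

* motility — counts and speeds of extension/retraction events, optionally
  summed over consecutive 5 min overlay windows;
* D-/T-indices — static orientation of a cell's processes relative to the
  electrode: D from counts of processes on the away vs toward side,
  T from the longest process length on each side, both offset into [0, 2]
  (0 = fully toward the target, 1 = balanced, 2 = fully away);
* polarity index ρ — the kernel-smoothed angular distribution of a cell's
  movement angles is integrated on either side of 90°, and
  ρ = (AUC_toward − AUC_away)/(AUC_toward + AUC_away) ∈ [−1, 1].

The angular density uses an Epanechnikov kernel K(u) = 0.75(1 − u²) on
|u| ≤ 1 with boundary reflection at 0° and 180°, so the density lives on the
compact support of physically possible angles and integrates to one.
Cells with fewer than four measurable movements are excluded from polarity
and directionality analysis (too few events to estimate a distribution).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .geometry import (
    DegenerateGeometryError,
    Point,
    movement_angle,
)

__all__ = [
    "ProcessMovement",
    "MovementKind",
    "MicrogliaSnapshot",
    "ProcessSide",
    "DTIndices",
    "PolarityResult",
    "MotilitySummary",
    "MIN_MOVEMENTS_FOR_POLARITY",
    "DEFAULT_MOVEMENT_INTERVAL_MIN",
    "movement_speed",
    "motility_counts",
    "cumulative_motility",
    "classify_process_side",
    "d_index",
    "t_index",
    "epanechnikov_density",
    "silverman_bandwidth",
    "polarity_index",
]

#: Two imaging frames at 2.16 min each: the overlay spacing used to call
#: a movement event.
DEFAULT_MOVEMENT_INTERVAL_MIN = 4.32

#: Cells with fewer measurable movements are excluded from polarity analysis.
MIN_MOVEMENTS_FOR_POLARITY = 4


class MovementKind(enum.Enum):
    EXTENSION = "extension"
    RETRACTION = "retraction"


@dataclass(frozen=True)
class ProcessMovement:
    """One extension or retraction of a process tip between two frames."""

    microglia_id: str
    t_min: float
    tip_start: Point
    tip_end: Point
    soma: Point
    kind: MovementKind
    interval_min: float = DEFAULT_MOVEMENT_INTERVAL_MIN

    def __post_init__(self) -> None:
        if self.interval_min <= 0:
            raise ValueError("interval must be positive")
        if (self.tip_start.x, self.tip_start.y) == (self.tip_end.x, self.tip_end.y):
            raise ValueError("tip_start and tip_end coincide")


@dataclass(frozen=True)
class MicrogliaSnapshot:
    """Soma position plus process tips and lengths at one timepoint."""

    microglia_id: str
    soma: Point
    processes: tuple  # of (tip: Point, length_um: float)

    def __post_init__(self) -> None:
        for _, length in self.processes:
            if length <= 0:
                raise ValueError("process lengths must be positive")


class ProcessSide(enum.Enum):
    NEAR = "near"   # oriented toward the target (angle < 90°)
    AWAY = "away"   # oriented away (angle > 90°)
    TIE = "tie"     # exactly perpendicular; excluded from both counts


@dataclass(frozen=True)
class DTIndices:
    d_index: float | None
    t_index: float | None
    f_count: int
    n_count: int
    f_len: float
    n_len: float


@dataclass(frozen=True)
class PolarityResult:
    """Polarity index ρ = (t − a)/(t + a) of one cell's movement angles."""

    rho: float | None
    n_movements: int
    auc_toward: float | None
    auc_away: float | None
    excluded: bool


@dataclass(frozen=True)
class MotilitySummary:
    window: tuple
    n_extensions: int
    n_retractions: int
    ext_retr_ratio: float | None
    mean_speed_ext: float | None
    mean_speed_retr: float | None


def movement_speed(m: ProcessMovement) -> float:
    """Tip displacement divided by the frame interval, µm/min."""
    d = math.hypot(m.tip_end.x - m.tip_start.x, m.tip_end.y - m.tip_start.y)
    return d / m.interval_min


def motility_counts(
    events: Iterable[ProcessMovement], window: tuple | None = None
) -> MotilitySummary:
    """Counts, extension/retraction ratio and mean speeds within a window.

    ``window`` is a half-open interval [start, end) in session minutes; None
    means all events. The ratio is undefined (None) when there are no
    retractions.
    """
    ext_speeds, retr_speeds = [], []
    for ev in events:
        if window is not None and not (window[0] <= ev.t_min < window[1]):
            continue
        (ext_speeds if ev.kind is MovementKind.EXTENSION else retr_speeds).append(
            movement_speed(ev)
        )
    n_ext, n_retr = len(ext_speeds), len(retr_speeds)
    return MotilitySummary(
        window=window if window is not None else (-math.inf, math.inf),
        n_extensions=n_ext,
        n_retractions=n_retr,
        ext_retr_ratio=(n_ext / n_retr) if n_retr > 0 else None,
        mean_speed_ext=float(np.mean(ext_speeds)) if n_ext else None,
        mean_speed_retr=float(np.mean(retr_speeds)) if n_retr else None,
    )


def cumulative_motility(
    events: Iterable[ProcessMovement],
    start_min: float,
    interval_len_min: float = 5.0,
    n_intervals: int = 4,
) -> dict:
    """Per-cell cumulative counts over consecutive overlay intervals.

    Sums extensions and retractions per microglia across ``n_intervals``
    consecutive windows of ``interval_len_min`` starting at ``start_min``
    (the 5 min × 4 overlay scheme by default). Returns
    {microglia_id: (cum_extensions, cum_retractions)}.
    """
    end = start_min + interval_len_min * n_intervals
    out: dict = {}
    for ev in events:
        if not (start_min <= ev.t_min < end):
            continue
        e, r = out.get(ev.microglia_id, (0, 0))
        if ev.kind is MovementKind.EXTENSION:
            e += 1
        else:
            r += 1
        out[ev.microglia_id] = (e, r)
    return out


def classify_process_side(tip: Point, soma: Point, target: Point) -> ProcessSide:
    """Side of a process relative to the target, judged from the soma.

    Uses the angle between (tip − soma) and (target − soma): < 90° NEAR,
    > 90° AWAY, exactly 90° TIE.
    """
    ang = movement_angle(soma, tip, target)
    if ang < 90.0:
        return ProcessSide.NEAR
    if ang > 90.0:
        return ProcessSide.AWAY
    return ProcessSide.TIE


def _classify_sides(snapshot: MicrogliaSnapshot, target: Point):
    near, away = [], []
    for tip, length in snapshot.processes:
        try:
            side = classify_process_side(tip, snapshot.soma, target)
        except DegenerateGeometryError:
            continue
        if side is ProcessSide.NEAR:
            near.append(length)
        elif side is ProcessSide.AWAY:
            away.append(length)
    return near, away


def d_index(snapshot: MicrogliaSnapshot, target: Point) -> DTIndices:
    """Count-based directionality index D = (f − n)/(f + n) + 1 in [0, 2].

    f is the number of processes on the away side, n on the toward side;
    perpendicular ties count for neither. With no classifiable processes
    both indices are undefined (None).
    """
    near, away = _classify_sides(snapshot, target)
    f_count, n_count = len(away), len(near)
    f_len = max(away) if away else 0.0
    n_len = max(near) if near else 0.0
    if f_count + n_count == 0:
        return DTIndices(None, None, 0, 0, 0.0, 0.0)
    d = (f_count - n_count) / (f_count + n_count) + 1.0
    t = (f_len - n_len) / (f_len + n_len) + 1.0
    return DTIndices(d, t, f_count, n_count, f_len, n_len)


def t_index(snapshot: MicrogliaSnapshot, target: Point) -> DTIndices:
    """Length-based index T from the longest process on each side; see d_index."""
    return d_index(snapshot, target)


def silverman_bandwidth(angles_deg: Sequence[float]) -> float:
    """Rule-of-thumb bandwidth for the Epanechnikov kernel, clamped to [5°, 45°].

    h = 2.345·σ̂·n^(−1/5), the Silverman factor rescaled for the
    Epanechnikov kernel's variance and roughness; the clamp avoids
    degenerate spikes for repeated angles and over-smoothing at tiny n.
    """
    a = np.asarray(angles_deg, dtype=float)
    sd = float(a.std(ddof=1)) if a.size > 1 else 0.0
    h = 2.345 * sd * a.size ** (-0.2) if sd > 0 else 0.0
    return float(min(45.0, max(5.0, h)))


def epanechnikov_density(
    angles_deg: Sequence[float],
    bandwidth_deg: float,
    grid_step_deg: float = 0.5,
):
    """Epanechnikov KDE of movement angles on [0°, 180°] with reflection.

    Kernel mass falling outside the support is reflected back at both
    boundaries; the result is renormalized to integrate to one on the grid.
    Returns (grid, density).
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise ValueError("empty angle list")
    if bandwidth_deg <= 0:
        raise ValueError("bandwidth must be positive")
    if np.any((a < 0) | (a > 180)):
        raise ValueError("angles must lie in [0, 180] degrees")
    grid = np.arange(0.0, 180.0 + grid_step_deg / 2, grid_step_deg)
    h = bandwidth_deg
    # reflect each sample across both boundaries: a -> -a and 360 - a
    samples = np.concatenate([a, -a, 360.0 - a])
    u = (grid[:, None] - samples[None, :]) / h
    k = np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - u * u), 0.0)
    density = k.sum(axis=1) / (a.size * h)
    total = np.trapezoid(density, grid)
    if total <= 0:
        raise ValueError("degenerate density")
    return grid, density / total


def polarity_index(
    angles_deg: Sequence[float],
    bandwidth_deg: float | None = None,
    grid_step_deg: float = 0.5,
    min_movements: int = MIN_MOVEMENTS_FOR_POLARITY,
) -> PolarityResult:
    """Polarity index ρ of one cell's movement angles.

    The smoothed angular density is integrated on [0°, 90°] (toward the
    target) and [90°, 180°] (away); ρ = (t − a)/(t + a) lies in [−1, 1],
    +1 meaning all movement toward the target and −1 all movement away.
    Cells with fewer than ``min_movements`` angles are excluded (no ρ).
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size < min_movements:
        return PolarityResult(None, int(a.size), None, None, excluded=True)
    if bandwidth_deg is None:
        bandwidth_deg = silverman_bandwidth(a)
    grid, dens = epanechnikov_density(a, bandwidth_deg, grid_step_deg)
    toward_mask = grid <= 90.0
    away_mask = grid >= 90.0
    t = float(np.trapezoid(dens[toward_mask], grid[toward_mask]))
    aa = float(np.trapezoid(dens[away_mask], grid[away_mask]))
    rho = (t - aa) / (t + aa)
    return PolarityResult(rho, int(a.size), t, aa, excluded=False)
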