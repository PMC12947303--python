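"""Coordinate geometry and stimulation-session bookkeeping.

All spatial analysis happens in a 2D plane (the imaging volume is collapsed
axially upstream), with coordinates in micrometres. Times are minutes
relative to stimulation onset (t = 0), so the pre-stimulation baseline is
negative time. These conventions are shared by every downstream stage.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

__all__ = [
    "Point",
    "ElectrodeSite",
    "StimulationParadigm",
    "PhaseLabel",
    "DistanceBin",
    "ChargeInfo",
    "CHARGE_SAFETY_LIMIT_NC",
    "euclidean_distance",
    "movement_angle",
    "assign_distance_bin",
    "phase_of_time",
    "charge_per_phase",
]

#: Charge-injection safety bound per pulse phase, nC.
CHARGE_SAFETY_LIMIT_NC = 4.0

#: Distance-bin boundaries from the electrode site, µm.
NEAR_BOUNDARY_UM = 150.0
FAR_BOUNDARY_UM = 300.0


class DegenerateGeometryError(ValueError):
    """Raised when an angle is requested for coincident points."""


@dataclass(frozen=True)
class Point:
    """A location in the analysis plane, µm."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates ({self.x}, {self.y})")


@dataclass(frozen=True)
class ElectrodeSite:
    """Center of the stimulating electrode site; reference for all angles."""

    center: Point


@dataclass(frozen=True)
class StimulationParadigm:
    """Pulse-train parameters and session timeline.

    Defaults describe a 10 Hz, 10 µA, 200 µs/phase biphasic paradigm with a
    20 min baseline, 60 min of stimulation and a 20 min post period.
    """

    frequency_hz: float = 10.0
    amplitude_ua: float = 10.0
    pulse_width_us: float = 200.0
    baseline_duration_min: float = 20.0
    stim_duration_min: float = 60.0
    post_duration_min: float = 20.0

    def __post_init__(self) -> None:
        for name in (
            "frequency_hz",
            "amplitude_ua",
            "pulse_width_us",
            "baseline_duration_min",
            "stim_duration_min",
            "post_duration_min",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def session_start_min(self) -> float:
        return -self.baseline_duration_min

    @property
    def session_end_min(self) -> float:
        return self.stim_duration_min + self.post_duration_min


class PhaseLabel(enum.Enum):
    """Peri-stimulation phase: baseline, three equal stimulation thirds, post."""

    PRE = "pre"
    EARLY = "early"
    MID = "mid"
    LATE = "late"
    POST = "post"


class DistanceBin(enum.Enum):
    """Radial distance bin from the electrode site."""

    NEAR = "near"  # < 150 µm
    MID = "mid"    # 150–300 µm inclusive
    FAR = "far"    # > 300 µm


@dataclass(frozen=True)
class ChargeInfo:
    """Charge injected per pulse phase and its safety-limit status."""

    charge_nc: float
    within_safety_limit: bool


def euclidean_distance(p: Point, q: Point) -> float:
    """Planar distance between two points, µm."""
    return math.hypot(p.x - q.x, p.y - q.y)


def movement_angle(tip_start: Point, tip_end: Point, target: Point) -> float:
    """Angle of a process movement relative to a target, degrees in [0, 180].

    The movement is the displacement ``tip_end - tip_start``; the reference
    direction points from the movement's start tip to ``target``. 0° means
    the tip moved directly toward the target, 180° directly away.
    """
    dx, dy = tip_end.x - tip_start.x, tip_end.y - tip_start.y
    rx, ry = target.x - tip_start.x, target.y - tip_start.y
    dn = math.hypot(dx, dy)
    rn = math.hypot(rx, ry)
    if dn == 0.0:
        raise DegenerateGeometryError("zero-length displacement")
    if rn == 0.0:
        raise DegenerateGeometryError("target coincides with movement start")
    cosang = (dx * rx + dy * ry) / (dn * rn)
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def assign_distance_bin(d_um: float) -> DistanceBin:
    """Bin a distance from the electrode: <150 µm NEAR, 150–300 MID, >300 FAR."""
    if d_um < 0 or not math.isfinite(d_um):
        raise ValueError(f"invalid distance {d_um}")
    if d_um < NEAR_BOUNDARY_UM:
        return DistanceBin.NEAR
    if d_um <= FAR_BOUNDARY_UM:
        return DistanceBin.MID
    return DistanceBin.FAR


def phase_of_time(t_min: float, paradigm: StimulationParadigm | None = None) -> PhaseLabel:
    """Map a session time (min from stimulation onset) to its phase label.

    The stimulation period is split into three equal consecutive segments
    (EARLY/MID/LATE); intervals are half-open on the left boundary except
    POST, which is closed at the session end.
    """
    paradigm = paradigm or StimulationParadigm()
    if t_min < paradigm.session_start_min or t_min > paradigm.session_end_min:
        raise ValueError(
            f"time {t_min} min outside session "
            f"[{paradigm.session_start_min}, {paradigm.session_end_min}]"
        )
    if t_min < 0:
        return PhaseLabel.PRE
    third = paradigm.stim_duration_min / 3.0
    if t_min < third:
        return PhaseLabel.EARLY
    if t_min < 2 * third:
        return PhaseLabel.MID
    if t_min < paradigm.stim_duration_min:
        return PhaseLabel.LATE
    return PhaseLabel.POST


def charge_per_phase(paradigm: StimulationParadigm) -> ChargeInfo:
    """Charge injected per pulse phase (amplitude × pulse width), nC.

    µA × µs = pC, hence the /1000. Also reports whether the value respects
    the 4 nC/phase biocompatibility limit.
    """
    charge_nc = paradigm.amplitude_ua * paradigm.pulse_width_us / 1000.0
    return ChargeInfo(charge_nc, charge_nc <= CHARGE_SAFETY_LIMIT_NC)
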