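"""Microglia–neuron contact analysis.

A contact log records CONNECT/DISCONNECT events between a microglial process
and a neuronal soma. Per (microglia, neuron) pair a legal log alternates
CONNECT → DISCONNECT → CONNECT …, since a process cannot disconnect from a
soma it is not touching. Analyses: proximity filtering of process movements
(a movement is "near" a neuron if its end tip lies within 20 µm of the soma
center), contact rates per neuronal adaptation profile, and the timing of
contacts relative to stimulation onset.
"""

from __future__ import annotations

import enum
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .calcium import StimProfile
from .geometry import Point, StimulationParadigm, euclidean_distance, phase_of_time
from .motility import ProcessMovement

__all__ = [
    "ContactEvent",
    "ContactKind",
    "ContactViolation",
    "NearMovement",
    "DEFAULT_NEAR_RADIUS_UM",
    "near_neuron_movements",
    "validate_contact_log",
    "contacts_per_neuron",
    "peri_stim_timing",
]

#: A process tip within this distance of a soma center counts as "near".
DEFAULT_NEAR_RADIUS_UM = 20.0


class ContactKind(enum.Enum):
    CONNECT = "connect"
    DISCONNECT = "disconnect"


@dataclass(frozen=True)
class ContactEvent:
    microglia_id: str
    neuron_id: str
    t_min: float
    kind: ContactKind


@dataclass(frozen=True)
class ContactViolation:
    microglia_id: str
    neuron_id: str
    t_min: float
    reason: str


@dataclass(frozen=True)
class NearMovement:
    movement: ProcessMovement
    nearest_neuron_id: str
    distance_um: float


def near_neuron_movements(
    movements: Iterable[ProcessMovement],
    somata: Mapping[str, Point],
    radius_um: float = DEFAULT_NEAR_RADIUS_UM,
) -> list[NearMovement]:
    """Annotate movements with their nearest soma; keep those within radius.

    Distance is measured from the movement's end tip to the soma center and
    the boundary is inclusive. Ties for nearest soma resolve to the smallest
    neuron id.
    """
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    somata = dict(somata)
    if not somata:
        raise ValueError("empty soma set")
    ids = sorted(somata)
    out = []
    for mv in movements:
        best_id, best_d = None, math.inf
        for nid in ids:
            d = euclidean_distance(mv.tip_end, somata[nid])
            if d < best_d:  # sorted ids give smallest-id tie-break
                best_id, best_d = nid, d
        if best_d <= radius_um:
            out.append(NearMovement(mv, best_id, best_d))
    return out


def validate_contact_log(events: Iterable[ContactEvent]) -> list[ContactViolation]:
    """Check CONNECT/DISCONNECT alternation per (microglia, neuron) pair.

    Violations (DISCONNECT while not in contact, CONNECT while already in
    contact) are reported, never raised — field logs are hand-curated and a
    bad row should surface, not abort the run.
    """
    by_pair: dict = defaultdict(list)
    for ev in events:
        by_pair[(ev.microglia_id, ev.neuron_id)].append(ev)
    violations = []
    for (mid, nid), evs in sorted(by_pair.items()):
        in_contact = False
        for ev in sorted(evs, key=lambda e: e.t_min):
            if ev.kind is ContactKind.CONNECT:
                if in_contact:
                    violations.append(
                        ContactViolation(mid, nid, ev.t_min, "double connect")
                    )
                in_contact = True
            else:
                if not in_contact:
                    violations.append(
                        ContactViolation(mid, nid, ev.t_min, "disconnect before connect")
                    )
                in_contact = False
    return violations


def contacts_per_neuron(
    events: Iterable[ContactEvent],
    neuron_labels: Mapping[str, StimProfile],
) -> pd.DataFrame:
    """Mean CONNECT events per neuron, by adaptation profile.

    Every labeled neuron enters its profile's denominator whether or not it
    was ever contacted. Returns one row per profile present among the labels
    with columns n_neurons, total_contacts, contacts_per_neuron, sem (SEM of
    per-neuron counts).
    """
    counts = {nid: 0 for nid in neuron_labels}
    for ev in events:
        if ev.kind is not ContactKind.CONNECT:
            continue
        if ev.neuron_id not in counts:
            raise KeyError(f"contact references unlabeled neuron {ev.neuron_id!r}")
        counts[ev.neuron_id] += 1
    rows = []
    by_profile: dict = defaultdict(list)
    for nid, profile in neuron_labels.items():
        by_profile[profile].append(counts[nid])
    for profile, per_neuron in sorted(by_profile.items(), key=lambda kv: kv[0].value):
        arr = np.asarray(per_neuron, dtype=float)
        sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else math.nan
        rows.append(
            {
                "profile": profile.value,
                "n_neurons": arr.size,
                "total_contacts": int(arr.sum()),
                "contacts_per_neuron": float(arr.mean()),
                "sem": sem,
            }
        )
    return pd.DataFrame(rows)


def peri_stim_timing(
    events: Iterable[ContactEvent],
    paradigm: StimulationParadigm | None = None,
    neuron_labels: Mapping[str, StimProfile] | None = None,
    bin_width_min: float = 1.0,
):
    """Timing of CONNECT events relative to stimulation onset.

    Returns (per_event, histogram): ``per_event`` has one row per in-session
    CONNECT with its phase label and minutes from onset (out-of-session
    events are flagged and excluded); ``histogram`` counts contacts in
    ``bin_width_min`` bins over the session, split by profile when labels
    are given.
    """
    paradigm = paradigm or StimulationParadigm()
    rows, excluded = [], []
    for ev in events:
        if ev.kind is not ContactKind.CONNECT:
            continue
        try:
            phase = phase_of_time(ev.t_min, paradigm)
        except ValueError:
            excluded.append(ev)
            continue
        profile = (
            neuron_labels[ev.neuron_id].value
            if neuron_labels is not None and ev.neuron_id in neuron_labels
            else None
        )
        rows.append(
            {
                "microglia_id": ev.microglia_id,
                "neuron_id": ev.neuron_id,
                "t_min": ev.t_min,
                "phase": phase.value,
                "profile": profile,
            }
        )
    per_event = pd.DataFrame(
        rows, columns=["microglia_id", "neuron_id", "t_min", "phase", "profile"]
    )
    edges = np.arange(
        paradigm.session_start_min,
        paradigm.session_end_min + bin_width_min,
        bin_width_min,
    )
    hist_rows = []
    groups = (
        per_event.groupby("profile", dropna=False)
        if neuron_labels is not None
        else [(None, per_event)]
    )
    for profile, grp in groups:
        counts, _ = np.histogram(grp["t_min"].to_numpy(), bins=edges)
        for left, c in zip(edges[:-1], counts):
            hist_rows.append(
                {
                    "profile": profile,
                    "bin_start_min": float(left),
                    "count": int(c),
                }
            )
    histogram = pd.DataFrame(hist_rows, columns=["profile", "bin_start_min", "count"])
    per_event.attrs["n_excluded_out_of_session"] = len(excluded)
    return per_event, histogram
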