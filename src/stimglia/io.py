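"""Table schemas, session bundles, config loading and the pipeline driver.

All on-disk formats are plain UTF-8 CSV with a header row; units are baked
into column names (``x_um``, ``t_min``) so a file can never silently carry
the wrong unit. A session lives in one directory:

    traces.csv     neuron_id, x_um, y_um, t_min, F
    movements.csv  microglia_id, t_min, x0_um, y0_um, x1_um, y1_um,
                   soma_x_um, soma_y_um, kind, interval_min
    snapshots.csv  microglia_id, soma_x_um, soma_y_um, tip_x_um, tip_y_um, length_um
    contacts.csv   microglia_id, neuron_id, t_min, kind

plus optional truth tables and a config/manifest from the generator.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calcium import (
    BaselineStats,
    CalciumTrace,
    ClassifierThresholds,
    classify_trace,
    fit_bleach_model,
)
from .geometry import Point, StimulationParadigm
from .interactions import (
    DEFAULT_NEAR_RADIUS_UM,
    ContactEvent,
    ContactKind,
    contacts_per_neuron,
    peri_stim_timing,
    validate_contact_log,
)
from .motility import (
    MicrogliaSnapshot,
    MovementKind,
    ProcessMovement,
    d_index,
    motility_counts,
    movement_angle,
    polarity_index,
)

log = logging.getLogger("stimglia")

__all__ = [
    "SessionBundle",
    "AnalysisConfig",
    "SchemaError",
    "read_session",
    "write_session",
    "load_config",
    "run_pipeline",
]

TRACE_COLUMNS = ["neuron_id", "x_um", "y_um", "t_min", "F"]
MOVEMENT_COLUMNS = [
    "microglia_id", "t_min", "x0_um", "y0_um", "x1_um", "y1_um",
    "soma_x_um", "soma_y_um", "kind", "interval_min",
]
SNAPSHOT_COLUMNS = [
    "microglia_id", "soma_x_um", "soma_y_um", "tip_x_um", "tip_y_um", "length_um",
]
CONTACT_COLUMNS = ["microglia_id", "neuron_id", "t_min", "kind"]


class SchemaError(ValueError):
    """A table failed schema or cross-reference validation."""


@dataclass
class SessionBundle:
    """One session's validated in-memory contents."""

    paradigm: StimulationParadigm
    electrode: Point
    traces: list = field(default_factory=list)
    movements: list = field(default_factory=list)
    snapshots: list = field(default_factory=list)
    contacts: list = field(default_factory=list)
    field_trace: CalciumTrace | None = None
    truth_neurons: pd.DataFrame | None = None
    truth_microglia: pd.DataFrame | None = None


@dataclass
class AnalysisConfig:
    """Analysis parameters with their field-standard defaults.

    Thresholds mirror the classifier rules (σ-units); bandwidth None means
    the Silverman rule; near_radius_um is the process-to-soma proximity cut.
    """

    paradigm: StimulationParadigm = field(default_factory=StimulationParadigm)
    electrode_x_um: float = 0.0
    electrode_y_um: float = 203.5
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    kde_bandwidth_deg: float | None = None
    kde_grid_step_deg: float = 0.5
    near_radius_um: float = DEFAULT_NEAR_RADIUS_UM
    bleach_mode: str = "multiplicative"
    seed: int | None = None

    @property
    def electrode(self) -> Point:
        return Point(self.electrode_x_um, self.electrode_y_um)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an AnalysisConfig from a YAML file; missing keys keep defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    if "paradigm" in raw:
        kwargs["paradigm"] = StimulationParadigm(**raw.pop("paradigm"))
    if "thresholds" in raw:
        kwargs["thresholds"] = ClassifierThresholds(**raw.pop("thresholds"))
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    kwargs.update(raw)
    return AnalysisConfig(**kwargs)


# --- readers / writers ------------------------------------------------------


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def traces_to_frame(traces) -> pd.DataFrame:
    rows = []
    for tr in traces:
        for t, f in zip(tr.times, tr.F):
            rows.append((tr.neuron_id, tr.soma.x, tr.soma.y, t, f))
    return pd.DataFrame(rows, columns=TRACE_COLUMNS)


def frame_to_traces(df: pd.DataFrame, path="traces") -> list:
    _require_columns(df, TRACE_COLUMNS, path)
    traces = []
    for nid, grp in df.groupby("neuron_id", sort=True):
        grp = grp.sort_values("t_min")
        soma = Point(float(grp["x_um"].iloc[0]), float(grp["y_um"].iloc[0]))
        traces.append(
            CalciumTrace(str(nid), soma, grp["t_min"].to_numpy(), grp["F"].to_numpy())
        )
    return traces


def movements_to_frame(movements) -> pd.DataFrame:
    rows = [
        (
            m.microglia_id, m.t_min, m.tip_start.x, m.tip_start.y,
            m.tip_end.x, m.tip_end.y, m.soma.x, m.soma.y,
            m.kind.value, m.interval_min,
        )
        for m in movements
    ]
    return pd.DataFrame(rows, columns=MOVEMENT_COLUMNS)


def frame_to_movements(df: pd.DataFrame, path="movements") -> list:
    _require_columns(df, MOVEMENT_COLUMNS, path)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ProcessMovement(
                microglia_id=str(row.microglia_id),
                t_min=float(row.t_min),
                tip_start=Point(float(row.x0_um), float(row.y0_um)),
                tip_end=Point(float(row.x1_um), float(row.y1_um)),
                soma=Point(float(row.soma_x_um), float(row.soma_y_um)),
                kind=MovementKind(row.kind),
                interval_min=float(row.interval_min),
            )
        )
    return out


def snapshots_to_frame(snapshots) -> pd.DataFrame:
    rows = []
    for s in snapshots:
        for tip, length in s.processes:
            rows.append((s.microglia_id, s.soma.x, s.soma.y, tip.x, tip.y, length))
    return pd.DataFrame(rows, columns=SNAPSHOT_COLUMNS)


def frame_to_snapshots(df: pd.DataFrame, path="snapshots") -> list:
    _require_columns(df, SNAPSHOT_COLUMNS, path)
    out = []
    for mid, grp in df.groupby("microglia_id", sort=True):
        soma = Point(float(grp["soma_x_um"].iloc[0]), float(grp["soma_y_um"].iloc[0]))
        procs = tuple(
            (Point(float(r.tip_x_um), float(r.tip_y_um)), float(r.length_um))
            for r in grp.itertuples(index=False)
        )
        out.append(MicrogliaSnapshot(str(mid), soma, procs))
    return out


def contacts_to_frame(contacts) -> pd.DataFrame:
    rows = [(c.microglia_id, c.neuron_id, c.t_min, c.kind.value) for c in contacts]
    return pd.DataFrame(rows, columns=CONTACT_COLUMNS)


def frame_to_contacts(df: pd.DataFrame, path="contacts") -> list:
    _require_columns(df, CONTACT_COLUMNS, path)
    return [
        ContactEvent(
            str(r.microglia_id), str(r.neuron_id), float(r.t_min), ContactKind(r.kind)
        )
        for r in df.itertuples(index=False)
    ]


def write_session(bundle: SessionBundle, outdir: str | Path) -> None:
    """Write every populated table of a bundle as CSVs under one directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if bundle.traces:
        traces_to_frame(bundle.traces).to_csv(outdir / "traces.csv", index=False)
    if bundle.movements:
        movements_to_frame(bundle.movements).to_csv(outdir / "movements.csv", index=False)
    if bundle.snapshots:
        snapshots_to_frame(bundle.snapshots).to_csv(outdir / "snapshots.csv", index=False)
    if bundle.contacts:
        contacts_to_frame(bundle.contacts).to_csv(outdir / "contacts.csv", index=False)
    if bundle.field_trace is not None:
        pd.DataFrame(
            {"t_min": bundle.field_trace.times, "F": bundle.field_trace.F}
        ).to_csv(outdir / "field.csv", index=False)
    if bundle.truth_neurons is not None:
        bundle.truth_neurons.to_csv(outdir / "truth_neurons.csv", index=False)
    if bundle.truth_microglia is not None:
        bundle.truth_microglia.to_csv(outdir / "truth_microglia.csv", index=False)
    meta = {
        "paradigm": dataclasses.asdict(bundle.paradigm),
        "electrode": {"x_um": bundle.electrode.x, "y_um": bundle.electrode.y},
    }
    (outdir / "session.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def read_session(indir: str | Path, config: AnalysisConfig | None = None) -> SessionBundle:
    """Read a session directory back into a validated bundle.

    Checks schemas, units columns and id cross-references (contacts must
    refer to known neurons and, when movements are present, known
    microglia).
    """
    indir = Path(indir)
    meta_path = indir / "session.yaml"
    if meta_path.exists():
        meta = yaml.safe_load(meta_path.read_text())
        paradigm = StimulationParadigm(**meta["paradigm"])
        electrode = Point(meta["electrode"]["x_um"], meta["electrode"]["y_um"])
    elif config is not None:
        paradigm, electrode = config.paradigm, config.electrode
    else:
        paradigm, electrode = StimulationParadigm(), AnalysisConfig().electrode

    bundle = SessionBundle(paradigm=paradigm, electrode=electrode)
    p = indir / "traces.csv"
    if p.exists():
        bundle.traces = frame_to_traces(pd.read_csv(p), p)
    p = indir / "movements.csv"
    if p.exists():
        bundle.movements = frame_to_movements(pd.read_csv(p), p)
    p = indir / "snapshots.csv"
    if p.exists():
        bundle.snapshots = frame_to_snapshots(pd.read_csv(p), p)
    p = indir / "contacts.csv"
    if p.exists():
        bundle.contacts = frame_to_contacts(pd.read_csv(p), p)
        known_neurons = {tr.neuron_id for tr in bundle.traces}
        if known_neurons:
            for c in bundle.contacts:
                if c.neuron_id not in known_neurons:
                    raise SchemaError(
                        f"{p}: contact references unknown neuron_id {c.neuron_id!r}"
                    )
        known_cells = {m.microglia_id for m in bundle.movements}
        if known_cells:
            for c in bundle.contacts:
                if c.microglia_id not in known_cells:
                    raise SchemaError(
                        f"{p}: contact references unknown microglia_id {c.microglia_id!r}"
                    )
    p = indir / "field.csv"
    if p.exists():
        df = pd.read_csv(p)
        _require_columns(df, ["t_min", "F"], p)
        df = df.sort_values("t_min")
        bundle.field_trace = CalciumTrace(
            "__field__", Point(0.0, 0.0), df["t_min"].to_numpy(), df["F"].to_numpy()
        )
    p = indir / "truth_neurons.csv"
    if p.exists():
        bundle.truth_neurons = pd.read_csv(p)
    p = indir / "truth_microglia.csv"
    if p.exists():
        bundle.truth_microglia = pd.read_csv(p)
    for name, n in [
        ("traces", len(bundle.traces)),
        ("movements", len(bundle.movements)),
        ("snapshots", len(bundle.snapshots)),
        ("contacts", len(bundle.contacts)),
    ]:
        log.info("read_session: %s rows=%d", name, n)
    return bundle


# --- pipeline ---------------------------------------------------------------


def _field_bleach_model(traces, paradigm, field_trace=None):
    """Fit the photobleaching line on the field-of-view fluorescence.

    Prefers the recorded FOV-average signal (dominated by stable tissue);
    falls back to the mean raw F across neuron traces at each shared
    timepoint. Stimulation samples are excluded from the fit either way.
    """
    if field_trace is not None:
        t0, field_F = field_trace.times, field_trace.F
    else:
        t0 = traces[0].times
        for tr in traces[1:]:
            if tr.times.shape != t0.shape or not np.allclose(tr.times, t0):
                raise SchemaError("traces do not share a common time grid")
        field_F = np.mean([tr.F for tr in traces], axis=0)
    stim_mask = (t0 >= 0) & (t0 < paradigm.stim_duration_min)
    return fit_bleach_model(field_F, t0, stim_mask)


def run_pipeline(
    bundle: SessionBundle,
    config: AnalysisConfig | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run every applicable analysis stage on a bundle.

    Produces a report dict of DataFrames — neuron classification, per-cell
    polarity, D/T indices, per-phase motility summaries, interaction
    summaries — plus a manifest (config hash, package version) that
    suffices to reproduce the outputs. Stages without input are skipped
    with a notice.
    """
    config = config or AnalysisConfig()
    report: dict = {"skipped": [], "flags": []}

    labels = None
    if bundle.traces:
        bleach = _field_bleach_model(
            bundle.traces, bundle.paradigm, bundle.field_trace
        )
        records = [
            classify_trace(
                tr, bundle.paradigm, config.electrode,
                bleach=bleach, thresholds=config.thresholds,
            )
            for tr in bundle.traces
        ]
        report["classification"] = pd.DataFrame(
            {
                "neuron_id": r.neuron_id,
                "profile": r.profile.value,
                "post_profile": r.post_profile.value,
                "distance_um": r.distance_um,
                "mean_stim_dff_sigma_units": r.mean_stim_dff_sigma,
                "flags": ";".join(r.flags),
            }
            for r in records
        )
        report["bleach_model"] = {"slope": bleach.slope, "intercept": bleach.intercept}
        for r in records:
            if r.flags:
                report["flags"].append({"neuron_id": r.neuron_id, "flags": r.flags})
        labels = {r.neuron_id: r.profile for r in records}
        log.info("classified %d neurons", len(records))
    else:
        report["skipped"].append("classification")

    if bundle.movements:
        by_cell: dict = {}
        for mv in bundle.movements:
            by_cell.setdefault(mv.microglia_id, []).append(mv)
        pol_rows = []
        for mid in sorted(by_cell):
            angles = [
                movement_angle(m.tip_start, m.tip_end, config.electrode)
                for m in by_cell[mid]
            ]
            res = polarity_index(
                angles,
                bandwidth_deg=config.kde_bandwidth_deg,
                grid_step_deg=config.kde_grid_step_deg,
            )
            pol_rows.append(
                {
                    "microglia_id": mid,
                    "n_movements": res.n_movements,
                    "rho": res.rho,
                    "excluded": res.excluded,
                }
            )
        report["polarity"] = pd.DataFrame(pol_rows)
        phase_windows = {
            "pre": (-bundle.paradigm.baseline_duration_min, 0.0),
            "early": (0.0, bundle.paradigm.stim_duration_min / 3),
            "mid": (bundle.paradigm.stim_duration_min / 3,
                    2 * bundle.paradigm.stim_duration_min / 3),
            "late": (2 * bundle.paradigm.stim_duration_min / 3,
                     bundle.paradigm.stim_duration_min),
            "post": (bundle.paradigm.stim_duration_min,
                     bundle.paradigm.session_end_min + 1e-9),
        }
        mot_rows = []
        for phase, window in phase_windows.items():
            s = motility_counts(bundle.movements, window)
            mot_rows.append(
                {
                    "phase": phase,
                    "n_extensions": s.n_extensions,
                    "n_retractions": s.n_retractions,
                    "ext_retr_ratio": s.ext_retr_ratio,
                    "mean_speed_ext": s.mean_speed_ext,
                    "mean_speed_retr": s.mean_speed_retr,
                }
            )
        report["motility"] = pd.DataFrame(mot_rows)
        n_excl = int(report["polarity"]["excluded"].sum())
        log.info("polarity: %d cells, %d excluded (<4 movements)",
                 len(pol_rows), n_excl)
    else:
        report["skipped"].append("motility")

    if bundle.snapshots:
        idx_rows = []
        for s in sorted(bundle.snapshots, key=lambda s: s.microglia_id):
            res = d_index(s, config.electrode)
            idx_rows.append(
                {
                    "microglia_id": s.microglia_id,
                    "d_index": res.d_index,
                    "t_index": res.t_index,
                    "n_processes": len(s.processes),
                }
            )
        report["indices"] = pd.DataFrame(idx_rows)
    else:
        report["skipped"].append("indices")

    if bundle.contacts and labels is not None:
        violations = validate_contact_log(bundle.contacts)
        report["contact_violations"] = pd.DataFrame(
            [dataclasses.asdict(v) for v in violations]
        )
        report["contacts_per_neuron"] = contacts_per_neuron(bundle.contacts, labels)
        per_event, hist = peri_stim_timing(
            bundle.contacts, bundle.paradigm, labels
        )
        report["contact_timing"] = per_event
        report["contact_histogram"] = hist
    else:
        report["skipped"].append("interactions")

    cfg_dict = config.to_dict()
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    report["manifest"] = {
        "package_version": __version__,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for key, val in report.items():
            if isinstance(val, pd.DataFrame):
                val.to_csv(outdir / f"{key}.csv", index=False)
        (outdir / "manifest.json").write_text(
            json.dumps(report["manifest"], indent=2, sort_keys=True, default=str)
        )
    return report
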