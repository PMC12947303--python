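"""Synthetic stimulation sessions with ground truth.

Generates the four input tables the analysis consumes — neuron calcium
traces, microglial process-movement events, morphology snapshots and a
microglia–neuron contact log — from a single seeded configuration, together
with per-entity truth labels for parameter-recovery testing.

The defaults emulate a Day-0 session: 10 Hz / 10 µA / 200 µs stimulation
with a 20-60-20 min timeline sampled every 2.16 min; 458 neurons mixed
across adaptation profiles in proportions matching a typical first-day
field; 39 microglia producing ≈6.3 movement events per cell per 20 min
window with extension speeds ≈0.73 and retraction speeds ≈0.78 µm/min; and
per-profile soma contact rates of 0.75 (depressed), 0.29 (baseline
adapting), 0.25 (adapting) and 0.18 (non-adapting) contacts per neuron.

Calcium templates are built in σ-units of ΔF/F₀ so that, at zero noise,
every template classifies to its intended label with margin from each
decision boundary; raw fluorescence is F₀·(1 + ΔF/F₀)·(1 + slope·t) with
Gaussian ΔF/F₀ noise and a linear photobleaching trend.

Randomness: one root seed spawns independent substreams in a fixed order
(neurons, movements, contacts, field), so regenerating one stage never
reshuffles another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calcium import CalciumTrace, PostStimProfile, StimProfile
from .geometry import (
    Point,
    StimulationParadigm,
    assign_distance_bin,
    euclidean_distance,
)
from .interactions import ContactEvent, ContactKind
from .motility import (
    DEFAULT_MOVEMENT_INTERVAL_MIN,
    MicrogliaSnapshot,
    MovementKind,
    ProcessMovement,
)

__all__ = ["GeneratorConfig", "SyntheticSession", "generate_neurons",
           "generate_movements", "generate_contacts", "generate_field_trace",
           "generate_session", "template_dff_sigma"]

# Day-0 field composition: activated profiles in Fig-level counts
# (29 depressed, 191 baseline adapting, 88 adapting, 27 non-adapting)
# plus 123 non-activated neurons split 98/25 plain/depressed.
_DEFAULT_PROFILE_MIX = {
    "depressed": 29 / 458,
    "baseline_adapting": 191 / 458,
    "adapting": 88 / 458,
    "non_adapting": 27 / 458,
    "non_activated": 98 / 458,
    "non_activated_depressed": 25 / 458,
}

_DEFAULT_CONTACT_RATES = {
    "depressed": 0.75,
    "baseline_adapting": 0.29,
    "adapting": 0.25,
    "non_adapting": 0.18,
    # the source field reports no rates for non-activated neurons;
    # modest values chosen as plausible surveillance-level contact
    "non_activated": 0.10,
    "non_activated_depressed": 0.30,
}

# toward-the-electrode movement probability by distance bin; calibrated so
# near cells polarize toward the electrode and far cells slightly away
_DEFAULT_P_TOWARD = {"near": 0.61, "mid": 0.47, "far": 0.39}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic session; defaults are the study conditions."""

    seed: int = 0
    # --- session geometry / timing ---
    field_size_um: float = 407.0
    electrode_x_um: float = 0.0
    electrode_y_um: float = 203.5
    sample_period_min: float = 2.16
    baseline_duration_min: float = 20.0
    stim_duration_min: float = 60.0
    post_duration_min: float = 20.0
    # --- neurons ---
    n_neurons: int = 458
    profile_mix: dict = field(default_factory=lambda: dict(_DEFAULT_PROFILE_MIX))
    baseline_F0: float = 100.0
    f0_jitter_frac: float = 0.3          # per-neuron F0 ~ U(F0·(1−j), F0·(1+j))
    sigma: float = 0.05                  # ΔF/F₀ template scale AND noise SD
    noise_on: bool = True
    bleach_slope_frac_per_min: float = -0.001
    # --- microglia movements ---
    n_microglia: int = 39
    events_per_cell_per_window: float = (654 + 583) / 39 / 5
    extension_fraction: float = 654 / (654 + 583)
    speed_mean_ext: float = 0.73
    speed_mean_retr: float = 0.78
    speed_sd: float = 0.15
    p_toward: dict = field(default_factory=lambda: dict(_DEFAULT_P_TOWARD))
    movement_interval_min: float = DEFAULT_MOVEMENT_INTERVAL_MIN
    processes_per_cell: tuple = (3, 6)
    process_length_range_um: tuple = (10.0, 40.0)
    # --- contacts ---
    contact_rates: dict = field(default_factory=lambda: dict(_DEFAULT_CONTACT_RATES))
    contact_dwell_mean_min: float = 5.0

    def __post_init__(self) -> None:
        total = sum(self.profile_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"profile_mix proportions sum to {total}, not 1")
        if any(r < 0 for r in self.contact_rates.values()):
            raise ValueError("contact rates must be non-negative")
        if self.events_per_cell_per_window < 0:
            raise ValueError("event rate must be non-negative")

    @property
    def paradigm(self) -> StimulationParadigm:
        return StimulationParadigm(
            baseline_duration_min=self.baseline_duration_min,
            stim_duration_min=self.stim_duration_min,
            post_duration_min=self.post_duration_min,
        )

    @property
    def electrode(self) -> Point:
        return Point(self.electrode_x_um, self.electrode_y_um)

    def time_grid(self) -> np.ndarray:
        """Uniform sample times covering the whole session, min from onset."""
        start = -self.baseline_duration_min
        end = self.stim_duration_min + self.post_duration_min
        n = int(math.floor((end - start) / self.sample_period_min)) + 1
        t = start + self.sample_period_min * np.arange(n)
        return t[t <= end]


@dataclass
class SyntheticSession:
    """Everything one generated session contains, truth included."""

    config: GeneratorConfig
    traces: list
    movements: list
    snapshots: list
    contacts: list
    truth_neurons: pd.DataFrame
    truth_microglia: pd.DataFrame
    field_trace: CalciumTrace | None = None


# --- calcium templates -----------------------------------------------------

_DECAY = 1.5  # per-sample exponential decay rate of adapting onsets


def template_dff_sigma(profile: str, n_stim: int, n_post: int):
    """Noise-free ΔF/F₀ template in σ-units for the stim and post windows.

    Each template keeps its stim-window mean at least 1σ away from every
    classification boundary so zero-noise classification is exact and noisy
    classification errs rarely:

    * non_adapting — sustained 5σ (all samples above θ = 3σ);
    * adapting — 2σ plateau with a 6σ onset transient (mean ≈ 2.2σ);
    * baseline_adapting — 5σ onset decaying to 0 (mean ≈ 0.23σ);
    * depressed — 5σ for two samples then a −3.5σ plateau (mean ≈ −2.9σ);
    * non_activated — flat 0;
    * non_activated_depressed — flat −3.5σ.

    Post window: −3.5σ for the two depressed templates, 0 otherwise.
    """
    k = np.arange(n_stim)
    if profile == "non_adapting":
        stim = np.full(n_stim, 5.0)
        post_level = 0.0
    elif profile == "adapting":
        stim = 2.0 + 4.0 * np.exp(-_DECAY * k)
        post_level = 0.0
    elif profile == "baseline_adapting":
        stim = 5.0 * np.exp(-_DECAY * k)
        post_level = 0.0
    elif profile == "depressed":
        stim = np.full(n_stim, -3.5)
        stim[:2] = 5.0
        post_level = -3.5
    elif profile == "non_activated":
        stim = np.zeros(n_stim)
        post_level = 0.0
    elif profile == "non_activated_depressed":
        stim = np.full(n_stim, -3.5)
        post_level = -3.5
    else:
        raise ValueError(f"unknown profile {profile!r}")
    post = np.full(n_post, post_level)
    return stim, post


_POST_TRUTH = {
    "depressed": PostStimProfile.DEPRESSED,
    "non_activated_depressed": PostStimProfile.DEPRESSED,
}


def generate_neurons(config: GeneratorConfig, rng: np.random.Generator | None = None):
    """Generate calcium traces and their truth table.

    Returns (traces, truth) where truth has one row per neuron with the
    intended stim/post profile, soma position and distance from the
    electrode.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    t = config.time_grid()
    base_mask = t < 0
    stim_mask = (t >= 0) & (t < config.stim_duration_min)
    post_mask = t > config.stim_duration_min
    n_stim, n_post = int(stim_mask.sum()), int(post_mask.sum())

    profiles = list(config.profile_mix)
    probs = np.array([config.profile_mix[p] for p in profiles])
    labels = rng.choice(profiles, size=config.n_neurons, p=probs)

    traces, rows = [], []
    for i, profile in enumerate(labels):
        nid = f"n{i:04d}"
        soma = Point(
            float(rng.uniform(0, config.field_size_um)),
            float(rng.uniform(0, config.field_size_um)),
        )
        stim_tpl, post_tpl = template_dff_sigma(profile, n_stim, n_post)
        dff_sigma = np.zeros(t.size)
        dff_sigma[stim_mask] = stim_tpl
        dff_sigma[post_mask] = post_tpl
        if config.noise_on:
            dff_sigma = dff_sigma + rng.standard_normal(t.size)
        dff = config.sigma * dff_sigma
        j = config.f0_jitter_frac
        F0 = config.baseline_F0 * float(rng.uniform(1 - j, 1 + j))
        F = F0 * (1.0 + dff) * (1.0 + config.bleach_slope_frac_per_min * t)
        F = np.clip(F, 0.0, None)
        traces.append(CalciumTrace(nid, soma, t.copy(), F))
        rows.append(
            {
                "neuron_id": nid,
                "profile": profile,
                "post_profile": _POST_TRUTH.get(profile, PostStimProfile.BASELINE).value,
                "x_um": soma.x,
                "y_um": soma.y,
                "F0": F0,
                "distance_um": euclidean_distance(soma, config.electrode),
            }
        )
    return traces, pd.DataFrame(rows)


def generate_field_trace(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> CalciumTrace:
    """Full-field-of-view average fluorescence for photobleaching fitting.

    The FOV signal is dominated by stable tissue, so it carries the linear
    bleach trend plus a small stimulation-evoked elevation (irrelevant to
    the fit, which excludes stimulation timepoints) and low-amplitude noise.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    t = config.time_grid()
    stim_mask = (t >= 0) & (t < config.stim_duration_min)
    evoked = np.where(stim_mask, 0.05, 0.0)
    noise = 0.005 * rng.standard_normal(t.size) if config.noise_on else 0.0
    F = config.baseline_F0 * (1.0 + evoked + noise) * (
        1.0 + config.bleach_slope_frac_per_min * t
    )
    return CalciumTrace(
        "__field__", Point(config.field_size_um / 2, config.field_size_um / 2),
        t, np.clip(F, 0.0, None),
    )


# --- microglial movements --------------------------------------------------


def _truncated_normal(rng, mean, sd, size):
    """Positive-truncated normal by rejection (fast at these means)."""
    out = rng.normal(mean, sd, size)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= 0
    return out


def generate_movements(config: GeneratorConfig, rng: np.random.Generator | None = None):
    """Generate process-movement events and morphology snapshots.

    Per cell and 20 min phase window the event count is Poisson at the
    configured rate; each event moves toward the electrode with the
    distance-bin probability p_toward (angle uniform on [0°, 90°)) or away
    (uniform on (90°, 180°]), at a positive-truncated-normal speed over one
    2-frame interval. Returns (events, snapshots, truth).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    paradigm = config.paradigm
    windows = []
    w0 = -config.baseline_duration_min
    while w0 < paradigm.session_end_min - 1e-9:
        windows.append((w0, min(w0 + 20.0, paradigm.session_end_min)))
        w0 += 20.0

    events, snapshots, rows = [], [], []
    for i in range(config.n_microglia):
        mid = f"m{i:03d}"
        soma = Point(
            float(rng.uniform(0, config.field_size_um)),
            float(rng.uniform(0, config.field_size_um)),
        )
        dist = euclidean_distance(soma, config.electrode)
        bin_label = assign_distance_bin(dist).value
        p_toward = float(config.p_toward[bin_label])
        for (w_start, w_end) in windows:
            n_ev = int(rng.poisson(config.events_per_cell_per_window))
            if n_ev == 0:
                continue
            t_ev = rng.uniform(w_start, w_end, n_ev)
            is_ext = rng.random(n_ev) < config.extension_fraction
            speeds = np.where(
                is_ext,
                _truncated_normal(rng, config.speed_mean_ext, config.speed_sd, n_ev),
                _truncated_normal(rng, config.speed_mean_retr, config.speed_sd, n_ev),
            )
            toward = rng.random(n_ev) < p_toward
            angles = np.where(
                toward, rng.uniform(0.0, 90.0, n_ev), rng.uniform(90.0, 180.0, n_ev)
            )
            for j in range(n_ev):
                r = float(rng.uniform(5.0, 20.0))
                phi = float(rng.uniform(0, 2 * math.pi))
                start = Point(soma.x + r * math.cos(phi), soma.y + r * math.sin(phi))
                # displacement at the drawn angle from the to-target direction
                tx = config.electrode.x - start.x
                ty = config.electrode.y - start.y
                base = math.atan2(ty, tx)
                sign = 1.0 if rng.random() < 0.5 else -1.0
                theta = base + sign * math.radians(angles[j])
                step = float(speeds[j]) * config.movement_interval_min
                end = Point(start.x + step * math.cos(theta),
                            start.y + step * math.sin(theta))
                events.append(
                    ProcessMovement(
                        microglia_id=mid,
                        t_min=float(t_ev[j]),
                        tip_start=start,
                        tip_end=end,
                        soma=soma,
                        kind=MovementKind.EXTENSION if is_ext[j] else MovementKind.RETRACTION,
                        interval_min=config.movement_interval_min,
                    )
                )
        lo, hi = config.processes_per_cell
        n_proc = int(rng.integers(lo, hi + 1))
        procs = []
        for _ in range(n_proc):
            length = float(rng.uniform(*config.process_length_range_um))
            phi = float(rng.uniform(0, 2 * math.pi))
            procs.append(
                (Point(soma.x + length * math.cos(phi),
                       soma.y + length * math.sin(phi)), length)
            )
        snapshots.append(MicrogliaSnapshot(mid, soma, tuple(procs)))
        rows.append(
            {
                "microglia_id": mid,
                "x_um": soma.x,
                "y_um": soma.y,
                "distance_um": dist,
                "distance_bin": bin_label,
                "p_toward": p_toward,
            }
        )
    events.sort(key=lambda e: e.t_min)
    return events, snapshots, pd.DataFrame(rows)


# --- contacts ---------------------------------------------------------------


def generate_contacts(
    config: GeneratorConfig,
    truth_neurons: pd.DataFrame,
    rng: np.random.Generator | None = None,
):
    """Generate an alternating CONNECT/DISCONNECT contact log.

    Per neuron the CONNECT count is Poisson at the profile's rate; contact
    times are uniform over the stimulation hour, each followed by a
    DISCONNECT after an exponential dwell (clipped so logs always alternate
    legally; a contact still open at session end gets no DISCONNECT).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    session_end = config.paradigm.session_end_min
    connects: dict = {}
    for _, row in truth_neurons.iterrows():
        rate = float(config.contact_rates[row["profile"]])
        k = int(rng.poisson(rate)) if rate > 0 else 0
        for _ in range(k):
            mid = f"m{int(rng.integers(0, config.n_microglia)):03d}"
            t = float(rng.uniform(0.0, config.stim_duration_min))
            connects.setdefault((mid, row["neuron_id"]), []).append(t)

    events: list[ContactEvent] = []
    for (mid, nid), times in sorted(connects.items()):
        times.sort()
        for idx, t in enumerate(times):
            events.append(ContactEvent(mid, nid, t, ContactKind.CONNECT))
            dwell = float(rng.exponential(config.contact_dwell_mean_min))
            d = t + dwell
            if idx + 1 < len(times):
                gap = times[idx + 1] - t
                d = min(d, t + 0.9 * gap)
            if d <= session_end:
                events.append(ContactEvent(mid, nid, d, ContactKind.DISCONNECT))
    events.sort(key=lambda e: (e.t_min, e.kind.value))
    return events


def generate_session(config: GeneratorConfig) -> SyntheticSession:
    """Generate a complete session with independent substreams per stage."""
    ss = np.random.SeedSequence(config.seed)
    rng_neurons, rng_moves, rng_contacts, rng_field = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    traces, truth_neurons = generate_neurons(config, rng_neurons)
    movements, snapshots, truth_microglia = generate_movements(config, rng_moves)
    contacts = generate_contacts(config, truth_neurons, rng_contacts)
    field_trace = generate_field_trace(config, rng_field)
    return SyntheticSession(
        config=config,
        traces=traces,
        movements=movements,
        snapshots=snapshots,
        contacts=contacts,
        truth_neurons=truth_neurons,
        truth_microglia=truth_microglia,
        field_trace=field_trace,
    )
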