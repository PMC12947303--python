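"""Neuronal calcium-trace preprocessing and adaptation-profile classification.

The pipeline is: collapse each Z-stack to its maximum intensity, correct slow
photobleaching with a linear model fitted on non-stimulation samples, express
activity as ΔF/F₀ against the 20 min pre-stimulation baseline, then classify
each neuron's trajectory during and after stimulation.

A neuron counts as *activated* if its ΔF/F₀ ever strictly exceeds
θ = 3σ during stimulation, where σ is the standard deviation of baseline
ΔF/F₀. Activated neurons fall into four mutually exclusive adaptation
profiles (non-adapting, depressed, baseline adapting, adapting) and
non-activated neurons into two (plain, depressed); all rules are expressed
in σ-units of ΔF/F₀ so classification is invariant to detector gain.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

from .geometry import Point, StimulationParadigm

__all__ = [
    "CalciumTrace",
    "BleachModel",
    "BaselineStats",
    "StimProfile",
    "PostStimProfile",
    "ClassifierThresholds",
    "ClassificationRecord",
    "collapse_stack_max",
    "fit_bleach_model",
    "correct_bleach",
    "baseline_stats",
    "compute_dff",
    "is_activated",
    "classify_stim_profile",
    "classify_post_stim_profile",
    "classify_trace",
]


class InsufficientDataError(ValueError):
    pass


@dataclass
class CalciumTrace:
    """One neuron's fluorescence time series with its soma position.

    ``times`` are minutes relative to stimulation onset (nominally one sample
    every 2.16 min); ``F`` is raw fluorescence in arbitrary units.
    """

    neuron_id: str
    soma: Point
    times: np.ndarray
    F: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.times.shape != self.F.shape or self.times.ndim != 1:
            raise ValueError("times and F must be 1D arrays of equal length")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.F)) or np.any(self.F < 0):
            raise ValueError("F must be finite and non-negative")


@dataclass(frozen=True)
class BleachModel:
    """Linear photobleaching model F ≈ intercept + slope·t (a.u., a.u./min)."""

    slope: float
    intercept: float

    def predict(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(t, dtype=float)


@dataclass(frozen=True)
class BaselineStats:
    """Baseline mean fluorescence F₀ and the SD σ of baseline ΔF/F₀.

    ``degenerate`` marks a constant baseline (σ = 0), for which the
    activation threshold θ = 3σ is undefined.
    """

    F0: float
    sigma: float
    degenerate: bool = False


class StimProfile(enum.Enum):
    """Adaptation profile of a neuron during the stimulation hour."""

    NON_ADAPTING = "non_adapting"
    ADAPTING = "adapting"
    BASELINE_ADAPTING = "baseline_adapting"
    DEPRESSED = "depressed"
    NON_ACTIVATED = "non_activated"
    NON_ACTIVATED_DEPRESSED = "non_activated_depressed"
    UNCLASSIFIED = "unclassified"


class PostStimProfile(enum.Enum):
    """Calcium profile in the post-stimulation rest period."""

    BASELINE = "baseline"
    DEPRESSED = "depressed"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ClassifierThresholds:
    """All classification cut-offs, in the units the rules are stated in.

    activation_mult: activation threshold θ = activation_mult·σ.
    depressed_theta_mult: depressed when mean stim ΔF/F₀ < depressed_theta_mult·θ.
    baseline_band_sigma: baseline-adapting band |m| ≤ band·σ.
    adapting_upper_sigma: adapting when band·σ < m ≤ upper·σ.
    nonadapting_frac: non-adapting when > frac of stim samples exceed θ.
    post_band_sigma: post-stimulation baseline band |m| ≤ band·σ.
    adapting_in_theta_units: if True, the adapting interval is read in
        multiples of θ rather than σ (alternative reading of the rule).
    """

    activation_mult: float = 3.0
    depressed_theta_mult: float = -0.5
    baseline_band_sigma: float = 1.0
    adapting_upper_sigma: float = 3.0
    nonadapting_frac: float = 0.5
    post_band_sigma: float = 0.5
    adapting_in_theta_units: bool = False


def collapse_stack_max(per_plane_intensities) -> np.ndarray:
    """Collapse per-timepoint Z-plane intensities to one value per timepoint.

    Takes the maximum across planes so somata only partially inside the
    stack are still represented at full brightness.
    """
    out = []
    for planes in per_plane_intensities:
        arr = np.asarray(planes, dtype=float)
        if arr.size == 0:
            raise ValueError("empty plane set at a timepoint")
        out.append(arr.max())
    return np.asarray(out)


def fit_bleach_model(field_F, times, stim_mask) -> BleachModel:
    """Ordinary least-squares line through non-stimulation samples only.

    ``stim_mask`` is True at stimulation timepoints, which are excluded so
    evoked activity does not bias the photobleaching estimate.
    """
    field_F = np.asarray(field_F, dtype=float)
    times = np.asarray(times, dtype=float)
    stim_mask = np.asarray(stim_mask, dtype=bool)
    keep = ~stim_mask
    if keep.sum() < 3:
        raise InsufficientDataError(
            f"need ≥3 non-stimulation samples, have {int(keep.sum())}"
        )
    t, y = times[keep], field_F[keep]
    if np.ptp(t) == 0:
        raise InsufficientDataError("non-stimulation samples share one timepoint")
    res = _sps.linregress(t, y)
    return BleachModel(slope=float(res.slope), intercept=float(res.intercept))


def correct_bleach(
    trace: CalciumTrace, model: BleachModel, mode: str = "multiplicative"
) -> CalciumTrace:
    """Remove the fitted linear bleach trend from a trace.

    Multiplicative mode rescales by ``model(t0)/model(t)`` with t₀ the first
    sample, which preserves ΔF/F₀ scale invariance; subtractive mode removes
    ``model(t) - model(t0)`` instead.
    """
    pred = np.asarray(model.predict(trace.times), dtype=float)
    if np.any(pred <= 0):
        raise ValueError("bleach model crosses zero within the session")
    ref = pred[0]
    if mode == "multiplicative":
        F_corr = trace.F * (ref / pred)
    elif mode == "subtractive":
        F_corr = trace.F - (pred - ref)
        F_corr = np.clip(F_corr, 0.0, None)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return CalciumTrace(trace.neuron_id, trace.soma, trace.times.copy(), F_corr)


def _baseline_mask(times: np.ndarray, paradigm: StimulationParadigm) -> np.ndarray:
    return (times >= -paradigm.baseline_duration_min) & (times < 0)


def _stim_mask(times: np.ndarray, paradigm: StimulationParadigm) -> np.ndarray:
    return (times >= 0) & (times < paradigm.stim_duration_min)


def _post_mask(times: np.ndarray, paradigm: StimulationParadigm) -> np.ndarray:
    return (times > paradigm.stim_duration_min) & (times <= paradigm.session_end_min)


def baseline_stats(
    trace: CalciumTrace, paradigm: StimulationParadigm | None = None
) -> BaselineStats:
    """Mean baseline fluorescence F₀ and SD of baseline ΔF/F₀.

    σ = SD(F_baseline)/F₀, equivalently the SD of baseline ΔF/F₀. A constant
    baseline yields σ = 0 and is flagged degenerate (thresholds undefined).
    """
    paradigm = paradigm or StimulationParadigm()
    base = trace.F[_baseline_mask(trace.times, paradigm)]
    if base.size < 3:
        raise InsufficientDataError(
            f"need ≥3 baseline samples, have {base.size}"
        )
    F0 = float(base.mean())
    if F0 <= 0:
        raise ValueError("non-positive baseline mean fluorescence")
    sigma = float(base.std(ddof=1) / F0)
    return BaselineStats(F0=F0, sigma=sigma, degenerate=(sigma == 0.0))


def compute_dff(trace: CalciumTrace, stats: BaselineStats) -> np.ndarray:
    """Fractional fluorescence change (F − F₀)/F₀."""
    if stats.F0 <= 0:
        raise ValueError("F0 must be positive")
    return (trace.F - stats.F0) / stats.F0


def is_activated(
    dff: np.ndarray,
    stats: BaselineStats,
    stim_mask: np.ndarray,
    thresholds: ClassifierThresholds | None = None,
) -> bool:
    """True iff any stimulation-window sample strictly exceeds θ = 3σ."""
    th = thresholds or ClassifierThresholds()
    if stats.degenerate:
        raise ValueError("degenerate baseline: activation threshold undefined")
    theta = th.activation_mult * stats.sigma
    stim = np.asarray(dff)[np.asarray(stim_mask, dtype=bool)]
    return bool(np.any(stim > theta))


def classify_stim_profile(
    dff: np.ndarray,
    stats: BaselineStats,
    stim_mask: np.ndarray,
    thresholds: ClassifierThresholds | None = None,
) -> StimProfile:
    """Assign the during-stimulation adaptation profile.

    For activated neurons the rules are applied in fixed precedence:
    NON_ADAPTING (more than half of stim samples above θ), DEPRESSED
    (mean < −0.5θ), BASELINE_ADAPTING (|mean| ≤ 1σ), ADAPTING
    (1σ < mean ≤ 3σ), else UNCLASSIFIED. Non-activated neurons are
    NON_ACTIVATED_DEPRESSED when mean < −0.5θ, else NON_ACTIVATED.
    """
    th = thresholds or ClassifierThresholds()
    if stats.degenerate:
        return StimProfile.UNCLASSIFIED
    sigma = stats.sigma
    theta = th.activation_mult * sigma
    stim = np.asarray(dff)[np.asarray(stim_mask, dtype=bool)]
    if stim.size == 0:
        raise InsufficientDataError("no stimulation-window samples")
    m = float(stim.mean())
    activated = bool(np.any(stim > theta))
    depressed_cut = th.depressed_theta_mult * theta  # −0.5θ = −1.5σ by default
    if not activated:
        if m < depressed_cut:
            return StimProfile.NON_ACTIVATED_DEPRESSED
        return StimProfile.NON_ACTIVATED
    if np.mean(stim > theta) > th.nonadapting_frac:
        return StimProfile.NON_ADAPTING
    if m < depressed_cut:
        return StimProfile.DEPRESSED
    band = th.baseline_band_sigma * (theta if th.adapting_in_theta_units else sigma)
    upper = th.adapting_upper_sigma * (theta if th.adapting_in_theta_units else sigma)
    if abs(m) <= band:
        return StimProfile.BASELINE_ADAPTING
    if band < m <= upper:
        return StimProfile.ADAPTING
    return StimProfile.UNCLASSIFIED


def classify_post_stim_profile(
    dff: np.ndarray,
    stats: BaselineStats,
    post_mask: np.ndarray,
    thresholds: ClassifierThresholds | None = None,
) -> PostStimProfile:
    """Assign the post-stimulation profile from the mean post-window ΔF/F₀.

    DEPRESSED when the mean is below −0.5θ (= −1.5σ); BASELINE when within
    0.5σ of baseline; means falling in the gap between the two printed
    criteria stay UNCLASSIFIED rather than being forced into either.
    """
    th = thresholds or ClassifierThresholds()
    if stats.degenerate:
        return PostStimProfile.UNCLASSIFIED
    post = np.asarray(dff)[np.asarray(post_mask, dtype=bool)]
    if post.size == 0:
        raise InsufficientDataError("no post-stimulation samples")
    m = float(post.mean())
    sigma = stats.sigma
    if m < th.depressed_theta_mult * th.activation_mult * sigma:
        return PostStimProfile.DEPRESSED
    if abs(m) <= th.post_band_sigma * sigma:
        return PostStimProfile.BASELINE
    return PostStimProfile.UNCLASSIFIED


@dataclass
class ClassificationRecord:
    """Per-neuron classifier output row."""

    neuron_id: str
    profile: StimProfile
    post_profile: PostStimProfile
    distance_um: float
    mean_stim_dff_sigma: float
    flags: list[str] = field(default_factory=list)


def classify_trace(
    trace: CalciumTrace,
    paradigm: StimulationParadigm,
    electrode: Point,
    bleach: BleachModel | None = None,
    thresholds: ClassifierThresholds | None = None,
    stats: BaselineStats | None = None,
) -> ClassificationRecord:
    """Run the full per-neuron pipeline: bleach correction → ΔF/F₀ → profiles.

    ``stats`` may be supplied to override baseline estimation (e.g. a known
    σ for noise-free synthetic traces whose estimated baseline SD is zero).
    """
    from .geometry import euclidean_distance

    flags: list[str] = []
    if bleach is not None:
        trace = correct_bleach(trace, bleach)
    if stats is None:
        stats = baseline_stats(trace, paradigm)
    if stats.degenerate:
        flags.append("degenerate_baseline")
    dff = compute_dff(trace, stats)
    sm = _stim_mask(trace.times, paradigm)
    pm = _post_mask(trace.times, paradigm)
    if stats.degenerate:
        profile, post_profile = StimProfile.UNCLASSIFIED, PostStimProfile.UNCLASSIFIED
        mean_sigma = math.nan
    else:
        profile = classify_stim_profile(dff, stats, sm, thresholds)
        post_profile = (
            classify_post_stim_profile(dff, stats, pm, thresholds)
            if pm.any()
            else PostStimProfile.UNCLASSIFIED
        )
        if not pm.any():
            flags.append("no_post_samples")
        mean_sigma = float(dff[sm].mean() / stats.sigma)
    return ClassificationRecord(
        neuron_id=trace.neuron_id,
        profile=profile,
        post_profile=post_profile,
        distance_um=euclidean_distance(trace.soma, electrode),
        mean_stim_dff_sigma=mean_sigma,
        flags=flags,
    )
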