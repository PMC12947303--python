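# Methods

## Scope and data model

The package starts where image processing ends: neurons arrive as
fluorescence time series with soma coordinates, microglial activity as
manually curated movement events (tip start/end per two-frame overlay),
morphology snapshots (process tips and lengths), and a contact log of
CONNECT/DISCONNECT events against neuron somata. All coordinates live in a
2D plane (the imaging volume is collapsed axially upstream), in µm; all
times are minutes relative to stimulation onset, so the session spans
[−20, 80] min under the default 20-60-20 paradigm. Image-domain steps
(deconvolution, motion correction, ROI drawing) are out of scope.

## Stimulation bookkeeping

The paradigm defaults to 10 Hz, 10 µA, 200 µs/phase biphasic pulses;
charge per phase is amplitude × pulse width (2 nC at the defaults) and is
checked against the 4 nC/phase biocompatibility bound. Session phases are
Pre [−20, 0), Early [0, 20), Mid [20, 40), Late [40, 60) and Post [60, 80];
interval edges are half-open on the left with Post closed at the session
end so the phases partition the session exactly. Distances from the
electrode bin at <150 µm (near), 150–300 µm inclusive (mid), >300 µm (far);
both printed boundaries belong to the middle bin, matching the interval
notation, and the 300 µm edge is a convention, not a fact about the method.

## Calcium pipeline

Per timepoint, Z-planes collapse by maximum so somata partially outside the
stack keep full brightness. Photobleaching is fitted as an ordinary
least-squares line through the *field-of-view* average signal at
non-stimulation timepoints (baseline + post); each neuron is then corrected
multiplicatively, F·model(t₀)/model(t), which is exact when bleaching acts
as a shared multiplicative gain and preserves ΔF/F₀ under detector-gain
changes. A subtractive mode exists behind `bleach_mode="subtractive"` for
data where bleaching is additive; the multiplicative form is the default
because every downstream rule is scale-free. When no field trace is
available the pipeline falls back to the mean of the neuron traces — note
this is biased if many neurons are truly depressed post-stimulation (in a
1200-neuron synthetic check the fallback over-estimated the bleach slope by
~50%, the field fit by <1%).

Baseline statistics use the 10 samples in [−20, 0): F₀ is their mean and
σ the SD (ddof 1) of baseline ΔF/F₀. A constant baseline (σ = 0) is flagged
degenerate and the neuron reports `unclassified` rather than a forced
label. All thresholds are strict where the rule says "exceeded"; boundary
equalities follow the rule text (≤ for band memberships). The during-
stimulation precedence — non-adapting, depressed, baseline adapting,
adapting — is fixed and recorded here because the four criteria are not
mutually exclusive for every conceivable trace (a mostly-supra-threshold
trace can also satisfy a mean rule); precedence makes the classifier total
and deterministic. The "adapting" interval is read in baseline-σ units
(1σ < m ≤ 3σ); a θ-unit alternative is available via
`ClassifierThresholds(adapting_in_theta_units=True)` since the phrase
"standard deviations of the activation threshold" admits both readings.
Post-stimulation means falling between the depressed (< −1.5σ) and baseline
(|m| ≤ 0.5σ) bands stay `unclassified`.

### Precision limits of the short baseline

With only ten baseline samples, σ̂ carries χ²₉ noise (relative SD ≈ 0.24)
and F̂₀ an error of σ/√10, which propagates into every σ-unit rule. In
synthetic populations this costs several percentage points of label
agreement relative to classification with the generator's true σ and F₀
(the examples print both paths). This is a property of the printed
procedure, not of the implementation; analyses needing per-neuron
certainty should lengthen the baseline or pool σ estimates.

## Motility, D/T indices, polarity

Movement speed is tip displacement over the 4.32 min (two-frame) overlay
interval. Cumulative motility sums events per cell over four consecutive
5 min intervals; totals are conserved for any partition of the same
window. For D/T indices a process is toward the target when the angle
between (tip − soma) and (target − soma) is below 90°, away above, and a
process exactly perpendicular counts for neither side; a cell whose only
processes are ties reports undefined indices rather than 1, distinguishing
"balanced" from "no data". When one side is empty the longest length on
that side is 0, driving T to its 0 or 2 endpoint.

The angular density uses the Epanechnikov kernel on the compact support
[0°, 180°] with reflection at both boundaries and renormalization on the
grid. The KDE runs directly on the angle samples (the equivalent of
fitting a histogram's PDF, without the arbitrary bin width). Bandwidth
defaults to Silverman's rule rescaled for the Epanechnikov kernel
(h = 2.345·σ̂·n^(−1/5)), clamped to [5°, 45°] so repeated angles cannot
produce degenerate spikes and tiny cells cannot oversmooth; any fixed
bandwidth can be passed instead (the endpoint checks use 30°). AUCs are
trapezoidal on a fixed 0.5° grid (the 90° split point is a grid node);
integration error is orders of magnitude below reported precision. Cells
with fewer than four movements are excluded from polarity, mirroring the
exclusion used for sparse, volume-truncated cells. ρ is exactly +1/−1 when
the smoothed density lies entirely on one side of 90°; kernels centered
within one bandwidth of 90° leak mass across the split, so "all toward"
cells with angles near 90° score slightly below +1 — the sign is still
guaranteed.

## Interactions

A contact is a CONNECT event; DISCONNECTs only close an open contact.
Validation reports (never raises) alternation violations per
(microglia, neuron) pair. Contacts per neuron divide CONNECT counts by all
labeled neurons of a profile — including neurons never approached — with
SEM across neurons; profiles with no neurons are omitted. Nearness of a
movement to a neuron is tip-end to soma-center distance, 20 µm inclusive,
with soma extent not modeled and nearest-soma ties broken by smallest id.

## Synthetic sessions

The generator emulates one Day-0 session: 458 neurons (profile mix from
first-day field composition — 6.3% depressed, 41.7% baseline adapting,
19.2% adapting, 5.9% non-adapting, 26.9% non-activated of which roughly a
fifth depressed), 39 microglia producing Poisson event counts of ≈6.34 per
cell per 20-min window with extension fraction 0.529, truncated-normal
speeds (0.73/0.78 ± 0.15 µm/min), angular toward-bias by distance bin
(0.61/0.47/0.39), and per-profile contact rates (0.75/0.29/0.25/0.18
contacts per neuron; the non-activated rates of 0.10/0.30 are this
package's choice — no field calibration exists for them). Times are a
uniform 2.16 min grid: 10 baseline, 28 stimulation and 9 post samples.

Calcium templates are σ-unit shapes: sustained 5σ (non-adapting); 2σ
plateau with a 6σ onset decaying at 1.5/sample (adapting, stim mean
≈ 2.18σ); 5σ onset decaying to 0 (baseline adapting, mean ≈ 0.23σ); 5σ for
two samples then −3.5σ (depressed, mean ≈ −2.9σ); flat 0 and flat −3.5σ
for the non-activated pair. The depressed plateau was set at −3.5σ
specifically so the stim-window mean clears the −1.5σ rule boundary by
≥ 1σ — a shallower plateau puts the mean on or near the boundary, making
even noise-free labels ambiguous. Raw fluorescence is
F₀·(1 + ΔF/F₀)·(1 + slope·t) with i.i.d. Gaussian ΔF/F₀ noise (σ = 0.05
serves as both template scale and noise SD — the classifier is scale-free,
so only the ratio structure matters), slope −0.001/min, and per-neuron F₀
jittered ±30% around 100 a.u. A separate FOV field trace carries the bleach
trend for fitting. One root seed spawns fixed-order substreams (neurons,
movements, contacts, field), so regenerating one stage never reshuffles
another and identical seeds give identical tables.

What the generator does **not** emulate: temporally correlated calcium
noise and indicator kinetics, soma extent and occlusion, process-tip
trajectories between overlay frames (only endpoints are drawn), day-to-day
progression (per-day values are alternative presets, not a mechanism), and
any feedback between neuronal state and microglial movement. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated statistical structure, not biological fidelity of that
structure.

## Problem sizes and tolerances

Recovery suites use 200 entities per condition (neurons per template,
cells per bias level, neurons per contact-rate profile) — enough for
binomial/Poisson 2-SEM checks while keeping the full suite around a few
seconds. Determinism checks compare full tables for equality; numerical
checks use 1e-6 for normalization/endpoint identities and 1e-9 for
oracle-vs-implementation equivalence. The KDE grid step (0.5°), bandwidth
clamp and tie conventions above are the only numerical free choices; all
are configurable at the API surface.
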