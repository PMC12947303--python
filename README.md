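# stimglia

Quantification of microglia–neuron dynamics during intracortical
microstimulation (ICMS) from two-photon imaging sessions, starting at the
trace/event level: neuron calcium traces, microglial process-movement
events, morphology snapshots and soma-contact logs.

Microglia — the brain's resident immune cells — continuously survey cortical
tissue with motile processes, and implanted stimulating microelectrodes
perturb both that surveillance and nearby neuronal activity. This package
implements the quantitative core of such an experiment for analysts working
with curated event tables: given a stimulation session (20 min baseline,
60 min of 10 Hz / 10 µA / 200 µs biphasic stimulation, 20 min rest), it
classifies each neuron's calcium adaptation profile, measures how fast and
in which directions microglial processes move relative to the electrode,
and relates microglia–neuron contacts to the neurons' activation profiles.

## Methods at its core

**Calcium adaptation profiles.** Fluorescence is max-collapsed per Z-stack,
corrected for photobleaching with a linear model fitted on non-stimulation
samples of the field-of-view signal, and expressed as ΔF/F₀ with F₀ the
mean over the 20 min baseline. With σ the SD of baseline ΔF/F₀ and
θ = 3σ the activation threshold, a neuron is *activated* if ΔF/F₀ > θ at
any stimulation sample, then classified by precedence: *non-adapting*
(more than half of stimulation samples above θ), *depressed*
(mean stim ΔF/F₀ < −0.5θ), *baseline adapting* (|mean| ≤ 1σ), *adapting*
(1σ < mean ≤ 3σ). Non-activated neurons split into *depressed*
(mean < −0.5θ) and plain. Post-stimulation activity is *depressed*
(mean < −0.5θ) or *baseline* (|mean| ≤ 0.5σ).

**Motility and directionality.** Process movements are extension/retraction
events on overlays 4.32 min (two frames) apart; speed = tip displacement /
interval. Per cell, static orientation indices use the processes split at
90° relative to the electrode (judged from the soma):

    D = (f − n)/(f + n) + 1,   f, n = number of processes away / toward
    T = (f − n)/(f + n) + 1,   f, n = longest process length away / toward

both in [0, 2] (0 = fully toward, 1 = balanced, 2 = fully away).

**Polarity index.** Movement angles relative to the electrode (0° = toward)
are smoothed with an Epanechnikov kernel K(u) = 0.75(1 − u²), |u| ≤ 1, with
reflection at 0° and 180°; with t and a the areas under the density on
[0°, 90°] and [90°, 180°],

    ρ = (t − a)/(t + a) ∈ [−1, 1].

Cells with fewer than four measurable movements are excluded.

**Interactions.** Contact logs alternate CONNECT/DISCONNECT per
(microglia, neuron) pair; contacts per neuron are reported per adaptation
profile, and contact timing is mapped to peri-stimulation phases
(Pre/Early/Mid/Late/Post) and 1-min bins. Movements within 20 µm of a soma
count as near that neuron.

**Synthetic sessions.** `stimglia.synthetic` generates complete sessions
with ground truth: σ-unit calcium templates per profile (margins ≥ 1σ from
every decision boundary, so noise-free classification is exact), Poisson
movement counts with distance-dependent angular bias and truncated-normal
speeds (extensions 0.73, retractions 0.78 µm/min), and per-profile Poisson
contact rates (0.75 / 0.29 / 0.25 / 0.18 contacts per neuron for depressed /
baseline adapting / adapting / non-adapting neurons).

## Worked example

```sh
$ stimglia simulate --seed 7 --out session/ --n-neurons 120 --n-microglia 15
$ stimglia report session/ --out results/
```

or from Python (see `examples/` for one narrative script per capability):

```python
>>> from stimglia import GeneratorConfig, generate_movements, movement_angle, polarity_index
>>> from stimglia.motility import motility_counts
>>> cfg = GeneratorConfig(seed=3, n_microglia=30)
>>> events, snapshots, truth = generate_movements(cfg)
>>> s = motility_counts(events)
```

Running `examples/03_motility_and_polarity.py` prints:

```
events: 533 extensions / 456 retractions (ratio 1.169)
mean speeds: ext 0.73, retr 0.78 µm/min

per-cell polarity (first 6 cells):
  m000 [near] n= 35  rho = +0.215
  m001 [ mid] n= 26  rho = +0.167
  m002 [near] n= 34  rho = +0.307
  m003 [ far] n= 31  rho = -0.219
```

The extension/retraction ratio slightly above 1 and speeds near 0.73 / 0.78
µm/min reflect the generator's calibration; cells in the near bin
(< 150 µm from the electrode) lean toward positive ρ (processes biased
toward the electrode) while far cells (> 300 µm) lean negative.

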