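import numpy as np
import pandas as pd
import pytest

from stimglia.calcium import BaselineStats, classify_stim_profile, compute_dff
from stimglia.geometry import Point, euclidean_distance, movement_angle
from stimglia.interactions import contacts_per_neuron, validate_contact_log
from stimglia.io import movements_to_frame, traces_to_frame
from stimglia.motility import movement_speed, polarity_index
from stimglia.synthetic import (
    GeneratorConfig,
    generate_contacts,
    generate_movements,
    generate_neurons,
    generate_session,
    template_dff_sigma,
)

PROFILES = [
    "non_adapting",
    "adapting",
    "baseline_adapting",
    "depressed",
    "non_activated",
    "non_activated_depressed",
]
EQUAL_MIX = {p: 1 / len(PROFILES) for p in PROFILES}


class TestDeterminism:
    def test_same_seed_identical_tables(self):
        a = generate_session(GeneratorConfig(seed=9, n_neurons=20, n_microglia=5))
        b = generate_session(GeneratorConfig(seed=9, n_neurons=20, n_microglia=5))
        pd.testing.assert_frame_equal(traces_to_frame(a.traces), traces_to_frame(b.traces))
        pd.testing.assert_frame_equal(
            movements_to_frame(a.movements), movements_to_frame(b.movements)
        )
        assert [(c.t_min, c.kind) for c in a.contacts] == [
            (c.t_min, c.kind) for c in b.contacts
        ]

    def test_different_seed_differs(self):
        a = generate_session(GeneratorConfig(seed=1, n_neurons=10, n_microglia=3))
        b = generate_session(GeneratorConfig(seed=2, n_neurons=10, n_microglia=3))
        assert not traces_to_frame(a.traces).equals(traces_to_frame(b.traces))


class TestNeuronGeneration:
    def test_invalid_mix_rejected(self):
        mix = dict(EQUAL_MIX)
        mix["adapting"] += 0.1
        with pytest.raises(ValueError):
            GeneratorConfig(profile_mix=mix)

    def test_noise_free_templates_classify_exactly(self):
        """With zero noise and bleach, every template hits its intended label
        (the templates keep ≥1σ margin from every decision boundary)."""
        cfg = GeneratorConfig(
            seed=3, n_neurons=120, profile_mix=EQUAL_MIX,
            noise_on=False, bleach_slope_frac_per_min=0.0,
        )
        traces, truth = generate_neurons(cfg)
        t = traces[0].times
        stim_mask = (t >= 0) & (t < cfg.stim_duration_min)
        truth = truth.set_index("neuron_id")
        for tr in traces:
            stats = BaselineStats(F0=float(truth.loc[tr.neuron_id, "F0"]), sigma=cfg.sigma)
            dff = compute_dff(tr, stats)
            got = classify_stim_profile(dff, stats, stim_mask)
            assert got.value == truth.loc[tr.neuron_id, "profile"]

    def test_realized_proportions_binomial(self):
        """Realized template counts stay within 3 binomial SDs of the mix."""
        mix = {p: 0.25 for p in PROFILES[:4]}
        cfg = GeneratorConfig(seed=5, n_neurons=1000, profile_mix=mix)
        _, truth = generate_neurons(cfg)
        counts = truth["profile"].value_counts()
        for p, frac in mix.items():
            sd = np.sqrt(1000 * frac * (1 - frac))
            assert abs(counts.get(p, 0) - 1000 * frac) <= 3 * sd

    def test_template_margins(self):
        """Every activated template's stim mean sits ≥1σ from the mean-rule
        boundaries (−1.5σ, ±1σ, 3σ)."""
        stim_means = {
            p: template_dff_sigma(p, 28, 9)[0].mean() for p in PROFILES
        }
        assert stim_means["adapting"] > 2.0 and stim_means["adapting"] <= 3.0 - 0.8
        assert abs(stim_means["baseline_adapting"]) <= 1.0 - 0.7
        assert stim_means["depressed"] <= -1.5 - 1.0
        assert stim_means["non_activated_depressed"] <= -1.5 - 1.0


class TestMovementGeneration:
    def test_speed_calibration(self):
        """Generated extension speeds recover the 0.73 µm/min mean within 2 SE."""
        cfg = GeneratorConfig(seed=8, n_microglia=60)
        events, _, _ = generate_movements(cfg)
        ext = [movement_speed(m) for m in events if m.kind.value == "extension"]
        assert len(ext) >= 500
        se = np.std(ext, ddof=1) / np.sqrt(len(ext))
        assert abs(np.mean(ext) - 0.73) <= 2 * se + 1e-9

    def test_angles_respect_bias(self):
        """p_toward = 1 gives every cell strictly positive ρ (each kernel is
        centered below 90°, so the toward-side AUC always dominates), and the
        recovered angles all lie in the toward half."""
        cfg = GeneratorConfig(
            seed=4, n_microglia=6, p_toward={"near": 1.0, "mid": 1.0, "far": 1.0}
        )
        events, _, _ = generate_movements(cfg)
        by_cell = {}
        for m in events:
            ang = movement_angle(m.tip_start, m.tip_end, cfg.electrode)
            assert ang < 90.0
            by_cell.setdefault(m.microglia_id, []).append(ang)
        for angles in by_cell.values():
            if len(angles) >= 4:
                assert polarity_index(angles, 30.0).rho > 0.0

    def test_unbiased_cells_average_zero(self):
        cfg = GeneratorConfig(
            seed=6, n_microglia=100, p_toward={"near": 0.5, "mid": 0.5, "far": 0.5}
        )
        events, _, _ = generate_movements(cfg)
        by_cell = {}
        for m in events:
            by_cell.setdefault(m.microglia_id, []).append(
                movement_angle(m.tip_start, m.tip_end, cfg.electrode)
            )
        rhos = [
            polarity_index(a, 30.0).rho for a in by_cell.values() if len(a) >= 4
        ]
        se = np.std(rhos, ddof=1) / np.sqrt(len(rhos))
        assert abs(np.mean(rhos)) <= 2 * se + 0.02

    def test_movement_geometry_consistent(self):
        """Stored tip coordinates reproduce the drawn speed and angle ranges."""
        cfg = GeneratorConfig(seed=7, n_microglia=5)
        events, snapshots, truth = generate_movements(cfg)
        for m in events[:200]:
            assert movement_speed(m) > 0
            ang = movement_angle(m.tip_start, m.tip_end, cfg.electrode)
            assert 0.0 <= ang <= 180.0
        assert len(snapshots) == 5
        assert set(truth["distance_bin"]).issubset({"near", "mid", "far"})


class TestContactGeneration:
    def test_zero_rate_profile(self):
        cfg = GeneratorConfig(seed=1, contact_rates={p: 0.0 for p in PROFILES})
        truth = pd.DataFrame(
            {"neuron_id": ["n0", "n1"], "profile": ["depressed", "adapting"]}
        )
        assert generate_contacts(cfg, truth) == []

    def test_log_always_legal(self, small_session):
        assert validate_contact_log(small_session.contacts) == []

    def test_rate_recovery(self):
        """Poisson generation at the calibrated per-profile rates is recovered
        by the contact-rate estimator within 2 SEM."""
        rates = {"depressed": 0.75, "baseline_adapting": 0.29,
                 "adapting": 0.25, "non_adapting": 0.18}
        n_per = 200
        rows = []
        for p in rates:
            rows += [{"neuron_id": f"{p}_{i}", "profile": p} for i in range(n_per)]
        truth = pd.DataFrame(rows)
        cfg = GeneratorConfig(seed=12, contact_rates={**rates, "non_activated": 0,
                                                      "non_activated_depressed": 0})
        from stimglia.calcium import StimProfile

        events = generate_contacts(cfg, truth)
        labels = {r["neuron_id"]: StimProfile(r["profile"]) for r in rows}
        df = contacts_per_neuron(events, labels).set_index("profile")
        for p, rate in rates.items():
            got = df.loc[p, "contacts_per_neuron"]
            sem = df.loc[p, "sem"]
            assert abs(got - rate) <= 2 * sem


class TestSessionClosure:
    def test_truth_tables_align(self, small_session):
        s = small_session
        assert len(s.truth_neurons) == len(s.traces) == 80
        assert len(s.truth_microglia) == len(s.snapshots) == 12
        assert s.field_trace is not None
        nids = {tr.neuron_id for tr in s.traces}
        assert set(s.truth_neurons["neuron_id"]) == nids
        assert all(c.neuron_id in nids for c in s.contacts)

    def test_distances_derived_not_assigned(self, small_session):
        s = small_session
        for _, row in s.truth_microglia.iterrows():
            d = euclidean_distance(
                Point(row["x_um"], row["y_um"]), s.config.electrode
            )
            assert d == pytest.approx(row["distance_um"])
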