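import numpy as np
import pytest

from stimglia.calcium import (
    BaselineStats,
    CalciumTrace,
    ClassifierThresholds,
    InsufficientDataError,
    PostStimProfile,
    StimProfile,
    baseline_stats,
    classify_post_stim_profile,
    classify_stim_profile,
    collapse_stack_max,
    compute_dff,
    correct_bleach,
    fit_bleach_model,
    is_activated,
)
from stimglia.geometry import Point, StimulationParadigm

PARADIGM = StimulationParadigm()
SOMA = Point(0.0, 0.0)


def make_trace(F, times=None):
    F = np.asarray(F, dtype=float)
    if times is None:
        times = -20.0 + 2.16 * np.arange(F.size)
    return CalciumTrace("n0", SOMA, times, F)


class TestCollapse:
    @pytest.mark.parametrize(
        "planes, expected",
        [([[3, 7, 5]], [7]), ([[4]], [4]), ([[0, 0, 0]], [0]), ([[1, 2], [5, 3]], [2, 5])],
    )
    def test_max_per_timepoint(self, planes, expected):
        assert collapse_stack_max(planes).tolist() == expected

    def test_empty_plane_set(self):
        with pytest.raises(ValueError):
            collapse_stack_max([[]])


class TestBleachFit:
    def test_constant_signal(self):
        t = np.arange(0, 40, 2.0)
        m = fit_bleach_model(np.full(t.size, 100.0), t, np.zeros(t.size, bool))
        assert m.slope == pytest.approx(0.0, abs=1e-12)
        assert m.intercept == pytest.approx(100.0)

    def test_exact_line(self):
        t = np.arange(0, 80, 2.0)
        m = fit_bleach_model(100 - 0.1 * t, t, np.zeros(t.size, bool))
        assert m.slope == pytest.approx(-0.1)

    def test_stim_samples_have_zero_influence(self):
        """Offset stimulation samples must not move the fit; oracle is the
        closed-form least-squares line on the unmasked samples alone."""
        rng = np.random.default_rng(7)
        t = -20 + 2.16 * np.arange(37)
        mask = (t >= 0) & (t < 60)
        F = 100 - 0.05 * t + rng.normal(0, 1, t.size)
        F_off = F.copy()
        F_off[mask] += 50.0
        m = fit_bleach_model(F_off, t, mask)
        slope_oracle, intercept_oracle = np.polyfit(t[~mask], F[~mask], 1)
        assert m.slope == pytest.approx(slope_oracle, abs=1e-12)
        assert m.intercept == pytest.approx(intercept_oracle, abs=1e-9)
        assert m.slope == pytest.approx(-0.05, abs=0.03)

    def test_insufficient_samples(self):
        t = np.arange(4.0)
        with pytest.raises(InsufficientDataError):
            fit_bleach_model(np.ones(4), t, np.array([0, 1, 1, 0], bool))


class TestBleachCorrection:
    def test_zero_slope_identity(self):
        tr = make_trace(np.linspace(90, 110, 47))
        from stimglia.calcium import BleachModel

        out = correct_bleach(tr, BleachModel(0.0, 100.0))
        np.testing.assert_allclose(out.F, tr.F)

    def test_analytic_division(self):
        from stimglia.calcium import BleachModel

        t = -20 + 2.16 * np.arange(47)
        F = 100.0 * (1 - 0.001 * t)
        out = correct_bleach(make_trace(F, t), BleachModel(-0.1, 100.0))
        np.testing.assert_allclose(out.F, F[0], rtol=1e-12)

    def test_refit_slope_vanishes(self):
        """Correcting an exact linear bleach then refitting gives slope ~0."""
        t = -20 + 2.16 * np.arange(47)
        F = 100.0 * (1 - 0.001 * t)
        m = fit_bleach_model(F, t, np.zeros(t.size, bool))
        out = correct_bleach(make_trace(F, t), m)
        m2 = fit_bleach_model(out.F, t, np.zeros(t.size, bool))
        assert abs(m2.slope) < 1e-6

    def test_model_crossing_zero_rejected(self):
        from stimglia.calcium import BleachModel

        tr = make_trace(np.full(47, 100.0))
        with pytest.raises(ValueError):
            correct_bleach(tr, BleachModel(-2.0, 100.0))

    def test_subtractive_mode(self):
        from stimglia.calcium import BleachModel

        t = -20 + 2.16 * np.arange(47)
        F = 100.0 - 0.1 * (t - t[0])
        out = correct_bleach(make_trace(F, t), BleachModel(-0.1, 100 - 0.1 * 20), "subtractive")
        np.testing.assert_allclose(out.F, 100.0, rtol=1e-12)


class TestBaselineStats:
    def test_mean(self):
        F = np.concatenate([np.tile([99, 100, 101], 3), [100] * 38])
        st = baseline_stats(make_trace(F[:47]), PARADIGM)
        assert st.F0 == pytest.approx(100.0)

    def test_degenerate_flag(self):
        st = baseline_stats(make_trace(np.full(47, 100.0)), PARADIGM)
        assert st.degenerate and st.sigma == 0.0

    def test_sigma_recovers_generator_sd(self):
        """σ̂ equals the sample-SD oracle per trace, and its average over many
        N(100, 5) baselines matches the unbiased expectation c₄·0.05."""
        from math import gamma, sqrt

        rng = np.random.default_rng(3)
        sigmas = []
        for _ in range(200):
            base = rng.normal(100, 5, 10)
            F = np.concatenate([base, np.full(37, 100.0)])
            st = baseline_stats(make_trace(F), PARADIGM)
            oracle = base.std(ddof=1) / base.mean()
            assert st.sigma == pytest.approx(oracle, rel=1e-12)
            sigmas.append(st.sigma)
        c4 = sqrt(2 / 9) * gamma(5.0) / gamma(4.5)  # E[s]/σ at n=10
        expected = 0.05 * c4
        se = np.std(sigmas, ddof=1) / np.sqrt(len(sigmas))
        assert abs(np.mean(sigmas) - expected) <= 3 * se

    def test_too_few_baseline_samples(self):
        with pytest.raises(InsufficientDataError):
            baseline_stats(make_trace(np.ones(5), times=np.arange(5.0)), PARADIGM)


class TestDff:
    def test_values(self):
        st = BaselineStats(100.0, 0.05)
        tr = make_trace(np.full(47, 100.0))
        assert compute_dff(tr, st)[0] == 0.0
        tr2 = make_trace(np.full(47, 150.0))
        assert compute_dff(tr2, st)[0] == pytest.approx(0.5)

    def test_gain_invariance(self):
        """Multiplying raw F by a gain (with recomputed F0) leaves ΔF/F₀ unchanged."""
        rng = np.random.default_rng(1)
        F = rng.uniform(90, 110, 47)
        tr = make_trace(F)
        st = baseline_stats(tr, PARADIGM)
        tr_g = make_trace(3.7 * F)
        st_g = baseline_stats(tr_g, PARADIGM)
        np.testing.assert_allclose(
            compute_dff(tr, st), compute_dff(tr_g, st_g), atol=1e-12
        )
        assert st_g.sigma == pytest.approx(st.sigma, rel=1e-9)


class TestActivation:
    STATS = BaselineStats(100.0, 0.05)

    def stim_mask(self, n=47):
        t = -20 + 2.16 * np.arange(n)
        return (t >= 0) & (t < 60)

    @pytest.mark.parametrize("peak_sigma, expected", [(3.5, True), (2.9, False), (3.0, False)])
    def test_threshold_strict(self, peak_sigma, expected):
        dff = np.zeros(47)
        dff[20] = peak_sigma * self.STATS.sigma
        assert is_activated(dff, self.STATS, self.stim_mask()) is expected


class TestStimProfileRules:
    STATS = BaselineStats(100.0, 0.05)

    def classify(self, stim_sigma):
        dff = np.zeros(47)
        mask = np.zeros(47, bool)
        mask[10:38] = True
        dff[mask] = np.asarray(stim_sigma) * self.STATS.sigma
        return classify_stim_profile(dff, self.STATS, mask)

    def test_non_adapting(self):
        assert self.classify(np.full(28, 5.0)) is StimProfile.NON_ADAPTING

    def test_depressed_after_activation(self):
        vals = np.full(28, -2.0)
        vals[:2] = 4.0  # mean −1.57σ < −1.5σ
        assert self.classify(vals) is StimProfile.DEPRESSED

    def test_baseline_adapting(self):
        vals = np.zeros(28)
        vals[0] = 4.0  # mean ≈ 0.14σ
        assert self.classify(vals) is StimProfile.BASELINE_ADAPTING

    def test_adapting(self):
        vals = np.full(28, 2.0)
        vals[0] = 4.0
        assert self.classify(vals) is StimProfile.ADAPTING

    def test_non_activated(self):
        assert self.classify(np.full(28, 1.0)) is StimProfile.NON_ACTIVATED

    def test_non_activated_depressed(self):
        assert self.classify(np.full(28, -2.0)) is StimProfile.NON_ACTIVATED_DEPRESSED

    def test_activated_gap_unclassified(self):
        vals = np.full(28, 4.0)  # activated, >3σ mean but not >half above θ?
        # exactly half above θ: 14 samples at 5σ, 14 at 3.5σ → all above θ actually
        vals = np.concatenate([np.full(14, 5.0), np.full(14, 2.9)])
        # half above θ is not "more than half" → falls through to mean rules:
        # mean = 3.95σ > 3σ → UNCLASSIFIED
        assert self.classify(vals) is StimProfile.UNCLASSIFIED

    def test_degenerate_baseline(self):
        st = BaselineStats(100.0, 0.0, degenerate=True)
        mask = np.ones(10, bool)
        assert classify_stim_profile(np.ones(10), st, mask) is StimProfile.UNCLASSIFIED

    def test_precedence_non_adapting_over_depressed(self):
        """A trace satisfying both the >half-above-θ and mean rules takes the
        first rule in the documented precedence."""
        vals = np.concatenate([np.full(20, 5.0), np.full(8, -20.0)])
        assert np.mean(vals) < -1.5
        assert self.classify(vals) is StimProfile.NON_ADAPTING


class TestPostProfile:
    STATS = BaselineStats(100.0, 0.05)

    def classify(self, m_sigma):
        dff = np.full(9, m_sigma * self.STATS.sigma)
        return classify_post_stim_profile(dff, self.STATS, np.ones(9, bool))

    @pytest.mark.parametrize(
        "m, expected",
        [
            (-2.0, PostStimProfile.DEPRESSED),
            (0.0, PostStimProfile.BASELINE),
            (0.5, PostStimProfile.BASELINE),
            (-1.0, PostStimProfile.UNCLASSIFIED),
            (0.8, PostStimProfile.UNCLASSIFIED),
        ],
    )
    def test_rules(self, m, expected):
        assert self.classify(m) is expected

    def test_no_post_samples(self):
        with pytest.raises(InsufficientDataError):
            classify_post_stim_profile(np.ones(5), self.STATS, np.zeros(5, bool))


class TestThresholdConfig:
    def test_adapting_in_theta_units_alternative(self):
        """The alternative reading (interval in multiples of θ = 3σ) widens
        the adapting band."""
        stats = BaselineStats(100.0, 0.05)
        mask = np.ones(28, bool)
        dff = np.full(28, 5.0 * stats.sigma)
        dff[1:] = 2.0 * stats.sigma  # mean ≈ 2.1σ, activated once
        th = ClassifierThresholds(adapting_in_theta_units=True)
        # 2.1σ = 0.7θ ≤ 1θ → baseline-adapting under θ-units reading
        assert classify_stim_profile(dff, stats, mask, th) is StimProfile.BASELINE_ADAPTING
        assert classify_stim_profile(dff, stats, mask) is StimProfile.ADAPTING
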