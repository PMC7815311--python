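"""AMUA chain, spike detection, tuning curves and the STVR statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import f_oneway, norm

from itdlab.neuro_sim import RecordingBlock, TuningFunction, make_trial_schedule, simulate_recording
from itdlab.neurometrics import (
    AMUAConfig,
    AnalysisWindows,
    ResponseMatrix,
    build_response_matrix,
    compute_amua,
    compute_stvr,
    detect_spikes,
    stvr_null_distribution,
    tuning_curve,
)

FS = 24414.0625


def _stvr_brute_force(groups):
    """Explicit two-pass double-loop ANOVA oracle."""
    allv = [x for g in groups for x in g]
    grand = sum(allv) / len(allv)
    ss_total = sum((x - grand) ** 2 for x in allv)
    ss_group = 0.0
    for g in groups:
        m = sum(g) / len(g)
        ss_group += len(g) * (m - grand) ** 2
    return ss_group / ss_total


class TestAMUA:
    def test_zero_trace_gives_zero(self):
        out = compute_amua(np.zeros(5000), FS)
        assert np.allclose(out, 0.0)

    def test_homogeneity_under_scaling(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20000)
        a = compute_amua(x, FS)
        b = compute_amua(3.5 * x, FS)
        assert np.allclose(b, 3.5 * a, rtol=1e-10, atol=1e-12)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="warm-up"):
            compute_amua(np.zeros(10), FS)

    def test_nyquist_clipping_warns(self):
        rng = np.random.default_rng(2)
        with pytest.warns(RuntimeWarning, match="Nyquist"):
            compute_amua(rng.normal(size=5000), 10000.0)

    def test_amua_tracks_spike_rate(self):
        """Mean AMUA is larger for a 100 Hz than a 10 Hz spiketrain (20/20 seeds)."""
        from itdlab.neuro_sim import spike_template

        template = spike_template(FS) * 8.0
        n = int(FS)  # 1 s
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            means = []
            for rate in (10.0, 100.0):
                trace = rng.normal(size=n)
                idx = rng.integers(0, n - template.size, rng.poisson(rate))
                for i in idx:
                    trace[i : i + template.size] += template
                means.append(compute_amua(trace, FS).mean())
            wins += means[1] > means[0]
        assert wins == 20


class TestDetectSpikes:
    def test_implanted_spike_detected(self):
        rng = np.random.default_rng(3)
        trace = rng.normal(0, 1.0, int(FS))
        from itdlab.neuro_sim import spike_template

        t_spike = 0.5
        i = int(t_spike * FS)
        w = spike_template(FS) * 30.0
        trace[i : i + w.size] += w
        times = detect_spikes(trace, FS, k_sd=10.0)
        assert times.size == 1
        assert abs(times[0] - t_spike) < 0.5e-3 + w.size / FS

    def test_noise_false_positive_rate_matches_gaussian_tail(self):
        """FP rate per sample on band-passed noise is on the 2(1-Phi(4)) order."""
        rng = np.random.default_rng(4)
        trace = rng.normal(size=int(20 * FS))
        times = detect_spikes(trace, FS, k_sd=4.0, refractory_ms=0.0)
        rate = times.size / trace.size
        expected = 2 * (1 - norm.cdf(4.0))  # 6.3e-5 per sample, before clustering
        assert expected / 5 < rate < expected * 5

    def test_high_threshold_detects_nothing(self):
        rng = np.random.default_rng(5)
        assert detect_spikes(rng.normal(size=int(FS)), FS, k_sd=50.0).size == 0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            detect_spikes(np.zeros(int(FS)), FS)


class TestResponseMatrix:
    def test_shape_and_blanking(self, small_recording):
        m = build_response_matrix(small_recording)
        assert m.values.shape == (5, 5)
        # blank (2.5 ms) lies before the 3 ms response start: window unchanged
        assert AnalysisWindows().effective_response_ms == (3.0, 80.0)
        assert AnalysisWindows(artifact_blank_ms=5.0).effective_response_ms == (5.0, 80.0)

    def test_spike_count_equals_direct_window_count(self, small_recording):
        rec = small_recording
        m = build_response_matrix(
            rec, measure="spike_count", spike_times_s=rec.ground_truth_spikes_s
        )
        t = rec.ground_truth_spikes_s
        for i, lv in enumerate(m.itd_levels_us):
            events = rec.event_times_s[rec.itd_labels_us == lv]
            expected = [
                np.sum((t >= e + 0.003) & (t < e + 0.080)) for e in events
            ]
            assert list(m.values[i]) == pytest.approx(expected)

    def test_out_of_bounds_events_dropped_with_warning(self):
        rng = np.random.default_rng(6)
        trace = rng.normal(size=int(2.0 * FS))
        block = RecordingBlock(
            trace, FS, np.array([0.2, 0.7, 1.9]), np.array([0.0, 50.0, 0.0])
        )
        with pytest.warns(RuntimeWarning):
            m = build_response_matrix(block)
        assert m.values.size < 3

    def test_tuned_recording_produces_significant_stvr(self, full_recording):
        m = build_response_matrix(full_recording)
        assert m.values.shape == (17, 30)
        res = compute_stvr(m)
        assert res.df_between == 16
        assert res.df_within == 493
        assert res.significant
        assert res.stvr > 0.2


class TestTuningCurve:
    def _matrix(self, values, baselines=None):
        v = np.asarray(values, float)
        return ResponseMatrix(v, np.arange(v.shape[0], dtype=float), "amua_mean",
                              baselines if baselines is None else np.asarray(baselines, float))

    def test_flat_above_baseline_normalizes_to_one(self):
        m = self._matrix(np.full((4, 3), 5.0), np.full((4, 3), 1.0))
        tc = tuning_curve(m)
        assert np.allclose(tc["norm_mean"], 1.0)

    def test_single_responsive_level(self):
        vals = np.full((3, 4), 1.0)
        vals[1] = 9.0
        tc = tuning_curve(self._matrix(vals, np.full((3, 4), 1.0)))
        assert tc.loc[1, "norm_mean"] == pytest.approx(1.0)
        assert abs(tc.loc[0, "norm_mean"]) < 1e-9

    def test_sigmoid_tuning_peaks_on_saturating_side(self, full_recording):
        m = build_response_matrix(full_recording)
        tc = tuning_curve(m)
        assert tc["norm_mean"].max() == pytest.approx(1.0)
        # ground-truth sigmoid saturates toward positive ITD
        assert tc.loc[tc["norm_mean"].idxmax(), "itd_us"] > 0

    def test_all_below_baseline_flagged(self):
        m = self._matrix(np.full((3, 3), 1.0) + np.arange(3)[:, None] * 0.1,
                         np.full((3, 3), 10.0))
        with pytest.warns(RuntimeWarning, match="baseline"):
            tc = tuning_curve(m)
        assert tc.attrs["normalized_by_abs"]


class TestSTVR:
    def test_hand_anova_example(self):
        res = compute_stvr([np.array([0.0, 2.0]), np.array([4.0, 6.0])])
        assert res.stvr == pytest.approx(0.8)  # ss_group 16, ss_total 20
        assert res.ss_group == pytest.approx(16.0)
        assert res.ss_total == pytest.approx(20.0)

    def test_zero_within_variance_gives_one(self):
        res = compute_stvr([np.array([1.0, 1.0]), np.array([3.0, 3.0])])
        assert res.stvr == 1.0
        assert res.p_value == 0.0

    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            k = rng.integers(2, 8)
            groups = [rng.normal(rng.normal(), 1.0, rng.integers(2, 12)) for _ in range(k)]
            res = compute_stvr(groups)
            assert res.stvr == pytest.approx(_stvr_brute_force(groups), rel=1e-12)

    def test_f_and_p_match_scipy_anova(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(i * 0.3, 1.0, 15) for i in range(5)]
        res = compute_stvr(groups)
        ref = f_oneway(*groups)
        assert res.f_stat == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    @settings(deadline=None, max_examples=50)
    @given(
        a=st.floats(0.1, 50.0),
        b=st.floats(-100.0, 100.0),
        seed=st.integers(0, 1000),
    )
    def test_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(4, 6)) + rng.normal(size=(4, 1))
        m1 = ResponseMatrix(vals, np.arange(4.0), "amua_mean")
        m2 = ResponseMatrix(a * vals + b, np.arange(4.0), "amua_mean")
        r1, r2 = compute_stvr(m1), compute_stvr(m2)
        assert r1.stvr == pytest.approx(r2.stvr, rel=1e-9)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-6)

    def test_zero_total_variance_rejected(self):
        with pytest.raises(ValueError, match="zero total variance"):
            compute_stvr([np.ones(3), np.ones(3)])

    def test_degenerate_designs_rejected(self):
        with pytest.raises(ValueError):
            compute_stvr([np.array([1.0, 2.0])])


class TestSTVRNull:
    def _null_matrix(self, seed):
        rng = np.random.default_rng(seed)
        return ResponseMatrix(rng.normal(size=(17, 30)), np.arange(17.0), "amua_mean")

    def test_null_mean_matches_exchangeable_expectation(self):
        null = stvr_null_distribution(self._null_matrix(9), n_perm=2000, seed=1)
        assert null.null_stvr.mean() == pytest.approx(16 / 509, abs=0.004)

    def test_parametric_and_permutation_p_agree_on_null_data(self):
        for seed in (10, 11, 12):
            m = self._null_matrix(seed)
            par = compute_stvr(m).p_value
            perm = stvr_null_distribution(m, n_perm=2000, seed=0).permutation_p
            assert abs(par - perm) < 0.05

    def test_perfect_separation_minimal_p(self):
        vals = np.arange(12.0).reshape(4, 3) * 10 + np.random.default_rng(0).normal(size=(4, 3)) * 0.01
        m = ResponseMatrix(vals, np.arange(4.0), "amua_mean")
        null = stvr_null_distribution(m, n_perm=500, seed=2)
        assert null.permutation_p <= 1 / 501 + 1e-12

    def test_seed_determinism(self):
        m = self._null_matrix(13)
        a = stvr_null_distribution(m, n_perm=300, seed=4)
        b = stvr_null_distribution(m, n_perm=300, seed=4)
        assert np.array_equal(a.null_stvr, b.null_stvr)
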