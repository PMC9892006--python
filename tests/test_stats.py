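"""Syllable-dopamine statistics."""

import numpy as np
import pandas as pd
import pytest

from dopaseq import stats as st
from dopaseq.generate import make_generative_params, simulate_session



class TestExtractPeaks:
    def test_zero_trace_gives_zero_peaks(self, coupled_params):
        s = simulate_session(coupled_params, n_steps=50, seed=0, render=False)
        tab = st.extract_syllable_peaks(s, np.zeros(s.n_frames))
        assert np.all(tab["peak"] == 0.0)
        assert len(tab) == 50

    def test_window_excludes_late_transients(self, coupled_params):
        """A bump 400 ms (12 frames) after an onset is outside that
        instance's 10-frame window."""
        s = simulate_session(coupled_params, n_steps=5, seed=1, render=False)
        z = np.zeros(s.n_frames + 60)
        onset = int(s.onset_frames[0])
        z[onset + 12] = 5.0
        tab = st.extract_syllable_peaks(s, z[: s.n_frames])
        if s.onset_frames[1] - onset > 12:  # bump falls in the next instance
            assert tab["peak"].iloc[0] == 0.0

    def test_noiseless_session_rank_recovery(self):
        """Extracted peaks rank-correlate >= 0.95 with ground-truth amplitudes
        on a noiseless rendered session with resolvable transients."""
        from scipy.stats import spearmanr

        from dopaseq import photometry as ph

        p = make_generative_params(
            10, seed=3, syllable_da_mean=np.linspace(1.2, 3.0, 10),
            syllable_da_sd=np.full(10, 0.8), noise_sd=0.0, artifact_rate_hz=0.0,
            duration_median_ms=700, duration_dispersion=0.25)
        s = simulate_session(p, n_steps=600, seed=42)
        ph.preprocess(s.photometry)
        tab = st.extract_syllable_peaks(s, s.photometry.zscored)
        assert spearmanr(tab["peak"], s.da_amplitudes).statistic >= 0.95

    def test_session_zscore_column(self, coupled_params):
        s = simulate_session(coupled_params, n_steps=300, seed=2, render=False)
        tab = st.extract_syllable_peaks(s, np.sin(np.arange(s.n_frames) / 7.0))
        assert abs(tab["peak_z_session"].mean()) < 1e-9
        assert abs(tab["peak_z_session"].std(ddof=0) - 1.0) < 1e-9


class TestTimewarp:
    def test_target_length_input_unchanged(self):
        x = np.random.default_rng(0).standard_normal(25)
        out = st.timewarp_traces([x], 25)
        assert np.max(np.abs(out[0] - x)) < 1e-12

    def test_ramp_maps_to_ramp_with_endpoints(self):
        out = st.timewarp_traces([np.linspace(2, 7, 40)], 25)[0]
        assert np.allclose(out, np.linspace(2, 7, 25), atol=1e-12)

    def test_sinusoid_matches_interp_oracle(self):
        x = np.sin(np.linspace(0, 3 * np.pi, 50))
        out = st.timewarp_traces([x], 25)[0]
        oracle = np.interp(np.linspace(0, 1, 25), np.linspace(0, 1, 50), x)
        assert np.max(np.abs(out - oracle)) < 1e-6


class TestAlignedAverage:
    def test_null_events_within_band(self):
        rng = np.random.default_rng(0)
        trace = rng.standard_normal(40_000)
        events = rng.integers(400, 39_600, 40)
        z = st.aligned_average_z(trace, events, rate=30, n_shuffles=200, seed=1)
        assert np.mean(np.abs(z) < 2.0) >= 0.95

    def test_locked_events_exceed_shuffle_band(self):
        rng = np.random.default_rng(1)
        trace = 0.5 * rng.standard_normal(40_000)
        events = np.arange(600, 39_000, 700)
        kern = np.exp(-np.arange(30) / 5.0)
        for e in events:
            trace[e: e + 30] += 2.0 * kern
        z = st.aligned_average_z(trace, events, rate=30, n_shuffles=200, seed=2)
        assert z[300: 310].max() > 3.0  # lag 0..10 frames after onset

    def test_single_shuffle_rejected(self):
        with pytest.raises(ValueError):
            st.aligned_average_z(np.zeros(2000), [900, 1000], n_shuffles=1)


class TestTransitionEntropy:
    def test_uniform_nine_successors_is_ln9(self):
        labels = []
        for i in range(10):
            for j in range(10):
                if i != j:
                    labels += [i, j]
        M = np.ones((10, 10)) / 9
        np.fill_diagonal(M, 0)
        H = st.transition_entropy(M)
        assert np.allclose(H, np.log(9), atol=1e-12)

    def test_deterministic_successor_zero(self):
        H = st.transition_entropy(np.array([0, 1, 0, 1, 0, 1]))
        assert H[0] == 0.0 and H[1] == 0.0

    def test_hand_computed_counts(self):
        # A->B x3, A->C x1: H = -(0.75 ln 0.75 + 0.25 ln 0.25)
        M = np.zeros((3, 3))
        M[0, 1], M[0, 2] = 3, 1
        expected = -(0.75 * np.log(0.75) + 0.25 * np.log(0.25))
        assert abs(st.transition_entropy(M)[0] - expected) < 1e-12
        assert abs(expected - 0.5623) < 1e-4

    def test_bounds(self, coupled_sessions):
        labels = coupled_sessions[0][0]
        H = st.transition_entropy(labels, 10)
        assert np.all(H[~np.isnan(H)] >= 0)
        assert np.all(H[~np.isnan(H)] <= np.log(9) + 1e-12)


class TestExpandingBin:
    BINS = (5, 10, 25, 50, 100, 200)

    def test_null_peaks_mostly_within_band(self, null_table):
        c = st.expanding_bin_correlation(null_table, "counts", self.BINS,
                                         n_shuffles=60, seed=0)
        assert np.mean(np.abs(c.r_z[~np.isnan(c.r_z)]) < 2.0) >= 0.8

    def test_coupled_counts_exceed_band_near_tau(self, coupled_table):
        c = st.expanding_bin_correlation(coupled_table, "counts", self.BINS,
                                         n_shuffles=60, seed=0)
        near_tau = c.r_z[np.isin(c.bin_sizes, (50, 100, 200))]
        assert np.all(near_tau > 2.0)

    def test_autocorr_mode_short_bins_beat_long_for_ar1(self):
        """AR(1) amplitudes: the forward-mean correlation at bin 5 exceeds
        bin 400 (analytic AR(1) autocovariance decays geometrically)."""
        rng = np.random.default_rng(3)
        labels = rng.permuted(np.tile(np.arange(10), 500))
        labels = labels[np.concatenate([[True], labels[1:] != labels[:-1]])]
        n = labels.size
        pk = np.zeros(n)
        for t in range(1, n):
            pk[t] = 0.9 * pk[t - 1] + rng.standard_normal()
        tab = pd.DataFrame({
            "mouse": "m0", "session": "s0", "syllable": labels,
            "peak": pk, "onset_frame": np.arange(n) * 12, "velocity": np.nan,
            "instance_index": np.arange(n), "duration_frames": 12})
        c = st.expanding_bin_correlation(tab, "autocorr", (5, 100, 400),
                                         n_shuffles=10, seed=0, segments=2)
        assert c.r_raw[0] > c.r_raw[-1]

    def test_insufficient_segment_data_yields_nan_not_error(self, null_table):
        small = null_table[null_table["session"] == "s0"].iloc[:80]
        c = st.expanding_bin_correlation(small, "counts", (5, 10, 200),
                                         n_shuffles=5, seed=0)
        assert np.isnan(c.r_raw[-1])


class TestDecayFit:
    def test_selfconsistency_on_exact_curve(self):
        n = np.array([5, 10, 25, 50, 100, 200, 300, 400])
        r = 0.5 * np.exp(-n / 100.0)
        curve = st.CorrelationCurve(n, r, r * 0, n_shuffles=0,
                                    segment_curves=np.tile(r, (5, 1)))
        fit = st.fit_decay_tau(curve, n_boot=200, seed=0)
        assert 95 <= fit.tau_median <= 105

    def test_constant_curve_flagged(self):
        n = np.array([5, 10, 25, 50])
        curve = st.CorrelationCurve(n, np.full(4, 0.3), np.zeros(4), 0,
                                    segment_curves=np.tile(0.3, (3, 4)))
        fit = st.fit_decay_tau(curve, n_boot=50, seed=0)
        assert fit.non_identifiable

    def test_too_few_bins_rejected(self):
        curve = st.CorrelationCurve(np.array([5, 10]), np.array([0.5, 0.4]),
                                    np.zeros(2), 0)
        with pytest.raises(ValueError):
            st.fit_decay_tau(curve)


class TestCrossCorrelation:
    def test_coupled_generator_peaks_at_nonnegative_lag(self, coupled_table):
        out = st.cross_correlation_usage(coupled_table, lags=range(-3, 4),
                                         window_s=24.0, n_shuffles=30, seed=0)
        best = out["lags"][np.nanargmax(out["r"])]
        assert best >= 0
        assert np.nanmax(out["r"]) > 0

    def test_independent_peaks_within_band(self, null_table):
        out = st.cross_correlation_usage(null_table, lags=range(-3, 4),
                                         n_shuffles=30, seed=0)
        ok = ~np.isnan(out["r_z"])
        assert np.mean(np.abs(out["r_z"][ok]) < 2.5) >= 0.7


class TestHuberCV:
    def test_strong_linear_relation(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100)
        out = st.huber_regression_cv(x, 2 * x + 1e-6 * rng.standard_normal(100),
                                     repeats=3, n_shuffles=20, seed=0)
        assert out["r"] > 0.999

    def test_analytic_correlation_recovered(self):
        # y = x + N(0,1): population correlation 1/sqrt(2)
        rng = np.random.default_rng(1)
        x = rng.standard_normal(200)
        out = st.huber_regression_cv(x, x + rng.standard_normal(200),
                                     repeats=10, n_shuffles=20, seed=0)
        assert abs(out["r"] - 1 / np.sqrt(2)) < 0.1

    def test_null_not_significant(self):
        rng = np.random.default_rng(2)
        out = st.huber_regression_cv(rng.standard_normal(80),
                                     rng.standard_normal(80),
                                     repeats=3, n_shuffles=60, seed=0)
        assert out["p"] > 0.05

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            st.huber_regression_cv(np.ones(50), np.random.default_rng(0).standard_normal(50))


class TestMovementInitiations:
    def test_constant_velocity_no_events(self):
        assert st.movement_initiations(np.full(2000, 5.0)).size == 0

    def test_single_step_one_event_near_step(self):
        v = np.zeros(3000)
        v[1000:] = 3.0
        ev = st.movement_initiations(v)
        assert ev.size == 1
        assert abs(ev[0] - 1000) <= 25

    def test_two_steps_two_events(self):
        v = np.zeros(3000)
        v[1000:1200] = 3.0
        v[1600:1800] = 3.0
        ev = st.movement_initiations(v)
        assert ev.size == 2


class TestPartialOut:
    def test_covariate_direction_removed(self):
        rng = np.random.default_rng(0)
        cov = rng.standard_normal(2000)
        dlight = 2.0 * cov + 0.01 * rng.standard_normal(2000)
        out = st.partial_out_kinematics(dlight, {"v2d": cov}, cov, n_boot=100, seed=0)
        assert abs(out["r"]) < 0.05

    def test_independent_target_within_null_band(self):
        rng = np.random.default_rng(1)
        out = st.partial_out_kinematics(
            rng.standard_normal(2000), {"v2d": rng.standard_normal(2000)},
            rng.standard_normal(2000), n_boot=200, seed=0)
        lo, hi = out["null_band"]
        assert lo <= out["r"] <= hi

    def test_analytic_partial_correlation(self):
        """dlight = cov + 0.5 * target (orthogonal): after removing cov the
        residual correlates with target at 0.5/sqrt(0.25 + sigma_resid^2)."""
        rng = np.random.default_rng(2)
        cov = rng.standard_normal(5000)
        target = rng.standard_normal(5000)
        noise_sd = 0.5
        dlight = cov + 0.5 * target + noise_sd * rng.standard_normal(5000)
        out = st.partial_out_kinematics(dlight, {"v": cov}, target,
                                        n_boot=50, seed=0)
        expect = 0.5 / np.sqrt(0.25 + noise_sd**2)
        assert abs(out["r"] - expect) < 0.05

    def test_collinear_covariate_dropped(self):
        rng = np.random.default_rng(3)
        cov = rng.standard_normal(500)
        with pytest.warns(UserWarning):
            out = st.partial_out_kinematics(
                rng.standard_normal(500), {"a": cov, "b": 2 * cov},
                rng.standard_normal(500), n_boot=20, seed=0)
        assert out["covariates_used"] == ["a"]


class TestEndoInfluence:
    BINS = (5, 10, 25, 50, 100)

    def test_null_index_near_unit(self, null_table):
        out = st.endo_da_influence(null_table, "counts", per="mouse",
                                   bin_sizes=self.BINS, n_shuffles=40, seed=0)
        assert 0.2 < out["influence"].iloc[0] < 3.0

    def test_coupled_exceeds_null(self, coupled_table, null_table):
        kw = dict(outcome="counts", per="mouse", bin_sizes=self.BINS,
                  n_shuffles=40, seed=0)
        strong = st.endo_da_influence(coupled_table, **kw)["influence"].iloc[0]
        null = st.endo_da_influence(null_table, **kw)["influence"].iloc[0]
        assert strong > null

    def test_scale_invariance(self, coupled_table):
        kw = dict(outcome="counts", per="mouse", bin_sizes=self.BINS,
                  n_shuffles=30, seed=0)
        a = st.endo_da_influence(coupled_table, **kw)["influence"].iloc[0]
        scaled = coupled_table.copy()
        scaled["peak"] = scaled["peak"] * 3.5
        b = st.endo_da_influence(scaled, **kw)["influence"].iloc[0]
        assert abs(a - b) < 0.3 * abs(a)
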