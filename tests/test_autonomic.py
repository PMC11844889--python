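"""Heartbeat cleaning, HR interpolation, multitaper PSD, and RSA strength."""

import numpy as np
import pytest
from scipy import signal

from spontlfp.autonomic import (AutonomicError, IBISeries, clean_ibi,
                                compare_contexts, interpolate_hr,
                                multitaper_psd, rsa_strength, slepian_tapers)


def beats_at_constant_ibi(ibi_s, duration_s, start=0.0):
    return np.arange(start, duration_s, ibi_s)


class TestCleanIBI:
    def test_constant_series_unchanged(self):
        series = clean_ibi(beats_at_constant_ibi(0.6, 60))
        assert np.allclose(series.ibis, 600.0)
        assert series.n_removed == 0

    def test_short_interval_removed(self):
        beats = np.array([0.0, 0.6, 0.8, 1.4, 2.0])   # one 200 ms interval
        series = clean_ibi(beats)
        assert 200.0 not in series.ibis
        assert series.n_removed == 1
        assert series.ibis.size == 3

    def test_long_interval_removed(self):
        beats = np.array([0.0, 0.6, 2.2, 2.8, 3.4])   # one 1600 ms interval
        series = clean_ibi(beats)
        assert series.n_removed == 1
        assert np.all((series.ibis >= 250) & (series.ibis <= 1500))

    def test_boundary_values_kept(self):
        beats = np.array([0.0, 0.25, 1.75])           # exactly 250 and 1500 ms
        series = clean_ibi(beats)
        assert series.n_removed == 0

    def test_too_few_beats_rejected(self):
        with pytest.raises(AutonomicError):
            clean_ibi(np.array([1.0]))

    def test_all_invalid_rejected(self):
        with pytest.raises(AutonomicError, match="valid beats"):
            clean_ibi(np.array([0.0, 0.1, 0.2]))

    def test_alignment_invariant(self):
        series = clean_ibi(np.array([0.0, 0.6, 0.8, 1.4, 2.0, 2.6]))
        assert series.ibis.size == series.beat_times.size - 1


class TestInterpolateHR:
    def test_constant_rate(self):
        series = IBISeries.from_beats(beats_at_constant_ibi(0.6, 30))
        t, hr = interpolate_hr(series)
        assert np.allclose(hr, 100.0)

    def test_grid_arithmetic(self):
        series = IBISeries.from_beats(beats_at_constant_ibi(0.5, 10.01))
        t, hr = interpolate_hr(series)
        span = series.beat_times[-1] - series.beat_times[1]
        assert t.size == int(np.floor(span * 1000)) + 1
        assert np.allclose(np.diff(t), 0.001)

    def test_passes_through_knots(self):
        rng = np.random.default_rng(0)
        beats = np.cumsum(0.6 + 0.05 * rng.standard_normal(40))
        series = IBISeries.from_beats(beats)
        t, hr = interpolate_hr(series)
        for tk, hk in zip(series.beat_times[1:], 60000.0 / series.ibis):
            i = int(round((tk - t[0]) / 0.001))
            if 0 <= i < t.size:
                assert hr[i] == pytest.approx(hk, abs=0.51)  # within grid step

    def test_monotone_between_knots_for_ramp(self):
        """Linear IBI ramp: the modified-Akima interpolant is monotone
        (checked against dense evaluation)."""
        ibis = np.linspace(0.5, 0.8, 30)
        beats = np.concatenate([[0.0], np.cumsum(ibis)])
        series = IBISeries.from_beats(beats)
        t, hr = interpolate_hr(series)
        assert np.all(np.diff(hr) <= 1e-9)

    def test_too_few_beats_rejected(self):
        with pytest.raises(AutonomicError):
            interpolate_hr(IBISeries.from_beats(np.array([0.0, 0.6, 1.2])))


class TestSlepianTapers:
    def test_orthonormality(self):
        ts = slepian_tapers(512, half_bandwidth=0.07, fs=4.0, k=7)
        gram = ts.tapers @ ts.tapers.T
        assert np.max(np.abs(gram - np.eye(7))) < 1e-8

    def test_eigenvalues_descending_in_unit_interval(self):
        # at NW = 4 the top-7 concentrations are distinct and below 1;
        # ordering is checked up to floating-point saturation
        ts = slepian_tapers(256, 0.0625, 4.0, k=7)
        assert np.all(np.diff(ts.eigenvalues) <= 1e-10)
        assert np.all((ts.eigenvalues > 0) & (ts.eigenvalues <= 1))
        assert ts.eigenvalues[-1] < 1 - 1e-6

    def test_matches_dense_eigenproblem_oracle(self):
        """Dense eigen-solve of the sinc concentration kernel for N = 256.

        NW = 4 keeps the top-7 eigenvalues well separated so the
        eigenvectors are numerically well-determined on both routes.
        """
        n, fs, w, k = 256, 4.0, 0.0625, 7
        wn = w / fs   # normalized half-bandwidth (cycles/sample)
        m = np.arange(n)
        diff = m[:, None] - m[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            kernel = np.sin(2 * np.pi * wn * diff) / (np.pi * diff)
        kernel[np.diag_indices(n)] = 2 * wn
        evals, evecs = np.linalg.eigh(kernel)
        order = np.argsort(evals)[::-1][:k]
        oracle = evecs[:, order].T
        ts = slepian_tapers(n, w, fs, k=k)
        for i in range(k):
            v, o = ts.tapers[i], oracle[i]
            o = o / np.linalg.norm(o)
            err = min(np.max(np.abs(v - o)), np.max(np.abs(v + o)))
            assert err < 1e-6

    def test_bandwidth_above_nyquist_rejected(self):
        with pytest.raises(AutonomicError, match="Nyquist"):
            slepian_tapers(256, half_bandwidth=3.0, fs=4.0)

    def test_too_many_tapers_warns(self):
        with pytest.warns(UserWarning, match="concentration"):
            slepian_tapers(64, 0.07, 4.0, k=7)   # 2NW-1 = 1.24


class TestMultitaperPSD:
    def test_peak_localization(self):
        rng = np.random.default_rng(0)
        fs = 4.0
        t = np.arange(int(600 * fs)) / fs
        x = np.sin(2 * np.pi * 0.3 * t) + 0.3 * rng.standard_normal(t.size)
        freqs, psd = multitaper_psd(x, fs)
        assert abs(freqs[np.argmax(psd)] - 0.3) <= 0.07


class TestRSAStrength:
    @staticmethod
    def hr_grid(duration=400.0, noise=0.5, seed=0, f_mod=None, depth=0.0):
        rng = np.random.default_rng(seed)
        t = np.arange(0, duration, 0.001)
        hr = 100.0 + noise * np.cumsum(rng.standard_normal(t.size)) * 0.01
        if f_mod is not None:
            hr = hr + depth * 100 * np.sin(2 * np.pi * f_mod * t)
        return t, hr

    def test_median_normalized_strength_is_zero_for_odd_window_count(self):
        t, hr = self.hr_grid(duration=60 + 6 * 57 + 1)   # 7 windows
        rsa = rsa_strength(t, hr)
        assert rsa.raw.size == 7
        assert np.median(rsa.normalized) == 0.0

    def test_window_hop_is_window_minus_overlap(self):
        t, hr = self.hr_grid(duration=300.0)
        rsa = rsa_strength(t, hr, window_s=60.0, overlap_s=3.0)
        hops = np.diff(rsa.window_centers)
        assert np.allclose(hops, 57.0)
        alt = rsa_strength(t, hr, window_s=60.0, overlap_s=3.0, step_mode="step")
        assert np.allclose(np.diff(alt.window_centers), 3.0)

    def test_peakless_windows_use_band_mean(self):
        """Without a respiratory peak the unit-area normalization forces
        P_rsa to ~1/0.25 (the uniform-density value)."""
        t, hr = self.hr_grid(duration=240.0, noise=2.0, seed=3)
        rsa = rsa_strength(t, hr, peak_prominence=1e9)   # force peakless path
        # 1/(0.5-0.25) = 4 up to trapezoid endpoint bias (~1/n_bins)
        assert np.allclose(rsa.raw, 4.0, rtol=0.15)

    def test_short_span_rejected(self):
        t, hr = self.hr_grid(duration=30.0)
        with pytest.raises(AutonomicError, match="span"):
            rsa_strength(t, hr)

    def test_context_modulation_recovered_from_simulated_heartbeats(self):
        """Touch-block respiratory modulation yields higher normalized RSA
        in touch than in airflow windows (ground-truth recovery)."""
        import spontlfp as sl

        proto = sl.generate_protocol(n_block_pairs=1, inter_block_gap=60.0, seed=2)
        series = sl.simulate_context_ibi(proto, depth_touch=0.1,
                                         depth_airflow=0.0, seed=2)
        cleaned = clean_ibi(series)
        t, hr = interpolate_hr(cleaned)
        rsa = rsa_strength(t, hr, protocol=proto)
        means = rsa.context_means()
        assert means["touch"] > means["airflow"]


class TestCompareContexts:
    def test_identical_values_give_t_zero_p_half(self):
        t, p = compare_contexts([(0.2, 0.2), (0.5, 0.5), (0.1, 0.1)])
        assert t == 0.0 and p == 0.5

    def test_zero_variance_positive_differences(self):
        with pytest.warns(UserWarning, match="degenerate"):
            t, p = compare_contexts([(1.0, 0.0)] * 4)
        assert p == 0.0 and t == np.inf

    def test_matches_hand_computed_paired_t(self):
        touch = np.array([0.5, 0.8, 0.6, 0.9, 0.7])
        airflow = np.array([0.3, 0.5, 0.6, 0.4, 0.5])
        t, p = compare_contexts(list(zip(touch, airflow)))
        d = touch - airflow
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        from scipy import stats

        p_hand = stats.t.sf(t_hand, df=d.size - 1)
        assert t == pytest.approx(t_hand, rel=1e-12)
        assert p == pytest.approx(p_hand, rel=1e-12)

    def test_needs_two_sessions(self):
        with pytest.raises(AutonomicError):
            compare_contexts([(0.5, 0.4)])

    def test_rejection_rates_under_effect_and_null(self):
        """Groups of 6 simulated sessions: the one-sided test rejects nearly
        always with touch-only modulation and at ~alpha under the null."""
        import spontlfp as sl

        proto = sl.generate_protocol(n_block_pairs=1, inter_block_gap=60.0, seed=0)

        def run(depth_touch, seed):
            pairs = []
            for s in range(6):
                series = sl.simulate_context_ibi(proto, depth_touch=depth_touch,
                                                 depth_airflow=0.0,
                                                 seed=1000 * seed + s)
                t, hr = interpolate_hr(clean_ibi(series))
                rsa = rsa_strength(t, hr, protocol=proto)
                m = rsa.context_means()
                pairs.append((m["touch"], m["airflow"]))
            return compare_contexts(pairs)[1] < 0.05

        effect_rejections = sum(run(0.1, s) for s in range(10))
        assert effect_rejections >= 9
        null_rejections = sum(run(0.0, s) for s in range(40))
        assert null_rejections / 40 <= 0.15
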