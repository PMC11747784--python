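"""Spectral estimation and canonical-correlation features, each checked
against an independent route (direct DFT, scipy.signal.welch, time-domain
variance, explicit optimization over reference weights)."""

import numpy as np
import pytest
from scipy import optimize, signal

from ssvep_cvd import (
    SimConfig,
    build_reference,
    cca_max_correlation,
    extract_feature_vector,
    feature_names,
    periodogram_segment,
    psd_feature,
    psd_group_ratio,
    synthesize_trial,
    welch_psd,
)
from ssvep_cvd.features import FEATURE_CHANNELS, hann_window, segment_starts
from ssvep_cvd.preprocessing import TrialSegment
from ssvep_cvd.io_recording import STIMULATION


def brute_force_max_corr(x, y, n_starts=8, seed=0):
    """Oracle: maximize |corr(x, w'Y)| over weight vectors w by numerical
    optimization from several random starts."""
    rng = np.random.default_rng(seed)
    xc = x - x.mean()

    def neg_corr_sq(w):
        proj = w @ y
        proj = proj - proj.mean()
        denom = np.linalg.norm(xc) * np.linalg.norm(proj)
        if denom == 0:
            return 0.0
        return -float((xc @ proj) / denom) ** 2

    best = 0.0
    for _ in range(n_starts):
        res = optimize.minimize(
            neg_corr_sq, rng.standard_normal(y.shape[0]), method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000},
        )
        best = max(best, np.sqrt(-res.fun))
    return best


class TestPeriodogram:
    def test_zero_vector_all_zero(self):
        _, p = periodogram_segment(np.zeros(256), fs=250.0)
        np.testing.assert_array_equal(p, 0.0)

    def test_pure_tone_single_bin(self):
        t = np.arange(250) / 250.0
        x = np.sin(2 * np.pi * 15 * t)
        freqs, p = periodogram_segment(x, fs=250.0)
        assert freqs[np.argmax(p)] == 15.0
        others = p[freqs != 15.0]
        assert np.all(others < 1e-10 * p.max())

    def test_parseval_rectangular_window(self, rng):
        x = rng.standard_normal(1000)
        x -= x.mean()
        freqs, p = periodogram_segment(x, fs=250.0)
        df = freqs[1] - freqs[0]
        assert np.sum(p) * df == pytest.approx(np.var(x), rel=0.01)

    def test_raw_textbook_scaling_mode(self):
        """density=False returns the unscaled |X(k)|^2 / M form."""
        t = np.arange(250) / 250.0
        x = np.sin(2 * np.pi * 15 * t)
        _, p = periodogram_segment(x, fs=250.0, density=False)
        spec = np.fft.rfft(x)
        np.testing.assert_allclose(p, np.abs(spec) ** 2 / 250, atol=1e-9)

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError):
            periodogram_segment(np.array([1.0]))


class TestWelch:
    def test_nineteen_segments_at_protocol_defaults(self):
        spec = welch_psd(np.random.default_rng(0).standard_normal(2500))
        assert spec.n_segments == 19
        assert len(segment_starts(2500, 250, 0.5)) == 19

    def test_one_hz_bins_hit_stimulation_frequencies(self):
        spec = welch_psd(np.zeros(2500), fs=250.0, nperseg=250)
        assert spec.freqs[1] - spec.freqs[0] == 1.0
        assert 15.0 in spec.freqs and 18.0 in spec.freqs

    def test_equals_mean_of_segment_periodograms(self, rng):
        """Exact algebraic identity with the segment decomposition."""
        x = rng.standard_normal(2500)
        spec = welch_psd(x, fs=250.0)
        w = hann_window(250)
        manual = np.mean(
            [
                periodogram_segment(x[s : s + 250], 250.0, w)[1]
                for s in segment_starts(2500, 250, 0.5)
            ],
            axis=0,
        )
        np.testing.assert_allclose(spec.psd[0], manual, rtol=1e-12)

    def test_matches_scipy_welch(self, rng):
        """Independent library oracle for the full windowed density estimate."""
        x = rng.standard_normal(2500)
        spec = welch_psd(x, fs=250.0, nperseg=250, overlap=0.5)
        f_ref, p_ref = signal.welch(
            x, fs=250.0, window="hann", nperseg=250, noverlap=125,
            detrend="constant",
        )
        np.testing.assert_allclose(spec.freqs, f_ref)
        np.testing.assert_allclose(spec.psd[0], p_ref, rtol=1e-10)

    def test_averaging_reduces_bin_variance(self, rng):
        """Welch bins vary less than single-periodogram bins on white noise."""
        welch_vals, perio_vals = [], []
        for _ in range(200):
            x = rng.standard_normal(2500)
            welch_vals.append(welch_psd(x, fs=250.0).psd[0, 20])
            perio_vals.append(
                periodogram_segment(x[:250], 250.0, hann_window(250))[1][20]
            )
        assert np.var(welch_vals) < 0.5 * np.var(perio_vals)

    def test_nperseg_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            welch_psd(np.zeros(100), nperseg=250)


class TestPsdFeature:
    def test_exact_bin_lookup(self, rng):
        spec = welch_psd(rng.standard_normal(2500), fs=250.0)
        k = int(np.flatnonzero(spec.freqs == 15.0)[0])
        assert psd_feature(spec, 15.0) == spec.psd[0, k]

    def test_nearest_bin_rule(self, rng):
        spec = welch_psd(rng.standard_normal(2500), fs=250.0)
        assert psd_feature(spec, 15.4) == psd_feature(spec, 15.0)

    def test_tie_breaks_toward_lower_frequency(self, rng):
        spec = welch_psd(rng.standard_normal(2500), fs=250.0)
        assert psd_feature(spec, 15.5) == psd_feature(spec, 15.0)

    def test_agrees_with_linear_scan(self, rng):
        spec = welch_psd(rng.standard_normal(2500), fs=250.0)
        for f in rng.uniform(1, 100, size=20):
            k = min(range(len(spec.freqs)), key=lambda i: abs(spec.freqs[i] - f))
            assert psd_feature(spec, f) == spec.psd[0, k]

    def test_out_of_range_rejected(self, rng):
        spec = welch_psd(rng.standard_normal(2500), fs=250.0)
        with pytest.raises(ValueError):
            psd_feature(spec, 200.0)


class TestReferenceSet:
    def test_row_structure(self):
        ref = build_reference(15.0, n_harmonics=3, fs=250.0, n=2500)
        assert ref.matrix.shape == (6, 2500)
        t = np.arange(2500) / 250.0
        np.testing.assert_allclose(ref.matrix[0], np.sin(2 * np.pi * 15 * t))
        np.testing.assert_allclose(ref.matrix[5], np.cos(2 * np.pi * 45 * t))

    def test_rows_orthogonal_over_integer_cycles(self):
        ref = build_reference(15.0, n_harmonics=3, fs=250.0, n=2500)
        gram = ref.matrix @ ref.matrix.T
        off_diag = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off_diag)) < 1e-8 * np.max(np.diag(gram))

    def test_sin_cos_pair_uncorrelated(self):
        ref = build_reference(15.0, n_harmonics=1, fs=250.0, n=2500)
        assert abs(ref.matrix[0] @ ref.matrix[1]) < 1e-8

    def test_harmonic_above_nyquist_names_offender(self):
        with pytest.raises(ValueError, match="harmonic 3"):
            build_reference(45.0, n_harmonics=3, fs=250.0, n=2500)


class TestCCA:
    def test_in_span_signal_gives_unit_correlation(self):
        ref = build_reference(15.0, 3, 250.0, 2500)
        t = np.arange(2500) / 250.0
        x = np.sin(2 * np.pi * 15 * t + 0.7)
        assert cca_max_correlation(x, ref) == pytest.approx(1.0, abs=1e-9)

    def test_third_harmonic_needs_enough_harmonics(self):
        t = np.arange(2500) / 250.0
        x = np.sin(2 * np.pi * 45 * t)
        assert cca_max_correlation(x, build_reference(15.0, 3, 250.0, 2500)) == (
            pytest.approx(1.0, abs=1e-9)
        )
        assert cca_max_correlation(x, build_reference(15.0, 1, 250.0, 2500)) < 0.05

    def test_scale_and_offset_invariance(self, rng):
        ref = build_reference(18.0, 3, 250.0, 1000)
        x = rng.standard_normal(1000)
        rho = cca_max_correlation(x, ref)
        assert cca_max_correlation(-3.2 * x + 11.0, ref) == pytest.approx(
            rho, abs=1e-9
        )

    def test_constant_signal_rejected(self):
        ref = build_reference(15.0, 1, 250.0, 100)
        with pytest.raises(ValueError, match="constant"):
            cca_max_correlation(np.full(100, 3.0), ref)

    def test_agrees_with_brute_force_optimizer(self, rng):
        """20 random small instances vs explicit weight-space optimization."""
        for i in range(20):
            n = int(rng.integers(40, 80))
            h = int(rng.integers(1, 3))
            f = float(rng.uniform(5, 20))
            ref = build_reference(f, h, 250.0, n)
            x = rng.standard_normal(n)
            rho = cca_max_correlation(x, ref)
            oracle = brute_force_max_corr(x, ref.matrix, seed=i)
            assert rho == pytest.approx(oracle, abs=1e-6)

    def test_monotone_in_ssvep_amplitude(self):
        """rho at the attended frequency rises with SSVEP amplitude."""
        rhos = []
        for amp in (0.5, 1.0, 2.0, 4.0, 8.0):
            cfg = SimConfig(
                ssvep_amp={"O1": amp, "O2": amp, "Pz": amp, "Cz": amp},
                artifact_rate=0.0,
            )
            trial = synthesize_trial(15.0, cfg, np.random.default_rng(3))
            ref = build_reference(15.0, 3, cfg.fs, trial.shape[1])
            rhos.append(np.mean([cca_max_correlation(ch, ref) for ch in trial]))
        assert rhos == sorted(rhos)


class TestFeatureVector:
    def _segments_by_freq(self, attended_by_freq, cfg, seed=0):
        rng = np.random.default_rng(seed)
        return {
            f: TrialSegment(
                synthesize_trial(attended, cfg, rng), 0, 0, STIMULATION, cfg.fs
            )
            for f, attended in attended_by_freq.items()
        }

    def test_canonical_length_and_order(self):
        cfg = SimConfig(artifact_rate=0.0)
        segs = self._segments_by_freq({15.0: 15.0, 18.0: 18.0}, cfg)
        fv = extract_feature_vector(segs, channel_names=cfg.channel_names)
        assert fv.values.shape == (16,)
        names = feature_names()
        assert len(names) == 16
        assert names[0] == "psd_O1_15Hz" and names[7] == "psd_Cz_18Hz"
        assert names[8] == "cca_O1_15Hz" and names[15] == "cca_Cz_18Hz"

    def test_noise_free_attended_frequency_dominates(self):
        """A 15 Hz-attending read: CCA at 15 ~ 1, CCA at 18 ~ 0."""
        cfg = SimConfig(alpha_amp=0, noise_scale=0, line_amp=0, artifact_rate=0)
        segs = self._segments_by_freq({15.0: 15.0, 18.0: 15.0}, cfg)
        fv = extract_feature_vector(segs, channel_names=cfg.channel_names)
        cca15, cca18 = fv.values[8:12], fv.values[12:16]
        np.testing.assert_allclose(cca15, 1.0, atol=1e-6)
        assert np.all(cca18 < 0.05)

    def test_channel_order_is_canonical_regardless_of_input(self):
        cfg = SimConfig(artifact_rate=0.0)
        segs = self._segments_by_freq({15.0: 15.0, 18.0: 18.0}, cfg, seed=1)
        fv = extract_feature_vector(segs, channel_names=cfg.channel_names)
        shuffled_names = ("Cz", "O1", "Pz", "O2")
        reorder = [cfg.channel_names.index(c) for c in shuffled_names]
        segs_shuffled = {
            f: TrialSegment(s.data[reorder], 0, 0, STIMULATION, s.fs)
            for f, s in segs.items()
        }
        fv2 = extract_feature_vector(segs_shuffled, channel_names=shuffled_names)
        np.testing.assert_allclose(fv2.values, fv.values, rtol=1e-12)

    def test_missing_channel_named_in_error(self):
        cfg = SimConfig(artifact_rate=0.0)
        segs = self._segments_by_freq({15.0: 15.0, 18.0: 18.0}, cfg)
        with pytest.raises(ValueError, match="Pz"):
            extract_feature_vector(segs, channel_names=("O1", "O2", "XX", "Cz"))

    def test_feature_channels_constant(self):
        assert FEATURE_CHANNELS == ("O1", "O2", "Pz", "Cz")


class TestGroupRatio:
    def test_identical_groups_ratio_one(self, rng):
        spec = welch_psd(rng.standard_normal(2500), fs=250.0)
        assert psd_group_ratio(spec, spec, (14, 16)) == pytest.approx(1.0)

    def test_doubled_power_gives_ratio_two(self, rng):
        x = rng.standard_normal(2500)
        spec = welch_psd(x, fs=250.0)
        doubled = welch_psd(np.sqrt(2) * x, fs=250.0)
        assert psd_group_ratio(doubled, spec, (14, 16)) == pytest.approx(2.0)

    def test_direction_on_simulated_groups(self):
        """15 Hz-target sessions: normal attends 15 (power in 14-16 Hz),
        CVD attends 18 (power in 17-19 Hz) — ratio >1 then <1."""
        cfg = SimConfig(noise_scale=0.5, artifact_rate=0.0)
        rng = np.random.default_rng(4)
        spec_n = welch_psd(synthesize_trial(15.0, cfg, rng)[0], fs=cfg.fs)
        spec_c = welch_psd(synthesize_trial(18.0, cfg, rng)[0], fs=cfg.fs)
        assert psd_group_ratio(spec_n, spec_c, (14, 16)) > 1.0
        assert psd_group_ratio(spec_n, spec_c, (17, 19)) < 1.0

    def test_mismatched_grids_rejected(self, rng):
        a = welch_psd(rng.standard_normal(2500), fs=250.0, nperseg=250)
        b = welch_psd(rng.standard_normal(2500), fs=250.0, nperseg=500)
        with pytest.raises(ValueError):
            psd_group_ratio(a, b, (14, 16))
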