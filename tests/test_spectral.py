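"""Spectral estimation: windows, coherence, Z-coherence, bands, surrogates."""

import numpy as np
import pytest

from hdclamp import (WindowSpec, band_power, band_summarize, coherence,
                     coherence_with_reference, default_bands,
                     phase_scramble, pool_spectra, windowed_spectra,
                     z_coherence)

FS = 500.0


def _segment(f_hz, seconds=8.0, fs=FS, n_ch=1, amp=1.0):
    t = np.arange(int(seconds * fs)) / fs
    return np.tile(amp * np.sin(2 * np.pi * f_hz * t), (n_ch, 1))


def _noise_spectra(rng, n_ch, n_win=8, seconds_per_win=1.0, fs=FS):
    x = rng.standard_normal((n_ch, int(n_win * seconds_per_win * fs)))
    return windowed_spectra(x, fs)


class TestWindowedSpectra:
    def test_eight_windows_for_eight_seconds(self):
        ss = windowed_spectra(_segment(5.0), FS)
        assert ss.F.shape[1] == 8
        assert ss.freqs[1] - ss.freqs[0] == pytest.approx(1.0)

    def test_sine_peaks_at_its_bin(self):
        ss = windowed_spectra(_segment(5.0), FS)
        mags = np.abs(ss.F[0])
        assert np.all(np.argmax(mags, axis=1) == 5)

    def test_parseval_per_window(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((1, 4000))
        ss = windowed_spectra(x, FS)
        taper = np.hamming(500)
        for w in range(8):
            seg = x[0, w * 500:(w + 1) * 500] * taper
            time_energy = np.sum(seg ** 2)
            spec = ss.F[0, w]
            # rfft double-counts nothing: DC and Nyquist once, rest twice
            freq_energy = (np.abs(spec[0]) ** 2
                           + 2 * np.sum(np.abs(spec[1:-1]) ** 2)
                           + np.abs(spec[-1]) ** 2) / 500
            assert time_energy == pytest.approx(freq_energy, rel=1e-9)

    def test_length_mismatch_names_expected(self):
        with pytest.raises(ValueError, match="multiple"):
            windowed_spectra(np.zeros((1, 4321)), FS)


class TestCoherence:
    def test_self_coherence_is_one(self):
        rng = np.random.default_rng(1)
        ss = _noise_spectra(rng, 2)
        res = coherence(ss, 0, 0)
        valid = ~np.isnan(res.coh)
        assert np.allclose(res.coh[valid], 1.0)
        assert res.df == 16

    def test_independent_noise_bias_is_one_over_n(self):
        """E[coh^2] ~ 1/N for independent channels with N windows."""
        rng = np.random.default_rng(2)
        coh2 = []
        for _ in range(300):
            ss = _noise_spectra(rng, 2)
            res = coherence(ss, 0, 1)
            coh2.append(np.nanmean(res.coh[1:-1] ** 2))
        assert np.mean(coh2) == pytest.approx(1 / 8, rel=0.1)

    def test_snr_closed_form(self):
        """coh^2 = s/(1+s) for y = x + noise at per-frequency SNR s."""
        rng = np.random.default_rng(3)
        snr = 1.5
        est = []
        for _ in range(60):
            n = 8 * 500
            x = rng.standard_normal(n)
            y = np.sqrt(snr) * x + rng.standard_normal(n)
            ss = windowed_spectra(np.stack([np.sqrt(snr) * x, y]), FS)
            res = coherence(ss, 0, 1)
            est.append(np.nanmean(res.coh[5:200] ** 2))
        # finite-N estimator bias inflates coh^2 by roughly (1-c^2)^2/N
        expected = snr / (1 + snr)
        assert np.mean(est) == pytest.approx(expected, abs=0.03)

    def test_scaling_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((2, 4000))
        a = coherence(windowed_spectra(x, FS), 0, 1)
        x2 = x * np.array([[3.7], [0.002]])
        b = coherence(windowed_spectra(x2, FS), 0, 1)
        np.testing.assert_allclose(a.coh, b.coh, rtol=1e-9)

    def test_zero_power_is_missing_not_extreme(self):
        x = np.zeros((2, 4000))
        x[0] = _segment(5.0)[0]
        res = coherence(windowed_spectra(x, FS), 0, 1)
        assert np.all(np.isnan(res.coh))

    def test_pooling_across_trials_increases_df(self):
        rng = np.random.default_rng(5)
        sets = [_noise_spectra(rng, 2) for _ in range(3)]
        res = coherence(sets, 0, 1)
        assert res.df == 2 * 24

    def test_reference_mode_matches_pairwise(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((3, 4000))
        ss = windowed_spectra(x, FS)
        ref = windowed_spectra(x[2], FS)
        res = coherence_with_reference(ss, ref)
        for ch in range(3):
            pair = coherence(ss, ch, 2)
            np.testing.assert_allclose(res.coh[ch], pair.coh, atol=1e-12)


class TestZCoherence:
    def test_equal_conditions_give_zero(self):
        c = np.array([0.3, 0.6, 0.9])
        assert np.allclose(z_coherence(c, 18, c, 18), 0.0)

    def test_sign_follows_condition_order(self):
        assert z_coherence(0.6, 18, 0.3, 18) > 0
        assert z_coherence(0.3, 18, 0.6, 18) < 0

    def test_hand_evaluated_value(self):
        # atanh(0.6)=0.6931472, atanh(0.3)=0.3095196, bias terms cancel,
        # denominator sqrt(2/16)=0.3535534 -> Z = 1.0850295
        z = z_coherence(0.6, 18, 0.3, 18)
        assert z == pytest.approx((np.arctanh(0.6) - np.arctanh(0.3))
                                  / np.sqrt(2.0 / 16.0), rel=1e-12)
        assert z == pytest.approx(1.0850626, rel=1e-6)

    def test_antisymmetry_exact(self):
        rng = np.random.default_rng(7)
        a = rng.uniform(0, 0.99, 50)
        b = rng.uniform(0, 0.99, 50)
        np.testing.assert_array_equal(z_coherence(a, 18, b, 30),
                                      -z_coherence(b, 30, a, 18))

    def test_unit_coherence_clipped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clipped"):
            z = z_coherence(np.array([1.0]), 18, np.array([0.5]), 18)
        assert np.isfinite(z).all()

    def test_df_guard(self):
        with pytest.raises(ValueError, match="freedom"):
            z_coherence(0.5, 2, 0.5, 18)


class TestBands:
    def test_movement_relative_bands(self):
        bands = {b.name: (b.lower_hz, b.higher_hz)
                 for b in default_bands(1.6)}
        assert bands["F0"] == (pytest.approx(0.6), pytest.approx(2.6))
        assert bands["F1"] == (pytest.approx(2.2), pytest.approx(4.2))
        assert bands["Theta"] == (4.0, 7.0)
        assert bands["High-alpha"] == (10.0, 13.0)

    def test_flat_map_means_one(self):
        freqs = np.arange(0.0, 100.0)
        vals = np.ones_like(freqs)
        out = band_summarize(vals, freqs, default_bands())
        for name, v in out.items():
            assert v == pytest.approx(1.0)

    def test_band_outside_grid_raises(self):
        freqs = np.arange(0.0, 10.0)
        with pytest.raises(ValueError, match="High-alpha"):
            band_summarize(np.ones_like(freqs), freqs, default_bands())


class TestBandPower:
    def test_alpha_sine_dominates_high_alpha(self):
        ss = windowed_spectra(_segment(10.5), FS)
        power = band_power(ss, default_bands())
        assert max(power, key=lambda k: power[k][0]) == "High-alpha"

    def test_quadratic_amplitude_scaling(self):
        p1 = band_power(windowed_spectra(_segment(10.5), FS),
                        default_bands())
        p2 = band_power(windowed_spectra(_segment(10.5, amp=2.0), FS),
                        default_bands())
        for name in p1:
            if p1[name][0] > 0:
                assert p2[name][0] / p1[name][0] == pytest.approx(4.0,
                                                                  rel=1e-9)

    def test_white_noise_power_tracks_bandwidth(self):
        rng = np.random.default_rng(8)
        sets = [_noise_spectra(rng, 1) for _ in range(50)]
        power = band_power(sets, default_bands())
        # per-bin power is flat, so per-band MEANS are all equal
        assert power["Beta"][0] == pytest.approx(power["Theta"][0],
                                                 rel=0.15)


class TestPhaseScramble:
    def test_amplitude_spectrum_preserved(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(4000)
        s = phase_scramble(x, seed=1)
        np.testing.assert_allclose(np.abs(np.fft.rfft(s)),
                                   np.abs(np.fft.rfft(x)), rtol=1e-9)

    def test_variance_preserved(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(4001)  # odd length too
        s = phase_scramble(x, seed=2)
        assert s.var() == pytest.approx(x.var(), rel=1e-9)

    def test_deterministic_per_seed(self):
        x = np.sin(np.arange(1000) * 0.1)
        np.testing.assert_array_equal(phase_scramble(x, seed=3),
                                      phase_scramble(x, seed=3))
        assert not np.allclose(phase_scramble(x, seed=3),
                               phase_scramble(x, seed=4))

    def test_destroys_coherence_to_surrogate_null_level(self):
        """Coherence with one's own surrogate matches the
        surrogate-vs-surrogate null distribution.

        Note the windowed estimator's null level between series sharing
        one amplitude spectrum sits somewhat above the independent-noise
        1/N floor (their per-window envelopes correlate), so the correct
        reference is two *different* surrogates of the same series.
        """
        rng = np.random.default_rng(11)
        own, null = [], []
        for i in range(150):
            x = rng.standard_normal(4000)
            s = phase_scramble(x, seed=2 * i)
            s2 = phase_scramble(x, seed=2 * i + 1)
            res = coherence(windowed_spectra(np.stack([x, s]), FS), 0, 1)
            own.append(np.nanmean(res.coh[1:-1] ** 2))
            res0 = coherence(windowed_spectra(np.stack([s2, s]), FS), 0, 1)
            null.append(np.nanmean(res0.coh[1:-1] ** 2))
        assert np.mean(own) == pytest.approx(np.mean(null), rel=0.1)
        assert np.mean(own) < 3 / 8  # far below any planted coherence
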