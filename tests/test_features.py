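"""Feature operators against constructed signals, surrogate nulls, and
independent brute-force reimplementations."""

import numpy as np
import pytest
from scipy import signal as sps

from neuroload.features import (asym_psd, band_power_series, hb_stats,
                                nv_features, pac, plv, psd_features)
from neuroload.montage import BandScheme, Montage
from neuroload.types import EEG_CHANNELS

FS = 250.0
BANDS = BandScheme().psd_bands


def _sine(freq, dur=5.0, fs=FS, phase=0.0):
    t = np.arange(int(dur * fs)) / fs
    return np.sin(2 * np.pi * freq * t + phase)


class TestPSD:
    def test_10hz_sine_concentrates_in_alpha(self):
        p = psd_features(_sine(10.0), FS, BANDS)[0]
        assert p[2] / p.sum() > 0.90         # f3 = 8-12 Hz

    def test_zero_signal_gives_zero(self):
        assert np.allclose(psd_features(np.zeros(1250), FS, BANDS), 0.0)

    def test_white_noise_flat_across_bands(self, rng):
        p = np.zeros(8)
        for _ in range(40):
            p += psd_features(rng.standard_normal(1250), FS, BANDS)[0]
        # equal 4 Hz bandwidths -> equal power; the first band keeps its
        # half-weight DC bin so compare the interior bands strictly
        rel = p[1:] / p[1:].mean()
        assert np.all(np.abs(rel - 1.0) < 0.15)
        assert 0.5 < p[0] / p[1:].mean() < 1.1

    def test_frame_count_invariant(self):
        for dur in (5.0, 10.0, 25.0):
            bp = band_power_series(np.zeros(int(dur * FS)), FS, BANDS)
            assert bp.shape[-1] == int((dur - 1.0) / 0.5) + 1

    def test_nonnegative(self, rng):
        assert (band_power_series(rng.standard_normal(1250), FS, BANDS) >= 0).all()


class TestPLV:
    BAND = (9.0, 11.0)

    def test_identical_channels_unity(self):
        x = _sine(10.0)
        assert plv(x, x, self.BAND, FS) == pytest.approx(1.0, abs=1e-9)

    def test_constant_phase_lag_unity(self):
        a = _sine(10.0)
        b = _sine(10.0, phase=np.pi / 2)
        assert plv(a, b, self.BAND, FS) == pytest.approx(1.0, abs=5e-3)

    def test_independent_noise_low(self, rng):
        vals = [plv(rng.standard_normal(1250), rng.standard_normal(1250),
                    self.BAND, FS) for _ in range(20)]
        assert np.mean(vals) < 0.5

    def test_matches_bruteforce_oracle(self, rng):
        # direct per-sample sum of unit phasors, explicit loops
        a = rng.standard_normal(500)
        b = rng.standard_normal(500)
        got = plv(a, b, self.BAND, FS)
        sos = sps.butter(4, list(self.BAND), btype="bandpass", fs=FS,
                         output="sos")
        pa = np.angle(sps.hilbert(sps.sosfiltfilt(sos, a)))
        pb = np.angle(sps.hilbert(sps.sosfiltfilt(sos, b)))
        m = int(round(0.25 * FS))
        re = im = 0.0
        n = 0
        for k in range(m, 500 - m):
            d = pa[k] - pb[k]
            re += np.cos(d)
            im += np.sin(d)
            n += 1
        expected = np.sqrt(re * re + im * im) / n
        assert got == pytest.approx(expected, rel=1e-9)

    def test_bounded_unit_interval(self, rng):
        for _ in range(5):
            v = plv(rng.standard_normal(600), rng.standard_normal(600),
                    self.BAND, FS)
            assert 0.0 <= v <= 1.0


class TestPAC:
    PHASE = (4.0, 7.0)
    AMP = (15.0, 35.0)

    @staticmethod
    def _components(rng, dur=5.0, fs=FS, depth=0.9):
        # the slow rhythm must be aperiodic (narrowband noise): a shifted
        # copy of a pure sinusoid would stay phase-locked to the original
        n = int(dur * fs)
        sos = sps.butter(4, [4.0, 7.0], btype="bandpass", fs=fs, output="sos")
        slow = sps.sosfiltfilt(sos, rng.standard_normal(n + 1000))[500:500 + n]
        slow = slow / np.abs(slow).max()
        fast = (1 + depth * slow) * np.sin(2 * np.pi * 25.0 * np.arange(n) / fs)
        noise = 0.1 * rng.standard_normal(n)
        return slow, fast, noise

    def _surrogate_null(self, slow, fast, noise, rng, n=200):
        # rolling the fast component against the slow one destroys the
        # phase-amplitude relationship while preserving both spectra
        # (shifting the whole signal would preserve its internal coupling)
        vals = np.empty(n)
        for i in range(n):
            shift = rng.integers(len(slow) // 4, 3 * len(slow) // 4)
            vals[i] = pac(slow + np.roll(fast, shift) + noise,
                          self.PHASE, self.AMP, FS)
        return vals

    def test_coupled_signal_beats_surrogates(self, rng):
        slow, fast, noise = self._components(rng)
        null = self._surrogate_null(slow, fast, noise, rng)
        assert (pac(slow + fast + noise, self.PHASE, self.AMP, FS)
                > np.quantile(null, 0.95))

    def test_independent_amplitude_within_null(self, rng):
        t = np.arange(1250) / FS
        slow = np.sin(2 * np.pi * 5 * t)
        fast = np.sin(2 * np.pi * 25 * t) * (1 + 0.5 * rng.standard_normal(1250))
        noise = 0.1 * rng.standard_normal(1250)
        null = self._surrogate_null(slow, fast, noise, rng)
        assert (pac(slow + fast + noise, self.PHASE, self.AMP, FS)
                <= np.quantile(null, 0.99))

    def test_constant_amplitude_near_zero(self):
        t = np.arange(2500) / FS
        x = np.sin(2 * np.pi * 5 * t) + np.sin(2 * np.pi * 25 * t)
        assert pac(x, self.PHASE, self.AMP, FS) < 0.1

    def test_too_short_window_flagged(self):
        assert np.isnan(pac(np.zeros(50), self.PHASE, self.AMP, FS))

    def test_matches_bruteforce_oracle(self, rng):
        x = rng.standard_normal(750)
        got = pac(x, self.PHASE, self.AMP, FS)
        sos_p = sps.butter(4, list(self.PHASE), btype="bandpass", fs=FS,
                           output="sos")
        sos_a = sps.butter(4, list(self.AMP), btype="bandpass", fs=FS,
                           output="sos")
        ph = np.angle(sps.hilbert(sps.sosfiltfilt(sos_p, x)))
        am = np.abs(sps.hilbert(sps.sosfiltfilt(sos_a, x)))
        m = int(round(0.25 * FS))
        re = im = asum = 0.0
        n = 0
        for k in range(m, 750 - m):
            re += am[k] * np.cos(ph[k])
            im += am[k] * np.sin(ph[k])
            asum += am[k]
            n += 1
        expected = np.sqrt(re ** 2 + im ** 2) / n / (asum / n)
        assert got == pytest.approx(expected, rel=1e-9)


class TestAsym:
    def test_equal_power_zero(self):
        assert asym_psd(2.0, 2.0) == 0.0

    def test_all_power_right_plus_one(self):
        assert asym_psd(5.0, 0.0) == 1.0

    def test_numeric_case(self):
        assert asym_psd(3.0, 1.0) == pytest.approx(0.5)

    def test_degenerate_zero_power(self):
        assert asym_psd(0.0, 0.0) == 0.0


class TestHbStats:
    def test_linear_trend_slope_and_midpoint(self):
        fs = 8.93
        t = np.arange(int(5 * fs)) / fs
        hbo = 2.0 * t
        d = hb_stats(hbo, np.ones_like(hbo), fs)
        assert d["HbSlope_HbO"] == pytest.approx(2.0, rel=1e-9)
        assert d["HbAmp_HbO"] == pytest.approx(2.0 * t.mean(), rel=1e-9)

    def test_anticorrelated_series(self):
        fs = 8.93
        hbo = np.sin(np.arange(40) / 3.0)
        d = hb_stats(hbo, -hbo, fs)
        assert d["HbCorr"] == pytest.approx(-1.0, abs=1e-12)

    def test_constant_series_corr_zero(self):
        d = hb_stats(np.ones(30), np.arange(30.0), 8.93)
        assert d["HbCorr"] == 0.0

    def test_normal_moments(self, rng):
        x = rng.standard_normal(10_000)
        d = hb_stats(x, x, 8.93)
        assert abs(d["HbSkew_HbO"]) < 0.1
        assert d["HbKurt_HbO"] == pytest.approx(3.0, abs=0.2)  # non-excess


class TestNV:
    def test_dimensionality(self, rng):
        eeg = rng.standard_normal((19, 1250))
        hb_t = np.arange(44) / 8.93
        hb = rng.standard_normal((2, 19, 44))
        nvo, nvr = nv_features(eeg, FS, 0.0, hb, hb_t, Montage(), BANDS)
        assert nvo.shape == (19, 8) and nvr.shape == (19, 8)
        assert np.isfinite(nvo).all() and np.isfinite(nvr).all()
        assert (np.abs(nvo) <= 1.0 + 1e-12).all()

    def test_perfect_coupling_gives_unity(self, rng):
        eeg = rng.standard_normal((19, 1250))
        hb_t = 0.1 + np.arange(44) / 8.93
        idx = {ch: i for i, ch in enumerate(EEG_CHANNELS)}
        bp = band_power_series(eeg[[idx["F7"]]], FS, BANDS)[0]   # (8, frames)
        frame_t = 0.5 + 0.5 * np.arange(bp.shape[-1])
        hb = np.zeros((2, 19, 44))
        hb[0, 0] = np.interp(hb_t, frame_t, bp[2])   # CH1 HbO = F7 alpha power
        hb[1, :] = rng.standard_normal((19, 44))
        nvo, _ = nv_features(eeg, FS, 0.0, hb, hb_t, Montage(), BANDS)
        assert nvo[0, 2] == pytest.approx(1.0, abs=1e-9)

    def test_independent_series_centered_at_zero(self, rng):
        vals = []
        for _ in range(10):
            eeg = rng.standard_normal((19, 1250))
            hb = rng.standard_normal((2, 19, 44))
            hb_t = np.arange(44) / 8.93
            nvo, nvr = nv_features(eeg, FS, 0.0, hb, hb_t, Montage(), BANDS)
            vals.append(np.mean(nvo))
        assert abs(np.mean(vals)) < 0.1


class TestAssembledTable:
    def test_column_counts(self, short_table):
        assert short_table.n_features == 873
        assert short_table.subset_system("eeg").n_features == 360
        assert short_table.subset_system("fnirs").n_features == 209

    def test_bounded_features(self, short_table):
        meta = short_table.meta
        X = short_table.X
        plv_cols = (meta["subgroup"] == "PLV").to_numpy()
        assert (X[:, plv_cols] >= 0).all() and (X[:, plv_cols] <= 1).all()
        psd_cols = (meta["subgroup"] == "PSD").to_numpy()
        assert (X[:, psd_cols] >= 0).all()
        pac_cols = (meta["subgroup"] == "PAC").to_numpy()
        assert (X[:, pac_cols] >= 0).all()
        corrish = (meta["subgroup"].isin(["HbCorr", "NV"])).to_numpy()
        assert (np.abs(X[:, corrish]) <= 1.0 + 1e-9).all()

    def test_offset_invariance_through_preprocessing(self, short_subject):
        """A constant offset on the raw EEG vanishes after preprocessing."""
        from neuroload.pipeline import extract_subject, preprocess_subject
        shifted = short_subject.eeg.copy_with(short_subject.eeg.data[:, :7500] + 100.0)
        base = short_subject.eeg.copy_with(short_subject.eeg.data[:, :7500])
        pre_a = preprocess_subject(short_subject.events, base,
                                   short_subject.fnirs)
        pre_b = preprocess_subject(short_subject.events, shifted,
                                   short_subject.fnirs)
        assert np.allclose(pre_a.eeg.data, pre_b.eeg.data, atol=1e-6)
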