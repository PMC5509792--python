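"""Per-window feature operators and assembly of the three feature systems.

EEG features: band power (PSD, 19 channels x 8 bands of 4 Hz tiling
0-32 Hz), phase-locking value (17 electrode pairs x 4 narrow bands),
phase-amplitude coupling (19 channels x 4 phase/amplitude band
combinations, normalized mean-vector-length estimator), and hemispheric
band-power asymmetry (8 homologous pairs x 8 bands).

fNIRS features: mean amplitude, linear slope, standard deviation, skewness
and kurtosis of HbO and HbR per channel, plus the zero-lag HbO-HbR
correlation.

Hybrid (neurovascular) features: zero-lag correlation between each fNIRS
channel's HbO (NVO) or HbR (NVR) series and the band-power time course of
the mapped forehead electrode (CH1-9 -> F7, CH11-19 -> F8, CH10 -> mean of
both), the EEG course being resampled down onto the fNIRS sample times.

The full EEG, fNIRS and Hybrid systems contain 360, 209 and 873 columns.

Spectrograms use 1 s Hann windows with half-window overlap (1 Hz
resolution).  Phase quantities use the analytic signal of the band-passed
segment; a 0.25 s margin at each window edge is excluded from the time
averages to suppress filter/Hilbert edge effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .montage import BandScheme, Montage, band_label
from .types import (EEG_CHANNELS, FeatureTable, FNIRS_CHANNELS, Recording,
                    Window)

STFT_LEN = 1.0      # s
STFT_STEP = 0.5     # s
EDGE_MARGIN = 0.25  # s excluded from phase averages at each window edge

HB_STATS = ("HbAmp", "HbSlope", "HbStd", "HbSkew", "HbKurt")


def _bandpass(x: np.ndarray, band: tuple[float, float], fs: float,
              order: int = 4) -> np.ndarray:
    sos = signal.butter(order, list(band), btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def _interior(n: int, fs: float, margin: float = EDGE_MARGIN) -> slice:
    m = int(round(margin * fs))
    if 2 * m >= n:
        m = 0
    return slice(m, n - m if m else None)


# ---------------------------------------------------------------------------
# spectral power


def band_power_series(seg: np.ndarray, fs: float,
                      bands: tuple[tuple[float, float], ...]) -> np.ndarray:
    """Band-integrated spectrogram power course, (channels, bands, frames).

    1 s Hann frames, 0.5 s step, 1 Hz resolution; power integrated over the
    band's frequency bins (units signal^2).  Frame count for a window of
    T seconds is floor((T-1)/0.5)+1.
    """
    seg = np.atleast_2d(seg)
    nper = int(round(STFT_LEN * fs))
    step = int(round(STFT_STEP * fs))
    f, _, sxx = signal.spectrogram(seg, fs=fs, window="hann", nperseg=nper,
                                   noverlap=nper - step, scaling="density",
                                   mode="psd")
    df = f[1] - f[0]
    out = np.empty((seg.shape[0], len(bands), sxx.shape[-1]))
    for bi, (lo, hi) in enumerate(bands):
        sel = (f >= lo) & (f < hi)
        out[:, bi] = sxx[:, sel, :].sum(axis=1) * df
    return out


def psd_features(seg: np.ndarray, fs: float,
                 bands: tuple[tuple[float, float], ...]) -> np.ndarray:
    """Mean over frames of the band power course -> (channels, bands)."""
    return band_power_series(seg, fs, bands).mean(axis=-1)


def asym_psd(p_right: float, p_left: float) -> float:
    """Normalized hemispheric power asymmetry, 0 when both powers are 0."""
    tot = p_right + p_left
    return float((p_right - p_left) / tot) if tot != 0 else 0.0


# ---------------------------------------------------------------------------
# phase synchrony and cross-frequency coupling


def plv(a: np.ndarray, b: np.ndarray, band: tuple[float, float],
        fs: float) -> float:
    """Phase-locking value between two channels in one narrow band.

    Both signals are band-passed, instantaneous phases are taken from the
    analytic signal, and PLV = |mean of exp(i * phase difference)| over the
    window interior.  1 means perfect phase locking.
    """
    xa = _bandpass(np.asarray(a, float), band, fs)
    xb = _bandpass(np.asarray(b, float), band, fs)
    pa = np.angle(signal.hilbert(xa))
    pb = np.angle(signal.hilbert(xb))
    keep = _interior(len(pa), fs)
    return float(np.abs(np.mean(np.exp(1j * (pa[keep] - pb[keep])))))


def pac(x: np.ndarray, phase_band: tuple[float, float],
        amp_band: tuple[float, float], fs: float) -> float:
    """Phase-amplitude coupling by the normalized mean-vector-length.

    The low-band phase and high-band amplitude envelope come from analytic
    signals of the band-passed segment; the estimator is
    |mean(A(t) exp(i phi(t)))| / mean(A(t)).  Returns NaN when the window
    holds fewer than two cycles of the phase band.
    """
    x = np.asarray(x, float)
    if len(x) / fs < 2.0 / phase_band[0]:
        return float("nan")
    phase = np.angle(signal.hilbert(_bandpass(x, phase_band, fs)))
    amp = np.abs(signal.hilbert(_bandpass(x, amp_band, fs)))
    keep = _interior(len(x), fs)
    phase, amp = phase[keep], amp[keep]
    denom = amp.mean()
    if denom == 0:
        return 0.0
    return float(np.abs(np.mean(amp * np.exp(1j * phase))) / denom)


# ---------------------------------------------------------------------------
# hemoglobin statistics


def _corr0(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-lag Pearson correlation; 0 when either series is constant."""
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def hb_stats(hbo: np.ndarray, hbr: np.ndarray, fs: float) -> dict[str, float]:
    """Window statistics of the two hemoglobin series.

    amp = mean; slope = least-squares linear trend per second; std, skew
    and kurtosis are the standard sample moments (kurtosis non-excess, so
    a normal series gives ~3); corr = zero-lag Pearson HbO vs HbR.
    """
    if len(hbo) < 3:
        raise ValueError("hemoglobin window must hold at least 3 samples")
    t = np.arange(len(hbo)) / fs
    out: dict[str, float] = {}
    for name, x in (("HbO", hbo), ("HbR", hbr)):
        tc = t - t.mean()
        denom = (tc ** 2).sum()
        slope = float((tc * (x - x.mean())).sum() / denom) if denom else 0.0
        out[f"HbAmp_{name}"] = float(x.mean())
        out[f"HbSlope_{name}"] = slope
        out[f"HbStd_{name}"] = float(x.std(ddof=1))
        if np.ptp(x) == 0:      # moments undefined for a constant series
            out[f"HbSkew_{name}"] = 0.0
            out[f"HbKurt_{name}"] = 0.0
        else:
            out[f"HbSkew_{name}"] = float(stats.skew(x))
            out[f"HbKurt_{name}"] = float(stats.kurtosis(x, fisher=False))
    out["HbCorr"] = _corr0(np.asarray(hbo, float), np.asarray(hbr, float))
    return out


# ---------------------------------------------------------------------------
# neurovascular coupling


def nv_features(eeg_seg: np.ndarray, eeg_fs: float, eeg_t0: float,
                hb_seg: np.ndarray, hb_times: np.ndarray,
                montage: Montage, bands: tuple[tuple[float, float], ...],
                eeg_channels: tuple[str, ...] = EEG_CHANNELS,
                ) -> tuple[np.ndarray, np.ndarray]:
    """Zero-lag correlation of Hb series with mapped EEG band power.

    ``eeg_seg`` is the window's (channels, samples) EEG segment starting at
    absolute time ``eeg_t0``; ``hb_seg`` is (2, 19, samples) with absolute
    sample times ``hb_times``.  For every fNIRS channel and band the mapped
    electrode's band-power course (frame centers) is linearly interpolated
    onto the fNIRS sample times and correlated with HbO (NVO) and HbR
    (NVR).  Returns two (19, n_bands) arrays; NaN where fewer than 3 common
    samples exist.
    """
    idx = {ch: i for i, ch in enumerate(eeg_channels)}
    need = sorted({e for v in montage.nv_mapping.values() for e in v})
    bp = band_power_series(eeg_seg[[idx[e] for e in need]], eeg_fs, bands)
    frame_t = eeg_t0 + STFT_LEN / 2.0 + STFT_STEP * np.arange(bp.shape[-1])
    course = {e: bp[i] for i, e in enumerate(need)}       # (bands, frames)

    nvo = np.full((len(FNIRS_CHANNELS), len(bands)), np.nan)
    nvr = np.full_like(nvo, np.nan)
    if len(hb_times) < 3 or bp.shape[-1] < 2:
        return nvo, nvr
    for c, ch in enumerate(FNIRS_CHANNELS):
        electrodes = montage.nv_mapping[ch]
        pow_course = np.mean([course[e] for e in electrodes], axis=0)
        for bi in range(len(bands)):
            resampled = np.interp(hb_times, frame_t, pow_course[bi])
            nvo[c, bi] = _corr0(resampled, hb_seg[0, c])
            nvr[c, bi] = _corr0(resampled, hb_seg[1, c])
    return nvo, nvr


# ---------------------------------------------------------------------------
# assembly


def feature_metadata(montage: Montage | None = None,
                     bands: BandScheme | None = None,
                     system: str = "hybrid") -> pd.DataFrame:
    """Enumerate the feature columns of a system, in extraction order."""
    montage = montage or Montage()
    bands = bands or BandScheme()
    rows: list[dict] = []

    def add(subgroup, nv_type="", band="", chromophore="", channel=""):
        rows.append(dict(subgroup=subgroup, nv_type=nv_type, band=band,
                         chromophore=chromophore, channel=channel))

    if system in ("eeg", "hybrid"):
        for b in bands.psd_bands:
            for ch in EEG_CHANNELS:
                add("PSD", band=band_label(b), channel=ch)
        for b in bands.plv_bands:
            for a, c in montage.all_plv_pairs():
                add("PLV", band=band_label(b), channel=f"{a}-{c}")
        for pb, ab in bands.pac_combos:
            for ch in EEG_CHANNELS:
                add("PAC", band=f"{band_label(pb)}x{band_label(ab)}", channel=ch)
        for b in bands.psd_bands:
            for r, l in montage.asym_pairs:
                add("Asym_PSD", band=band_label(b), channel=f"{r}-{l}")
    if system in ("fnirs", "hybrid"):
        for stat in HB_STATS:
            for chrom in ("HbO", "HbR"):
                for ch in FNIRS_CHANNELS:
                    add(stat, chromophore=chrom, channel=ch)
        for ch in FNIRS_CHANNELS:
            add("HbCorr", channel=ch)
    if system == "hybrid":
        for nv_type, chrom in (("NVO", "HbO"), ("NVR", "HbR")):
            for b in bands.psd_bands:
                for ch in FNIRS_CHANNELS:
                    add("NV", nv_type=nv_type, band=band_label(b),
                        chromophore=chrom, channel=ch)
    return pd.DataFrame(rows)


@dataclass
class FeatureExtractor:
    """Computes the full Hybrid feature table for a list of windows.

    Continuous signals are band-pass filtered once per narrow band; per
    window only the analytic signal / spectrogram bookkeeping is done,
    which keeps the cost linear in recording length.
    """

    montage: Montage = field(default_factory=Montage)
    bands: BandScheme = field(default_factory=BandScheme)

    def extract(self, windows: list[Window], eeg: Recording,
                hb: Recording) -> FeatureTable:
        if eeg.modality != "eeg" or hb.modality != "hb":
            raise ValueError("extract() needs an eeg and an hb Recording")
        montage, bands = self.montage, self.bands
        fs = eeg.sample_rate
        idx = {ch: i for i, ch in enumerate(eeg.channel_labels)}

        # continuous per-band filtered signals for phase features
        plv_channels = sorted({c for p in montage.all_plv_pairs() for c in p})
        plv_rows = [idx[c] for c in plv_channels]
        plv_pos = {c: i for i, c in enumerate(plv_channels)}
        plv_filt = {b: _bandpass(eeg.data[plv_rows], b, fs)
                    for b in bands.plv_bands}
        pac_phase_filt = {b: _bandpass(eeg.data, b, fs)
                          for b in bands.pac_phase_bands}
        pac_amp_filt = {b: _bandpass(eeg.data, b, fs)
                        for b in bands.pac_amp_bands}

        hb_times = hb.times
        meta = feature_metadata(montage, bands, "hybrid")
        X = np.empty((len(windows), len(meta)))

        for wi, w in enumerate(windows):
            i0 = int(round((w.t_start - eeg.start_time) * fs))
            i1 = int(round((w.t_end - eeg.start_time) * fs))
            seg = eeg.data[:, i0:i1]
            keep = _interior(seg.shape[1], fs)

            psd = psd_features(seg, fs, bands.psd_bands)      # (19, 8)

            plv_vals = np.empty((len(bands.plv_bands), 17))
            for bi, b in enumerate(bands.plv_bands):
                analytic = signal.hilbert(plv_filt[b][:, i0:i1], axis=-1)
                phases = np.angle(analytic[:, keep])
                for pi, (a, c) in enumerate(montage.all_plv_pairs()):
                    d = phases[plv_pos[a]] - phases[plv_pos[c]]
                    plv_vals[bi, pi] = np.abs(np.mean(np.exp(1j * d)))

            phase_sig = {b: np.angle(signal.hilbert(
                pac_phase_filt[b][:, i0:i1], axis=-1))[:, keep]
                for b in bands.pac_phase_bands}
            amp_sig = {b: np.abs(signal.hilbert(
                pac_amp_filt[b][:, i0:i1], axis=-1))[:, keep]
                for b in bands.pac_amp_bands}
            pac_vals = np.empty((len(bands.pac_combos), len(EEG_CHANNELS)))
            for ci, (pb, ab) in enumerate(bands.pac_combos):
                amp, ph = amp_sig[ab], phase_sig[pb]
                denom = amp.mean(axis=-1)
                num = np.abs(np.mean(amp * np.exp(1j * ph), axis=-1))
                pac_vals[ci] = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)

            asym_vals = np.empty((len(bands.psd_bands), len(montage.asym_pairs)))
            for bi in range(len(bands.psd_bands)):
                for pi, (r, l) in enumerate(montage.asym_pairs):
                    asym_vals[bi, pi] = asym_psd(psd[idx[r], bi], psd[idx[l], bi])

            tsel = (hb_times >= w.t_start) & (hb_times < w.t_end)
            hb_seg = hb.data[:, :, tsel]
            hstat = np.empty((len(HB_STATS), 2, len(FNIRS_CHANNELS)))
            hcorr = np.empty(len(FNIRS_CHANNELS))
            for c in range(len(FNIRS_CHANNELS)):
                d = hb_stats(hb_seg[0, c], hb_seg[1, c], hb.sample_rate)
                for si, stat in enumerate(HB_STATS):
                    hstat[si, 0, c] = d[f"{stat}_HbO"]
                    hstat[si, 1, c] = d[f"{stat}_HbR"]
                hcorr[c] = d["HbCorr"]

            nvo, nvr = nv_features(seg, fs, w.t_start, hb_seg,
                                   hb_times[tsel], montage, bands.psd_bands,
                                   tuple(eeg.channel_labels))

            X[wi] = np.concatenate([
                psd.T.ravel(),          # band-major: (band, channel)
                plv_vals.ravel(),
                pac_vals.ravel(),
                asym_vals.ravel(),
                hstat.ravel(),
                hcorr,
                nvo.T.ravel(),          # (band, channel)
                nvr.T.ravel(),
            ])

        y = np.array([w.code for w in windows])
        return FeatureTable(X, meta, y, windows)


def assemble_features(windows: list[Window], eeg: Recording, hb: Recording,
                      system: str = "hybrid",
                      montage: Montage | None = None,
                      bands: BandScheme | None = None) -> FeatureTable:
    """Extract one system's feature table (thin wrapper over the extractor)."""
    ext = FeatureExtractor(montage or Montage(), bands or BandScheme())
    table = ext.extract(windows, eeg, hb)
    return table if system == "hybrid" else table.subset_system(system)
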