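"""Signal conditioning and screening.

EEG: zero-phase 0.5-80 Hz band-pass with a 60 Hz notch, then a surface
Laplacian (each channel minus the mean of its montage neighbors).  fNIRS:
dual-wavelength intensities are converted to oxy-/deoxyhemoglobin
concentration changes through the modified Beer-Lambert law and band-pass
filtered 0.01-0.5 Hz to suppress cardiac pulsation and drift while keeping
the Mayer-wave/hemodynamic band.  Behavioral and artifact screening decide
whether a subject/recording enters the analysis at all.

All filters are order-4 Butterworth applied forward-backward (zero phase).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .montage import Montage
from .types import CONDITIONS, EventLog, Recording

# Chromophore extinction coefficients, 1/(mM*cm), at (760, 850) nm.
# Row order follows the wavelength planes; columns are (HbO, HbR).
EXTINCTION_MM_CM = np.array([
    [1.4866, 3.8437],   # 760 nm
    [2.5264, 1.7986],   # 850 nm
])


@dataclass(frozen=True)
class MBLLConstants:
    """Constants of the modified Beer-Lambert conversion."""

    wavelengths: tuple[int, int] = (760, 850)
    extinction: tuple[tuple[float, float], ...] = tuple(
        tuple(row) for row in EXTINCTION_MM_CM
    )
    dpf: tuple[float, float] = (6.0, 6.0)   # differential path-length factor
    distance: float = 3.0                   # source-detector separation, cm

    def extinction_matrix(self) -> np.ndarray:
        eps = np.asarray(self.extinction, dtype=float)
        if abs(np.linalg.det(eps)) < 1e-12:
            raise ValueError("extinction matrix is singular")
        return eps


def _band_sos(lo: float, hi: float, fs: float, order: int = 4) -> np.ndarray:
    return signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def filter_eeg(rec: Recording, lo: float = 0.5, hi: float = 80.0,
               notch: float = 60.0, notch_q: float = 30.0) -> Recording:
    """Zero-phase band-pass plus power-line notch, per channel."""
    if rec.modality != "eeg":
        raise ValueError("filter_eeg expects an eeg Recording")
    if rec.sample_rate < 2 * hi:
        raise ValueError(
            f"sample rate {rec.sample_rate} Hz too low for {hi} Hz band edge"
        )
    sos = _band_sos(lo, hi, rec.sample_rate)
    out = signal.sosfiltfilt(sos, rec.data, axis=-1)
    b, a = signal.iirnotch(notch, notch_q, fs=rec.sample_rate)
    out = signal.filtfilt(b, a, out, axis=-1)
    return rec.copy_with(out)


def laplacian(rec: Recording, montage: Montage) -> Recording:
    """Surface Laplacian: subtract the mean of each channel's neighbors."""
    if rec.modality != "eeg":
        raise ValueError("laplacian expects an eeg Recording")
    idx = {ch: i for i, ch in enumerate(rec.channel_labels)}
    out = np.empty_like(rec.data)
    for ch, i in idx.items():
        neigh = montage.eeg_adjacency.get(ch, ())
        if not neigh:
            raise ValueError(f"channel {ch} has no Laplacian neighbors")
        out[i] = rec.data[i] - rec.data[[idx[n] for n in neigh]].mean(axis=0)
    return rec.copy_with(out)


def mbll(rec: Recording, constants: MBLLConstants | None = None,
         i0: np.ndarray | str = "mean") -> Recording:
    """Modified Beer-Lambert law: intensities -> (HbO, HbR) changes.

    Optical density change per wavelength is ``dOD = -log10(I / I0)`` with
    ``I0`` the per-channel temporal mean intensity by default (pass an
    explicit ``(2, n_channels)`` baseline to override).  Concentrations then
    follow from inverting ``dOD = d * DPF * eps @ dC``; with extinction in
    1/(mM*cm) and distance in cm the output is in mM.
    """
    if rec.modality != "fnirs_intensity":
        raise ValueError("mbll expects an fnirs_intensity Recording")
    constants = constants or MBLLConstants()
    I = rec.data
    if np.any(I <= 0):
        lam, ch, t = np.argwhere(I <= 0)[0]
        raise ValueError(
            f"non-positive intensity at wavelength plane {lam}, "
            f"channel {rec.channel_labels[ch]}, sample {t}"
        )
    if isinstance(i0, str):
        if i0 != "mean":
            raise ValueError("i0 must be 'mean' or an explicit baseline array")
        baseline = I.mean(axis=-1)
    else:
        baseline = np.asarray(i0, dtype=float)
        if baseline.shape != I.shape[:2]:
            raise ValueError("explicit i0 must have shape (2, n_channels)")
    dod = -np.log10(I / baseline[..., None])            # (2, ch, t)
    eps = constants.extinction_matrix()
    path = constants.distance * np.asarray(constants.dpf)  # effective path, cm
    # solve  dod[lam] = path[lam] * (eps @ dC)[lam]  for dC = (HbO, HbR)
    A = eps * path[:, None]
    hb = np.einsum("ij,jct->ict", np.linalg.inv(A), dod)
    out = rec.copy_with(hb, modality="hb")
    out.meta["mbll"] = {
        "distance_cm": constants.distance,
        "dpf": tuple(constants.dpf),
        "i0": "mean" if isinstance(i0, str) else "explicit",
    }
    return out


def mbll_forward(hb: np.ndarray, constants: MBLLConstants | None = None,
                 i0: np.ndarray | float = 1.0) -> np.ndarray:
    """Forward Beer-Lambert map: (HbO, HbR) changes -> raw intensities.

    The exact inverse of :func:`mbll` when the same baseline is supplied.
    Used by the synthetic generator and by round-trip checks.
    """
    constants = constants or MBLLConstants()
    eps = constants.extinction_matrix()
    path = constants.distance * np.asarray(constants.dpf)
    A = eps * path[:, None]
    dod = np.einsum("ij,jct->ict", A, np.asarray(hb, dtype=float))
    baseline = np.asarray(i0, dtype=float)
    if baseline.ndim == 0:
        baseline = np.full(dod.shape[:2], float(baseline))
    return baseline[..., None] * 10.0 ** (-dod)


def filter_fnirs(rec: Recording, lo: float = 0.01, hi: float = 0.5) -> Recording:
    """Zero-phase 0.01-0.5 Hz band-pass on each hemoglobin plane."""
    if rec.modality != "hb":
        raise ValueError("filter_fnirs expects an hb Recording")
    sos = _band_sos(lo, hi, rec.sample_rate)
    out = signal.sosfiltfilt(sos, rec.data, axis=-1)
    return rec.copy_with(out)


@dataclass
class PerformanceReport:
    accuracy: pd.Series       # per condition
    mean_rt: pd.Series        # over correct target responses, per condition
    exclude: bool             # insufficiently-focused cutoff triggered


def performance(log: EventLog, cutoff_0back: float = 0.90,
                cutoff_1back: float = 0.80) -> PerformanceReport:
    """Per-condition behavioral accuracy and response time.

    A letter is scored correct when the subject responded to a target or
    withheld response to a non-target; a missed target counts as incorrect.
    The exclusion flag fires when 0-back accuracy < 90% or 1-back < 80%.
    """
    f = log.frame
    correct = (f["is_target"] & f["responded"]) | (~f["is_target"] & ~f["responded"])
    acc = correct.groupby(f["condition"]).mean().reindex(list(CONDITIONS))
    hit = f["is_target"] & f["responded"]
    rt = f.loc[hit, "response_time"].groupby(f.loc[hit, "condition"]).mean()
    rt = rt.reindex(list(CONDITIONS))
    exclude = bool(acc.get("0back", 1.0) < cutoff_0back
                   or acc.get("1back", 1.0) < cutoff_1back)
    return PerformanceReport(accuracy=acc, mean_rt=rt, exclude=exclude)


@dataclass
class ArtifactReport:
    fraction: float
    keep: bool


def artifact_screen(rec: Recording, threshold: float = 0.10,
                    amp_limit: float | None = None,
                    grad_limit: float | None = None,
                    mask: np.ndarray | None = None) -> ArtifactReport:
    """Whole-recording exclusion when artifact contamination exceeds 10%.

    The per-sample artifact mask marks samples where any channel exceeds an
    amplitude or sample-to-sample gradient limit (a pragmatic, configurable
    stand-in for visual inspection); an explicit mask can be supplied
    instead.  The record is dropped when the masked fraction is strictly
    greater than ``threshold``.
    """
    if mask is None:
        flat = rec.data.reshape(-1, rec.n_samples)
        mask = np.zeros(rec.n_samples, dtype=bool)
        if amp_limit is not None:
            mask |= (np.abs(flat) > amp_limit).any(axis=0)
        if grad_limit is not None:
            grad = np.abs(np.diff(flat, axis=-1, prepend=flat[:, :1]))
            mask |= (grad > grad_limit).any(axis=0)
    frac = float(np.mean(mask))
    return ArtifactReport(fraction=frac, keep=not frac > threshold)
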