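"""Protocol-faithful synthetic subjects: events, EEG, and fNIRS intensities.

The generator emulates the statistical structure the analysis assumes:

- behavior: per-condition accuracy decreasing and response time increasing
  with working-memory load;
- EEG: 1/f background plus narrowband theta and alpha oscillations; during
  task blocks frontal-midline theta amplitude grows with load and
  parietal/occipital alpha attenuates at the higher loads;
- hemodynamics: a canonical double-gamma response to each task block whose
  oxyhemoglobin amplitude rises from 0- to 2-back and dips at 3-back, an
  anticipatory HbO rise late in each rest block, Mayer-wave (~0.1 Hz) and
  cardiac (~1 Hz) physiological noise;
- neurovascular coupling: a shared slow latent drive modulates the forehead
  EEG amplitude (F7/F8) and feeds additively into the hemoglobin series, so
  EEG-band-power/Hb correlations carry real shared variance.

Concentrations are pushed through the forward modified Beer-Lambert map so
the preprocessing stage has genuine dual-wavelength intensities to invert.

All randomness flows from a single integer seed via independent
``numpy.random.default_rng([seed, stream])`` streams; the same seed and
parameters give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal, special

from .preprocess import MBLLConstants, mbll_forward
from .types import (CONDITIONS, EEG_CHANNELS, EEG_RATE, FNIRS_CHANNELS,
                    FNIRS_RATE, EventLog, ProtocolSpec, Recording)

LETTER_POOL = ("B", "C", "D", "F", "G", "H", "K", "N", "P", "T")
ZERO_BACK_REFERENCE = "T"   # fixed target letter of the 0-back condition

_FRONTAL_MIDLINE = ("Fz", "Fc1", "Fc2")
_POSTERIOR = ("P3", "P4", "Pz", "Poz", "O1", "O2")
_COUPLED = ("F7", "F8")     # electrodes driven by the neurovascular latent

# rng stream indices
_PROTOCOL, _BEHAVIOR, _LATENT, _EEG, _FNIRS = range(5)


@dataclass(frozen=True)
class SubjectParams:
    """Effect sizes and noise levels of one synthetic subject.

    Magnitudes are chosen to reproduce the qualitative orderings the
    analysis tests for (accuracy decreasing in load, theta up / alpha down,
    HbO peak 0<1<2-back with a 3-back dip), not any particular empirical
    effect size.  Hemoglobin quantities are in mM, EEG in microvolts.
    """

    # behavior
    accuracy: tuple[float, ...] = (0.98, 0.97, 0.90, 0.80)
    rt_mean: tuple[float, ...] = (0.45, 0.55, 0.75, 0.95)      # s
    rt_sigma: float = 0.25          # lognormal shape parameter
    target_rate: float = 0.3

    # EEG task effects (fractional amplitude gain per condition, task blocks)
    theta_gain: tuple[float, ...] = (0.05, 0.12, 0.25, 0.40)
    alpha_gain: tuple[float, ...] = (0.0, 0.0, -0.12, -0.22)

    # EEG composition (microvolt rms)
    pink_level: float = 10.0
    theta_amp: float = 4.0
    alpha_amp: float = 5.0
    eeg_white: float = 2.0

    # hemodynamics (mM)
    hbo_amp: tuple[float, ...] = (1.5e-4, 3e-4, 5e-4, 4e-4)
    hbr_ratio: float = -0.35        # HbR response relative to HbO
    anticipatory_rise: float = 10.0  # s before rest end
    anticipatory_amp: float = 1.5e-4
    mayer_amp: float = 1.5e-4
    cardiac_amp: float = 0.5e-4
    hb_noise: float = 1.0e-4

    # neurovascular coupling via the shared latent drive
    coupling_strength: float = 3e-4   # mM per unit latent
    coupling_eeg_gain: float = 0.4    # fractional F7/F8 amplitude modulation

    def __post_init__(self) -> None:
        if not all(0.0 <= a <= 1.0 for a in self.accuracy):
            raise ValueError("accuracies must lie in [0, 1]")
        for name in ("pink_level", "theta_amp", "alpha_amp", "eeg_white",
                     "mayer_amp", "cardiac_amp", "hb_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def without_condition_effects(self) -> "SubjectParams":
        """All load-dependent effects zeroed: signals carry no class label."""
        z4 = (0.0,) * 4
        return replace(self, theta_gain=z4, alpha_gain=z4, hbo_amp=z4,
                       anticipatory_amp=0.0)

    def without_eeg_effects(self) -> "SubjectParams":
        return replace(self, theta_gain=(0.0,) * 4, alpha_gain=(0.0,) * 4)

    def without_hb_effects(self) -> "SubjectParams":
        return replace(self, hbo_amp=(0.0,) * 4, anticipatory_amp=0.0)


# ---------------------------------------------------------------------------
# protocol and behavior


def simulate_protocol(spec: ProtocolSpec | None = None, seed: int = 0,
                      target_rate: float = 0.3) -> EventLog:
    """Pseudorandom session order and letter streams with n-back targets.

    Targets are planted at ``target_rate``; non-target letters are drawn
    avoiding accidental targets, so ``is_target`` follows exactly from the
    n-back rule applied to the letter stream.
    """
    spec = spec or ProtocolSpec()
    rng = np.random.default_rng([seed, _PROTOCOL])
    pool = LETTER_POOL[:spec.letter_pool_size]

    order = np.repeat(np.arange(len(spec.conditions)), spec.sessions_per_condition)
    rng.shuffle(order)

    rows = []
    for sess, cond_i in enumerate(order):
        cond = spec.conditions[cond_i]
        n = int(cond[0])
        t0 = sess * spec.session_dur + spec.instruction_dur
        letters: list[str] = []
        for k in range(spec.n_letters):
            ref = (ZERO_BACK_REFERENCE if n == 0
                   else (letters[k - n] if k >= n else None))
            if ref is not None and rng.random() < target_rate:
                letter = ref
            else:
                choices = [c for c in pool if c != ref]
                letter = choices[rng.integers(len(choices))]
            letters.append(letter)
            is_target = (letter == ZERO_BACK_REFERENCE if n == 0
                         else (k >= n and letter == letters[k - n]))
            rows.append({
                "onset": t0 + k * spec.letter_period,
                "session_index": sess,
                "condition": cond,
                "letter": letter,
                "is_target": bool(is_target),
                "responded": False,
                "response_time": np.nan,
            })
    return EventLog(pd.DataFrame(rows), spec)


def simulate_behavior(log: EventLog, params: SubjectParams | None = None,
                      seed: int = 0) -> EventLog:
    """Draw responses: condition-specific accuracy, right-skewed RTs."""
    params = params or SubjectParams()
    rng = np.random.default_rng([seed, _BEHAVIOR])
    cond_i = {c: i for i, c in enumerate(CONDITIONS)}

    frame = log.frame.copy()
    acc = np.array([params.accuracy[cond_i[c]] for c in frame["condition"]])
    correct = rng.random(len(frame)) < acc
    responded = np.where(correct, frame["is_target"], ~frame["is_target"])
    mu = np.log([params.rt_mean[cond_i[c]] for c in frame["condition"]])
    rt = rng.lognormal(mean=mu - params.rt_sigma ** 2 / 2.0,
                       sigma=params.rt_sigma)
    rt = np.clip(rt, 0.15, log.spec.response_window)
    frame["responded"] = responded
    frame["response_time"] = np.where(responded, rt, np.nan)
    return EventLog(frame, log.spec)


# ---------------------------------------------------------------------------
# shared latent drive

def latent_drive(duration: float, seed: int, lo: float = 0.02,
                 hi: float = 0.15, grid_rate: float = 4.0) -> tuple[np.ndarray, float]:
    """Unit-variance slow Gaussian drive shared by both modalities.

    Returned on a coarse grid (``grid_rate`` Hz); callers interpolate onto
    their own sample times.  The drive is class-independent: any class
    information in the outputs enters only through the condition effects.
    """
    rng = np.random.default_rng([seed, _LATENT])
    n = int(np.ceil(duration * grid_rate)) + 1
    white = rng.standard_normal(n + int(20 * grid_rate))  # padding vs filter edges
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=grid_rate, output="sos")
    s = signal.sosfiltfilt(sos, white)[int(10 * grid_rate):][:n]
    s = (s - s.mean()) / s.std()
    return s, grid_rate


def _interp_latent(s: np.ndarray, grid_rate: float, times: np.ndarray) -> np.ndarray:
    grid_t = np.arange(len(s)) / grid_rate
    return np.interp(times, grid_t, s)


# ---------------------------------------------------------------------------
# EEG


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """1/f-amplitude noise, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    shape = np.ones_like(f)
    shape[1:] = 1.0 / np.sqrt(f[1:] / f[1])
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n)
    return x / x.std()


def _narrowband(rng: np.random.Generator, n: int, lo: float, hi: float,
                fs: float) -> np.ndarray:
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _condition_envelope(log: EventLog, times: np.ndarray,
                        gains: tuple[float, ...]) -> np.ndarray:
    """Piecewise-constant fractional gain: gains[cond] inside task blocks."""
    cond_i = {c: i for i, c in enumerate(CONDITIONS)}
    env = np.zeros_like(times)
    for block in log.blocks():
        if block.kind != "task":
            continue
        sel = (times >= block.t_start) & (times < block.t_end)
        env[sel] = gains[cond_i[block.label]]
    return env


def simulate_eeg(log: EventLog, params: SubjectParams | None = None,
                 seed: int = 0, latent: tuple[np.ndarray, float] | None = None,
                 ) -> Recording:
    """19-channel 250 Hz EEG with load-dependent band-power structure."""
    params = params or SubjectParams()
    spec = log.spec
    rng = np.random.default_rng([seed, _EEG])
    n = int(round(spec.total_dur * EEG_RATE))
    times = np.arange(n) / EEG_RATE
    if latent is None:
        latent = latent_drive(spec.total_dur, seed)
    s = _interp_latent(*latent, times)

    theta_env = 1.0 + _condition_envelope(log, times, params.theta_gain)
    alpha_env = 1.0 + _condition_envelope(log, times, params.alpha_gain)
    coupling_env = np.clip(1.0 + params.coupling_eeg_gain * s, 0.05, None)

    data = np.empty((len(EEG_CHANNELS), n))
    for i, ch in enumerate(EEG_CHANNELS):
        x = params.pink_level * _pink_noise(rng, n)
        theta = params.theta_amp * _narrowband(rng, n, 4.0, 8.0, EEG_RATE)
        alpha = params.alpha_amp * _narrowband(rng, n, 8.0, 12.0, EEG_RATE)
        if ch in _FRONTAL_MIDLINE:
            theta = theta * theta_env
        if ch in _POSTERIOR:
            alpha = alpha * alpha_env
        x = x + theta + alpha
        if ch in _COUPLED:
            x = x * coupling_env
        x = x + params.eeg_white * rng.standard_normal(n)
        data[i] = x
    return Recording("eeg", EEG_CHANNELS, EEG_RATE, data,
                     meta={"seed": seed})


# ---------------------------------------------------------------------------
# fNIRS


def double_gamma_hrf(t: np.ndarray, peak: float = 6.0, under: float = 16.0,
                     ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic impulse response, peak amplitude 1."""
    t = np.asarray(t, dtype=float)
    h = (t ** (peak - 1) * np.exp(-t) / special.gamma(peak)
         - t ** (under - 1) * np.exp(-t) / (ratio * special.gamma(under)))
    h[t < 0] = 0.0
    m = h.max()
    return h / m if m > 0 else h


def _hemodynamic_drive(log: EventLog, times: np.ndarray,
                       amps: tuple[float, ...], anticipatory_amp: float,
                       anticipatory_rise: float) -> np.ndarray:
    """Condition-scaled boxcar convolved with the double-gamma kernel,
    plus a linear anticipatory ramp late in each rest block."""
    cond_i = {c: i for i, c in enumerate(CONDITIONS)}
    dt = times[1] - times[0]
    box = np.zeros_like(times)
    for block in log.blocks():
        if block.kind == "task":
            sel = (times >= block.t_start) & (times < block.t_end)
            box[sel] = amps[cond_i[block.label]]
    kernel = double_gamma_hrf(np.arange(0.0, 32.0, dt))
    drive = signal.fftconvolve(box, kernel * dt, mode="full")[:len(times)]
    # normalize the kernel to unit block response scale: convolving a unit
    # boxcar with the unit-peak kernel (times dt) gives a plateau ~ integral
    area = kernel.sum() * dt
    drive = drive / area
    for block in log.blocks():
        if block.kind != "rest":
            continue
        t_ramp = block.t_end - anticipatory_rise
        sel = (times >= t_ramp) & (times < block.t_end)
        drive[sel] += (anticipatory_amp
                       * (times[sel] - t_ramp) / anticipatory_rise)
    return drive


def simulate_fnirs(log: EventLog, params: SubjectParams | None = None,
                   seed: int = 0, latent: tuple[np.ndarray, float] | None = None,
                   constants: MBLLConstants | None = None) -> Recording:
    """Dual-wavelength raw intensities at 8.93 Hz via the forward MBLL.

    The true concentration series (mM) are synthesized per channel, then
    mapped to 760/850 nm intensities around a unit baseline; the baseline
    is recorded in ``meta["i0"]`` so exact inversion can be tested.
    """
    params = params or SubjectParams()
    constants = constants or MBLLConstants()
    spec = log.spec
    rng = np.random.default_rng([seed, _FNIRS])
    n = int(round(spec.total_dur * FNIRS_RATE))
    times = np.arange(n) / FNIRS_RATE
    if latent is None:
        latent = latent_drive(spec.total_dur, seed)
    s = _interp_latent(*latent, times)

    base_drive = _hemodynamic_drive(log, times, params.hbo_amp,
                                    params.anticipatory_amp,
                                    params.anticipatory_rise)
    ch_scale = rng.uniform(0.8, 1.2, size=len(FNIRS_CHANNELS))
    mayer_phase = rng.uniform(0, 2 * np.pi, size=len(FNIRS_CHANNELS))
    cardiac_phase = rng.uniform(0, 2 * np.pi, size=len(FNIRS_CHANNELS))
    cardiac_freq = rng.uniform(0.9, 1.1)

    hb = np.empty((2, len(FNIRS_CHANNELS), n))
    for c in range(len(FNIRS_CHANNELS)):
        mayer = params.mayer_amp * np.sin(2 * np.pi * 0.1 * times + mayer_phase[c])
        cardiac = params.cardiac_amp * np.sin(
            2 * np.pi * cardiac_freq * times + cardiac_phase[c])
        shared = params.coupling_strength * s
        hbo = (ch_scale[c] * base_drive + shared + mayer + cardiac
               + params.hb_noise * rng.standard_normal(n))
        hbr = (params.hbr_ratio * ch_scale[c] * base_drive
               + params.hbr_ratio * shared
               + 0.5 * params.hb_noise * rng.standard_normal(n))
        hb[0, c] = hbo
        hb[1, c] = hbr

    i0 = np.ones((2, len(FNIRS_CHANNELS)))
    intensity = mbll_forward(hb, constants, i0=i0)
    return Recording("fnirs_intensity", FNIRS_CHANNELS, FNIRS_RATE, intensity,
                     meta={"seed": seed, "i0": i0, "wavelengths": (760, 850)})


# ---------------------------------------------------------------------------
# one-call subject


@dataclass
class SyntheticSubject:
    events: EventLog
    eeg: Recording
    fnirs: Recording
    params: SubjectParams
    seed: int


def simulate_subject(seed: int = 0, params: SubjectParams | None = None,
                     spec: ProtocolSpec | None = None) -> SyntheticSubject:
    """Full synthetic subject: events with responses, EEG, fNIRS."""
    params = params or SubjectParams()
    spec = spec or ProtocolSpec()
    log = simulate_protocol(spec, seed)
    log = simulate_behavior(log, params, seed)
    latent = latent_drive(spec.total_dur, seed)
    eeg = simulate_eeg(log, params, seed, latent)
    fnirs = simulate_fnirs(log, params, seed, latent)
    return SyntheticSubject(log, eeg, fnirs, params, seed)
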