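"""Core domain types for the hybrid EEG+fNIRS workload pipeline.

The experiment is a letter n-back protocol: 40 sessions (10 per load level
n in {0,1,2,3}), each session being a 5 s instruction block, a 44 s task
block (22 letters at 2 s each) and a 25 s rest block.  Everything downstream
(preprocessing, windowing, feature extraction, classification) speaks the
types defined here.

Time is expressed in seconds from recording start; analysis windows are
half-open intervals ``[t_start, t_end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Canonical EEG channel order (10-20 sites, no frontopolar electrodes).
EEG_CHANNELS: tuple[str, ...] = (
    "F7", "F8", "F3", "F4", "Fz", "Fc1", "Fc2", "T3", "T4", "C3", "C4",
    "Cp1", "Cp2", "P3", "P4", "Pz", "Poz", "O1", "O2",
)

#: Forehead optical channels (source-detector pairs, left to right).
FNIRS_CHANNELS: tuple[str, ...] = tuple(f"CH{i}" for i in range(1, 20))

#: Dual-wavelength continuous-wave system wavelengths, nm, in plane order.
WAVELENGTHS: tuple[int, int] = (760, 850)

#: Chromophore plane order for hemoglobin recordings.
HB_PLANES: tuple[str, str] = ("HbO", "HbR")

#: Task conditions in increasing working-memory load order.
CONDITIONS: tuple[str, ...] = ("0back", "1back", "2back", "3back")

#: Reference integer codes used to build the label series for R^2 ranking.
CLASS_CODES: dict[str, int] = {
    "rest": 0, "0back": 1, "1back": 2, "2back": 3, "3back": 4,
}

EEG_RATE = 250.0
FNIRS_RATE = 8.93

EVENT_COLUMNS = (
    "onset", "session_index", "condition", "letter",
    "is_target", "responded", "response_time",
)


@dataclass(frozen=True)
class ProtocolSpec:
    """Timeline of the letter n-back experiment.

    Defaults describe the full protocol: 40 sessions of
    instruction (5 s) + task (22 letters x 2 s = 44 s) + rest (25 s).
    """

    sessions_per_condition: int = 10
    conditions: tuple[str, ...] = CONDITIONS
    instruction_dur: float = 5.0
    n_letters: int = 22
    letter_display: float = 0.5
    response_window: float = 1.5
    rest_dur: float = 25.0
    letter_pool_size: int = 10

    def __post_init__(self) -> None:
        if self.sessions_per_condition < 1:
            raise ValueError("sessions_per_condition must be >= 1")
        if self.letter_pool_size < 2:
            raise ValueError("letter pool needs at least 2 letters")

    @property
    def n_sessions(self) -> int:
        return self.sessions_per_condition * len(self.conditions)

    @property
    def letter_period(self) -> float:
        return self.letter_display + self.response_window

    @property
    def task_dur(self) -> float:
        return self.n_letters * self.letter_period

    @property
    def session_dur(self) -> float:
        return self.instruction_dur + self.task_dur + self.rest_dur

    @property
    def total_dur(self) -> float:
        return self.n_sessions * self.session_dur


@dataclass(frozen=True)
class Block:
    """A contiguous single-class segment of the recording."""

    kind: str              # "instruction" | "task" | "rest"
    label: str             # class label: condition name, or "rest"
    t_start: float
    t_end: float
    session_index: int

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


class EventLog:
    """Stimulus/response records of one subject's n-back run.

    Wraps a DataFrame with columns ``onset, session_index, condition,
    letter, is_target, responded, response_time`` (one row per presented
    letter).  ``response_time`` is NaN where no response was made.
    """

    def __init__(self, frame: pd.DataFrame, spec: ProtocolSpec | None = None):
        missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"event log missing columns: {missing}")
        self.frame = frame.reset_index(drop=True)
        self.spec = spec or ProtocolSpec()
        self.validate()

    def validate(self) -> None:
        f = self.frame
        for sess, grp in f.groupby("session_index"):
            onsets = grp["onset"].to_numpy()
            if not np.all(np.diff(onsets) > 0):
                raise ValueError(
                    f"onsets not strictly increasing in session {sess}"
                )
            conds = grp["condition"].unique()
            if len(conds) != 1:
                raise ValueError(f"mixed conditions in session {sess}: {conds}")

    def __len__(self) -> int:
        return len(self.frame)

    def session_table(self) -> pd.DataFrame:
        """Per-session condition and start time (instruction onset)."""
        rows = []
        for sess, grp in self.frame.groupby("session_index"):
            rows.append({
                "session_index": int(sess),
                "condition": grp["condition"].iloc[0],
                "t_start": float(grp["onset"].min()) - self.spec.instruction_dur,
            })
        return pd.DataFrame(rows).sort_values("session_index").reset_index(drop=True)

    def blocks(self) -> list[Block]:
        """Instruction/task/rest block boundaries for every session."""
        spec = self.spec
        out: list[Block] = []
        for _, row in self.session_table().iterrows():
            t0 = row["t_start"]
            i = int(row["session_index"])
            cond = row["condition"]
            t_task = t0 + spec.instruction_dur
            t_rest = t_task + spec.task_dur
            out.append(Block("instruction", cond, t0, t_task, i))
            out.append(Block("task", cond, t_task, t_rest, i))
            out.append(Block("rest", "rest", t_rest, t_rest + spec.rest_dur, i))
        return out


@dataclass
class Recording:
    """Time-aligned multichannel series.

    ``data`` layout by modality:

    - ``eeg``: (19, n_samples), microvolts
    - ``fnirs_intensity``: (2, 19, n_samples), normalized intensity;
      wavelength planes ordered (760, 850) nm
    - ``hb``: (2, 19, n_samples), concentration change (mM);
      chromophore planes ordered (HbO, HbR)
    """

    modality: str
    channel_labels: tuple[str, ...]
    sample_rate: float
    data: np.ndarray
    start_time: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.modality == "eeg":
            if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
                raise ValueError("eeg data must be (channels, samples)")
        elif self.modality in ("fnirs_intensity", "hb"):
            if self.data.ndim != 3 or self.data.shape[:2] != (2, len(self.channel_labels)):
                raise ValueError(f"{self.modality} data must be (2, channels, samples)")
        else:
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[-1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sample_rate

    def copy_with(self, data: np.ndarray, modality: str | None = None,
                  channel_labels: Sequence[str] | None = None) -> "Recording":
        return Recording(
            modality=modality or self.modality,
            channel_labels=tuple(channel_labels or self.channel_labels),
            sample_rate=self.sample_rate,
            data=data,
            start_time=self.start_time,
            meta=dict(self.meta),
        )

    def time_slice(self, t0: float, t1: float) -> np.ndarray:
        """Samples with start_time-relative times in [t0, t1)."""
        i0 = int(np.ceil((t0 - self.start_time) * self.sample_rate - 1e-9))
        i1 = int(np.ceil((t1 - self.start_time) * self.sample_rate - 1e-9))
        return self.data[..., max(i0, 0):max(i1, 0)]


@dataclass(frozen=True)
class Window:
    """A labeled analysis epoch, half-open ``[t_start, t_end)``."""

    label: str
    t_start: float
    t_end: float
    source_block: int

    def __post_init__(self) -> None:
        if self.label not in CLASS_CODES:
            raise ValueError(f"unknown window label {self.label!r}")
        if not self.t_end > self.t_start:
            raise ValueError("window must have positive duration")

    @property
    def code(self) -> int:
        return CLASS_CODES[self.label]

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


#: Subgroups whose columns come from EEG alone.
EEG_SUBGROUPS = ("PSD", "PLV", "PAC", "Asym_PSD")
#: Subgroups whose columns come from fNIRS alone.
FNIRS_SUBGROUPS = ("HbAmp", "HbSlope", "HbStd", "HbSkew", "HbKurt", "HbCorr")
#: The 11 feature subgroups.
SUBGROUPS = EEG_SUBGROUPS + FNIRS_SUBGROUPS + ("NV",)

META_COLUMNS = ("subgroup", "nv_type", "band", "chromophore", "channel")


class FeatureTable:
    """Windows x features matrix plus per-feature metadata.

    ``meta`` has one row per column of ``X`` with fields
    ``subgroup`` (one of the 11 subgroups), ``nv_type`` ("NVO"/"NVR" for
    neurovascular columns, "" otherwise), ``band`` (e.g. "8-12", "" where
    not applicable), ``chromophore`` ("HbO"/"HbR"/""), and ``channel``
    (channel label, pair label, or principal-component index).
    """

    def __init__(self, X: np.ndarray, meta: pd.DataFrame,
                 y: np.ndarray, windows: Sequence[Window] | None = None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (windows x features)")
        if len(meta) != X.shape[1]:
            raise ValueError("meta rows must match feature columns")
        missing = [c for c in META_COLUMNS if c not in meta.columns]
        if missing:
            raise ValueError(f"meta missing columns: {missing}")
        if len(y) != X.shape[0]:
            raise ValueError("labels must match window rows")
        self.X = X
        self.meta = meta.reset_index(drop=True)
        self.y = np.asarray(y, dtype=int)
        self.windows = list(windows) if windows is not None else None

    @property
    def n_windows(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def system_mask(self, system: str) -> np.ndarray:
        system = system.lower()
        sub = self.meta["subgroup"]
        if system == "eeg":
            return sub.isin(EEG_SUBGROUPS).to_numpy()
        if system == "fnirs":
            return sub.isin(FNIRS_SUBGROUPS).to_numpy()
        if system == "hybrid":
            return np.ones(self.n_features, dtype=bool)
        raise ValueError(f"unknown system {system!r}")

    def subset_system(self, system: str) -> "FeatureTable":
        m = self.system_mask(system)
        return FeatureTable(self.X[:, m], self.meta.loc[m], self.y, self.windows)

    def subset_labels(self, labels: Iterable[str]) -> "FeatureTable":
        codes = {CLASS_CODES[l] for l in labels}
        rows = np.isin(self.y, sorted(codes))
        windows = ([w for w, r in zip(self.windows, rows) if r]
                   if self.windows is not None else None)
        return FeatureTable(self.X[rows], self.meta, self.y[rows], windows)


@dataclass
class EvalReport:
    """Cross-validation outcome: fold accuracies and pooled confusion."""

    fold_accuracies: list[float]
    pooled_confusion: pd.DataFrame     # rows true class, cols predicted
    classes: tuple[str, ...]
    k: int
    metrics: pd.DataFrame | None = None  # per-class Sens/Spec/PPV/NPV

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1)) if self.k > 1 else 0.0

    @property
    def pooled_accuracy(self) -> float:
        c = self.pooled_confusion.to_numpy()
        return float(np.trace(c) / c.sum())

    @property
    def n_test(self) -> int:
        return int(self.pooled_confusion.to_numpy().sum())
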