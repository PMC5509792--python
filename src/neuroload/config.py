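"""Run configuration: one structured file supplies every tunable constant."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .windows import WINDOW_LENGTHS


@dataclass
class RunConfig:
    window_len: float = 5.0
    k_folds: int = 10
    seed: int = 0
    case: tuple[str, ...] = ("rest", "3back")
    system: str = "hybrid"
    n_features: int | None = None
    svm_c: float = 1.0
    partition: str = "window"          # or "block"
    normalize: str = "subject"         # or "fold" (strict train-only)
    eeg_band: tuple[float, float] = (0.5, 80.0)
    eeg_notch: float = 60.0
    fnirs_band: tuple[float, float] = (0.01, 0.5)
    artifact_threshold: float = 0.10
    montage_path: str | None = None
    bands_path: str | None = None

    def __post_init__(self) -> None:
        if float(self.window_len) not in WINDOW_LENGTHS:
            raise ValueError(f"window_len must be one of {WINDOW_LENGTHS}")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        self.case = tuple(self.case)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
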