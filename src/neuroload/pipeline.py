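"""End-to-end orchestration: simulate -> preprocess -> windows -> features
-> selection -> classification, with the per-stage functions exposed so any
stage can be re-run from its predecessor's artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .evaluate import crossvalidate
from .features import FeatureExtractor
from .montage import BandScheme, Montage, load_montage, validate_montage
from .preprocess import (MBLLConstants, filter_eeg, filter_fnirs, laplacian,
                         mbll, performance)
from .simulate import SubjectParams, SyntheticSubject, simulate_subject
from .types import EventLog, FeatureTable, ProtocolSpec, Recording
from .windows import make_windows


@dataclass
class PreprocessedSubject:
    events: EventLog
    eeg: Recording      # filtered + Laplacian
    hb: Recording       # MBLL + band-passed
    excluded: bool      # behavioral cutoff


def preprocess_subject(events: EventLog, eeg: Recording, fnirs: Recording,
                       montage: Montage | None = None,
                       constants: MBLLConstants | None = None,
                       config: RunConfig | None = None) -> PreprocessedSubject:
    montage = montage or Montage()
    config = config or RunConfig()
    report = validate_montage(montage)
    if not report.ok:
        raise ValueError(f"invalid montage: {report.problems}")
    eeg_f = laplacian(filter_eeg(eeg, *config.eeg_band, notch=config.eeg_notch),
                      montage)
    hb = filter_fnirs(mbll(fnirs, constants), *config.fnirs_band)
    perf = performance(events)
    return PreprocessedSubject(events, eeg_f, hb, excluded=perf.exclude)


def extract_subject(pre: PreprocessedSubject, window_len: float = 5.0,
                    montage: Montage | None = None,
                    bands: BandScheme | None = None) -> FeatureTable:
    windows = make_windows(pre.events.blocks(), window_len)
    ext = FeatureExtractor(montage or Montage(), bands or BandScheme())
    return ext.extract(windows, pre.eeg, pre.hb)


def run_subject(seed: int = 0, params: SubjectParams | None = None,
                spec: ProtocolSpec | None = None, window_len: float = 5.0,
                montage: Montage | None = None,
                bands: BandScheme | None = None) -> FeatureTable:
    """Synthetic subject straight to its Hybrid feature table."""
    subject = simulate_subject(seed, params, spec)
    montage = montage or Montage()
    pre = preprocess_subject(subject.events, subject.eeg, subject.fnirs,
                             montage)
    return extract_subject(pre, window_len, montage, bands)


def classify_subject(table: FeatureTable, config: RunConfig):
    return crossvalidate(
        table, list(config.case), system=config.system, k=config.k_folds,
        seed=config.seed, n_features=config.n_features, C=config.svm_c,
        partition=config.partition, normalize=config.normalize,
    )


def montage_from_config(config: RunConfig) -> Montage:
    if config.montage_path:
        return load_montage(config.montage_path)
    return Montage()


def cohort_accuracies(seeds, params: SubjectParams | None = None,
                      spec: ProtocolSpec | None = None,
                      window_len: float = 25.0,
                      case=("rest", "3back"),
                      systems=("eeg", "fnirs", "hybrid"), k: int = 10,
                      partition: str = "window") -> dict[str, list[float]]:
    """Per-seed CV accuracies for each system (paired over seeds)."""
    out: dict[str, list[float]] = {s: [] for s in systems}
    for seed in seeds:
        table = run_subject(int(seed), params, spec, window_len)
        for system in systems:
            rep = crossvalidate(table, list(case), system=system, k=k,
                                seed=int(seed), partition=partition)
            out[system].append(rep.pooled_accuracy)
    return out


def null_accuracy(seeds, spec: ProtocolSpec | None = None,
                  window_len: float = 25.0, k: int = 10,
                  partition: str = "window") -> tuple[float, int]:
    """Pooled five-class CV accuracy on label-free (zero-effect) subjects.

    Returns the pooled accuracy over all seeds and the total number of
    test windows, for comparison against the binomial chance band.
    """
    params = SubjectParams().without_condition_effects()
    correct = 0
    total = 0
    for seed in seeds:
        table = run_subject(int(seed), params, spec, window_len)
        rep = crossvalidate(
            table, ["rest", "0back", "1back", "2back", "3back"],
            system="hybrid", k=k, seed=int(seed), partition=partition)
        c = rep.pooled_confusion.to_numpy()
        correct += int(np.trace(c))
        total += int(c.sum())
    return correct / total, total
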