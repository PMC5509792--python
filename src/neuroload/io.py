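"""Readers and writers for the pipeline's interchange formats.

EEG travels as EDF (read through :mod:`mne`) or as a documented TSV
fallback (a ``time`` column plus one column per electrode, microvolts).
fNIRS travels as a SNIRF-layout HDF5 file (written/read with h5py) or as a
TSV fallback with ``CH<i>_<wavelength>`` columns.  Events are a
BIDS-events-like TSV.  Feature tables and evaluation reports round-trip
through TSV/JSON with their metadata embedded.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd


def _check_rate(found: float, expected: float | None, path) -> None:
    if expected is not None and abs(found - expected) > 0.01 * expected:
        warnings.warn(f"{path}: sample rate {found:g} Hz differs from the "
                      f"configured {expected:g} Hz; using the file's rate")

from .types import (EEG_CHANNELS, EvalReport, EventLog, FeatureTable,
                    FNIRS_CHANNELS, ProtocolSpec, Recording, WAVELENGTHS,
                    Window)

# ---------------------------------------------------------------------------
# EEG


def read_eeg(path, sample_rate: float | None = None) -> Recording:
    """Load a 19-channel EEG recording from EDF or the TSV fallback.

    Channels are matched case-insensitively and reordered to the canonical
    label order; a missing channel is fatal and names every absent label.
    When ``sample_rate`` is given and the file disagrees, a warning is
    issued and the file's own rate wins.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        have = {ch.lower(): ch for ch in raw.ch_names}
        missing = [ch for ch in EEG_CHANNELS if ch.lower() not in have]
        if missing:
            raise ValueError(f"EDF missing channels: {missing}")
        picks = [have[ch.lower()] for ch in EEG_CHANNELS]
        data = raw.get_data(picks=picks) * 1e6   # MNE loads volts
        fs = float(raw.info["sfreq"])
        _check_rate(fs, sample_rate, path)
        return Recording("eeg", EEG_CHANNELS, fs, data)

    frame = pd.read_csv(path, sep="\t")
    have = {c.lower(): c for c in frame.columns}
    missing = [ch for ch in EEG_CHANNELS if ch.lower() not in have]
    if missing:
        raise ValueError(f"EEG table missing channels: {missing}")
    if "time" in have:
        t = frame[have["time"]].to_numpy()
        fs = 1.0 / float(np.median(np.diff(t)))
        _check_rate(fs, sample_rate, path)
    elif sample_rate is not None:
        fs = float(sample_rate)
    else:
        raise ValueError("EEG table has no time column and no sample_rate given")
    data = frame[[have[ch.lower()] for ch in EEG_CHANNELS]].to_numpy().T
    return Recording("eeg", EEG_CHANNELS, fs, data)


def write_eeg(rec: Recording, path) -> None:
    """Write the TSV fallback carrier (time + one column per electrode)."""
    frame = pd.DataFrame(rec.data.T, columns=list(rec.channel_labels))
    frame.insert(0, "time", rec.times)
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# fNIRS


def read_fnirs(path) -> Recording:
    """Load dual-wavelength intensities from SNIRF-layout HDF5 or TSV.

    Wavelength planes are reordered to (760, 850) nm regardless of storage
    order; a single-wavelength file is fatal.
    """
    path = Path(path)
    if path.suffix.lower() in (".snirf", ".h5", ".hdf5"):
        return _read_snirf(path)
    frame = pd.read_csv(path, sep="\t")
    cols = {}
    for lam in WAVELENGTHS:
        names = [f"{ch}_{lam}" for ch in FNIRS_CHANNELS]
        missing = [n for n in names if n not in frame.columns]
        if missing:
            raise ValueError(f"fNIRS table missing columns: {missing}")
        cols[lam] = frame[names].to_numpy().T
    t = frame["time"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t)))
    data = np.stack([cols[lam] for lam in WAVELENGTHS])
    return Recording("fnirs_intensity", FNIRS_CHANNELS, fs, data)


def _read_snirf(path) -> Recording:
    with h5py.File(path, "r") as fh:
        nirs = fh["nirs1"] if "nirs1" in fh else fh["nirs"]
        data = nirs["data1"]
        series = np.asarray(data["dataTimeSeries"])      # (T, n_measurements)
        t = np.asarray(data["time"]).ravel()
        wavelengths = np.asarray(nirs["probe"]["wavelengths"]).ravel()
        if len(wavelengths) < 2:
            raise ValueError("SNIRF file holds a single wavelength")
        ml = []
        keys = [k for k in data.keys() if k.startswith("measurementList")]
        for key in sorted(keys, key=lambda k: int(k[len("measurementList"):])):
            g = data[key]
            ml.append((int(np.asarray(g["sourceIndex"])),
                       int(np.asarray(g["wavelengthIndex"]))))
        fs = 1.0 / float(np.median(np.diff(t)))
        n_ch = len({s for s, _ in ml})
        out = np.empty((2, n_ch, series.shape[0]))
        lam_plane = {int(lam): p for p, lam in enumerate(WAVELENGTHS)}
        for col, (src, wli) in enumerate(ml):
            lam = int(round(float(wavelengths[wli - 1])))
            if lam not in lam_plane:
                raise ValueError(f"unexpected wavelength {lam} nm")
            out[lam_plane[lam], src - 1] = series[:, col]
    labels = tuple(f"CH{i}" for i in range(1, n_ch + 1))
    return Recording("fnirs_intensity", labels, fs, out)


def write_snirf(rec: Recording, path) -> None:
    """Write intensities as a minimal SNIRF-layout HDF5 file."""
    if rec.modality != "fnirs_intensity":
        raise ValueError("write_snirf expects an fnirs_intensity Recording")
    n_ch = len(rec.channel_labels)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("formatVersion", data="1.0")
        data = fh.create_group("nirs1/data1")
        series = np.concatenate([rec.data[0].T, rec.data[1].T], axis=1)
        data.create_dataset("dataTimeSeries", data=series)
        data.create_dataset("time", data=rec.times)
        for plane in range(2):
            for c in range(n_ch):
                g = data.create_group(
                    f"measurementList{plane * n_ch + c + 1}")
                g.create_dataset("sourceIndex", data=c + 1)
                g.create_dataset("detectorIndex", data=c + 1)
                g.create_dataset("wavelengthIndex", data=plane + 1)
        probe = fh.create_group("nirs1/probe")
        probe.create_dataset("wavelengths", data=np.asarray(WAVELENGTHS, float))


def write_fnirs_tsv(rec: Recording, path) -> None:
    cols = {"time": rec.times}
    for p, lam in enumerate(WAVELENGTHS):
        for c, ch in enumerate(rec.channel_labels):
            cols[f"{ch}_{lam}"] = rec.data[p, c]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# events


def read_events(path, spec: ProtocolSpec | None = None) -> EventLog:
    frame = pd.read_csv(path, sep="\t")
    frame["is_target"] = frame["is_target"].astype(bool)
    frame["responded"] = frame["responded"].astype(bool)
    frame["response_time"] = pd.to_numeric(frame["response_time"],
                                           errors="coerce")
    return EventLog(frame, spec)


def write_events(log: EventLog, path) -> None:
    log.frame.to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# feature tables and reports

_MAGIC = "#neuroload-feature-table v1"


def write_feature_table(table: FeatureTable, path, extra_header: dict | None = None) -> None:
    """TSV with the per-column metadata embedded as commented header lines."""
    with open(path, "w") as fh:
        fh.write(_MAGIC + "\n")
        for key, val in (extra_header or {}).items():
            fh.write(f"#{key}\t{val}\n")
        for col in ("subgroup", "nv_type", "band", "chromophore", "channel"):
            vals = "\t".join(str(v) for v in table.meta[col])
            fh.write(f"#meta:{col}\t{vals}\n")
        if table.windows is not None:
            for name, vals in (
                ("t_start", (w.t_start for w in table.windows)),
                ("t_end", (w.t_end for w in table.windows)),
                ("source_block", (w.source_block for w in table.windows)),
            ):
                fh.write(f"#window:{name}\t" +
                         "\t".join(repr(v) for v in vals) + "\n")
        cols = "\t".join(f"f{i}" for i in range(table.n_features))
        fh.write(f"label\t{cols}\n")
        for yi, row in zip(table.y, table.X):
            fh.write(str(int(yi)) + "\t" +
                     "\t".join(repr(float(v)) for v in row) + "\n")


def read_feature_table(path) -> tuple[FeatureTable, dict]:
    header: dict[str, str] = {}
    meta_cols: dict[str, list[str]] = {}
    win_cols: dict[str, list[str]] = {}
    rows: list[list[float]] = []
    ys: list[int] = []
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != _MAGIC:
            raise ValueError(f"{path} is not a feature table file")
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#meta:"):
                key, vals = line[6:].split("\t", 1)
                meta_cols[key] = vals.split("\t")
            elif line.startswith("#window:"):
                key, vals = line[8:].split("\t", 1)
                win_cols[key] = vals.split("\t")
            elif line.startswith("#"):
                key, _, val = line[1:].partition("\t")
                header[key] = val
            elif line.startswith("label"):
                continue
            elif line:
                parts = line.split("\t")
                ys.append(int(parts[0]))
                rows.append([float(v) for v in parts[1:]])
    meta = pd.DataFrame(meta_cols)
    X = np.array(rows) if rows else np.empty((0, len(meta)))
    windows = None
    if win_cols:
        code_to_label = {0: "rest", 1: "0back", 2: "1back", 3: "2back", 4: "3back"}
        windows = [
            Window(label=code_to_label[y], t_start=float(t0), t_end=float(t1),
                   source_block=int(b))
            for y, t0, t1, b in zip(ys, win_cols["t_start"], win_cols["t_end"],
                                    win_cols["source_block"])
        ]
    return FeatureTable(X, meta, np.array(ys, dtype=int), windows), header


def write_report(report: EvalReport, path, extra: dict | None = None) -> None:
    payload = {
        "k": report.k,
        "classes": list(report.classes),
        "fold_accuracies": report.fold_accuracies,
        "mean_accuracy": report.mean_accuracy,
        "sd_accuracy": report.sd_accuracy,
        "pooled_confusion": report.pooled_confusion.to_numpy().tolist(),
        "metrics": (report.metrics.where(pd.notna(report.metrics), None)
                    .to_dict(orient="index") if report.metrics is not None else None),
    }
    payload.update(extra or {})
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
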