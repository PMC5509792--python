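"""Electrode montage: Laplacian neighborhoods, channel pairings, band schemes.

The Laplacian adjacency ships as an explicit, editable table.  The default
is a geometric nearest-neighbor approximation on the 10-20 layout for the
19 recorded sites; runs log a hash of whatever table is in force so a
customized table is always identifiable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .types import EEG_CHANNELS, FNIRS_CHANNELS

# Nearest-neighbor adjacency on the 10-20 layout (symmetric as a relation).
DEFAULT_ADJACENCY: dict[str, tuple[str, ...]] = {
    "F7": ("F3", "T3"),
    "F8": ("F4", "T4"),
    "F3": ("F7", "Fz", "Fc1"),
    "F4": ("F8", "Fz", "Fc2"),
    "Fz": ("F3", "F4", "Fc1", "Fc2"),
    "Fc1": ("F3", "Fz", "C3"),
    "Fc2": ("F4", "Fz", "C4"),
    "T3": ("F7", "C3"),
    "T4": ("F8", "C4"),
    "C3": ("Fc1", "T3", "Cp1"),
    "C4": ("Fc2", "T4", "Cp2"),
    "Cp1": ("C3", "P3", "Pz"),
    "Cp2": ("C4", "P4", "Pz"),
    "P3": ("Cp1", "Pz", "O1"),
    "P4": ("Cp2", "Pz", "O2"),
    "Pz": ("Cp1", "Cp2", "P3", "P4", "Poz"),
    "Poz": ("Pz", "O1", "O2"),
    "O1": ("P3", "Poz"),
    "O2": ("P4", "Poz"),
}

# 17 phase-locking pairs grouped by synchrony type.
DEFAULT_PLV_PAIRS: dict[str, tuple[tuple[str, str], ...]] = {
    "intra": (("F3", "P3"), ("F4", "P4"), ("Fc1", "Cp1"),
              ("Fc2", "Cp2"), ("Fz", "Poz")),
    "symmetric": (("F7", "F8"), ("F3", "F4"), ("Fc1", "Fc2"), ("C3", "C4"),
                  ("T3", "T4"), ("Cp1", "Cp2"), ("P3", "P4"), ("O1", "O2")),
    "asymmetric": (("F3", "P4"), ("F4", "P3"), ("Fc1", "Cp2"), ("Fc2", "Cp1")),
}

# Right-left homologous pairs for hemispheric power asymmetry
# (right listed first so positive asymmetry means right-dominant power).
DEFAULT_ASYM_PAIRS: tuple[tuple[str, str], ...] = (
    ("F8", "F7"), ("F4", "F3"), ("Fc2", "Fc1"), ("T4", "T3"),
    ("C4", "C3"), ("Cp2", "Cp1"), ("P4", "P3"), ("O2", "O1"),
)


def default_nv_mapping() -> dict[str, tuple[str, ...]]:
    """fNIRS channel -> forehead EEG electrode(s) used for coupling features.

    Left-hemisphere optical channels map to F7, right-hemisphere ones to F8;
    the central channel CH10 uses the mean of both.
    """
    mapping: dict[str, tuple[str, ...]] = {}
    for i in range(1, 10):
        mapping[f"CH{i}"] = ("F7",)
    mapping["CH10"] = ("F7", "F8")
    for i in range(11, 20):
        mapping[f"CH{i}"] = ("F8",)
    return mapping


@dataclass(frozen=True)
class BandScheme:
    """Frequency intervals used by each EEG operator (Hz)."""

    psd_bands: tuple[tuple[float, float], ...] = tuple(
        (4.0 * i, 4.0 * (i + 1)) for i in range(8)
    )
    plv_bands: tuple[tuple[float, float], ...] = (
        (3, 5), (9, 11), (19, 21), (39, 41)
    )
    pac_phase_bands: tuple[tuple[float, float], ...] = ((4, 7), (9, 13))
    pac_amp_bands: tuple[tuple[float, float], ...] = ((15, 35), (30, 60))

    def __post_init__(self) -> None:
        # power bands must tile [0, 32] Hz without gap or overlap
        edges = [b[0] for b in self.psd_bands] + [self.psd_bands[-1][1]]
        for (lo, hi), nxt in zip(self.psd_bands, edges[1:]):
            if hi != nxt or hi <= lo:
                raise ValueError("psd_bands must tile contiguously")

    @property
    def pac_combos(self) -> tuple[tuple[tuple[float, float], tuple[float, float]], ...]:
        return tuple((p, a) for p in self.pac_phase_bands for a in self.pac_amp_bands)


def band_label(band: tuple[float, float]) -> str:
    fmt = lambda v: f"{v:g}"
    return f"{fmt(band[0])}-{fmt(band[1])}"


@dataclass(frozen=True)
class Montage:
    eeg_adjacency: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ADJACENCY))
    nv_mapping: dict[str, tuple[str, ...]] = field(default_factory=default_nv_mapping)
    plv_pairs: dict[str, tuple[tuple[str, str], ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_PLV_PAIRS.items()})
    asym_pairs: tuple[tuple[str, str], ...] = DEFAULT_ASYM_PAIRS

    def all_plv_pairs(self) -> tuple[tuple[str, str], ...]:
        out: list[tuple[str, str]] = []
        for group in ("intra", "symmetric", "asymmetric"):
            out.extend(self.plv_pairs.get(group, ()))
        return tuple(out)

    def table_hash(self) -> str:
        """Stable digest of the montage tables, for provenance logs."""
        blob = json.dumps({
            "adjacency": {k: list(v) for k, v in sorted(self.eeg_adjacency.items())},
            "nv": {k: list(v) for k, v in sorted(self.nv_mapping.items())},
            "plv": {k: [list(p) for p in v] for k, v in sorted(self.plv_pairs.items())},
            "asym": [list(p) for p in self.asym_pairs],
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class MontageReport:
    ok: bool
    problems: list[str]


def validate_montage(montage: Montage) -> MontageReport:
    """Check the montage invariants; fatal on unknown electrode labels.

    Returns a pass/fail report naming every violated invariant.  An
    electrode label outside the 19-channel set is an error because silent
    typos there would corrupt every downstream pairing.
    """
    problems: list[str] = []
    known = set(EEG_CHANNELS)

    def check_label(label: str, where: str) -> None:
        if label not in known:
            raise ValueError(f"unknown electrode label {label!r} in {where}")

    for ch, neigh in montage.eeg_adjacency.items():
        check_label(ch, "adjacency")
        for n in neigh:
            check_label(n, f"adjacency[{ch}]")
        if len(neigh) == 0:
            problems.append(f"channel {ch} has no Laplacian neighbors")
    missing = known - set(montage.eeg_adjacency)
    if missing:
        problems.append(f"adjacency missing channels: {sorted(missing)}")

    pairs = montage.all_plv_pairs()
    for a, b in pairs:
        check_label(a, "plv_pairs")
        check_label(b, "plv_pairs")
    if len(pairs) != 17:
        problems.append(f"expected 17 PLV pairs, found {len(pairs)}")

    for a, b in montage.asym_pairs:
        check_label(a, "asym_pairs")
        check_label(b, "asym_pairs")
    if len(montage.asym_pairs) != 8:
        problems.append(f"expected 8 asymmetry pairs, found {len(montage.asym_pairs)}")

    nv_missing = set(FNIRS_CHANNELS) - set(montage.nv_mapping)
    if nv_missing:
        problems.append(f"nv_mapping missing channels: {sorted(nv_missing)}")
    for ch, electrodes in montage.nv_mapping.items():
        for e in electrodes:
            check_label(e, f"nv_mapping[{ch}]")

    return MontageReport(ok=not problems, problems=problems)


def load_montage(path) -> Montage:
    """Load a montage from a YAML file with keys adjacency/nv/plv/asym."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    kwargs = {}
    if "adjacency" in raw:
        kwargs["eeg_adjacency"] = {k: tuple(v) for k, v in raw["adjacency"].items()}
    if "nv" in raw:
        kwargs["nv_mapping"] = {k: tuple(v) for k, v in raw["nv"].items()}
    if "plv" in raw:
        kwargs["plv_pairs"] = {
            k: tuple(tuple(p) for p in v) for k, v in raw["plv"].items()
        }
    if "asym" in raw:
        kwargs["asym_pairs"] = tuple(tuple(p) for p in raw["asym"])
    return Montage(**kwargs)
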