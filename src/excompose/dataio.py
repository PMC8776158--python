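"""Tabular and geometry I/O plus the bundled in-paper benchmark dataset.

CSV schemas (UTF-8, comma separator, '.' decimal mark, one header row):

* energy tables:    system,conformer,method,e_vert_eV,e_ad_eV,e00_eV
                    (optional extra column ``unit`` = eV | hartree)
* frequency tables: system,conformer,method,state,mode_class,site_label,
                    value_cm1,coupled,experimental_cm1
* shift tables:     system,conformer,method,site_label,mode_class,
                    harmonic_cm1,corrected_cm1,experimental_cm1,coupled

Geometries use standard XYZ (angstrom); named internal coordinates live in a
plain-text annotation file with 0-based indices into XYZ atom order::

    dihedral chi1 0 1 2 3
    distance NH_O 4 10
    ring phenyl 12 13 14 15 16 17
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from .errors import FormatError, ParseError, ValidationError
from .freqscale import MODE_CLASSES, STATES, ShiftRecord
from .geomcompare import Annotations, Structure

__all__ = [
    "HARTREE_TO_EV",
    "MethodLevel",
    "ConformerRecord",
    "EnergyTerms",
    "FrequencyRecord",
    "BenchmarkDataset",
    "method_level",
    "read_energy_table",
    "write_energy_table",
    "read_frequency_table",
    "write_frequency_table",
    "read_shift_table",
    "write_shift_table",
    "read_xyz",
    "write_xyz",
    "read_annotations",
    "write_annotations",
    "load_bundled_benchmark",
]

# CODATA-2018
HARTREE_TO_EV = 27.211386245988

ENERGY_COLUMNS = ("system", "conformer", "method", "e_vert_eV", "e_ad_eV", "e00_eV")
FREQUENCY_COLUMNS = (
    "system",
    "conformer",
    "method",
    "state",
    "mode_class",
    "site_label",
    "value_cm1",
    "coupled",
    "experimental_cm1",
)
SHIFT_COLUMNS = (
    "system",
    "conformer",
    "method",
    "site_label",
    "mode_class",
    "harmonic_cm1",
    "corrected_cm1",
    "experimental_cm1",
    "coupled",
)

_FAMILY_BY_NAME = {
    "CC2": "wavefunction",
    "wB97X-D": "dft",
    "CAM-B3LYP": "dft",
    "LC-wPBE": "dft",
    "P1": "composite",
    "P2": "composite",
    "experiment": "experiment",
}

# Residue counts of the bundled capped-peptide systems (Ac-[X-]Phe-NH2).
_RESIDUE_COUNTS = {"Fa": 1, "GFa": 2, "FFa": 2, "QFa": 2}


@dataclass(frozen=True)
class MethodLevel:
    """An energy/frequency provenance label (engine method or protocol)."""

    name: str
    family: str = "dft"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("method name must be nonempty")
        if self.family not in {"wavefunction", "dft", "composite", "experiment"}:
            raise ValidationError(f"unknown method family {self.family!r}")


def method_level(name: str) -> MethodLevel:
    """Build a MethodLevel, inferring the family for known names."""
    return MethodLevel(name=name, family=_FAMILY_BY_NAME.get(name, "dft"))


@dataclass(frozen=True)
class ConformerRecord:
    """One conformer of one benchmark system."""

    system: str
    conformer: str
    residue_count: Optional[int] = None
    structure_labels: str = ""

    @property
    def key(self) -> tuple[str, str]:
        return (self.system, self.conformer)


@dataclass(frozen=True)
class EnergyTerms:
    """(vertical, adiabatic, ZPVE-corrected 0-0) energies in eV; None = missing."""

    conformer: ConformerRecord
    method: MethodLevel
    e_vert: Optional[float] = None
    e_ad: Optional[float] = None
    e_00: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("e_vert", "e_ad", "e_00"):
            v = getattr(self, name)
            if v is not None and not math.isfinite(v):
                raise ValidationError(f"{name} must be finite, got {v}")


@dataclass(frozen=True)
class FrequencyRecord:
    """One harmonic (or experimental-reference) N-H stretch frequency."""

    conformer: ConformerRecord
    method: MethodLevel
    state: str
    mode_class: str
    site_label: str
    value: float
    coupled: bool = False
    experimental: Optional[float] = None

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise FormatError(f"state {self.state!r} not in {STATES}")
        if self.mode_class not in MODE_CLASSES:
            raise FormatError(
                f"mode_class {self.mode_class!r}; allowed: {', '.join(MODE_CLASSES)}"
            )
        if not self.value > 0:
            raise ValidationError(f"frequency must be positive, got {self.value}")
        if self.experimental is not None and not self.experimental > 0:
            raise ValidationError("experimental frequency must be positive")


def _check_header(fieldnames, required, path) -> None:
    if fieldnames is None:
        raise FormatError(f"{path}: empty file, expected a header row")
    missing = [c for c in required if c not in fieldnames]
    if missing:
        raise FormatError(f"{path}: header is missing column(s) {', '.join(missing)}")


def _cell_float(row: dict, column: str, rowno: int, path) -> Optional[float]:
    raw = (row.get(column) or "").strip()
    if raw == "":
        return None
    try:
        return float(raw)
    except ValueError:
        raise ParseError(
            f"{path}: row {rowno}: non-numeric value {raw!r} in column {column}"
        ) from None


def _cell_bool(row: dict, column: str, rowno: int, path) -> bool:
    raw = (row.get(column) or "").strip().lower()
    if raw in ("", "false", "0", "no"):
        return False
    if raw in ("true", "1", "yes"):
        return True
    raise ParseError(f"{path}: row {rowno}: bad boolean {raw!r} in column {column}")


def _conformer(system: str, conformer: str) -> ConformerRecord:
    return ConformerRecord(
        system=system,
        conformer=conformer,
        residue_count=_RESIDUE_COUNTS.get(system),
    )


def read_energy_table(path) -> list[EnergyTerms]:
    """Read an energy CSV into EnergyTerms records.

    Empty cells become missing values (never zero). An optional ``unit``
    column with value ``hartree`` converts that row's energies to eV.
    """
    records: list[EnergyTerms] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, ENERGY_COLUMNS, path)
        for rowno, row in enumerate(reader, start=2):
            unit = (row.get("unit") or "eV").strip() or "eV"
            if unit not in ("eV", "hartree"):
                raise FormatError(f"{path}: row {rowno}: unknown unit {unit!r}")
            scale = HARTREE_TO_EV if unit == "hartree" else 1.0
            vals = {}
            for col, attr in (
                ("e_vert_eV", "e_vert"),
                ("e_ad_eV", "e_ad"),
                ("e00_eV", "e_00"),
            ):
                v = _cell_float(row, col, rowno, path)
                vals[attr] = None if v is None else v * scale
            records.append(
                EnergyTerms(
                    conformer=_conformer(row["system"].strip(), row["conformer"].strip()),
                    method=method_level(row["method"].strip()),
                    **vals,
                )
            )
    return records


def write_energy_table(records: Iterable[EnergyTerms], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ENERGY_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.conformer.system,
                    r.conformer.conformer,
                    r.method.name,
                    *("" if v is None else f"{v:.6f}" for v in (r.e_vert, r.e_ad, r.e_00)),
                ]
            )


def read_frequency_table(path) -> list[FrequencyRecord]:
    """Read a frequency CSV; the ``coupled`` column defaults to false."""
    records: list[FrequencyRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, FREQUENCY_COLUMNS, path)
        for rowno, row in enumerate(reader, start=2):
            value = _cell_float(row, "value_cm1", rowno, path)
            if value is None:
                raise ParseError(f"{path}: row {rowno}: missing value_cm1")
            records.append(
                FrequencyRecord(
                    conformer=_conformer(row["system"].strip(), row["conformer"].strip()),
                    method=method_level(row["method"].strip()),
                    state=row["state"].strip(),
                    mode_class=row["mode_class"].strip(),
                    site_label=row["site_label"].strip(),
                    value=value,
                    coupled=_cell_bool(row, "coupled", rowno, path),
                    experimental=_cell_float(row, "experimental_cm1", rowno, path),
                )
            )
    return records


def write_frequency_table(records: Iterable[FrequencyRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(FREQUENCY_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.conformer.system,
                    r.conformer.conformer,
                    r.method.name,
                    r.state,
                    r.mode_class,
                    r.site_label,
                    f"{r.value:.6f}",
                    "true" if r.coupled else "false",
                    "" if r.experimental is None else f"{r.experimental:.6f}",
                ]
            )


def read_shift_table(path) -> list[ShiftRecord]:
    """Read an S1-S0 shift CSV (integer cm^-1 cells; blanks = missing)."""
    records: list[ShiftRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, SHIFT_COLUMNS, path)
        for rowno, row in enumerate(reader, start=2):
            harm = _cell_float(row, "harmonic_cm1", rowno, path)
            if harm is None:
                raise ParseError(f"{path}: row {rowno}: missing harmonic_cm1")
            corr = _cell_float(row, "corrected_cm1", rowno, path)
            exp = _cell_float(row, "experimental_cm1", rowno, path)
            mode_class = row["mode_class"].strip()
            if mode_class not in MODE_CLASSES:
                raise FormatError(
                    f"{path}: row {rowno}: mode_class {mode_class!r}; "
                    f"allowed: {', '.join(MODE_CLASSES)}"
                )
            records.append(
                ShiftRecord(
                    system=row["system"].strip(),
                    conformer=row["conformer"].strip(),
                    method=row["method"].strip(),
                    site_label=row["site_label"].strip(),
                    mode_class=mode_class,
                    harmonic_shift=int(harm),
                    corrected_shift=None if corr is None else int(corr),
                    experimental_shift=None if exp is None else int(exp),
                    coupled=_cell_bool(row, "coupled", rowno, path),
                )
            )
    return records


def write_shift_table(records: Iterable[ShiftRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SHIFT_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.system,
                    r.conformer,
                    r.method,
                    r.site_label,
                    r.mode_class,
                    r.harmonic_shift,
                    "" if r.corrected_shift is None else r.corrected_shift,
                    "" if r.experimental_shift is None else r.experimental_shift,
                    "true" if r.coupled else "false",
                ]
            )


def read_xyz(path) -> Structure:
    """Read a standard XYZ file (count line, comment line, element + x y z)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty XYZ file")
    try:
        declared = int(lines[0].strip())
    except ValueError:
        raise FormatError(f"{path}: first line must be the atom count") from None
    comment = lines[1] if len(lines) > 1 else ""
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) != declared:
        raise FormatError(
            f"{path}: declared {declared} atoms but found {len(body)} coordinate lines"
        )
    elements: list[str] = []
    coords = np.empty((declared, 3))
    for i, ln in enumerate(body):
        parts = ln.split()
        if len(parts) < 4:
            raise FormatError(f"{path}: bad coordinate line {i + 3}: {ln!r}")
        elements.append(parts[0].capitalize())
        try:
            coords[i] = [float(p) for p in parts[1:4]]
        except ValueError:
            raise ParseError(f"{path}: non-numeric coordinate on line {i + 3}") from None
    return Structure(elements=elements, coords=coords, comment=comment)


def write_xyz(s: Structure, path) -> None:
    lines = [str(s.n_atoms), s.comment]
    for el, (x, y, z) in zip(s.elements, s.coords):
        lines.append(f"{el} {x:.8f} {y:.8f} {z:.8f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotations(path) -> Annotations:
    """Read a named-internal-coordinate annotation file (see module docstring)."""
    dihedrals: dict[str, tuple[int, int, int, int]] = {}
    distances: dict[str, tuple[int, int]] = {}
    rings: dict[str, tuple[int, ...]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        kind, name, idx_tokens = parts[0], parts[1] if len(parts) > 1 else "", parts[2:]
        try:
            indices = tuple(int(t) for t in idx_tokens)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-integer atom index") from None
        if kind == "dihedral":
            if len(indices) != 4:
                raise FormatError(f"{path}:{lineno}: dihedral needs 4 indices")
            dihedrals[name] = indices  # type: ignore[assignment]
        elif kind == "distance":
            if len(indices) != 2:
                raise FormatError(f"{path}:{lineno}: distance needs 2 indices")
            distances[name] = indices  # type: ignore[assignment]
        elif kind == "ring":
            if len(indices) < 3:
                raise FormatError(f"{path}:{lineno}: ring needs >= 3 indices")
            rings[name] = indices
        else:
            raise FormatError(
                f"{path}:{lineno}: unknown annotation kind {kind!r} "
                "(allowed: dihedral, distance, ring)"
            )
    return Annotations(dihedrals=dihedrals, distances=distances, rings=rings)


def write_annotations(ann: Annotations, path) -> None:
    lines = []
    for name, idx in ann.dihedrals.items():
        lines.append("dihedral " + name + " " + " ".join(map(str, idx)))
    for name, idx in ann.distances.items():
        lines.append("distance " + name + " " + " ".join(map(str, idx)))
    for name, idx in ann.rings.items():
        lines.append("ring " + name + " " + " ".join(map(str, idx)))
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class BenchmarkDataset:
    """Energies and S1-S0 shifts for the 11-conformer capped-peptide benchmark."""

    conformers: list[ConformerRecord]
    energies: list[EnergyTerms]
    shifts: list[ShiftRecord]
    # Alternate values printed elsewhere in the source tables, keyed by
    # (system, conformer, method); the main table is the default.
    alternates: dict[tuple[str, str, str], float] = field(default_factory=dict)

    def e00(self, system: str, conformer: str, method: str) -> float:
        for rec in self.energies:
            if (
                rec.conformer.system == system
                and rec.conformer.conformer == conformer
                and rec.method.name == method
                and rec.e_00 is not None
            ):
                return rec.e_00
        raise KeyError(f"no e_00 for ({system}, {conformer}, {method})")

    def e00_series(self, method: str) -> dict[tuple[str, str], float]:
        """Conformer-keyed e_00 values for one method (missing values skipped)."""
        return {
            rec.conformer.key: rec.e_00
            for rec in self.energies
            if rec.method.name == method and rec.e_00 is not None
        }

    def residue_counts(self) -> dict[tuple[str, str], int]:
        return {c.key: c.residue_count for c in self.conformers}


def _data_path(name: str):
    return resources.files("excompose.data").joinpath(name)


def load_bundled_benchmark() -> BenchmarkDataset:
    """Load the packaged 11-conformer benchmark tables.

    Energies: 0-0 values for CC2, wB97X-D, P1, P2 and experiment on all 11
    conformers, plus CAM-B3LYP for the four Fa conformers. Shifts: harmonic
    and mode-dependent corrected amide-A S1-S0 shifts with experimental
    counterparts where measured.
    """
    with resources.as_file(_data_path("benchmark_energies.csv")) as p:
        energies = read_energy_table(p)
    with resources.as_file(_data_path("benchmark_shifts.csv")) as p:
        shifts = read_shift_table(p)
    seen: dict[tuple[str, str], ConformerRecord] = {}
    for rec in energies:
        seen.setdefault(rec.conformer.key, rec.conformer)
    dataset = BenchmarkDataset(
        conformers=list(seen.values()),
        energies=energies,
        shifts=shifts,
        alternates={("Fa", "C", "experiment"): 4.653},
    )
    return dataset
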