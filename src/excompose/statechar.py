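"""Natural transition orbital decomposition and excited-state character labels.

The occupied x virtual transition-amplitude matrix is normalized to unit
Frobenius norm and factored by singular value decomposition; each singular
couple is one NTO pair with weight = (singular value)^2, so weights sum to
one. Fragment compositions (sum of squared coefficients over the orbitals
assigned to each fragment) turn the dominant pairs into a character label:
locally pi-pi* on a phenyl ring, n-pi* on a peptide-bond carbonyl, or
backbone-to-ring charge transfer.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from ._util import read_keyvalues
from .errors import UsageError, ValidationError

__all__ = [
    "FRAGMENTS",
    "TransitionAmplitudes",
    "NTOPair",
    "CharacterLabel",
    "nto_decompose",
    "classify_character",
    "read_amplitudes",
    "write_nto_report",
]

FRAGMENTS = ("phenyl_1", "phenyl_2", "peptide_bond_1", "peptide_bond_2", "other")
REPORT_THRESHOLD = 0.10
MIXED_THRESHOLD = 0.70

_PHENYL = {"phenyl_1", "phenyl_2"}
_PEPTIDE = {"peptide_bond_1", "peptide_bond_2"}


@dataclass
class TransitionAmplitudes:
    """Occupied x virtual amplitudes with per-orbital fragment labels."""

    matrix: np.ndarray
    occ_fragments: Sequence[str]
    virt_fragments: Sequence[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValidationError("amplitude matrix must be 2-D (occ x virt)")
        n_occ, n_virt = self.matrix.shape
        if len(self.occ_fragments) != n_occ or len(self.virt_fragments) != n_virt:
            raise ValidationError("fragment labels must cover every orbital index")
        for lab in (*self.occ_fragments, *self.virt_fragments):
            if lab not in FRAGMENTS:
                raise ValidationError(
                    f"unknown fragment {lab!r}; allowed: {', '.join(FRAGMENTS)}"
                )


@dataclass(frozen=True)
class NTOPair:
    """One weighted occupied/virtual transition-orbital couple."""

    weight: float
    occupied: np.ndarray
    virtual: np.ndarray
    occ_fragment_composition: dict[str, float]
    virt_fragment_composition: dict[str, float]
    reportable: bool

    def dominant_occ_fragment(self) -> str:
        return max(self.occ_fragment_composition, key=self.occ_fragment_composition.get)

    def dominant_virt_fragment(self) -> str:
        return max(
            self.virt_fragment_composition, key=self.virt_fragment_composition.get
        )


@dataclass(frozen=True)
class CharacterLabel:
    """Dominant excited-state character with per-character contributions."""

    label: str
    contributions: dict[str, float] = field(default_factory=dict)


def _composition(vector: np.ndarray, fragments: Sequence[str]) -> dict[str, float]:
    comp: dict[str, float] = {}
    sq = vector**2
    for frag, w in zip(fragments, sq):
        comp[frag] = comp.get(frag, 0.0) + float(w)
    total = sum(comp.values())
    return {k: v / total for k, v in comp.items()}


def nto_decompose(
    t: TransitionAmplitudes, report_threshold: float = REPORT_THRESHOLD
) -> list[NTOPair]:
    """SVD of the unit-Frobenius-normalized amplitudes into weighted NTO pairs.

    Weights are squared singular values in descending order and sum to one;
    pairs above ``report_threshold`` are flagged reportable.
    """
    norm = np.linalg.norm(t.matrix)
    if norm == 0:
        raise ValidationError("cannot decompose a zero amplitude matrix")
    u, s, vt = np.linalg.svd(t.matrix / norm, full_matrices=False)
    pairs = []
    for i in range(s.size):
        w = float(s[i] ** 2)
        occ = u[:, i]
        virt = vt[i, :]
        pairs.append(
            NTOPair(
                weight=w,
                occupied=occ,
                virtual=virt,
                occ_fragment_composition=_composition(occ, t.occ_fragments),
                virt_fragment_composition=_composition(virt, t.virt_fragments),
                reportable=w > report_threshold,
            )
        )
    return pairs


def _pair_character(pair: NTOPair) -> str:
    occ = pair.dominant_occ_fragment()
    virt = pair.dominant_virt_fragment()
    if occ in _PHENYL and virt == occ:
        return "pipi*"
    if occ in _PEPTIDE and virt == occ:
        k = occ.rsplit("_", 1)[-1]
        return f"npi*_CO({k})"
    if occ in _PEPTIDE and virt in _PHENYL:
        return "CT"
    return "other"


def classify_character(
    pairs: Iterable[NTOPair], mixed_threshold: float = MIXED_THRESHOLD
) -> CharacterLabel:
    """Weight-averaged character over NTO pairs.

    Each pair contributes its weight to the elementary character determined
    by its dominant occupied/virtual fragments. If no character reaches
    ``mixed_threshold`` of the total weight the state is labeled ``mixed``
    (contributions are listed either way).
    """
    pairs = list(pairs)
    if not pairs:
        raise UsageError("no NTO pairs to classify")
    for p in pairs:
        if not p.occ_fragment_composition or not p.virt_fragment_composition:
            raise UsageError("NTO pair lacks fragment composition")
    total = sum(p.weight for p in pairs)
    contributions: dict[str, float] = {}
    for p in pairs:
        char = _pair_character(p)
        contributions[char] = contributions.get(char, 0.0) + p.weight / total
    dominant = max(contributions, key=contributions.get)
    if contributions[dominant] < mixed_threshold:
        return CharacterLabel(label="mixed", contributions=contributions)
    return CharacterLabel(label=dominant, contributions=contributions)


def read_amplitudes(matrix_path, fragments_path) -> TransitionAmplitudes:
    """Read a bare CSV matrix plus a fragment key-value file.

    The fragment file maps ``occ_<i>``/``virt_<j>`` (0-based) to fragment
    labels, e.g. ``occ_0 = peptide_bond_1``.
    """
    matrix = np.loadtxt(matrix_path, delimiter=",", ndmin=2)
    kv = read_keyvalues(fragments_path)
    n_occ, n_virt = matrix.shape
    try:
        occ = [kv[f"occ_{i}"] for i in range(n_occ)]
        virt = [kv[f"virt_{j}"] for j in range(n_virt)]
    except KeyError as exc:
        raise UsageError(f"fragment file is missing entry {exc.args[0]!r}") from None
    return TransitionAmplitudes(matrix=matrix, occ_fragments=occ, virt_fragments=virt)


def write_nto_report(pairs: list[NTOPair], label: CharacterLabel, path) -> None:
    """CSV report: one row per pair with weight, dominant fragments and label."""
    with open(Path(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["pair", "weight", "occ_fragment", "virt_fragment", "reportable", "label"]
        )
        for i, p in enumerate(pairs, start=1):
            writer.writerow(
                [
                    i,
                    f"{p.weight:.6f}",
                    p.dominant_occ_fragment(),
                    p.dominant_virt_fragment(),
                    "true" if p.reportable else "false",
                    label.label,
                ]
            )
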