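"""Annotated Cartesian structures, internal coordinates and rigid superposition.

Deviation summaries between two conformer geometries are computed on named
internal coordinates (dihedrals in degrees, distances in angstrom), which are
invariant under rigid motion; Kabsch superposition on an atom subset (e.g. a
phenyl ring) is provided separately for overlays and subset RMSD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GeometryError, UsageError

__all__ = [
    "Annotations",
    "Structure",
    "DeviationReport",
    "dihedral_angle",
    "atom_distance",
    "wrap_degrees",
    "compare_internal_coordinates",
    "kabsch_superpose",
]

_COLLINEAR_TOL = 1e-8


@dataclass(frozen=True)
class Annotations:
    """Named internal coordinates over 0-based atom indices.

    dihedrals : name -> (i, j, k, l)
    distances : name -> (i, j)
    rings     : name -> tuple of indices (e.g. the phenyl-ring subset used
                for superposition overlays)
    """

    dihedrals: dict[str, tuple[int, int, int, int]] = field(default_factory=dict)
    distances: dict[str, tuple[int, int]] = field(default_factory=dict)
    rings: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def max_index(self) -> int:
        idx = [-1]
        for tup in self.dihedrals.values():
            idx.extend(tup)
        for tup in self.distances.values():
            idx.extend(tup)
        for tup in self.rings.values():
            idx.extend(tup)
        return max(idx)


@dataclass
class Structure:
    """Ordered elements + Cartesian coordinates (angstrom) + annotations."""

    elements: list[str]
    coords: np.ndarray
    comment: str = ""
    annotations: Annotations = field(default_factory=Annotations)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.elements), 3):
            raise UsageError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.elements)} elements"
            )
        if self.annotations.max_index() >= len(self.elements):
            raise UsageError("annotation index out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def copy(self) -> "Structure":
        return Structure(
            list(self.elements), self.coords.copy(), self.comment, self.annotations
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with coordinates mapped to R @ x + t."""
        new = self.copy()
        new.coords = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return new


@dataclass(frozen=True)
class DeviationReport:
    """Signed per-coordinate deviations (a - b) with summary statistics."""

    names: tuple[str, ...]
    deviations: tuple[float, ...]
    units: str
    mad: float
    range: tuple[float, float]
    rmsd: float

    @classmethod
    def from_deviations(cls, names, deviations, units) -> "DeviationReport":
        dev = np.asarray(deviations, dtype=float)
        if dev.size == 0:
            return cls(tuple(names), (), units, 0.0, (0.0, 0.0), 0.0)
        return cls(
            names=tuple(names),
            deviations=tuple(float(d) for d in dev),
            units=units,
            mad=float(np.mean(np.abs(dev))),
            range=(float(dev.min()), float(dev.max())),
            rmsd=float(np.sqrt(np.mean(dev**2))),
        )


def _check_indices(s: Structure, indices, distinct=True) -> None:
    for i in indices:
        if not 0 <= i < s.n_atoms:
            raise UsageError(f"atom index {i} out of range for {s.n_atoms} atoms")
    if distinct and len(set(indices)) != len(indices):
        raise UsageError(f"atom indices must be distinct, got {tuple(indices)}")


def dihedral_angle(s: Structure, indices) -> float:
    """Torsion i-j-k-l in degrees, IUPAC sign, in (-180, 180].

    Looking from atom j towards atom k, a clockwise rotation of the far bond
    k-l relative to the near bond j-i is positive.
    """
    _check_indices(s, indices)
    p0, p1, p2, p3 = (s.coords[i] for i in indices)
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < _COLLINEAR_TOL or np.linalg.norm(n2) < _COLLINEAR_TOL:
        raise GeometryError(f"collinear atoms in dihedral {tuple(indices)}")
    b1u = b1 / np.linalg.norm(b1)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b1u))
    angle = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if angle == -180.0 else angle


def atom_distance(s: Structure, indices) -> float:
    """Euclidean distance (angstrom) between two atoms."""
    _check_indices(s, indices)
    i, j = indices
    return float(np.linalg.norm(s.coords[i] - s.coords[j]))


def wrap_degrees(angle: float) -> float:
    """Map an angle difference into (-180, 180]."""
    wrapped = float((angle + 180.0) % 360.0 - 180.0)
    return 180.0 if wrapped == -180.0 else wrapped


def compare_internal_coordinates(a: Structure, b: Structure) -> dict[str, DeviationReport]:
    """Per-family deviation reports (a - b) on the shared named coordinates.

    Dihedral deviations are wrapped into (-180, 180] so that 179 vs -179
    deviates by -2, never 358. Both structures must carry identical
    annotation names.
    """
    ann_a, ann_b = a.annotations, b.annotations
    for family in ("dihedrals", "distances"):
        names_a = set(getattr(ann_a, family))
        names_b = set(getattr(ann_b, family))
        if names_a != names_b:
            raise UsageError(
                f"annotation mismatch in {family}: "
                f"only in a: {sorted(names_a - names_b)}, "
                f"only in b: {sorted(names_b - names_a)}"
            )
    dih_names = sorted(ann_a.dihedrals)
    dih_dev = [
        wrap_degrees(
            dihedral_angle(a, ann_a.dihedrals[n]) - dihedral_angle(b, ann_b.dihedrals[n])
        )
        for n in dih_names
    ]
    dist_names = sorted(ann_a.distances)
    dist_dev = [
        atom_distance(a, ann_a.distances[n]) - atom_distance(b, ann_b.distances[n])
        for n in dist_names
    ]
    return {
        "dihedrals": DeviationReport.from_deviations(dih_names, dih_dev, "degrees"),
        "distances": DeviationReport.from_deviations(dist_names, dist_dev, "angstrom"),
    }


def kabsch_superpose(a: Structure, b: Structure, subset) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of b onto a over an atom subset.

    Returns ``(rotation, translation, rmsd)`` such that ``R @ x_b + t``
    best matches ``x_a`` over the subset. Only proper rotations are allowed
    (det(R) = +1): mirror images are rejected to preserve chirality.
    """
    subset = list(subset)
    if len(subset) < 3:
        raise GeometryError("superposition subset needs at least 3 atoms")
    _check_indices(a, subset)
    _check_indices(b, subset)
    pa = a.coords[subset]
    pb = b.coords[subset]
    ca = pa.mean(axis=0)
    cb = pb.mean(axis=0)
    qa = pa - ca
    qb = pb - cb
    if np.linalg.matrix_rank(qa, tol=1e-8) < 2 or np.linalg.matrix_rank(qb, tol=1e-8) < 2:
        raise GeometryError("superposition subset is collinear/degenerate")
    # Kabsch: covariance, SVD, proper-rotation correction
    h = qb.T @ qa
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = ca - rotation @ cb
    moved = qb @ rotation.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - qa) ** 2, axis=1))))
    return rotation, translation, rmsd
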