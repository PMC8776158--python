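"""Seeded synthetic datasets with known ground truth.

Stands in for the raw benchmark data that is not deposited: energy triples
on shared true surfaces plus per-method offsets and Gaussian noise,
frequency calibration points on a known line, geometries with exactly
injected internal-coordinate deviations, and block-structured transition
amplitudes with a known character. Everything is a pure function of
(spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .dataio import ConformerRecord, EnergyTerms, MethodLevel, method_level
from .errors import UsageError, ValidationError
from .geomcompare import Annotations, Structure
from .statechar import FRAGMENTS, TransitionAmplitudes, CharacterLabel

__all__ = [
    "MethodErrorSpec",
    "SyntheticSpec",
    "CalibrationSet",
    "default_spec",
    "gen_energy_benchmark",
    "gen_frequency_calibration",
    "make_chain_structure",
    "gen_perturbed_structures",
    "gen_transition_amplitudes",
]


@dataclass(frozen=True)
class MethodErrorSpec:
    """Systematic offsets (eV) on each term plus Gaussian noise on each term."""

    offset_vert: float = 0.0
    offset_relax: float = 0.0
    offset_zpve: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SyntheticSpec:
    n_conformers: int = 11
    seed: int = 0
    true_e00_range: tuple[float, float] = (4.4, 4.9)
    methods: dict[str, MethodErrorSpec] = field(default_factory=dict)
    scaling_a: float = 0.956
    scaling_b: float = 120.0
    scaling_noise_sd: float = 3.0
    scaling_n_points: int = 40
    dihedral_sd: float = 3.0
    distance_sd: float = 0.05
    coordinate_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_conformers < 1:
            raise ValidationError("n_conformers must be >= 1")
        for sd in (self.scaling_noise_sd, self.dihedral_sd, self.distance_sd,
                   self.coordinate_sd):
            if sd < 0:
                raise ValidationError("noise sd must be >= 0")


def default_spec(seed: int = 0) -> SyntheticSpec:
    """Benchmark-scale default: an exact reference method and a test method
    with the observed-scale +0.4 eV ZPVE-path bias and 0.02 eV scatter."""
    return SyntheticSpec(
        seed=seed,
        methods={
            "REF": MethodErrorSpec(),
            "TEST": MethodErrorSpec(offset_zpve=0.4, noise_sd=0.02),
        },
    )


def _truth_conformers(spec: SyntheticSpec, rng) -> list[tuple[ConformerRecord, EnergyTerms]]:
    lo, hi = spec.true_e00_range
    out = []
    for i in range(spec.n_conformers):
        conf = ConformerRecord(system="SYN", conformer=f"C{i + 1:02d}", residue_count=1)
        e_00 = float(rng.uniform(lo, hi))
        dd_00 = float(rng.uniform(-0.20, -0.05))  # ZPVE difference, S1 below S0
        dd_ad = float(rng.uniform(-0.50, -0.20))  # excited-state relaxation
        e_ad = e_00 - dd_00
        e_vert = e_ad - dd_ad
        out.append(
            (
                conf,
                EnergyTerms(
                    conformer=conf,
                    method=MethodLevel("truth", "wavefunction"),
                    e_vert=e_vert,
                    e_ad=e_ad,
                    e_00=e_00,
                ),
            )
        )
    return out


def gen_energy_benchmark(
    spec: SyntheticSpec,
) -> tuple[list[EnergyTerms], dict[tuple[str, str], EnergyTerms]]:
    """Per-method energy triples = shared truth + term offsets + noise.

    Offsets act term-wise: ``offset_vert`` shifts the vertical energy,
    ``offset_relax`` the relaxation term (e_ad - e_vert) and ``offset_zpve``
    the ZPVE-difference term (e_00 - e_ad), so with zero noise a method's
    e_00 is truth + offset_vert + offset_relax + offset_zpve. Returns the
    noisy records and the truth keyed by conformer.
    """
    methods = spec.methods or default_spec(spec.seed).methods
    rng = np.random.default_rng(spec.seed)
    truth_rows = _truth_conformers(spec, rng)
    records: list[EnergyTerms] = []
    for conf, truth in truth_rows:
        for name, err in methods.items():
            noise = rng.normal(0.0, err.noise_sd, size=3) if err.noise_sd > 0 else np.zeros(3)
            e_vert = truth.e_vert + err.offset_vert + float(noise[0])
            e_ad = e_vert + (truth.e_ad - truth.e_vert) + err.offset_relax + float(noise[1])
            e_00 = e_ad + (truth.e_00 - truth.e_ad) + err.offset_zpve + float(noise[2])
            records.append(
                EnergyTerms(
                    conformer=conf,
                    method=method_level(name),
                    e_vert=e_vert,
                    e_ad=e_ad,
                    e_00=e_00,
                )
            )
    return records, {conf.key: truth for conf, truth in truth_rows}


@dataclass(frozen=True)
class CalibrationSet:
    """Synthetic (nu_theo, nu_exp) calibration points and the generating line."""

    nu_theo: np.ndarray
    nu_exp: np.ndarray
    a: float
    b: float

    @property
    def pairs(self) -> list[tuple[float, float]]:
        return list(zip(self.nu_theo.tolist(), self.nu_exp.tolist()))


def gen_frequency_calibration(spec: SyntheticSpec) -> CalibrationSet:
    """nu_theo uniform in the amide-A window, nu_exp = a*nu_theo + b + noise."""
    if spec.scaling_n_points < 2:
        raise ValidationError("calibration needs at least 2 points")
    rng = np.random.default_rng(spec.seed)
    nu_theo = rng.uniform(3300.0, 3700.0, size=spec.scaling_n_points)
    noise = (
        rng.normal(0.0, spec.scaling_noise_sd, size=spec.scaling_n_points)
        if spec.scaling_noise_sd > 0
        else np.zeros(spec.scaling_n_points)
    )
    nu_exp = spec.scaling_a * nu_theo + spec.scaling_b + noise
    return CalibrationSet(nu_theo=nu_theo, nu_exp=nu_exp, a=spec.scaling_a, b=spec.scaling_b)


def make_chain_structure(seed: int = 0) -> Structure:
    """A deterministic 30-atom pseudo-peptide chain with annotations.

    24 chain atoms on a gently curling walk plus a 6-atom planar ring.
    Annotated dihedrals, distances and the ring are chosen so that the atoms
    moved by exact deviation injection are disjoint.
    """
    rng = np.random.default_rng(seed)
    n_chain = 24
    coords = np.zeros((30, 3))
    pos = np.zeros(3)
    for i in range(1, n_chain):
        theta = 0.9 * i + 0.15 * rng.standard_normal()
        phi = 0.5 * i + 0.15 * rng.standard_normal()
        step = np.array(
            [math.cos(theta) * math.cos(phi), math.sin(theta) * math.cos(phi), math.sin(phi)]
        )
        pos = pos + 1.5 * step
        coords[i] = pos
    # planar hexagon (the "phenyl" subset), offset from the chain
    center = pos + np.array([3.0, 0.0, 1.0])
    for k in range(6):
        ang = math.pi * k / 3.0
        coords[n_chain + k] = center + 1.39 * np.array([math.cos(ang), math.sin(ang), 0.0])
    elements = (["C", "C", "N", "C", "O"] * 6)[:n_chain] + ["C"] * 6
    annotations = Annotations(
        dihedrals={"d0": (0, 1, 2, 3), "d1": (4, 5, 6, 7), "d2": (8, 9, 10, 11)},
        distances={"r0": (12, 16), "r1": (13, 18), "r2": (14, 20)},
        rings={"phenyl": tuple(range(n_chain, n_chain + 6))},
    )
    return Structure(
        elements=elements, coords=coords, comment="synthetic chain", annotations=annotations
    )


def _rotate_about_axis(point, origin, axis, angle_deg):
    rot = Rotation.from_rotvec(np.radians(angle_deg) * axis / np.linalg.norm(axis))
    return origin + rot.apply(point - origin)


def gen_perturbed_structures(
    spec: SyntheticSpec,
    base: Structure,
    *,
    dihedral_deltas: Optional[dict[str, float]] = None,
    distance_deltas: Optional[dict[str, float]] = None,
    rigid_motion: bool = True,
) -> tuple[Structure, Structure, dict[str, dict[str, float]]]:
    """(reference copy, perturbed copy, injected deviations).

    Each annotated dihedral (i, j, k, l) is changed by exactly its delta by
    rotating atom l about the j-k axis (right-handed about k - j increases
    the torsion); each annotated distance (a, b) by moving atom b along the
    a-b line. Deltas default to Gaussian draws at the spec's sd. Optional
    coordinate noise and a random rigid motion are applied afterwards.
    """
    if not base.annotations.dihedrals and not base.annotations.distances:
        raise UsageError("base structure has no annotated internal coordinates")
    rng = np.random.default_rng(spec.seed)
    perturbed = base.copy()
    injected: dict[str, dict[str, float]] = {"dihedrals": {}, "distances": {}}

    for name, (i, j, k, l) in base.annotations.dihedrals.items():
        if dihedral_deltas is not None:
            delta = float(dihedral_deltas.get(name, 0.0))
        else:
            delta = float(rng.normal(0.0, spec.dihedral_sd)) if spec.dihedral_sd > 0 else 0.0
        axis = perturbed.coords[k] - perturbed.coords[j]
        perturbed.coords[l] = _rotate_about_axis(
            perturbed.coords[l], perturbed.coords[k], axis, delta
        )
        injected["dihedrals"][name] = delta

    for name, (a_idx, b_idx) in base.annotations.distances.items():
        if distance_deltas is not None:
            delta = float(distance_deltas.get(name, 0.0))
        else:
            delta = float(rng.normal(0.0, spec.distance_sd)) if spec.distance_sd > 0 else 0.0
        pa = perturbed.coords[a_idx]
        pb = perturbed.coords[b_idx]
        d = np.linalg.norm(pb - pa)
        perturbed.coords[b_idx] = pa + (d + delta) * (pb - pa) / d
        injected["distances"][name] = delta

    if spec.coordinate_sd > 0:
        perturbed.coords = perturbed.coords + rng.normal(
            0.0, spec.coordinate_sd, size=perturbed.coords.shape
        )

    if rigid_motion:
        rot = Rotation.random(rng=rng).as_matrix()
        trans = rng.uniform(-5.0, 5.0, size=3)
        perturbed = perturbed.transformed(rot, trans)

    return base.copy(), perturbed, injected


def _block_unit_vector(rng, size: int, support: np.ndarray) -> np.ndarray:
    v = np.zeros(size)
    v[support] = rng.standard_normal(support.size)
    return v / np.linalg.norm(v)


def gen_transition_amplitudes(
    seed: int = 0,
    *,
    n_occ: int = 6,
    n_virt: int = 8,
    occ_fragment: str = "peptide_bond_1",
    virt_fragment: str = "phenyl_1",
    contamination: float = 0.0,
    contamination_occ: str = "phenyl_1",
    contamination_virt: str = "phenyl_1",
) -> tuple[TransitionAmplitudes, CharacterLabel]:
    """Amplitudes concentrated on one (occ -> virt) fragment block.

    The matrix is sqrt(1-c) on a random vector pair inside the main block
    plus sqrt(c) inside the contamination block (disjoint orbital supports,
    so the SVD weights are exactly 1-c and c). Returns the amplitudes and
    the constructed truth label.
    """
    for frag in (occ_fragment, virt_fragment, contamination_occ, contamination_virt):
        if frag not in FRAGMENTS:
            raise ValidationError(f"unknown fragment {frag!r}")
    if not 0.0 <= contamination < 1.0:
        raise ValidationError("contamination must be in [0, 1)")
    if n_occ < 2 or n_virt < 2:
        raise ValidationError("need at least 2 occupied and 2 virtual orbitals")
    rng = np.random.default_rng(seed)

    occ_labels = [occ_fragment] * (n_occ // 2) + [contamination_occ] * (n_occ - n_occ // 2)
    virt_labels = [virt_fragment] * (n_virt // 2) + [contamination_virt] * (n_virt - n_virt // 2)

    main_occ = np.arange(n_occ // 2)
    main_virt = np.arange(n_virt // 2)
    cont_occ = np.arange(n_occ // 2, n_occ)
    cont_virt = np.arange(n_virt // 2, n_virt)

    u1 = _block_unit_vector(rng, n_occ, main_occ)
    v1 = _block_unit_vector(rng, n_virt, main_virt)
    matrix = math.sqrt(1.0 - contamination) * np.outer(u1, v1)
    if contamination > 0:
        u2 = _block_unit_vector(rng, n_occ, cont_occ)
        v2 = _block_unit_vector(rng, n_virt, cont_virt)
        matrix = matrix + math.sqrt(contamination) * np.outer(u2, v2)

    def block_char(occ_f: str, virt_f: str) -> str:
        if occ_f.startswith("phenyl") and virt_f == occ_f:
            return "pipi*"
        if occ_f.startswith("peptide_bond") and virt_f == occ_f:
            return f"npi*_CO({occ_f.rsplit('_', 1)[-1]})"
        if occ_f.startswith("peptide_bond") and virt_f.startswith("phenyl"):
            return "CT"
        return "other"

    contributions = {block_char(occ_fragment, virt_fragment): 1.0 - contamination}
    if contamination > 0:
        char2 = block_char(contamination_occ, contamination_virt)
        contributions[char2] = contributions.get(char2, 0.0) + contamination
    dominant = max(contributions, key=contributions.get)
    label = CharacterLabel(
        label=dominant if contributions[dominant] >= 0.70 else "mixed",
        contributions=contributions,
    )
    return (
        TransitionAmplitudes(
            matrix=matrix, occ_fragments=occ_labels, virt_fragments=virt_labels
        ),
        label,
    )
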