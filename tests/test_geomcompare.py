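import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from excompose.errors import GeometryError, UsageError
from excompose.geomcompare import (
    Annotations,
    Structure,
    atom_distance,
    compare_internal_coordinates,
    dihedral_angle,
    kabsch_superpose,
    wrap_degrees,
)
from excompose.synthetic import SyntheticSpec, gen_perturbed_structures, make_chain_structure


def simple(coords, **ann):
    n = len(coords)
    return Structure(["C"] * n, np.asarray(coords, float), annotations=Annotations(**ann))


def oracle_dihedral(coords):
    """Independent construction: rotate the j->k bond onto +z, then read the
    torsion as the planar angle between the xy-projections of the outer bonds."""
    p0, p1, p2, p3 = np.asarray(coords, float)
    axis = p2 - p1
    rot, _ = Rotation.align_vectors([[0.0, 0.0, 1.0]], [axis / np.linalg.norm(axis)])
    a = rot.apply(p0 - p1)[:2]  # xy-projection of the near bond j->i
    b = rot.apply(p3 - p2)[:2]
    cross = a[0] * b[1] - a[1] * b[0]
    dot = a @ b
    return float(np.degrees(np.arctan2(cross, dot)))


def random_isometry(rng):
    return Rotation.random(rng=rng).as_matrix(), rng.uniform(-10, 10, 3)


class TestDihedral:
    def test_planar_trans(self):
        s = simple([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]])
        assert dihedral_angle(s, (0, 1, 2, 3)) == pytest.approx(180.0)

    def test_planar_cis(self):
        s = simple([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]])
        assert dihedral_angle(s, (0, 1, 2, 3)) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(-3, 3, (4, 3))
        s = simple(coords)
        assert dihedral_angle(s, (0, 1, 2, 3)) == pytest.approx(
            oracle_dihedral(coords), abs=1e-9
        )

    def test_collinear_rejected(self):
        s = simple([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]])
        with pytest.raises(GeometryError):
            dihedral_angle(s, (0, 1, 2, 3))

    def test_range_half_open(self):
        s = simple([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]])
        assert dihedral_angle(s, (0, 1, 2, 3)) == 180.0  # never -180

    @pytest.mark.parametrize("seed", range(5))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(-3, 3, (4, 3))
        s = simple(coords)
        rot, trans = random_isometry(rng)
        moved = s.transformed(rot, trans)
        assert dihedral_angle(moved, (0, 1, 2, 3)) == pytest.approx(
            dihedral_angle(s, (0, 1, 2, 3)), abs=1e-9
        )


class TestDistance:
    def test_pythagorean(self):
        s = simple([[0, 0, 0], [3, 4, 0]])
        assert atom_distance(s, (0, 1)) == pytest.approx(5.0)

    def test_near_coincident(self):
        s = simple([[1, 1, 1], [1, 1, 1 + 1e-12]])
        assert atom_distance(s, (0, 1)) == pytest.approx(0.0, abs=1e-9)

    def test_isometry_invariance(self):
        rng = np.random.default_rng(0)
        s = simple(rng.uniform(-5, 5, (2, 3)))
        rot, trans = random_isometry(rng)
        moved = s.transformed(rot, trans)
        assert atom_distance(moved, (0, 1)) == pytest.approx(
            atom_distance(s, (0, 1)), abs=1e-9
        )

    def test_duplicate_index_rejected(self):
        s = simple([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(UsageError):
            atom_distance(s, (1, 1))


class TestCompare:
    def test_equal_structures_all_zero(self, chain):
        report = compare_internal_coordinates(chain, chain.copy())
        assert report["dihedrals"].mad == 0.0
        assert report["distances"].mad == 0.0

    def test_periodic_wrap(self):
        # dihedral pair 179 vs -179 deviates by -2, never 358
        assert wrap_degrees(-179.0 - 179.0) == pytest.approx(2.0)
        assert wrap_degrees(179.0 - (-179.0)) == pytest.approx(-2.0)

    @pytest.mark.parametrize("delta", [-361.0, -180.0, -0.5, 0.0, 179.9, 360.0, 725.0])
    def test_wrap_range(self, delta):
        w = wrap_degrees(delta)
        assert -180.0 < w <= 180.0

    def test_injected_deviations_recovered(self, chain):
        spec = SyntheticSpec(seed=1)
        _ref, pert, _ = gen_perturbed_structures(
            spec, chain,
            dihedral_deltas={"d0": 5.0, "d1": -3.0, "d2": 1.0},
            distance_deltas={"r0": 0.0, "r1": 0.0, "r2": 0.0},
        )
        report = compare_internal_coordinates(pert, chain)["dihedrals"]
        devs = dict(zip(report.names, report.deviations))
        assert devs["d0"] == pytest.approx(5.0, abs=1e-9)
        assert devs["d1"] == pytest.approx(-3.0, abs=1e-9)
        assert devs["d2"] == pytest.approx(1.0, abs=1e-9)
        assert report.mad == pytest.approx(3.0, abs=1e-9)
        assert report.range == (pytest.approx(-3.0), pytest.approx(5.0))

    def test_annotation_mismatch_lists_names(self, chain):
        other = chain.copy()
        ann = chain.annotations
        other.annotations = Annotations(
            dihedrals={**ann.dihedrals, "extra": (0, 1, 2, 4)},
            distances=ann.distances,
            rings=ann.rings,
        )
        with pytest.raises(UsageError, match="extra"):
            compare_internal_coordinates(chain, other)

    def test_rigid_motion_gives_zero_deviations(self, chain):
        rng = np.random.default_rng(9)
        rot, trans = random_isometry(rng)
        moved = chain.transformed(rot, trans)
        report = compare_internal_coordinates(chain, moved)
        assert report["dihedrals"].mad == pytest.approx(0.0, abs=1e-8)
        assert report["distances"].mad == pytest.approx(0.0, abs=1e-9)


def oracle_superpose_rmsd(pa, pb, seed=0, n_restarts=8):
    """Brute-force rigid superposition via rotation-vector optimization."""
    qa = pa - pa.mean(axis=0)
    qb = pb - pb.mean(axis=0)

    def cost(rotvec):
        moved = Rotation.from_rotvec(rotvec).apply(qb)
        return np.sqrt(np.mean(np.sum((moved - qa) ** 2, axis=1)))

    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(n_restarts):
        x0 = rng.uniform(-np.pi, np.pi, 3)
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
        best = min(best, res.fun)
    return best


class TestKabsch:
    def test_identical_structures(self, chain):
        subset = chain.annotations.rings["phenyl"]
        _r, _t, rmsd = kabsch_superpose(chain, chain.copy(), subset)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_rmsd_zero(self, chain):
        rng = np.random.default_rng(4)
        rot, trans = random_isometry(rng)
        moved = chain.transformed(rot, trans)
        subset = chain.annotations.rings["phenyl"]
        r, t, rmsd = kabsch_superpose(chain, moved, subset)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        # returned transform maps b onto a
        back = moved.coords[list(subset)] @ r.T + t
        assert np.allclose(back, chain.coords[list(subset)], atol=1e-9)

    def test_proper_rotation_only(self, chain):
        rng = np.random.default_rng(5)
        mirrored = chain.copy()
        mirrored.coords = mirrored.coords * np.array([-1.0, 1.0, 1.0])
        rot, trans = random_isometry(rng)
        mirrored = mirrored.transformed(rot, trans)
        r, _t, _rmsd = kabsch_superpose(chain, mirrored, chain.annotations.rings["phenyl"])
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)

    def test_noisy_subset_matches_brute_force_optimizer(self, chain):
        rng = np.random.default_rng(11)
        subset = list(chain.annotations.rings["phenyl"])
        noisy = chain.copy()
        noisy.coords[subset] += rng.normal(0.0, 0.05, (len(subset), 3))
        rot, trans = random_isometry(rng)
        noisy = noisy.transformed(rot, trans)
        _r, _t, rmsd = kabsch_superpose(chain, noisy, subset)
        assert rmsd == pytest.approx(oracle_superpose_rmsd(
            chain.coords[subset], noisy.coords[subset]), abs=1e-6)

    def test_optimality_against_random_rotations(self, chain):
        rng = np.random.default_rng(12)
        subset = list(chain.annotations.rings["phenyl"])
        noisy = chain.copy()
        noisy.coords[subset] += rng.normal(0.0, 0.1, (len(subset), 3))
        _r, _t, rmsd = kabsch_superpose(chain, noisy, subset)
        qa = chain.coords[subset] - chain.coords[subset].mean(axis=0)
        qb = noisy.coords[subset] - noisy.coords[subset].mean(axis=0)
        for _ in range(200):
            trial = Rotation.random(rng=rng).apply(qb)
            trial_rmsd = np.sqrt(np.mean(np.sum((trial - qa) ** 2, axis=1)))
            assert rmsd <= trial_rmsd + 1e-12

    def test_collinear_subset_rejected(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        a = simple(coords)
        b = simple(coords + 1.0)
        with pytest.raises(GeometryError):
            kabsch_superpose(a, b, [0, 1, 2, 3])

    def test_too_few_atoms_rejected(self, chain):
        with pytest.raises(GeometryError):
            kabsch_superpose(chain, chain.copy(), [0, 1])
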