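import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from absasfit.structures import (
    CysPair, RegionScheme, center_of_mass, clash_check, disulphide_distances,
    read_structure, region_distances, superpose, write_structure,
)
from conftest import point_model

PDB_ONE_ATOM = (
    "ATOM      1  CA  ALA A   1      10.000   0.000   0.000  1.00  0.00"
    "           C\nEND\n")

PDB_TWO_MODELS = """MODEL        1
ATOM      1  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1       9.000   0.000   0.000  1.00  0.00           C
ENDMDL
END
"""


class TestReadStructure:
    def test_angstrom_to_nm(self, tmp_path):
        p = tmp_path / "one.pdb"
        p.write_text(PDB_ONE_ATOM)
        m = read_structure(str(p))
        assert m.n_atoms == 1
        np.testing.assert_allclose(m.coords[0], [1.0, 0.0, 0.0], atol=1e-9)

    def test_first_model_only(self, tmp_path):
        p = tmp_path / "two.pdb"
        p.write_text(PDB_TWO_MODELS)
        m = read_structure(str(p))
        assert m.n_atoms == 1
        np.testing.assert_allclose(m.coords[0], [0.1, 0.0, 0.0], atol=1e-9)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("")
        with pytest.raises(ValueError, match="no ATOM"):
            read_structure(str(p))

    def test_missing_chain_id_names_line(self, tmp_path):
        p = tmp_path / "bad.pdb"
        bad = PDB_ONE_ATOM.replace("ALA A", "ALA  ")
        p.write_text(bad)
        with pytest.raises(ValueError, match=":1:"):
            read_structure(str(p))

    def test_roundtrip_preserves_coordinates(self, tmp_path):
        rng = np.random.default_rng(4)
        n = 30
        model = point_model(rng.uniform(0, 5, size=(n, 3)),
                            chains=["A"] * 15 + ["B"] * 15,
                            resnums=list(range(1, 16)) * 2)
        out = tmp_path / "rt.pdb"
        write_structure(model, str(out))
        back = read_structure(str(out))
        assert back.n_atoms == n
        # PDB precision is 0.001 A = 0.0001 nm
        np.testing.assert_allclose(np.sort(back.coords, axis=0),
                                   np.sort(model.coords, axis=0), atol=1e-4)


class TestCenterOfMass:
    def test_geometric(self):
        model = point_model([[0, 0, 0], [2, 0, 0]])
        scheme = RegionScheme(intervals=[("A", 1, 2, "Fc")])
        np.testing.assert_allclose(
            center_of_mass(model, "Fc", scheme, "geometric"), [1, 0, 0])

    def test_mass_weighted(self):
        model = point_model([[0, 0, 0], [2, 0, 0]], elements=["H", "C"])
        scheme = RegionScheme(intervals=[("A", 1, 2, "Fc")])
        masses = model.masses()
        expected_x = 2.0 * masses[1] / masses.sum()
        com = center_of_mass(model, "Fc", scheme, "mass")
        np.testing.assert_allclose(com, [expected_x, 0, 0], rtol=1e-9)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(0)
        model = point_model(rng.normal(size=(20, 3)))
        scheme = RegionScheme(intervals=[("A", 1, 20, "Fab1")])
        c0 = center_of_mass(model, "Fab1", scheme)
        shifted = model.with_coords(model.coords + [1.0, -2.0, 0.5])
        c1 = center_of_mass(shifted, "Fab1", scheme)
        np.testing.assert_allclose(c1 - c0, [1.0, -2.0, 0.5], atol=1e-12)

    def test_empty_region_errors(self):
        model = point_model([[0, 0, 0]])
        scheme = RegionScheme(intervals=[("A", 1, 1, "Fc")])
        with pytest.raises(ValueError, match="no atoms"):
            center_of_mass(model, "Fab1", scheme)


class TestRegionDistances:
    def test_345_triangle(self, triangle_345):
        model, scheme = triangle_345
        d = region_distances(model, scheme)
        assert d.d1 == pytest.approx(3.0)
        assert sorted([d.d2, d.d3]) == pytest.approx([4.0, 5.0])
        assert d.abs_diff == pytest.approx(1.0)
        assert d.max_d23 == pytest.approx(5.0)
        assert d.min_d23 == pytest.approx(4.0)

    def test_fab_swap_invariance(self, triangle_345):
        model, _ = triangle_345
        scheme = RegionScheme(intervals=[("B", 1, 1, "Fab1"),
                                         ("A", 1, 1, "Fab2"),
                                         ("C", 1, 1, "Fc")])
        d = region_distances(model, scheme)
        assert d.d1 == pytest.approx(3.0)
        assert d.abs_diff == pytest.approx(1.0)
        assert (d.max_d23, d.min_d23) == pytest.approx((5.0, 4.0))

    def test_rigid_motion_invariance(self, triangle_345):
        model, scheme = triangle_345
        d0 = region_distances(model, scheme)
        rng = np.random.default_rng(7)
        for _ in range(5):
            rot = Rotation.random(rng=rng)
            moved = model.with_coords(rot.apply(model.coords)
                                      + rng.normal(size=3))
            d1 = region_distances(moved, scheme)
            assert d1.d1 == pytest.approx(d0.d1, abs=1e-9)
            assert d1.abs_diff == pytest.approx(d0.abs_diff, abs=1e-9)

    def test_mirror_symmetric_zero_asymmetry(self):
        model = point_model([[0, 0, 0], [4, 0, 0], [2, 3, 0]],
                            chains=["A", "B", "C"], resnums=[1, 1, 1])
        scheme = RegionScheme(intervals=[("A", 1, 1, "Fab1"),
                                         ("B", 1, 1, "Fab2"),
                                         ("C", 1, 1, "Fc")])
        assert region_distances(model, scheme).abs_diff == pytest.approx(0.0)


class TestDisulphide:
    def _two_ca(self, d):
        return point_model([[0, 0, 0], [d, 0, 0]], chains=["A", "B"],
                           resnums=[5, 5], resnames=["CYS", "CYS"],
                           atom_names=["CA", "CA"])

    @pytest.mark.parametrize("d", [0.74, 0.0, 1.3])
    def test_distance_values(self, d):
        model = self._two_ca(d)
        pairs = [CysPair(("A", 5), ("B", 5), label="p")]
        out = disulphide_distances(model, pairs)
        assert out[0] == ("p", pytest.approx(d))

    def test_missing_ca_names_residue(self):
        model = self._two_ca(0.5)
        with pytest.raises(ValueError, match="B:9"):
            disulphide_distances(model, [CysPair(("A", 5), ("B", 9))])


class TestClashCheck:
    def test_no_clash_beyond_cutoff(self):
        model = point_model([[0, 0, 0], [0.5, 0, 0]], chains=["A", "B"])
        assert clash_check(model, [0], [1], 0.22) == (False, 0)

    def test_clash_within_cutoff(self):
        model = point_model([[0, 0, 0], [0.1, 0, 0]], chains=["A", "B"])
        hit, n = clash_check(model, [0], [1], 0.22)
        assert hit and n == 1

    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        coords = rng.uniform(0, 3.0, size=(200, 3))
        model = point_model(coords,
                            chains=["A"] * 100 + ["B"] * 100,
                            resnums=list(range(1, 101)) * 2)
        a, b = np.arange(100), np.arange(100, 200)
        _, count = clash_check(model, a, b, 0.35, exclude_bonded=False)
        diff = coords[a][:, None, :] - coords[b][None, :, :]
        brute = int((np.sqrt((diff ** 2).sum(-1)) < 0.35).sum())
        assert count == brute

    def test_groups_must_be_disjoint(self):
        model = point_model([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError, match="disjoint"):
            clash_check(model, [0, 1], [1], 0.2)


def _quaternion_rmsd(P, Q):
    """Closed-form optimal RMSD via the quaternion eigenvalue method."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    M = Pc.T @ Qc
    sxx, sxy, sxz = M[0]
    syx, syy, syz = M[1]
    szx, szy, szz = M[2]
    K = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz]])
    lam = np.linalg.eigvalsh(K)[-1]
    e0 = (Pc ** 2).sum() + (Qc ** 2).sum()
    return np.sqrt(max(e0 - 2 * lam, 0.0) / len(P))


class TestSuperpose:
    def _random_model(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        return point_model(rng.normal(size=(n, 3)))

    def test_rotated_copy_rmsd_zero(self):
        ref = self._random_model()
        rot = Rotation.from_euler("z", 90, degrees=True)
        mob = ref.with_coords(rot.apply(ref.coords) + [1, 2, 3])
        amap = [(i, i) for i in range(ref.n_atoms)]
        fitted, rmsd = superpose(mob, ref, amap)
        assert rmsd < 1e-9
        np.testing.assert_allclose(fitted.coords, ref.coords, atol=1e-9)

    def test_self_superposition_identity(self):
        ref = self._random_model(seed=3)
        amap = [(i, i) for i in range(ref.n_atoms)]
        fitted, rmsd = superpose(ref, ref, amap)
        assert rmsd < 1e-9
        np.testing.assert_allclose(fitted.coords, ref.coords, atol=1e-12)

    def test_noisy_copy_matches_quaternion_oracle(self):
        rng = np.random.default_rng(8)
        ref = self._random_model(n=40, seed=8)
        rot = Rotation.random(rng=rng)
        noisy = rot.apply(ref.coords) + rng.normal(0, 0.01, size=(40, 3)) + 2.0
        mob = ref.with_coords(noisy)
        amap = [(i, i) for i in range(40)]
        _, rmsd = superpose(mob, ref, amap)
        oracle = _quaternion_rmsd(mob.coords, ref.coords)
        assert rmsd == pytest.approx(oracle, abs=1e-9)

    def test_collinear_mapping_rejected(self):
        ref = point_model([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            superpose(ref, ref, [(0, 0), (1, 1), (2, 2)])
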