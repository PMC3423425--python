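"""Molecular data model, PDB round-trips and geometry utilities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from mrcgbsa.errors import (
    ConditioningError,
    DomainError,
    FormatError,
    ParameterizationError,
    ShapeError,
)
from mrcgbsa.structures import (
    AtomRecord,
    Bond,
    ComplexSystem,
    MolecularStructure,
    ParameterTable,
    center_of_mass,
    kabsch_superpose,
    ligand_rmsd_after_receptor_fit,
    read_pdb,
    write_pdb,
)

PDB_ONE_ATOM = (
    "ATOM      1  C1  MOL A   1       1.500  -2.250   3.125  1.00  0.00           C\n"
    "END\n"
)

PDB_BONDED = (
    "HETATM    1  C1  LIG A   1       0.000   0.000   0.000  1.00  0.00           C\n"
    "HETATM    2  C2  LIG A   1       1.400   0.000   0.000  1.00  0.00           C\n"
    "CONECT    1    2\n"
    "END\n"
)


@pytest.fixture
def params():
    return ParameterTable({
        "*C": {"charge": 0.0, "sigma": 3.0, "epsilon": 0.1,
               "born_radius": 1.5, "mass": 12.011},
    })


def _mol(coords, masses=None, names=None, bonds=(), role="ligand"):
    coords = np.asarray(coords, float)
    n = len(coords)
    masses = masses or [12.0] * n
    names = names or [f"C{k+1}" for k in range(n)]
    atoms = [AtomRecord(name=names[k], element="C", position=coords[k],
                        mass=masses[k]) for k in range(n)]
    return MolecularStructure(atoms, list(bonds), role=role)


class TestPdbIO:
    def test_single_atom_identity_parse(self, tmp_path, params):
        path = tmp_path / "one.pdb"
        path.write_text(PDB_ONE_ATOM)
        s = read_pdb(path, params, role="receptor")
        assert s.n_atoms == 1
        np.testing.assert_allclose(s.coords[0], [1.5, -2.25, 3.125], atol=1e-3)
        assert s.atoms[0].name == "C1"

    def test_conect_becomes_zero_based_bond(self, tmp_path, params):
        path = tmp_path / "bonded.pdb"
        path.write_text(PDB_BONDED)
        s = read_pdb(path, params)
        assert [(b.i, b.j) for b in s.bonds] == [(0, 1)]
        assert s.bonds[0].b0 == pytest.approx(1.4, abs=1e-3)

    def test_roundtrip_coordinates_names_and_bonds(self, tmp_path):
        rng = np.random.default_rng(7)
        s = _mol(rng.uniform(-9, 9, (5, 3)), names=["N1", "C2", "O3", "C4", "H5"],
                 bonds=[Bond(0, 1), Bond(1, 2)])
        path = tmp_path / "round.pdb"
        write_pdb(s, path)
        table = ParameterTable({"*C": {"charge": 0, "sigma": 3, "epsilon": 0.1,
                                       "born_radius": 1.5, "mass": 12.0},
                                "*N": {"charge": 0, "sigma": 3, "epsilon": 0.1,
                                       "born_radius": 1.5, "mass": 14.0},
                                "*O": {"charge": 0, "sigma": 3, "epsilon": 0.1,
                                       "born_radius": 1.5, "mass": 16.0},
                                "*H": {"charge": 0, "sigma": 1, "epsilon": 0.01,
                                       "born_radius": 1.0, "mass": 1.0}})
        back = read_pdb(path, table)
        np.testing.assert_allclose(back.coords, s.coords, atol=5e-4)
        assert [a.name for a in back.atoms] == [a.name for a in s.atoms]
        assert [a.element for a in back.atoms] == [a.element for a in s.atoms]
        assert {(b.i, b.j) for b in back.bonds} == {(0, 1), (1, 2)}

    def test_written_file_has_one_record_per_atom(self, tmp_path):
        s = _mol([[0, 0, 0], [2, 0, 0]])
        path = tmp_path / "two.pdb"
        write_pdb(s, path)
        lines = path.read_text().splitlines()
        assert sum(1 for ln in lines if ln[:6] in ("ATOM  ", "HETATM")) == 2
        assert lines[-1].startswith("END")

    def test_empty_structure_is_invalid(self):
        with pytest.raises(DomainError):
            MolecularStructure([], [])

    def test_unparseable_record_names_line(self, tmp_path, params):
        path = tmp_path / "bad.pdb"
        path.write_text("ATOM      1  C1  MOL A   1       x.xxx   0.000   0.000\nEND\n")
        with pytest.raises(FormatError, match="line 1"):
            read_pdb(path, params)

    def test_missing_parameter_names_atom(self, tmp_path):
        path = tmp_path / "one.pdb"
        path.write_text(PDB_ONE_ATOM)
        table = ParameterTable({"XX": {"charge": 0, "sigma": 3, "epsilon": 0.1,
                                       "born_radius": 1.5, "mass": 12.0}})
        with pytest.raises(ParameterizationError, match="C1"):
            read_pdb(path, table)


class TestParameterTable:
    def test_exact_match_beats_wildcard(self):
        t = ParameterTable({
            "CA": {"charge": 0.5, "sigma": 3.2, "epsilon": 0.2,
                   "born_radius": 1.6, "mass": 12.0},
            "*C": {"charge": 0.0, "sigma": 3.0, "epsilon": 0.1,
                   "born_radius": 1.5, "mass": 12.0},
        })
        assert t.lookup("CA", "C")["charge"] == 0.5
        assert t.lookup("CB", "C")["charge"] == 0.0

    def test_tsv_roundtrip(self, tmp_path):
        t = ParameterTable({
            "CA": {"charge": 0.5, "sigma": 3.2, "epsilon": 0.2,
                   "born_radius": 1.6, "mass": 12.0},
            "*N": {"charge": -0.1, "sigma": 3.1, "epsilon": 0.15,
                   "born_radius": 1.4, "mass": 14.0},
        })
        path = tmp_path / "params.tsv"
        t.to_tsv(path)
        back = ParameterTable.from_tsv(path)
        assert back.lookup("CA", "C") == t.lookup("CA", "C")
        assert back.lookup("ND", "N") == t.lookup("ANY", "N")


class TestCenterOfMass:
    @pytest.mark.parametrize("coords,masses,expected", [
        ([[1, 2, 3]], [5.0], [1, 2, 3]),
        ([[0, 0, 0], [2, 0, 0]], [3.0, 3.0], [1, 0, 0]),
        ([[0, 0, 0], [4, 0, 0]], [1.0, 3.0], [3, 0, 0]),
    ])
    def test_weighted_mean(self, coords, masses, expected):
        np.testing.assert_allclose(center_of_mass(_mol(coords, masses)), expected)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_equivariance_under_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        s = _mol(rng.uniform(-5, 5, (4, 3)), list(rng.uniform(1, 20, 4)))
        R = Rotation.random(rng=np.random.default_rng(seed + 1)).as_matrix()
        t = rng.uniform(-10, 10, 3)
        moved = s.with_coords(s.coords @ R.T + t)
        np.testing.assert_allclose(center_of_mass(moved),
                                   R @ center_of_mass(s) + t, atol=1e-10)


class TestKabsch:
    def _points(self):
        return np.array([[0., 0, 0], [1, 0, 0], [0, 2, 0], [0.5, 0.5, 3]])

    def test_identical_sets(self):
        x = self._points()
        R, t, rmsd = kabsch_superpose(x, x)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(t, 0, atol=1e-10)
        assert rmsd == pytest.approx(0, abs=1e-6)

    def test_translation_recovered(self):
        x = self._points()
        R, t, rmsd = kabsch_superpose(x, x + [5, 0, 0])
        assert rmsd == pytest.approx(0, abs=1e-6)
        np.testing.assert_allclose(t, [5, 0, 0], atol=1e-10)

    def test_rotation_recovered(self):
        x = self._points()
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        R, t, rmsd = kabsch_superpose(x, x @ Rz.T)
        assert rmsd == pytest.approx(0, abs=1e-6)
        np.testing.assert_allclose(R, Rz, atol=1e-8)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_count_mismatch(self):
        with pytest.raises(ShapeError):
            kabsch_superpose(self._points(), self._points()[:3])

    def test_collinear_points_rejected(self):
        line = np.array([[0., 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ConditioningError):
            kabsch_superpose(line, line[::-1])

    def test_matches_brute_force_rotation_grid(self):
        """Kabsch rmsd equals the minimum over a dense grid of rotations."""
        rng = np.random.default_rng(3)
        x = rng.uniform(-2, 2, (4, 3))
        y = rng.uniform(-2, 2, (4, 3))
        _, _, rmsd = kabsch_superpose(x, y)
        xc, yc = x - x.mean(0), y - y.mean(0)
        n = 72
        grid = np.stack(np.meshgrid(
            np.linspace(0, 2 * np.pi, n, endpoint=False),
            np.linspace(0, np.pi, n // 2),
            np.linspace(0, 2 * np.pi, n, endpoint=False),
            indexing="ij"), axis=-1).reshape(-1, 3)
        mats = Rotation.from_euler("zyz", grid).as_matrix()
        rotated = np.einsum("kij,nj->kni", mats, xc)
        vals = np.sqrt(((rotated - yc) ** 2).sum(-1).mean(-1))
        best = float(vals.min())
        assert rmsd <= best + 1e-9
        assert best - rmsd < 1e-3


class TestLigandRmsd:
    def _complex(self, lig_coords):
        rng = np.random.default_rng(11)
        rec = _mol(rng.uniform(-4, 4, (6, 3)), role="receptor")
        for k, a in enumerate(rec.atoms):
            a.resid = k + 1
        lig = _mol(lig_coords, role="ligand")
        return ComplexSystem(rec, lig)

    def test_identical_pose_is_zero(self):
        ref = self._complex([[0., 0, 0], [1, 0, 0], [0, 1, 0]])
        assert ligand_rmsd_after_receptor_fit(ref, ref) == pytest.approx(0, abs=1e-9)

    def test_global_rigid_transform_absorbed_by_receptor_fit(self):
        ref = self._complex([[0., 0, 0], [1, 0, 0], [0, 1, 0]])
        R = Rotation.from_euler("xyz", [0.4, -1.1, 2.2]).as_matrix()
        t = np.array([3., -7, 2])
        rec = ref.receptor.with_coords(ref.receptor.coords @ R.T + t)
        lig = ref.ligand.with_coords(ref.ligand.coords @ R.T + t)
        pose = ComplexSystem(rec, lig)
        assert ligand_rmsd_after_receptor_fit(ref, pose) == pytest.approx(0, abs=1e-8)

    def test_pure_ligand_translation_gives_its_magnitude(self):
        ref = self._complex([[0., 0, 0], [1, 0, 0], [0, 1, 0]])
        pose = ComplexSystem(ref.receptor,
                             ref.ligand.with_coords(ref.ligand.coords + [3, 0, 0]))
        assert ligand_rmsd_after_receptor_fit(ref, pose) == pytest.approx(3.0, abs=1e-9)

    def test_hydrogens_excluded(self):
        ref = self._complex([[0., 0, 0], [1, 0, 0], [0, 1, 0]])
        ref.ligand.atoms[2].element = "H"
        moved = ref.ligand.coords.copy()
        moved[2] += [50, 0, 0]  # hydrogen flies away: RMSD must ignore it
        pose = ComplexSystem(ref.receptor, ref.ligand.with_coords(moved))
        pose.ligand.atoms[2].element = "H"
        assert ligand_rmsd_after_receptor_fit(ref, pose) == pytest.approx(0, abs=1e-9)
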