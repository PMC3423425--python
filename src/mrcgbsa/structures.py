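"""Molecular data model, PDB I/O and geometry utilities.

Structures are lists of :class:`AtomRecord` with explicit per-atom force-field
parameters (partial charge, Lennard-Jones sigma/epsilon, Born radius, mass)
supplied by a sidecar :class:`ParameterTable` (TSV).  Coordinates are in
angstroms, energies in kcal/mol throughout the package.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    ConditioningError,
    DomainError,
    FormatError,
    MappingError,
    ParameterizationError,
    ShapeError,
)

__all__ = [
    "AtomRecord",
    "Bond",
    "MolecularStructure",
    "ComplexSystem",
    "ParameterTable",
    "read_pdb",
    "write_pdb",
    "read_complex_pdb",
    "write_complex_pdb",
    "center_of_mass",
    "kabsch_superpose",
    "ligand_rmsd_after_receptor_fit",
]


@dataclass
class AtomRecord:
    """One atom: identity, position (A) and per-atom force-field parameters."""

    name: str
    element: str
    position: np.ndarray
    charge: float = 0.0
    lj_sigma: float = 3.0
    lj_epsilon: float = 0.1
    born_radius: float = 1.5
    mass: float = 12.011
    resid: int = 1
    resname: str = "MOL"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise DomainError(f"atom {self.name}: non-finite position")
        if self.lj_sigma <= 0:
            raise DomainError(f"atom {self.name}: lj_sigma must be > 0")
        if self.lj_epsilon < 0:
            raise DomainError(f"atom {self.name}: lj_epsilon must be >= 0")
        if self.born_radius <= 0:
            raise DomainError(f"atom {self.name}: born_radius must be > 0")
        if self.mass <= 0:
            raise DomainError(f"atom {self.name}: mass must be > 0")


@dataclass(frozen=True)
class Bond:
    """Harmonic bond i-j with force constant k_b (kcal/mol/A^2) and rest length b0 (A)."""

    i: int
    j: int
    k_b: float = 300.0
    b0: float = 1.5

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise DomainError(f"self-bond on atom index {self.i}")
        if self.i < 0 or self.j < 0:
            raise DomainError("negative bond index")


@dataclass
class MolecularStructure:
    """An ordered collection of atoms with bonds; role is 'receptor' or 'ligand'."""

    atoms: list[AtomRecord]
    bonds: list[Bond] = field(default_factory=list)
    role: str = "ligand"
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.atoms) < 1:
            raise DomainError("structure must contain at least one atom")
        n = len(self.atoms)
        for b in self.bonds:
            if b.i >= n or b.j >= n:
                raise DomainError(f"bond ({b.i},{b.j}) out of range for {n} atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def heavy_indices(self) -> np.ndarray:
        return np.array(
            [k for k, a in enumerate(self.atoms) if a.element.upper() != "H"],
            dtype=int,
        )

    def with_coords(self, coords: np.ndarray) -> "MolecularStructure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ShapeError(f"expected coords of shape ({self.n_atoms}, 3)")
        atoms = [replace(a, position=coords[k].copy()) for k, a in enumerate(self.atoms)]
        return MolecularStructure(atoms, list(self.bonds), self.role, self.label)


@dataclass
class ComplexSystem:
    """A receptor-ligand pair; optionally a second (apo, open-state) receptor.

    ``reference_ligand_com`` is the ligand center of mass at load time; shell
    distances r are displacements of the placed-ligand COM from this point.
    """

    receptor: MolecularStructure
    ligand: MolecularStructure
    receptor_apo: MolecularStructure | None = None
    reference_ligand_com: np.ndarray = None  # type: ignore[assignment]
    label: str = ""

    def __post_init__(self) -> None:
        if self.reference_ligand_com is None:
            self.reference_ligand_com = center_of_mass(self.ligand)
        self.reference_ligand_com = np.asarray(self.reference_ligand_com, float).reshape(3)
        if self.receptor_apo is not None:
            if self.receptor_apo.n_atoms != self.receptor.n_atoms:
                raise MappingError(
                    "apo receptor atom count differs from holo receptor "
                    f"({self.receptor_apo.n_atoms} vs {self.receptor.n_atoms})"
                )

    @property
    def n_atoms(self) -> int:
        return self.receptor.n_atoms + self.ligand.n_atoms

    @property
    def ligand_slice(self) -> slice:
        return slice(self.receptor.n_atoms, self.n_atoms)

    @property
    def receptor_slice(self) -> slice:
        return slice(0, self.receptor.n_atoms)

    def all_coords(self, receptor_variant: str = "holo") -> np.ndarray:
        rec = self.receptor
        if receptor_variant == "apo":
            if self.receptor_apo is None:
                raise DomainError("no apo receptor available")
            rec = self.receptor_apo
        return np.vstack([rec.coords, self.ligand.coords])


class ParameterTable:
    """Per-atom parameters keyed by atom name, with ``*<element>`` wildcard fallback.

    TSV columns: atom_name, charge, sigma, epsilon, born_radius, mass.
    A row whose atom_name is e.g. ``*C`` supplies defaults for any carbon whose
    name has no exact entry.
    """

    COLUMNS = ("atom_name", "charge", "sigma", "epsilon", "born_radius", "mass")

    def __init__(self, rows: dict[str, dict[str, float]]):
        self._exact: dict[str, dict[str, float]] = {}
        self._wild: dict[str, dict[str, float]] = {}
        for name, params in rows.items():
            if name.startswith("*"):
                self._wild[name[1:].upper()] = dict(params)
            else:
                self._exact[name] = dict(params)

    @classmethod
    def from_tsv(cls, path) -> "ParameterTable":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", comment="#")
        missing = set(cls.COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"parameter table {path} missing columns {sorted(missing)}")
        rows = {}
        for _, r in df.iterrows():
            rows[str(r["atom_name"])] = {
                "charge": float(r["charge"]),
                "sigma": float(r["sigma"]),
                "epsilon": float(r["epsilon"]),
                "born_radius": float(r["born_radius"]),
                "mass": float(r["mass"]),
            }
        return cls(rows)

    def to_tsv(self, path) -> None:
        import pandas as pd

        recs = []
        for name, p in self._exact.items():
            recs.append({"atom_name": name, **p})
        for el, p in self._wild.items():
            recs.append({"atom_name": f"*{el}", **p})
        pd.DataFrame(recs, columns=list(self.COLUMNS)).to_csv(path, sep="\t", index=False)

    def lookup(self, atom_name: str, element: str) -> dict[str, float]:
        if atom_name in self._exact:
            return self._exact[atom_name]
        if element.upper() in self._wild:
            return self._wild[element.upper()]
        raise ParameterizationError(
            f"no parameters for atom '{atom_name}' (element {element}) "
            "and no element wildcard row"
        )


def _guess_element(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def _validate_pdb_lines(path) -> None:
    with open(path, "r", newline="") as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if line[:6] not in ("ATOM  ", "HETATM"):
                continue
            if len(line) < 54:
                raise FormatError(f"{path}: line {ln}: truncated coordinate record")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError as exc:
                raise FormatError(f"{path}: line {ln}: unparseable coordinates") from exc


def _universe_from_pdb(path):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mda.Universe(str(path))


def _atoms_from_universe(u, params: ParameterTable) -> tuple[list[AtomRecord], list[str]]:
    n = len(u.atoms)
    names = [str(s) for s in u.atoms.names]
    try:
        elements = [str(e) if str(e).strip() else _guess_element(names[k])
                    for k, e in enumerate(u.atoms.elements)]
    except Exception:
        elements = [_guess_element(nm) for nm in names]
    try:
        resids = [int(r) for r in u.atoms.resids]
    except Exception:
        resids = [1] * n
    try:
        resnames = [str(r) for r in u.atoms.resnames]
    except Exception:
        resnames = ["MOL"] * n
    try:
        record_types = [str(t) for t in u.atoms.record_types]
    except Exception:
        record_types = ["ATOM"] * n
    atoms = []
    for k in range(n):
        p = params.lookup(names[k], elements[k])
        atoms.append(
            AtomRecord(
                name=names[k],
                element=elements[k],
                position=np.asarray(u.atoms.positions[k], dtype=float),
                charge=p["charge"],
                lj_sigma=p["sigma"],
                lj_epsilon=p["epsilon"],
                born_radius=p["born_radius"],
                mass=p["mass"],
                resid=resids[k],
                resname=resnames[k],
            )
        )
    return atoms, record_types


def _bonds_from_universe(u, coords: np.ndarray, bond_k: float) -> list[Bond]:
    bonds: list[Bond] = []
    try:
        pairs = [(int(b[0].ix), int(b[1].ix)) for b in u.bonds]
    except Exception:
        pairs = []
    for i, j in pairs:
        b0 = float(np.linalg.norm(coords[i] - coords[j]))
        bonds.append(Bond(i, j, k_b=bond_k, b0=b0))
    return bonds


def read_pdb(path, params: ParameterTable, role: str = "ligand",
             label: str | None = None, bond_k: float = 300.0) -> MolecularStructure:
    """Read ATOM/HETATM/CONECT records; parameters come from ``params``.

    Bond rest lengths are taken from the coordinates in the file; the force
    constant defaults to ``bond_k``.
    """
    _validate_pdb_lines(path)
    u = _universe_from_pdb(path)
    atoms, _ = _atoms_from_universe(u, params)
    coords = np.array([a.position for a in atoms])
    bonds = _bonds_from_universe(u, coords, bond_k)
    return MolecularStructure(atoms, bonds, role=role,
                              label=label if label is not None else str(path))


def read_complex_pdb(path, params: ParameterTable, label: str = "",
                     bond_k: float = 300.0) -> ComplexSystem:
    """Read a complex PDB: ATOM records form the receptor, HETATM the ligand."""
    _validate_pdb_lines(path)
    u = _universe_from_pdb(path)
    atoms, record_types = _atoms_from_universe(u, params)
    coords = np.array([a.position for a in atoms])
    bonds = _bonds_from_universe(u, coords, bond_k)
    rec_idx = [k for k, t in enumerate(record_types) if t.strip() == "ATOM"]
    lig_idx = [k for k, t in enumerate(record_types) if t.strip() != "ATOM"]
    if not rec_idx or not lig_idx:
        raise FormatError(
            f"{path}: complex PDB needs both ATOM (receptor) and HETATM (ligand) records"
        )
    remap = {old: new for new, old in enumerate(rec_idx)}
    lmap = {old: new for new, old in enumerate(lig_idx)}
    rec_bonds = [Bond(remap[b.i], remap[b.j], b.k_b, b.b0)
                 for b in bonds if b.i in remap and b.j in remap]
    lig_bonds = [Bond(lmap[b.i], lmap[b.j], b.k_b, b.b0)
                 for b in bonds if b.i in lmap and b.j in lmap]
    receptor = MolecularStructure([atoms[k] for k in rec_idx], rec_bonds,
                                  role="receptor", label=f"{label}:receptor")
    ligand = MolecularStructure([atoms[k] for k in lig_idx], lig_bonds,
                                role="ligand", label=f"{label}:ligand")
    return ComplexSystem(receptor, ligand, label=label or str(path))


def _write_structures_pdb(structures: list[MolecularStructure], path) -> None:
    import MDAnalysis as mda
    from MDAnalysis.core.topologyattrs import (
        Atomnames, Bonds, Elements, Masses, Occupancies, RecordTypes,
        Resids, Resnames, Segids, Tempfactors,
    )

    n = sum(s.n_atoms for s in structures)
    names, elements, resids, resnames, rectypes, masses = [], [], [], [], [], []
    coords = []
    bonds = []
    offset = 0
    for s in structures:
        rectype = "ATOM" if s.role == "receptor" else "HETATM"
        for a in s.atoms:
            names.append(a.name)
            elements.append(a.element)
            resids.append(a.resid)
            resnames.append(a.resname)
            rectypes.append(rectype)
            masses.append(a.mass)
            coords.append(a.position)
        bonds.extend((b.i + offset, b.j + offset) for b in s.bonds)
        offset += s.n_atoms
    # contiguous residue index per (structure, resid) pair
    res_keys: list[tuple[int, int]] = []
    atom_resindex = []
    key_base = 0
    pos = 0
    for si, s in enumerate(structures):
        for a in s.atoms:
            key = (si, a.resid)
            if not res_keys or res_keys[-1] != key:
                res_keys.append(key)
            atom_resindex.append(len(res_keys) - 1)
            pos += 1
    n_res = len(res_keys)
    res_resids = []
    res_resnames = []
    seen = -1
    for k, key in enumerate(res_keys):
        res_resids.append(key[1])
    # resnames per residue: first atom in that residue
    res_resnames = [None] * n_res
    for k, ri in enumerate(atom_resindex):
        if res_resnames[ri] is None:
            res_resnames[ri] = resnames[k]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n, n_residues=n_res, atom_resindex=np.array(atom_resindex),
                               residue_segindex=np.zeros(n_res, dtype=int), trajectory=True)
        u.add_TopologyAttr(Atomnames(np.array(names, dtype=object)))
        u.add_TopologyAttr(Elements(np.array(elements, dtype=object)))
        u.add_TopologyAttr(RecordTypes(np.array(rectypes, dtype=object)))
        u.add_TopologyAttr(Masses(np.array(masses)))
        u.add_TopologyAttr(Resids(np.array(res_resids)))
        u.add_TopologyAttr(Resnames(np.array(res_resnames, dtype=object)))
        u.add_TopologyAttr(Segids(np.array(["SYS"], dtype=object)))
        u.add_TopologyAttr(Occupancies(np.ones(n)))
        u.add_TopologyAttr(Tempfactors(np.zeros(n)))
        if bonds:
            u.add_TopologyAttr(Bonds(bonds))
        u.atoms.positions = np.array(coords, dtype=float)
        u.atoms.write(str(path), bonds="all" if bonds else None, reindex=True)


def write_pdb(structure: MolecularStructure, path) -> None:
    """Write standard ATOM/HETATM (+CONECT, END) records, 3-decimal coordinates."""
    _write_structures_pdb([structure], path)


def write_complex_pdb(system: ComplexSystem, path) -> None:
    """Write receptor (ATOM) and ligand (HETATM) as one complex PDB."""
    _write_structures_pdb([system.receptor, system.ligand], path)


def center_of_mass(structure: MolecularStructure) -> np.ndarray:
    """Mass-weighted mean position, sum(m_i x_i) / sum(m_i)."""
    m = structure.masses
    total = m.sum()
    if total <= 0:
        raise DomainError("zero total mass")
    return (structure.coords * m[:, None]).sum(axis=0) / total


def _check_nondegenerate(x: np.ndarray, what: str) -> None:
    c = x - x.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    if s[1] <= 1e-8 * max(s[0], 1.0):
        raise ConditioningError(f"{what}: points are (near-)collinear")


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation, translation, rmsd) with det(rotation) = +1 such that
    ``rotation @ x + translation`` best matches the reference.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ShapeError(f"point sets differ in shape: {mobile.shape} vs {reference.shape}")
    if mobile.shape[0] < 3:
        raise ShapeError("need at least 3 points for superposition")
    _check_nondegenerate(mobile, "mobile")
    _check_nondegenerate(reference, "reference")
    com_m = mobile.mean(axis=0)
    com_r = reference.mean(axis=0)
    rot, rssd = Rotation.align_vectors(reference - com_r, mobile - com_m)
    R = rot.as_matrix()
    t = com_r - R @ com_m
    rmsd = float(rssd / math.sqrt(mobile.shape[0]))
    return R, t, rmsd


def ligand_rmsd_after_receptor_fit(reference: ComplexSystem, pose: ComplexSystem) -> float:
    """Heavy-atom ligand RMSD after superposing the pose receptor onto the reference.

    Receptor atoms correspond by (resid, atom name); ligand atoms by order.
    The receptor-fit transform is applied to the pose ligand and the ligand is
    *not* re-fitted.
    """
    ref_key = {(a.resid, a.name): k for k, a in enumerate(reference.receptor.atoms)}
    if len(ref_key) != reference.receptor.n_atoms:
        raise MappingError("duplicate (resid, name) keys in reference receptor")
    order = []
    for a in pose.receptor.atoms:
        key = (a.resid, a.name)
        if key not in ref_key:
            raise MappingError(f"pose receptor atom {key} absent from reference receptor")
        order.append(ref_key[key])
    if len(set(order)) != reference.receptor.n_atoms:
        raise MappingError("receptor correspondence is not one-to-one")
    ref_rec = reference.receptor.coords[order]
    R, t, _ = kabsch_superpose(pose.receptor.coords, ref_rec)
    heavy = pose.ligand.heavy_indices
    ref_heavy = reference.ligand.heavy_indices
    if heavy.size != ref_heavy.size or heavy.size == 0:
        raise MappingError("ligand heavy-atom counts differ between pose and reference")
    moved = pose.ligand.coords[heavy] @ R.T + t
    diff = moved - reference.ligand.coords[ref_heavy]
    return float(np.sqrt((diff ** 2).sum(axis=1).mean()))
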