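"""Deterministic toy receptor/ligand systems, pose sets and brute-force oracles.

The toy complex is a rigid cup-shaped cage of Lennard-Jones sites (the
"receptor") with a small star-shaped bonded cluster (the "ligand") seated at
the pocket center.  The pocket opens along +z, so randomly placed ligands can
leave the pocket through the opening while placements into the walls are
redrawn by the clash guard.  ``pocket_depth`` sets the combined receptor-ligand
Lennard-Jones well depth per contact (kcal/mol): the ligand epsilon is chosen
so the Lorentz-Berthelot combination with the fixed receptor epsilon equals
the requested depth exactly, which keeps single-structure interaction energies
linear in the depth parameter across a ligand series.

Every fixture is reproducible from (spec, seed) alone.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .conformers import RSchedule
from .energy import EnergyModel, ToyGBSAForceField
from .errors import DomainError, GenerationError, SizeError
from .rescoring import PoseSet
from .scoring import KT_300, ScoreResult
from .structures import (
    AtomRecord,
    Bond,
    ComplexSystem,
    MolecularStructure,
    ParameterTable,
    center_of_mass,
)

__all__ = [
    "ToySystemSpec",
    "HarmonicWellModel",
    "make_toy_complex",
    "make_ligand_series",
    "make_pose_set",
    "toy_parameter_table",
    "enumerated_energy_grid",
    "brute_force_score_oracle",
]

_RECEPTOR_EPS = 0.1  # fixed cage-site LJ epsilon, kcal/mol
_RECEPTOR_SIGMA = 2.0
_LIGAND_SIGMA = 2.0
_POCKET_RADIUS = 2.8  # A, bowl radius about the pocket center
_ARM_LENGTH = 0.8  # A, ligand bond rest length
_BOWL_ZMAX = -0.35  # bowl covers directions with z in [-1, _BOWL_ZMAX]


@dataclass(frozen=True)
class ToySystemSpec:
    """Parameters of one toy receptor/ligand complex.

    ``geometry_scale`` multiplies every length (bowl radius, ligand arm, LJ
    sigmas) and is used to build systems whose full interaction range —
    including the fixed-probe surface-area occlusion — ends well inside the
    sampled distance window.
    """

    n_receptor_atoms: int = 32
    pocket_depth: float = 2.0  # combined LJ well depth per contact, kcal/mol
    ligand_size: int = 4
    ligand_charge: float = 0.0
    seed: int = 2012
    geometry_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.pocket_depth < 0:
            raise DomainError("pocket_depth must be >= 0")
        if self.n_receptor_atoms < 1 or self.ligand_size < 1:
            raise DomainError("atom counts must be >= 1")
        if self.geometry_scale <= 0:
            raise DomainError("geometry_scale must be > 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


class HarmonicWellModel:
    """Isotropic harmonic well about fixed centers; a minimal EnergyModel.

    E = 0.5 k sum_i |x_i - x0_i|^2.  Used as an analytically solvable engine
    for minimizer and thermostat checks.
    """

    def __init__(self, centers: np.ndarray, k: float = 1.0,
                 eps_in: float = 1.0, eps_w: float = 78.5):
        self.centers = np.asarray(centers, float)
        self.k = float(k)
        self.eps_in = eps_in
        self.eps_w = eps_w
        self.max_stable_dt_fs = math.inf

    def energy(self, coords: np.ndarray) -> float:
        d = np.asarray(coords, float) - self.centers
        return float(0.5 * self.k * (d ** 2).sum())

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        return self.k * (np.asarray(coords, float) - self.centers)

    def energy_and_gradient(self, coords):
        return self.energy(coords), self.gradient(coords)


def _cap_points(n: int) -> np.ndarray:
    """Golden-spiral points on the lower spherical cap z <= _BOWL_ZMAX (unit sphere)."""
    k = np.arange(n) + 0.5
    z = _BOWL_ZMAX - (1.0 + _BOWL_ZMAX) * k / n
    phi = k * math.pi * (3.0 - math.sqrt(5.0))
    s = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _ligand_geometry(size: int) -> np.ndarray:
    """Star cluster: central atom plus arms at tetrahedral-ish directions."""
    dirs = np.array([
        [1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0],
        [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0],
    ])
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    pts = [np.zeros(3)]
    for a in range(size - 1):
        pts.append(_ARM_LENGTH * dirs[a % len(dirs)])
    return np.array(pts)


def make_toy_complex(spec: ToySystemSpec, with_apo: bool = False,
                     apo_dilation: float = 1.25, label: str | None = None,
                     name_prefix: str = "L") -> ComplexSystem:
    """Build the cup-cage receptor with the ligand seated at the pocket center.

    With ``with_apo=True`` an open-state receptor variant (the cage dilated
    radially about the pocket center) is attached, exercising the holo/apo
    protocol used for hinged, flexible targets.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.geometry_scale
    cage = s * _POCKET_RADIUS * _cap_points(spec.n_receptor_atoms)
    cage = cage + rng.normal(0.0, 0.05 * s, cage.shape)  # small seeded corrugation

    def receptor_from(coords: np.ndarray) -> MolecularStructure:
        atoms = [
            AtomRecord(name=f"R{k+1}", element="C", position=coords[k],
                       charge=0.0, lj_sigma=s * _RECEPTOR_SIGMA,
                       lj_epsilon=_RECEPTOR_EPS, born_radius=1.7,
                       mass=12.011, resid=k + 1, resname="CAG")
            for k in range(len(coords))
        ]
        return MolecularStructure(atoms, [], role="receptor", label="cage")

    lig_eps = spec.pocket_depth ** 2 / _RECEPTOR_EPS
    lig_coords = s * _ligand_geometry(spec.ligand_size)
    q = spec.ligand_charge / spec.ligand_size
    lig_atoms = [
        AtomRecord(name=f"{name_prefix}{k+1}", element="C", position=lig_coords[k],
                   charge=q, lj_sigma=s * _LIGAND_SIGMA, lj_epsilon=lig_eps,
                   born_radius=1.5, mass=12.011, resid=1, resname="LIG")
        for k in range(spec.ligand_size)
    ]
    lig_bonds = [Bond(0, k, k_b=300.0, b0=s * _ARM_LENGTH)
                 for k in range(1, spec.ligand_size)]
    ligand = MolecularStructure(lig_atoms, lig_bonds, role="ligand", label="star")
    apo = receptor_from(cage * apo_dilation) if with_apo else None
    return ComplexSystem(receptor_from(cage), ligand, receptor_apo=apo,
                         label=label or f"toy-d{spec.pocket_depth:g}")


def toy_parameter_table(spec: ToySystemSpec) -> ParameterTable:
    """Parameter TSV content matching :func:`make_toy_complex` atom names."""
    lig_eps = spec.pocket_depth ** 2 / _RECEPTOR_EPS
    q = spec.ligand_charge / spec.ligand_size
    s = spec.geometry_scale
    rows = {
        "*C": {"charge": 0.0, "sigma": s * _RECEPTOR_SIGMA, "epsilon": _RECEPTOR_EPS,
               "born_radius": 1.7, "mass": 12.011},
    }
    for k in range(spec.ligand_size):
        rows[f"L{k+1}"] = {"charge": q, "sigma": s * _LIGAND_SIGMA, "epsilon": lig_eps,
                           "born_radius": 1.5, "mass": 12.011}
    return ParameterTable(rows)


@dataclass
class LigandSeriesEntry:
    label: str
    system: ComplexSystem
    dg_exp: float
    pocket_depth: float


def make_ligand_series(
    base: ToySystemSpec,
    depths,
    dg0: float = -2.0,
    slope: float = -1.8,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> list[LigandSeriesEntry]:
    """Ligand series with pseudo-experimental affinities.

    Pseudo dG_exp = dg0 + slope * depth + N(0, noise_sigma), an affine map of
    pocket depth; with noise_sigma = 0 deeper pockets have strictly lower
    dG_exp by construction.
    """
    depths = list(depths)
    if len(depths) < 3:
        raise DomainError("need at least 3 depths for a series")
    rng = np.random.default_rng(base.seed if seed is None else seed)
    out = []
    for k, depth in enumerate(depths):
        spec = ToySystemSpec(
            n_receptor_atoms=base.n_receptor_atoms,
            pocket_depth=float(depth),
            ligand_size=base.ligand_size,
            ligand_charge=base.ligand_charge,
            seed=base.seed,
        )
        dg = dg0 + slope * float(depth) + (rng.normal(0.0, noise_sigma)
                                           if noise_sigma > 0 else 0.0)
        out.append(LigandSeriesEntry(
            label=f"lig{k+1:02d}",
            system=make_toy_complex(spec, label=f"lig{k+1:02d}",
                                    name_prefix=f"L{k+1}"),
            dg_exp=float(dg), pocket_depth=float(depth)))
    return out


def parameter_table_from_structures(structures) -> ParameterTable:
    """Exact-name parameter table collected from existing atom records.

    Raises if one atom name maps to conflicting parameters (names must be
    unique per parameter set, as in the emitted toy fixtures).
    """
    rows: dict[str, dict[str, float]] = {}
    for s in structures:
        for a in s.atoms:
            params = {"charge": a.charge, "sigma": a.lj_sigma,
                      "epsilon": a.lj_epsilon, "born_radius": a.born_radius,
                      "mass": a.mass}
            if a.name in rows and rows[a.name] != params:
                raise DomainError(f"conflicting parameters for atom name {a.name!r}")
            rows[a.name] = params
    return ParameterTable(rows)


def make_pose_set(reference: ComplexSystem, target_rmsds, seed: int = 0,
                  label: str = "ligand") -> PoseSet:
    """Poses whose receptor-fit ligand RMSD hits each target within 0.01 A.

    Even-indexed targets use pure COM translation (RMSD equals the translation
    magnitude exactly); odd-indexed targets mix a rigid rotation about the
    ligand centroid with a translation.  Because a rotation about the centroid
    produces zero mean displacement, the combined RMSD obeys
    rmsd^2 = rmsd_rot^2 + |t|^2 in closed form.
    """
    rng = np.random.default_rng(seed)
    poses = []
    lig = reference.ligand
    x0 = lig.coords
    heavy = lig.heavy_indices
    for k, target in enumerate(target_rmsds):
        if target < 0:
            raise GenerationError("target RMSD must be >= 0")
        if target == 0:
            poses.append(ComplexSystem(reference.receptor, lig.with_coords(x0),
                                       label=f"{label}_pose{k}"))
            continue
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        rot_rmsd = 0.0
        y = x0.copy()
        if k % 2 == 1 and len(heavy) > 1:
            centroid = x0.mean(axis=0)
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            angle = 0.2 * target  # small enough that rotation alone undershoots
            for _ in range(60):  # bisect down if the rotation overshoots
                R = Rotation.from_rotvec(angle * axis).as_matrix()
                y = (x0 - centroid) @ R.T + centroid
                rot_rmsd = float(np.sqrt(((y - x0)[heavy] ** 2).sum(1).mean()))
                if rot_rmsd < target:
                    break
                angle *= 0.5
        shift = math.sqrt(max(target ** 2 - rot_rmsd ** 2, 0.0))
        y = y + shift * direction
        poses.append(ComplexSystem(reference.receptor, lig.with_coords(y),
                                   label=f"{label}_pose{k}"))
    return PoseSet(label=label, reference=reference, poses=poses)


# -- brute-force enumeration oracle --------------------------------------


def _direction_grid(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    z = 1.0 - 2.0 * k / n
    phi = k * math.pi * (3.0 - math.sqrt(5.0))
    s = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _orientation_grid(n: int) -> list[np.ndarray]:
    """Deterministic low-discrepancy orientation set (seeded quaternions)."""
    rng = np.random.default_rng(1234567)
    mats = [np.eye(3)]
    while len(mats) < n:
        q = rng.standard_normal(4)
        mats.append(Rotation.from_quat(q / np.linalg.norm(q)).as_matrix())
    return mats[:n]


def enumerated_energy_grid(
    system: ComplexSystem,
    schedule: RSchedule,
    engine: EnergyModel,
    n_directions: int = 4,
    n_orientations: int = 6,
    max_points: int = 10_000,
) -> np.ndarray:
    """Energy grid over the full direction x orientation placement grid.

    No sampling and no minimization: each shell's column holds the engine
    energies of every grid placement (at r = 0 the displacement vanishes, so
    each orientation repeats across directions, keeping the grid rectangular).
    """
    n_points = n_directions * n_orientations
    if n_points > max_points:
        raise SizeError(f"{n_points} grid points exceed the {max_points} budget")
    dirs = _direction_grid(n_directions)
    mats = _orientation_grid(n_orientations)
    x0 = system.all_coords("holo")
    ls = system.ligand_slice
    m = system.ligand.masses
    com = (x0[ls] * m[:, None]).sum(0) / m.sum()
    rec_holo = system.receptor.coords
    U = np.empty((n_points, len(schedule)))
    for i, r in enumerate(schedule.distances):
        rec = rec_holo
        if system.receptor_apo is not None and r > 0:
            rec = system.receptor_apo.coords
        col = 0
        for d in dirs:
            for R in mats:
                x = x0.copy()
                x[system.receptor_slice] = rec
                x[ls] = (x0[ls] - com) @ R.T + com + r * d
                U[col, i] = engine.energy(x)
                col += 1
    return U


def brute_force_score_oracle(
    system: ComplexSystem,
    schedule: RSchedule,
    engine: EnergyModel,
    n_directions: int = 4,
    n_orientations: int = 6,
    kT: float = KT_300,
    max_points: int = 10_000,
) -> ScoreResult:
    """Reference score from exhaustive enumeration and direct Boltzmann sums.

    Per transition the oracle evaluates -kT ln(Z_near / Z_far) with plain
    shifted exponential sums over the enumerated grid, independently of the
    scoring module's estimator path.
    """
    U = enumerated_energy_grid(system, schedule, engine,
                               n_directions, n_orientations, max_points)
    scores = []
    for i in range(U.shape[1] - 1):
        near, far = U[:, i], U[:, i + 1]
        score = 0.0
        # direct log-mean-exp with explicit max shift, written independently
        for col, sign in ((near, +1.0), (far, -1.0)):
            a = -col / kT
            m = a.max()
            score += sign * (-kT) * (m + math.log(np.mean(np.exp(a - m))))
        scores.append(score)
    return ScoreResult(
        shell_scores=scores,
        total_score=float(sum(scores)),
        kT=kT,
        epsilon_in=engine.eps_in,
        pairing_mode="ensemble",
        n_replicates=U.shape[0],
        schedule=schedule,
    )
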