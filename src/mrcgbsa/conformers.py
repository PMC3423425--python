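"""Replicate x shell grids of ligand placements.

Shell 0 (r = 0, the bound state) is sampled from a short thermostatted
trajectory of the complex; every nonzero shell is filled with rigid-body
ligand placements derived from the bound-state snapshots: a random rotation
about the ligand center of mass followed by a COM displacement of magnitude
exactly r in a random direction.  Every conformation is then energy-minimized
for a fixed number of steps and the final-step potential energy U[j, i] is
recorded for scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .energy import EnergyModel, minimize_conformation, run_langevin
from .errors import DomainError, GenerationError
from .structures import ComplexSystem, MolecularStructure

__all__ = [
    "RSchedule",
    "PlacementDraw",
    "ConformationSet",
    "BoundStateParams",
    "sample_bound_state",
    "random_placement_draw",
    "apply_placement",
    "select_receptor_variant",
    "generate_conformation_set",
    "DEFAULT_N_CONF",
    "DEFAULT_N_MIN",
]

DEFAULT_N_CONF = 100
DEFAULT_N_MIN = 100

_DEFAULT_DISTANCES = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0)
_FINE_DISTANCES = (0.0, 0.1, 0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0,
                   9.0, 10.0, 11.0, 12.0, 13.0, 14.0, 15.0)


@dataclass(frozen=True)
class RSchedule:
    """Ordered protein-ligand distances; shell 0 is the bound state (r = 0)."""

    distances: tuple[float, ...] = _DEFAULT_DISTANCES

    def __post_init__(self) -> None:
        d = self.distances
        if len(d) < 1 or d[0] != 0.0:
            raise DomainError("schedule must start at exactly 0.0")
        arr = np.asarray(d, float)
        if not np.all(np.isfinite(arr)):
            raise DomainError("schedule distances must be finite")
        if np.any(np.diff(arr) <= 0):
            raise DomainError("schedule distances must be strictly increasing")

    def __len__(self) -> int:
        return len(self.distances)

    @property
    def r_max(self) -> float:
        return self.distances[-1]

    @classmethod
    def default(cls) -> "RSchedule":
        """12-point coarse schedule, 0 to 10 A."""
        return cls(_DEFAULT_DISTANCES)

    @classmethod
    def fine(cls) -> "RSchedule":
        """19-point fine schedule with extra shells at 0.1/0.25/0.5 and out to 15 A."""
        return cls(_FINE_DISTANCES)

    @classmethod
    def from_string(cls, text: str) -> "RSchedule":
        if text.strip().lower() == "default":
            return cls.default()
        if text.strip().lower() == "fine":
            return cls.fine()
        try:
            vals = tuple(float(tok) for tok in text.replace(",", " ").split())
        except ValueError as exc:
            raise DomainError(f"unparseable schedule: {text!r}") from exc
        return cls(vals)


@dataclass(frozen=True)
class PlacementDraw:
    """Six random numbers defining one rigid-body placement.

    theta_x/y/z are intrinsic xyz Euler angles (radians); (r_x, r_y, r_z) is
    the COM displacement with r^2 = r_x^2 + r_y^2 + r_z^2.
    """

    theta_x: float
    theta_y: float
    theta_z: float
    r_x: float
    r_y: float
    r_z: float

    @property
    def displacement(self) -> np.ndarray:
        return np.array([self.r_x, self.r_y, self.r_z])

    @property
    def r(self) -> float:
        return float(np.linalg.norm(self.displacement))

    @property
    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler(
            "xyz", [self.theta_x, self.theta_y, self.theta_z]
        ).as_matrix()


@dataclass
class BoundStateParams:
    """Settings for the bound-state sampler (defaults: 10 ps at 300 K, 1 fs)."""

    t_total_ps: float = 10.0
    dt_fs: float = 1.0
    temperature: float = 300.0
    friction_per_ps: float = 2.0


@dataclass
class ConformationSet:
    """The replicate x shell grid with minimized final energies U[j][i]."""

    schedule: RSchedule
    n_replicates: int
    conformations: list[list[np.ndarray]]
    energies: np.ndarray  # (n_replicates, n_shells)
    draws: list[list[PlacementDraw | None]]
    receptor_variant_used: list[str]

    def __post_init__(self) -> None:
        ns = len(self.schedule)
        if self.energies.shape != (self.n_replicates, ns):
            raise GenerationError("energies grid shape does not match schedule")
        if not np.all(np.isfinite(self.energies)):
            j, i = np.argwhere(~np.isfinite(self.energies))[0]
            raise GenerationError(f"non-finite minimized energy at replicate {j}, shell {i}")


def random_placement_draw(r: float, rng: np.random.Generator,
                          orientation_mode: str = "quaternion") -> PlacementDraw:
    """Draw one rigid-body placement at COM displacement magnitude exactly r.

    The displacement direction is uniform on the sphere.  With
    ``orientation_mode='quaternion'`` (default) the rotation is uniform over
    orientations (random unit quaternion); ``'euler'`` draws three independent
    uniform Euler angles instead.
    """
    if r <= 0:
        raise DomainError("placement distance r must be > 0")
    v = rng.standard_normal(3)
    nv = np.linalg.norm(v)
    while nv < 1e-12:
        v = rng.standard_normal(3)
        nv = np.linalg.norm(v)
    disp = v * (r / nv)
    if orientation_mode == "quaternion":
        q = rng.standard_normal(4)
        q /= np.linalg.norm(q)
        ang = Rotation.from_quat(q).as_euler("xyz")
    elif orientation_mode == "euler":
        ang = rng.uniform(0.0, 2.0 * math.pi, 3)
    else:
        raise DomainError(f"unknown orientation_mode {orientation_mode!r}")
    return PlacementDraw(float(ang[0]), float(ang[1]), float(ang[2]),
                         float(disp[0]), float(disp[1]), float(disp[2]))


def apply_placement(system: ComplexSystem, coords: np.ndarray,
                    draw: PlacementDraw) -> np.ndarray:
    """Rigidly rotate the ligand about its COM, then displace the COM.

    Receptor coordinates are untouched; ligand internal distances are
    preserved exactly.
    """
    x = np.array(coords, dtype=float)
    ls = system.ligand_slice
    lig = x[ls]
    m = system.ligand.masses
    com = (lig * m[:, None]).sum(axis=0) / m.sum()
    R = draw.rotation_matrix
    x[ls] = (lig - com) @ R.T + com + draw.displacement
    return x


def select_receptor_variant(shell_r: float, system: ComplexSystem
                            ) -> tuple[MolecularStructure, str]:
    """Holo receptor at r = 0, apo receptor for r > 0 when one is provided."""
    if system.receptor_apo is None:
        return system.receptor, "holo"
    if shell_r == 0.0:
        return system.receptor, "holo"
    return system.receptor_apo, "apo"


def sample_bound_state(
    system: ComplexSystem,
    engine: EnergyModel,
    n_snapshots: int = 100,
    sim_params: BoundStateParams | None = None,
    seed=0,
) -> list[np.ndarray]:
    """Sample bound-state (r = 0) conformations from a thermostatted trajectory.

    Runs Langevin dynamics of the complex (holo receptor held rigid, ligand
    mobile) and returns exactly ``n_snapshots`` frames at uniform time
    intervals ending at the final step.
    """
    p = sim_params or BoundStateParams()
    n_steps = int(round(p.t_total_ps * 1000.0 / p.dt_fs))
    if n_snapshots < 1 or n_snapshots > n_steps:
        raise DomainError(f"n_snapshots must be in [1, {n_steps}]")
    save_every = n_steps // n_snapshots
    x0 = system.all_coords("holo")
    movable = np.zeros(system.n_atoms, dtype=bool)
    movable[system.ligand_slice] = True
    masses = np.concatenate([system.receptor.masses, system.ligand.masses])
    frames = run_langevin(
        x0, engine, masses,
        temperature=p.temperature, friction_per_ps=p.friction_per_ps,
        dt_fs=p.dt_fs, n_steps=n_steps, seed=seed,
        movable=movable, save_every=save_every,
    )
    return [frames[k] for k in range(len(frames) - n_snapshots, len(frames))]


def _min_receptor_ligand_distance(rec: np.ndarray, lig: np.ndarray) -> float:
    d2 = ((rec[:, None, :] - lig[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.min()))


def generate_conformation_set(
    system: ComplexSystem,
    schedule: RSchedule | None = None,
    n_conf: int = DEFAULT_N_CONF,
    engine: EnergyModel = None,
    n_min: int = DEFAULT_N_MIN,
    seed=0,
    orientation_mode: str = "quaternion",
    sim_params: BoundStateParams | None = None,
    clash_distance: float | None = None,
    max_redraws: int = 50,
    switch_step: int = 10,
) -> ConformationSet:
    """Build the full replicate x shell grid and its minimized energy grid.

    Replicate lineage: the conformation at (j, i) descends from bound-state
    snapshot j for every shell i, each nonzero shell via an independent
    placement draw (per-(j, i) RNG substreams derived from ``seed``).
    Placements bringing any receptor-ligand pair closer than
    ``clash_distance`` are redrawn up to ``max_redraws`` times, then accepted
    and left to the displacement-capped minimizer.  The default threshold is
    0.9 of the smallest receptor-ligand LJ sigma, i.e. just inside contact,
    which keeps every accepted placement within reach of an N_min-step
    displacement-capped relaxation (a fixed small threshold admits placements
    wedged deep into the repulsive wall that no local minimization can
    rescue, and single extreme energies dominate exponential work averages).
    """
    if engine is None:
        raise DomainError("an energy engine is required")
    if n_conf < 1:
        raise DomainError("n_conf must be >= 1")
    schedule = schedule or RSchedule.default()
    if clash_distance is None:
        sig_r = min(a.lj_sigma for a in system.receptor.atoms)
        sig_l = min(a.lj_sigma for a in system.ligand.atoms)
        clash_distance = 0.9 * 0.5 * (sig_r + sig_l)
    md_seed = np.random.SeedSequence(seed, spawn_key=(0,))
    snapshots = sample_bound_state(system, engine, n_conf, sim_params, seed=md_seed)

    n_shells = len(schedule)
    movable = np.zeros(system.n_atoms, dtype=bool)
    movable[system.ligand_slice] = True
    rs = system.receptor_slice

    conformations: list[list[np.ndarray]] = [[None] * n_shells for _ in range(n_conf)]
    draws: list[list[PlacementDraw | None]] = [[None] * n_shells for _ in range(n_conf)]
    energies = np.empty((n_conf, n_shells))
    variants: list[str] = []
    for i, r in enumerate(schedule.distances):
        rec, variant = select_receptor_variant(r, system)
        variants.append(variant)
        rec_coords = rec.coords
        for j in range(n_conf):
            base = np.array(snapshots[j])
            if i == 0:
                x = base
            else:
                rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(j, i)))
                draw = None
                for _ in range(max_redraws + 1):
                    cand = random_placement_draw(r, rng, orientation_mode)
                    placed = apply_placement(system, base, cand)
                    placed[rs] = rec_coords
                    draw = cand
                    if _min_receptor_ligand_distance(
                            placed[rs], placed[system.ligand_slice]) >= clash_distance:
                        break
                draws[j][i] = draw
                x = placed
            try:
                res = minimize_conformation(x, engine, n_min=n_min,
                                            switch_step=switch_step, movable=movable)
            except Exception as exc:
                raise GenerationError(
                    f"minimization failed at replicate {j}, shell {i} (r={r})"
                ) from exc
            conformations[j][i] = res.final_coordinates
            energies[j, i] = res.final_energy
    return ConformationSet(
        schedule=schedule,
        n_replicates=n_conf,
        conformations=conformations,
        energies=energies,
        draws=draws,
        receptor_variant_used=variants,
    )
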