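"""Energy model contract, toy MM-GBSA force field, minimizer, Langevin integrator.

The built-in force field is a compact molecular-mechanics + generalized-Born +
surface-area model over explicit per-atom parameters:

    E = sum_bonds k_b (b - b0)^2
      + sum_pairs 4 eps_LJ [(sigma/d)^12 - (sigma/d)^6]
      + sum_pairs 332.0636 q_i q_j / (eps_in d)
      + E_GB + gamma_SASA * SASA

with the Still pairwise generalized-Born polar term

    E_GB = -0.5 * 332.0636 * (1/eps_in - 1/eps_w) * sum_{i,j} q_i q_j / f_GB,
    f_GB = sqrt(d^2 + a_i a_j exp(-d^2 / (4 a_i a_j))),

using fixed input Born radii ``a``.  Nonbonded pairs are all inter-molecular
pairs plus intramolecular pairs separated by at least three bonds; the GB sum
runs over *all* pairs including the i=j self terms.  The nonpolar term is
gamma_SASA (0.005 kcal/mol/A^2 by default) times a sphere-point
(Shrake-Rupley) solvent-accessible surface area with a 1.4 A probe, evaluated
in a canonical principal-axes frame so the total energy is exactly invariant
under global rigid motions.

Units: angstrom, kcal/mol, amu, fs.  The interior dielectric ``eps_in`` enters
both the Coulomb denominator and the GB prefactor; the solvent dielectric is
fixed at 78.5 by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import networkx as nx
import numpy as np

from .errors import DomainError, InstabilityError, SingularEnergyError
from .structures import ComplexSystem, MolecularStructure

__all__ = [
    "COULOMB_CONSTANT",
    "KB_KCAL",
    "EnergyModel",
    "ToyGBSAForceField",
    "MinimizationResult",
    "minimize_template",
    "minimize_conformation",
    "run_langevin",
    "build_engine",
]

COULOMB_CONSTANT = 332.0636  # kcal/mol * A / e^2
KB_KCAL = 0.0019872041  # kcal/mol/K
_FORCE_TO_ACC = 4.184e-4  # (kcal/mol/A)/amu -> A/fs^2


@runtime_checkable
class EnergyModel(Protocol):
    """Contract every engine (built-in or external adapter) must satisfy."""

    eps_in: float
    eps_w: float

    def energy(self, coords: np.ndarray) -> float: ...

    def gradient(self, coords: np.ndarray) -> np.ndarray: ...


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral unit sphere points."""
    k = np.arange(n) + 0.5
    z = 1.0 - 2.0 * k / n
    phi = k * math.pi * (3.0 - math.sqrt(5.0))
    s = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _canonical_frame(x: np.ndarray) -> np.ndarray:
    """Rotate centered coordinates into a principal-axes frame.

    Axis signs are fixed by third-moment (skewness) signs and handedness by a
    cross product, making the frame — and hence the sphere-point SASA —
    invariant under global rigid motions of the input.
    """
    c = x - x.mean(axis=0)
    if len(c) < 2:
        return c
    cov = c.T @ c
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    a1, a2 = v[:, order[0]], v[:, order[1]]
    for k, ax in enumerate((a1, a2)):
        s = float(np.sum((c @ ax) ** 3))
        if abs(s) < 1e-12:
            s = float(np.sum(c @ ax))
        if s < 0:
            if k == 0:
                a1 = -a1
            else:
                a2 = -a2
    a3 = np.cross(a1, a2)
    return c @ np.column_stack([a1, a2, a3])


class ToyGBSAForceField:
    """Built-in MM-GBSA force field over explicit per-atom parameters.

    Parameters are taken from the atoms of the supplied structures.  Pairs
    inside each index group in ``rigid_groups`` can be excluded from the
    LJ/Coulomb sums (their contribution is constant for a rigid body); GB self
    and cross terms always run over all atoms.
    """

    def __init__(
        self,
        structures: list[MolecularStructure],
        eps_in: float = 1.0,
        eps_w: float = 78.5,
        gamma_sasa: float = 0.005,
        n_sphere_points: int = 32,
        probe_radius: float = 1.4,
        rigid_groups: list[np.ndarray] | None = None,
        cutoff: float | None = None,
    ):
        if eps_in <= 0 or eps_w <= 0:
            raise DomainError("dielectric constants must be positive")
        if cutoff is not None and cutoff <= 0:
            raise DomainError("cutoff must be positive or None")
        self.eps_in = float(eps_in)
        self.eps_w = float(eps_w)
        self.gamma_sasa = float(gamma_sasa)
        self.probe_radius = float(probe_radius)
        self.cutoff = cutoff
        self._pts = _sphere_points(int(n_sphere_points))

        charges, sigmas, epsilons, born, masses = [], [], [], [], []
        bonds = []
        mol_id = []
        offset = 0
        for mi, s in enumerate(structures):
            for a in s.atoms:
                charges.append(a.charge)
                sigmas.append(a.lj_sigma)
                epsilons.append(a.lj_epsilon)
                born.append(a.born_radius)
                masses.append(a.mass)
                mol_id.append(mi)
            for b in s.bonds:
                bonds.append((b.i + offset, b.j + offset, b.k_b, b.b0))
            offset += s.n_atoms
        n = offset
        self.n_atoms = n
        self.charges = np.array(charges)
        self.sigmas = np.array(sigmas)
        self.epsilons = np.array(epsilons)
        self.born = np.array(born)
        self.masses = np.array(masses)
        self.mol_id = np.array(mol_id)
        self.bond_i = np.array([b[0] for b in bonds], dtype=int)
        self.bond_j = np.array([b[1] for b in bonds], dtype=int)
        self.bond_k = np.array([b[2] for b in bonds])
        self.bond_b0 = np.array([b[3] for b in bonds])

        # nonbonded pair list: inter-molecular pairs + intra pairs >= 3 bonds apart
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(zip(self.bond_i, self.bond_j))
        near = dict(nx.all_pairs_shortest_path_length(g, cutoff=2))
        rigid_mask = np.zeros((0, 2), dtype=int)
        rigid_sets = [set(np.asarray(gr, dtype=int).tolist()) for gr in (rigid_groups or [])]
        pi, pj = [], []
        for i in range(n):
            for j in range(i + 1, n):
                if self.mol_id[i] == self.mol_id[j]:
                    if j in near.get(i, {}):
                        continue
                    if any(i in rs and j in rs for rs in rigid_sets):
                        continue
                pi.append(i)
                pj.append(j)
        self.pair_i = np.array(pi, dtype=int)
        self.pair_j = np.array(pj, dtype=int)
        self.pair_sigma = 0.5 * (self.sigmas[self.pair_i] + self.sigmas[self.pair_j])
        self.pair_eps = np.sqrt(self.epsilons[self.pair_i] * self.epsilons[self.pair_j])
        self.pair_qq = self.charges[self.pair_i] * self.charges[self.pair_j]

        # GB cross pairs (all i<j with q_i q_j != 0) and constant self term
        gi, gj = np.triu_indices(n, k=1)
        qq = self.charges[gi] * self.charges[gj]
        keep = qq != 0.0
        self.gb_i = gi[keep]
        self.gb_j = gj[keep]
        self.gb_qq = qq[keep]
        self.gb_aa = self.born[self.gb_i] * self.born[self.gb_j]
        self._gb_self = float(np.sum(self.charges ** 2 / self.born))
        # SASA radii: LJ minimum-distance based van der Waals radius + probe
        self.sasa_radii = (2.0 ** (1.0 / 6.0)) * self.sigmas / 2.0 + self.probe_radius

        # conservative Langevin stability bound from the stiffest bond
        if len(self.bond_k):
            m_red = np.minimum(self.masses[self.bond_i], self.masses[self.bond_j])
            omega = np.sqrt(2.0 * self.bond_k * _FORCE_TO_ACC / m_red).max()
            self.max_stable_dt_fs = 0.3 / omega
        else:
            self.max_stable_dt_fs = math.inf

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_complex(cls, system: ComplexSystem, rigid_receptor: bool = True,
                     **kwargs) -> "ToyGBSAForceField":
        groups = None
        if rigid_receptor:
            groups = [np.arange(system.receptor.n_atoms)]
        return cls([system.receptor, system.ligand], rigid_groups=groups, **kwargs)

    # -- terms ------------------------------------------------------------

    def _gb_prefactor(self) -> float:
        return -0.5 * COULOMB_CONSTANT * (1.0 / self.eps_in - 1.0 / self.eps_w)

    def sasa(self, coords: np.ndarray) -> float:
        """Shrake-Rupley solvent-accessible surface area (A^2), canonical frame."""
        x = _canonical_frame(np.asarray(coords, float))
        n = self.n_atoms
        R = self.sasa_radii
        if n == 1:
            return float(4.0 * math.pi * R[0] ** 2)
        m = len(self._pts)
        # surface points of every atom against every atom via one GEMM:
        # |p - y|^2 = |p|^2 - 2 p.y + |y|^2
        pts = (x[:, None, :] + R[:, None, None] * self._pts[None, :, :]).reshape(n * m, 3)
        d2 = ((pts ** 2).sum(1)[:, None] - 2.0 * (pts @ x.T)
              + (x ** 2).sum(1)[None, :]).reshape(n, m, n)
        within = d2 < (R ** 2)[None, None, :]
        idx = np.arange(n)
        within[idx, :, idx] = False
        frac = 1.0 - within.any(-1).mean(axis=1)
        return float((4.0 * math.pi * R ** 2 * frac).sum())

    def _pair_distances(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        dx = x[self.pair_i] - x[self.pair_j]
        d = np.sqrt((dx ** 2).sum(-1))
        if d.size and d.min() < 1e-6:
            k = int(np.argmin(d))
            raise SingularEnergyError(
                f"coincident nonbonded atoms {self.pair_i[k]} and {self.pair_j[k]}"
            )
        return dx, d

    def energy(self, coords: np.ndarray) -> float:
        return self._energy_gradient(coords, want_gradient=False)[0]

    def minimization_energy(self, coords: np.ndarray) -> float:
        """Smooth part of the energy (SASA excluded), used in line searches.

        The sphere-point area is piecewise constant, so its jumps would stall
        a backtracking line search while contributing nothing to the gradient;
        treating it as locally constant during minimization is exactly
        consistent with the zero-a.e. SASA gradient.
        """
        return self._energy_gradient(coords, want_gradient=False, skip_sasa=True)[0]

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        # SASA is piecewise constant, so its gradient contribution is zero and
        # the (comparatively costly) area evaluation can be skipped here.
        return self._energy_gradient(coords, want_gradient=True, skip_sasa=True)[1]

    def energy_and_gradient(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        return self._energy_gradient(coords, want_gradient=True)

    def _energy_gradient(self, coords: np.ndarray, want_gradient: bool,
                         skip_sasa: bool = False
                         ) -> tuple[float, np.ndarray | None]:
        x = np.asarray(coords, float).reshape(self.n_atoms, 3)
        e = 0.0
        g = np.zeros_like(x) if want_gradient else None

        if len(self.bond_i):
            dxb = x[self.bond_i] - x[self.bond_j]
            db = np.sqrt((dxb ** 2).sum(-1))
            delta = db - self.bond_b0
            e += float(np.sum(self.bond_k * delta ** 2))
            if want_gradient:
                coef = (2.0 * self.bond_k * delta / np.maximum(db, 1e-12))[:, None]
                f = coef * dxb
                np.add.at(g, self.bond_i, f)
                np.add.at(g, self.bond_j, -f)

        if len(self.pair_i):
            dx, d = self._pair_distances(x)
            sr6 = (self.pair_sigma / d) ** 6
            e_lj = 4.0 * self.pair_eps * (sr6 ** 2 - sr6)
            e_c = COULOMB_CONSTANT * self.pair_qq / (self.eps_in * d)
            if self.cutoff is not None:
                # potential-shift truncation: V(d) - V(rc) inside, 0 outside
                inside = d < self.cutoff
                src6 = (self.pair_sigma / self.cutoff) ** 6
                e_lj = np.where(inside,
                                e_lj - 4.0 * self.pair_eps * (src6 ** 2 - src6), 0.0)
                e_c = np.where(inside,
                               e_c - COULOMB_CONSTANT * self.pair_qq
                               / (self.eps_in * self.cutoff), 0.0)
            e += float(e_lj.sum()) + float(e_c.sum())
            if want_gradient:
                # dE/dd for LJ and Coulomb (shift leaves forces unchanged inside)
                dlj = 4.0 * self.pair_eps * (-12.0 * sr6 ** 2 + 6.0 * sr6) / d
                dc = -COULOMB_CONSTANT * self.pair_qq / (self.eps_in * d ** 2)
                dd = dlj + dc
                if self.cutoff is not None:
                    dd = np.where(d < self.cutoff, dd, 0.0)
                coef = (dd / d)[:, None]
                f = coef * dx
                np.add.at(g, self.pair_i, f)
                np.add.at(g, self.pair_j, -f)

        pref = self._gb_prefactor()
        e += pref * self._gb_self
        if len(self.gb_i):
            dxg = x[self.gb_i] - x[self.gb_j]
            d2 = (dxg ** 2).sum(-1)
            expo = np.exp(-d2 / (4.0 * self.gb_aa))
            f2 = d2 + self.gb_aa * expo
            fgb = np.sqrt(f2)
            e += float(pref * 2.0 * np.sum(self.gb_qq / fgb))
            if want_gradient:
                d = np.sqrt(d2)
                df2_dd = d * (2.0 - 0.5 * expo)
                dE_dd = pref * 2.0 * (-self.gb_qq / f2) * (df2_dd / (2.0 * fgb))
                coef = (dE_dd / np.maximum(d, 1e-12))[:, None]
                f = coef * dxg
                np.add.at(g, self.gb_i, f)
                np.add.at(g, self.gb_j, -f)

        if self.gamma_sasa != 0.0 and not skip_sasa:
            # piecewise constant in coordinates: exact gradient is zero a.e.
            e += self.gamma_sasa * self.sasa(x)

        return float(e), g


@dataclass
class MinimizationResult:
    final_coordinates: np.ndarray
    final_energy: float
    energy_trace: list[float]
    gradient_rms_final: float
    steps_taken: int
    method_switch_step: int
    converged: bool = False


def _grad_rms(g: np.ndarray, movable: np.ndarray) -> float:
    gm = g[movable]
    return float(np.sqrt((gm ** 2).mean())) if gm.size else 0.0


def _minimize(
    x0: np.ndarray,
    engine: EnergyModel,
    max_steps: int,
    switch_step: int,
    grad_tol: float | None,
    movable: np.ndarray | None,
    max_disp: float = 0.01,
) -> MinimizationResult:
    """Steepest-descent -> conjugate-gradient (Polak-Ribiere) minimizer.

    The line search backtracks by halving from a trial step scaled so the
    largest atomic displacement equals the current trial length; the trial
    recovers (doubles) after accepted steps but never exceeds ``max_disp``,
    so an N-step minimization moves no atom further than N * max_disp and
    stays local to its shell.
    """
    x = np.array(x0, dtype=float)
    n = x.shape[0]
    mov = np.ones(n, dtype=bool) if movable is None else np.asarray(movable, bool)
    # line searches compare the smooth part of the energy where the engine
    # distinguishes one (piecewise-constant terms otherwise stall descent)
    efun = getattr(engine, "minimization_energy", engine.energy)
    e = efun(x)
    g = engine.gradient(x)
    if not math.isfinite(e):
        raise InstabilityError("non-finite energy at minimization start")
    trace = [e]
    gm = np.where(mov[:, None], g, 0.0)
    d_prev = None
    g_prev = None
    trial = max_disp
    steps = 0
    converged = False
    for step in range(1, max_steps + 1):
        rms = _grad_rms(g, mov)
        if grad_tol is not None and rms < grad_tol:
            converged = True
            break
        gnorm = float(np.abs(gm).max())
        if gnorm < 1e-14:
            converged = True
            break
        if step <= switch_step or d_prev is None:
            d = -gm
        else:
            denom = float((g_prev * g_prev).sum())
            beta = max(0.0, float((gm * (gm - g_prev)).sum()) / max(denom, 1e-300))
            d = -gm + beta * d_prev
            if float((d * gm).sum()) >= 0.0:  # not a descent direction: restart
                d = -gm
        dmax = float(np.sqrt((d ** 2).sum(axis=1)).max())
        s = trial / max(dmax, 1e-300)
        accepted = False
        for _ in range(60):
            xt = x + s * d
            et = efun(xt)
            if not math.isfinite(et):
                raise InstabilityError(f"non-finite energy in line search at step {step}")
            if et < e:
                accepted = True
                break
            s *= 0.5
        if not accepted:
            converged = True
            break
        x, e = xt, et
        g_prev, d_prev = gm, d
        g = engine.gradient(x)  # energy already known from the line search
        gm = np.where(mov[:, None], g, 0.0)
        trace.append(e)
        steps = step
        trial = max(min(max_disp, 2.0 * s * dmax), 1e-6)
    return MinimizationResult(
        final_coordinates=x,
        final_energy=float(engine.energy(x)),
        energy_trace=trace,
        gradient_rms_final=_grad_rms(g, mov),
        steps_taken=steps,
        method_switch_step=switch_step,
        converged=converged,
    )


def minimize_template(
    coords: np.ndarray,
    engine: EnergyModel,
    tol: float = 0.1,
    switch_step: int = 100,
    max_steps: int = 5000,
    movable: np.ndarray | None = None,
) -> MinimizationResult:
    """Minimize until the gradient RMS drops below ``tol`` (kcal/mol/A).

    The method switches from steepest descent to conjugate gradient after
    ``switch_step`` steps (default 100), the protocol used for template
    (reference-complex) structures.
    """
    return _minimize(coords, engine, max_steps, switch_step, tol, movable)


def minimize_conformation(
    coords: np.ndarray,
    engine: EnergyModel,
    n_min: int = 100,
    switch_step: int = 10,
    movable: np.ndarray | None = None,
) -> MinimizationResult:
    """Run exactly ``n_min`` minimization steps (SD -> CG at step 10 by default).

    The final-step energy is the sampled U used for scoring.
    """
    if n_min < 0:
        raise DomainError("n_min must be >= 0")
    if n_min == 0:
        e = engine.energy(np.asarray(coords, float))
        g = engine.gradient(np.asarray(coords, float))
        mov = np.ones(len(coords), bool) if movable is None else np.asarray(movable, bool)
        return MinimizationResult(np.array(coords, float), float(e), [float(e)],
                                  _grad_rms(g, mov), 0, switch_step)
    return _minimize(coords, engine, n_min, switch_step, None, movable)


def run_langevin(
    coords: np.ndarray,
    engine: EnergyModel,
    masses: np.ndarray,
    temperature: float = 300.0,
    friction_per_ps: float = 2.0,
    dt_fs: float = 1.0,
    n_steps: int = 1000,
    seed=0,
    movable: np.ndarray | None = None,
    save_every: int | None = None,
) -> np.ndarray:
    """BAOAB Langevin dynamics; returns frames saved every ``save_every`` steps.

    Temperature in K, friction in ps^-1, timestep in fs.  With T=0 the noise
    vanishes and the integrator performs damped descent.  The timestep must
    resolve the stiffest bond; engines expose ``max_stable_dt_fs``.
    """
    x = np.array(coords, dtype=float)
    n = x.shape[0]
    m = np.asarray(masses, float).reshape(n, 1)
    if dt_fs <= 0 or n_steps < 1:
        raise DomainError("dt_fs must be > 0 and n_steps >= 1")
    dt_cap = getattr(engine, "max_stable_dt_fs", math.inf)
    if dt_fs > dt_cap:
        raise DomainError(
            f"dt_fs={dt_fs} exceeds the stability bound {dt_cap:.3f} fs "
            "for the stiffest bond in this system"
        )
    mov = np.ones(n, dtype=bool) if movable is None else np.asarray(movable, bool)
    mask = mov[:, None]
    rng = np.random.default_rng(seed)
    kT = KB_KCAL * max(temperature, 0.0)
    gamma = friction_per_ps * 1e-3  # fs^-1
    c1 = math.exp(-gamma * dt_fs)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))
    sigma_v = np.sqrt(kT * _FORCE_TO_ACC / m)  # A/fs per-coordinate thermal width
    v = np.where(mask, rng.standard_normal((n, 3)) * sigma_v, 0.0)
    if save_every is None:
        save_every = n_steps
    frames = []
    g = engine.gradient(x)
    a = -g * _FORCE_TO_ACC / m
    for step in range(1, n_steps + 1):
        v = np.where(mask, v + 0.5 * dt_fs * a, 0.0)
        x = x + np.where(mask, 0.5 * dt_fs * v, 0.0)
        v = np.where(mask, c1 * v + c2 * sigma_v * rng.standard_normal((n, 3)), 0.0)
        x = x + np.where(mask, 0.5 * dt_fs * v, 0.0)
        g = engine.gradient(x)
        a = -g * _FORCE_TO_ACC / m
        v = np.where(mask, v + 0.5 * dt_fs * a, 0.0)
        if step % save_every == 0:
            frames.append(x.copy())
        if step % 200 == 0 or step == n_steps:
            if not np.all(np.isfinite(x)):
                raise InstabilityError(f"trajectory diverged at step {step}")
    e_final = engine.energy(x)
    if not math.isfinite(e_final):
        raise InstabilityError(f"trajectory diverged at step {n_steps}")
    return np.array(frames)


def build_engine(system: ComplexSystem, eps_in: float = 1.0,
                 receptor_variant: str = "holo", **kwargs) -> ToyGBSAForceField:
    """Convenience constructor for the built-in engine over a complex.

    The engine is coordinate-free; the receptor variant only matters for which
    coordinates the caller evaluates, so this just validates the request.
    """
    if receptor_variant == "apo" and system.receptor_apo is None:
        raise DomainError("system has no apo receptor")
    return ToyGBSAForceField.from_complex(system, eps_in=eps_in, **kwargs)
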