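"""Score aggregation: Jarzynski shell free energies, comparator, scaling, ranking.

The central estimator treats each adjacent-shell transition as a quasi-static
pulling step: the work of moving the ligand between shells reduces to the
potential-energy difference between the two states, and the free-energy change
of the transition follows from the exponential work average

    dG_i = -kT ln < exp(-W_i / kT) >.

Work is accumulated in the *binding* direction (far shell -> near shell), so a
stronger binder accumulates a more negative total score.  The total score is
the sum of dG_i over all transitions of the schedule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .conformers import RSchedule
from .energy import (
    KB_KCAL,
    EnergyModel,
    ToyGBSAForceField,
    minimize_template,
)
from .errors import (
    ConfigurationError,
    DataError,
    DomainError,
    UndefinedCorrelationError,
)
from .structures import ComplexSystem

__all__ = [
    "KT_300",
    "ScoreResult",
    "shell_work_samples",
    "jarzynski_free_energy",
    "jarzynski_jackknife_se",
    "mrc_score",
    "s_mmgbsa_score",
    "linear_affinity",
    "make_affinity_table",
    "delta_delta_g",
    "pearson_r",
    "GENERALIZED_ALPHA",
]

logger = logging.getLogger(__name__)

KT_300 = KB_KCAL * 300.0  # ~0.5961 kcal/mol, the sampler temperature
GENERALIZED_ALPHA = 0.20  # generalized score -> ddG weighting factor


@dataclass
class ScoreResult:
    """Per-transition shell scores and their sum (the MRC-MMGBSA score)."""

    shell_scores: list[float]
    total_score: float
    kT: float
    epsilon_in: float
    pairing_mode: str
    n_replicates: int
    schedule: RSchedule | None = None
    shell_sems: list[float] | None = None
    direction: str = "binding"

    def __post_init__(self) -> None:
        if self.kT <= 0:
            raise DomainError("kT must be positive")


def shell_work_samples(energies: np.ndarray, transition: int,
                       pairing_mode: str = "replicate") -> np.ndarray:
    """Per-replicate work for the transition between shells i and i+1.

    In the binding direction the work along replicate j is
    W_j = U[j, i] - U[j, i+1] (near minus far).  Ensemble pairing produces a
    single downstream value inside :func:`mrc_score` instead.
    """
    U = np.asarray(energies, float)
    if U.ndim != 2 or transition < 0 or transition + 1 >= U.shape[1]:
        raise DataError("transition index outside the energy grid")
    if not np.all(np.isfinite(U[:, transition: transition + 2])):
        raise DataError(f"incomplete grid at transition {transition}")
    if pairing_mode != "replicate":
        raise DomainError("per-sample work is defined only for replicate pairing")
    return U[:, transition] - U[:, transition + 1]


def jarzynski_free_energy(work: np.ndarray, kT: float = KT_300) -> float:
    """Exponential work average, dG = -kT ln[(1/N) sum exp(-W/kT)].

    Computed through a log-sum-exp shift so |W|/kT far beyond the float
    exponent range stays finite.
    """
    w = np.asarray(work, float).ravel()
    if w.size == 0:
        raise DomainError("empty work sample list")
    if kT <= 0:
        raise DomainError("kT must be positive")
    return float(-kT * (logsumexp(-w / kT) - np.log(w.size)))


def jarzynski_jackknife_se(work: np.ndarray, kT: float = KT_300) -> float:
    """Leave-one-out jackknife standard error of the Jarzynski estimate."""
    w = np.asarray(work, float).ravel()
    n = w.size
    if n < 2:
        return float("nan")
    loo = np.empty(n)
    for k in range(n):
        loo[k] = jarzynski_free_energy(np.delete(w, k), kT)
    return float(np.sqrt((n - 1) / n * ((loo - loo.mean()) ** 2).sum()))


def _log_mean_exp(a: np.ndarray) -> float:
    return float(logsumexp(a) - np.log(len(a)))


def mrc_score(
    energies: np.ndarray,
    schedule: RSchedule,
    kT: float = KT_300,
    pairing_mode: str = "replicate",
    direction: str = "binding",
    epsilon_in: float = 1.0,
    with_sems: bool = False,
) -> ScoreResult:
    """Aggregate the U grid into per-transition shell scores and their total.

    ``pairing_mode='replicate'`` (default) pairs shell energies along snapshot
    lineage, giving one work sample per replicate and transition;
    ``'ensemble'`` uses the ratio of per-shell Boltzmann averages,
    -kT [ln <e^(-U_near/kT)> - ln <e^(-U_far/kT)>].  More negative totals mean
    stronger predicted binding.
    """
    U = np.asarray(energies, float)
    if U.ndim != 2 or U.shape[1] != len(schedule):
        raise DataError("energy grid does not match the schedule")
    if U.shape[1] < 2:
        raise DomainError("need at least 2 shells to score")
    if direction not in ("binding", "unbinding"):
        raise DomainError(f"unknown direction {direction!r}")
    n_tr = U.shape[1] - 1
    scores = []
    sems: list[float] | None = [] if (with_sems and pairing_mode == "replicate") else None
    for i in range(n_tr):
        if pairing_mode == "replicate":
            w = shell_work_samples(U, i)
            if direction == "unbinding":
                w = -w
            scores.append(jarzynski_free_energy(w, kT))
            if sems is not None:
                sems.append(jarzynski_jackknife_se(w, kT))
        elif pairing_mode == "ensemble":
            near, far = U[:, i], U[:, i + 1]
            if direction == "unbinding":
                near, far = far, near
            scores.append(float(-kT * (_log_mean_exp(-near / kT)
                                       - _log_mean_exp(-far / kT))))
        else:
            raise DomainError(f"unknown pairing_mode {pairing_mode!r}")
    return ScoreResult(
        shell_scores=scores,
        total_score=float(sum(scores)),
        kT=kT,
        epsilon_in=epsilon_in,
        pairing_mode=pairing_mode,
        n_replicates=U.shape[0],
        schedule=schedule,
        shell_sems=sems,
        direction=direction,
    )


def s_mmgbsa_score(
    system: ComplexSystem,
    eps_in: float = 1.0,
    engine_factory=None,
    minimize: bool = True,
    tol: float = 0.1,
    max_steps: int = 2000,
    **engine_kwargs,
) -> float:
    """Single-structure comparator: G_complex - G_receptor - G_ligand.

    Each term is the final energy of an independent minimization of that
    species (complex: mobile ligand against the rigid receptor; isolated
    ligand: fully mobile; isolated rigid receptor: evaluated as-is).
    """
    if engine_factory is None:
        def engine_factory(structs, rigid_groups=None):
            return ToyGBSAForceField(structs, eps_in=eps_in,
                                     rigid_groups=rigid_groups, **engine_kwargs)

    terms = {}
    n_rec = system.receptor.n_atoms
    specs = {
        "complex": ([system.receptor, system.ligand], [np.arange(n_rec)],
                    np.concatenate([np.zeros(n_rec, bool),
                                    np.ones(system.ligand.n_atoms, bool)]),
                    system.all_coords("holo")),
        "receptor": ([system.receptor], [np.arange(n_rec)],
                     np.zeros(n_rec, bool), system.receptor.coords),
        "ligand": ([system.ligand], None,
                   np.ones(system.ligand.n_atoms, bool), system.ligand.coords),
    }
    for name, (structs, rigid, movable, coords) in specs.items():
        try:
            engine = engine_factory(structs, rigid_groups=rigid)
            if minimize and movable.any():
                res = minimize_template(coords, engine, tol=tol,
                                        max_steps=max_steps, movable=movable)
                terms[name] = res.final_energy
            else:
                terms[name] = engine.energy(coords)
        except Exception as exc:
            raise type(exc)(f"S-MMGBSA {name} term failed: {exc}") from exc
    return float(terms["complex"] - terms["receptor"] - terms["ligand"])


def linear_affinity(score: float, alpha: float, beta: float) -> float:
    """Linear response map dG_calc = alpha * score + beta."""
    return alpha * score + beta


def make_affinity_table(labels, scores, dg_exp=None) -> pd.DataFrame:
    """Assemble a per-ligand table with columns ligand, score[, dg_exp]."""
    df = pd.DataFrame({"ligand": list(labels), "score": list(scores)})
    if df["ligand"].duplicated().any():
        raise DataError("ligand labels must be unique")
    if dg_exp is not None:
        df["dg_exp"] = list(dg_exp)
    return df


def delta_delta_g(table: pd.DataFrame, alpha: float = GENERALIZED_ALPHA,
                  reference: str | None = None) -> pd.DataFrame:
    """Relative binding free energies ddG_calc = alpha (score_X - score_ref).

    The reference ligand is the one with the highest dg_exp (the weakest
    binder) unless named explicitly; ties break deterministically by ligand
    label order (with a logged warning).  The reference row gets ddG_calc = 0.
    """
    if len(table) < 2:
        raise ConfigurationError("need at least 2 ligands for ddG")
    df = table.copy()
    if reference is None:
        if "dg_exp" not in df.columns:
            raise ConfigurationError(
                "no dg_exp column and no explicit reference ligand")
        top = df["dg_exp"].max()
        cands = sorted(df.loc[df["dg_exp"] == top, "ligand"])
        if len(cands) > 1:
            logger.warning(
                "tie in dg_exp among %s; using label order, reference=%s",
                cands, cands[0])
        reference = cands[0]
    if reference not in set(df["ligand"]):
        raise ConfigurationError(f"reference ligand {reference!r} not in table")
    ref_score = float(df.loc[df["ligand"] == reference, "score"].iloc[0])
    df["ddg_calc"] = alpha * (df["score"] - ref_score)
    return df


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be equal-length 1-D sequences")
    if x.size < 3:
        raise DomainError("need at least 3 points for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero variance in correlation input")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r, _ = stats.pearsonr(x, y)
    return float(r)
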