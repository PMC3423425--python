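"""Post-docking workflow: rescore pose sets, flag optimal poses, rank ligands."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError
from .scoring import pearson_r
from .structures import ComplexSystem, ligand_rmsd_after_receptor_fit

__all__ = [
    "OPTIMAL_POSE_CUTOFF",
    "PoseSet",
    "PoseScore",
    "classify_optimal_pose",
    "rescore_poses",
    "rank_ligands_by_top_pose",
    "two_stage_rank",
]

logger = logging.getLogger(__name__)

OPTIMAL_POSE_CUTOFF = 2.0  # A; a pose below this ligand RMSD is 'optimal'


@dataclass
class PoseSet:
    """A ligand's reference complex plus its docking poses (same topology)."""

    label: str
    reference: ComplexSystem
    poses: list[ComplexSystem]

    def __post_init__(self) -> None:
        if len(self.poses) < 1:
            raise DomainError("a pose set needs at least one pose")
        n = self.reference.ligand.n_atoms
        for k, p in enumerate(self.poses):
            if p.ligand.n_atoms != n:
                raise DomainError(
                    f"pose {k} ligand atom count differs from reference")


@dataclass
class PoseScore:
    pose_index: int
    score: float
    method: str
    rmsd_to_reference: float
    is_optimal: bool
    failed: bool = False


def classify_optimal_pose(rmsd: float, cutoff: float = OPTIMAL_POSE_CUTOFF) -> bool:
    """True iff the receptor-fit ligand RMSD is strictly below the cutoff."""
    if rmsd < 0:
        raise DomainError("rmsd cannot be negative")
    return rmsd < cutoff


def rescore_poses(
    pose_set: PoseSet,
    scorer,
    method: str = "smmgbsa",
    cutoff: float = OPTIMAL_POSE_CUTOFF,
) -> list[PoseScore]:
    """Score every pose with ``scorer(pose) -> kcal/mol`` and sort best-first.

    Sorting is ascending by score (more negative = better) with deterministic
    tie-break by pose index; failed poses are logged and placed last,
    excluded from ranking.
    """
    results: list[PoseScore] = []
    for k, pose in enumerate(pose_set.poses):
        rmsd = ligand_rmsd_after_receptor_fit(pose_set.reference, pose)
        try:
            score = float(scorer(pose))
            failed = False
        except Exception as exc:
            logger.warning("pose %d of %s failed scoring: %s", k, pose_set.label, exc)
            score, failed = float("nan"), True
        results.append(PoseScore(k, score, method, rmsd,
                                 classify_optimal_pose(rmsd, cutoff), failed))
    ok = sorted((p for p in results if not p.failed),
                key=lambda p: (p.score, p.pose_index))
    bad = [p for p in results if p.failed]
    return ok + bad


def rank_ligands_by_top_pose(
    pose_sets: list[PoseSet],
    scorer,
    method: str = "smmgbsa",
    affinities: dict[str, float] | None = None,
    cutoff: float = OPTIMAL_POSE_CUTOFF,
) -> tuple[pd.DataFrame, float | None]:
    """Per ligand, the top-scored pose enters the ranking table.

    Returns the table (ligand, pose, score, rmsd, is_optimal and, when
    experimental affinities are supplied, dg_exp) plus the Pearson R between
    top-pose scores and dg_exp (None with a warning below 3 ligands).
    """
    rows = []
    for ps in pose_sets:
        ranked = rescore_poses(ps, scorer, method=method, cutoff=cutoff)
        usable = [p for p in ranked if not p.failed]
        if not usable:
            logger.warning("all poses failed for ligand %s; skipped", ps.label)
            continue
        top = usable[0]
        row = {
            "ligand": ps.label,
            "pose": top.pose_index,
            "method": method,
            "score": top.score,
            "rmsd": top.rmsd_to_reference,
            "is_optimal": top.is_optimal,
        }
        if affinities and ps.label in affinities:
            row["dg_exp"] = affinities[ps.label]
        rows.append(row)
    table = pd.DataFrame(rows)
    r = None
    if affinities:
        have = table.dropna(subset=["dg_exp"]) if "dg_exp" in table else table.iloc[0:0]
        if len(have) >= 3:
            r = pearson_r(have["score"].to_numpy(), have["dg_exp"].to_numpy())
        else:
            logger.warning("fewer than 3 ligands with affinities; correlation omitted")
    return table, r


def two_stage_rank(
    pose_sets: list[PoseSet],
    stage1_scorer,
    stage2_scorer,
    affinities: dict[str, float] | None = None,
    cutoff: float = OPTIMAL_POSE_CUTOFF,
) -> tuple[pd.DataFrame, float | None]:
    """Pick each ligand's pose with a fast stage-1 scorer, rank with stage 2.

    Mirrors the screening strategy of choosing the optimal docking structure
    with the single-structure method and ranking the chosen poses with the
    ensemble method.
    """
    rows = []
    for ps in pose_sets:
        ranked = rescore_poses(ps, stage1_scorer, method="stage1", cutoff=cutoff)
        usable = [p for p in ranked if not p.failed]
        if not usable:
            logger.warning("all poses failed for ligand %s; skipped", ps.label)
            continue
        top = usable[0]
        pose = ps.poses[top.pose_index]
        score2 = float(stage2_scorer(pose))
        row = {
            "ligand": ps.label,
            "pose": top.pose_index,
            "method": "two-stage",
            "score": score2,
            "rmsd": top.rmsd_to_reference,
            "is_optimal": top.is_optimal,
        }
        if affinities and ps.label in affinities:
            row["dg_exp"] = affinities[ps.label]
        rows.append(row)
    table = pd.DataFrame(rows)
    r = None
    if affinities and "dg_exp" in table and len(table.dropna(subset=["dg_exp"])) >= 3:
        have = table.dropna(subset=["dg_exp"])
        r = pearson_r(have["score"].to_numpy(), have["dg_exp"].to_numpy())
    return table, r
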