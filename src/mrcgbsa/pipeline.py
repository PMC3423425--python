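"""High-level runs binding conformer generation, engines and scoring together."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .conformers import (
    DEFAULT_N_CONF,
    DEFAULT_N_MIN,
    BoundStateParams,
    ConformationSet,
    RSchedule,
    generate_conformation_set,
)
from .energy import ToyGBSAForceField, build_engine
from .errors import ConfigurationError
from .scoring import KT_300, ScoreResult, mrc_score, s_mmgbsa_score
from .structures import ComplexSystem

__all__ = ["RunConfig", "run_mrc", "run_smmgbsa", "score_report_rows"]


@dataclass
class RunConfig:
    """Resolved run parameters; embedded verbatim in every report."""

    engine: str = "toy"
    eps_in: float = 4.0
    schedule: str = "default"
    n_conf: int = DEFAULT_N_CONF
    n_min: int = DEFAULT_N_MIN
    seed: int = 0
    pairing_mode: str = "replicate"
    direction: str = "binding"
    orientation_mode: str = "quaternion"
    temperature: float = 300.0
    t_total_ps: float = 10.0
    gamma_sasa: float = 0.005
    n_sphere_points: int = 32
    cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.n_conf < 1 or self.n_min < 0 or self.eps_in <= 0:
            raise ConfigurationError("n_conf >= 1, n_min >= 0 and eps_in > 0 required")

    @property
    def rschedule(self) -> RSchedule:
        return RSchedule.from_string(self.schedule)

    @property
    def kT(self) -> float:
        from .energy import KB_KCAL

        return KB_KCAL * self.temperature

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["version"] = __version__
        return d


def _make_engine(system: ComplexSystem, config: RunConfig) -> ToyGBSAForceField:
    if config.engine == "toy":
        return build_engine(system, eps_in=config.eps_in,
                            gamma_sasa=config.gamma_sasa,
                            n_sphere_points=config.n_sphere_points,
                            cutoff=config.cutoff)
    if config.engine.startswith("external:"):
        import importlib

        mod = importlib.import_module(config.engine.split(":", 1)[1])
        return mod.make_engine(system, config)
    raise ConfigurationError(f"unknown engine {config.engine!r}")


def run_mrc(system: ComplexSystem, config: RunConfig, with_sems: bool = True,
            template_max_steps: int = 5000) -> tuple[ConformationSet, ScoreResult]:
    """Minimize the template, generate the grid, aggregate into an MRC score."""
    import numpy as _np

    from .energy import minimize_template

    engine = _make_engine(system, config)
    movable = _np.zeros(system.n_atoms, dtype=bool)
    movable[system.ligand_slice] = True
    tmpl = minimize_template(system.all_coords("holo"), engine, movable=movable,
                             max_steps=template_max_steps)
    system = ComplexSystem(
        system.receptor,
        system.ligand.with_coords(tmpl.final_coordinates[system.ligand_slice]),
        receptor_apo=system.receptor_apo,
        label=system.label,
    )
    cs = generate_conformation_set(
        system,
        schedule=config.rschedule,
        n_conf=config.n_conf,
        engine=engine,
        n_min=config.n_min,
        seed=config.seed,
        orientation_mode=config.orientation_mode,
        sim_params=BoundStateParams(t_total_ps=config.t_total_ps,
                                    temperature=config.temperature),
    )
    result = mrc_score(
        cs.energies, cs.schedule, kT=config.kT,
        pairing_mode=config.pairing_mode, direction=config.direction,
        epsilon_in=config.eps_in, with_sems=with_sems,
    )
    return cs, result


def run_smmgbsa(system: ComplexSystem, config: RunConfig,
                minimize: bool = True, max_steps: int = 2000) -> float:
    """Single-minimized-structure comparator score for a complex."""
    return s_mmgbsa_score(system, eps_in=config.eps_in, minimize=minimize,
                          max_steps=max_steps,
                          gamma_sasa=config.gamma_sasa,
                          n_sphere_points=config.n_sphere_points,
                          cutoff=config.cutoff)


#: relaxation depth for pose rescoring: with the 0.01 A displacement cap this
#: allows ~1.5 A of motion — enough to relax contacts, too little to re-dock a
#: displaced pose into the binding site and erase pose identity
POSE_RELAX_MAX_STEPS = 150


def pose_scorer(method: str, config: RunConfig):
    """Scoring callable for docking-pose rescoring workflows.

    The single-structure method relaxes each pose locally
    (``POSE_RELAX_MAX_STEPS`` capped-displacement steps) so that distinct
    docking poses keep distinct geometries; the ensemble method runs the full
    placement pipeline seeded from the run configuration.
    """
    def scorer(pose: ComplexSystem) -> float:
        if method == "smmgbsa":
            return run_smmgbsa(pose, config, max_steps=POSE_RELAX_MAX_STEPS)
        if method == "mrc":
            _, result = run_mrc(pose, config, with_sems=False,
                                template_max_steps=POSE_RELAX_MAX_STEPS)
            return result.total_score
        raise ConfigurationError(f"unknown pose-scoring method {method!r}")

    return scorer


def score_report_rows(label: str, result: ScoreResult) -> dict:
    """Flatten a ScoreResult into one TSV report row."""
    row = {"ligand": label}
    sched = result.schedule.distances if result.schedule else range(len(result.shell_scores) + 1)
    for i, s in enumerate(result.shell_scores):
        row[f"score_r_{sched[i]:g}_{sched[i + 1]:g}"] = s
    row["total_score"] = result.total_score
    return row


def report_json(config: RunConfig, payload: dict) -> str:
    return json.dumps({"config": config.to_dict(), **payload}, indent=2)
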