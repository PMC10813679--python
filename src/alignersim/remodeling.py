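"""Iterative remodeling loop: staged aligner updates driving tooth movement.

Per staging step the aligner's programmed shape is advanced (TCM expansion),
seated onto the current dentition by rigid best fit (wear-in), and two
equilibrium + remodeling iterations are run: each solves the quasi-static
spring system and then repositions every tooth's unloaded configuration at
its equilibrium pose, zeroing PDL strain. An optional third diagnostic
equilibrium records the residual PDL strain without remodeling, verifying
that two iterations suffice.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from . import aligner as aligner_mod
from . import mechanics
from .aligner import AlignerModel, expand_aligner_step, make_aligner, wear_in_registration
from .archframe import fit_arch_curve
from .dentition import FDI_ORDER, DentitionModel, ToothGeometry, generate_synthetic_dentition
from .errors import DiagnosticsUnavailableError, SolverError
from .mechanics import (AnchorageConfig, CoupledSystem, CouplingConstants,
                        EquilibriumState, LoadSet, PDLConstants, anchorage_loads,
                        solve_equilibrium)
from .staging import StagingPlan, build_v_pattern_plan, step_prescriptions

logger = logging.getLogger(__name__)

TRACE_COLUMNS = ["step", "fdi", "dx", "dy", "dz", "rx", "ry", "rz",
                 "gap_mm", "strain_it1", "strain_it2", "strain_it3"]


@dataclass
class SimulationTrace:
    """Per-step, per-tooth cumulative kinematics plus run metadata."""

    data: pd.DataFrame
    anchorage_group: str
    config_hash: str = ""
    seed: int = 0
    metadata: dict = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return 0 if self.data.empty else int(self.data["step"].max())

    def tooth_series(self, fdi: int) -> pd.DataFrame:
        return self.data[self.data["fdi"] == fdi].set_index("step").sort_index()

    def final_row(self, fdi: int) -> pd.Series:
        series = self.tooth_series(fdi)
        return series.iloc[-1]

    def max_third_iteration_strain(self) -> float:
        """Max diagnostic third-iteration PDL strain over the run (fraction)."""
        if self.data.empty:
            return 0.0
        col = self.data["strain_it3"]
        if col.isna().all():
            raise DiagnosticsUnavailableError(
                "third-iteration diagnostics were disabled for this run")
        return float(col.max())

    def max_gap(self) -> tuple[float, int, int]:
        """(max aligner gap mm, argmax fdi, argmax step)."""
        if self.data.empty:
            return 0.0, 0, 0
        idx = self.data["gap_mm"].idxmax()
        row = self.data.loc[idx]
        return float(row["gap_mm"]), int(row["fdi"]), int(row["step"])

    def to_csv(self, path) -> None:
        df = self.data.copy()
        df.insert(0, "config_hash", self.config_hash)
        df.insert(1, "anchorage_group", self.anchorage_group)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SimulationTrace":
        df = pd.read_csv(path)
        config_hash = str(df["config_hash"].iloc[0]) if len(df) else ""
        group = str(df["anchorage_group"].iloc[0]) if len(df) else "control"
        data = df.drop(columns=["config_hash", "anchorage_group"])
        return cls(data=data, anchorage_group=group, config_hash=config_hash)

    def summary(self) -> dict:
        gap, gap_fdi, gap_step = self.max_gap()
        out = {
            "anchorage_group": self.anchorage_group,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "n_steps": self.n_steps,
            "max_gap_mm": gap,
            "max_gap_fdi": gap_fdi,
            "max_gap_step": gap_step,
            "metadata": self.metadata,
        }
        try:
            out["max_third_iteration_strain_pct"] = 100.0 * self.max_third_iteration_strain()
        except DiagnosticsUnavailableError:
            out["max_third_iteration_strain_pct"] = None
        return out


@dataclass
class SimulationSettings:
    """Knobs of the remodeling loop itself."""

    iterations_per_step: int = 2
    third_iteration_diagnostic: bool = True
    refit_curve_each_step: bool = True


@dataclass
class SimulationState:
    """Mutable state carried across staging steps.

    ``aligner`` is the working shell: regenerated over the current dentition
    at the start of every step and then advanced by that step's programmed
    displacements, mirroring the removal/regeneration of the shell between
    steps. ``planned_aligner`` accumulates the full programmed trajectory
    from step 1 and is used only for the programmed-vs-achieved gap metric
    and the TCM deformation bookkeeping.
    """

    dentition: DentitionModel
    initial_dentition: DentitionModel
    aligner: AlignerModel
    planned_aligner: AlignerModel
    tooth_rotations: dict[int, Rotation]
    tcm: aligner_mod.TCMParams | None = None

    @classmethod
    def initial(cls, dentition: DentitionModel,
                tcm: aligner_mod.TCMParams | None = None) -> "SimulationState":
        return cls(dentition=dentition.copy(),
                   initial_dentition=dentition.copy(),
                   aligner=make_aligner(dentition, tcm),
                   planned_aligner=make_aligner(dentition, tcm),
                   tooth_rotations={f: Rotation.identity() for f in FDI_ORDER},
                   tcm=tcm)


def _apply_pose_increment(tooth: ToothGeometry, dof: np.ndarray) -> ToothGeometry:
    """Move a tooth's rest configuration by (u, theta) about its CR."""
    u, theta = dof[:3], dof[3:]
    R = Rotation.from_rotvec(theta).as_matrix()
    cr = tooth.resistance_center
    out = tooth.copy()
    for name in ("crown_point", "mesial_margin", "distal_margin", "apex"):
        p = getattr(tooth, name)
        setattr(out, name, cr + R @ (p - cr) + u)
    out.resistance_center = cr + u
    axis = R @ tooth.long_axis
    out.long_axis = axis / np.linalg.norm(axis)
    return out


def remodel_iteration(state: SimulationState, constants: PDLConstants,
                      coupling: CouplingConstants,
                      loads: LoadSet) -> EquilibriumState:
    """One equilibrium solve followed by bone-remodeling repositioning.

    Teeth are moved to their equilibrium poses (PDL strain zeroed at the new
    rest state); the aligner's programmed shape is untouched.
    """
    system = CoupledSystem(state.dentition, state.aligner, constants, coupling,
                           loads=loads)
    eq = solve_equilibrium(system)
    teeth = []
    for i, fdi in enumerate(FDI_ORDER):
        dof = eq.tooth_dofs[i]
        teeth.append(_apply_pose_increment(state.dentition.tooth(fdi), dof))
        state.tooth_rotations[fdi] = (Rotation.from_rotvec(dof[3:])
                                      * state.tooth_rotations[fdi])
    state.dentition = DentitionModel(
        teeth=teeth,
        alveolar_crest_height=state.dentition.alveolar_crest_height,
        generation_seed=state.dentition.generation_seed)
    return eq


def run_step(state: SimulationState, plan: StagingPlan, step: int,
             constants: PDLConstants, coupling: CouplingConstants,
             anchorage: AnchorageConfig,
             settings: SimulationSettings | None = None) -> list[dict]:
    """Advance one staging step; returns the trace rows for all teeth."""
    settings = settings or SimulationSettings()

    source = state.dentition if settings.refit_curve_each_step else state.initial_dentition
    curve = fit_arch_curve(source.crown_points()[:, :2])
    targets = step_prescriptions(plan, step, state.dentition, curve)

    # (1) regenerate the working shell: it seats over the current crowns,
    # carries a fraction of the residual planned-vs-achieved correction
    # (programming memory: the shell is manufactured from the planned model,
    # not the achieved one) and is advanced by this step's programmed
    # displacements through the TCM
    wear_in_registration(state.planned_aligner, state.dentition)
    working = make_aligner(state.dentition, state.tcm)
    beta = coupling.programming_memory
    for fdi, seg in working.segments.items():
        residual = (state.planned_aligner.segments[fdi].position
                    - state.dentition.tooth(fdi).crown_point)
        seg.position = seg.position + beta * residual
    for key, region in working.regions.items():
        region.cumulative_delta = state.planned_aligner.regions[key].cumulative_delta
    state.aligner = expand_aligner_step(working, targets)
    state.planned_aligner = expand_aligner_step(state.planned_aligner, targets)

    # programmed-vs-achieved lag: seat the full programmed trajectory on the
    # current dentition and measure per-tooth residuals
    wear_in_registration(state.planned_aligner, state.dentition)
    gaps = aligner_mod.aligner_gap(state.planned_aligner, state.dentition)

    loads = anchorage_loads(anchorage, state.dentition)

    strains: list[float] = []
    for it in range(settings.iterations_per_step):
        # (2) wear-in before every iteration
        wear_in_registration(state.aligner, state.dentition)
        eq = remodel_iteration(state, constants, coupling, loads)
        strains.append(eq.pdl_max_strain)
        logger.info("step %d iteration %d: %d solver iterations, max strain %.4f%%",
                    step, it + 1, eq.n_iterations, 100 * eq.pdl_max_strain)

    strain3 = np.nan
    if settings.third_iteration_diagnostic:
        wear_in_registration(state.aligner, state.dentition)
        system = CoupledSystem(state.dentition, state.aligner, constants, coupling,
                               loads=loads)
        eq3 = solve_equilibrium(system)
        strain3 = eq3.pdl_max_strain
        logger.info("step %d diagnostic: max strain %.4f%%", step, 100 * strain3)

    rows = []
    for fdi in FDI_ORDER:
        disp = (state.dentition.tooth(fdi).crown_point
                - state.initial_dentition.tooth(fdi).crown_point)
        rot = np.rad2deg(state.tooth_rotations[fdi].as_rotvec())
        rows.append({
            "step": step, "fdi": fdi,
            "dx": disp[0], "dy": disp[1], "dz": disp[2],
            "rx": rot[0], "ry": rot[1], "rz": rot[2],
            "gap_mm": gaps[fdi] if gaps else np.nan,
            "strain_it1": strains[0] if len(strains) > 0 else np.nan,
            "strain_it2": strains[1] if len(strains) > 1 else np.nan,
            "strain_it3": strain3,
        })
    return rows


def convergence_residual(trace: SimulationTrace) -> float:
    """Maximum diagnostic third-iteration PDL strain over the run, percent."""
    return 100.0 * trace.max_third_iteration_strain()


def run_simulation(dentition: DentitionModel | None = None,
                   plan: StagingPlan | None = None,
                   constants: PDLConstants | None = None,
                   coupling: CouplingConstants | None = None,
                   anchorage: AnchorageConfig | None = None,
                   tcm: aligner_mod.TCMParams | None = None,
                   settings: SimulationSettings | None = None,
                   config_hash: str = "",
                   seed: int = 0,
                   progress: bool = False) -> SimulationTrace:
    """Run the full staged simulation; deterministic for fixed inputs.

    On a solver failure the partial trace collected so far is attached to the
    raised :class:`SolverError` as ``partial_trace``.
    """
    dentition = dentition or generate_synthetic_dentition(seed=seed)
    plan = plan or build_v_pattern_plan()
    constants = constants or PDLConstants()
    coupling = coupling or CouplingConstants()
    anchorage = anchorage or AnchorageConfig()
    settings = settings or SimulationSettings()

    state = SimulationState.initial(dentition, tcm)
    rows: list[dict] = []
    for step in range(1, plan.n_steps + 1):
        try:
            rows.extend(run_step(state, plan, step, constants, coupling,
                                 anchorage, settings))
        except SolverError as exc:
            exc.partial_trace = SimulationTrace(
                data=pd.DataFrame(rows, columns=TRACE_COLUMNS),
                anchorage_group=anchorage.group, config_hash=config_hash,
                seed=seed)
            logger.error("step %d aborted: %s", step, exc)
            raise
        if progress:  # pragma: no cover - cosmetic
            print(f"\rstep {step}/{plan.n_steps}", end="", flush=True)
    if progress:  # pragma: no cover
        print()

    data = pd.DataFrame(rows, columns=TRACE_COLUMNS)
    return SimulationTrace(data=data, anchorage_group=anchorage.group,
                           config_hash=config_hash, seed=seed,
                           metadata=mechanics.run_metadata())


def write_summary(trace: SimulationTrace, path) -> None:
    with open(path, "w") as fh:
        json.dump(trace.summary(), fh, indent=2)
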