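"""Outcome measures computed from a simulation trace.

Conventions (occlusal frame): incisor retraction is the +Y (posterior)
crown-point displacement of the central incisors; intrusion is +Z (apical)
crown-point displacement; arch widths are transverse (X) distances between
mirror-pair crown points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.spatial.transform import Rotation

from .archframe import ArchCurve, distal_direction, fit_arch_curve
from .dentition import DentitionModel, ToothGeometry
from .errors import ValidationError
from .remodeling import SimulationTrace


class MovementClass(str, Enum):
    BODILY = "bodily"
    CONTROLLED_TIPPING = "controlled_tipping"
    UNCONTROLLED_TIPPING = "uncontrolled_tipping"
    ROOT_MOVEMENT = "root_movement"
    INDETERMINATE = "indeterminate"


def distalization_efficiency(achieved_mm: float, prescribed_mm: float) -> float:
    """Percent of the prescribed movement that was expressed."""
    if prescribed_mm <= 0:
        raise ValidationError("prescribed_mm must be positive")
    return 100.0 * achieved_mm / prescribed_mm


def achieved_distal_displacement(trace: SimulationTrace,
                                 initial_dentition: DentitionModel,
                                 fdi: int,
                                 curve: ArchCurve | None = None) -> float:
    """Crown-point displacement projected on the tooth's initial distal direction."""
    if curve is None:
        curve = fit_arch_curve(initial_dentition.crown_points()[:, :2])
    tooth = initial_dentition.tooth(fdi)
    tangent = distal_direction(curve, tooth)
    row = trace.final_row(fdi)
    return float(row["dx"] * tangent[0] + row["dy"] * tangent[1])


def incisor_retraction(trace: SimulationTrace, fdis: tuple[int, int] = (11, 21)) -> float:
    """Mean +Y (palatal) crown-point displacement of the central incisors, mm."""
    return float(np.mean([trace.final_row(f)["dy"] for f in fdis]))


def arch_width_change(trace: SimulationTrace, level: str) -> float:
    """Final minus initial transverse distance between mirror crown points.

    ``level`` is ``"molar"`` (first molars) or ``"premolar"`` (second
    premolars). Positive values mean expansion.
    """
    pairs = {"molar": (16, 26), "premolar": (15, 25)}
    if level not in pairs:
        raise ValidationError(f"level must be one of {sorted(pairs)}")
    right, left = pairs[level]
    # crown points are mirror pairs at baseline; width change is the change in
    # their transverse separation
    return float(trace.final_row(left)["dx"] - trace.final_row(right)["dx"])


@dataclass
class MovementClassification:
    movement: MovementClass
    rotation_center_axial: float | None      # mm along the long axis from the crown point
    rotation_center_root_fraction: float | None  # 0 at cervix, 1 at apex


def classify_movement(crown_disp: np.ndarray, rotation_deg: np.ndarray,
                      tooth: ToothGeometry,
                      rotation_threshold_deg: float = 0.1,
                      displacement_threshold_mm: float = 1e-3,
                      apex_tolerance_mm: float = 2.0) -> MovementClassification:
    """Classify a tooth's motion from its crown displacement and rotation.

    The in-plane center of rotation is located along the long axis where the
    transverse displacement vanishes; its position relative to the root span
    determines the class: inside the root (between crown and apex, short of
    the apical tolerance band) is uncontrolled tipping, at or beyond the apex
    is controlled tipping, occlusal of the crown point is root movement, and
    negligible rotation is bodily movement.
    """
    crown_disp = np.asarray(crown_disp, dtype=float)
    rotation_deg = np.asarray(rotation_deg, dtype=float)
    axis = tooth.long_axis
    disp_transverse = crown_disp - np.dot(crown_disp, axis) * axis
    rot = np.deg2rad(rotation_deg)
    rot_transverse = rot - np.dot(rot, axis) * axis
    omega = float(np.linalg.norm(rot_transverse))

    if (np.linalg.norm(crown_disp) < displacement_threshold_mm
            and np.rad2deg(omega) < rotation_threshold_deg):
        return MovementClassification(MovementClass.INDETERMINATE, None, None)
    if np.rad2deg(omega) < rotation_threshold_deg:
        return MovementClassification(MovementClass.BODILY, None, None)

    # in-plane speed at axial coordinate s (crown point at s=0, apex positive):
    # u(s) = u_crown + omega x (s * axis); the transverse component vanishes at
    # s* = |u_t| / |omega x axis| with sign from the motion reversal direction
    e_rot = rot_transverse / omega
    tangential = np.cross(e_rot, axis)  # direction of d u / d s
    denom = float(np.dot(tangential, tangential))
    s_star = -float(np.dot(disp_transverse, tangential)) / (omega * denom)

    cervix = float(np.dot(tooth.cervical_point - tooth.crown_point, axis))
    apex = float(np.dot(tooth.apex - tooth.crown_point, axis))
    root_fraction = (s_star - cervix) / (apex - cervix)

    if s_star < 0:
        movement = MovementClass.ROOT_MOVEMENT
    elif s_star >= apex - apex_tolerance_mm:
        movement = MovementClass.CONTROLLED_TIPPING
    else:
        movement = MovementClass.UNCONTROLLED_TIPPING
    return MovementClassification(movement, s_star, root_fraction)


def axis_rotation_decomposition(initial_axis: np.ndarray, final_axis: np.ndarray,
                                axial_twist_deg: float = 0.0) -> np.ndarray:
    """Rotation components (deg, right-hand rule about the frame axes) taking
    the initial long axis to the final one, with axial twist appended."""
    a = np.asarray(initial_axis, dtype=float)
    b = np.asarray(final_axis, dtype=float)
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    dot = float(np.clip(np.dot(a, b), -1.0, 1.0))
    if dot < -1.0 + 1e-12:
        raise ValidationError("antiparallel axes: rotation decomposition undefined")
    cross = np.cross(a, b)
    n = np.linalg.norm(cross)
    if n < 1e-15:
        align = Rotation.identity()
    else:
        align = Rotation.from_rotvec(cross / n * np.arccos(dot))
    twist = Rotation.from_rotvec(np.deg2rad(axial_twist_deg) * b)
    return np.rad2deg((twist * align).as_rotvec())


# ---------------------------------------------------------------------------
# report generation
# ---------------------------------------------------------------------------

def group_metrics(trace: SimulationTrace, initial_dentition: DentitionModel,
                  prescribed_posterior_mm: float = 2.0) -> dict:
    """Per-group outcome table mirroring the trace reductions."""
    curve = fit_arch_curve(initial_dentition.crown_points()[:, :2])
    gap, gap_fdi, gap_step = trace.max_gap()
    per_tooth = {}
    for tooth in initial_dentition.teeth:
        fdi = tooth.fdi_id
        row = trace.final_row(fdi)
        disp = np.array([row["dx"], row["dy"], row["dz"]])
        rot = np.array([row["rx"], row["ry"], row["rz"]])
        cls = classify_movement(disp, rot, tooth)
        per_tooth[fdi] = {
            "displacement_mm": disp.tolist(),
            "rotation_deg": rot.tolist(),
            "movement": cls.movement.value,
            "rotation_center_root_fraction": cls.rotation_center_root_fraction,
        }
    efficiencies = {}
    for fdi in (16, 26, 17, 27):
        achieved = achieved_distal_displacement(trace, initial_dentition, fdi, curve)
        efficiencies[fdi] = {
            "achieved_mm": achieved,
            "efficiency_pct": (
                distalization_efficiency(achieved, prescribed_posterior_mm)
                if prescribed_posterior_mm > 0 else None),
        }
    return {
        "config_hash": trace.config_hash,
        "anchorage_group": trace.anchorage_group,
        "incisor_retraction_mm": incisor_retraction(trace),
        "molar_efficiency": efficiencies,
        "arch_width_change_mm": {
            "molar": arch_width_change(trace, "molar"),
            "premolar": arch_width_change(trace, "premolar"),
        },
        "max_aligner_gap": {"mm": gap, "fdi": gap_fdi, "step": gap_step},
        "per_tooth": per_tooth,
    }


def write_report(metrics: dict | list[dict], json_path=None, markdown_path=None) -> str:
    """Emit metrics as JSON and/or a small Markdown comparison table."""
    entries = metrics if isinstance(metrics, list) else [metrics]
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(entries, fh, indent=2)
    lines = [
        "# Distalization outcome report",
        "",
        "Conventions: retraction = +Y (posterior) crown displacement of central "
        "incisors; intrusion = +Z (apical); widths from mirror-pair crown points.",
        "",
        "| group | incisor retraction (mm) | M1 efficiency (%) | M2 efficiency (%) "
        "| molar width change (mm) | premolar width change (mm) | max gap (mm) |",
        "|---|---|---|---|---|---|---|",
    ]
    def _mean_eff(m, fdis):
        values = [m["molar_efficiency"][f]["efficiency_pct"] for f in fdis]
        if any(v is None for v in values):
            return "n/a"
        return f"{np.mean(values):.1f}"

    for m in entries:
        m1 = _mean_eff(m, (16, 26))
        m2 = _mean_eff(m, (17, 27))
        lines.append(
            f"| {m['anchorage_group']} | {m['incisor_retraction_mm']:.2f} "
            f"| {m1} | {m2} "
            f"| {m['arch_width_change_mm']['molar']:.2f} "
            f"| {m['arch_width_change_mm']['premolar']:.2f} "
            f"| {m['max_aligner_gap']['mm']:.2f} |")
    text = "\n".join(lines) + "\n"
    if markdown_path is not None:
        with open(markdown_path, "w") as fh:
            fh.write(text)
    return text
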