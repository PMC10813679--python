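"""Segment-chain aligner with temperature-changing-method shape updating.

The aligner is reduced to one rigid segment per tooth (its programmed crown
frame) plus the interdental deformation regions. Per staging step, active
segments are displaced through the thermal-expansion bookkeeping

    U = k * (d + sum(Delta)) * t                 (preset deformation)
    (X, Y)_n = (X, Y)_{n-1} + U * e * lambda     (node update)

where ``d`` is the deformation-region width, ``Delta`` the deformation
accumulated in previous steps, ``t`` a per-step temperature change chosen so
the programmed displacement equals the staged prescription, ``e`` the demand
direction and ``lambda`` the displacement control factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .dentition import FDI_ORDER, DentitionModel
from .errors import DegenerateRegionError, RegistrationError, ValidationError

#: Aligner / attachment material moduli and contact friction from the source
#: appliance description. In this reduced-order model they are provenance
#: metadata only; the actual couplings are the calibrated spring constants in
#: :mod:`alignersim.mechanics`.
MATERIAL_METADATA = {
    "aligner_elastic_modulus_mpa": 1500.0,
    "attachment_elastic_modulus_mpa": 20000.0,
    "poisson_ratio": 0.30,
    "contact_friction_coefficient": 0.2,
}


@dataclass
class TCMParams:
    """Thermal bookkeeping constants of the shape-update formulas."""

    k: float = 0.025          # linear-expansion coefficient per degC
    lambda_: float = 1.0      # displacement control factor
    half_width: float = 1.0   # mm, deformation band half width about P_c

    def __post_init__(self) -> None:
        if self.k <= 0 or self.lambda_ <= 0 or self.half_width <= 0:
            raise ValidationError("TCM parameters must be positive")


def tcm_preset_deformation(k: float, d: float, cumulative_delta: float,
                           t: float) -> float:
    """Preset deformation U = k * (d + cumulative_delta) * t."""
    if d <= 0:
        raise ValidationError("region width d must be positive")
    if cumulative_delta < 0:
        raise ValidationError("cumulative_delta must be non-negative")
    return k * (d + cumulative_delta) * t


def tcm_node_update(coords: np.ndarray, U: float, e_vec: np.ndarray,
                    lambda_: float) -> np.ndarray:
    """Node coordinate update: coords + U * lambda * e_vec."""
    coords = np.asarray(coords, dtype=float)
    e_vec = np.asarray(e_vec, dtype=float)
    return coords + U * lambda_ * e_vec


def tcm_temperature_for(delta: float, params: TCMParams, d: float,
                        cumulative_delta: float) -> float:
    """Temperature change producing a programmed displacement ``delta``.

    Inverts the preset-deformation formula so that
    ``tcm_preset_deformation(...) * lambda == delta``.
    """
    return delta / (params.k * (d + cumulative_delta) * params.lambda_)


@dataclass
class DeformationRegion:
    """Interdental band in which the aligner is allowed to deform."""

    tooth_pair: tuple[int, int]
    c_i: np.ndarray
    c_j: np.ndarray
    p_i: np.ndarray
    p_j: np.ndarray
    half_width: float = 1.0
    cumulative_delta: float = 0.0

    def __post_init__(self) -> None:
        for name in ("c_i", "c_j", "p_i", "p_j"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.half_width <= 0:
            raise DegenerateRegionError("half_width must be positive")
        if self.cumulative_delta < 0:
            raise DegenerateRegionError("cumulative_delta must be non-negative")

    @property
    def p_c(self) -> np.ndarray:
        return (self.p_i + self.p_j) / 2.0

    @property
    def line_direction(self) -> np.ndarray:
        """Unit vector along C_i -> C_j."""
        d = self.c_j - self.c_i
        return d / np.linalg.norm(d)

    @property
    def width(self) -> float:
        """Total band width d = 2 * half_width."""
        return 2.0 * self.half_width

    def contains(self, point: np.ndarray) -> bool:
        """True if the occlusal-view point lies within the deformation band.

        The band is bounded by the two lines perpendicular to C_i-C_j at
        ``half_width`` mesial and distal of P_c.
        """
        offset = float(np.dot(np.asarray(point, float) - self.p_c, self.line_direction))
        return abs(offset) <= self.half_width


def locate_deformation_region(dentition: DentitionModel, fdi_i: int, fdi_j: int,
                              half_width: float = 1.0) -> DeformationRegion:
    """Construct the deformation region between two arch-adjacent teeth.

    Crown centers are projected to the occlusal view; the crown margin facing
    the neighbor, projected onto the C_i-C_j line, gives the boundary points
    P_i and P_j.
    """
    ia, ib = FDI_ORDER.index(fdi_i), FDI_ORDER.index(fdi_j)
    if abs(ia - ib) != 1:
        raise ValidationError(f"teeth {fdi_i} and {fdi_j} are not adjacent in the arch")
    tooth_i = dentition.tooth(fdi_i)
    tooth_j = dentition.tooth(fdi_j)
    c_i = tooth_i.crown_point[:2].copy()
    c_j = tooth_j.crown_point[:2].copy()
    gap = np.linalg.norm(c_j - c_i)
    if gap < 1e-9:
        raise DegenerateRegionError(f"crown centers of {fdi_i}/{fdi_j} coincide")
    u = (c_j - c_i) / gap

    def facing_extent(tooth, center, toward):
        extents = [float(np.dot(m[:2] - center, toward))
                   for m in (tooth.mesial_margin, tooth.distal_margin)]
        return max(extents)

    t_i = facing_extent(tooth_i, c_i, u)
    t_j = facing_extent(tooth_j, c_j, -u)
    if t_i + t_j >= gap:
        raise DegenerateRegionError(
            f"crowns of {fdi_i}/{fdi_j} overlap along the C_i-C_j line")
    p_i = c_i + t_i * u
    p_j = c_j - t_j * u
    return DeformationRegion(tooth_pair=(fdi_i, fdi_j), c_i=c_i, c_j=c_j,
                             p_i=p_i, p_j=p_j, half_width=half_width)


@dataclass
class AlignerSegment:
    """Programmed rest pose of the aligner shell over one crown."""

    tooth_fdi: int
    position: np.ndarray                  # programmed crown point, mm
    rotation: Rotation = field(default_factory=Rotation.identity)
    coupling_ref: str = "default"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValidationError("segment position must be finite")

    def copy(self) -> "AlignerSegment":
        return AlignerSegment(tooth_fdi=self.tooth_fdi,
                              position=self.position.copy(),
                              rotation=Rotation.from_quat(self.rotation.as_quat()),
                              coupling_ref=self.coupling_ref)


@dataclass
class AlignerModel:
    """Chain of per-tooth segments plus the interdental deformation regions."""

    segments: dict[int, AlignerSegment]
    regions: dict[tuple[int, int], DeformationRegion]
    tcm: TCMParams = field(default_factory=TCMParams)

    def segment(self, fdi: int) -> AlignerSegment:
        return self.segments[fdi]

    def copy(self) -> "AlignerModel":
        return AlignerModel(
            segments={f: s.copy() for f, s in self.segments.items()},
            regions={k: DeformationRegion(
                tooth_pair=r.tooth_pair, c_i=r.c_i.copy(), c_j=r.c_j.copy(),
                p_i=r.p_i.copy(), p_j=r.p_j.copy(), half_width=r.half_width,
                cumulative_delta=r.cumulative_delta) for k, r in self.regions.items()},
            tcm=self.tcm,
        )

    def positions(self) -> np.ndarray:
        return np.array([self.segments[f].position for f in FDI_ORDER])

    def state_dict(self) -> dict:
        return {
            "segments": {str(f): self.segments[f].position.tolist() for f in FDI_ORDER},
            "cumulative_delta": {f"{i}-{j}": r.cumulative_delta
                                 for (i, j), r in self.regions.items()},
        }


def make_aligner(dentition: DentitionModel, tcm: TCMParams | None = None) -> AlignerModel:
    """Aligner programmed to the current dentition (zero mismatch everywhere)."""
    tcm = tcm or TCMParams()
    segments = {t.fdi_id: AlignerSegment(tooth_fdi=t.fdi_id,
                                         position=t.crown_point.copy())
                for t in dentition.teeth}
    regions = {}
    for a, b in zip(FDI_ORDER, FDI_ORDER[1:]):
        regions[(a, b)] = locate_deformation_region(dentition, a, b,
                                                    half_width=tcm.half_width)
    return AlignerModel(segments=segments, regions=regions, tcm=tcm)


def mesial_region_key(fdi: int) -> tuple[int, int] | None:
    """Region between ``fdi`` and its mesial (toward-midline) neighbor."""
    idx = FDI_ORDER.index(fdi)
    mid = len(FDI_ORDER) // 2  # boundary between quadrants
    if idx < mid:
        neighbor = idx + 1
        if neighbor >= mid:
            return (FDI_ORDER[idx], FDI_ORDER[neighbor])
        return (FDI_ORDER[idx], FDI_ORDER[neighbor])
    neighbor = idx - 1
    return (FDI_ORDER[neighbor], FDI_ORDER[idx])


def expand_aligner_step(aligner: AlignerModel,
                        plan_targets: dict[int, np.ndarray]) -> AlignerModel:
    """Apply one staging step's programmed displacements to the aligner.

    Each active segment is moved through the TCM formulas: the temperature
    change is chosen so the preset deformation reproduces the prescribed
    displacement magnitude in the region mesial to the tooth. Region
    bookkeeping records the relative deformation between the adjoining
    segments projected on the C_i-C_j line, so inter-segment spacing is
    conserved outside active regions.
    """
    out = aligner.copy()
    params = out.tcm
    targets = {f: np.asarray(v, dtype=float) for f, v in plan_targets.items()}

    for fdi in FDI_ORDER:
        target = targets.get(fdi)
        if target is None or np.linalg.norm(target) == 0.0:
            continue
        delta = float(np.linalg.norm(target[:2]))
        e_vec = target[:2] / delta
        key = mesial_region_key(fdi)
        region = out.regions[key] if key in out.regions else None
        if region is None:  # pragma: no cover - all arch teeth have a mesial region
            raise DegenerateRegionError(f"no deformation region mesial to {fdi}")
        d = region.width
        t_change = tcm_temperature_for(delta, params, d, region.cumulative_delta)
        U = tcm_preset_deformation(params.k, d, region.cumulative_delta, t_change)
        seg = out.segments[fdi]
        new_xy = tcm_node_update(seg.position[:2], U, e_vec, params.lambda_)
        seg.position = np.array([new_xy[0], new_xy[1], seg.position[2] + target[2]])

    # region bookkeeping: magnitude of the relative displacement of the
    # adjoining segments (the deformation the region absorbed this step)
    for (i, j), region in out.regions.items():
        vi = targets.get(i, np.zeros(3))[:2]
        vj = targets.get(j, np.zeros(3))[:2]
        rel = float(np.linalg.norm(vj - vi))
        if rel > 0:
            region.cumulative_delta += rel

    return out


@dataclass
class RigidTransform:
    """Rigid pose R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation


def wear_in_registration(aligner: AlignerModel,
                         dentition: DentitionModel,
                         apply: bool = True) -> RigidTransform:
    """Least-squares rigid best fit of the aligner onto the dentition.

    Finds the rotation + translation (no scaling) minimizing the summed
    squared distance between programmed crown points and actual crown points,
    and (by default) applies it to every segment in place.
    """
    if len(aligner.segments) < 3:
        raise RegistrationError("wear-in requires at least 3 segments")
    src = aligner.positions()
    dst = dentition.crown_points()
    src_c = src - src.mean(axis=0)
    dst_c = dst - dst.mean(axis=0)
    if np.linalg.matrix_rank(src_c, tol=1e-9) < 2:
        raise RegistrationError("crown points are collinear; registration is degenerate")
    H = src_c.T @ dst_c
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = dst.mean(axis=0) - R @ src.mean(axis=0)
    transform = RigidTransform(rotation=R, translation=t)
    if apply:
        rot = Rotation.from_matrix(R)
        for seg in aligner.segments.values():
            seg.position = R @ seg.position + t
            seg.rotation = rot * seg.rotation
    return transform


def aligner_gap(aligner: AlignerModel, dentition: DentitionModel) -> dict[int, float]:
    """Per-tooth distance between programmed and achieved crown points."""
    return {fdi: float(np.linalg.norm(aligner.segments[fdi].position
                                      - dentition.tooth(fdi).crown_point))
            for fdi in FDI_ORDER}
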