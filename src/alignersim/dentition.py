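"""Parametric synthetic maxillary dentition generator.

Produces the 14-tooth upper arch (FDI 17..27) as a set of labeled landmarks:
crown points, crown margins, centers of resistance, apices and long axes.
All coordinates live in the occlusal frame used throughout the package:

* origin at the central incisors' midpoint,
* +X toward the patient's left,
* +Y posterior (distal),
* +Z apical (right-handed).

Units are millimeters. Crown points lie in the occlusal plane z = 0; roots
extend in +Z.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .errors import ValidationError

#: Arch order, right second molar -> left second molar.
FDI_ORDER: tuple[int, ...] = (17, 16, 15, 14, 13, 12, 11, 21, 22, 23, 24, 25, 26, 27)

#: Tooth-type key per FDI position digit.
TOOTH_TYPE_BY_POSITION: dict[int, str] = {
    1: "central_incisor",
    2: "lateral_incisor",
    3: "canine",
    4: "first_premolar",
    5: "second_premolar",
    6: "first_molar",
    7: "second_molar",
}

#: Default per-tooth-type dimensions (mm): mesiodistal crown width,
#: crown height, root length, cervical root radius. Representative values
#: from standard dental anatomy tables; editable via ``ArchParams.tooth_dims``.
DEFAULT_TOOTH_DIMS: dict[str, dict[str, float]] = {
    "central_incisor": {"md_width": 8.5, "crown_height": 7.5, "root_length": 13.0, "root_radius": 3.0},
    "lateral_incisor": {"md_width": 6.5, "crown_height": 7.0, "root_length": 12.5, "root_radius": 2.5},
    "canine": {"md_width": 7.5, "crown_height": 8.0, "root_length": 13.0, "root_radius": 3.2},
    "first_premolar": {"md_width": 7.0, "crown_height": 7.0, "root_length": 12.0, "root_radius": 3.0},
    "second_premolar": {"md_width": 6.8, "crown_height": 6.5, "root_length": 12.0, "root_radius": 3.0},
    "first_molar": {"md_width": 10.0, "crown_height": 6.5, "root_length": 12.0, "root_radius": 4.2},
    "second_molar": {"md_width": 9.5, "crown_height": 6.0, "root_length": 11.0, "root_radius": 4.0},
}

#: Fraction of root length from the cervical line to the center of resistance.
CR_ROOT_FRACTION = 0.4


def tooth_type(fdi: int) -> str:
    """Tooth-type key for an FDI code (upper arch only)."""
    quadrant, position = divmod(fdi, 10)
    if quadrant not in (1, 2) or position not in TOOTH_TYPE_BY_POSITION:
        raise ValidationError(f"unsupported FDI code {fdi}")
    return TOOTH_TYPE_BY_POSITION[position]


def quadrant_sign(fdi: int) -> int:
    """+1 for the patient's left quadrant (2x), -1 for the right (1x)."""
    return 1 if fdi >= 20 else -1


@dataclass
class ToothGeometry:
    """Landmark bundle for a single tooth (mm, occlusal frame)."""

    fdi_id: int
    crown_point: np.ndarray
    mesial_margin: np.ndarray
    distal_margin: np.ndarray
    resistance_center: np.ndarray
    apex: np.ndarray
    long_axis: np.ndarray
    root_length: float
    root_radius: float
    crown_height: float

    def __post_init__(self) -> None:
        for name in ("crown_point", "mesial_margin", "distal_margin",
                     "resistance_center", "apex", "long_axis"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if abs(np.linalg.norm(self.long_axis) - 1.0) > 1e-9:
            raise ValidationError(f"tooth {self.fdi_id}: long_axis must be a unit vector")
        apical = float(np.dot(self.apex - self.resistance_center, self.long_axis))
        if apical <= 0:
            raise ValidationError(f"tooth {self.fdi_id}: apex must lie apically of the CR")
        occlusal = float(np.dot(self.resistance_center - self.crown_point, self.long_axis))
        if occlusal <= 0:
            raise ValidationError(f"tooth {self.fdi_id}: crown point must lie occlusal to the CR")
        if np.allclose(self.mesial_margin, self.distal_margin):
            raise ValidationError(f"tooth {self.fdi_id}: crown margins coincide")
        if min(self.root_length, self.root_radius, self.crown_height) <= 0:
            raise ValidationError(f"tooth {self.fdi_id}: non-positive dimension")

    @property
    def cervical_point(self) -> np.ndarray:
        """Point where the root meets the crown, on the long axis."""
        return self.crown_point + self.long_axis * self.crown_height

    def copy(self) -> "ToothGeometry":
        return ToothGeometry(
            fdi_id=self.fdi_id,
            crown_point=self.crown_point.copy(),
            mesial_margin=self.mesial_margin.copy(),
            distal_margin=self.distal_margin.copy(),
            resistance_center=self.resistance_center.copy(),
            apex=self.apex.copy(),
            long_axis=self.long_axis.copy(),
            root_length=self.root_length,
            root_radius=self.root_radius,
            crown_height=self.crown_height,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ToothGeometry":
        """Return a rigidly transformed copy (x -> R x + t)."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        out = self.copy()
        for name in ("crown_point", "mesial_margin", "distal_margin",
                     "resistance_center", "apex"):
            setattr(out, name, R @ getattr(self, name) + t)
        out.long_axis = R @ self.long_axis
        return out

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ToothGeometry":
        return cls(**d)


@dataclass
class ArchParams:
    """Template-arch shape parameters.

    The crown centers are laid out by arc length along the quartic template
    ``y = c2 x^2 + c4 x^4``, so a quartic refit of the generated centers is
    well-posed by construction.
    """

    c2: float = 0.05
    c4: float = 1.5e-5
    interdental_gap: float = 0.5
    crest_height: float = 7.0
    tooth_dims: dict[str, dict[str, float]] = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_TOOTH_DIMS.items()
    })

    def __post_init__(self) -> None:
        if self.c2 <= 0 or self.c4 < 0:
            raise ValidationError("arch curvature coefficients must be positive")
        if self.interdental_gap < 0:
            raise ValidationError("interdental_gap must be non-negative")
        if self.crest_height <= 0:
            raise ValidationError("crest_height must be positive")
        for key, dims in self.tooth_dims.items():
            if key not in DEFAULT_TOOTH_DIMS:
                raise ValidationError(f"unknown tooth-type key {key!r}")
            for name, value in dims.items():
                if name not in DEFAULT_TOOTH_DIMS[key]:
                    raise ValidationError(f"unknown dimension {name!r} for {key!r}")
                if value <= 0:
                    raise ValidationError(f"{key}.{name} must be positive")


@dataclass
class DentitionModel:
    """The 14-tooth maxillary arch in the occlusal coordinate frame."""

    teeth: list[ToothGeometry]
    alveolar_crest_height: float
    generation_seed: int

    def __post_init__(self) -> None:
        codes = tuple(t.fdi_id for t in self.teeth)
        if codes != FDI_ORDER:
            raise ValidationError(f"teeth must be ordered {FDI_ORDER}, got {codes}")

    def tooth(self, fdi: int) -> ToothGeometry:
        for t in self.teeth:
            if t.fdi_id == fdi:
                return t
        raise ValidationError(f"tooth {fdi} not in dentition")

    def crown_points(self) -> np.ndarray:
        return np.array([t.crown_point for t in self.teeth])

    def copy(self) -> "DentitionModel":
        return DentitionModel(
            teeth=[t.copy() for t in self.teeth],
            alveolar_crest_height=self.alveolar_crest_height,
            generation_seed=self.generation_seed,
        )

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "alveolar_crest_height": self.alveolar_crest_height,
            "generation_seed": self.generation_seed,
            "teeth": [t.to_dict() for t in self.teeth],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DentitionModel":
        return cls(
            teeth=[ToothGeometry.from_dict(t) for t in d["teeth"]],
            alveolar_crest_height=d["alveolar_crest_height"],
            generation_seed=d["generation_seed"],
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "DentitionModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_csv(self, path) -> None:
        """Landmark table, one row per tooth."""
        cols = ["fdi_id"]
        for name in ("crown_point", "mesial_margin", "distal_margin",
                     "resistance_center", "apex", "long_axis"):
            cols += [f"{name}_{ax}" for ax in "xyz"]
        cols += ["root_length", "root_radius", "crown_height"]
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(cols)
            for t in self.teeth:
                row = [t.fdi_id]
                for name in ("crown_point", "mesial_margin", "distal_margin",
                             "resistance_center", "apex", "long_axis"):
                    row += list(getattr(t, name))
                row += [t.root_length, t.root_radius, t.crown_height]
                writer.writerow(row)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _arc_length(c2: float, c4: float, x: float) -> float:
    def speed(u: float) -> float:
        dy = 2 * c2 * u + 4 * c4 * u ** 3
        return float(np.hypot(1.0, dy))

    value, _ = quad(speed, 0.0, x, limit=200)
    return value


def _x_for_arc_length(c2: float, c4: float, s: float) -> float:
    """Solve for x >= 0 with arc length s along y = c2 x^2 + c4 x^4."""
    hi = max(s, 1.0)
    while _arc_length(c2, c4, hi) < s:
        hi *= 2.0
    return brentq(lambda x: _arc_length(c2, c4, x) - s, 0.0, hi, xtol=1e-12)


def _template_positions(params: ArchParams) -> dict[int, tuple[float, float, np.ndarray]]:
    """Per-FDI (x, y, distal tangent xy) on the template curve, incisor
    midpoint shifted to the origin."""
    half_types = [TOOTH_TYPE_BY_POSITION[p] for p in range(1, 8)]
    widths = [params.tooth_dims[tt]["md_width"] for tt in half_types]
    gap = params.interdental_gap
    # arc-length positions of crown centers from the midline contact point
    s_positions = []
    s = widths[0] / 2.0
    s_positions.append(s)
    for prev_w, w in zip(widths, widths[1:]):
        s += (prev_w + w) / 2.0 + gap
        s_positions.append(s)

    c2, c4 = params.c2, params.c4
    xs = [_x_for_arc_length(c2, c4, sp) for sp in s_positions]
    y0 = c2 * xs[0] ** 2 + c4 * xs[0] ** 4  # incisor-midpoint y offset

    out: dict[int, tuple[float, float, np.ndarray]] = {}
    for position, x in zip(range(1, 8), xs):
        y = c2 * x ** 2 + c4 * x ** 4 - y0
        dy = 2 * c2 * x + 4 * c4 * x ** 3
        for quadrant, sgn in ((1, -1), (2, 1)):
            # distal direction = away from the midline, posterior component >= 0
            tangent = np.array([sgn * 1.0, dy])
            tangent /= np.linalg.norm(tangent)
            out[quadrant * 10 + position] = (sgn * x, y, tangent)
    return out


def _build_tooth(fdi: int, center_xy: np.ndarray, distal_xy: np.ndarray,
                 long_axis: np.ndarray, dims: dict[str, float]) -> ToothGeometry:
    crown_point = np.array([center_xy[0], center_xy[1], 0.0])
    half = dims["md_width"] / 2.0
    distal3 = np.array([distal_xy[0], distal_xy[1], 0.0])
    cervical = crown_point + long_axis * dims["crown_height"]
    cr = cervical + long_axis * (CR_ROOT_FRACTION * dims["root_length"])
    apex = cervical + long_axis * dims["root_length"]
    return ToothGeometry(
        fdi_id=fdi,
        crown_point=crown_point,
        mesial_margin=crown_point - distal3 * half,
        distal_margin=crown_point + distal3 * half,
        resistance_center=cr,
        apex=apex,
        long_axis=long_axis,
        root_length=dims["root_length"],
        root_radius=dims["root_radius"],
        crown_height=dims["crown_height"],
    )


def generate_synthetic_dentition(arch_params: ArchParams | None = None,
                                 jitter_sd: float = 0.0,
                                 seed: int = 0) -> DentitionModel:
    """Generate the synthetic 14-tooth maxillary arch.

    With ``jitter_sd == 0`` the arch is exactly mirror-symmetric about the
    midsagittal plane and the crown centers lie on the quartic template.
    Positive ``jitter_sd`` perturbs each tooth's in-plane position (mm) and
    tilts its long axis (0.02 rad per mm of jitter_sd), reproducibly for a
    given ``seed``.
    """
    params = arch_params or ArchParams()
    if jitter_sd < 0:
        raise ValidationError("jitter_sd must be non-negative")

    positions = _template_positions(params)
    rng = np.random.default_rng(seed)

    teeth: list[ToothGeometry] = []
    for fdi in FDI_ORDER:
        x, y, tangent = positions[fdi]
        dims = params.tooth_dims[tooth_type(fdi)]
        center = np.array([x, y])
        axis = np.array([0.0, 0.0, 1.0])
        if jitter_sd > 0:
            center = center + rng.normal(0.0, jitter_sd, size=2)
            tilt = rng.normal(0.0, 0.02 * jitter_sd, size=2)
            axis = np.array([tilt[0], tilt[1], 1.0])
            axis /= np.linalg.norm(axis)
        teeth.append(_build_tooth(fdi, center, tangent, axis, dims))

    return DentitionModel(teeth=teeth,
                          alveolar_crest_height=params.crest_height,
                          generation_seed=seed)


def tad_position(dentition: DentitionModel, side: str, quadrant: str,
                 lateral_offset: float = 4.0,
                 height_above_crest: float = 4.0) -> np.ndarray:
    """Coordinate of a mini-screw between first and second molars.

    The point is the interradicular midpoint of the quadrant's first/second
    molar crown centers, offset ``lateral_offset`` mm buccally (outward) or
    palatally (inward) from the arch, ``height_above_crest`` mm apical to the
    alveolar crest.
    """
    if side not in ("buccal", "palatal"):
        raise ValidationError(f"side must be 'buccal' or 'palatal', got {side!r}")
    if quadrant not in ("left", "right"):
        raise ValidationError(f"quadrant must be 'left' or 'right', got {quadrant!r}")
    base = 20 if quadrant == "left" else 10
    m1 = dentition.tooth(base + 6).crown_point
    m2 = dentition.tooth(base + 7).crown_point
    mid = (m1 + m2) / 2.0
    chord = (m2 - m1)[:2]
    normal = np.array([chord[1], -chord[0]])
    normal /= np.linalg.norm(normal)
    # buccal = outward: positive projection on the lateral (away-from-midline) direction
    if normal[0] * np.sign(mid[0]) < 0:
        normal = -normal
    if side == "palatal":
        normal = -normal
    return np.array([
        mid[0] + lateral_offset * normal[0],
        mid[1] + lateral_offset * normal[1],
        dentition.alveolar_crest_height + height_above_crest,
    ])
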