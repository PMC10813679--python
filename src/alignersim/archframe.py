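"""Occlusal coordinate frame and fitted fourth-order arch curve.

The frame is built from three reference points: the crown points of the two
first molars (stand-ins for their mesio-buccal cusps in this landmark-level
model) and the midpoint of the central incisors' crown points, which becomes
the origin. X runs parallel to the inter-molar line toward the patient's
left, Y is perpendicular to X within the occlusal plane pointing posteriorly,
and Z = X x Y points apically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as npoly

from .dentition import DentitionModel, ToothGeometry, quadrant_sign
from .errors import ExtrapolationError, FitError


@dataclass
class OcclusalFrame:
    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        for name in ("x_axis", "y_axis", "z_axis"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v)
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise FitError("frame axes are not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise FitError("frame is not right-handed")

    @property
    def rotation(self) -> np.ndarray:
        """Rows are the frame axes: maps world vectors to frame components."""
        return np.vstack([self.x_axis, self.y_axis, self.z_axis])

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return (points - self.origin) @ self.rotation.T

    def from_frame(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation + self.origin


def establish_occlusal_frame(dentition: DentitionModel) -> OcclusalFrame:
    """Construct the occlusal frame from the molar and incisor reference points."""
    right_molar = dentition.tooth(16).crown_point
    left_molar = dentition.tooth(26).crown_point
    incisor_mid = (dentition.tooth(11).crown_point + dentition.tooth(21).crown_point) / 2.0

    x = left_molar - right_molar
    nx = np.linalg.norm(x)
    if nx < 1e-12:
        raise FitError("molar reference points coincide")
    x = x / nx

    posterior = (left_molar + right_molar) / 2.0 - incisor_mid
    in_plane = posterior - np.dot(posterior, x) * x
    ny = np.linalg.norm(in_plane)
    if ny < 1e-9:
        raise FitError("frame reference points are collinear")
    y = in_plane / ny
    z = np.cross(x, y)
    return OcclusalFrame(origin=incisor_mid, x_axis=x, y_axis=y, z_axis=z)


@dataclass
class ArchCurve:
    """Quartic arch form y = sum a_k x^k in the occlusal plane."""

    coefficients: np.ndarray  # a0..a4, ascending powers
    fit_rmse: float
    x_domain: tuple[float, float]

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (5,):
            raise FitError("arch curve must have exactly 5 coefficients (order 4)")
        if self.fit_rmse < 0:
            raise FitError("fit_rmse must be non-negative")

    def y(self, x: float | np.ndarray) -> float | np.ndarray:
        return npoly.polyval(x, self.coefficients)

    def dy(self, x: float | np.ndarray) -> float | np.ndarray:
        return npoly.polyval(x, npoly.polyder(self.coefficients))

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.tolist(),
            "fit_rmse": self.fit_rmse,
            "x_domain": list(self.x_domain),
        }


def fit_arch_curve(crown_centers: np.ndarray, order: int = 4) -> ArchCurve:
    """Least-squares polynomial fit of occlusal-projection crown centers.

    ``crown_centers`` is an (n, 2) array of (x, y) coordinates; n must be at
    least ``order + 1`` with distinct x values.
    """
    pts = np.asarray(crown_centers, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise FitError("crown_centers must be an (n, 2) array")
    x, y = pts[:, 0], pts[:, 1]
    if len(x) < order + 1:
        raise FitError(f"need at least {order + 1} points for an order-{order} fit")
    if len(np.unique(np.round(x, 9))) < order + 1:
        raise FitError("design matrix is rank-deficient (duplicated x values)")
    coeffs = npoly.polyfit(x, y, order)
    if order < 4:  # pad so the stored polynomial is always quartic
        coeffs = np.concatenate([coeffs, np.zeros(4 - order)])
    residuals = npoly.polyval(x, coeffs) - y
    rmse = float(np.sqrt(np.mean(residuals ** 2)))
    return ArchCurve(coefficients=coeffs, fit_rmse=rmse,
                     x_domain=(float(x.min()), float(x.max())))


def distal_direction(curve: ArchCurve, tooth: ToothGeometry,
                     sign: int | None = None,
                     domain_tolerance: float = 1.0) -> np.ndarray:
    """Unit occlusal-plane tangent of the arch at the tooth, oriented distally.

    ``sign`` is the quadrant sign (+1 left, -1 right); by default it is taken
    from the tooth's FDI code. Distal means away from the midline along the
    curve, which for this arch orientation has a posterior (+Y) component.
    """
    x = float(tooth.crown_point[0])
    lo, hi = curve.x_domain
    if not (lo - domain_tolerance <= x <= hi + domain_tolerance):
        raise ExtrapolationError(
            f"x={x:.3f} outside curve domain [{lo:.3f}, {hi:.3f}] (tol {domain_tolerance})")
    if sign is None:
        sign = quadrant_sign(tooth.fdi_id)
    slope = float(curve.dy(x))
    tangent = np.array([1.0, slope])
    tangent /= np.linalg.norm(tangent)
    if sign < 0:
        tangent = -tangent
    return tangent
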