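"""Quasi-static force system and equilibrium solver.

Each tooth is a rigid body suspended in a bilinear periodontal-ligament (PDL)
spring field sampled over an idealized paraboloid root surface; each aligner
segment is a rigid body tied to its crown by interface springs and to its
neighbors by chain springs encoding the programmed (post-TCM, post-wear-in)
rest shape. Anchorage elastics enter as point loads on the canine segments.

The total potential is convex (the bilinear PDL stiffens with strain), so the
damped Newton solve below converges to the unique equilibrium.

Degrees of freedom per body: 3 translations (mm) + 3 linearized rotations
(rad); teeth rotate about their center of resistance, segments about their
programmed crown point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aligner import AlignerModel, MATERIAL_METADATA
from .archframe import OcclusalFrame
from .dentition import DentitionModel, FDI_ORDER, ToothGeometry
from .errors import DomainError, SolverError, ValidationError

GRAMS_FORCE_TO_N = 9.80665e-3  # exact conversion, N per gram-force

N_TEETH = len(FDI_ORDER)


# ---------------------------------------------------------------------------
# PDL constitutive model
# ---------------------------------------------------------------------------

@dataclass
class PDLConstants:
    """Bilinear PDL stress-strain constants.

    Defaults are widely used bilinear PDL values (toe modulus e1, post-break
    modulus e2, branch point strain_break); the source model cites its own
    constitutive reference without printing numbers, so these are
    configuration, not reproduction.
    """

    e1: float = 0.05            # MPa, low-strain modulus
    e2: float = 0.22            # MPa, high-strain modulus
    strain_break: float = 0.075  # dimensionless branch point
    pdl_thickness: float = 0.85  # mm, effective compliance-layer thickness
    sample_count: int = 160     # spring sample points per root
    #: volumetric-confinement surrogate: a thin, nearly incompressible layer
    #: carries load far stiffer than its uniaxial modulus suggests; scales
    #: sample spring forces without changing the strain measure
    confinement_factor: float = 20.0

    def __post_init__(self) -> None:
        if self.e1 <= 0 or self.e2 <= 0:
            raise ValidationError("PDL moduli must be positive")
        if not 0 < self.strain_break < 1:
            raise ValidationError("strain_break must be in (0, 1)")
        if self.pdl_thickness <= 0:
            raise ValidationError("pdl_thickness must be positive")
        if self.sample_count < 8:
            raise ValidationError("sample_count must be at least 8")
        if self.confinement_factor <= 0:
            raise ValidationError("confinement_factor must be positive")


def _bilinear_stress_raw(eps_abs: np.ndarray, constants: PDLConstants) -> np.ndarray:
    """Bilinear stress magnitude without the |strain| < 1 domain check."""
    e1, e2, eb = constants.e1, constants.e2, constants.strain_break
    return np.where(eps_abs <= eb, e1 * eps_abs, e1 * eb + e2 * (eps_abs - eb))


def pdl_bilinear_stress(strain, constants: PDLConstants):
    """Odd bilinear stress-strain law, continuous at +-strain_break.

    Accepts scalars or arrays; strains at or beyond |1| are outside the model.
    """
    eps = np.asarray(strain, dtype=float)
    if np.any(np.abs(eps) >= 1.0):
        raise DomainError("PDL strain magnitude must be below 1")
    out = np.sign(eps) * _bilinear_stress_raw(np.abs(eps), constants)
    return float(out) if np.isscalar(strain) else out


def pdl_strain_energy_density(strain, constants: PDLConstants):
    """Integral of the bilinear law from 0 to |strain| (MPa = N*mm/mm^3)."""
    eps = np.abs(np.asarray(strain, dtype=float))
    e1, e2, eb = constants.e1, constants.e2, constants.strain_break
    low = 0.5 * e1 * eps ** 2
    high = 0.5 * e1 * eb ** 2 + e1 * eb * (eps - eb) + 0.5 * e2 * (eps - eb) ** 2
    out = np.where(eps <= eb, low, high)
    return float(out) if np.isscalar(strain) else out


# ---------------------------------------------------------------------------
# root sampling and tooth stiffness
# ---------------------------------------------------------------------------

def root_surface_samples(tooth: ToothGeometry, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Sample points and tributary areas on an idealized paraboloid root.

    The root surface has radius ``r(z) = root_radius * sqrt(1 - z/L)`` from
    the cervical line (z = 0) to the apex (z = L), swept about the long axis.
    Returns (points (n,3) world coords, areas (n,)).
    """
    if tooth.root_length <= 0 or tooth.root_radius <= 0:
        raise ValidationError(f"tooth {tooth.fdi_id}: degenerate root dimensions")
    n_rings = max(4, int(round(np.sqrt(n / 4))))
    n_phi = max(4, n // n_rings)
    L, r0 = tooth.root_length, tooth.root_radius

    # orthonormal basis about the long axis
    axis = tooth.long_axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, axis)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)

    zs = (np.arange(n_rings) + 0.5) / n_rings * L
    dz = L / n_rings
    radii = r0 * np.sqrt(1.0 - zs / L)
    drdz = -r0 / (2.0 * np.sqrt(L * (L - zs)))
    ring_area = 2.0 * np.pi * radii * np.sqrt(1.0 + drdz ** 2) * dz

    phis = (np.arange(n_phi) + 0.5) / n_phi * 2.0 * np.pi
    cos_p, sin_p = np.cos(phis), np.sin(phis)

    cervical = tooth.cervical_point
    points = []
    areas = []
    for z, r, a_ring in zip(zs, radii, ring_area):
        ring = (cervical[None, :] + z * axis[None, :]
                + r * (cos_p[:, None] * e1[None, :] + sin_p[:, None] * e2[None, :]))
        points.append(ring)
        areas.append(np.full(n_phi, a_ring / n_phi))
    return np.vstack(points), np.concatenate(areas)


def _sample_kinematics(points: np.ndarray, center: np.ndarray) -> np.ndarray:
    """B matrices (n, 3, 6) mapping body DOFs (u, theta) to point displacement."""
    r = points - center
    n = len(points)
    B = np.zeros((n, 3, 6))
    B[:, :, :3] = np.eye(3)
    # -skew(r): theta x r
    B[:, 0, 4] = r[:, 2]
    B[:, 0, 5] = -r[:, 1]
    B[:, 1, 3] = -r[:, 2]
    B[:, 1, 5] = r[:, 0]
    B[:, 2, 3] = r[:, 1]
    B[:, 2, 4] = -r[:, 0]
    return B


class ToothPDL:
    """Per-tooth PDL spring field with force, energy and tangent stiffness."""

    def __init__(self, tooth: ToothGeometry, constants: PDLConstants):
        self.tooth = tooth
        self.constants = constants
        self.points, self.areas = root_surface_samples(tooth, constants.sample_count)
        # load-bearing weights: tributary area times the confinement surrogate
        self.weights = self.areas * constants.confinement_factor
        self.B = _sample_kinematics(self.points, tooth.resistance_center)

    def point_displacements(self, dof: np.ndarray) -> np.ndarray:
        return np.einsum("nij,j->ni", self.B, dof)

    def strains(self, dof: np.ndarray) -> np.ndarray:
        """Per-sample strain magnitudes |u_point| / thickness."""
        u = self.point_displacements(dof)
        return np.linalg.norm(u, axis=1) / self.constants.pdl_thickness

    def force(self, dof: np.ndarray) -> np.ndarray:
        """Generalized restoring force (6,) conjugate to the DOFs (sign: internal)."""
        c = self.constants
        u = self.point_displacements(dof)
        mag = np.linalg.norm(u, axis=1)
        eps = mag / c.pdl_thickness
        stress = _bilinear_stress_raw(eps, c)
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(mag > 0, stress * self.weights / np.maximum(mag, 1e-300), 0.0)
        f_points = scale[:, None] * u
        return np.einsum("nij,ni->j", self.B, f_points)

    def energy(self, dof: np.ndarray) -> float:
        c = self.constants
        eps = self.strains(dof)
        density = pdl_strain_energy_density(eps, c)
        # energy per sample = density * weighted tributary volume
        return float(np.sum(density * self.weights * c.pdl_thickness))

    def tangent(self, dof: np.ndarray) -> np.ndarray:
        """6x6 tangent stiffness at the current pose."""
        c = self.constants
        u = self.point_displacements(dof)
        mag = np.linalg.norm(u, axis=1)
        eps = mag / c.pdl_thickness
        eb = c.strain_break
        secant = np.where(eps <= eb, c.e1,
                          _bilinear_stress_raw(eps, c) / np.maximum(eps, 1e-300))
        tangent_mod = np.where(eps <= eb, c.e1, c.e2)
        k_iso = secant * self.weights / c.pdl_thickness          # (n,)
        k_dir = (tangent_mod - secant) * self.weights / c.pdl_thickness
        with np.errstate(invalid="ignore", divide="ignore"):
            n_hat = np.where(mag[:, None] > 0, u / np.maximum(mag, 1e-300)[:, None], 0.0)
        # k_point = k_iso I + k_dir n n^T per sample
        K = np.einsum("n,nia,nib->ab", k_iso, self.B, self.B)
        Bn = np.einsum("nia,ni->na", self.B, n_hat)
        K += np.einsum("n,na,nb->ab", k_dir, Bn, Bn)
        return K


def assemble_tooth_stiffness(tooth: ToothGeometry, constants: PDLConstants,
                             dof: np.ndarray | None = None) -> np.ndarray:
    """6x6 generalized PDL stiffness about the CR at the given pose increment."""
    pdl = ToothPDL(tooth, constants)
    if dof is None:
        dof = np.zeros(6)
    return pdl.tangent(np.asarray(dof, dtype=float))


# ---------------------------------------------------------------------------
# anchorage loads
# ---------------------------------------------------------------------------

@dataclass
class AnchorageConfig:
    """Anchorage reinforcement group and its load geometry."""

    group: str = "control"
    force_gf: float = 150.0
    elastic_angle_deg: float = 15.0
    tad_lateral_offset: float = 4.0
    tad_height_above_crest: float = 4.0
    cut_lateral_offset: float = 3.0
    cut_mesial_fraction: float = 0.25

    GROUPS = ("control", "class2_elastic", "buccal_tad", "palatal_tad")

    def __post_init__(self) -> None:
        if self.group not in self.GROUPS:
            raise ValidationError(f"unknown anchorage group {self.group!r}")
        if self.force_gf < 0:
            raise ValidationError("force_gf must be non-negative")


@dataclass
class Load:
    """Point force on an aligner segment."""

    fdi: int
    point: np.ndarray
    force: np.ndarray


@dataclass
class LoadSet:
    loads: list[Load] = field(default_factory=list)

    def total_force(self) -> np.ndarray:
        if not self.loads:
            return np.zeros(3)
        return np.sum([l.force for l in self.loads], axis=0)


def precision_cut_point(dentition: DentitionModel, quadrant: str, side: str,
                        config: AnchorageConfig) -> np.ndarray:
    """Elastic attachment point at the mesial cervical region of the canine."""
    base = 20 if quadrant == "left" else 10
    canine = dentition.tooth(base + 3)
    mesial_dir = canine.mesial_margin - canine.crown_point
    mesial_dir = mesial_dir / np.linalg.norm(mesial_dir)
    point = canine.crown_point + mesial_dir * (config.cut_mesial_fraction
                                               * 2 * np.linalg.norm(canine.mesial_margin
                                                                    - canine.crown_point))
    normal = np.array([-mesial_dir[1], mesial_dir[0], 0.0])
    if normal[0] * np.sign(canine.crown_point[0]) < 0:
        normal = -normal  # buccal = outward
    if side == "lingual":
        normal = -normal
    point = point + normal * config.cut_lateral_offset
    # cervical region: near the crown/root junction
    point[2] = 0.8 * canine.crown_height
    return point


def _class2_direction(dentition: DentitionModel, quadrant: str,
                      angle_deg: float) -> np.ndarray:
    """Distal direction along the arch at the canine, depressed below the
    occlusal plane by ``angle_deg`` (the elastic runs along the buccal
    corridor toward the opposing molar)."""
    base = 20 if quadrant == "left" else 10
    canine = dentition.tooth(base + 3)
    molar = dentition.tooth(base + 6)
    horiz = (molar.crown_point - canine.crown_point)[:2]
    horiz = horiz / np.linalg.norm(horiz)
    a = np.deg2rad(angle_deg)
    return np.array([horiz[0] * np.cos(a), horiz[1] * np.cos(a), -np.sin(a)])


def anchorage_loads(config: AnchorageConfig, dentition: DentitionModel,
                    frame: OcclusalFrame | None = None) -> LoadSet:
    """Resolve the anchorage group into point loads on the canine segments.

    The control group carries no load. All test groups apply
    ``force_gf * 9.80665 mN`` per quadrant at the canine precision-cut point:
    Class II elastics pull distally ``elastic_angle_deg`` below the occlusal
    plane; TAD groups pull toward the respective mini-screw position.
    """
    from .dentition import tad_position  # local import to avoid cycle at module load

    if config.group == "control" or config.force_gf == 0:
        return LoadSet([])
    magnitude = config.force_gf * GRAMS_FORCE_TO_N
    loads: list[Load] = []
    for quadrant in ("right", "left"):
        base = 20 if quadrant == "left" else 10
        if config.group == "class2_elastic":
            cut = precision_cut_point(dentition, quadrant, "buccal", config)
            direction = _class2_direction(dentition, quadrant, config.elastic_angle_deg)
        elif config.group == "buccal_tad":
            cut = precision_cut_point(dentition, quadrant, "buccal", config)
            tad = tad_position(dentition, "buccal", quadrant,
                               config.tad_lateral_offset, config.tad_height_above_crest)
            direction = (tad - cut) / np.linalg.norm(tad - cut)
        else:  # palatal_tad
            cut = precision_cut_point(dentition, quadrant, "lingual", config)
            tad = tad_position(dentition, "palatal", quadrant,
                               config.tad_lateral_offset, config.tad_height_above_crest)
            direction = (tad - cut) / np.linalg.norm(tad - cut)
        loads.append(Load(fdi=base + 3, point=cut, force=magnitude * direction))
    return LoadSet(loads)


# ---------------------------------------------------------------------------
# coupled aligner-dentition system
# ---------------------------------------------------------------------------

@dataclass
class CouplingConstants:
    """Aligner-tooth interface and inter-segment chain spring constants.

    Calibrated defaults (see scripts/calibrate.py): chosen so that the
    control-group whole-run molar distalization efficiency falls in the
    0.25-0.55 band and the residual third-iteration PDL strain stays below
    0.1%. The shell/attachment moduli of the source appliance are carried as
    metadata in :data:`alignersim.aligner.MATERIAL_METADATA`.
    """

    k_interface: float = 8000.0        # N/mm, segment-crown translation
    k_interface_rot: float = 50.0      # N*mm/rad, segment-crown rotation
    k_chain: float = 60000.0           # N/mm, inter-segment translation
    k_chain_rot: float = 2.0e6         # N*mm/rad, inter-segment rotation (shell bending)
    attachment_rot_multiplier: float = 10.0
    attachment_teeth: tuple[int, ...] = (17, 16, 15, 14, 13, 23, 24, 25, 26, 27)
    #: fraction of the residual planned-vs-achieved correction the freshly
    #: seated shell carries per step, in addition to the step's new target
    programming_memory: float = 0.0

    def __post_init__(self) -> None:
        if min(self.k_interface, self.k_interface_rot,
               self.k_chain, self.k_chain_rot) <= 0:
            raise ValidationError("coupling stiffnesses must be positive")
        if self.attachment_rot_multiplier <= 0:
            raise ValidationError("attachment_rot_multiplier must be positive")
        if not 0.0 <= self.programming_memory <= 1.0:
            raise ValidationError("programming_memory must be in [0, 1]")


@dataclass
class EquilibriumState:
    """Result of one quasi-static solve."""

    tooth_dofs: np.ndarray      # (14, 6) translation mm + rotation rad about CR
    segment_dofs: np.ndarray    # (14, 6) about programmed crown point
    residual_norm: float
    pdl_max_strain: float
    energy: float
    n_iterations: int

    def tooth_dof(self, fdi: int) -> np.ndarray:
        return self.tooth_dofs[FDI_ORDER.index(fdi)]


class CoupledSystem:
    """Assembled tooth + aligner-segment spring system for one solve.

    DOF layout: 14 teeth x 6 then 14 segments x 6 (order of FDI_ORDER).
    """

    def __init__(self, dentition: DentitionModel, aligner: AlignerModel,
                 constants: PDLConstants, coupling: CouplingConstants,
                 loads: LoadSet | None = None,
                 fixed_segments: bool = False):
        self.dentition = dentition
        self.aligner = aligner
        self.coupling = coupling
        self.fixed_segments = fixed_segments
        self.pdls = [ToothPDL(t, constants) for t in dentition.teeth]
        self.ndof = 12 * N_TEETH

        K = np.zeros((self.ndof, self.ndof))
        c0 = np.zeros(self.ndof)  # constant gradient terms from rest mismatch
        f_ext = np.zeros(self.ndof)
        self._e0 = 0.0            # constant part of coupling energy

        # interface springs: tooth crown point <-> segment crown point
        for i, fdi in enumerate(FDI_ORDER):
            tooth = dentition.tooth(fdi)
            seg = aligner.segments[fdi]
            ti = 6 * i
            si = 6 * (N_TEETH + i)
            k = coupling.k_interface
            k_rot = coupling.k_interface_rot
            if fdi in coupling.attachment_teeth:
                k_rot *= coupling.attachment_rot_multiplier
            g0 = seg.position - tooth.crown_point  # programmed-minus-achieved gap
            r = tooth.crown_point - tooth.resistance_center
            Bt = np.zeros((3, 6))
            Bt[:, :3] = np.eye(3)
            Bt[0, 4], Bt[0, 5] = r[2], -r[1]
            Bt[1, 3], Bt[1, 5] = -r[2], r[0]
            Bt[2, 3], Bt[2, 4] = r[1], -r[0]
            Bs = np.zeros((3, 6))
            Bs[:, :3] = np.eye(3)
            # energy = 1/2 k |Bs xs - Bt xt + g0|^2
            K[si:si + 6, si:si + 6] += k * Bs.T @ Bs
            K[ti:ti + 6, ti:ti + 6] += k * Bt.T @ Bt
            K[si:si + 6, ti:ti + 6] += -k * Bs.T @ Bt
            K[ti:ti + 6, si:si + 6] += -k * Bt.T @ Bs
            c0[si:si + 6] += k * Bs.T @ g0
            c0[ti:ti + 6] += -k * Bt.T @ g0
            self._e0 += 0.5 * k * float(g0 @ g0)

            # rotational coupling acts on the rotation increment within this
            # solve only: the regenerated shell seats over the tipped crowns,
            # so accumulated tip carries no memory torque
            Ir = np.eye(3)
            K[si + 3:si + 6, si + 3:si + 6] += k_rot * Ir
            K[ti + 3:ti + 6, ti + 3:ti + 6] += k_rot * Ir
            K[si + 3:si + 6, ti + 3:ti + 6] += -k_rot * Ir
            K[ti + 3:ti + 6, si + 3:si + 6] += -k_rot * Ir

        # chain springs between adjacent segments (rest = programmed shape)
        for a, b in zip(range(N_TEETH), range(1, N_TEETH)):
            fa, fb = FDI_ORDER[a], FDI_ORDER[b]
            pa = aligner.segments[fa].position
            pb = aligner.segments[fb].position
            mid = (pa + pb) / 2.0
            ia = 6 * (N_TEETH + a)
            ib = 6 * (N_TEETH + b)
            k = coupling.k_chain
            k_rot = coupling.k_chain_rot

            def point_map(ref: np.ndarray) -> np.ndarray:
                r = mid - ref
                B = np.zeros((3, 6))
                B[:, :3] = np.eye(3)
                B[0, 4], B[0, 5] = r[2], -r[1]
                B[1, 3], B[1, 5] = -r[2], r[0]
                B[2, 3], B[2, 4] = r[1], -r[0]
                return B

            Ba, Bb = point_map(pa), point_map(pb)
            K[ia:ia + 6, ia:ia + 6] += k * Ba.T @ Ba
            K[ib:ib + 6, ib:ib + 6] += k * Bb.T @ Bb
            K[ia:ia + 6, ib:ib + 6] += -k * Ba.T @ Bb
            K[ib:ib + 6, ia:ia + 6] += -k * Bb.T @ Ba
            Ir = np.eye(3)
            K[ia + 3:ia + 6, ia + 3:ia + 6] += k_rot * Ir
            K[ib + 3:ib + 6, ib + 3:ib + 6] += k_rot * Ir
            K[ia + 3:ia + 6, ib + 3:ib + 6] += -k_rot * Ir
            K[ib + 3:ib + 6, ia + 3:ia + 6] += -k_rot * Ir

        # external loads on segments
        if loads is not None:
            for load in loads.loads:
                i = FDI_ORDER.index(load.fdi)
                si = 6 * (N_TEETH + i)
                ref = aligner.segments[load.fdi].position
                r = load.point - ref
                f_ext[si:si + 3] += load.force
                f_ext[si + 3:si + 6] += np.cross(r, load.force)

        self.K_lin = K
        self.c0 = c0
        self.f_ext = f_ext

    # -- split helpers ----------------------------------------------------

    def tooth_slice(self, i: int) -> slice:
        return slice(6 * i, 6 * i + 6)

    def _pdl_force(self, x: np.ndarray) -> np.ndarray:
        out = np.zeros(self.ndof)
        for i, pdl in enumerate(self.pdls):
            out[self.tooth_slice(i)] = pdl.force(x[self.tooth_slice(i)])
        return out

    def gradient(self, x: np.ndarray) -> np.ndarray:
        g = self.K_lin @ x + self.c0 - self.f_ext + self._pdl_force(x)
        if self.fixed_segments:
            g[6 * N_TEETH:] = 0.0
        return g

    def energy(self, x: np.ndarray) -> float:
        e = 0.5 * float(x @ self.K_lin @ x) + float(self.c0 @ x) + self._e0 \
            - float(self.f_ext @ x)
        for i, pdl in enumerate(self.pdls):
            e += pdl.energy(x[self.tooth_slice(i)])
        return e

    def tangent(self, x: np.ndarray) -> np.ndarray:
        K = self.K_lin.copy()
        for i, pdl in enumerate(self.pdls):
            s = self.tooth_slice(i)
            K[s, s] += pdl.tangent(x[s])
        if self.fixed_segments:
            seg = slice(6 * N_TEETH, self.ndof)
            K[seg, :] = 0.0
            K[:, seg] = 0.0
            K[seg, seg] = np.eye(6 * N_TEETH)
        return K

    def max_strain(self, x: np.ndarray) -> float:
        return max(float(pdl.strains(x[self.tooth_slice(i)]).max())
                   for i, pdl in enumerate(self.pdls))


def solve_equilibrium(system: CoupledSystem,
                      tol: float = 1e-9,
                      max_iterations: int = 60) -> EquilibriumState:
    """Damped Newton solve of the piecewise-linear static system.

    The energy is convex, so Newton steps with backtracking on the total
    potential converge monotonically; ``tol`` bounds the residual inf-norm in
    N (and N*mm for moments).
    """
    x = np.zeros(system.ndof)
    energy = system.energy(x)
    n_iter = 0
    for n_iter in range(1, max_iterations + 1):
        g = system.gradient(x)
        res = float(np.abs(g).max())
        if res < tol:
            break
        K = system.tangent(x)
        try:
            dx = np.linalg.solve(K, -g)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise SolverError(f"singular tangent stiffness: {exc}") from exc
        # backtracking line search on the convex potential
        alpha = 1.0
        for _ in range(40):
            trial = x + alpha * dx
            try:
                e_trial = system.energy(trial)
            except DomainError:
                alpha *= 0.5
                continue
            if e_trial <= energy + 1e-12 * max(1.0, abs(energy)):
                break
            alpha *= 0.5
        else:  # pragma: no cover
            raise SolverError("line search failed to reduce energy")
        x = x + alpha * dx
        energy = system.energy(x)
    else:
        g = system.gradient(x)
        res = float(np.abs(g).max())
        if res >= tol:
            raise SolverError(
                f"equilibrium did not converge: residual {res:.3e} after "
                f"{max_iterations} iterations")
    return EquilibriumState(
        tooth_dofs=x[:6 * N_TEETH].reshape(N_TEETH, 6),
        segment_dofs=x[6 * N_TEETH:].reshape(N_TEETH, 6),
        residual_norm=float(np.abs(system.gradient(x)).max()),
        pdl_max_strain=system.max_strain(x),
        energy=energy,
        n_iterations=n_iter,
    )


def run_metadata() -> dict:
    """Provenance metadata echoed into run summaries."""
    return dict(MATERIAL_METADATA)
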