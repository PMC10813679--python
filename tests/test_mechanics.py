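import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alignersim.aligner import make_aligner
from alignersim.archframe import establish_occlusal_frame
from alignersim.dentition import FDI_ORDER
from alignersim.errors import DomainError, ValidationError
from alignersim.mechanics import (GRAMS_FORCE_TO_N, AnchorageConfig,
                                  CoupledSystem, CouplingConstants,
                                  PDLConstants, ToothPDL, anchorage_loads,
                                  assemble_tooth_stiffness, pdl_bilinear_stress,
                                  pdl_strain_energy_density, root_surface_samples,
                                  solve_equilibrium)

C = PDLConstants()


class TestBilinearStress:
    def test_origin(self):
        assert pdl_bilinear_stress(0.0, C) == 0.0

    def test_continuity_at_branch_point(self):
        eb = C.strain_break
        low = C.e1 * eb
        high = C.e1 * eb + C.e2 * (eb - eb)
        assert low == high == pdl_bilinear_stress(eb, C)

    def test_hand_evaluated_value(self):
        # defaults e1=0.05, eps12=0.075, e2=0.22 at eps=0.15
        expected = 0.05 * 0.075 + 0.22 * 0.075
        assert pdl_bilinear_stress(0.15, C) == pytest.approx(0.02025, abs=1e-12)
        assert pdl_bilinear_stress(0.15, C) == pytest.approx(expected, abs=1e-12)

    def test_odd_function(self):
        for eps in (0.01, 0.075, 0.3, 0.9):
            assert pdl_bilinear_stress(-eps, C) == -pdl_bilinear_stress(eps, C)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            pdl_bilinear_stress(1.0, C)
        with pytest.raises(DomainError):
            pdl_bilinear_stress(np.array([0.1, -1.2]), C)

    @settings(max_examples=200, deadline=None)
    @given(eps=st.floats(min_value=-0.999, max_value=0.999, allow_nan=False))
    def test_matches_independent_expression(self, eps):
        a = abs(eps)
        expected = (C.e1 * a if a <= C.strain_break
                    else C.e1 * C.strain_break + C.e2 * (a - C.strain_break))
        assert pdl_bilinear_stress(eps, C) == np.sign(eps) * expected

    def test_energy_density_is_integral(self):
        # numerical-integration oracle
        for eps in (0.04, 0.075, 0.3):
            grid = np.linspace(0, eps, 20001)
            integral = np.trapezoid(pdl_bilinear_stress(grid, C), grid)
            assert pdl_strain_energy_density(eps, C) == pytest.approx(integral, rel=1e-6)

    def test_constant_validation(self):
        with pytest.raises(ValidationError):
            PDLConstants(e1=0.0)
        with pytest.raises(ValidationError):
            PDLConstants(strain_break=1.5)
        with pytest.raises(ValidationError):
            PDLConstants(sample_count=4)


class TestToothStiffness:
    def test_linearity_in_modulus(self, dentition):
        tooth = dentition.tooth(16)
        k1 = assemble_tooth_stiffness(tooth, PDLConstants())
        k2 = assemble_tooth_stiffness(tooth, PDLConstants(e1=0.10))
        assert np.allclose(k2, 2.0 * k1, rtol=1e-9)

    def test_symmetry(self, dentition):
        for fdi in (17, 13, 11):
            K = assemble_tooth_stiffness(dentition.tooth(fdi), C)
            assert np.allclose(K, K.T, rtol=1e-9, atol=1e-12)

    def test_positive_definite_in_linear_branch(self, dentition):
        K = assemble_tooth_stiffness(dentition.tooth(14), C)
        assert np.all(np.linalg.eigvalsh(K) > 0)

    def test_brute_force_spring_sum_oracle(self, dentition):
        # independent sample-spring summation for a transverse unit force at CR
        tooth = dentition.tooth(15)
        pdl = ToothPDL(tooth, C)
        dof = np.array([0.004, -0.002, 0.001, 0.0008, -0.0005, 0.0003])
        force = pdl.force(dof)
        expected = np.zeros(6)
        for p, w in zip(pdl.points, pdl.areas * C.confinement_factor):
            r = p - tooth.resistance_center
            u = dof[:3] + np.cross(dof[3:], r)
            eps = np.linalg.norm(u) / C.pdl_thickness
            if eps == 0:
                continue
            sigma = (C.e1 * eps if eps <= C.strain_break
                     else C.e1 * C.strain_break + C.e2 * (eps - C.strain_break))
            f = w * sigma * u / np.linalg.norm(u)
            expected[:3] += f
            expected[3:] += np.cross(r, f)
        assert np.allclose(force, expected, rtol=1e-9, atol=1e-12)

    def test_root_sampling_area(self, dentition):
        # sampled tributary areas approximate the analytic paraboloid area
        tooth = dentition.tooth(11)
        pts, areas = root_surface_samples(tooth, 4000)
        L, r0 = tooth.root_length, tooth.root_radius
        from scipy.integrate import quad
        analytic, _ = quad(
            lambda z: 2 * np.pi * r0 * np.sqrt(1 - z / L)
            * np.sqrt(1 + r0 ** 2 / (4 * L * (L - z))), 0, L)
        assert areas.sum() == pytest.approx(analytic, rel=2e-2)


class TestAnchorageLoads:
    def test_control_zero(self, dentition):
        loads = anchorage_loads(AnchorageConfig(group="control"), dentition)
        assert loads.loads == []
        assert np.allclose(loads.total_force(), 0.0)

    def test_force_magnitude_150gf(self, dentition):
        for group in ("class2_elastic", "buccal_tad", "palatal_tad"):
            loads = anchorage_loads(AnchorageConfig(group=group), dentition)
            assert len(loads.loads) == 2  # both quadrants
            for load in loads.loads:
                assert np.linalg.norm(load.force) == pytest.approx(
                    150.0 * GRAMS_FORCE_TO_N, abs=1e-12)
                assert np.linalg.norm(load.force) == pytest.approx(1.47100, abs=1e-4)

    def test_class2_angle_below_occlusal_plane(self, dentition):
        loads = anchorage_loads(AnchorageConfig(group="class2_elastic"), dentition)
        frame = establish_occlusal_frame(dentition)
        for load in loads.loads:
            f = load.force / np.linalg.norm(load.force)
            below = -np.dot(f, frame.z_axis)
            assert np.degrees(np.arcsin(below)) == pytest.approx(15.0, abs=1e-9)

    def test_tad_force_points_at_tad(self, dentition):
        from alignersim.dentition import tad_position
        cfg = AnchorageConfig(group="palatal_tad")
        loads = anchorage_loads(cfg, dentition)
        left = [l for l in loads.loads if l.fdi == 23][0]
        tad = tad_position(dentition, "palatal", "left")
        expected = (tad - left.point) / np.linalg.norm(tad - left.point)
        assert np.allclose(left.force / np.linalg.norm(left.force), expected,
                           atol=1e-12)

    def test_sagittal_component_ordering(self, dentition):
        ys = {}
        for group in ("class2_elastic", "buccal_tad", "palatal_tad"):
            loads = anchorage_loads(AnchorageConfig(group=group), dentition)
            f = loads.loads[0].force
            ys[group] = f[1] / np.linalg.norm(f)
        assert ys["palatal_tad"] > ys["buccal_tad"] > ys["class2_elastic"]

    def test_unknown_group(self):
        with pytest.raises(ValidationError):
            AnchorageConfig(group="headgear")


class TestCoupledSystem:
    def test_rest_state_zero_forces(self, dentition):
        aligner = make_aligner(dentition)
        system = CoupledSystem(dentition, aligner, C, CouplingConstants())
        g = system.gradient(np.zeros(system.ndof))
        assert np.max(np.abs(g)) < 1e-12

    def test_interface_hooke_and_newton3(self, dentition):
        aligner = make_aligner(dentition)
        coupling = CouplingConstants()
        offset = np.array([0.1, 0.0, 0.0])
        aligner.segments[14].position = aligner.segments[14].position + offset
        system = CoupledSystem(dentition, aligner, C, coupling)
        g = system.gradient(np.zeros(system.ndof))
        i = FDI_ORDER.index(14)
        tooth_force = -g[6 * i:6 * i + 3]          # gradient = -force
        seg_force = -g[6 * (14 + i):6 * (14 + i) + 3]
        assert np.allclose(tooth_force, coupling.k_interface * offset, rtol=1e-9)
        assert np.allclose(seg_force, -tooth_force, rtol=1e-9)

    def test_global_coupling_force_balance(self, dentition, rng):
        # assembly-conservation oracle: internal coupling forces sum to zero
        aligner = make_aligner(dentition)
        for seg in aligner.segments.values():
            seg.position = seg.position + rng.normal(size=3) * 0.1
        system = CoupledSystem(dentition, aligner, C, CouplingConstants())
        x = rng.normal(size=system.ndof) * 0.01
        internal = system.K_lin @ x + system.c0
        total = np.zeros(3)
        for body in range(2 * 14):
            total += internal[6 * body:6 * body + 3]
        assert np.max(np.abs(total)) < 1e-9


class TestSolver:
    def test_trivial_equilibrium(self, dentition):
        aligner = make_aligner(dentition)
        system = CoupledSystem(dentition, aligner, C, CouplingConstants())
        eq = solve_equilibrium(system)
        assert np.max(np.abs(eq.tooth_dofs)) < 1e-12
        assert eq.pdl_max_strain < 1e-12

    def test_linear_branch_equals_one_shot_solve(self, dentition):
        aligner = make_aligner(dentition)
        aligner.segments[15].position = aligner.segments[15].position + [0.0, 0.01, 0.0]
        system = CoupledSystem(dentition, aligner, C, CouplingConstants())
        eq = solve_equilibrium(system)
        assert eq.pdl_max_strain < C.strain_break  # all samples in the toe
        K = system.tangent(np.zeros(system.ndof))
        x_lin = np.linalg.solve(K, system.f_ext - system.c0)
        x_solver = np.concatenate([eq.tooth_dofs.ravel(), eq.segment_dofs.ravel()])
        assert np.allclose(x_solver, x_lin, atol=1e-9)

    def test_energy_not_increased(self, dentition):
        aligner = make_aligner(dentition)
        aligner.segments[17].position = aligner.segments[17].position + [0.0, 0.1, 0.0]
        system = CoupledSystem(dentition, aligner, C, CouplingConstants())
        e0 = system.energy(np.zeros(system.ndof))
        eq = solve_equilibrium(system)
        assert eq.energy < e0

    def test_newton_third_law_with_loads(self, dentition):
        # total PDL reaction equals total applied force at equilibrium
        aligner = make_aligner(dentition)
        loads = anchorage_loads(AnchorageConfig(group="palatal_tad"), dentition)
        system = CoupledSystem(dentition, aligner, C, CouplingConstants(),
                               loads=loads)
        eq = solve_equilibrium(system)
        total_pdl = np.zeros(3)
        x = np.concatenate([eq.tooth_dofs.ravel(), eq.segment_dofs.ravel()])
        for i, pdl in enumerate(system.pdls):
            total_pdl += pdl.force(x[6 * i:6 * i + 6])[:3]
        assert np.allclose(total_pdl, loads.total_force(), atol=1e-9)

    def test_energy_minimization_oracle(self, dentition, rng):
        # brute-force oracle: scipy minimization of the same convex energy
        from scipy.optimize import minimize
        aligner = make_aligner(dentition)
        for fdi in (17, 14, 21):  # three perturbed teeth
            aligner.segments[fdi].position = (aligner.segments[fdi].position
                                              + rng.normal(size=3) * 0.08)
        system = CoupledSystem(dentition, aligner, C, CouplingConstants())
        eq = solve_equilibrium(system)
        res = minimize(system.energy, np.zeros(system.ndof), jac=system.gradient,
                       method="L-BFGS-B",
                       options={"maxiter": 5000, "ftol": 1e-18, "gtol": 1e-12})
        x_solver = np.concatenate([eq.tooth_dofs.ravel(), eq.segment_dofs.ravel()])
        assert np.max(np.abs(x_solver[:84] - res.x[:84])) < 1e-6
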