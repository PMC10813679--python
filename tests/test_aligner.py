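import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from alignersim.aligner import (TCMParams, aligner_gap, expand_aligner_step,
                                locate_deformation_region, make_aligner,
                                mesial_region_key, tcm_node_update,
                                tcm_preset_deformation, tcm_temperature_for,
                                wear_in_registration)
from alignersim.dentition import FDI_ORDER
from alignersim.errors import (DegenerateRegionError, RegistrationError,
                               ValidationError)

finite = st.floats(min_value=-100, max_value=100, allow_nan=False)
positive = st.floats(min_value=1e-3, max_value=100, allow_nan=False)


class TestDeformationRegion:
    def test_pc_at_interdental_midpoint(self, dentition):
        region = locate_deformation_region(dentition, 16, 17)
        assert np.allclose(region.p_c, (region.p_i + region.p_j) / 2, atol=1e-9)
        # p_i / p_j lie between the two crown centers
        u = region.line_direction
        for p in (region.p_i, region.p_j):
            s = np.dot(p - region.c_i, u)
            assert 0 < s < np.linalg.norm(region.c_j - region.c_i)

    def test_band_width_is_2mm_at_defaults(self, dentition):
        region = locate_deformation_region(dentition, 15, 16)
        assert region.width == pytest.approx(2.0)

    def test_probe_points(self, dentition):
        # direct distance computation oracle
        region = locate_deformation_region(dentition, 16, 17)
        u = region.line_direction
        assert region.contains(region.p_c + 0.5 * u)
        assert region.contains(region.p_c - 0.5 * u)
        assert not region.contains(region.p_c + 1.5 * u)
        assert not region.contains(region.p_c - 1.5 * u)

    def test_non_adjacent_error(self, dentition):
        with pytest.raises(ValidationError):
            locate_deformation_region(dentition, 17, 15)

    def test_overlapping_crowns_degenerate(self, dentition):
        d = dentition.copy()
        t16, t17 = d.tooth(16), d.tooth(17)
        # push 16's distal margin past 17's mesial margin along the arch
        t16.distal_margin[:] = t16.crown_point + 4.0 * (t17.crown_point
                                                        - t16.crown_point)
        with pytest.raises(DegenerateRegionError):
            locate_deformation_region(d, 16, 17)


class TestTCMFormulas:
    def test_zero_temperature(self):
        assert tcm_preset_deformation(k=0.025, d=2.0, cumulative_delta=0.4, t=0.0) == 0.0

    def test_first_step_reduction(self):
        assert tcm_preset_deformation(0.025, 2.0, 0.0, 3.0) == pytest.approx(
            0.025 * 2.0 * 3.0)

    def test_algebraic_inversion(self):
        # U = 0.1 mm with d = 2 mm, delta = 0, k = 0.025/degC -> t = 2.0 degC
        params = TCMParams(k=0.025, lambda_=1.0)
        t = tcm_temperature_for(0.1, params, d=2.0, cumulative_delta=0.0)
        assert t == pytest.approx(2.0)
        assert tcm_preset_deformation(0.025, 2.0, 0.0, t) == pytest.approx(0.1)

    def test_node_update_null(self):
        coords = np.array([1.0, -2.0])
        assert np.array_equal(tcm_node_update(coords, 0.0, np.array([0, 1.0]), 1.0),
                              coords)

    def test_node_update_unit_direction(self):
        out = tcm_node_update(np.zeros(2), 0.1, np.array([0.0, 1.0]), 1.0)
        assert np.allclose(out, [0.0, 0.1])

    def test_node_update_additivity(self):
        e = np.array([0.6, 0.8])
        out = tcm_node_update(tcm_node_update(np.zeros(2), 0.07, e, 0.5),
                              0.03, e, 0.5)
        assert np.allclose(out, (0.07 + 0.03) * 0.5 * e, atol=1e-15)

    @settings(max_examples=200, deadline=None)
    @given(k=positive, d=positive, delta=st.floats(min_value=0, max_value=50),
           t=finite)
    def test_preset_matches_independent_expression(self, k, d, delta, t):
        assert tcm_preset_deformation(k, d, delta, t) == k * (d + delta) * t

    @settings(max_examples=200, deadline=None)
    @given(x=finite, y=finite, U=finite, ex=finite, ey=finite, lam=finite)
    def test_node_update_matches_independent_expression(self, x, y, U, ex, ey, lam):
        out = tcm_node_update(np.array([x, y]), U, np.array([ex, ey]), lam)
        assert out[0] == x + U * lam * ex
        assert out[1] == y + U * lam * ey

    def test_invalid_params(self):
        with pytest.raises(ValidationError):
            TCMParams(k=0.0)
        with pytest.raises(ValidationError):
            tcm_preset_deformation(0.025, -1.0, 0.0, 1.0)
        with pytest.raises(ValidationError):
            tcm_preset_deformation(0.025, 2.0, -0.1, 1.0)


class TestExpandAligner:
    def test_identity_step(self, dentition):
        aligner = make_aligner(dentition)
        out = expand_aligner_step(aligner, {})
        assert np.array_equal(out.positions(), aligner.positions())
        assert all(r.cumulative_delta == 0 for r in out.regions.values())

    def test_single_molar_updates_mesial_region(self, dentition, arch_curve):
        from alignersim.archframe import distal_direction
        aligner = make_aligner(dentition)
        tangent = distal_direction(arch_curve, dentition.tooth(17))
        target = np.array([tangent[0] * 0.1, tangent[1] * 0.1, 0.0])
        out = expand_aligner_step(aligner, {17: target})
        key = mesial_region_key(17)
        assert out.regions[key].cumulative_delta == pytest.approx(0.1, abs=1e-6)
        moved = out.segments[17].position - aligner.segments[17].position
        assert np.allclose(moved, target, atol=1e-12)

    def test_twenty_expansions_accumulate(self, dentition, arch_curve):
        from alignersim.archframe import distal_direction
        aligner = make_aligner(dentition)
        tangent = distal_direction(arch_curve, dentition.tooth(17))
        target = np.array([tangent[0] * 0.1, tangent[1] * 0.1, 0.0])
        for _ in range(20):
            aligner = expand_aligner_step(aligner, {17: target})
        key = mesial_region_key(17)
        assert aligner.regions[key].cumulative_delta == pytest.approx(2.0, abs=1e-6)

    def test_spacing_conserved_outside_active_regions(self, dentition):
        aligner = make_aligner(dentition)
        target = np.array([0.0, 0.1, 0.0])
        out = expand_aligner_step(aligner, {17: target, 27: target})
        for a, b in zip(FDI_ORDER, FDI_ORDER[1:]):
            if 17 in (a, b) or 27 in (a, b):
                continue
            before = aligner.segments[b].position - aligner.segments[a].position
            after = out.segments[b].position - out.segments[a].position
            assert np.allclose(before, after, atol=1e-12)

    def test_cumulative_delta_monotone(self, dentition):
        aligner = make_aligner(dentition)
        rng = np.random.default_rng(0)
        prev = {k: 0.0 for k in aligner.regions}
        for _ in range(10):
            fdi = int(rng.choice([17, 16, 15, 26]))
            target = np.array([rng.normal(), abs(rng.normal()), 0.0]) * 0.05
            aligner = expand_aligner_step(aligner, {fdi: target})
            for key, region in aligner.regions.items():
                assert region.cumulative_delta >= prev[key] - 1e-15
                prev[key] = region.cumulative_delta


class TestWearIn:
    def test_identity_when_matching(self, dentition):
        aligner = make_aligner(dentition)
        transform = wear_in_registration(aligner, dentition)
        assert np.allclose(transform.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(transform.translation, 0.0, atol=1e-10)
        assert max(aligner_gap(aligner, dentition).values()) < 1e-10

    def test_recovers_known_transform(self, dentition, rng):
        aligner = make_aligner(dentition)
        R = Rotation.random(random_state=np.random.RandomState(2)).as_matrix()
        t = rng.normal(size=3) * 8
        for seg in aligner.segments.values():
            seg.position = R @ seg.position + t
        recovered = wear_in_registration(aligner, dentition, apply=False)
        # oracle: the inverse of the applied transform
        assert np.allclose(recovered.rotation, R.T, atol=1e-8)
        assert np.allclose(recovered.translation, -R.T @ t, atol=1e-8)
        wear_in_registration(aligner, dentition)
        assert max(aligner_gap(aligner, dentition).values()) < 1e-8

    def test_residual_invariant_under_common_motion(self, dentition, rng):
        aligner = make_aligner(dentition)
        for seg in aligner.segments.values():
            seg.position = seg.position + rng.normal(size=3) * 0.2
        a1 = aligner.copy()
        wear_in_registration(a1, dentition)
        res1 = sum(g ** 2 for g in aligner_gap(a1, dentition).values())

        R = Rotation.random(random_state=np.random.RandomState(9)).as_matrix()
        t = np.array([3.0, -2.0, 1.0])
        from alignersim.dentition import DentitionModel
        moved = DentitionModel(teeth=[tt.transformed(R, t) for tt in dentition.teeth],
                               alveolar_crest_height=dentition.alveolar_crest_height,
                               generation_seed=0)
        a2 = aligner.copy()
        for seg in a2.segments.values():
            seg.position = R @ seg.position + t
        wear_in_registration(a2, moved)
        res2 = sum(g ** 2 for g in aligner_gap(a2, moved).values())
        assert res2 == pytest.approx(res1, rel=1e-9, abs=1e-12)

    def test_registration_reduces_summed_squared_gap(self, dentition, rng):
        # least-squares optimality oracle
        aligner = make_aligner(dentition)
        for seg in aligner.segments.values():
            seg.position = seg.position + rng.normal(size=3) * 0.3 + [0.5, 0.2, -0.1]
        before = sum(g ** 2 for g in aligner_gap(aligner, dentition).values())
        wear_in_registration(aligner, dentition)
        after = sum(g ** 2 for g in aligner_gap(aligner, dentition).values())
        assert after <= before + 1e-12

    def test_too_few_segments(self, dentition):
        aligner = make_aligner(dentition)
        aligner.segments = {17: aligner.segments[17], 16: aligner.segments[16]}
        with pytest.raises(RegistrationError):
            wear_in_registration(aligner, dentition)


def test_gap_definition(dentition):
    aligner = make_aligner(dentition)
    offset = np.array([0.3, 0.0, 0.0])
    aligner.segments[14].position = aligner.segments[14].position + offset
    gaps = aligner_gap(aligner, dentition)
    assert gaps[14] == pytest.approx(0.3, abs=1e-12)
    assert gaps[15] == 0.0
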