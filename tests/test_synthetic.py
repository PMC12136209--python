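"""Synthetic cohort generator: geometry conventions, determinism, growth
application and the cohort-level ground-truth structure."""

import dataclasses

import numpy as np
import pytest

from aortastress import (
    AnatomyParams,
    GrowthField,
    apply_growth,
    make_cohort,
    make_dissected_aorta,
)
from aortastress.synthetic import cohort_table, laplace_stress_pattern


class TestMakeDissectedAorta:
    def test_default_grid_is_50_by_200_with_descending_landmarks(self):
        case = make_dissected_aorta()
        assert case.baseline.grid_shape == (200, 50)
        assert case.baseline.landmark_layers == (49, 200)
        case.baseline.validate()

    def test_seeded_determinism_is_bit_identical(self):
        a = make_dissected_aorta(AnatomyParams(seed=1))
        b = make_dissected_aorta(AnatomyParams(seed=1))
        assert np.array_equal(a.baseline.nodes, b.baseline.nodes)
        assert np.array_equal(a.flap.nodes, b.flap.nodes)
        assert np.array_equal(a.thrombus_mask, b.thrombus_mask)

    def test_half_extent_flap_splits_tube_cross_section_evenly(self):
        # straight tube, flap extent 0.5, no bow -> the flap chord is a
        # diameter, so the two lumens each enclose half the luminal disc.
        params = AnatomyParams.straight_tube(
            radius=17.0, length=100.0, n_circ=48, n_axial=40,
            include_flap=True, flap_extent=0.5, flap_bow=0.0,
        )
        case = make_dissected_aorta(params)
        mid = case.baseline.n_axial // 2
        assert case.flap.span[0] <= mid <= case.flap.span[1]
        k, nk = case.flap.attach_indices
        ring = case.baseline.nodes[mid - 1]
        centroid = ring.mean(axis=0)

        def poly_area(pts):
            pts = pts - centroid
            return 0.5 * abs(
                sum(
                    pts[i][0] * pts[i + 1][1] - pts[i + 1][0] * pts[i][1]
                    for i in range(len(pts) - 1)
                )
                + (pts[-1][0] * pts[0][1] - pts[0][0] * pts[-1][1])
            )

        flap_line = case.flap.nodes[mid - case.flap.span[0]]
        # FL region: outer arc through the seam (nk .. n_circ-1, 0 .. k) closed
        # by the flap chord; TL region: the complementary arc and the chord.
        fl_idx = list(range(nk, case.baseline.n_circ)) + list(range(0, k + 1))
        fl_pts = np.vstack([ring[fl_idx], flap_line[::-1]])
        tl_idx = list(range(k, nk + 1))
        tl_pts = np.vstack([ring[tl_idx], flap_line])
        fl_area, tl_area = poly_area(fl_pts), poly_area(tl_pts)
        assert fl_area == pytest.approx(tl_area, rel=0.01)

    def test_flap_carries_at_least_one_fenestration(self):
        case = make_dissected_aorta()
        assert case.flap.open_quads.any()

    def test_invalid_params_raise(self):
        with pytest.raises(ValueError, match="flap_extent"):
            AnatomyParams(flap_extent=1.5).validate()
        with pytest.raises(ValueError, match="positive"):
            AnatomyParams(radius_profile=((0.0, -1.0), (1.0, 5.0))).validate()


class TestApplyGrowth:
    def test_zero_rate_is_identity(self, default_case):
        g = GrowthField(np.zeros(default_case.baseline.grid_shape))
        out = apply_growth(default_case, g, years=2.0)
        assert np.allclose(out.followup.nodes, default_case.baseline.nodes)

    @pytest.mark.parametrize("rate,years", [(5.0, 2.0), (-5.0, 1.0), (12.5, 0.8)])
    def test_uniform_rate_scales_every_ring_circumference(self, default_case, rate, years):
        g = GrowthField(np.full(default_case.baseline.grid_shape, rate))
        out = apply_growth(default_case, g, years=years)
        ratio = out.followup.ring_perimeters() / default_case.baseline.ring_perimeters()
        assert np.allclose(ratio, np.exp(rate * years / 100.0), rtol=1e-12)

    def test_negative_rate_shrinks_diameters(self, default_case):
        g = GrowthField(np.full(default_case.baseline.grid_shape, -5.0))
        out = apply_growth(default_case, g, years=1.0)
        assert np.all(out.followup.effective_diameters() < default_case.baseline.effective_diameters())
        ratio = out.followup.ring_perimeters() / default_case.baseline.ring_perimeters()
        assert np.allclose(ratio, np.exp(-0.05), rtol=1e-12)

    def test_grid_mismatch_raises(self, default_case):
        g = GrowthField(np.zeros((10, 10)))
        with pytest.raises(ValueError, match="does not match"):
            apply_growth(default_case, g, years=1.0)


class TestMakeCohort:
    def test_default_cohort_shape_and_metadata(self):
        cases = make_cohort(9, seed=7)
        assert len(cases) == 9
        for c in cases:
            assert c.dt_years > 0
            assert c.systolic_bp_kpa > 0
            assert c.baseline.grid_shape == (200, 50)
            assert c.followup is not None
            assert c.growth_truth is not None

    def test_seeded_cohort_metadata_reproducible(self):
        t1 = cohort_table(make_cohort(4, seed=7))
        t2 = cohort_table(make_cohort(4, seed=7))
        assert t1.equals(t2)

    def test_zero_variation_collapses_to_identical_patients(self):
        cases = make_cohort(3, inter_patient_variation=0.0, seed=3)
        for c in cases[1:]:
            assert np.array_equal(c.baseline.nodes, cases[0].baseline.nodes)
            assert c.systolic_bp_kpa == cases[0].systolic_bp_kpa
            assert c.dt_years == cases[0].dt_years
            assert np.array_equal(c.growth_truth.values, cases[0].growth_truth.values)

    def test_single_patient_gets_no_variation(self):
        (case,) = make_cohort(1, seed=5)
        base = make_dissected_aorta(dataclasses.replace(AnatomyParams(), seed=6))
        assert case.systolic_bp_kpa == pytest.approx(18.36)
        assert case.dt_years == pytest.approx(3.18)

    def test_cohort_size_validated(self):
        with pytest.raises(ValueError):
            make_cohort(0)


class TestLaplacePattern:
    def test_thrombosed_segments_have_lower_tension_and_negative_growth_link(self):
        case = make_dissected_aorta()
        tension = laplace_stress_pattern(case)
        thr = case.thrombus_mask
        node_thr = np.zeros(case.baseline.grid_shape, bool)
        node_thr[:-1] |= thr
        fl_only = case.fl_node_mask & ~node_thr
        fl_thr = case.fl_node_mask & node_thr
        assert tension[fl_thr].mean() < tension[fl_only].mean()

    def test_false_lumen_wall_is_most_stressed(self):
        # thin (1 mm) FL wall under nearly the same pressure as the 2 mm TL
        case = make_dissected_aorta(AnatomyParams(thrombus_span=None))
        tension = laplace_stress_pattern(case)
        assert tension[case.fl_node_mask].mean() > 1.5 * tension[~case.fl_node_mask].mean()
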