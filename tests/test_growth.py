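"""Growth quantification: ICP, correspondence, log strain, rates, recovery."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter
from scipy.spatial.transform import Rotation

from aortastress import GrowthField, apply_growth, make_dissected_aorta
from aortastress.growth import (
    RigidTransform,
    circumferential_log_strain,
    correspond,
    growth_rate,
    icp_align,
    mean_diameter_growth,
    quantify_growth,
)


def smooth_field(shape, seed=0, sd=2.0, mean=4.0, corr=10.0):
    rng = np.random.default_rng(seed)
    f = gaussian_filter(rng.standard_normal(shape), sigma=corr, mode=("nearest", "wrap"))
    return GrowthField(mean + sd * f / f.std())


class TestICP:
    def test_identical_clouds_give_identity(self, default_case):
        pts = default_case.baseline.points()
        t = icp_align(pts, pts)
        assert np.abs(t.rotation - np.eye(3)).max() < 1e-6
        assert np.abs(t.translation).max() < 1e-6

    def test_recovers_known_rigid_motion(self, default_case):
        pts = default_case.baseline.points()
        rot = Rotation.from_euler("z", 10, degrees=True).as_matrix()
        trans = np.array([5.0, -3.0, 2.0])
        moved = pts @ rot.T + trans
        t = icp_align(moved, pts)
        comp_rot = t.rotation @ rot
        assert np.abs(comp_rot - np.eye(3)).max() < 1e-4
        assert np.abs(t.rotation @ trans + t.translation).max() < 1e-4

    def test_translation_recovered_under_noise(self, default_case):
        rng = np.random.default_rng(42)
        pts = default_case.baseline.points()
        noise_sd = 0.05
        moved = pts + np.array([2.0, -1.0, 3.0]) + rng.normal(0, noise_sd, pts.shape)
        t = icp_align(moved, pts)
        assert np.abs(t.translation + np.array([2.0, -1.0, 3.0])).max() < 5 * noise_sd

    def test_collinear_points_rejected(self):
        line = np.column_stack([np.linspace(0, 1, 10), np.zeros(10), np.zeros(10)])
        with pytest.raises(ValueError, match="collinear"):
            icp_align(line, line)

    def test_rigid_transform_validates_rotation(self):
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))


class TestCorrespondence:
    def test_identical_surfaces_zero_displacement(self, default_case):
        c = correspond(default_case.baseline, default_case.baseline, mode="index")
        assert np.allclose(c.matched, default_case.baseline.nodes)

    def test_dilated_pair_gives_radial_displacement(self, default_case):
        g = GrowthField(np.full(default_case.baseline.grid_shape, 10.0))
        grown = apply_growth(default_case, g, years=1.0)
        c = correspond(default_case.baseline, grown.followup, mode="index")
        disp = c.matched - default_case.baseline.nodes
        radial = default_case.baseline.nodes - default_case.baseline.ring_centroids()[:, None, :]
        expected = radial * (np.exp(0.1) - 1.0)
        assert np.allclose(disp, expected, atol=1e-9)

    def test_closest_point_mode_close_to_index_truth(self, default_case):
        g = GrowthField(np.full(default_case.baseline.grid_shape, 6.0))
        grown = apply_growth(default_case, g, years=1.0)
        idx = correspond(default_case.baseline, grown.followup, mode="index")
        cp = correspond(
            default_case.baseline, grown.followup, mode="closest-point-smoothed"
        )
        d_idx = np.linalg.norm(idx.matched - default_case.baseline.nodes, axis=2)
        d_cp = np.linalg.norm(cp.matched - default_case.baseline.nodes, axis=2)
        interior = slice(10, -10)
        rel = np.abs(d_cp[interior] - d_idx[interior]) / d_idx[interior].mean()
        assert np.median(rel) < 0.05

    def test_grid_mismatch_raises_in_index_mode(self, default_case):
        import dataclasses

        from aortastress import AnatomyParams, make_dissected_aorta

        other = make_dissected_aorta(AnatomyParams(n_circ=20, n_axial=40))
        with pytest.raises(ValueError, match="matching grids"):
            correspond(default_case.baseline, other.baseline, mode="index")


class TestLogStrain:
    @pytest.mark.parametrize("scale", [1.1, 0.9, 1.0])
    def test_uniform_scaling_gives_closed_form_strain(self, default_case, scale):
        base = default_case.baseline
        c = base.ring_centroids()[:, None, :]
        matched = c + (base.nodes - c) * scale
        corr = correspond(base, base, mode="index")
        corr.matched = matched
        eps = circumferential_log_strain(base, corr)
        assert np.allclose(eps, np.log(scale), atol=1e-12)

    def test_rates_are_strain_over_time(self):
        eps = np.full((4, 6), 0.0953)
        rate = growth_rate(eps, dt_years=2.0)
        assert np.allclose(rate, 4.765)
        assert np.allclose(growth_rate(np.zeros((4, 6)), 1.0), 0.0)
        assert np.allclose(growth_rate(np.full((4, 6), 0.5), 1.0), 50.0)
        with pytest.raises(ValueError):
            growth_rate(eps, 0.0)


class TestRecovery:
    def test_noiseless_roundtrip_recovers_prescribed_field(self, default_case):
        g = smooth_field(default_case.baseline.grid_shape, seed=1)
        grown = apply_growth(default_case, g, years=3.0)
        gmap = quantify_growth(default_case.baseline, grown.followup, 3.0)
        assert np.abs(gmap.rate - g.values).max() < 0.1

    def test_rigid_motion_invariance_with_icp(self, default_case):
        g = smooth_field(default_case.baseline.grid_shape, seed=2)
        rot = Rotation.from_euler("yx", [7, -4], degrees=True).as_matrix()
        trans = np.array([4.0, 2.0, -6.0])
        plain = apply_growth(default_case, g, years=3.0)
        moved = apply_growth(default_case, g, years=3.0, rigid=(rot, trans))
        r_plain = quantify_growth(default_case.baseline, plain.followup, 3.0).rate
        r_moved = quantify_growth(
            default_case.baseline, moved.followup, 3.0, pre_align=True
        ).rate
        assert np.abs(r_moved - r_plain).max() < 0.2

    def test_shrinkage_yields_negative_rates(self, default_case):
        g = GrowthField(np.full(default_case.baseline.grid_shape, -4.0))
        grown = apply_growth(default_case, g, years=2.0)
        gmap = quantify_growth(default_case.baseline, grown.followup, 2.0)
        assert np.all(gmap.rate < 0)


class TestMeanDiameterGrowth:
    def test_uniform_dilation_known_rate(self, default_case):
        base = default_case.baseline
        # add exactly 2 mm to every effective diameter over 1 year
        d0 = base.effective_diameters()
        scale = (d0 + 2.0) / d0
        c = base.ring_centroids()[:, None, :]
        matched = c + (base.nodes - c) * scale[:, None, None]
        assert mean_diameter_growth(base, matched, 1.0) == pytest.approx(2.0, abs=1e-9)

    def test_no_change_is_zero(self, default_case):
        base = default_case.baseline
        assert mean_diameter_growth(base, base.nodes, 2.5) == 0.0

    def test_span_validation(self, default_case):
        with pytest.raises(ValueError, match="outside the grid"):
            mean_diameter_growth(
                default_case.baseline, default_case.baseline.nodes, 1.0, layer_span=(0, 500)
            )

    def test_strain_diameter_consistency_on_uniform_growth(self, default_case):
        # uniform rate r: mean diameter growth = D0 * (exp(r dt/100) - 1) / dt
        g = GrowthField(np.full(default_case.baseline.grid_shape, 5.0))
        grown = apply_growth(default_case, g, years=2.0)
        gmap = quantify_growth(default_case.baseline, grown.followup, 2.0)
        lsa, bif = default_case.baseline.landmark_layers
        d0 = default_case.baseline.effective_diameters()[lsa - 1 : bif]
        expected = float(np.mean(d0 * (np.exp(0.05 * 2.0) - 1.0) / 2.0))
        assert gmap.mean_diameter_growth == pytest.approx(expected, rel=1e-9)
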