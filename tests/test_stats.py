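"""Regional sampling and the mixed-effects stress-growth analysis.

The mixed-model oracle is a direct region-level simulation with stated fixed
slope, random-effect SDs and residual SD: estimates must recover the truth
(bias, CI coverage) over replicated cohorts.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from aortastress import make_dissected_aorta
from aortastress.stats import (
    build_dataset,
    fit_lmm,
    partition_regions,
    pearson_per_patient,
    region_means,
    register_stress_to_grid,
)


def simulate_region_table(
    rng,
    n_patients=9,
    n_regions=38,
    slope=0.06,
    intercept=-10.0,
    intercept_sd=2.0,
    slope_sd=0.02,
    residual_sd=1.0,
):
    """Region-level generative model matching the cohort generator's link."""
    rows = []
    for pid in range(1, n_patients + 1):
        x = rng.uniform(120.0, 330.0, n_regions)
        a = intercept + rng.normal(0.0, intercept_sd)
        b = slope + rng.normal(0.0, slope_sd)
        y = a + b * x + rng.normal(0.0, residual_sd, n_regions)
        for r, (xi, yi) in enumerate(zip(x, y), start=1):
            rows.append(
                {
                    "patient_id": pid,
                    "region": r,
                    "stress_kpa": xi,
                    "growth_pct_per_year": yi,
                    "wss_pa": rng.uniform(1, 10),
                    "pressure_kpa": 18.0,
                    "descending": True,
                }
            )
    return pd.DataFrame(rows)


class TestPartition:
    def test_default_grid_partitions_into_50_regions(self, default_case):
        regions = partition_regions(default_case.baseline)
        assert len(regions) == 50
        assert regions["descending"].sum() == 38  # landmarks (49, 200)

    def test_descending_regions_lie_fully_between_landmarks(self, default_case):
        regions = partition_regions(default_case.baseline)
        lsa, bif = default_case.baseline.landmark_layers
        desc = regions[regions["descending"]]
        assert desc["layer_start"].min() >= lsa
        assert desc["layer_end"].max() <= bif
        # the boundary region straddling the landmark is excluded
        assert not regions.iloc[11]["descending"]

    def test_non_divisible_layer_count_raises(self, default_case):
        with pytest.raises(ValueError, match="not divisible"):
            partition_regions(default_case.baseline, layers_per_region=3)


class TestRegionMeans:
    def test_constant_field_gives_constant_means(self, default_case):
        means = region_means(np.full((200, 50), 7.5), default_case.baseline)
        assert np.allclose(means, 7.5)

    def test_layer_index_field_gives_midpoint_means(self, default_case):
        field = np.tile(np.arange(1, 201)[:, None], (1, 50)).astype(float)
        means = region_means(field, default_case.baseline)
        assert np.allclose(means, np.arange(50) * 4 + 2.5)

    def test_shape_mismatch_raises(self, default_case):
        with pytest.raises(ValueError, match="does not match"):
            region_means(np.zeros((10, 10)), default_case.baseline)


class TestRegisterStress:
    def test_field_already_on_grid_unchanged(self, coarse_dissected, dissected_solution):
        _, stress = dissected_solution
        out = register_stress_to_grid(stress, coarse_dissected.baseline, coarse_dissected.baseline)
        assert np.array_equal(out, stress.transmural_grid)

    def test_rigidly_displaced_grid_resamples_identically(
        self, coarse_dissected, dissected_solution
    ):
        _, stress = dissected_solution
        rot = Rotation.from_euler("z", 5, degrees=True).as_matrix()
        moved = coarse_dissected.baseline.transformed(rot, np.array([3.0, -1.0, 2.0]))
        direct = register_stress_to_grid(
            stress, coarse_dissected.baseline, coarse_dissected.baseline
        )
        via_icp = register_stress_to_grid(stress, moved, coarse_dissected.baseline)
        ok = np.isfinite(direct)
        assert np.allclose(via_icp[ok], direct[ok], atol=1e-6)

    def test_coarse_field_samples_onto_fine_grid(
        self, default_case, coarse_dissected, dissected_solution
    ):
        _, stress = dissected_solution
        out = register_stress_to_grid(stress, coarse_dissected.baseline, default_case.baseline)
        assert out.shape == default_case.baseline.grid_shape
        assert np.all(np.isfinite(out))


class TestBuildDataset:
    def _entries(self, n_patients, grid):
        rng = np.random.default_rng(0)
        na, nc = grid.grid_shape
        return [
            {
                "patient_id": m,
                "stress": rng.uniform(100, 300, (na, nc)),
                "growth": rng.normal(4, 2, (na, nc)),
                "wss": rng.uniform(1, 10, (na, nc)),
                "pressure": rng.uniform(17, 19, (na, nc)),
            }
            for m in range(1, n_patients + 1)
        ]

    def test_nine_patients_give_342_rows(self, default_case):
        table = build_dataset(self._entries(9, default_case.baseline), default_case.baseline)
        assert len(table) == 342

    def test_single_patient_gives_38_rows(self, default_case):
        table = build_dataset(self._entries(1, default_case.baseline), default_case.baseline)
        assert len(table) == 38
        assert table["region"].between(1, 50).all()

    def test_zero_patients_give_empty_table(self, default_case):
        table = build_dataset([], default_case.baseline)
        assert len(table) == 0

    def test_missing_field_raises(self, default_case):
        entries = self._entries(1, default_case.baseline)
        del entries[0]["wss"]
        with pytest.raises(ValueError, match="missing field"):
            build_dataset(entries, default_case.baseline)

    def test_patient_region_pairs_unique(self, default_case):
        table = build_dataset(self._entries(3, default_case.baseline), default_case.baseline)
        assert not table.duplicated(["patient_id", "region"]).any()


class TestFitLMM:
    def test_exact_shared_line_recovered(self):
        rng = np.random.default_rng(0)
        rows = []
        for m in range(1, 6):
            x = rng.uniform(100, 300, 10)
            for xi in x:
                rows.append(
                    {"patient_id": m, "stress_kpa": xi, "growth_pct_per_year": 0.5 + 0.1 * xi}
                )
        fit = fit_lmm(pd.DataFrame(rows), "stress")
        assert fit.beta1 == pytest.approx(0.1, abs=1e-6)
        assert fit.beta0 == pytest.approx(0.5, abs=1e-4)
        assert fit.random_slope_sd < 1e-4
        assert fit.p_value < 1e-6

    def test_predictor_equal_to_response_gives_unit_slope(self):
        rng = np.random.default_rng(1)
        rows = []
        for m in range(1, 5):
            y = rng.normal(5, 3, 12)
            for yi in y:
                rows.append({"patient_id": m, "stress_kpa": yi, "growth_pct_per_year": yi})
        fit = fit_lmm(pd.DataFrame(rows), "stress")
        assert fit.beta1 == pytest.approx(1.0, abs=1e-6)
        assert fit.p_value < 1e-8

    def test_parameter_recovery_and_ci_coverage(self):
        # 60 replicate cohorts at the stated truth; the dedicated acceptance
        # check runs 200 — this guards the estimator at suite scale.
        rng = np.random.default_rng(11)
        s_true = 0.06
        est, covered = [], 0
        n_rep = 60
        for _ in range(n_rep):
            fit = fit_lmm(simulate_region_table(rng, slope=s_true), "stress")
            est.append(fit.beta1)
            lo, hi = fit.beta1_ci
            covered += lo <= s_true <= hi
        bias = abs(np.mean(est) - s_true)
        assert bias < 0.05 * s_true + 3 * np.std(est) / np.sqrt(n_rep)
        assert 0.85 <= covered / n_rep <= 1.0

    def test_predictor_scaling_equivariance(self):
        rng = np.random.default_rng(3)
        table = simulate_region_table(rng)
        fit1 = fit_lmm(table, "stress")
        scaled = table.copy()
        scaled["stress_kpa"] *= 10.0
        fit10 = fit_lmm(scaled, "stress")
        assert fit10.beta1 == pytest.approx(fit1.beta1 / 10.0, rel=1e-4)

    def test_constant_predictor_rejected(self):
        rows = [
            {"patient_id": m, "stress_kpa": 5.0, "growth_pct_per_year": float(i)}
            for m in range(1, 4)
            for i in range(5)
        ]
        with pytest.raises(ValueError, match="constant within"):
            fit_lmm(pd.DataFrame(rows), "stress")

    def test_single_patient_rejected(self):
        rng = np.random.default_rng(4)
        table = simulate_region_table(rng, n_patients=1)
        with pytest.raises(ValueError, match="at least 2 patients"):
            fit_lmm(table, "stress")


class TestPearson:
    def test_exact_linear_correlations(self):
        x = np.linspace(100, 300, 38)
        rows = [
            {"patient_id": 1, "stress_kpa": xi, "growth_pct_per_year": 2 * xi + 1}
            for xi in x
        ] + [
            {"patient_id": 2, "stress_kpa": xi, "growth_pct_per_year": -0.5 * xi}
            for xi in x
        ]
        res = pearson_per_patient(pd.DataFrame(rows))
        assert res[0].r == pytest.approx(1.0)
        assert res[1].r == pytest.approx(-1.0)
        assert res[0].significant and res[1].significant

    def test_independent_noise_gives_small_r_and_flat_p(self):
        rng = np.random.default_rng(5)
        rs, ps = [], []
        for rep in range(40):
            rows = [
                {
                    "patient_id": 1,
                    "stress_kpa": rng.normal(200, 40),
                    "growth_pct_per_year": rng.normal(4, 2),
                }
                for _ in range(38)
            ]
            res = pearson_per_patient(pd.DataFrame(rows))[0]
            rs.append(res.r)
            ps.append(res.p_value)
        assert np.abs(np.mean(rs)) < 0.1
        # under the null, p-values should spread over [0, 1]
        assert np.std(ps) > 0.2

    def test_zero_variance_rejected(self):
        rows = [
            {"patient_id": 1, "stress_kpa": 5.0, "growth_pct_per_year": float(i)}
            for i in range(6)
        ]
        with pytest.raises(ValueError, match="zero variance"):
            pearson_per_patient(pd.DataFrame(rows))
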