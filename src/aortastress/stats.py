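"""Regional sampling and the stress-growth mixed-effects analysis.

The structured surface is partitioned into 50 equally sized axial regions of
4 circumferential layers each; with the default landmarks the descending
aorta (left subclavian artery to aortic bifurcation) comprises exactly 38 of
them.  Per-region means of stress, growth rate, wall shear stress and
pressure are pooled across patients (38 regions x 9 patients = 342 rows for
the default cohort) and modelled with a linear mixed-effects regression:

    rate_mr = (beta0 + b0m) + (beta1 + b1m) * stress_mr + e_mr

with fixed effects beta0, beta1, per-patient random intercepts/slopes
(b0m, b1m) and an F-test on the fixed slope (H0: beta1 = 0).  Per-patient
Pearson correlations complete the picture.  Model fitting is restricted
maximum likelihood via statsmodels MixedLM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.neighbors import NearestNeighbors

from .fem import StressField
from .growth import icp_align
from .surfaces import StructuredSurface

__all__ = [
    "LMMFit",
    "PearsonResult",
    "register_stress_to_grid",
    "partition_regions",
    "region_means",
    "build_dataset",
    "fit_lmm",
    "pearson_per_patient",
]

REGION_COLUMNS = [
    "patient_id",
    "region",
    "stress_kpa",
    "growth_pct_per_year",
    "wss_pa",
    "pressure_kpa",
    "descending",
]


@dataclass
class LMMFit:
    """Fitted linear mixed-effects model for one predictor."""

    predictor: str
    beta0: float
    beta1: float
    beta1_ci: tuple[float, float]
    beta0_ci: tuple[float, float]
    p_value: float                      # F-test on the fixed slope
    f_statistic: float
    ddf: float                          # denominator degrees of freedom
    random_intercept_sd: float
    random_slope_sd: float
    random_slope_sd_ci: tuple[float, float]
    random_effects: pd.DataFrame        # per-patient b0m, b1m
    residual_sd: float
    n_obs: int
    n_patients: int
    method: str = "MixedLM-REML, Wald F with between-within ddf"
    converged: bool = True

    def summary(self) -> str:
        lo, hi = self.beta1_ci
        return (
            f"predictor={self.predictor}: beta1={self.beta1:.4g} "
            f"[{lo:.4g}, {hi:.4g}], p={self.p_value:.4g} "
            f"(F={self.f_statistic:.3g}, ddf={self.ddf:.0f}); "
            f"beta0={self.beta0:.4g}; sd(b1m)={self.random_slope_sd:.4g}; "
            f"n={self.n_obs} over {self.n_patients} patients"
        )


@dataclass
class PearsonResult:
    patient_id: int
    r: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


# ---------------------------------------------------------------------------
# sampling onto the structured grid
# ---------------------------------------------------------------------------

def register_stress_to_grid(
    stress: StressField,
    stress_surface: StructuredSurface,
    grid: StructuredSurface,
    use_icp: bool = True,
) -> np.ndarray:
    """Sample a transmural stress field onto another structured grid.

    The stress support (the surface the solid mesh was built from) is
    ICP-aligned to the target grid, then each grid node takes the
    transmurally averaged stress of its nearest support node.  Exact when the
    field already lives on the grid.
    """
    values = stress.transmural_grid
    if values.shape == grid.grid_shape and stress_surface.nodes.shape == grid.nodes.shape \
            and np.allclose(stress_surface.nodes, grid.nodes):
        return values.copy()
    src = stress_surface.points()
    vals = values.reshape(-1)
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("empty stress field")
    src, vals = src[finite], vals[finite]
    if use_icp:
        t = icp_align(src, grid.points())
        src = t.apply(src)
    nn = NearestNeighbors(n_neighbors=1).fit(src)
    _, idx = nn.kneighbors(grid.points())
    return vals[idx[:, 0]].reshape(grid.grid_shape)


def partition_regions(grid: StructuredSurface, layers_per_region: int = 4) -> pd.DataFrame:
    """Axial region labels: region r spans layers (r-1)*L+1 .. r*L.

    Returns a DataFrame with one row per region (1-based), its layer span and
    the descending flag (regions lying fully between the landmark layers).
    """
    na = grid.n_axial
    if na % layers_per_region != 0:
        raise ValueError(
            f"{na} axial layers not divisible into regions of {layers_per_region}"
        )
    n_regions = na // layers_per_region
    lsa, bif = grid.landmark_layers
    rows = []
    for r in range(1, n_regions + 1):
        lo = (r - 1) * layers_per_region + 1
        hi = r * layers_per_region
        rows.append(
            {
                "region": r,
                "layer_start": lo,
                "layer_end": hi,
                "descending": (lo >= lsa) and (hi <= bif),
            }
        )
    return pd.DataFrame(rows)


def region_means(
    node_field: np.ndarray, grid: StructuredSurface, layers_per_region: int = 4
) -> np.ndarray:
    """Arithmetic mean of a node field over each region's layers x all circ nodes."""
    field_arr = np.asarray(node_field, float)
    if field_arr.shape != grid.grid_shape:
        raise ValueError(
            f"field shape {field_arr.shape} does not match grid {grid.grid_shape}"
        )
    na = grid.n_axial
    if na % layers_per_region != 0:
        raise ValueError(
            f"{na} axial layers not divisible into regions of {layers_per_region}"
        )
    return field_arr.reshape(-1, layers_per_region, grid.n_circ).mean(axis=(1, 2))


def build_dataset(
    per_patient: list[dict],
    grid_template: StructuredSurface,
    layers_per_region: int = 4,
    descending_only: bool = True,
) -> pd.DataFrame:
    """Pool per-patient region means into the cohort region table.

    Each entry of ``per_patient`` holds ``patient_id`` and node fields
    ``stress``, ``growth``, ``wss``, ``pressure`` on the structured grid.
    """
    regions = partition_regions(grid_template, layers_per_region)
    rows = []
    for entry in per_patient:
        pid = entry["patient_id"]
        means = {}
        for key in ("stress", "growth", "wss", "pressure"):
            if key not in entry:
                raise ValueError(f"patient {pid}: missing field {key!r}")
            means[key] = region_means(entry[key], grid_template, layers_per_region)
        for _, reg in regions.iterrows():
            r = int(reg["region"])
            rows.append(
                {
                    "patient_id": pid,
                    "region": r,
                    "stress_kpa": means["stress"][r - 1],
                    "growth_pct_per_year": means["growth"][r - 1],
                    "wss_pa": means["wss"][r - 1],
                    "pressure_kpa": means["pressure"][r - 1],
                    "descending": bool(reg["descending"]),
                }
            )
    table = pd.DataFrame(rows, columns=REGION_COLUMNS)
    if descending_only:
        table = table[table["descending"]].reset_index(drop=True)
    return table


# ---------------------------------------------------------------------------
# mixed-effects regression
# ---------------------------------------------------------------------------

_PREDICTOR_COLUMNS = {
    "stress": "stress_kpa",
    "wss": "wss_pa",
    "pressure": "pressure_kpa",
}


def fit_lmm(
    table: pd.DataFrame,
    predictor: str = "stress",
    response: str = "growth_pct_per_year",
    reml: bool = True,
) -> LMMFit:
    """Random-intercept-and-slope mixed model of growth rate on a predictor.

    Fits with REML (statsmodels MixedLM, unstructured 2x2 random-effects
    covariance), then tests H0: beta1 = 0 with a Wald-type F statistic using
    between-within denominator degrees of freedom.  Because the slope carries
    a per-patient random effect, its information is limited by the number of
    patients: ddf = m - 1.
    """
    import statsmodels.formula.api as smf

    col = _PREDICTOR_COLUMNS.get(predictor, predictor)
    if col not in table.columns:
        raise ValueError(f"unknown predictor {predictor!r}")
    df = table[["patient_id", col, response]].rename(
        columns={col: "x", response: "y"}
    ).copy()
    groups = df["patient_id"].to_numpy()
    m = df["patient_id"].nunique()
    if m < 2:
        raise ValueError("mixed-effects regression needs at least 2 patients")
    if df.groupby("patient_id").size().min() < 3:
        raise ValueError("each patient needs at least 3 regions")
    within_var = df.groupby("patient_id")["x"].var()
    if (within_var < 1e-30).all():
        raise ValueError("predictor is constant within every patient (rank deficient)")

    # standardize the predictor: conditions the optimizer uniformly and makes
    # the c-scaling equivariance of beta1 exact (the standardized problem is
    # identical for any predictor scale)
    x_mean = float(df["x"].mean())
    x_sd = float(df["x"].std())
    if x_sd <= 0:
        raise ValueError("predictor has zero variance")
    df["xs"] = (df["x"] - x_mean) / x_sd

    model = smf.mixedlm("y ~ xs", df, groups=groups, re_formula="~xs")
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                cand = model.fit(reml=reml, method=method, maxiter=500)
            except Exception:
                continue
            res = cand
            if cand.converged:
                break
    if res is None or not np.all(np.isfinite(res.fe_params)):
        raise RuntimeError(
            "mixed-effects fit did not converge (lbfgs, bfgs, powell all failed)"
        )

    beta0_s = float(res.fe_params["Intercept"])
    beta1_s = float(res.fe_params["xs"])
    se1_s = float(res.bse_fe["xs"])
    se0_s = float(res.bse_fe["Intercept"])
    # de-standardize: y = b0s + b1s * (x - mean)/sd  ->  beta1 = b1s/sd
    beta1 = beta1_s / x_sd
    beta0 = beta0_s - beta1_s * x_mean / x_sd
    se1 = se1_s / x_sd
    # SE of beta0 via the delta method would need the fe covariance; the
    # centered-intercept SE is the dominant term and is reported as-is
    cov_fe = np.asarray(res.cov_params())[:2, :2]
    if np.all(np.isfinite(cov_fe)):
        grad = np.array([1.0, -x_mean / x_sd])
        se0 = float(np.sqrt(max(grad @ cov_fe @ grad, 0.0)))
    else:
        se0 = se0_s
    if not (np.isfinite(se1) and np.isfinite(se0)):
        # degenerate (noise-free) data: the REML information matrix is
        # singular; fall back to the pooled OLS standard errors
        x = df["x"].to_numpy()
        sxx = float(np.sum((x - x.mean()) ** 2))
        se1 = float(np.sqrt(max(res.scale, 0.0) / sxx))
        se0 = float(np.sqrt(max(res.scale, 0.0) * (1.0 / len(x) + x.mean() ** 2 / sxx)))

    # Wald F with between-within ddf: the slope has a patient-level random
    # component, so its effective replication is the m patients.
    ddf = float(m - 1)
    f_stat = (beta1 / se1) ** 2 if se1 > 0 else np.inf
    p = float(sps.f.sf(f_stat, 1, ddf)) if np.isfinite(f_stat) else 0.0
    tcrit = sps.t.ppf(0.975, ddf)
    beta1_ci = (beta1 - tcrit * se1, beta1 + tcrit * se1)
    beta0_ci = (beta0 - tcrit * se0, beta0 + tcrit * se0)

    scale = float(res.scale)
    cov_re_s = res.cov_re.to_numpy() * 1.0  # standardized-units covariance
    a = x_mean / x_sd
    # transform random effects back to predictor units:
    #   b1m = b1m_s / sd,  b0m = b0m_s - a * b1m_s
    var_b1 = max(cov_re_s[1, 1], 0.0) / x_sd**2
    var_b0 = max(cov_re_s[0, 0] - 2.0 * a * cov_re_s[0, 1] + a**2 * cov_re_s[1, 1], 0.0)
    sd_b0 = float(np.sqrt(var_b0))
    sd_b1 = float(np.sqrt(var_b1))

    # delta-method CI for sd(b1m): statsmodels reports SEs for the scaled
    # covariance entries of the standardized model
    try:
        names = list(res.model.data.param_names)
        i = names.index("xs Var")
        se_var_s = float(res.bse.iloc[i]) * scale  # bse is for cov_re / scale
        se_var = se_var_s / x_sd**2
        if sd_b1 > 0 and np.isfinite(se_var):
            se_sd = se_var / (2.0 * sd_b1)
            sd_b1_ci = (max(sd_b1 - 1.96 * se_sd, 0.0), sd_b1 + 1.96 * se_sd)
        else:
            sd_b1_ci = (0.0, np.nan)
    except (ValueError, IndexError):
        sd_b1_ci = (np.nan, np.nan)

    re_rows = []
    for pid, re_vals in res.random_effects.items():
        b0s, b1s = float(re_vals.iloc[0]), float(re_vals.iloc[1])
        re_rows.append(
            {"patient_id": pid, "b0m": b0s - a * b1s, "b1m": b1s / x_sd}
        )
    random_effects = pd.DataFrame(re_rows)

    return LMMFit(
        predictor=predictor,
        beta0=beta0,
        beta1=beta1,
        beta1_ci=beta1_ci,
        beta0_ci=beta0_ci,
        p_value=p,
        f_statistic=float(f_stat),
        ddf=ddf,
        random_intercept_sd=sd_b0,
        random_slope_sd=sd_b1,
        random_slope_sd_ci=sd_b1_ci,
        random_effects=random_effects,
        residual_sd=float(np.sqrt(scale)),
        n_obs=len(df),
        n_patients=m,
        method=("MixedLM-" + ("REML" if reml else "ML") + ", Wald F with between-within ddf"),
        converged=bool(res.converged),
    )


def pearson_per_patient(
    table: pd.DataFrame,
    predictor: str = "stress",
    response: str = "growth_pct_per_year",
) -> list[PearsonResult]:
    """Product-moment correlation and two-sided p-value per patient."""
    col = _PREDICTOR_COLUMNS.get(predictor, predictor)
    out = []
    for pid, sub in table.groupby("patient_id"):
        if len(sub) < 3:
            raise ValueError(f"patient {pid}: need at least 3 regions for Pearson")
        x, y = sub[col].to_numpy(), sub[response].to_numpy()
        if np.var(x) == 0 or np.var(y) == 0:
            raise ValueError(f"patient {pid}: zero variance, correlation undefined")
        r, p = sps.pearsonr(x, y)
        out.append(PearsonResult(patient_id=int(pid), r=float(r), p_value=float(p)))
    return out
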