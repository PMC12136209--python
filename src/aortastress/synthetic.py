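"""Synthetic dissected-aorta cohort generator.

Real type B aortic dissection (TBAD) studies start from segmented CT
angiography; nothing equivalent is publicly deposited, so this module generates
idealized, seeded stand-ins with the geometric and statistical structure the
downstream stages assume:

* a candy-cane outer wall surface on the structured 50 x 200 grid (ascending
  limb, arch, long descending limb), with a dilated dissected descending
  segment;
* an intimal flap strip that splits each dissected cross-section into a true
  lumen (TL) and a false lumen (FL), with one or more fenestrations (holes);
* an optional mural thrombus region lining the false lumen;
* patient metadata (systolic blood pressure, follow-up interval, inlet flow,
  outlet diameters for the branch vessels);
* a prescribed ground-truth circumferential growth-rate field (%/year) with a
  known linear link to a wall-tension pattern, so the mixed-effects stage has a
  recoverable ground truth.

Units: mm, kPa, years, %/year.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import gaussian_filter

from .surfaces import StructuredSurface

__all__ = [
    "AnatomyParams",
    "FlapSurface",
    "GrowthField",
    "GrowthLinkConfig",
    "PatientCase",
    "make_dissected_aorta",
    "apply_growth",
    "make_cohort",
    "cohort_table",
    "laplace_stress_pattern",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

#: default branch-vessel outlet diameters in mm (brachiocephalic, left common
#: carotid, left subclavian, celiac, superior mesenteric, two renals, two
#: common iliacs) — population-plausible calibres, carried as metadata only.
DEFAULT_OUTLET_DIAMETERS: tuple[float, ...] = (12.0, 8.0, 10.0, 8.0, 7.0, 5.0, 5.0, 8.0, 8.0)


@dataclass
class AnatomyParams:
    """Geometry controls for one synthetic dissected aorta."""

    n_circ: int = 50
    n_axial: int = 200
    #: outer radius control points as (fraction of axial span, radius mm);
    #: interpolated monotonically-smoothly (PCHIP) along the axial index.
    radius_profile: tuple[tuple[float, float], ...] = (
        (0.00, 16.0),
        (0.12, 16.5),
        (0.24, 16.0),
        (0.45, 18.0),
        (0.75, 16.0),
        (1.00, 9.0),
    )
    ascending_length: float = 60.0       # mm, vertical ascending limb
    arch_radius: float = 32.0            # mm, semicircular arch in the x-z plane
    descending_length: float = 480.0     # mm, straight descending limb
    lsa_layer: int | None = None         # left-subclavian landmark; default 0.24*n_axial + 1
    include_flap: bool = True            # False -> intact (undissected) vessel benchmark
    flap_extent: float = 0.40            # fraction of circumference forming the FL
    flap_span: tuple[int, int] | None = None  # 1-based axial layers; default descending span
    flap_bow: float = 0.12               # flap sagitta as fraction of chord, bulging into the TL
    #: fenestrations as (axial start layer, axial extent in layers,
    #: chord-fraction start, chord-fraction extent); None -> one default tear
    #: near the proximal end of the flap.
    fenestrations: tuple[tuple[int, int, float, float], ...] | None = None
    thrombus_span: tuple[int, int] | None = (150, 180)  # FL thrombosed layers
    thrombus_thickness: float = 3.0      # mm, mural thrombus lining thickness
    wall_thickness_tl: float = 2.0       # mm (double offset convention)
    wall_thickness_fl: float = 1.0       # mm
    flap_thickness: float = 1.0          # mm
    outlet_diameters: tuple[float, ...] = DEFAULT_OUTLET_DIAMETERS
    seed: int = 0

    def validate(self) -> None:
        if self.n_circ < 8 or self.n_axial < 8:
            raise ValueError("grid too small: need n_circ >= 8 and n_axial >= 8")
        radii = [r for _, r in self.radius_profile]
        if any(r <= 0 for r in radii):
            raise ValueError("all radii in radius_profile must be positive")
        if not (0.0 < self.flap_extent < 1.0):
            raise ValueError("flap_extent must lie in (0, 1)")
        for t in (self.wall_thickness_tl, self.wall_thickness_fl, self.flap_thickness):
            if t <= 0:
                raise ValueError("wall/flap thickness values must be positive")
        if any(d <= 0 for d in self.outlet_diameters):
            raise ValueError("outlet diameters must be positive")

    # resolved defaults ------------------------------------------------------
    @property
    def lsa_layer_resolved(self) -> int:
        if self.lsa_layer is not None:
            return self.lsa_layer
        return int(round(0.24 * self.n_axial)) + 1  # 49 on the default 200-layer grid

    @property
    def flap_span_resolved(self) -> tuple[int, int]:
        if self.flap_span is not None:
            return self.flap_span
        lsa = self.lsa_layer_resolved
        return (lsa, min(self.n_axial, lsa + int(round(0.72 * self.n_axial))))

    @classmethod
    def straight_tube(
        cls,
        radius: float = 15.0,
        length: float = 100.0,
        n_circ: int = 50,
        n_axial: int = 200,
        **kwargs,
    ) -> "AnatomyParams":
        """Parameters for a straight vertical tube (benchmark geometry)."""
        kwargs.setdefault("thrombus_span", None)
        kwargs.setdefault("include_flap", False)
        return cls(
            n_circ=n_circ,
            n_axial=n_axial,
            radius_profile=((0.0, radius), (1.0, radius)),
            ascending_length=0.0,
            arch_radius=0.0,
            descending_length=length,
            **kwargs,
        )


@dataclass
class FlapSurface:
    """Intimal flap strip on its own (axial x chord) structured grid.

    ``nodes[i, j]`` is the flap mid-surface node on (absolute 1-based) axial
    layer ``span[0] + i`` at chord position j; j = 0 and j = n_across - 1 are
    the attachment lines, coincident with the luminal wall surface at the
    circumferential attachment indices.  ``open_quads`` marks fenestration
    holes (removed quads).
    """

    nodes: np.ndarray                      # (n_layers, n_across, 3)
    span: tuple[int, int]                  # 1-based axial layers (inclusive)
    attach_indices: tuple[int, int]        # circumferential wall node indices (FL side: between them through 0)
    open_quads: np.ndarray                 # (n_layers - 1, n_across - 1) bool

    @property
    def n_layers(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_across(self) -> int:
        return self.nodes.shape[1]


@dataclass
class GrowthField:
    """Prescribed circumferential log-strain rate in %/year on the surface grid."""

    values: np.ndarray  # (n_axial, n_circ)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("growth field must be a 2-D (n_axial, n_circ) array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("growth field must be finite everywhere")


@dataclass
class PatientCase:
    """One synthetic patient: geometry, metadata and ground truth."""

    patient_id: int
    params: AnatomyParams
    baseline: StructuredSurface
    flap: FlapSurface | None
    thrombus_mask: np.ndarray              # (n_axial - 1, n_circ) bool over wall quads
    fl_node_mask: np.ndarray               # (n_axial, n_circ) bool: node faces the false lumen
    systolic_bp_kpa: float = 18.36
    inlet_flow_l_min: float = 25.0
    followup: StructuredSurface | None = None
    dt_years: float | None = None
    growth_truth: GrowthField | None = None
    rigid_truth: tuple[np.ndarray, np.ndarray] | None = None

    def validate(self) -> None:
        if self.patient_id < 1:
            raise ValueError("patient id must be >= 1")
        if self.systolic_bp_kpa <= 0:
            raise ValueError("systolic BP must be positive")
        if self.dt_years is not None and self.dt_years <= 0:
            raise ValueError("follow-up interval must be positive")
        self.baseline.validate()

    def wall_thickness_map(self) -> np.ndarray:
        """Per-node wall thickness (mm): TL 2 mm, FL wall 1 mm."""
        p = self.params
        t = np.full(self.baseline.grid_shape, p.wall_thickness_tl)
        t[self.fl_node_mask] = p.wall_thickness_fl
        return t


# ---------------------------------------------------------------------------
# geometry construction
# ---------------------------------------------------------------------------

def _centerline(params: AnatomyParams) -> tuple[np.ndarray, np.ndarray]:
    """Centerline positions and unit tangents at each axial layer.

    The ascending limb runs vertically up the +z axis, the arch is a semicircle
    in the x-z plane, and the descending limb runs vertically down, so both end
    rings are horizontal (their axial direction is +/- z).  The left-subclavian
    landmark layer is pinned to the arch-descending junction.
    """
    na = params.n_axial
    lsa = params.lsa_layer_resolved
    s_arch_end = params.ascending_length + np.pi * params.arch_radius
    total = s_arch_end + params.descending_length

    if s_arch_end <= 0:  # straight tube running down the -z axis
        s = np.linspace(0.0, total, na)
        pos = np.zeros((na, 3))
        pos[:, 2] = -s
        tan = np.tile(np.array([0.0, 0.0, -1.0]), (na, 1))
        return pos, tan

    s = np.concatenate(
            [
            np.linspace(0.0, s_arch_end, lsa),
            np.linspace(s_arch_end, total, na - lsa + 1)[1:],
        ]
    )

    pos = np.zeros((na, 3))
    tan = np.zeros((na, 3))
    for i, si in enumerate(s):
        if si <= params.ascending_length:
            pos[i] = (0.0, 0.0, si)
            tan[i] = (0.0, 0.0, 1.0)
        elif si <= s_arch_end:
            phi = (si - params.ascending_length) / params.arch_radius
            cx, cz = params.arch_radius, params.ascending_length
            pos[i] = (cx - params.arch_radius * np.cos(phi), 0.0, cz + params.arch_radius * np.sin(phi))
            tan[i] = (np.sin(phi), 0.0, np.cos(phi))
        else:
            d = si - s_arch_end
            pos[i] = (2.0 * params.arch_radius, 0.0, params.ascending_length - d)
            tan[i] = (0.0, 0.0, -1.0)
    return pos, tan


def _radius_profile(params: AnatomyParams) -> np.ndarray:
    fr, rr = zip(*params.radius_profile)
    fr, rr = np.asarray(fr, float), np.asarray(rr, float)
    x = np.linspace(0.0, 1.0, params.n_axial)
    if len(fr) < 2:
        return np.full(params.n_axial, rr[0])
    return PchipInterpolator(fr, rr)(x)


def _attach_offset(params: AnatomyParams) -> int:
    """Circumferential half-width (in node steps) of the false-lumen sector."""
    k = int(round(params.flap_extent * params.n_circ / 2.0))
    return int(np.clip(k, 2, params.n_circ // 2 - 1))


def make_dissected_aorta(params: AnatomyParams | None = None) -> PatientCase:
    """Generate a baseline dissected-aorta case from anatomy parameters.

    The outer wall is a structured ``n_circ x n_axial`` surface; the false
    lumen occupies the circumferential sector of angular extent
    ``flap_extent`` centred on the outer curvature; the flap is a bowed chord
    strip attached along two longitudinal lines, with at least one
    fenestration; the thrombus mask flags false-lumen wall quads in the
    thrombosed axial span.  Only the baseline is populated — use
    :func:`apply_growth` to create the follow-up geometry.
    """
    if params is None:
        params = AnatomyParams()
    params.validate()

    pos, tan = _centerline(params)
    radii = _radius_profile(params)
    na, nc = params.n_axial, params.n_circ

    # ring frames: e1 = global y (the centerline lies in the x-z plane), e2 = t x e1
    e1 = np.tile(np.array([0.0, 1.0, 0.0]), (na, 1))
    e2 = np.cross(tan, e1)
    e2 /= np.linalg.norm(e2, axis=1, keepdims=True)

    theta = 2.0 * np.pi * np.arange(nc) / nc
    ring_dirs = (
        np.cos(theta)[None, :, None] * e2[:, None, :]
        + np.sin(theta)[None, :, None] * e1[:, None, :]
    )
    nodes = pos[:, None, :] + radii[:, None, None] * ring_dirs

    lsa = params.lsa_layer_resolved
    surface = StructuredSurface(nodes=nodes, landmark_layers=(lsa, na))
    surface.validate()

    # --- false lumen sector and flap ---------------------------------------
    fl_node_mask = np.zeros((na, nc), dtype=bool)
    if params.include_flap:
        k = _attach_offset(params)
        f0, f1 = params.flap_span_resolved
        f0, f1 = max(1, f0), min(na, f1)
        circ = np.arange(nc)
        fl_circ = (circ <= k) | (circ >= nc - k)  # sector centred on theta = 0
        fl_node_mask[f0 - 1 : f1, :] = fl_circ[None, :]
        # attachment node columns belong to the TL wall (full thickness)
        fl_node_mask[:, k] = False
        fl_node_mask[:, nc - k] = False
        flap = _build_flap(params, surface, k, (f0, f1))
    else:
        flap = None
        f0, f1 = 1, 0
        fl_circ = np.zeros(nc, dtype=bool)

    # --- thrombus mask over FL wall quads -----------------------------------
    thrombus_mask = np.zeros((na - 1, nc), dtype=bool)
    if params.thrombus_span is not None:
        t0, t1 = params.thrombus_span
        t0, t1 = max(t0, f0), min(t1, f1)
        if t1 > t0:
            quad_fl = fl_circ & np.roll(fl_circ, -1)  # both quad nodes in the sector
            quad_fl = quad_fl.copy()
            quad_fl[k] = False          # quads incident to the attachments stay clear
            quad_fl[nc - k - 1] = False
            thrombus_mask[t0 - 1 : t1 - 1, :] = quad_fl[None, :]

    case = PatientCase(
        patient_id=1,
        params=params,
        baseline=surface,
        flap=flap,
        thrombus_mask=thrombus_mask,
        fl_node_mask=fl_node_mask,
    )
    case.validate()
    return case


def _build_flap(
    params: AnatomyParams,
    surface: StructuredSurface,
    k: int,
    span: tuple[int, int],
) -> FlapSurface:
    """Flap strip: a bowed chord from attachment node +k to node -k.

    The chord crosses the lumen interior and is bowed toward the true lumen by
    ``flap_bow`` times the chord length.  Attachment ends lie on the luminal
    wall surface (outer wall offset inward by the TL wall thickness).
    """
    f0, f1 = span
    nc = params.n_circ
    n_across = 2 * k + 1
    normals = surface.node_normals()
    t_tl = params.wall_thickness_tl

    layers = np.arange(f0 - 1, f1)
    a_pts = surface.nodes[layers, k] - t_tl * normals[layers, k]
    b_pts = surface.nodes[layers, nc - k] - t_tl * normals[layers, nc - k]
    centroids = surface.ring_centroids()[layers]
    # bulge direction: from the FL-side wall toward the TL (through the centroid)
    fl_mid = surface.nodes[layers, 0]
    d = centroids - fl_mid
    d /= np.linalg.norm(d, axis=1, keepdims=True)

    chord = np.linalg.norm(b_pts - a_pts, axis=1)
    ctrl = 0.5 * (a_pts + b_pts) + (2.0 * params.flap_bow * chord)[:, None] * d

    t = np.linspace(0.0, 1.0, n_across)[None, :, None]
    nodes = (
        (1 - t) ** 2 * a_pts[:, None, :]
        + 2 * (1 - t) * t * ctrl[:, None, :]
        + t**2 * b_pts[:, None, :]
    )

    open_quads = np.zeros((len(layers) - 1, n_across - 1), dtype=bool)
    fen = params.fenestrations
    if fen is None:
        # one default tear (primary entry) near the proximal end of the flap
        fen = ((f0 + 2, max(2, (f1 - f0) // 20), 0.35, 0.3),)
    for a_start, a_ext, c_start, c_ext in fen:
        i0 = int(np.clip(a_start - f0, 0, open_quads.shape[0]))
        i1 = int(np.clip(i0 + a_ext, 0, open_quads.shape[0]))
        j0 = int(np.clip(round(c_start * (n_across - 1)), 0, open_quads.shape[1]))
        j1 = int(np.clip(j0 + max(1, round(c_ext * (n_across - 1))), 0, open_quads.shape[1]))
        open_quads[i0:i1, j0:j1] = True
    if not open_quads.any():
        raise ValueError("flap must carry at least one fenestration")

    return FlapSurface(
        nodes=nodes, span=(f0, f1), attach_indices=(k, nc - k), open_quads=open_quads
    )


# ---------------------------------------------------------------------------
# growth application (the synthetic inverse of the growth quantification)
# ---------------------------------------------------------------------------

def apply_growth(
    case: PatientCase,
    growth: GrowthField,
    years: float,
    rigid: tuple[np.ndarray, np.ndarray] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PatientCase:
    """Create the follow-up surface by applying a growth field to the baseline.

    Each node is scaled about its ring centroid by ``exp(rate * years / 100)``,
    which multiplies the local circumferential dimension by that factor (the
    exact inverse of circumferential log strain for uniform fields).  An
    optional known rigid transform ``(R, t)`` is applied afterwards, and
    Gaussian node jitter with standard deviation ``noise_sd`` mm is added last.
    The ground truth is stored on the returned case.
    """
    if growth.values.shape != case.baseline.grid_shape:
        raise ValueError(
            f"growth grid {growth.values.shape} does not match surface grid "
            f"{case.baseline.grid_shape}"
        )
    if years <= 0:
        raise ValueError("follow-up interval must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")

    base = case.baseline
    target_eps = growth.values * years / 100.0
    centroids = base.ring_centroids()[:, None, :]

    def incident_lengths(nodes: np.ndarray) -> np.ndarray:
        seg = np.linalg.norm(np.roll(nodes, -1, axis=1) - nodes, axis=2)
        return seg + np.roll(seg, 1, axis=1)

    l0 = incident_lengths(base.nodes)
    # Radially scaling node i by exp(eps_i) about the ring centroid realizes a
    # spatially varying strain field only to first order; a few fixed-point
    # corrections make the local circumferential dimensions match the
    # prescribed factors to numerical precision.
    factor = np.exp(target_eps)
    nodes = centroids + (base.nodes - centroids) * factor[:, :, None]
    for _ in range(12):
        eps_meas = np.log(incident_lengths(nodes) / l0)
        err = target_eps - eps_meas
        if np.abs(err).max() < 1e-9:
            break
        factor = factor * np.exp(err)
        nodes = centroids + (base.nodes - centroids) * factor[:, :, None]

    if rigid is not None:
        rot, trans = np.asarray(rigid[0], float), np.asarray(rigid[1], float)
        nodes = nodes @ rot.T + trans
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        nodes = nodes + rng.normal(0.0, noise_sd, size=nodes.shape)

    followup = StructuredSurface(nodes=nodes, landmark_layers=base.landmark_layers)
    out = dataclasses.replace(
        case,
        followup=followup,
        dt_years=float(years),
        growth_truth=growth,
        rigid_truth=rigid,
    )
    out.validate()
    return out


# ---------------------------------------------------------------------------
# wall-tension pattern (Laplace-law) used as the growth link
# ---------------------------------------------------------------------------

def laplace_stress_pattern(case: PatientCase) -> np.ndarray:
    """Per-node Laplace-law wall tension estimate p*r/t in kPa.

    This closed-form pattern (local luminal pressure x local radius / local
    load-bearing thickness, with mural thrombus counted into the thickness) is
    the prescribed stress field that the cohort generator links growth to.  It
    mirrors the leading-order behaviour of the finite-element stress — thin
    false-lumen wall and dilated segments are stressed, thrombosed segments
    are shielded — without requiring a solve at generation time.
    """
    base = case.baseline
    r = np.linalg.norm(base.nodes - base.ring_centroids()[:, None, :], axis=2)
    t = case.wall_thickness_map().copy()

    # thrombus thickening: a node is shielded if any incident quad is thrombosed
    thr = case.thrombus_mask
    node_thr = np.zeros(base.grid_shape, dtype=bool)
    node_thr[:-1] |= thr | np.roll(thr, 1, axis=1)
    node_thr[1:] |= thr | np.roll(thr, 1, axis=1)
    t[node_thr] += case.params.thrombus_thickness

    p = np.full(base.grid_shape, case.systolic_bp_kpa)
    p[case.fl_node_mask] -= 0.76  # default TL-FL mean pressure gap, kPa
    return p * r / t


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class GrowthLinkConfig:
    """Generative link between the wall-tension pattern and growth rate.

    rate(node) = intercept + b0m + (slope + b1m) * tension(node) + noise(node)

    with per-patient random effects b0m ~ N(0, intercept_sd^2),
    b1m ~ N(0, slope_sd^2) and a smooth spatial noise field.  Defaults put the
    cohort in the regime the clinical literature reports for acute TBAD:
    mostly ~5 %/year growth with thrombosed segments shrinking, and a
    population slope of a few hundredths of %/year per kPa of wall stress.
    """

    intercept: float = -10.0        # %/year
    slope: float = 0.06             # %/(year kPa)
    intercept_sd: float = 2.0       # %/year, across patients
    slope_sd: float = 0.02          # %/(year kPa), across patients
    noise_sd: float = 1.0           # %/year, within-patient spatial noise
    noise_corr_len: float = 8.0     # grid units, correlation length of the noise


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], corr_len: float) -> np.ndarray:
    """Unit-variance smooth random field, periodic circumferentially."""
    white = rng.standard_normal(shape)
    f = gaussian_filter(white, sigma=corr_len, mode=("nearest", "wrap"))
    sd = f.std()
    return f / sd if sd > 0 else f


def make_cohort(
    n_patients: int,
    base_params: AnatomyParams | None = None,
    inter_patient_variation: float = 1.0,
    seed: int = 7,
    growth_link: GrowthLinkConfig | None = None,
    followup_noise_sd: float = 0.05,
) -> list[PatientCase]:
    """Generate a cohort of synthetic patients with known growth ground truth.

    Anatomy (radius scale, flap extent, thrombus presence/span), systolic BP,
    follow-up interval and per-patient random growth effects all vary across
    patients; ``inter_patient_variation`` scales every source of between- and
    within-patient variability (0 gives identical patients with the pure
    fixed-effect growth field).  All sub-seeds derive deterministically from
    ``seed``.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if base_params is None:
        base_params = AnatomyParams()
    if growth_link is None:
        growth_link = GrowthLinkConfig()
    ipv = float(inter_patient_variation)
    if n_patients == 1:
        ipv = 0.0  # single case: no inter-patient variation applied

    root = np.random.SeedSequence(seed)
    cases: list[PatientCase] = []
    for m in range(1, n_patients + 1):
        rng = np.random.default_rng(root.spawn(1)[0])

        radius_scale = 1.0 + ipv * rng.normal(0.0, 0.06)
        flap_extent = float(np.clip(base_params.flap_extent + ipv * rng.normal(0.0, 0.04), 0.25, 0.55))
        has_thrombus = (base_params.thrombus_span is not None) and (
            ipv == 0.0 or rng.random() < 2.0 / 3.0
        )
        thrombus_span = base_params.thrombus_span
        if has_thrombus and thrombus_span is not None and ipv > 0:
            shift = int(round(ipv * rng.normal(0.0, 8.0)))
            t0, t1 = thrombus_span
            thrombus_span = (max(2, t0 + shift), min(base_params.n_axial, t1 + shift))
        params = dataclasses.replace(
            base_params,
            radius_profile=tuple((f, r * radius_scale) for f, r in base_params.radius_profile),
            flap_extent=flap_extent,
            thrombus_span=thrombus_span if has_thrombus else None,
            seed=seed + m,
        )
        case = make_dissected_aorta(params)

        bp = 18.36 + ipv * rng.normal(0.0, 1.2)
        dt = float(3.18 * np.exp(ipv * rng.normal(0.0, 0.45)))
        case = dataclasses.replace(case, patient_id=m, systolic_bp_kpa=float(bp))

        tension = laplace_stress_pattern(case)
        b0 = ipv * rng.normal(0.0, growth_link.intercept_sd)
        b1 = ipv * rng.normal(0.0, growth_link.slope_sd)
        noise = ipv * growth_link.noise_sd * _smooth_noise(
            rng, case.baseline.grid_shape, growth_link.noise_corr_len
        )
        rate = growth_link.intercept + b0 + (growth_link.slope + b1) * tension + noise
        growth = GrowthField(values=rate)

        case = apply_growth(
            case,
            growth,
            years=dt,
            rigid=None,
            noise_sd=ipv * followup_noise_sd,
            seed=seed + 1000 + m,
        )
        cases.append(case)
    return cases


def cohort_table(cases: list[PatientCase]):
    """Cohort metadata index as a pandas DataFrame (one row per patient)."""
    import pandas as pd

    rows = []
    for c in cases:
        rows.append(
            {
                "patient_id": c.patient_id,
                "n_circ": c.baseline.n_circ,
                "n_axial": c.baseline.n_axial,
                "systolic_bp_kpa": c.systolic_bp_kpa,
                "dt_years": c.dt_years,
                "inlet_flow_l_min": c.inlet_flow_l_min,
                "flap_extent": c.params.flap_extent,
                "has_thrombus": bool(c.thrombus_mask.any()),
                "lsa_layer": c.baseline.landmark_layers[0],
                "bifurcation_layer": c.baseline.landmark_layers[1],
            }
        )
    return pd.DataFrame(rows)
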