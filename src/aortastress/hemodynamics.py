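"""Reduced-order hemodynamic loading: Murray's-law flow splits, resistance
Windkessel calibration, luminal pressure fields and synthetic wall shear
stress.

This module stands in for a full CFD stage.  Pressure is the quantity that
transfers into the structural solve, so the model produces controllable
pressure fields with the features reported for dissected aortas: a mild
proximal-to-distal pressure drop in the narrow true lumen and a more uniform
false-lumen pressure offset from the true-lumen mean.  Wall shear stress is a
smooth random comparator field in the physiological 1-10 Pa band.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from sklearn.neighbors import NearestNeighbors

from .synthetic import PatientCase, _smooth_noise

__all__ = [
    "OutletSpec",
    "LumenPressureField",
    "WSSField",
    "PressureConfig",
    "WSSConfig",
    "murray_outlet_split",
    "make_outlets",
    "calibrate_windkessel",
    "network_inlet_pressure",
    "lumen_pressure_field",
    "map_pressure_to_solid",
    "sample_wss_field",
]


@dataclass
class OutletSpec:
    """One lumped outlet of the reduced arterial network."""

    outlet_id: str
    diameter_mm: float
    flow_l_min: float = 0.0
    resistance_kpa_min_l: float = 0.0
    distal_pressure_kpa: float = 0.0

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError(f"outlet {self.outlet_id}: diameter must be positive")
        if self.resistance_kpa_min_l < 0:
            raise ValueError(f"outlet {self.outlet_id}: resistance must be >= 0")


@dataclass
class LumenPressureField:
    """Per-node pressure (kPa) on the structured surface grid with lumen labels.

    ``values[a, c]`` is the pressure acting on the luminal face behind node
    (a, c): the true-lumen pressure for TL wall nodes, the false-lumen pressure
    for FL wall nodes.  ``fl_mask`` carries the lumen label; ``thrombosed``
    flags nodes whose luminal face is covered by thrombus (the solver loads the
    thrombus lining there instead of the wall itself).
    """

    values: np.ndarray          # (n_axial, n_circ) kPa
    fl_mask: np.ndarray         # (n_axial, n_circ) bool
    thrombosed: np.ndarray      # (n_axial, n_circ) bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("pressures must be finite and positive")

    def tl_mean(self) -> float:
        return float(self.values[~self.fl_mask].mean())

    def fl_mean(self) -> float:
        return float(self.values[self.fl_mask].mean())


@dataclass
class WSSField:
    """Per-node wall shear stress magnitude (Pa) on the luminal surface."""

    values: np.ndarray  # (n_axial, n_circ) Pa
    band: tuple[float, float] = (0.5, 20.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        lo, hi = self.band
        if not np.all((self.values >= lo) & (self.values <= hi)):
            raise ValueError(f"WSS values outside the physiological band [{lo}, {hi}] Pa")


# ---------------------------------------------------------------------------
# Murray's law and Windkessel calibration
# ---------------------------------------------------------------------------

def murray_outlet_split(diameters_mm, inlet_flow_l_min: float) -> np.ndarray:
    """Split the inlet flow over outlets in proportion to diameter cubed.

    Murray's law: flow_i = Q * d_i^3 / sum_j d_j^3.  The last outlet absorbs
    floating-point rounding so the flows sum to the inlet flow exactly.
    """
    d = np.asarray(diameters_mm, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one outlet diameter")
    if np.any(d <= 0):
        raise ValueError("outlet diameters must be positive")
    if inlet_flow_l_min <= 0:
        raise ValueError("inlet flow must be positive")
    w = d**3
    flows = inlet_flow_l_min * w / w.sum()
    flows[-1] = inlet_flow_l_min - flows[:-1].sum()
    return flows


def make_outlets(diameters_mm, inlet_flow_l_min: float, distal_pressure_kpa: float = 0.0):
    """Build outlet specs with Murray flows assigned (no resistances yet)."""
    flows = murray_outlet_split(diameters_mm, inlet_flow_l_min)
    return [
        OutletSpec(
            outlet_id=f"outlet_{i + 1}",
            diameter_mm=float(d),
            flow_l_min=float(q),
            distal_pressure_kpa=distal_pressure_kpa,
        )
        for i, (d, q) in enumerate(zip(diameters_mm, flows))
    ]


def calibrate_windkessel(outlets: list[OutletSpec], systolic_bp_kpa: float) -> list[OutletSpec]:
    """Set each outlet resistance so the network reproduces the systolic BP.

    With parallel resistance-only outlets fed at a common inlet pressure P and
    prescribed Murray flows Q_i, R_i = (P - P_distal,i) / Q_i makes every
    branch consistent with the measured systolic pressure.
    """
    out = []
    for o in outlets:
        if o.flow_l_min == 0:
            raise ValueError(f"outlet {o.outlet_id} carries zero flow; cannot calibrate")
        if systolic_bp_kpa < o.distal_pressure_kpa:
            raise ValueError("systolic BP must exceed the distal reference pressure")
        r = (systolic_bp_kpa - o.distal_pressure_kpa) / o.flow_l_min
        out.append(replace(o, resistance_kpa_min_l=r))
    return out


def network_inlet_pressure(outlets: list[OutletSpec]) -> float:
    """Re-evaluate the calibrated network: inlet pressure implied by the outlets.

    Each branch gives P = P_distal,i + R_i Q_i; the network value is their
    flow-weighted mean (identical across branches after calibration).
    """
    p = np.array([o.distal_pressure_kpa + o.resistance_kpa_min_l * o.flow_l_min for o in outlets])
    q = np.array([o.flow_l_min for o in outlets])
    return float(np.average(p, weights=q))


# ---------------------------------------------------------------------------
# luminal pressure field
# ---------------------------------------------------------------------------

@dataclass
class PressureConfig:
    """Controls for the reduced-order luminal pressure model."""

    tl_drop_fraction: float = 0.05   # total TL proximal-to-distal drop, fraction of systolic
    tl_drop_exponent: float = 1.0    # 1.0 = linear decline along the axial coordinate
    fl_offset_kpa: float = -0.76     # FL uniform pressure minus the TL mean
    distal_pressure_kpa: float = 0.0


def lumen_pressure_field(case: PatientCase, config: PressureConfig | None = None) -> LumenPressureField:
    """Spatially varying luminal pressure on the structured grid.

    The true-lumen pressure declines from the Windkessel-calibrated inlet value
    (the systolic BP) along the axial coordinate with a configurable total drop
    and exponent; the false-lumen pressure is uniform at a configurable offset
    from the true-lumen mean.  Flap faces receive their adjacent lumen's
    pressure (handled by the solver via the lumen labels).  Thrombosed nodes
    are flagged so the thrombus lining is loaded instead of the wall.
    """
    if config is None:
        config = PressureConfig()
    if case.systolic_bp_kpa is None or case.systolic_bp_kpa <= 0:
        raise ValueError("case is missing a positive systolic blood pressure")
    if case.inlet_flow_l_min is None or case.inlet_flow_l_min <= 0:
        raise ValueError("case is missing a positive inlet flow")

    outlets = make_outlets(
        case.params.outlet_diameters, case.inlet_flow_l_min, config.distal_pressure_kpa
    )
    outlets = calibrate_windkessel(outlets, case.systolic_bp_kpa)
    p_inlet = network_inlet_pressure(outlets)

    na, nc = case.baseline.grid_shape
    x = np.linspace(0.0, 1.0, na)[:, None]
    tl = p_inlet * (1.0 - config.tl_drop_fraction * x**config.tl_drop_exponent)
    values = np.broadcast_to(tl, (na, nc)).copy()

    fl_mask = case.fl_node_mask
    if fl_mask.any():
        values[fl_mask] = values[~fl_mask].mean() + config.fl_offset_kpa

    thr = case.thrombus_mask
    thrombosed = np.zeros((na, nc), dtype=bool)
    thrombosed[:-1] |= thr | np.roll(thr, 1, axis=1)
    thrombosed[1:] |= thr | np.roll(thr, 1, axis=1)

    return LumenPressureField(values=values, fl_mask=fl_mask.copy(), thrombosed=thrombosed)


def map_pressure_to_solid(
    source_points: np.ndarray,
    source_values: np.ndarray,
    target_points: np.ndarray,
    k: int = 4,
    power: float = 2.0,
    max_distance: float = 2.0,
) -> tuple[np.ndarray, int]:
    """Inverse-distance-weighted interpolation of a surface field onto a mesh.

    Interpolates from the ``k`` nearest source nodes with weights 1/d^power;
    exact at coincident nodes and constant-preserving.  Returns the target
    values and the count of extrapolated targets (nearest source farther than
    ``max_distance`` mm, the nominal mesh element size), which callers should
    surface as a warning.
    """
    source_points = np.asarray(source_points, float).reshape(-1, 3)
    source_values = np.asarray(source_values, float).ravel()
    if source_points.shape[0] == 0:
        raise ValueError("empty source field")
    if source_points.shape[0] != source_values.shape[0]:
        raise ValueError("source points/values length mismatch")
    target_points = np.asarray(target_points, float).reshape(-1, 3)

    k = min(k, source_points.shape[0])
    nn = NearestNeighbors(n_neighbors=k).fit(source_points)
    dist, idx = nn.kneighbors(target_points)

    exact = dist[:, 0] < 1e-12
    with np.errstate(divide="ignore"):
        w = 1.0 / dist**power
    w[exact] = 0.0
    w[exact, 0] = 1.0
    values = (w * source_values[idx]).sum(axis=1) / w.sum(axis=1)
    n_extrapolated = int(np.count_nonzero(dist[:, 0] > max_distance))
    return values, n_extrapolated


# ---------------------------------------------------------------------------
# synthetic wall shear stress comparator
# ---------------------------------------------------------------------------

@dataclass
class WSSConfig:
    """Controls for the synthetic wall shear stress field."""

    band: tuple[float, float] = (1.0, 10.0)   # target Pa band of the generated field
    physiological_band: tuple[float, float] = (0.5, 20.0)
    corr_len: float = 6.0                     # grid units
    fenestration_factor: float = 1.8          # elevation factor near fenestrations
    fenestration_halo: float = 4.0            # grid units, extent of the elevation


def sample_wss_field(case: PatientCase, config: WSSConfig | None = None, seed: int = 0) -> WSSField:
    """Smooth random wall-shear-stress field scaled into the target band.

    The field is a correlated Gaussian random field on the grid, elevated near
    flap fenestrations (jet impingement region), then min-max scaled into the
    configured band.  It is a comparator predictor for the statistics stage,
    not a flow solution.
    """
    if config is None:
        config = WSSConfig()
    lo, hi = config.band
    if lo > hi:
        raise ValueError("WSS band is inverted")

    na, nc = case.baseline.grid_shape
    rng = np.random.default_rng(seed)
    f = _smooth_noise(rng, (na, nc), config.corr_len)

    if case.flap is not None and config.fenestration_factor != 1.0:
        bump = np.zeros((na, nc))
        open_q = case.flap.open_quads
        f0, _ = case.flap.span
        k_att = case.flap.attach_indices[0]
        for i, j in zip(*np.nonzero(open_q)):
            layer = f0 - 1 + i
            # elevate around the attachment-side wall ring at the tear's layer
            bump[layer, :] += 1.0
        if bump.any():
            bump = gaussian_filter(bump, sigma=config.fenestration_halo, mode=("nearest", "wrap"))
            bump /= bump.max()
            f = f + (config.fenestration_factor - 1.0) * bump * (f.std() + 1.0)

    if hi == lo:
        values = np.full((na, nc), lo)
    else:
        fmin, fmax = f.min(), f.max()
        if fmax - fmin < 1e-15:
            values = np.full((na, nc), 0.5 * (lo + hi))
        else:
            values = lo + (hi - lo) * (f - fmin) / (fmax - fmin)
    return WSSField(values=values, band=config.physiological_band)
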