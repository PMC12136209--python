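"""Reduced-order loading: Murray splits, Windkessel calibration, pressure and
WSS fields, and the surface-to-solid interpolation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aortastress import make_dissected_aorta
from aortastress.hemodynamics import (
    PressureConfig,
    WSSConfig,
    calibrate_windkessel,
    lumen_pressure_field,
    make_outlets,
    map_pressure_to_solid,
    murray_outlet_split,
    network_inlet_pressure,
    sample_wss_field,
)


class TestMurraySplit:
    @pytest.mark.parametrize(
        "diameters,flow,expected",
        [
            ([3.0, 3.0, 3.0], 25.0, [25 / 3] * 3),   # symmetry
            ([1.0, 2.0], 9.0, [1.0, 8.0]),           # d^3 ratio 1:8
            ([7.0], 25.0, [25.0]),                   # conservation, single outlet
        ],
    )
    def test_known_splits(self, diameters, flow, expected):
        assert np.allclose(murray_outlet_split(diameters, flow), expected)

    @given(
        st.lists(st.floats(0.5, 30.0), min_size=1, max_size=12),
        st.floats(0.1, 60.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_flow_conservation_property(self, diameters, flow):
        flows = murray_outlet_split(diameters, flow)
        assert flows.sum() == pytest.approx(flow, abs=1e-12)
        assert np.all(flows >= 0)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            murray_outlet_split([], 10.0)
        with pytest.raises(ValueError):
            murray_outlet_split([1.0, -2.0], 10.0)


class TestWindkessel:
    def test_known_resistance(self):
        # one 9 L/min outlet at 18.36 kPa systolic, zero distal pressure
        outlets = make_outlets([9.0], 9.0)
        out = calibrate_windkessel(outlets, 18.36)
        assert out[0].resistance_kpa_min_l == pytest.approx(2.04)

    def test_distal_equal_to_bp_gives_zero_resistance(self):
        outlets = make_outlets([5.0, 8.0], 20.0, distal_pressure_kpa=15.0)
        out = calibrate_windkessel(outlets, 15.0)
        assert all(o.resistance_kpa_min_l == 0.0 for o in out)

    @given(st.floats(10.0, 25.0), st.integers(1, 8))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_calibration_round_trip(self, bp, n_outlets):
        diam = np.linspace(4.0, 12.0, n_outlets)
        outlets = calibrate_windkessel(make_outlets(diam, 25.0), bp)
        assert network_inlet_pressure(outlets) == pytest.approx(bp, rel=1e-9)


class TestLumenPressureField:
    def test_no_drop_no_offset_is_uniform_systolic(self, default_case):
        cfg = PressureConfig(tl_drop_fraction=0.0, fl_offset_kpa=0.0)
        field = lumen_pressure_field(default_case, cfg)
        assert np.allclose(field.values, default_case.systolic_bp_kpa)

    def test_default_tl_fl_mean_gap(self, default_case):
        field = lumen_pressure_field(default_case)
        assert field.tl_mean() - field.fl_mean() == pytest.approx(0.76, abs=1e-6)

    def test_configured_axial_drop(self, default_case):
        cfg = PressureConfig(tl_drop_fraction=0.10, tl_drop_exponent=1.0)
        field = lumen_pressure_field(default_case)
        field10 = lumen_pressure_field(default_case, cfg)
        tl = ~field10.fl_mask
        proximal = field10.values[0][tl[0]].mean()
        distal = field10.values[-1][tl[-1]].mean()
        assert proximal - distal == pytest.approx(0.10 * default_case.systolic_bp_kpa)

    def test_thrombosed_nodes_flagged(self, default_case):
        field = lumen_pressure_field(default_case)
        assert field.thrombosed.any()
        # thrombosed nodes are confined to the false-lumen sector (plus the
        # one-node rim that incident thrombosed quads touch)
        assert field.thrombosed.sum() < 1.5 * field.fl_mask.sum()


class TestMapPressureToSolid:
    def test_constant_field_preserved_exactly(self):
        rng = np.random.default_rng(0)
        src = rng.uniform(-1, 1, (200, 3))
        tgt = rng.uniform(-1, 1, (50, 3))
        vals, n_extrap = map_pressure_to_solid(src, np.full(200, 17.6), tgt)
        assert np.allclose(vals, 17.6)

    def test_exact_at_coincident_nodes(self):
        rng = np.random.default_rng(1)
        src = rng.uniform(-1, 1, (100, 3))
        field = rng.uniform(10, 20, 100)
        vals, _ = map_pressure_to_solid(src, field, src.copy())
        assert np.allclose(vals, field)

    def test_linear_field_interpolated_within_one_percent(self):
        # dense source grid, coarse target: axially linear field
        xs = np.linspace(0, 10, 60)
        ys = np.linspace(0, 10, 60)
        gx, gy = np.meshgrid(xs, ys)
        src = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
        field = 10.0 + 0.5 * src[:, 0]
        rng = np.random.default_rng(2)
        tgt = np.column_stack([rng.uniform(1, 9, 40), rng.uniform(1, 9, 40), np.zeros(40)])
        vals, _ = map_pressure_to_solid(src, field, tgt)
        expected = 10.0 + 0.5 * tgt[:, 0]
        assert np.abs(vals - expected).max() < 0.01 * (field.max() - field.min())

    def test_empty_source_raises_and_extrapolation_counted(self):
        with pytest.raises(ValueError, match="empty"):
            map_pressure_to_solid(np.zeros((0, 3)), np.zeros(0), np.zeros((5, 3)))
        src = np.zeros((4, 3))
        tgt = np.array([[10.0, 0, 0]])
        _, n_extrap = map_pressure_to_solid(src, np.ones(4), tgt, max_distance=2.0)
        assert n_extrap == 1


class TestWSSField:
    def test_degenerate_band_gives_constant_field(self, default_case):
        f = sample_wss_field(default_case, WSSConfig(band=(5.0, 5.0)))
        assert np.allclose(f.values, 5.0)

    def test_default_band_respected(self, default_case):
        f = sample_wss_field(default_case, seed=3)
        assert f.values.min() >= 1.0
        assert f.values.max() <= 10.0

    def test_seeded_determinism(self, default_case):
        a = sample_wss_field(default_case, seed=11)
        b = sample_wss_field(default_case, seed=11)
        assert np.array_equal(a.values, b.values)

    def test_inverted_band_rejected(self, default_case):
        with pytest.raises(ValueError, match="inverted"):
            sample_wss_field(default_case, WSSConfig(band=(10.0, 1.0)))
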