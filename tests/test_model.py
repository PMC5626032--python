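"""Scaling, depth transform, decay kernel, rate conversion, Stokes law."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sinkassay import (
    StokesParams,
    depth_transform,
    forward_scaled,
    scale_rfu,
    slope_to_rate,
    stokes_velocity,
)


class TestScaleRfu:
    def test_maps_bounds_to_unit_interval(self):
        tr = scale_rfu([0, 10, 20, 30], [10.0, 6.0, 4.0, 2.0])
        assert tr.scaled.max() == 1.0
        assert tr.scaled.min() == 0.0
        np.testing.assert_allclose(tr.scaled, [1.0, 0.5, 0.25, 0.0])
        assert tr.rfu_min == 2.0 and tr.rfu_max == 10.0

    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError, match="no fluorescence decline"):
            scale_rfu([0, 1, 2, 3], [5.0, 5.0, 5.0, 5.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            scale_rfu([0, 1, 2], [3.0, 2.0, 1.0])

    def test_nan_reads_dropped_pairwise(self):
        tr = scale_rfu([0, 5, 10, 15, 20], [10, np.nan, 6, 4, 2])
        assert tr.times.tolist() == [0, 10, 15, 20]
        assert tr.scaled.size == 4

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a=st.floats(0.1, 100),
        b=st.floats(-50, 50),
        seed=st.integers(0, 2**16),
    )
    def test_affine_invariance(self, a, b, seed):
        """Scaling is invariant to positive affine transforms of the RFU."""
        rng = np.random.default_rng(seed)
        rfu = rng.uniform(1, 100, 12)
        rfu[0], rfu[-1] = 120.0, 0.5  # guarantee a decline
        t = np.arange(12.0)
        ref = scale_rfu(t, rfu).scaled
        tra = scale_rfu(t, a * rfu + b).scaled
        np.testing.assert_allclose(tra, ref, atol=1e-12)

    def test_early_minimum_flagged(self):
        rfu = np.array([10.0, 8, 1, 5, 4.5, 4.4, 4.3, 4.2, 4.1, 4.05])
        assert scale_rfu(np.arange(10.0), rfu).early_min
        declining = np.linspace(10, 1, 10)
        assert not scale_rfu(np.arange(10.0), declining).early_min


class TestDepthTransform:
    @pytest.mark.parametrize(
        "scaled,expected",
        [(1.0, 3.8), (0.25, 1.9), (0.0, 0.0)],
    )
    def test_sqrt_times_depth(self, scaled, expected):
        assert depth_transform(np.array([scaled]), 3.8)[0] == pytest.approx(expected)

    def test_negative_scaled_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            depth_transform(np.array([-0.1]), 3.8)


class TestForwardScaled:
    def test_unity_at_time_zero(self):
        for s in (0.0, 0.01, 1.0):
            assert forward_scaled(0.0, s) == 1.0

    def test_closed_form_value(self):
        assert forward_scaled(10.0, 0.01) == pytest.approx(1.0 / 1.1**2)
        assert forward_scaled(10.0, 0.1) == pytest.approx(0.25)

    def test_strictly_decreasing(self):
        t = np.linspace(0, 100, 200)
        v = forward_scaled(t, 0.05)
        assert np.all(np.diff(v) < 0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(t=st.floats(0, 500), s=st.floats(0, 1))
    def test_sqrt_identity(self, t, s):
        """sqrt of the inverse-square kernel is the simple hyperbola."""
        assert np.sqrt(forward_scaled(t, s)) == pytest.approx(
            1.0 / (1.0 + t * s), rel=1e-12
        )

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(ts=st.floats(0, 0.999))
    def test_linearization_remainder_bound(self, ts):
        """|(1 - ts) - 1/(1+ts)| <= (ts)^2 (geometric-series remainder)."""
        assert abs((1 - ts) - 1.0 / (1 + ts)) <= ts**2 + 1e-15


class TestSlopeToRate:
    def test_zero_slope(self):
        assert slope_to_rate(0.0) == 0.0

    def test_unit_conversion(self):
        # 1 mm/min * 1440 min/d / 1000 mm/m
        assert slope_to_rate(1.0) == pytest.approx(1.44)

    def test_scaled_slope_multiplied_by_depth(self):
        assert slope_to_rate(0.01, depth_mm=3.8) == pytest.approx(0.01 * 3.8 * 1.44)

    def test_linearity(self):
        assert slope_to_rate(0.06) == pytest.approx(3 * slope_to_rate(0.02))

    def test_small_diatom_literature_scale(self):
        # 0.01875 mm/min corresponds to ~0.027 m/d, a typical small-diatom rate
        assert slope_to_rate(0.01875) == pytest.approx(0.027)

    def test_negative_magnitude_rejected(self):
        with pytest.raises(ValueError):
            slope_to_rate(-0.1)


class TestStokes:
    def test_neutral_buoyancy(self):
        p = StokesParams(r=1e-5, rho_particle=1025.0, rho_water=1025.0, eta=1e-3)
        assert stokes_velocity(p) == 0.0

    def test_quadratic_in_radius(self):
        p1 = StokesParams(r=5e-6, rho_particle=1100, rho_water=1000, eta=1e-3)
        p2 = StokesParams(r=1e-5, rho_particle=1100, rho_water=1000, eta=1e-3)
        assert stokes_velocity(p2) == pytest.approx(4 * stokes_velocity(p1))

    def test_closed_form_value(self):
        p = StokesParams(r=5e-6, rho_particle=1100, rho_water=1000, eta=1e-3, phi=1.0)
        assert stokes_velocity(p) == pytest.approx(5.444e-6, rel=1e-3)

    def test_form_resistance_slows_sinking(self):
        p1 = StokesParams(r=5e-6, rho_particle=1100, rho_water=1000, eta=1e-3, phi=1.0)
        p2 = StokesParams(r=5e-6, rho_particle=1100, rho_water=1000, eta=1e-3, phi=2.0)
        assert stokes_velocity(p2) == pytest.approx(stokes_velocity(p1) / 2)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            StokesParams(r=-1e-6, rho_particle=1100, rho_water=1000, eta=1e-3)
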