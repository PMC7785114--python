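"""Sliding-window regression dynamics against closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from auda.dynamics import (
    compute_dynamics,
    effective_window,
    first_order_dynamics,
    median3,
    second_order_dynamics,
    window_slope,
    window_span_seconds,
)
from auda.types import IntensitySeries


def make_series(values, fps=50.0):
    values = np.asarray(values, dtype=float)
    return IntensitySeries(values=values, timestamps=np.arange(len(values)) / fps, fps=fps)


class TestMedian3:
    def test_spike_removed(self):
        assert median3(np.array([1.0, 9.0, 1.0])).tolist() == [1.0, 1.0, 1.0]

    def test_monotone_invariant(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        assert median3(v).tolist() == v.tolist()

    def test_matches_sort_based_oracle(self, rng):
        v = rng.normal(size=100)
        padded = np.concatenate([v[:1], v, v[-1:]])
        oracle = np.array(
            [sorted(padded[i : i + 3])[1] for i in range(len(v))]
        )
        np.testing.assert_allclose(median3(v), oracle)

    def test_short_inputs_unchanged(self):
        assert median3(np.array([5.0])).tolist() == [5.0]
        assert median3(np.array([1.0, 2.0])).tolist() == [1.0, 2.0]


class TestWindowSlope:
    def test_exact_linear_signal(self):
        delta, r = window_slope([0.0, 1.0, 2.0], [0.0, 0.02, 0.04])
        assert delta == pytest.approx(50.0)
        assert r == pytest.approx(1.0)

    def test_constant_signal_convention(self):
        delta, r = window_slope([3.0, 3.0, 3.0], [0.0, 0.1, 0.2])
        assert delta == 0.0 and r == 0.0

    def test_matches_linregress_oracle(self, rng):
        for _ in range(50):
            t = np.sort(rng.uniform(0, 1, size=9))
            v = rng.normal(size=9)
            delta, r = window_slope(v, t)
            ref = stats.linregress(t, v)
            assert delta == pytest.approx(ref.slope, abs=1e-10)
            assert r == pytest.approx(ref.rvalue, abs=1e-10)


class TestFirstOrderDynamics:
    def test_constant_series_zero_everywhere(self):
        dyn = first_order_dynamics(make_series(np.full(60, 0.4)), omega=9)
        assert np.all(dyn.slope == 0.0)
        assert np.all(dyn.reg_coef == 0.0)

    def test_ramp_recovers_slope_at_all_frames(self):
        # replicated boundary (t, v) pairs stay on the trend line, so even
        # edge windows recover the exact slope
        s = 0.7
        series = make_series(s * np.arange(80) / 50.0)
        dyn = first_order_dynamics(series, omega=9)
        np.testing.assert_allclose(dyn.slope, s, atol=1e-9)
        np.testing.assert_allclose(dyn.reg_coef, 1.0, atol=1e-9)

    def test_length_preserved(self, rng):
        v = rng.normal(size=37)
        dyn = first_order_dynamics(make_series(v), omega=9)
        assert len(dyn.slope) == len(dyn.reg_coef) == len(dyn.r_adjusted) == 37

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            first_order_dynamics(make_series(np.zeros(20)), omega=8)

    def test_r_adjusted_definition(self, rng):
        v = rng.normal(size=50)
        dyn = first_order_dynamics(make_series(v), omega=9)
        np.testing.assert_allclose(dyn.r_adjusted, dyn.slope * np.abs(dyn.reg_coef))
        assert np.all(np.abs(dyn.r_adjusted) <= np.abs(dyn.slope) + 1e-15)
        assert np.all(np.abs(dyn.reg_coef) <= 1.0)

    def test_time_shift_equivariance(self, rng):
        v = rng.normal(size=40)
        a = first_order_dynamics(make_series(v), omega=9)
        shifted = IntensitySeries(values=v, timestamps=np.arange(40) / 50.0 + 123.0, fps=50.0)
        b = first_order_dynamics(shifted, omega=9)
        np.testing.assert_allclose(a.slope, b.slope, atol=1e-8)
        np.testing.assert_allclose(a.reg_coef, b.reg_coef, atol=1e-10)

    def test_scale_covariance(self, rng):
        v = rng.normal(size=40)
        a = first_order_dynamics(make_series(v), omega=9)
        b = first_order_dynamics(make_series(3.5 * v), omega=9)
        np.testing.assert_allclose(b.slope, 3.5 * a.slope, rtol=1e-10)
        np.testing.assert_allclose(b.reg_coef, a.reg_coef, atol=1e-10)


class TestSecondOrderDynamics:
    def test_linear_ramp_zero_second_order(self):
        series = make_series(0.3 * np.arange(60) / 50.0)
        dyn = compute_dynamics(series, omega=9)
        np.testing.assert_allclose(dyn.second_order, 0.0, atol=1e-8)

    def test_quadratic_recovers_curvature(self):
        a = 0.4
        t = np.arange(200) / 50.0
        series = make_series(a * t**2)
        dyn = first_order_dynamics(series, omega=9)
        d2 = second_order_dynamics(dyn, series.timestamps)
        interior = d2[20:-20]
        np.testing.assert_allclose(interior, 2 * a, rtol=0.05)

    def test_concave_peak_negative_curvature(self):
        t = np.arange(100) / 50.0
        series = make_series(-((t - 1.0) ** 2))
        dyn = compute_dynamics(series, omega=9)
        assert np.all(dyn.second_order[10:-10] < 0)


class TestEffectiveWindow:
    @pytest.mark.parametrize(
        "omega_ref,fps,expected",
        [(27, 50, 27), (9, 50, 9), (15, 50, 15), (9, 25, 5), (27, 25, 13), (27, 100, 53)],
    )
    def test_span_preserving_rescale(self, omega_ref, fps, expected):
        assert effective_window(omega_ref, fps) == expected

    def test_result_always_odd_and_clamped(self):
        with pytest.warns(UserWarning):
            assert effective_window(3, 10) == 3

    @pytest.mark.parametrize("omega,fps,span_ms", [(9, 50, 160), (15, 50, 280), (27, 50, 520)])
    def test_window_spans_at_reference_rate(self, omega, fps, span_ms):
        assert window_span_seconds(omega, fps) * 1000 == pytest.approx(span_ms)


finite_values = st.lists(
    st.floats(min_value=-10, max_value=10, allow_nan=False), min_size=3, max_size=60
)


@settings(max_examples=50, derandomize=True)
@given(finite_values)
def test_median3_bounded_by_local_extremes(values):
    """Each filtered value lies within its 3-frame neighborhood."""
    v = np.array(values)
    out = median3(v)
    assert len(out) == len(v)
    padded = np.concatenate([v[:1], v, v[-1:]])
    for i in range(len(v)):
        lo, hi = padded[i : i + 3].min(), padded[i : i + 3].max()
        assert lo <= out[i] <= hi


@settings(max_examples=50, derandomize=True)
@given(finite_values, st.integers(min_value=1, max_value=13))
def test_regression_coefficient_always_bounded(values, half):
    """|r| <= 1 and |r-adjusted slope| <= |slope| for arbitrary signals."""
    omega = 2 * half + 1
    dyn = first_order_dynamics(make_series(values), omega)
    assert np.all(np.abs(dyn.reg_coef) <= 1.0)
    assert np.all(np.abs(dyn.r_adjusted) <= np.abs(dyn.slope) + 1e-12)


def test_windowed_equals_bruteforce_ols(rng):
    """Full-series dynamics equal per-window closed-form regression."""
    v = rng.normal(size=60)
    series = make_series(v)
    omega = 9
    dyn = first_order_dynamics(series, omega)
    vf = median3(v)
    half = omega // 2
    pv = np.concatenate([np.full(half, vf[0]), vf, np.full(half, vf[-1])])
    pt = np.concatenate(
        [np.full(half, series.timestamps[0]), series.timestamps,
         np.full(half, series.timestamps[-1])]
    )
    for i in range(len(v)):
        delta, r = window_slope(pv[i : i + omega], pt[i : i + omega])
        assert dyn.slope[i] == pytest.approx(delta, abs=1e-10)
        assert dyn.reg_coef[i] == pytest.approx(r, abs=1e-10)
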