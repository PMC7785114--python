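"""Multi-scale signal dynamics via sliding-window linear regression.

An intensity signal v(t) is first median-filtered over three consecutive
frames, then a regression line is fitted inside a sliding window of omega
subsequent frames (unit stride, window centered on the output frame).  The
slope delta of that line is the first-order dynamics of the signal; the
in-window correlation r says how well a line fits; delta * |r| down-weights
slopes from poorly linear windows.  Applying the slope pass to delta itself
yields the second-order dynamics delta2.

Window lengths are given at a 50 fps reference rate; `effective_window`
rescales them so the temporal span (omega - 1) / fps is preserved for other
frame rates.
"""

from __future__ import annotations

import warnings

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .types import DynamicsSeries, IntensitySeries

REFERENCE_FPS = 50.0


def median3(v: np.ndarray) -> np.ndarray:
    """Median filter over three consecutive values, edges replicated.

    Length-preserving; a length-1 or length-2 input is returned unchanged
    (replication makes the 3-window median the identity there).
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError("median3 expects a 1-D array")
    if len(v) == 0:
        raise ValueError("median3 requires length >= 1")
    if len(v) < 3:
        return v.copy()
    padded = np.concatenate([v[:1], v, v[-1:]])
    return np.median(sliding_window_view(padded, 3), axis=-1)


def window_slope(v_win: np.ndarray, t_win: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and correlation of one window.

    delta = S_tv / S_tt and r = S_tv / sqrt(S_tt * S_vv), where S are the
    centered cross/auto sums over the window.  A constant-v window has no
    trend evidence: both delta and r are defined as 0.
    """
    v_win = np.asarray(v_win, dtype=float)
    t_win = np.asarray(t_win, dtype=float)
    if len(v_win) != len(t_win) or len(v_win) < 2:
        raise ValueError("window_slope needs two equal-length arrays, length >= 2")
    t_c = t_win - t_win.mean()
    v_c = v_win - v_win.mean()
    s_tt = float(t_c @ t_c)
    s_vv = float(v_c @ v_c)
    s_tv = float(t_c @ v_c)
    if s_tt == 0.0:
        raise ValueError("zero timestamp variance in window")
    # a window constant up to float rounding carries no trend evidence
    if s_vv <= (1e-13 * np.max(np.abs(v_win), initial=0.0)) ** 2 * len(v_win):
        return 0.0, 0.0
    delta = s_tv / s_tt
    r = s_tv / np.sqrt(s_tt * s_vv)
    return delta, float(np.clip(r, -1.0, 1.0))


def _check_omega(omega: int) -> int:
    omega = int(omega)
    if omega < 3 or omega % 2 == 0:
        raise ValueError(f"window length must be an odd integer >= 3, got {omega}")
    return omega


def _windowed_regression(
    v: np.ndarray, t: np.ndarray, omega: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized centered-window slope/correlation with edge replication.

    Both the value and its timestamp are replicated at the edges, so
    replicated points stay on the signal's trend line (a pure ramp keeps
    slope exactly s at every frame, boundaries included).
    """
    half = omega // 2
    n = len(v)
    if n == 1:
        return np.zeros(1), np.zeros(1)
    pad_v = np.concatenate([np.full(half, v[0]), v, np.full(half, v[-1])])
    pad_t = np.concatenate([np.full(half, t[0]), t, np.full(half, t[-1])])
    w_v = sliding_window_view(pad_v, omega)
    w_t = sliding_window_view(pad_t, omega)
    t_c = w_t - w_t.mean(axis=-1, keepdims=True)
    v_c = w_v - w_v.mean(axis=-1, keepdims=True)
    s_tt = np.einsum("ij,ij->i", t_c, t_c)
    s_vv = np.einsum("ij,ij->i", v_c, v_c)
    s_tv = np.einsum("ij,ij->i", t_c, v_c)
    # windows constant up to float rounding carry no trend evidence
    v_scale = np.max(np.abs(w_v), axis=-1)
    nonconst = s_vv > (1e-13 * v_scale) ** 2 * omega
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(nonconst, s_tv / s_tt, 0.0)
        r = np.where(nonconst, s_tv / np.sqrt(s_tt * s_vv), 0.0)
    return delta, np.clip(r, -1.0, 1.0)


def first_order_dynamics(series: IntensitySeries, omega: int) -> DynamicsSeries:
    """Median-filter the signal, then slide the regression window over it.

    Returns per-frame slope delta (intensity/s), correlation r and the
    r-adjusted slope delta * |r|, all of the same length as the input.
    """
    omega = _check_omega(omega)
    v = median3(series.values)
    delta, r = _windowed_regression(v, series.timestamps, omega)
    return DynamicsSeries(
        omega=omega, slope=delta, reg_coef=r, r_adjusted=delta * np.abs(r)
    )


def second_order_dynamics(
    dyn: DynamicsSeries, timestamps: np.ndarray, omega: int | None = None
) -> np.ndarray:
    """Windowed slope of the slope signal (no second median filter).

    Uses the same window length as the first-order pass unless overridden.
    """
    omega = _check_omega(dyn.omega if omega is None else omega)
    d2, _ = _windowed_regression(
        np.asarray(dyn.slope, dtype=float), np.asarray(timestamps, dtype=float), omega
    )
    return d2


def compute_dynamics(series: IntensitySeries, omega: int) -> DynamicsSeries:
    """First-order dynamics with the second-order signal attached."""
    dyn = first_order_dynamics(series, omega)
    dyn.second_order = second_order_dynamics(dyn, series.timestamps)
    return dyn


def effective_window(omega_ref: int, fps: float) -> int:
    """Rescale a 50 fps reference window length to another frame rate.

    Preserves the temporal span: omega' = 2 * floor((omega_ref - 1) * fps
    / 100) + 1, so (omega' - 1) / fps ~ (omega_ref - 1) / 50.  Always odd;
    clamped to 3 (with a warning) when the rate is too low.
    """
    omega_ref = _check_omega(omega_ref)
    if fps <= 0:
        raise ValueError("fps must be positive")
    omega = 2 * int(np.floor((omega_ref - 1) * fps / (2 * REFERENCE_FPS))) + 1
    if omega < 3:
        warnings.warn(
            f"effective window for omega_ref={omega_ref} at {fps} fps "
            "is below 3 frames; clamping to 3",
            stacklevel=2,
        )
        omega = 3
    return omega


def window_span_seconds(omega: int, fps: float) -> float:
    """Temporal span covered by a window of ``omega`` frames at ``fps``."""
    return (omega - 1) / fps
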