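"""Vertical kinematics: double integration and stride-anchored resampling.

Acceleration is integrated twice with the trapezoidal rule per stride
window, removing the per-stride mean of velocity and of displacement (the
integration constants).  For stride-periodic motion the true stride-mean
vertical velocity is zero — the displacement returns to its starting value
— so mean removal recovers the waveform without the distortion a fitted
linear trend would introduce into full-period periodic components.  No
global high-pass filtering is applied: stride anchors are available and the
analysis granularity is per stride.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import CubicSpline

from .core import AxialTrace, StrideWindow

log = logging.getLogger(__name__)


def _window_integral(y: np.ndarray, dy: np.ndarray, t: np.ndarray,
                     start: float, end: float) -> float:
    """Integral of y over the exact interval [start, end] (trapezoid plus
    first-order end panels using the known derivative ``dy``)."""
    total = float(np.trapezoid(y, t))
    d0 = t[0] - start
    if d0 > 0:
        total += d0 * y[0] - 0.5 * d0 ** 2 * dy[0]
    d1 = end - t[-1]
    if d1 > 0:
        total += d1 * y[-1] + 0.5 * d1 ** 2 * dy[-1]
    return total


def _window_mean(y: np.ndarray, dy: np.ndarray, t: np.ndarray,
                 start: float, end: float) -> float:
    """Mean of y over the exact interval [start, end].

    Window boundaries rarely coincide with sample times; a raw sample mean
    is then biased by up to one endpoint sample, which leaks a visible
    linear drift into the integrated displacement.  Exact-window quadrature
    makes the estimate O(h²) accurate regardless of how the window falls on
    the grid.
    """
    return _window_integral(y, dy, t, start, end) / (end - start)


def integrate_displacement(accel: AxialTrace,
                           windows: list[StrideWindow]) -> AxialTrace:
    """Double-integrate vertical acceleration (m/s²) to displacement (mm).

    Each stride window is integrated independently; samples outside every
    window are NaN.  Windows shorter than 4 samples are dropped.
    """
    if accel.kind != "acceleration_mps2":
        raise ValueError(f"expected acceleration trace, got {accel.kind}")
    t = accel.times()
    h = 1.0 / accel.fs_hz
    out = np.full(t.size, np.nan)
    for w in windows:
        i0 = int(np.searchsorted(t, w.start_s, side="left"))
        i1 = int(np.searchsorted(t, w.end_s, side="left"))
        if i1 - i0 < 4:
            log.warning("stride %d dropped: only %d samples", w.index, i1 - i0)
            continue
        tw = t[i0:i1]
        a_mm = accel.samples[i0:i1] * 1000.0
        v = cumulative_trapezoid(a_mm, dx=h, initial=0.0)
        # Stride-periodic motion has zero net velocity change over the
        # stride, so the total acceleration integral is pure drift
        # (sensor bias, discretization error): remove it as a ramp.  A
        # fitted linear trend would instead absorb real within-stride
        # signal.  Endpoint values come from the full trace so the
        # fractional-sample panels at the window edges stay accurate.
        a_full = accel.samples * 1000.0
        grid = np.concatenate([[w.start_s], tw, [w.end_s]])
        vals = np.concatenate([[np.interp(w.start_s, t, a_full)], a_mm,
                               [np.interp(w.end_s, t, a_full)]])
        drift = float(np.trapezoid(vals, grid)) / w.duration_s
        v -= drift * (tw - w.start_s)
        v -= _window_mean(v, a_mm, tw, w.start_s, w.end_s)
        z = cumulative_trapezoid(v, dx=h, initial=0.0)
        z -= _window_mean(z, v, tw, w.start_s, w.end_s)
        out[i0:i1] = z
    return AxialTrace(accel.segment, "displacement_mm", accel.fs_hz, out,
                      accel.t0_s)


@dataclass
class DisplacementStride:
    """One stride of one segment, resampled to a fixed normalized grid."""

    segment: str
    stride_index: int
    window: StrideWindow
    normalized: np.ndarray          # n_points samples over 0..100 % of stride
    raw_t: np.ndarray               # original sample times inside the window
    raw_z: np.ndarray               # original displacement values (mm)
    stance_pct: dict[str, tuple[float, float]]  # limb -> (on, off) % of stride

    @property
    def n_points(self) -> int:
        return self.normalized.size

    def spline(self) -> CubicSpline:
        return CubicSpline(self.raw_t, self.raw_z)


def segment_and_normalize(displacement: AxialTrace,
                          windows: list[StrideWindow],
                          n_points: int = 101) -> list[DisplacementStride]:
    """Resample each stride to ``n_points`` samples spanning 0–100 %StrD.

    Piecewise-cubic interpolation preserves extremum positions that a linear
    scheme would bias.  Stance boundaries are carried along in normalized
    units.  Windows not fully covered by the trace are dropped.
    """
    if displacement.kind != "displacement_mm":
        raise ValueError(f"expected displacement trace, got {displacement.kind}")
    t = displacement.times()
    z = displacement.samples
    strides = []
    for w in windows:
        i0 = int(np.searchsorted(t, w.start_s, side="left"))
        i1 = int(np.searchsorted(t, w.end_s, side="left"))
        if i0 >= i1 or i1 > t.size or w.end_s > t[-1] + 1e-12:
            log.warning("stride %d dropped: window beyond trace", w.index)
            continue
        # In-window samples only: neighbouring strides carry their own
        # integration offsets, so bracketing samples would distort the fit.
        # The sub-sample gap to the exact window end is spline-extrapolated.
        raw_t, raw_z = t[i0:i1], z[i0:i1]
        if not np.isfinite(raw_z).all() or raw_t.size < 4:
            log.warning("stride %d dropped: trace not covered", w.index)
            continue
        grid = w.start_s + w.duration_s * np.linspace(0.0, 1.0, n_points)
        zi = CubicSpline(raw_t, raw_z)(grid)
        zi = zi - zi.mean()
        stance = {limb: w.stance_pct(limb) for limb in w.onsets}
        strides.append(DisplacementStride(
            segment=displacement.segment, stride_index=w.index, window=w,
            normalized=zi, raw_t=raw_t, raw_z=raw_z, stance_pct=stance))
    return strides
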