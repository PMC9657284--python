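"""Synthetic gait generator: footfalls, limb signals and axial sensor traces.

A trial is built from a :class:`~hoofbeat.templates.GaitTemplate`.  Footfall
times realize the template's stride duration, stance durations and
dissociation geometry exactly (before optional per-stride jitter).  Each
axial segment's vertical displacement is a chain of quintic-smoothstep arcs
joining the prescribed per-stride extrema, giving a twice-per-stride
oscillation that is C²-smooth, places every minimum and maximum exactly at
the template's stance-referenced phase, and is exactly periodic under a
half-stride shift when asymmetry and noise are zero.  The emitted
acceleration is the analytic second derivative of the ground-truth
displacement (plus optional seeded measurement noise), so the analysis
pipeline's double integration can be validated against the truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import AxialTrace, LimbEventSeries, LimbSignal
from .templates import (GaitTemplate, SEGMENTS, TemplateError, iqr_to_sd,
                        _validate_waveform_geometry)

log = logging.getLogger(__name__)

_ASYM_KEYS = {"head": ("HDmin", "HDmax"),
              "withers": ("WDmin", "WDmax"),
              "pelvis": ("PDmin", "PDmax")}


def _smoothstep(tau: np.ndarray) -> np.ndarray:
    """Quintic smoothstep: S(0)=0, S(1)=1, S'=S''=0 at both ends."""
    return tau ** 3 * (10.0 - 15.0 * tau + 6.0 * tau ** 2)


def _smoothstep_dd(tau: np.ndarray) -> np.ndarray:
    """Second derivative of the quintic smoothstep."""
    return 60.0 * tau - 180.0 * tau ** 2 + 120.0 * tau ** 3


@dataclass
class Trial:
    """One simulated (or loaded) trial: events, limb signals, axial traces."""

    template: GaitTemplate | None
    events: dict[str, LimbEventSeries]
    limb_signals: dict[str, LimbSignal]
    acceleration: dict[str, AxialTrace]
    displacement_truth: dict[str, AxialTrace]
    truth_extrema: pd.DataFrame | None = None
    # Waveform node lists (time, value, kind, side) per segment; retained so
    # asymmetry can be injected by exact re-synthesis.
    _nodes: dict[str, pd.DataFrame] = field(default_factory=dict, repr=False)
    _accel_noise: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def fs_hz(self) -> float:
        if self.template is not None:
            return self.template.fs_hz
        return next(iter(self.acceleration.values())).fs_hz


def _stride_boundaries(template: GaitTemplate, rng: np.random.Generator,
                       jit: dict[str, float]) -> np.ndarray:
    """Cumulative stride-cell boundaries B_0..B_m (m = n_strides + 2)."""
    m = template.n_strides + 2
    T = template.stride_duration_s
    durs = np.full(m, T)
    if jit["stride_s"] > 0:
        durs = durs + np.clip(rng.normal(0.0, jit["stride_s"], m),
                              -0.4 * T, 0.4 * T)
    return np.concatenate([[0.0], np.cumsum(durs)])


def _jitter_magnitudes(template: GaitTemplate) -> dict[str, float]:
    s = template.jitter_scale
    iqr = template.jitter_iqr
    T = template.stride_duration_s
    out = {
        "stride_s": s * iqr_to_sd(iqr.get("stride_s", 0.0)),
        "stance_fl_s": s * iqr_to_sd(iqr.get("stance_fl_s", 0.0)),
        "stance_hl_s": s * iqr_to_sd(iqr.get("stance_hl_s", 0.0)),
        "event_s": s * iqr_to_sd(iqr.get("lateral_pct", 0.0)) / 100.0 * T,
    }
    for seg in SEGMENTS:
        ref = (template.stance_duration_fl_s if seg != "pelvis"
               else template.stance_duration_hl_s)
        for kind in ("min", "max"):
            key = f"phase_{seg}_{kind}_pct"
            out[(seg, kind, "time_s")] = (
                s * iqr_to_sd(iqr.get(key, 0.0)) / 100.0 * ref)
        # Amplitude scatter has no published IQR; 5 % of ROMz at scale 1.
        out[(seg, "amp_mm")] = s * 0.05 * template.romz_mm[seg]
    return out


def _make_events(template: GaitTemplate, bounds: np.ndarray,
                 rng: np.random.Generator, jit: dict,
                 t_end: float) -> tuple[dict[str, LimbEventSeries],
                                        dict[str, np.ndarray]]:
    """Footfall times per limb.

    Returns the emitted event series (stances fully inside (0, t_end)) and
    the full internal stance set used to build the limb signals.
    """
    phases = template.footfall_phases()
    m = bounds.size - 1
    emitted, internal = {}, {}
    for limb, p in phases.items():
        stance = (template.stance_duration_fl_s if limb in ("LF", "RF")
                  else template.stance_duration_hl_s)
        sd_st = jit["stance_fl_s"] if limb in ("LF", "RF") else jit["stance_hl_s"]
        ons, offs = [], []
        # One extrapolated cell beyond each end so that the limb signal has
        # proper swing phases bracketing the first and last interior stance.
        T = template.stride_duration_s
        for i in range(-1, m + 1):
            if i == -1:
                b0, Ti = bounds[0] - T, T
            elif i == m:
                b0, Ti = bounds[m], T
            else:
                b0, Ti = bounds[i], bounds[i + 1] - bounds[i]
            on = b0 + p / 100.0 * Ti
            if limb != "LH" and jit["event_s"] > 0:
                on += np.clip(rng.normal(0.0, jit["event_s"]),
                              -0.1 * Ti, 0.1 * Ti)
            st = stance
            if sd_st > 0:
                st += np.clip(rng.normal(0.0, sd_st), -0.4 * stance,
                              0.4 * stance)
            ons.append(on)
            offs.append(on + st)
        ons, offs = np.asarray(ons), np.asarray(offs)
        # Jitter may push a hoof-off past the next hoof-on; keep interleaving.
        offs[:-1] = np.minimum(offs[:-1],
                               ons[1:] - 1e-3 * template.stride_duration_s)
        internal[limb] = np.column_stack([ons, offs])
        keep = (ons > 0.0) & (offs < t_end)
        emitted[limb] = LimbEventSeries(limb, ons[keep], offs[keep])
    return emitted, internal


def _make_nodes(template: GaitTemplate, segment: str, bounds: np.ndarray,
                rng: np.random.Generator, jit: dict) -> pd.DataFrame:
    """Extremum node list for one segment over cells -1..m (sorted in time)."""
    ph = template.extremum_stride_phases(segment)
    R = template.romz_mm[segment]
    kmin, kmax = _ASYM_KEYS[segment]
    dmin = template.asymmetry_mm.get(kmin, 0.0)
    dmax = template.asymmetry_mm.get(kmax, 0.0)
    base = {("left", "min"): -R / 2 + dmin / 2,
            ("right", "min"): -R / 2 - dmin / 2,
            ("left", "max"): R / 2 + dmax / 2,
            ("right", "max"): R / 2 - dmax / 2}
    T = template.stride_duration_s
    m = bounds.size - 1
    rows = []
    for cell in range(-1, m + 1):
        if cell == -1:
            b0, Ti = bounds[0] - T, T
        elif cell == m:
            b0, Ti = bounds[m], T
        else:
            b0, Ti = bounds[cell], bounds[cell + 1] - bounds[cell]
        for (side, kind), p in ph.items():
            t = b0 + p / 100.0 * Ti
            v = base[(side, kind)]
            sd_t = jit.get((segment, kind, "time_s"), 0.0)
            sd_v = jit.get((segment, "amp_mm"), 0.0)
            if sd_t > 0:
                t += np.clip(rng.normal(0.0, sd_t), -0.08 * Ti, 0.08 * Ti)
            if sd_v > 0:
                v += np.clip(rng.normal(0.0, sd_v), -0.3 * R, 0.3 * R)
            rows.append((t, v, kind, side, cell))
    nodes = pd.DataFrame(rows, columns=["time_s", "value_mm", "kind",
                                        "side", "cell"])
    nodes = nodes.sort_values("time_s", ignore_index=True)
    kinds = nodes["kind"].to_numpy()
    if (kinds[1:] == kinds[:-1]).any():
        raise TemplateError(
            f"degenerate waveform for {segment}: consecutive extrema of the "
            "same kind; check extremum_phase and jitter settings")
    return nodes


def _eval_nodes(nodes: pd.DataFrame,
                t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Displacement (mm) and its second derivative (mm/s²) at times ``t``."""
    tn = nodes["time_s"].to_numpy()
    vn = nodes["value_mm"].to_numpy()
    idx = np.clip(np.searchsorted(tn, t, side="right") - 1, 0, tn.size - 2)
    t0, t1 = tn[idx], tn[idx + 1]
    v0, v1 = vn[idx], vn[idx + 1]
    L = t1 - t0
    tau = np.clip((t - t0) / L, 0.0, 1.0)
    z = v0 + (v1 - v0) * _smoothstep(tau)
    a = (v1 - v0) / L ** 2 * _smoothstep_dd(tau)
    return z, a


def simulate_trial(template: GaitTemplate,
                   rng: np.random.Generator | None = None) -> Trial:
    """Simulate one trial from a gait template.

    Returns a :class:`Trial` with per-limb hoof events, stylized metapodial
    limb signals, per-segment vertical acceleration (m/s²) and ground-truth
    displacement (mm), plus the table of true per-stride extrema.
    """
    _validate_waveform_geometry(template)
    if rng is None:
        rng = np.random.default_rng(template.seed)
    jit = _jitter_magnitudes(template)
    bounds = _stride_boundaries(template, rng, jit)
    h = 1.0 / template.fs_hz
    n_samp = int(np.floor(bounds[-1] / h))
    t = np.arange(n_samp) * h
    events, internal = _make_events(template, bounds, rng, jit, t[-1])

    displacement, acceleration, node_map, noise_map = {}, {}, {}, {}
    truth_rows = []
    n = template.n_strides
    for seg in SEGMENTS:
        nodes = _make_nodes(template, seg, bounds, rng, jit)
        z, a_mm = _eval_nodes(nodes, t)
        # Zero-mean over the analysis span (stride cells 1..n).
        span = (t >= bounds[1]) & (t < bounds[n + 1])
        offset = float(z[span].mean()) if span.any() else float(z.mean())
        z = z - offset
        nodes["value_mm"] -= offset
        noise = np.zeros_like(a_mm)
        if template.noise_sd_mm > 0:
            w2 = (4.0 * np.pi / template.stride_duration_s) ** 2
            noise = rng.normal(0.0, template.noise_sd_mm * w2, a_mm.shape)
        displacement[seg] = AxialTrace(seg, "displacement_mm",
                                       template.fs_hz, z)
        acceleration[seg] = AxialTrace(seg, "acceleration_mps2",
                                       template.fs_hz,
                                       (a_mm + noise) / 1000.0)
        node_map[seg] = nodes
        noise_map[seg] = noise
        analysis = nodes[(nodes["cell"] >= 1) & (nodes["cell"] <= n)]
        for _, r in analysis.iterrows():
            truth_rows.append((seg, int(r["cell"]) - 1, r["side"], r["kind"],
                               r["time_s"], r["value_mm"]))

    limb_signals = _make_limb_signals(template, internal, t, rng)
    truth = pd.DataFrame(truth_rows, columns=["segment", "stride", "side",
                                              "kind", "time_s", "value_mm"])
    return Trial(template=template, events=events, limb_signals=limb_signals,
                 acceleration=acceleration, displacement_truth=displacement,
                 truth_extrema=truth, _nodes=node_map,
                 _accel_noise=noise_map)


def _make_limb_signals(template: GaitTemplate, internal: dict,
                       t: np.ndarray,
                       rng: np.random.Generator) -> dict[str, LimbSignal]:
    """Stylized metapodial signals: zero in stance, oscillatory burst in swing.

    The swing burst is ``sin(pi*u)**0.3 * cos(6*pi*u)`` in normalized swing
    time u, so the signal departs from and returns to full amplitude within
    a fraction of a sample of the true hoof-off/hoof-on — the surrogate
    detector can localize events to single-sample accuracy.
    """
    out = {}
    for limb, stances in internal.items():
        s = np.zeros_like(t)
        ons, offs = stances[:, 0], stances[:, 1]
        for k in range(len(ons) - 1):
            a, b = offs[k], ons[k + 1]
            if b <= a:
                continue
            m = (t > a) & (t < b)
            u = (t[m] - a) / (b - a)
            s[m] = np.sin(np.pi * u) ** 0.3 * np.cos(6.0 * np.pi * u)
        if template.noise_sd_mm > 0:
            s = s + rng.normal(0.0, 0.01, s.shape)
        out[limb] = LimbSignal(limb, template.fs_hz, s)
    return out


def inject_asymmetry(trial: Trial, deltas: dict[str, float]) -> Trial:
    """Displace alternate minima/maxima of the ground-truth displacement.

    ``deltas`` maps symmetry-index names (HDmin, HDmax, WDmin, WDmax, PDmin,
    PDmax, or "all") to millimetres; the left-referenced extremum moves up
    and the right-referenced one down by half the requested difference, so
    the recomputed symmetry index equals the injected value.  The waveform
    is re-synthesized exactly from the modified node lists, and the
    acceleration trace (including any original noise realization) is kept
    consistent with the new displacement.
    """
    key_to_seg = {k: (seg, kind)
                  for seg, keys in _ASYM_KEYS.items()
                  for k, kind in zip(keys, ("min", "max"))}
    if set(deltas) == {"all"}:
        deltas = {k: deltas["all"] for k in key_to_seg}
    unknown = set(deltas) - set(key_to_seg)
    if unknown:
        raise ValueError(f"unknown asymmetry keys: {sorted(unknown)}")
    missing = {k for k in deltas if key_to_seg[k][0] not in trial.displacement_truth}
    if missing:
        raise ValueError(
            f"deltas for segments not present in trial: {sorted(missing)}")

    new_disp, new_accel, new_nodes = (dict(trial.displacement_truth),
                                      dict(trial.acceleration),
                                      dict(trial._nodes))
    truth = trial.truth_extrema.copy()
    for key, d in deltas.items():
        seg, kind = key_to_seg[key]
        if d == 0.0:
            continue
        nodes = new_nodes[seg].copy()
        sel = nodes["kind"] == kind
        sign = np.where(nodes.loc[sel, "side"] == "left", 0.5, -0.5)
        nodes.loc[sel, "value_mm"] += sign * d
        new_nodes[seg] = nodes
        old = trial.displacement_truth[seg]
        t = old.times()
        z, a_mm = _eval_nodes(nodes, t)
        z = z - (z.mean() - old.samples.mean())  # keep comparable offset
        new_disp[seg] = AxialTrace(seg, "displacement_mm", old.fs_hz, z,
                                   old.t0_s)
        noise = trial._accel_noise.get(seg, 0.0)
        new_accel[seg] = AxialTrace(seg, "acceleration_mps2", old.fs_hz,
                                    (a_mm + noise) / 1000.0, old.t0_s)
        tsel = (truth["segment"] == seg) & (truth["kind"] == kind)
        tsign = np.where(truth.loc[tsel, "side"] == "left", 0.5, -0.5)
        truth.loc[tsel, "value_mm"] += tsign * d

    return replace(trial, displacement_truth=new_disp, acceleration=new_accel,
                   truth_extrema=truth, _nodes=new_nodes)
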