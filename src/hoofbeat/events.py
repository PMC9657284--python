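"""Hoof event handling: surrogate detector and stride pairing.

The study hardware detects hoof-on/off from limb-mounted inertial sensors
with a proprietary algorithm; here a documented surrogate operates on the
stylized metapodial signal (quiet in stance, oscillatory in swing): stance
is declared wherever the rectified signal stays below a configurable
fraction of the per-limb robust amplitude for at least a minimum dwell.
Ground-truth pass-through (``mode="truth"``) is the default analysis path
for simulated data; the detector exists so the pipeline does not depend on
truth labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import LimbEventSeries, LimbSignal, StrideWindow

log = logging.getLogger(__name__)


class DetectionError(ValueError):
    """Signal unusable for event detection."""


@dataclass(frozen=True)
class DetectorConfig:
    quiet_fraction: float = 0.05   # of robust (95th pct) amplitude
    min_stance_s: float = 0.04     # shortest quiet run accepted as stance
    min_gap_s: float = 0.02        # above-threshold blips shorter than this
    # inside a quiet run are ignored


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, stop) runs of True in ``mask``."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    stops = list(np.nonzero(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def detect_events(signal: LimbSignal,
                  config: DetectorConfig | None = None) -> LimbEventSeries:
    """Detect hoof-on/off times from a stylized limb signal.

    Quiet runs at least ``min_stance_s`` long become stance phases; runs
    touching the trace edges are dropped (their true boundary is unseen).
    Raises :class:`DetectionError` for flat signals or when fewer than two
    stances (one stride) are found.
    """
    config = config or DetectorConfig()
    s = np.abs(np.asarray(signal.samples, dtype=float))
    amp = np.percentile(s, 95)
    if amp <= 0 or not np.isfinite(amp):
        raise DetectionError(f"{signal.limb}: no events detected (flat signal)")
    h = 1.0 / signal.fs_hz
    quiet = s < config.quiet_fraction * amp
    min_run = int(round(config.min_stance_s * signal.fs_hz))
    max_blip = int(round(config.min_gap_s * signal.fs_hz))
    # Stance candidates are long quiet runs; brief quiet dips at swing
    # carrier zero-crossings never reach min_stance and stay swing.
    cands = [(a, b) for a, b in _runs(quiet) if b - a >= min_run]
    # A noise spike inside a stance splits it into two long quiet runs
    # separated by a very short active blip; merge those back.
    merged: list[list[int]] = []
    for a, b in cands:
        if merged and a - merged[-1][1] <= max_blip:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    ons, offs = [], []
    for a, b in merged:
        if a == 0 or b == quiet.size:
            continue  # boundary unseen
        ons.append(signal.t0_s + a * h)
        offs.append(signal.t0_s + b * h)
    if len(ons) < 2:
        raise DetectionError(
            f"{signal.limb}: fewer than 2 stances detected; limb excluded")
    return LimbEventSeries(signal.limb, np.array(ons), np.array(offs))


def detect_all(signals: dict[str, LimbSignal],
               config: DetectorConfig | None = None) -> dict[str, LimbEventSeries]:
    out = {}
    for limb, sig in signals.items():
        out[limb] = detect_events(sig, config)
    return out


def pair_strides(events: dict[str, LimbEventSeries]) -> list[StrideWindow]:
    """Split the trial into strides between consecutive left-hind contacts.

    Each half-open window [LH-on_i, LH-on_{i+1}) is annotated with the
    stance of every limb that begins inside it; windows missing any limb's
    contact are dropped with a logged reason.
    """
    if "LH" not in events or events["LH"].n_stances < 2:
        raise DetectionError("left hind limb needs at least 2 contacts "
                             "to define strides")
    lh_on = events["LH"].hoof_on_s
    windows: list[StrideWindow] = []
    for i in range(lh_on.size - 1):
        w = StrideWindow(index=i, start_s=lh_on[i], end_s=lh_on[i + 1])
        ok = True
        for limb, series in events.items():
            sel = np.nonzero((series.hoof_on_s >= w.start_s)
                             & (series.hoof_on_s < w.end_s))[0]
            if sel.size == 0:
                log.warning("stride window %d [%0.3f, %0.3f) dropped: "
                            "no %s contact (reason=missing_limb_event)",
                            i, w.start_s, w.end_s, limb)
                ok = False
                break
            if sel.size > 1:
                log.warning("stride window %d: %d %s contacts, using first",
                            i, sel.size, limb)
            w.onsets[limb] = float(series.hoof_on_s[sel[0]])
            w.offsets[limb] = float(series.hoof_off_s[sel[0]])
        if ok:
            windows.append(w)
    return windows
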