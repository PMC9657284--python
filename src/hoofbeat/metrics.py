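"""Per-stride gait variables: temporal limb measures, extrema, symmetry.

Definitions follow the standard equine gait-analysis conventions:

* stride = time between consecutive left-hind hoof contacts;
* duty factor = stance duration / stride duration, per limb pair
  (left/right averaged within the stride);
* diagonal / lateral dissociation = time between hoof contacts of a
  diagonal / ipsilateral limb pair as a percent of stride duration
  (%StrD), signed positive when the hind hoof lands first, averaged over
  the two pairs of the stride;
* suspension = %StrD during which no hoof is on the ground;
* Hmin/Hmax, Wmin/Wmax, Pmin/Pmax = per-stride lowest/highest vertical
  positions of head, withers and pelvis (two each per stride), timed as a
  percent of the reference-limb stance — forelimb stance for head and
  withers, hindlimb stance for pelvis; values below 0 or above 100 mark
  extrema before hoof contact or after lift-off;
* HDmin/HDmax, WDmin/WDmax, PDmin/PDmax = signed left-minus-right
  difference of the two minima/maxima — the movement-asymmetry indices;
* ROMz = highest minus lowest position of a segment over the stride.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import LimbEventSeries, StrideWindow
from .kinematics import DisplacementStride
from .templates import default_extremum_phase

log = logging.getLogger(__name__)

DIAGONAL_PARTNER = {"LH": "RF", "RH": "LF"}
LATERAL_PARTNER = {"LH": "LF", "RH": "RF"}

#: Straight-line trot inclusion thresholds (mm); "exceeded" is strict.
HEAD_THRESHOLD_MM = 16.0
PELVIS_THRESHOLD_MM = 8.0


def _wrap_half(x: float, period: float) -> float:
    """Wrap to (-period/2, period/2]."""
    y = (x + period / 2.0) % period - period / 2.0
    return period / 2.0 if y == -period / 2.0 else y


@dataclass(frozen=True)
class TemporalVariables:
    stride_duration_s: float
    stance_duration_fl_s: float
    stance_duration_hl_s: float
    swing_duration_fl_s: float
    swing_duration_hl_s: float
    duty_factor_fl: float
    duty_factor_hl: float
    diagonal_dissociation_pct: float | None
    lateral_dissociation_pct: float
    suspension_pct: float


def _pair_dissociation(window: StrideWindow,
                       events: dict[str, LimbEventSeries],
                       partner: dict[str, str]) -> float:
    """Mean signed hind-to-fore contact interval over both pairs (%StrD).

    For each hind limb contact in the window, the fore partner's nearest
    contact (which may fall in a neighbouring window) defines the interval;
    positive when the hind hoof lands first.
    """
    vals = []
    for hind, fore in partner.items():
        t_h = window.onsets[hind]
        fore_ons = events[fore].hoof_on_s
        d = fore_ons - t_h
        vals.append(d[np.argmin(np.abs(d))])
    return 100.0 * float(np.mean(vals)) / window.duration_s


def _union_coverage(intervals: list[tuple[float, float]],
                    start: float, end: float) -> float:
    """Total length of [start, end) covered by the union of intervals."""
    clipped = sorted((max(a, start), min(b, end))
                     for a, b in intervals if b > start and a < end)
    covered, cursor = 0.0, start
    for a, b in clipped:
        if b <= cursor:
            continue
        covered += b - max(a, cursor)
        cursor = max(cursor, b)
    return covered


def temporal_variables(window: StrideWindow,
                       events: dict[str, LimbEventSeries],
                       gait: str | None = None) -> TemporalVariables:
    """Compute all temporal limb variables for one stride window."""
    T = window.duration_s
    st = {limb: window.offsets[limb] - window.onsets[limb]
          for limb in ("LF", "RF", "LH", "RH")}
    stance_fl = 0.5 * (st["LF"] + st["RF"])
    stance_hl = 0.5 * (st["LH"] + st["RH"])
    diag = _pair_dissociation(window, events, DIAGONAL_PARTNER)
    lat = _pair_dissociation(window, events, LATERAL_PARTNER)
    stances = [(on, off) for s in events.values()
               for on, off in zip(s.hoof_on_s, s.hoof_off_s)]
    covered = _union_coverage(stances, window.start_s, window.end_s)
    susp = max(0.0, 100.0 * (T - covered) / T)
    if gait in ("walk", "tolt") and susp > 1.0:
        log.warning("stride %d: suspension %.1f%% inconsistent with %s",
                    window.index, susp, gait)
    return TemporalVariables(
        stride_duration_s=T,
        stance_duration_fl_s=stance_fl,
        stance_duration_hl_s=stance_hl,
        swing_duration_fl_s=T - stance_fl,
        swing_duration_hl_s=T - stance_hl,
        duty_factor_fl=stance_fl / T,
        duty_factor_hl=stance_hl / T,
        diagonal_dissociation_pct=diag,
        lateral_dissociation_pct=lat,
        suspension_pct=susp,
    )


@dataclass
class SegmentExtrema:
    """Both minima and maxima of one segment in one stride."""

    segment: str
    # (side, kind) -> fields; side in {left, right}, kind in {min, max}
    value_mm: dict[tuple[str, str], float] = field(default_factory=dict)
    time_pct_stance: dict[tuple[str, str], float] = field(default_factory=dict)
    time_pct_stride: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass
class ExtremaRecord:
    stride_index: int
    segments: dict[str, SegmentExtrema] = field(default_factory=dict)


class FlatTraceError(ValueError):
    """No strict extrema found (flat displacement trace)."""


def _two_extrema(dense_pct: np.ndarray, dense_z: np.ndarray,
                 minimum: bool) -> list[tuple[float, float]]:
    """The stride's two minima (or maxima): global one, then the best at
    least a quarter stride away (circular distance)."""
    z = dense_z if minimum else -dense_z
    i1 = int(np.argmin(z))
    circ = np.abs((dense_pct - dense_pct[i1] + 50.0) % 100.0 - 50.0)
    mask = circ >= 25.0
    i2 = int(np.flatnonzero(mask)[np.argmin(z[mask])])
    return [(float(dense_pct[i]), float(dense_z[i])) for i in (i1, i2)]


def find_segment_extrema(stride: DisplacementStride,
                         expected_phase: dict[tuple[str, str], float] | None = None,
                         gait: str | None = None,
                         n_dense: int = 2000) -> SegmentExtrema:
    """Locate the stride's two minima and two maxima for one segment.

    The displacement is evaluated on a dense grid through a cubic spline of
    the raw stride window.  Extremum timing is then expressed both as a
    percent of stride and as a percent of the left/right reference-limb
    stance (forelimb for head/withers, hindlimb for pelvis); stance-phase
    values are wrapped to the half-open (−50, +50] %StrD offset around the
    reference contact, so out-of-stance extrema report values below 0 or
    above 100 without half-stride aliasing.

    Left/right assignment: the extremum whose stride phase lies (circularly)
    closest to the expected left phase — from ``expected_phase`` (% of
    reference stance) or, failing that, the built-in per-gait defaults — is
    the left-referenced one.  Without any expectation, the minimum inside
    the half stride starting at the left reference contact is "left", and
    the left maximum is the first maximum after it.
    """
    seg = stride.segment
    ref_left, ref_right = (("LF", "RF") if seg != "pelvis" else ("LH", "RH"))
    dense_pct = np.linspace(0.0, 100.0, n_dense, endpoint=False)
    dur = stride.window.duration_s
    sp = stride.spline()
    dense_z = sp(stride.window.start_s + dense_pct / 100.0 * dur)
    dense_z = dense_z - dense_z.mean()
    if float(dense_z.max() - dense_z.min()) < 1e-9:
        raise FlatTraceError(f"{seg}: flat trace, no strict extrema")

    on_l, off_l = stride.stance_pct[ref_left]
    on_r, off_r = stride.stance_pct[ref_right]
    stance_len = 0.5 * ((off_l - on_l) + (off_r - on_r))

    rec = SegmentExtrema(segment=seg)
    left_min_phase = None
    for kind, minimum in (("min", True), ("max", False)):
        cands = _two_extrema(dense_pct, dense_z, minimum)
        expect = None
        if expected_phase is not None and (seg, kind) in expected_phase:
            expect = expected_phase[(seg, kind)]
        elif gait is not None:
            expect = default_extremum_phase(gait, seg, kind)
        if expect is not None:
            p_exp = (on_l + expect / 100.0 * stance_len) % 100.0
            d0 = abs(_wrap_half(cands[0][0] - p_exp, 100.0))
            d1 = abs(_wrap_half(cands[1][0] - p_exp, 100.0))
            left, right = (cands[0], cands[1]) if d0 <= d1 else (cands[1],
                                                                 cands[0])
        elif kind == "min":
            in_half0 = (cands[0][0] - on_l) % 100.0 < 50.0
            left, right = (cands[0], cands[1]) if in_half0 else (cands[1],
                                                                 cands[0])
        else:
            assert left_min_phase is not None
            after0 = (cands[0][0] - left_min_phase) % 100.0
            after1 = (cands[1][0] - left_min_phase) % 100.0
            left, right = (cands[0], cands[1]) if after0 <= after1 else (
                cands[1], cands[0])
        if kind == "min":
            left_min_phase = left[0]
        for side, (p, v), on in (("left", left, on_l), ("right", right, on_r)):
            # Offset from the reference contact in %StrD, de-aliased to the
            # branch nearest the expected phase when one is known, otherwise
            # to [-25, +75) %StrD (covers every published extremum timing,
            # from just before contact to well past lift-off).
            off0 = (p - on) % 100.0
            if expect is not None:
                target = expect / 100.0 * stance_len
            else:
                target = 25.0
            offset = min((off0 + k * 100.0 for k in (-1, 0, 1)),
                         key=lambda x: abs(x - target))
            rec.value_mm[(side, kind)] = float(v)
            rec.time_pct_stride[(side, kind)] = p
            rec.time_pct_stance[(side, kind)] = 100.0 * offset / stance_len
    return rec


def find_extrema(strides: dict[str, DisplacementStride],
                 expected_phase: dict[tuple[str, str], float] | None = None,
                 gait: str | None = None) -> ExtremaRecord:
    """Extrema of all segments for one stride."""
    idx = next(iter(strides.values())).stride_index
    rec = ExtremaRecord(stride_index=idx)
    for seg, stride in strides.items():
        rec.segments[seg] = find_segment_extrema(stride, expected_phase, gait)
    return rec


@dataclass(frozen=True)
class SymmetryIndices:
    hdmin: float | None
    hdmax: float | None
    wdmin: float | None
    wdmax: float | None
    pdmin: float | None
    pdmax: float | None
    romz_mm: dict[str, float]


def symmetry_indices(record: ExtremaRecord) -> SymmetryIndices:
    """Left-minus-right extremum differences and per-segment ROMz."""
    def diff(seg: str, kind: str) -> float | None:
        if seg not in record.segments:
            return None
        ext = record.segments[seg]
        return ext.value_mm[("left", kind)] - ext.value_mm[("right", kind)]

    romz = {}
    for seg, ext in record.segments.items():
        romz[seg] = (max(ext.value_mm[("left", "max")],
                         ext.value_mm[("right", "max")])
                     - min(ext.value_mm[("left", "min")],
                           ext.value_mm[("right", "min")]))
    return SymmetryIndices(
        hdmin=diff("head", "min"), hdmax=diff("head", "max"),
        wdmin=diff("withers", "min"), wdmax=diff("withers", "max"),
        pdmin=diff("pelvis", "min"), pdmax=diff("pelvis", "max"),
        romz_mm=romz)


@dataclass(frozen=True)
class InclusionDecision:
    include: bool | None          # None = indeterminate (no trot data)
    reasons: tuple[str, ...] = ()


def inclusion_filter(hdmin: float | None, hdmax: float | None,
                     pdmin: float | None, pdmax: float | None,
                     head_threshold_mm: float = HEAD_THRESHOLD_MM,
                     pelvis_threshold_mm: float = PELVIS_THRESHOLD_MM,
                     ) -> InclusionDecision:
    """Straight-line trot soundness screen.

    A horse is excluded when the absolute head minimum/maximum difference
    exceeds 16 mm or the pelvis differences exceed 8 mm ("exceeded" is
    strict: a value exactly at the threshold is retained).  Every violated
    criterion is listed.  With no trot data the decision is indeterminate.
    """
    values = {"HDmin": hdmin, "HDmax": hdmax, "PDmin": pdmin, "PDmax": pdmax}
    if any(v is None for v in values.values()):
        return InclusionDecision(include=None, reasons=("no trot data",))
    reasons = []
    for name, v in values.items():
        thr = head_threshold_mm if name.startswith("H") else pelvis_threshold_mm
        if abs(v) > thr:
            reasons.append(name)
    return InclusionDecision(include=not reasons, reasons=tuple(reasons))
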