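"""Between-segment timing differences of vertical minima and maxima.

For each segment pair (head–withers, head–pelvis, withers–pelvis) and each
extremum kind, the difference in timing is computed per stride in percent
of stride duration, based on the left-hind hoof-on stride split.  Because a
symmetric gait carries two extrema per stride half a stride apart, each
segment's extremum timing is reduced to its first occurrence within the
stride (stride phase modulo 50 %StrD) before differencing; the raw
difference then lives in (−50, +50) and is wrapped to (−50, +50].  The sign
convention is positive when the first-named segment reaches its extremum
first.
"""

from __future__ import annotations

from itertools import combinations

from .metrics import ExtremaRecord, _wrap_half

PAIRS = (("head", "withers"), ("head", "pelvis"), ("withers", "pelvis"))


def phase_differences(record: ExtremaRecord) -> dict[tuple[str, str, str], float]:
    """Pairwise extremum-timing differences for one stride.

    Returns a mapping (segment_a, segment_b, kind) -> signed %StrD,
    positive when ``segment_a`` reaches the extremum first.  Pairs with a
    missing segment are skipped.
    """
    out: dict[tuple[str, str, str], float] = {}
    for a, b in combinations(("head", "withers", "pelvis"), 2):
        if a not in record.segments or b not in record.segments:
            continue
        for kind in ("min", "max"):
            ta = record.segments[a].time_pct_stride[("left", kind)] % 50.0
            tb = record.segments[b].time_pct_stride[("left", kind)] % 50.0
            out[(a, b, kind)] = _wrap_half(tb - ta, 100.0)
    return out
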