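"""Shared data containers for events, traces and stride windows.

All times are absolute seconds from trial start; sample indexing is 0-based.
Conversions to percent of stride or stance happen only in the metrics layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .templates import LIMBS, SEGMENTS


class EventSeriesError(ValueError):
    """Hoof-on/off series violates ordering or interleaving."""


@dataclass
class LimbEventSeries:
    """Ordered hoof-on / hoof-off times for one limb.

    Strictly interleaved: each hoof-on is followed by exactly one hoof-off
    before the next hoof-on, and every stance duration is positive.
    """

    limb: str
    hoof_on_s: np.ndarray
    hoof_off_s: np.ndarray

    def __post_init__(self) -> None:
        if self.limb not in LIMBS:
            raise EventSeriesError(f"unknown limb {self.limb!r}")
        self.hoof_on_s = np.asarray(self.hoof_on_s, dtype=float)
        self.hoof_off_s = np.asarray(self.hoof_off_s, dtype=float)
        if self.hoof_on_s.size != self.hoof_off_s.size:
            raise EventSeriesError(
                f"{self.limb}: {self.hoof_on_s.size} hoof-on vs "
                f"{self.hoof_off_s.size} hoof-off events")
        dur = self.hoof_off_s - self.hoof_on_s
        bad = np.nonzero(dur <= 0)[0]
        if bad.size:
            raise EventSeriesError(
                f"{self.limb}: stance {bad[0]} has hoof-off at "
                f"{self.hoof_off_s[bad[0]]:.6g} s not after hoof-on at "
                f"{self.hoof_on_s[bad[0]]:.6g} s")
        if self.hoof_on_s.size > 1:
            overlap = np.nonzero(self.hoof_on_s[1:] <= self.hoof_off_s[:-1])[0]
            if overlap.size:
                raise EventSeriesError(
                    f"{self.limb}: stance {overlap[0] + 1} begins before "
                    f"stance {overlap[0]} ends (row {overlap[0] + 1})")

    @property
    def n_stances(self) -> int:
        return int(self.hoof_on_s.size)

    def stances(self) -> np.ndarray:
        """(n, 2) array of [on, off] intervals."""
        return np.column_stack([self.hoof_on_s, self.hoof_off_s])


@dataclass
class AxialTrace:
    """Uniformly sampled vertical signal for one axial sensor site."""

    segment: str
    kind: str  # "acceleration_mps2" | "displacement_mm"
    fs_hz: float
    samples: np.ndarray
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        if self.segment not in SEGMENTS:
            raise ValueError(f"unknown segment {self.segment!r}")
        if self.kind not in ("acceleration_mps2", "displacement_mm"):
            raise ValueError(f"unknown trace kind {self.kind!r}")
        self.samples = np.asarray(self.samples, dtype=float)

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.samples.size) / self.fs_hz


@dataclass
class LimbSignal:
    """Stylized metapodial signal: near-zero in stance, oscillatory in swing."""

    limb: str
    fs_hz: float
    samples: np.ndarray
    t0_s: float = 0.0

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self.samples)) / self.fs_hz


@dataclass
class StrideWindow:
    """One stride: half-open interval [LH hoof-on, next LH hoof-on).

    ``onsets``/``offsets`` hold, per limb, the stance that *begins* inside
    the window (the hoof-off may fall beyond the window end).
    """

    index: int
    start_s: float
    end_s: float
    onsets: dict[str, float] = field(default_factory=dict)
    offsets: dict[str, float] = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def onset_pct(self, limb: str) -> float:
        """Hoof-on of ``limb`` in percent of stride."""
        return 100.0 * (self.onsets[limb] - self.start_s) / self.duration_s

    def stance_pct(self, limb: str) -> tuple[float, float]:
        """(hoof-on, hoof-off) of ``limb`` in percent of stride."""
        d = self.duration_s
        return (100.0 * (self.onsets[limb] - self.start_s) / d,
                100.0 * (self.offsets[limb] - self.start_s) / d)
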