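"""Gait templates: published stride parameters for walk, trot, tölt and pace.

The template tables below hold the study-condition defaults for the four
symmetrical equine gaits across three breeds/conditions: Warmblood and
Iberian horses measured in hand, and Icelandic horses measured in hand
(walk, trot) and ridden (walk, trot, tölt, pace).  Stride/stance durations
and limb dissociations are per-gait medians with interquartile ranges;
vertical range of motion (ROMz) per axial segment is in millimetres; the
timing of each segment's vertical minimum/maximum is expressed as percent of
the reference-limb stance phase (forelimb stance for head and withers,
hindlimb stance for pelvis; values below 0 or above 100 denote extrema
before hoof contact or after lift-off).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

GAITS = ("walk", "trot", "tolt", "pace")
CONDITIONS = ("iberian", "icelandic_inhand", "icelandic_ridden", "warmblood")
SEGMENTS = ("head", "withers", "pelvis")
LIMBS = ("LF", "RF", "LH", "RH")

#: IQR -> SD for a normal distribution (1/1.349).
IQR_TO_SD = 0.7413


class TemplateError(ValueError):
    """Invalid gait/condition pair or geometrically impossible template."""


def _v(value: float, iqr: float) -> dict[str, float]:
    return {"value": value, "iqr": iqr}


# Stride parameters: median and IQR per gait x condition.
# Dissociations in percent of stride, signed positive when the hind hoof
# lands before the fore hoof of the pair.  Diagonal dissociation is not
# reported for tölt and pace.
_STRIDE_TABLE: dict[tuple[str, str], dict] = {
    ("walk", "iberian"): dict(
        stride=_v(1.2, 0.15), stance_fl=_v(0.77, 0.13), stance_hl=_v(0.71, 0.12),
        diag=_v(-23.0, 3.0), lat=_v(27.0, 2.9)),
    ("walk", "icelandic_inhand"): dict(
        stride=_v(1.0, 0.20), stance_fl=_v(0.63, 0.13), stance_hl=_v(0.58, 0.14),
        diag=_v(-26.0, 4.0), lat=_v(23.0, 4.0)),
    ("walk", "icelandic_ridden"): dict(
        stride=_v(0.99, 0.13), stance_fl=_v(0.63, 0.11), stance_hl=_v(0.59, 0.075),
        diag=_v(-25.0, 2.7), lat=_v(25.0, 2.4)),
    ("walk", "warmblood"): dict(
        stride=_v(1.3, 0.11), stance_fl=_v(0.85, 0.090), stance_hl=_v(0.74, 0.077),
        diag=_v(-25.0, 2.5), lat=_v(25.0, 2.1)),
    ("trot", "iberian"): dict(
        stride=_v(0.74, 0.037), stance_fl=_v(0.37, 0.051), stance_hl=_v(0.32, 0.042),
        diag=_v(-1.2, 3.5), lat=_v(49.0, 3.6)),
    ("trot", "icelandic_inhand"): dict(
        stride=_v(0.63, 0.083), stance_fl=_v(0.30, 0.052), stance_hl=_v(0.27, 0.028),
        diag=_v(-4.8, 3.3), lat=_v(45.0, 2.9)),
    ("trot", "icelandic_ridden"): dict(
        stride=_v(0.59, 0.085), stance_fl=_v(0.27, 0.060), stance_hl=_v(0.28, 0.047),
        diag=_v(-5.7, 5.4), lat=_v(44.0, 5.5)),
    ("trot", "warmblood"): dict(
        stride=_v(0.78, 0.048), stance_fl=_v(0.38, 0.042), stance_hl=_v(0.31, 0.040),
        diag=_v(-2.6, 4.0), lat=_v(47.0, 4.2)),
    ("tolt", "icelandic_ridden"): dict(
        stride=_v(0.55, 0.068), stance_fl=_v(0.25, 0.061), stance_hl=_v(0.25, 0.054),
        diag=None, lat=_v(18.0, 7.7)),
    ("pace", "icelandic_ridden"): dict(
        stride=_v(0.42, 0.029), stance_fl=_v(0.15, 0.018), stance_hl=_v(0.17, 0.0080),
        diag=None, lat=_v(9.7, 4.3)),
}

# Vertical range of motion (mm) per segment, estimated marginal means for
# in-hand walk and trot.  Tölt and pace ROMz are not tabulated in the source
# tables; Icelandic trot values are reused as generator defaults (documented
# modeling choice), and ridden Icelandic walk/trot reuse the in-hand values.
_ROMZ_TABLE: dict[tuple[str, str], dict[str, float]] = {
    ("walk", "iberian"): {"head": 104.7, "withers": 26.8, "pelvis": 68.0},
    ("walk", "icelandic_inhand"): {"head": 79.3, "withers": 36.0, "pelvis": 65.8},
    ("walk", "icelandic_ridden"): {"head": 79.3, "withers": 36.0, "pelvis": 65.8},
    ("walk", "warmblood"): {"head": 117.1, "withers": 33.4, "pelvis": 78.8},
    ("trot", "iberian"): {"head": 63.7, "withers": 66.2, "pelvis": 70.8},
    ("trot", "icelandic_inhand"): {"head": 60.7, "withers": 46.8, "pelvis": 56.0},
    ("trot", "icelandic_ridden"): {"head": 60.7, "withers": 46.8, "pelvis": 56.0},
    ("trot", "warmblood"): {"head": 78.1, "withers": 92.2, "pelvis": 89.1},
    ("tolt", "icelandic_ridden"): {"head": 60.7, "withers": 46.8, "pelvis": 56.0},
    ("pace", "icelandic_ridden"): {"head": 60.7, "withers": 46.8, "pelvis": 56.0},
}

# Timing of the left-referenced vertical minimum and maximum per segment,
# as percent of the reference-limb stance, median and IQR.
_PHASE_TABLE: dict[tuple[str, str], dict[tuple[str, str], dict]] = {
    ("walk", "iberian"): {
        ("head", "min"): _v(48, 5.4), ("head", "max"): _v(88, 5.6),
        ("withers", "min"): _v(5.3, 14), ("withers", "max"): _v(42, 6.6),
        ("pelvis", "min"): _v(10, 2.5), ("pelvis", "max"): _v(55, 44)},
    ("walk", "warmblood"): {
        ("head", "min"): _v(47, 5.5), ("head", "max"): _v(87, 5.5),
        ("withers", "min"): _v(13, 11), ("withers", "max"): _v(44, 4.8),
        ("pelvis", "min"): _v(7.7, 2.6), ("pelvis", "max"): _v(51, 3.3)},
    ("walk", "icelandic_inhand"): {
        ("head", "min"): _v(46, 4.6), ("head", "max"): _v(86, 3.6),
        ("withers", "min"): _v(4.6, 5.3), ("withers", "max"): _v(48, 5.3),
        ("pelvis", "min"): _v(11, 2.4), ("pelvis", "max"): _v(57, 3.8)},
    ("walk", "icelandic_ridden"): {
        ("head", "min"): _v(46, 5.5), ("head", "max"): _v(88, 4.7),
        ("withers", "min"): _v(3.7, 4.7), ("withers", "max"): _v(45, 6.3),
        ("pelvis", "min"): _v(11, 2.5), ("pelvis", "max"): _v(56, 6.1)},
    ("trot", "iberian"): {
        ("head", "min"): _v(41, 9.4), ("head", "max"): _v(92, 20),
        ("withers", "min"): _v(39, 5.0), ("withers", "max"): _v(91, 6.7),
        ("pelvis", "min"): _v(45, 7.1), ("pelvis", "max"): _v(100, 5.5)},
    ("trot", "warmblood"): {
        ("head", "min"): _v(46, 7.9), ("head", "max"): _v(97, 6.6),
        ("withers", "min"): _v(40, 4.4), ("withers", "max"): _v(92, 4.6),
        ("pelvis", "min"): _v(42, 6.0), ("pelvis", "max"): _v(110, 3.8)},
    ("trot", "icelandic_inhand"): {
        ("head", "min"): _v(39, 5.2), ("head", "max"): _v(92, 9.1),
        ("withers", "min"): _v(42, 5.6), ("withers", "max"): _v(94, 5.6),
        ("pelvis", "min"): _v(41, 6.7), ("pelvis", "max"): _v(100, 6.2)},
    ("trot", "icelandic_ridden"): {
        ("head", "min"): _v(40, 13), ("head", "max"): _v(94, 11),
        ("withers", "min"): _v(41, 9.8), ("withers", "max"): _v(98, 7.5),
        ("pelvis", "min"): _v(37, 5.5), ("pelvis", "max"): _v(92, 5.2)},
    ("tolt", "icelandic_ridden"): {
        ("head", "min"): _v(49, 15), ("head", "max"): _v(4.8, 20),
        ("withers", "min"): _v(39, 13), ("withers", "max"): _v(-0.31, 24),
        ("pelvis", "min"): _v(40, 8.7), ("pelvis", "max"): _v(97, 7.1)},
    ("pace", "icelandic_ridden"): {
        ("head", "min"): _v(27, 12), ("head", "max"): _v(95, 11),
        ("withers", "min"): _v(27, 9.6), ("withers", "max"): _v(99, 14),
        ("pelvis", "min"): _v(41, 13), ("pelvis", "max"): _v(100, 17)},
}

VALID_PAIRS = tuple(sorted(_STRIDE_TABLE))


@dataclass(frozen=True)
class GaitTemplate:
    """Parameter set fully describing one simulated trial.

    ``extremum_phase`` maps (segment, "min"|"max") to percent of the
    reference-limb stance at which the *left-referenced* extremum occurs; the
    right-referenced twin is placed half a stride later.  ``asymmetry_mm``
    displaces the left extremum up and the right extremum down by half the
    requested difference, so the recovered symmetry index (left minus right)
    equals the injected value.
    """

    gait: str
    condition: str
    stride_duration_s: float
    stance_duration_fl_s: float
    stance_duration_hl_s: float
    lateral_dissociation_pct: float
    diagonal_dissociation_pct: float | None
    romz_mm: dict[str, float]
    extremum_phase: dict[tuple[str, str], float]
    n_strides: int = 20
    fs_hz: float = 200.0
    noise_sd_mm: float = 0.0
    jitter_scale: float = 0.0
    asymmetry_mm: dict[str, float] = field(default_factory=dict)
    seed: int | None = None
    # IQR-derived jitter magnitudes, populated by make_template.
    jitter_iqr: dict[str, float] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.gait not in GAITS:
            raise TemplateError(f"unknown gait {self.gait!r}; valid: {GAITS}")
        if self.stride_duration_s <= 0:
            raise TemplateError("stride_duration_s must be > 0")
        for name in ("stance_duration_fl_s", "stance_duration_hl_s"):
            dur = getattr(self, name)
            if not 0 < dur < self.stride_duration_s:
                raise TemplateError(
                    f"{name}={dur} must lie in (0, stride_duration_s); "
                    "stance plus dissociation geometry would imply a "
                    "negative swing duration")
        if self.n_strides < 1:
            raise TemplateError("n_strides must be >= 1")
        if self.fs_hz <= 0:
            raise TemplateError("fs_hz must be > 0")
        if self.noise_sd_mm < 0:
            raise TemplateError("noise_sd_mm must be >= 0")
        for seg in SEGMENTS:
            if self.romz_mm.get(seg, 1.0) <= 0:
                raise TemplateError(f"romz_mm[{seg!r}] must be > 0")
            pmin = self.extremum_phase.get((seg, "min"))
            pmax = self.extremum_phase.get((seg, "max"))
            if pmin is None or pmax is None:
                raise TemplateError(f"extremum_phase missing entries for {seg}")
        bad = set(self.asymmetry_mm) - {"HDmin", "HDmax", "PDmin", "PDmax",
                                        "WDmin", "WDmax"}
        if bad:
            raise TemplateError(f"unknown asymmetry keys: {sorted(bad)}")

    # -- derived geometry -------------------------------------------------

    def footfall_phases(self) -> dict[str, float]:
        """Hoof-on phase of each limb in percent of stride (LH anchored at 0).

        Contralateral limbs are half a stride apart; the left forelimb phase
        is set from the lateral dissociation (and, where reported, averaged
        with the value implied by the diagonal dissociation, since the two
        printed medians are consistent only to rounding).
        """
        lf = self.lateral_dissociation_pct
        if self.diagonal_dissociation_pct is not None:
            lf = 0.5 * (lf + (self.diagonal_dissociation_pct + 50.0))
        return {"LH": 0.0, "RH": 50.0, "LF": lf % 100.0, "RF": (lf + 50.0) % 100.0}

    def reference_stance_pct(self, segment: str) -> tuple[float, float]:
        """(hoof-on phase, stance length) of the left reference limb in %StrD.

        Head and withers timing references the left forelimb stance, pelvis
        the left hindlimb stance.
        """
        ph = self.footfall_phases()
        if segment == "pelvis":
            on, dur = ph["LH"], self.stance_duration_hl_s
        else:
            on, dur = ph["LF"], self.stance_duration_fl_s
        return on, 100.0 * dur / self.stride_duration_s

    def extremum_stride_phases(self, segment: str) -> dict[tuple[str, str], float]:
        """Stride-phase (%StrD, mod 100) of each extremum of one segment.

        Keys are (side, kind) with side in {"left", "right"}.
        """
        on, stance = self.reference_stance_pct(segment)
        out = {}
        for kind in ("min", "max"):
            p = on + self.extremum_phase[(segment, kind)] / 100.0 * stance
            out[("left", kind)] = p % 100.0
            out[("right", kind)] = (p + 50.0) % 100.0
        return out


def make_template(gait: str, condition: str, overrides: dict | None = None,
                  **kwargs) -> GaitTemplate:
    """Build a :class:`GaitTemplate` from the published defaults.

    Parameters
    ----------
    gait : {"walk", "trot", "tolt", "pace"}
    condition : {"iberian", "icelandic_inhand", "icelandic_ridden", "warmblood"}
        Breed/condition column.  Tölt and pace exist only for ridden
        Icelandic horses.
    overrides : dict, optional
        Field-by-field replacements applied to the populated template
        (e.g. ``{"n_strides": 5, "noise_sd_mm": 1.0}``).  Keyword arguments
        are merged with ``overrides``.
    """
    key = (gait, condition)
    if key not in _STRIDE_TABLE:
        raise TemplateError(
            f"no template for gait={gait!r}, condition={condition!r}; "
            f"valid pairs: {', '.join(f'{g}/{c}' for g, c in VALID_PAIRS)}")
    row = _STRIDE_TABLE[key]
    phases = _PHASE_TABLE[key]
    jitter_iqr = {
        "stride_s": row["stride"]["iqr"],
        "stance_fl_s": row["stance_fl"]["iqr"],
        "stance_hl_s": row["stance_hl"]["iqr"],
        "lateral_pct": row["lat"]["iqr"],
    }
    for (seg, kind), cell in phases.items():
        jitter_iqr[f"phase_{seg}_{kind}_pct"] = cell["iqr"]
    tpl = GaitTemplate(
        gait=gait,
        condition=condition,
        stride_duration_s=row["stride"]["value"],
        stance_duration_fl_s=row["stance_fl"]["value"],
        stance_duration_hl_s=row["stance_hl"]["value"],
        lateral_dissociation_pct=row["lat"]["value"],
        diagonal_dissociation_pct=(None if row["diag"] is None
                                   else row["diag"]["value"]),
        romz_mm=dict(_ROMZ_TABLE[key]),
        extremum_phase={k: cell["value"] for k, cell in phases.items()},
        jitter_iqr=jitter_iqr,
    )
    merged = dict(overrides or {})
    merged.update(kwargs)
    if merged:
        tpl = replace(tpl, **merged)
    return tpl


def default_extremum_phase(gait: str, segment: str, kind: str) -> float:
    """Canonical extremum phase (% of reference stance) for a gait.

    Median across the conditions tabulated for that gait; used to
    disambiguate left/right extremum assignment when no template is
    available.
    """
    vals = [cells[(segment, kind)]["value"]
            for (g, _), cells in _PHASE_TABLE.items() if g == gait]
    if not vals:
        raise TemplateError(f"unknown gait {gait!r}")
    vals.sort()
    n = len(vals)
    return vals[n // 2] if n % 2 else 0.5 * (vals[n // 2 - 1] + vals[n // 2])


def iqr_to_sd(iqr: float) -> float:
    return IQR_TO_SD * iqr


def _validate_waveform_geometry(template: GaitTemplate) -> None:
    """Reject templates whose extrema collide (no alternating min/max)."""
    for seg in SEGMENTS:
        ph = template.extremum_stride_phases(seg)
        gap = (ph[("left", "max")] - ph[("left", "min")]) % 50.0
        if math.isclose(gap, 0.0, abs_tol=1e-9):
            raise TemplateError(
                f"extremum phases for {seg} coincide modulo half a stride; "
                "waveform would be degenerate")
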