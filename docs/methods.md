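# Methods

## Scope and data model

`hoofbeat` analyzes straight-line locomotion in the four symmetrical
equine gaits (walk, trot, tölt, pace).  A trial consists of per-limb
hoof-on/off event times (LF, RF, LH, RH), vertical acceleration traces for
three axial segments (head, withers, pelvis) sampled uniformly at 200 or
500 Hz, and — for simulated trials — the ground-truth displacement those
accelerations derive from.  All times are absolute seconds; percent-of-
stride and percent-of-stance conversions happen only in the metrics layer.
A stride is the half-open interval between consecutive left-hind contacts,
so every instant belongs to exactly one stride.

## The synthetic gait generator

No public dataset exists for multi-breed axial-segment kinematics, so the
generator is a first-class component: its defaults are the published
per-gait/per-breed medians, and every downstream stage is validated by
round trip against it.

**Footfall geometry.**  Contralateral limbs are half a stride apart.  The
left-fore onset phase is set from the lateral dissociation (hind-to-
ipsilateral-fore interval, %StrD); where a diagonal dissociation is also
tabulated (walk, trot) the two published medians are mutually consistent
with `lateral = diagonal + 50` only to rounding (≤ 0.6 %StrD), and the
realized phase splits the difference so both recover within 1 %StrD.
Stance durations are applied per limb pair (fore/hind).  Suspension is not
a parameter: it emerges from the union of stance intervals, 0 for the walk
and tölt defaults, > 0 for trot and pace.

**Waveform family.**  Each segment's vertical displacement is a chain of
quintic-smoothstep arcs joining consecutive prescribed extrema (two minima
and two maxima per stride, the left-referenced pair placed at the
tabulated percent of the reference-limb stance, the right-referenced pair
half a stride later).  This family was chosen over a two-harmonic cosine
sum because (a) the published quantities are extremum *positions*, which
the arcs realize exactly while a truncated Fourier series cannot place
minima and maxima independently (walk withers: minimum at 13 % and maximum
at 44 % of a 65-%StrD stance, i.e. 20 %StrD apart rather than a quarter
stride), and (b) with zero asymmetry the waveform is exactly periodic
under a half-stride shift, which a stride-frequency harmonic would break.
The cost is a locally flat (cubic-order) extremum; with noiseless or
mildly noisy data this does not affect sub-sample extremum localization.
The quintic arcs are C²-continuous, so the emitted acceleration — the
analytic second derivative, in m/s² — is continuous.

**Asymmetry.**  `asymmetry_mm` (HDmin/HDmax/WDmin/WDmax/PDmin/PDmax)
raises the left-referenced extremum and lowers the right-referenced one by
half the requested difference, so the recovered left-minus-right index
equals the injected value.  `inject_asymmetry` applies the same
modification to an existing trial by exact re-synthesis from the stored
node list (preserving any noise realization), rather than by local bump
addition.

**Stochastic structure.**  One integer seed drives a single generator
threaded through all draws.  `jitter_scale` switches on per-stride
Gaussian perturbation of stride duration, event times, extremum times and
extremum amplitudes; magnitudes are the published IQRs × 0.7413 (the
IQR→SD factor for a normal), scaled by `jitter_scale`.  Published tables
report a single IQR that mixes within- and between-horse variability, so
the split is a modeling choice: `jitter_scale` covers within-horse
scatter, and the cohort helper (`simulate_cohort`) adds horse-level
offsets with `horse_scale` times the same SDs.  Amplitude scatter has no
published IQR (range-of-motion tables print confidence intervals); the
default is 5 % of ROMz per unit scale.  `noise_sd_mm` adds white
measurement noise to the acceleration trace, scaled by the squared
two-per-stride angular frequency so the value is displacement-equivalent
millimetres.

**Parameter defaults.**  Stride/stance durations and dissociations: the
published medians per gait × condition (Warmblood and Iberian in hand;
Icelandic in hand and ridden; tölt and pace exist only for ridden
Icelandic horses).  ROMz: the published estimated marginal means for
in-hand walk and trot; ridden Icelandic walk/trot reuse the in-hand
Icelandic values, and tölt/pace — for which no table exists — reuse the
Icelandic trot values (modeling choice; the ambling ROMz magnitudes are of
that order).  Extremum phases: the tabulated per-gait timings, e.g. trot
minima near mid-stance and maxima near or just past lift-off (Warmblood
trot pelvis maximum at 110 % of left-hind stance), walk withers minima
near stance onset, tölt head/withers maxima near 0 % of stance.

## Event detection

The study hardware's hoof-event algorithm is proprietary; analysis of
simulated data defaults to ground-truth pass-through.  The surrogate
detector exists so the pipeline also runs without truth labels: the
stylized metapodial signal is quiet during stance and an oscillatory burst
(`sin(πu)^0.3 · cos(6πu)` in normalized swing time) during swing.  Stance
is declared where the rectified signal stays below 5 % of the per-limb
robust (95th-percentile) amplitude for at least 40 ms; stances separated
by blips shorter than 20 ms are merged; runs touching the trace edges are
dropped because their true boundary is unseen.  On simulator output the
detector reproduces every event within one sample with no spurious
detections, and partial strides at trial boundaries are discarded (a
convention, not a claim about the original hardware).

## Double integration and drift correction

Acceleration is integrated per stride window with the trapezoidal rule.
Integration constants are fixed by stride periodicity rather than by
fitted trends:

1. the net acceleration integral over one stride is zero for
   stride-periodic motion, so the measured total (computed by exact-window
   quadrature with interpolated endpoint panels) is pure drift and is
   removed as a ramp from velocity;
2. the stride-mean of velocity and of displacement are removed, again via
   exact-window quadrature — window boundaries rarely coincide with sample
   times, and a raw sample mean would be biased by up to one endpoint
   sample, leaking ~0.5 mm of spurious left–right asymmetry.

A fitted linear trend is deliberately *not* removed: over one full period
the least-squares linear component of a periodic signal is generally
non-zero (for a sine it has ~0.95 of the amplitude), so trend removal
would distort the waveform it is meant to clean.  On noiseless simulated
trials the reconstruction error is < 0.1 % of ROMz; the acceptance bound
is 2 %.  Displacement is mean-zero per stride; all reported indices and
timings are invariant to the DC convention.

Each stride is then resampled to a fixed 101-point grid (0–100 %StrD
inclusive, so integer percent positions are addressable) by piecewise
cubic interpolation — linear interpolation would bias extremum positions,
the analysis target.

## Extremum location and left/right assignment

Extrema are located on a dense (2000-point) grid through a cubic spline of
the raw stride window: the global minimum, then the best minimum at least
a quarter stride away (circular distance); likewise for maxima.  Timing is
reported both in %StrD and as percent of the reference-limb stance, with
the offset from the reference contact de-aliased to the branch nearest the
expected phase (template phases for simulated trials, built-in per-gait
defaults otherwise), so out-of-stance values like 110 % or −0.3 % are
reported without half-stride aliasing.

Which of the two equivalent extrema is "left-referenced" is genuinely
conventional — the published per-gait values follow no single half-stride
window rule (walk head maximum at 87 % of stance vs tölt head maximum at
4.8 %).  The package assigns left = the extremum circularly closest to the
expected phase; without any expectation it falls back to: left minimum =
the minimum within the half stride after the left reference contact, left
maximum = the first maximum after the left minimum.  For symmetric strides
the choice only affects labeling; for asymmetric strides it fixes the sign
of the D-indices, which are stored signed and compared as absolute values
in the inclusion screen ("exceeded 16 mm / 8 mm" is strict `>`).

## Between-segment phase differences

Each segment contributes two extrema per stride half a stride apart, so
its timing is reduced to the first occurrence within the LH-anchored
stride (stride phase mod 50 %StrD).  The pairwise difference then lies in
(−50, +50) %StrD, positive when the first-named segment reaches its
extremum first.  This first-occurrence pairing reproduces the published
sign structure for walk (head–withers minima ≈ +28, maxima ≈ −28 %StrD,
withers a quarter stride out of phase), trot and pace (all differences
near zero).  For tölt, the published head–pelvis minima (+29) and maxima
(−32) differences imply opposite wrap conventions at the ±25 %StrD
boundary; that convention is not derivable from the published tables, and
the package reports the first-occurrence value (≈ −22 / +24 %StrD,
equivalent modulo half a stride) without attempting to match the sign.

## Statistics

Descriptives are median and IQR over strides pooled within the grouping
keys.  Group comparisons use linear mixed models (statsmodels `MixedLM`,
REML) with per-stride rows and a random horse intercept: (1) ROMz ~ breed
× anatomical location, (2) extremum timing ~ breed, (3) a temporal
variable ~ breed.  Estimated marginal means are computed on the balanced
factor grid from the fixed-effect estimates; pairwise contrasts average
over the remaining factors and are Tukey-adjusted via the
studentized-range distribution with containment denominator degrees of
freedom (horses minus between-horse parameters) — conservative for
stride-level noise.  Significance is α = 0.05.  Singular or under-
identified fits (fewer than two horses or levels) are reported as
non-estimable rather than silently dropped.

The statistical stage is validated generatively: per-stride ROMz drawn
from a two-level normal model (between-horse SD 20 mm, on the scale
implied by the published confidence intervals; within-horse SD 10 mm).
Over 200 replicates, three identical breeds yield no significant Tukey
contrast in ≥ 90 % of replicates, and a 25 mm head-ROMz offset with 20
horses per breed is detected in ≥ 80 %.

## Problem sizes

Unit and acceptance tests run 3–10-stride trials at 200 Hz and cohorts of
5–6 horses — the stride counts per horse (tens) are far below the study's
hundreds, which is why group checks use medians and tolerance bands
rather than exact reproduction of published group tables.  The statistical
validation uses 200 replicates of 20-horse cohorts at the ROMz level.

## What passing tests do and do not show

The simulator realizes the published footfall geometry and extremum
phases *exactly* (before jitter), so round-trip recovery demonstrates the
correctness of the analysis chain, not the realism of the waveform: real
trials contain soft-tissue and sensor-mounting artifacts, orientation
error, speed drift within a trial, asymmetric horses, and event-detection
noise with structure very different from the stylized limb signal.
Integration accuracy on C² synthetic waveforms does not bound errors on
real accelerometry with low-frequency drift, for which the per-stride
periodicity assumption is only approximate.  Published group tables enter
as generator defaults, and group-level outputs are validated for
statistical behaviour (type-I error, power, EMM identities), not for
numerical agreement with the original cohort.

## Known limitations

* Canter/gallop, circles and speed covariates are out of scope.
* The surrogate event detector is not the proprietary hardware algorithm.
* Per-stride drift correction assumes stride-periodic vertical motion;
  net elevation change over a stride is absorbed into the correction.
* Tölt/pace ROMz defaults are borrowed from Icelandic trot (no published
  table).
* The tölt head–pelvis phase-difference sign convention at the wrap
  boundary is left as first-occurrence (see above).
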