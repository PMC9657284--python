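# hoofbeat

Equine gait kinematics from wearable-sensor-style data: simulation and
analysis of the four symmetrical horse gaits — walk, trot, tölt and pace —
as performed by Warmblood, Iberian and Icelandic horses.

Quantitative lameness assessment rests on the vertical motion of three
axial body segments (head at the poll, withers, pelvis between the tubera
sacrale) relative to the footfalls of the four limbs.  In a symmetrical
gait each segment oscillates twice per stride; the signed differences
between the stride's two minima and two maxima (HDmin/HDmax for the head,
WDmin/WDmax for the withers, PDmin/PDmax for the pelvis) are the standard
movement-asymmetry indices, and their timing relative to limb stance
phases differs systematically between gaits and breeds.  `hoofbeat` is for
researchers and method developers in veterinary biomechanics who need a
fully controlled, reproducible test bed for this analysis chain — real
multi-breed IMU recordings of this kind are not publicly deposited.

## What the package computes

For a stride defined as the interval between consecutive left-hind hoof
contacts (`[LH-on_i, LH-on_{i+1})`):

* **Temporal limb variables** — stride duration; fore/hind stance and
  swing durations; duty factor `stance/stride`; diagonal and lateral
  dissociation in percent of stride (%StrD), positive when the hind hoof
  of the pair lands first; suspension (%StrD with no hoof on the ground).
* **Vertical kinematics** — double integration of vertical acceleration to
  displacement with per-stride drift correction, and resampling of each
  stride to a fixed 101-point grid (0–100 %StrD).
* **Extremum structure** — the two minima and two maxima per segment per
  stride, located by spline-based search, each expressed in millimetres
  and as percent of the reference-limb stance
  (`(t − t_on)/(t_off − t_on) × 100`; forelimb stance for head/withers,
  hindlimb for pelvis; values outside [0, 100] mark extrema before contact
  or after lift-off).
* **Symmetry** — HDmin/HDmax, WDmin/WDmax, PDmin/PDmax (left minus right),
  vertical range of motion (ROMz) per segment, and the in-hand trot
  inclusion screen (exclude when |HDmin| or |HDmax| > 16 mm, or |PDmin| or
  |PDmax| > 8 mm; "exceeded" is strict).
* **Phase relations** — head–withers, head–pelvis and withers–pelvis
  differences in extremum timing per stride, in %StrD, positive when the
  first-named segment reaches the extremum first.
* **Group statistics** — median/IQR descriptives and linear mixed models
  (horse as random intercept) with estimated marginal means and
  Tukey-adjusted pairwise contrasts.

The built-in generator simulates all of this from published
per-gait/per-breed stride parameters: footfall times realize the stride,
stance and dissociation geometry exactly; each segment's displacement is a
smooth two-cycle-per-stride waveform whose extrema sit at the published
stance-referenced phases; the emitted acceleration is the analytic second
derivative of the ground-truth displacement; asymmetry and noise can be
injected in controlled amounts.

## Worked example

```python
import hoofbeat as hb

tpl = hb.make_template("trot", "warmblood", n_strides=5, seed=0)
trial = hb.simulate_trial(tpl)
table = hb.analyze_trial(trial)          # one row per stride
print(table[["stride_duration_s", "duty_factor_fl", "duty_factor_hl",
             "diagonal_dissociation_pct", "suspension_pct",
             "romz_withers_mm", "pelvis_max_left_pct_stance",
             "HDmin", "PDmax"]].median().round(3))
```

prints

```
stride_duration_s               0.780
duty_factor_fl                  0.487
duty_factor_hl                  0.397
diagonal_dissociation_pct      -2.800
suspension_pct                  2.564
romz_withers_mm                92.150
pelvis_max_left_pct_stance    109.955
HDmin                          -0.000
PDmax                          -0.002
```

Reading: the simulated Warmblood trot has a 0.78 s stride; forelimb duty
factor 0.487 (stance 0.38 s / stride 0.78 s, i.e. the published 0.49);
fore-first diagonal dissociation of −2.8 %StrD; a short suspension phase;
withers ROMz of 92 mm recovered by double integration within a fraction of
a millimetre of the generative 92.2 mm; the pelvis reaches its highest
point at ~110 % of left-hind stance — just after lift-off; and the
symmetry indices of this sound, noiseless horse are zero.

A command-line interface chains the stages on disk bundles
(`hoofbeat simulate | detect | integrate | analyze | summarize | run-all`),
e.g.

```sh
hoofbeat run-all --gait tolt --condition icelandic_ridden --seed 7 --out out/
```

## Analysis scripts

Numbered drivers under `analysis/` regenerate study-style tables into
`results/`:

1. `01_simulate_cohorts.py` — simulate all breed/gait/condition cohorts,
   pooling per-stride variables;
2. `02_stride_parameters.py` — median/IQR stride-parameter table;
3. `03_timing_differences.py` — extremum timing (% of reference stance) and
   between-segment phase differences (%StrD);
4. `04_group_models.py` — mixed-model breed comparisons at trot (EMM,
   Tukey contrasts).

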