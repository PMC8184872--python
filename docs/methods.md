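# Methods notes

This note records the models, numerical choices and open design
decisions behind `toolgaze`, in the spirit of a methods appendix: what
the code assumes, why the defaults are what they are, and what passing
tests do and do not establish.

## The experiment being modelled

One session is 840 trials in 10 blocks of 84.  A trial is 2000 ms:
500 ms central fixation, 1000 ms with a tool image in the background,
500 ms return phase.  The colour go-cue follows image onset by an SOA
of 100, 200, 400 or 600 ms and instructs a 12° saccade left (blue),
right (green), or no saccade (red; SOA always 400 ms, 40 trials,
excluded from analysis).  Per subject: 320 trials congruent with the
tool's head, 320 with its handle, 160 with a no-handle control object.
The printed claim of "40 repetitions per Tool-end × SOA cell" cannot be
reconciled with these totals (320 head trials over 4 SOAs is 80/SOA);
the per-condition totals are treated as authoritative, giving head and
handle 40 trials per SOA × direction cell split over two orientations,
and control 20 per SOA × direction (horizontal only).  Left/right cues
are balanced within every cell; orientation splits 50/50 for head and
handle items.  Randomisation is a uniform shuffle over the session
(blocks are rest units, not strata; a per-block balancing flag exists).

## Gaze geometry

Conversions use a per-axis tangent model about the screen centre:
`deg = atan((p − c)·mm_per_px / D)·180/π` with the panel defaulting to
1920 × 1080 px on 509 × 286 mm viewed from 670 mm.  At those defaults
one pixel subtends ≈ 0.0227°; the analysis nonetheless rounds
subject-average saccadic errors to 0.03° — the value is treated as a
fixed rounding constant of the original analysis, not derived from
geometry, and both panel size and the constant are configurable.  A
small-angle (linear) mode exists for sensitivity checks.  Binocular
tables are combined into a cyclopean trace (average when both eyes
valid, single eye otherwise, missing when neither).

## Synthetic gaze

**Kinematics.** Saccade duration is `d0 + d1·A` (defaults 21 ms,
2.2 ms/deg) and peak velocity `vmax·(1 − e^{−A/a0})` (defaults
500 deg/s, 14°) — conventional main-sequence constants.  At A = 12°
these imply duration 47.4 ms and peak 288 deg/s, i.e. a mean/peak
velocity ratio of 0.88.  No bell-shaped velocity profile has such a
ratio, so the default waveform is a **flat-top profile**: cosine ramps
of duration τ into and out of a constant-velocity plateau, with τ
solving `v_peak·(d − τ) = A` (clipped to [0.1d, 0.5d]).  This honours
amplitude, duration and peak velocity simultaneously and gives the
sharp velocity rise that makes sample-accurate onset ground truth
meaningful.  Gaussian and minimum-jerk profiles are available as
alternatives; they preserve amplitude and duration but not the
main-sequence peak (Gaussian overshoots it roughly two-fold at 12°).

**Latencies.** Ex-Gaussian: condition mean + SOA term + subject offset
+ N(0, σ) + (Exp(τ) − τ), floored at 80 ms.  Defaults are calibrated
to the experiment's grand means: condition means 393.0 (head),
402.1 (handle), 402.66 ms (control); SOA terms +33.75, +8.75, −16.25,
−26.25 ms (the printed SOA means centred on their mean); between-subject
SD 52 ms (between-subject SEM scaled by √26 after removing the
trial-noise share); trial-level σ = 35 ms and τ = 50 ms chosen once as
conventional SRT phenomenology — the original report contains only
means and SEMs, so any trial-level spread is a modelling choice.  A
latency draw leaving no room for the saccade before trial end is an
omission (ground truth absent), not an error.

**Artefacts.** White per-axis position noise (default 0.05° RMS, the
scale of a remote 300 Hz tracker), blinks as Poisson events (default
3/min) of 100–250 ms set to missing — the minimum stays above the
10-sample blink-detection threshold so every generated blink is
recoverable — optionally flanked by ±3° eyelid excursions that exercise
the padding rule; isolated 1-sample dropouts (p = 0.002); a decaying
40 Hz post-saccadic oscillation (default 0.15°) exercising the
9-sample landing average; landing scatter 0.5° SD around the target.
A return saccade to centre occurs in the post-trial phase when it fits.

**What the generator does not emulate:** pink/drift components of
tracker noise, smooth pursuit, microsaccades, pupil-size artefacts,
object-identity structure, or any dependence of latency on stimulus
content beyond the additive condition/SOA terms.  Passing end-to-end
tests therefore shows the *pipeline* is correct and calibrated under
these statistical assumptions, not that the scientific effect exists in
new human data.

## Preprocessing

Blink detection runs on raw validity first (runs of ≥ 10 continuously
missing samples), each blink is padded by 20 samples on both sides and
set to NaN, and only then is the position filtered.  The written
description of the original analysis lists filtering first, but a
filter cannot cross NaN gaps and interpolating through blinks would
fabricate data, so masking-first is the only executable ordering.

The filter is Chebyshev type II of order 8 with its stopband edge at
0.3·π rad/sample (45 Hz at 300 Hz) and 60 dB stopband attenuation,
applied forward-backward (`filtfilt`) for exact zero phase.  Chebyshev
II is chosen because its design equations place the specification
exactly at the two printed numbers; the family, order, and the
interpretation of the edge (stopband vs cutoff) are configurable, since
the original description is ambiguous.  The forward-backward pass
squares the magnitude response, so 60 dB is a floor, and DC gain stays
exactly 1.  Contiguous finite segments shorter than the `filtfilt` pad
length (27 samples) are left unfiltered and logged.  The sharp cutoff
produces the ringing ("Gibbs") overshoot around saccade offsets that
the 9-sample landing average compensates.

## Saccade detection

Speed is `‖(Δx, Δy)‖/Δt` by central differences (no phase lag;
one-sided at segment edges), undefined wherever the sample itself or a
contributing neighbour is missing.  Detection runs at 50 deg/s: an
onset is the first sample of ≥ 3 consecutive samples at/above
threshold, the offset the last above-threshold sample before ≥ 3
consecutive finite below-threshold samples.  Sub-persistence dips never
split an event (filter ringing would otherwise fragment saccades), and
a missing sample always closes the event.  The 100 deg/s threshold
classifies events as the "large" saccades of interest by peak speed —
a single onset definition for all events; an `onset_at_big` switch
enables the alternative two-pass reading for sensitivity analysis.
Landing is the mean of up to 9 finite samples after the offset; the
count actually used is recorded.

Ground-truth onset comparisons quantise the continuous true onset to
the nearest sample: detection is sample-indexed, and without the
quantisation a detected onset can sit 1.007 samples from a true onset
that falls just past a grid point, purely from grid phase.

## Trial metrics

The response saccade is the first large event after cue onset.  Trials
are classified `valid` / `anticipatory` (latency < 80 ms) /
`wrong_direction` / `blink_contaminated` (no saccade found and a
≥ 10-sample gap after the cue) / `no_saccade` / `red_excluded`; only
valid trials enter cell means.  The original report states no
trial-level exclusion rules, so the taxonomy is configurable and every
exclusion is logged; direction checking also correctly rejects return
saccades when a blink swallowed the response.  SRT is cue onset →
saccade onset.  Saccadic error is measured to the horizontal ±12°
targets regardless of stimulus orientation, and rounding to 0.03° is
applied to subject-average errors only, never per trial.  Subjects are
excluded when their recording's missing-sample fraction exceeds 0.3 —
an operationalisation of "poor data quality", configurable.

## Inference

The ANOVA is a fully-within-subject factorial of arbitrary order
computed by explicit sums-of-squares decomposition over all subsets of
factors; every effect is tested against its own effect × subject
stratum.  Greenhouse–Geisser ε for an effect comes from the covariance
of within-subject scores projected onto an orthonormal (Helmert)
contrast basis — for interactions, the Kronecker product of the
factors' bases — as `tr(M)²/(df·tr(M²))`, clipped to [1/df, 1]; it is
applied to every effect with df > 1 regardless of a sphericity pretest,
matching the original reporting style.  η²_G uses the all-manipulated
convention: `SS_effect / (SS_effect + SS_subject + Σ error strata)`.
Degenerate zero-variance paired differences return a capped t (10⁶)
with an explicit flag.  Post-hoc paired t-tests report raw p-values
(the original convention) alongside Holm-adjusted ones.  The three-way
analysis (tool end × SOA × orientation) excludes control items, which
have no oblique orientation.

## Problem sizes and calibration checks

The package's own verification uses these simulation scales, chosen to
make the checks statistically meaningful at desk scale:

* **Effect recovery:** 26 subjects × 840 trials end to end.  The
  recovered handle − head difference is unbiased (seed-sweep mean
  9.18 ms against the calibrated 9.1 ms) with a Monte-Carlo SD of
  ≈ 1 ms, so a ±2 ms tolerance is the approximate 95% band of the
  estimator.
* **Null calibration:** 1000 replications of 8 subjects × 40
  trials/condition under a no-effect latency model, with blinks and
  dropouts disabled so the check isolates the latency → detection →
  inference chain.  The simulated null is compound-symmetric, so the
  uncorrected F test is exact at α = 0.05, while the G-G-corrected
  test is conservative at this small n (mean ε̂ ≈ 0.815 by sampling
  even under true sphericity).  The calibration check therefore holds
  the exact test to the nominal 3–7% band and requires the corrected
  test never to exceed it from above.
* **Detector oracle:** exact equivalence on 1000 random short traces
  against an independently written per-sample scan.
* **Ground truth:** noise-free sessions require 100% of extracted SRTs
  within one sample and landings within 0.05°.

## Known limitations

* The latency calibration reproduces means and between-subject spread,
  not the full RT distribution of any real subject.
* Velocity noise is treated only through the dual thresholds; adaptive
  (noise-scaled) thresholds are out of scope.
* The schedule models the factor structure only, not the 21 object
  identities with their unequal repetitions.
* `filtfilt` edge transients make filtering non-idempotent within
  ~30 samples of segment edges; events that close to a segment edge
  are rare in this design (saccades sit mid-trial) but the landing
  window can truncate (the used-sample count is recorded).
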