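# toolgaze

Eye-tracking analysis and simulation for a saccade-priming experiment:
do the functional ends of hand-held tools attract the eyes?

In the paradigm this package implements, subjects fixate a central dot
while a tool photograph appears in the background; after a stimulus
onset asynchrony (SOA) of 100–600 ms the dot changes colour, cueing a
12° saccade left or right (or withholding one).  Unbeknownst to the
subject, the cued side is congruent with either the tool's *head* (its
action end), its *handle*, or a no-handle control object.  The question
is carried entirely by saccadic reaction times (SRTs): saccades toward
the side of the tool head launch ~9 ms earlier than saccades toward the
handle side.

`toolgaze` re-implements the full analysis chain for 300 Hz gaze
recordings, plus a synthetic generator so every stage is verifiable
against known ground truth:

* **design** — randomised trial schedules for the 3 × 4 within-subject
  design (840 trials: 320 head-, 320 handle-congruent, 160 control, 40
  no-saccade catch trials) with validation as data, not exceptions.
* **simulate** — 300 Hz gaze traces with main-sequence saccade
  kinematics (duration `d0 + d1·A`, peak velocity
  `vmax·(1 − e^{−A/a0})`), ex-Gaussian latencies, position noise,
  blinks and dropouts, with per-trial ground truth.
* **preprocess** — blink rule (≥10 continuously lost samples, padded by
  20 samples each side, set to NaN) and a zero-phase Chebyshev-II
  low-pass (stopband 0.3·π rad/sample, 60 dB) applied per finite
  segment.
* **detect** — combined-axis velocity (central differences) with dual
  thresholds: 50 deg/s detects all saccades, 100 deg/s classifies the
  large response saccades, onsets/offsets requiring 3 consecutive
  samples.
* **metrics** — response-saccade selection, SRT (cue onset → saccade
  onset), saccadic error (Euclidean distance from the 9-sample-averaged
  landing point to the ±12° target, subject means rounded to 0.03°),
  trial status taxonomy and data-quality subject exclusion.
* **stats** — n-way fully-within-subject ANOVA by explicit SS
  decomposition, Greenhouse–Geisser ε from within-subject contrast
  covariance, generalized η²_G, paired t-tests with optional Holm
  adjustment.
* **pipeline / CLI** — one-call orchestration with a checksummed
  manifest; `toolgaze design|simulate|preprocess|detect|metrics|infer|
  run|describe`.

## Worked example

Simulate one noise-free head-congruent trial (SOA 400 ms, latency fixed
at 400 ms) and push it through the detection chain
(`examples/02_simulate_and_detect.py`):

```
main sequence at 12.0 deg: duration 47.4 ms, peak velocity 288 deg/s
ground truth: onset 1300.0 ms, landing (12.00, 0.00) deg
detected:     onset 1296.7 ms, landing (12.02, 0.00) deg, peak 315 deg/s
extracted SRT 396.7 ms vs true 400.0 ms (one sample = 3.33 ms)
```

The true onset is 500 ms fixation + 400 ms SOA + 400 ms latency =
1300 ms; the detector recovers it at the neighbouring sample (the
zero-phase filter spreads the onset symmetrically, and 300 Hz sampling
quantises to 3.33 ms).  The landing point is within 0.02° of truth; the
filtered peak velocity slightly overshoots the generated 288 deg/s
because of the filter's passband ringing — which is exactly why landing
points are averaged over nine samples.

Running the inference demo (`examples/04_rm_anova.py`, 10 simulated
subjects at quarter session size) prints the condition structure the
generator is calibrated to:

```
           effect       F  df1_corr  df2_corr  epsilon_gg   p_gg  eta_g2
         tool_end  6.4884    1.6987   15.2886      0.8494 0.0115  0.0076
           soa_ms 91.6445    2.4198   21.7779      0.8066 0.0000  0.1364
tool_end x soa_ms  1.1148    2.2530   20.2774      0.3755 0.3533  0.0044

handle - head: t(9) = 4.20, mean diff 11.1 ms, p = 0.0023 (Holm p = 0.0069)
```

Head-congruent saccades are faster; SRTs shorten with SOA; the two do
not interact.

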