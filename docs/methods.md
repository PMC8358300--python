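# Methods

## COP derivation and preprocessing

A force plate reports forces (Fx, Fy, Fz) and moments (Mx, My, Mz) about
its sensor origin, which on AMTI-class plates sits a vertical distance
*h* below the surface. The center of pressure in the plate frame is

    cop_x = (−My − Fx·h) / Fz,    cop_y = (Mx − Fy·h) / Fz.

Default *h* = 0 (moments about the surface); set `plate_origin_offset_h`
for sub-surface origins. Samples with |Fz| at or below 10 N (configurable)
raise an unloaded-plate error naming the first offending index rather than
dividing by a vanishing load.

Axis convention: by default AP ≡ plate x and ML ≡ plate y, both positive
signs, fully configurable via `AxisMap`. The convention is explicit
because two of the seven measures and the contrast directions are
sign-sensitive; nothing downstream assumes a particular plate mounting.

No filtering is applied by default — the battery is defined on the raw
path, and filtering materially changes velocity and frequency measures. An
optional zero-phase Butterworth low-pass (4th order, `filtfilt`) is
exposed for noisy hardware; its cutoff must sit below Nyquist.

Trials are cut as half-open windows `[t0, t0 + 20 s)` on integer sample
boundaries, so a 20-s trial at 200 Hz has exactly 4000 samples and
adjacent trials never share a boundary sample. The default schedule is 6
conditions × 3 trials × 20 s with 5-s breaks (also used between
conditions). Recordings are assumed time-aligned; no onset-latency
correction is attempted for manually synchronized starts.

Centering (per-axis mean removal) is explicit and required by the
distance-type measures; it is idempotent and never applied silently.

## The measure battery

All seven measures are classical time-domain stabilometry:

- mean distance `(1/N)Σ|x_i|` per axis (mm);
- mean velocity `Σ|Δx| / ((N−1)/fs)` per axis (mm/s) — the duration uses
  N−1 intervals because the path has N−1 increments;
- 95% confidence-ellipse area `2π·F·sqrt(det S)` with S the sample
  covariance of (AP, ML) and F the 0.95 quantile of F(2, N−2), computed
  from N rather than hard-coded at its large-N limit 3.00; collinear
  paths are flagged degenerate with area 0;
- directional mean frequency `Vel/(4√2·Mean)` (Hz). The 4√2 constant is
  the directional form of the classical battery: for a sinusoid it gives
  `Mf = (π/(2√2))·f ≈ 1.11·f`. The constant is overridable
  (`mf_constant`) for sensitivity analyses, since verbal definitions of
  this measure are ambiguous between 2π- and 4√2-style conventions and
  published tables generally cannot adjudicate the choice (averaging
  order across trials already shifts the ratio).

A measure undefined on its input (mean frequency of a constant series)
becomes NaN plus an entry in the battery's `undefined` set — never a
silent drop. Trial-to-condition aggregation is the per-field arithmetic
mean across the three trials (one value per participant-condition), with
undefined flags propagating to the aggregate; statistics then exclude
flagged participants listwise per contrast and log the count.

## Condition statistics

The cohort design is within-subject: every participant completes all six
conditions, so the analysis is rank-based and paired throughout.

- **Shapiro–Wilk** per condition is computed for reporting only; the
  nonparametric pipeline never branches on it.
- **Friedman omnibus** uses within-block midranks,
  `χ²_F = [12/(nk(k+1))]ΣR_j² − 3n(k+1)`, divided by the tie-correction
  factor `1 − Σ(t³−t)/(nk(k²−1))`; fully tied blocks yield statistic 0 and
  p = 1. The p-value comes from χ²(k−1) for n ≥ 8 and from a seeded
  within-block permutation null (20 000 draws, vectorized over permuted
  midranks) below that.
- **Wilcoxon signed-rank** discards zero differences by default (the
  convention of the mainstream statistics packages; Pratt's method is a
  flag), midranks |d|, and uses the exact 2ⁿ sign-flip distribution
  (discrete convolution over doubled midranks) when the effective n ≤ 15,
  else the normal approximation with tie-corrected variance. The Z value
  is always reported from the approximation formula so effect sizes are
  comparable across modes. No continuity correction by default
  (configurable); the exact and continuity-corrected approximate p agree
  within 0.03 for 8 ≤ n ≤ 15 in the test suite.
- **Effect size** is Rosenthal's `r = |Z|/√n` with n the number of pairs
  entering the contrast.
- **The four a-priori contrasts** are (2 vs 1), (4 vs 1), (5 vs 1),
  (6 vs 5) at α = 0.05 with **no multiplicity adjustment**; every report
  carries that caveat verbatim. An independent sign-flip permutation
  oracle (mean-difference statistic) is shipped for cross-checking and
  used in tests.

## Synthetic sway cohorts

The generator exists to validate the pipeline, not to model balance
physiology. Each axis of each trial is Gaussian white noise passed through
a zero-phase 4th-order Butterworth low-pass at the condition's cutoff,
mean-removed, and rescaled to a target RMS. Amplitude and bandwidth steer
the distance-type and frequency-type measures nearly independently
(`E|x| = σ√(2/π)` for Gaussian sway; mean frequency tracks the cutoff),
which is exactly the structure the analysis assumes.

Hierarchy: one log-normal amplitude effect per participant
(`exp(N(0, τ²))`, τ = 0.25 log-mm) shared across all conditions — the
source of within-subject correlation — plus log-normal trial jitter
(SD 0.10). Both values were fixed once to give between-participant
coefficients of variation around 25%, typical of healthy-young-adult
cohort tables. AP and ML are generated independently; real sway has
modest cross-correlation, so synthetic confidence ellipses are
near-axis-aligned. This is a documented simplification.

`calibrate_defaults` tunes per-condition RMS and cutoff by iterating
simulate → compare cohort measure means to targets → multiplicative
update, from closed-form starting points, until all relative errors are
within 5%. The shipped `data/sway_defaults.yaml` was produced this way
against published per-condition means for healthy young adults (firm
conditions ~3.7–4.2 mm mean AP distance, foam ~5.5–5.9 mm; AP mean
frequency rising and ML falling with difficulty) and is what
`default_params()` loads. Everything is reproducible bit-for-bit from
(params, seed) via spawned seed sequences.

The surround motion profile is `θ(t) = A sin(2πft)` with
`f = Vmax/(2πA)`; defaults A = 20°, Vmax = 15°/s give f ≈ 0.1194 Hz.

### What passing tests do and do not show

Passing recovery tests show the pipeline correctly detects the amplitude
and bandwidth structure the generator puts in. They do not show the
pipeline is sensitive to features of real sway the generator lacks:
nonstationarity, intermittent postural corrections, AP–ML coupling, or
learning/fatigue across trials.

## Problem sizes in the test suite

The headline cohort checks run at full study scale (23 participants × 6
conditions × 3 trials of 20 s at 200 Hz; ~1 s to generate and analyze).
Heavily replicated properties are scaled down as a deliberate choice to
keep the suite snappy: the type-I-error check uses 1000 null cohorts of
23 × 6 × 1 trials of 2 s at 100 Hz (the rank tests only need the
per-trial mean AP distance), and the seed-robustness ordering check uses
60 cohorts with 5-s trials at 100 Hz. Ellipse coverage is averaged over
150 seeded 4000-sample Gaussian trajectories in tests and 200 in the
acceptance script.

## Questionnaire scoring choices

The SSQ item→subscale map (16 symptoms, three overlapping 7-item
subscales) and the presence questionnaire's category map and reverse
keying ship as editable YAML data assets, since instruments are data, not
code. Shared SSQ symptoms contribute to every subscale they belong to;
the total multiplies the sum of the three *unweighted* subscale sums by
3.74. The presence items are anchored 1–5 here (scale maximum 70, neutral
35); reverse-keyed items are inverted (`6 − rating`) before summing. SUS
uses standard Brooke scoring. All scorers validate item counts and ranges
deterministically and name the offending item.

## Known limitations

- The sway generator is statistical, not biomechanical (no inverted
  pendulum, no rambling–trembling decomposition).
- Confidence-interval construction for the effect size r is not provided.
- Single-plate recordings only; no C3D/proprietary binary ingestion.
- The mean-frequency constant is a convention; compare values across
  studies only when the convention and the trial-averaging order match.
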