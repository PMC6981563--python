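# Methods

## Accelerometer processing model

The unit of measurement is a 60-s epoch carrying one MET value from a
hip-worn triaxial device; 0 METs is the no-signal sentinel ("below the
detectable intensity"). Real device exports would be mapped to this sentinel
by the reader — conversion from raw accelerations to METs is device firmware
and out of scope.

Rules, in processing order (all thresholds are CLI/config tunable; defaults
in parentheses):

* **Non-wear**: every maximal run of ≥ 20 (`nonwear_min`) consecutive
  zero-MET epochs within one calendar day is non-wear. Runs do not span
  midnight, since days are the analysis unit. Zero-MET epochs in shorter
  runs remain wear time and are counted as SB in summaries — they are worn
  time at ≤ 1.5 METs, and this keeps SB + LPA + MVPA = wear minutes an
  exact identity per window.
* **Intensity**: SB ≤ 1.5 METs, MVPA ≥ 3.0 METs, LPA strictly between.
  The nominal LPA band "1.6–3.0" leaves (1.5, 1.6) unaddressed on a
  continuous output; we classify that sliver LPA because the SB and MVPA
  bounds are the explicit ones. 3.0 exactly is MVPA ("≥" is explicit).
* **Windows**: epochs belong to a window by start time, half-open
  [start, end). The standard workday window is 8:40–17:20: 520 min, 8.67 h.
* **Prolonged SB**: total minutes in maximal SB runs ≥ 30 epochs
  (zero-tolerance — any LPA/MVPA/non-wear epoch breaks a bout; the source
  procedure does not mention interruption tolerances).
* **Validity**: a valid day has ≥ 600 min (`valid-day-min`) all-day wear;
  weekends are dropped entirely; a participant-phase is retained when every
  covered Mon–Fri week has ≥ 4 (`min-valid-days`) valid weekdays. Whether
  the original rule was per calendar week or over the whole wear period is
  ambiguous; both are implemented (`--week-rule {per-week, overall}`),
  per-week is the default.
* **Normalisation**: workday metrics are rescaled per day as
  observed/wearing × 520 and then averaged across valid days (per-day
  normalisation before averaging matches per-workday reporting); all-day
  metrics stay raw, so all-day SB + total PA equals all-day wear time.
  Normalisation is undefined (error) on a day with zero wear in the window.

## Split-plot ANOVA

For subjects s in groups g observed at all within levels t, the classical
two-stratum decomposition is computed from scratch in numpy:

* between stratum: SS_group = T·Σ_g n_g (ȳ_g − ȳ)², tested against
  subjects-within-groups, df (N − G);
* within stratum: SS_time (weighted marginal means), SS_interaction by
  subtraction from the cell model, both tested against the subject × within
  residual, df (N − G)(T − 1).

With unequal group sizes this is the weighted (Type II) convention; the test
suite verifies exact agreement with pingouin's independent implementation on
balanced and unbalanced designs, and against exact-fraction hand
computations on a toy design. Subjects missing a within level are dropped
listwise (a split-plot needs complete rows); a between level with < 2
subjects raises a "not applicable" error rather than a number. No
sphericity correction is applied: with two within levels it is moot, and for
the 28-slot video design the output carries a limitation note instead.

The covariate-adjusted variant runs an ANCOVA on the subject means
(incremental least squares; covariate SS removed from the between error, one
error df consumed) and leaves the within stratum untouched. When the
covariate is collinear with the between factor — e.g. zone area with
day-within-space subjects, where area is constant per space — the model is
rank-deficient and the package raises an aliasing error naming the problem;
the pipeline then reports the unadjusted ANOVA with the reason in the output
metadata rather than silently dropping a term.

Post hoc: when the interaction is significant at α (0.05), paired t
contrasts of pre vs post within each group, Bonferroni-adjusted over the m
within-group contrasts (m = 2 for two groups); otherwise an empty record
set. Baseline comparisons use the equal-variance independent t-test
(the plain "independent t-test" is taken as the classical pooled one) and
Pearson chi-square without continuity correction.

For the video analysis the repeated-measures subject is taken as
day-within-space (the source design is silent on this; the choice is flagged
in the output). Analysis spaces pool zones by category except
multiple-usage aisles, which stay distinct zones, mirroring the per-space
reporting.

## Space utilization

Zone assignment is boundary-inclusive point-in-polygon (shapely), with
overlaps resolved by explicit priority then lexicographic label —
workstations carry higher priority than the aisles they abut. Slots are
half-open and partition [10:00, 17:00) into 28 15-min bins; detections
outside the window or outside every zone are dropped and counted, never
imputed. "Space utilization" is defined operationally as detection records
per (zone, day, slot) cell. Per-space dispersion is the SE across day × slot
cells by default; across-days and across-slots variants are available since
the appropriate unit is genuinely ambiguous. Missing cells (a lost camera
day) simply reduce the reported n.

## Synthetic cohorts

The generator emulates the study conditions: two arms (29 control, 13
renovation, the analysed sample sizes), two phases of 10 weekdays, a
07:00–22:00 wear day (≈ 870–900 min all-day wear), one ~30-min non-wear gap
per day on average, and working-hours SB/LPA/MVPA compositions set per
group × phase cell to the observed baselines (control 365.0/122.3/32.7,
renovation 346.8/130.4/42.8 min/working-hours — each summing to 520). The
renovation-post cell moves `effect_sb_change` (default 25) minutes from SB
to LPA, the headline per-workday effect magnitude.

Within a day, activity is an alternating-renewal process: the day's
category minute targets are drawn first — a stable per-participant SB↔LPA
shift (SD 25 min) shared across phases, a per-day shift (SD 10 min), and an
analogous MVPA↔LPA component at half the between-person SD — then laid out
over the wear epochs as shuffled geometric-length bouts with exact
per-category totals. Exact totals mean the normalised day values equal the
drawn targets regardless of gap placement, so cohort calibration error is
governed only by the configured SDs (recovery within 3 Monte-Carlo SE is a
tested invariant); geometric bouts (SB mean 6 min before same-category
merging) reproduce a realistic prolonged-SB share (~27% of SB time in
≥ 30-min bouts) so bout detection is exercised non-vacuously. Off-window
epochs reuse the day's working-hours composition, which lands all-day SB
near the observed ~570–590 min/day.

What the generator does **not** emulate: posture (sitting vs standing at
≤ 1.5 METs), circadian structure beyond the working window, weekend
behaviour, device error (MET noise, misclassification), correlated
non-wear (e.g. meetings), or dropout/invalid-wear participants (every
simulated participant passes the validity rules unless configured
otherwise). Passing tests therefore demonstrate correctness of the
processing and inference machinery under the assumed data-generating
process, not robustness to real-device artefacts. Day-to-day within-person
variability (SD 10 min) is kept modest so calibration checks are sharp;
free-living cohorts vary more.

Floor plans are synthetic rectangle layouts (28 × 13 m ≈ the described
371 m² floor) with the reported category structure — the pre layout has main
and around-workstation aisles only; the post layout adds two multiple-usage
aisles and four shared workstations. Detection counts are Poisson per
(zone, day, slot) — the simplest count model with the mean-recovery
property — with per-zone means defaulting to the reported per-space
magnitudes, optionally per-slot to plant time-of-day structure; coordinates
are uniform strictly inside the source polygon, in floor meters (no
camera/pixel model: the frame-sampling rate behind "detections per 15 min"
is unknown, so intensity is a free parameter).

## Numerical choices and degenerate inputs

* SS obtained by subtraction are clamped to zero below 1e-12 of SS_total;
  an all-constant response or a zero-variance error stratum raises a
  degenerate-design error instead of returning F = 0/0.
* Largest-remainder rounding converts day proportions to integer epoch
  counts (off-by-≤ 0.5-min rounding per category per segment).
* Day targets are clipped to the feasible simplex (SB ∈ [0, 520 − MVPA]);
  with default SDs clipping is vanishingly rare, so it introduces no
  measurable bias.
* Empty epoch series yield empty summaries; a fully non-wear day reports
  zero wear and is invalid; a retained phase with no valid days is an error.
* Ties at zone boundaries are deterministic (priority, then label); the
  detection sampler draws strictly interior points so round-tripping is
  exact.
* All generator streams derive from `numpy.random.default_rng` seeded by
  (config seed, group, phase, participant) tuples, so any cell is
  reproducible in isolation and participant effects are shared across
  phases without generating both.

## Problem sizes

Default test and acceptance runs use the study-scale cohort (42
participants × 2 phases × 10 weekdays × 900 epochs ≈ 750k epochs, a few
seconds) and desk-scale detection logs; the full-intensity video simulation
(~200k detections per phase) runs in the end-to-end pipeline in ~15 s. Null
calibration of the interaction test uses 5000 simulated designs.
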