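# Methods

## Scope and model

fatiguekit analyses a standardized monitoring design: a small squad of
athletes (default n = 8) observed over 4 weeks with (2, 2, 1, 1) sessions
per week. Each session yields (i) a mean heart rate from a wrist monitor
sampling every 5 s, (ii) a covered distance from the GNSS track of a fixed
shuttle protocol, and (iii) pre- and post-protocol trials of a 30-s Wingate
cycling test and a 30-s repeated-jump (Bosco) test.

The ballistic core is the flight-time method. A foot-mounted accelerometer
measures specific force: ≈ 1 g while standing, ≈ 0 g in free fall, a large
pulse during ground contact. From each contact→flight cycle's contact time
T_c and flight time T_f:

- h_max = g·T_f²/8 — projectile kinematics of the centre of mass;
- P̄ = (m·g²/T_c)·(T_f²/4 + T_c·|T_c+T_f|/π − T_c²/4) — mean exerted power;
- RSI = h_max/T_c — reactive strength index;
- K = m·π·(T_f+T_c)/(T_c²·((T_f+T_c)/π − T_c/4)) — spring-mass leg
  stiffness. The denominator is positive for all positive (T_c, T_f); the
  domain check only guards non-physical inputs.

All four are computed from the *trial-aggregate* (mean) T_c and T_f over
valid jumps, not averaged per jump. This keeps the identity
h_max = g·T_f²/8 exactly true for the reported aggregates. Whether trial
summaries should be means, medians or best-jump values is genuinely open in
the field; the mean is the package's choice and is configurable at the
event-filter level only.

## Jump event detection

Flight phases are maximal runs where |a| < 0.3 g lasting ≥ 80 ms; 0.3 g
separates the free-fall level (0 g) from standing (1 g) robustly under
realistic sensor noise (σ ≈ 0.02–0.05 g). Contacts are the gaps between
consecutive flights; gaps shorter than 50 ms are treated as in-flight
spikes and merged. The first contact starts at movement onset: the first
sustained (≥ 50 ms) excursion of |a − 1 g| beyond max(3·σ̂, 0.005 g), with
σ̂ estimated from the first 0.2 s of quiet standing. Validity bounds
(0.10 s ≤ T_c ≤ 1.00 s, 0.20 s ≤ T_f ≤ 0.90 s) drop artifacts before
aggregation; they cover the physiological range of repeated vertical jumps.

Only the specific-force magnitude is used — no orientation estimation,
no sensor fusion — because the formulas need durations only.

## Session metrics

- Mean heart rate: arithmetic mean of the non-missing 5-s samples; missing
  samples are omitted, never interpolated.
- Distance: summed haversine segments on a sphere of radius 6371 km, with
  an optional 12 m/s speed gate to drop GNSS spikes. Adequate at the 25-m
  shuttle scale; no geodesic refinement is warranted.
- Wingate: mean power is the trace's time average; peak power is the
  maximum of a centred 1-s rolling mean, because instantaneous maxima are
  noise-dominated and peak anaerobic power is conventionally windowed. The
  window is configurable.

## Statistical battery

All tests are implemented in-package; scipy is used only as an independent
cross-check in the test suite.

- **Wilcoxon signed-rank** (paired pre/post): zero differences dropped,
  mid-ranks for tied magnitudes. For n ≤ 12 without tied magnitudes the
  two-sided p is exact — the doubled smaller tail of the full 2^n
  enumeration (the null is symmetric). With ties, a tie-corrected normal
  approximation is used and flagged in the result notes. At n = 8 the
  smallest attainable two-sided p is 2/256 ≈ 0.0078.
- **Friedman** across weeks: within-athlete mid-ranks, tie-corrected
  statistic against χ²(k−1). At n = 8, k = 4 the χ² reference gives a
  simulated type-I rate of ≈ 0.043 at α = 0.05 (slightly conservative),
  verified by the acceptance suite.
- **Bonferroni post hoc**: all k(k−1)/2 pairwise signed-rank tests with
  multiplicative correction (default), or the Friedman rank
  critical-difference variant behind a config switch. Note that at n = 8
  the smallest adjusted p is 6·2/256 ≈ 0.047, so post hoc significance is
  attainable but only barely — an honest reflection of the design's power.
- **Cliff's delta** for pre/post effect sizes: normalized excess of
  concordant pairs, in [−1, 1]; positive when fatigue lowers the values.
- **CQV** = 100·(Q3−Q1)/(Q3+Q1) for inter-subject dispersion of heart rate
  and distance. Normalized variations (100·(post−pre)/pre) replace raw
  values for power and jump parameters, removing between-athlete level
  differences.
- **Normality**: one-sample KS statistic against the fitted normal, with a
  seeded Monte-Carlo (Lilliefors) p-value (default 10,000 replicates),
  since the plain KS null is anticonservative with estimated parameters.
  Whether to fit parameters or fix a reference was an open choice; fitting
  is the defensible default for monitoring data.

Quartiles use linear interpolation of order statistics at position
(n−1)·p + 1 throughout (numpy's default), fixed once so IQR/CQV values are
reproducible.

## Pipeline conventions

- Weeks are 1-based. Weeks with two acquisitions are averaged per athlete
  before any test.
- The temporal (Friedman) analysis runs on raw weekly values for heart
  rate and distance, and on normalized variations for Wingate and jump
  parameters; the mapping is hard-coded with a config override.
- Orientation is explicit per parameter: heart rate and contact time are
  smaller-is-better; everything else larger-is-better. Phase detection
  takes the nadir as the worst weekly median under that orientation (ties
  toward the earlier week), labelling weeks ≤ nadir "downfall" and the
  rest "recovery".
- Sessions missing a pre or post trial lose only that parameter, with a
  logged warning.

## Synthetic cohort

The generator renders every input with known ground truth.

*Jump traces.* Durations are rounded to whole samples and segments
concatenated on the sample grid, so ground-truth boundaries are exact
indices; the residual against requested durations is ≤ half a sample. The
contact pulse is a half-sine rising from 1 g to the peak gain (default
3 g): unlike a Hann-shaped pulse it has non-zero slope at its edges, which
keeps noiseless onset detection within one sample. Flight is 0 g (ideal
free fall); Gaussian sensor noise is added on top. By construction the
detector recovers every T_c and T_f within one sample on noiseless traces,
and the maximum height error scales as 1/f_s — the basis of the 100 Hz vs
1 kHz accuracy check.

*Protocol geometry.* The shuttle drill is 5 phases of 32 out-and-back
25-m legs (4 km prescribed total) at constant speed, separated by 2-min
rests, converted to lat/lon by a local equirectangular inverse around a
fixed origin. Leg vertices are always emitted, so the polyline length
equals the prescribed distance exactly and noiseless tracks are identical
across weeks — protocol reproducibility by construction. Phase durations
beyond the first/last and the prescribed total are package defaults, not
study-reported values. GNSS error modelling is out of scope (jitter is a
config knob, default 0).

*Scalar trajectory.* Pre-effort baselines (Wingate 420/525 W mean/peak,
T_c 0.25 s, T_f 0.50 s) are scaled by per-athlete lognormal factors
(CV 8%) and multiplicative session noise (CV 3% — within the 2–5%
test-retest range reported for repeated power testing). Post-effort values
are pre × a weekly fatigue effect in (0, 1]: Wingate (0.92, 0.78, 0.92,
0.95) and jump tests (0.90, 0.80, 0.90, 1.00) by default — worst at the
week-2 nadir, recovering afterwards, with the jump tests back to baseline
at week 4 so their pre/post contrast goes null while the Wingate contrast
persists. Jump fatigue acts physically: T_f shrinks as √effect (heights
scale with the effect) and T_c grows as effect^(−1/4). Weekly heart-rate
levels default to (157, 158, 146, 141) bpm. The two lockdown-training
subgroups scale the weekly *deficit* (1 − effect) by 1.25 (< 45 min group)
and 0.75 (≥ 45 min group) and the < 45 min group carries a +4 bpm offset —
this preserves a configured null week in both groups while ordering the
subgroup medians every non-null week.

*What the generator does not emulate:* heart-rate measurement dropout and
photoplethysmography artifacts, GNSS multipath/drift, within-trial fatigue
drift across the 30 s, and any correlation structure between parameters
beyond the shared athlete factor. Passing tests therefore demonstrate the
correctness of the extraction and statistics under a clean, physically
consistent signal model — not robustness to every field-data pathology.

## Problem sizes and determinism

Calibration checks use scalar-only cohort generation (no trace rendering):
1,000 seeded null cohorts for the Friedman type-I rate and 200 seeded
stochastic cohorts for nadir recovery; the ballistic check uses 100 trials
of 5 jumps at 100 Hz and 1 kHz. All randomness flows from explicit seeds
through `numpy.random.Generator`; identical (config, seed) gives
bit-identical datasets and byte-identical report CSVs.

## Known limitations

- With an exact α = 0.05 test, a genuinely null week is still flagged in
  ~5% of cohorts; the week-4 jump-test "significance lost" pattern is
  therefore probabilistic across seeds, exactly as it would be in repeated
  real studies.
- The first jump's contact onset depends on a noise-floor threshold; at
  very high sampling rates it can be one sample late (accounted for in the
  accuracy contracts).
- The Wingate trace model (ramp–plateau–decay) is a convenience profile;
  its time-average and windowed peak match the configured values, but its
  shape is not a physiological model of cadence or torque.
- Subgroup contrasts are descriptive only; no inferential test is attached
  to the two training groups.
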