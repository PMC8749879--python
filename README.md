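# fatiguekit

Wearable-sensor monitoring of athlete fatigue and recovery: ballistic jump
parameters from foot-mounted accelerometry, session physiology (heart rate,
covered distance, Wingate anaerobic power), and an exact small-sample
nonparametric pipeline for week-by-week pre/post-effort analysis.

## Who this is for

Sport scientists and biomechanists tracking small squads (n ≈ 8) through a
standardized fatigue protocol: each session an athlete runs a fixed shuttle
drill wearing a heart-rate/GNSS watch, and performs a 30-s all-out cycling
(Wingate) test and a 30-s repeated-jump (Bosco) test before and after the
protocol. The package turns the raw traces into parameters, and the
parameters into a defensible statistical report of the *downfall → nadir →
recovery* trajectory across weeks.

## The model

From the repeated-jump accelerometer signal, flight time T_f and contact
time T_c are detected per jump (an accelerometer in free fall reads ≈ 0 g;
standing, 1 g). The four ballistic parameters follow from the flight-time
method, with m the body mass and g gravitational acceleration:

- jump height — h_max = g·T_f²/8
- mean exerted power — P = (m·g²/T_c)·(T_f²/4 + T_c·|T_c+T_f|/π − T_c²/4)
- reactive strength index — RSI = h_max / T_c
- spring-mass leg stiffness — K = m·π·(T_f+T_c) / (T_c²·((T_f+T_c)/π − T_c/4))

Session metrics are the mean of the 5-s heart-rate samples, the haversine
path length of the GNSS track, and the time-average and 1-s-windowed peak of
the Wingate power trace.

Because n is small and the parameters are non-Gaussian, the statistics are
nonparametric and exact where it matters: Wilcoxon signed-rank pre/post
contrasts with the p-value from full enumeration of the 2^n sign
assignments, Cliff's delta effect sizes, Friedman tests across weeks with
Bonferroni post hoc pairs, the coefficient of quartile variation
(100·(Q3−Q1)/(Q3+Q1)) for inter-subject dispersion, and a Monte-Carlo
(Lilliefors) Kolmogorov–Smirnov normality check. A synthetic-cohort
generator with exact ground truth stands in for raw recordings, so every
stage is testable end to end.

## Worked example

```python
import fatiguekit as fk

# a 15-jump repeated-jump trial, rendered and then analysed
body = fk.BodyParams(mass_kg=72.4)
trace, truth = fk.simulate_jump_trace([fk.JumpSpec(tc_s=0.25, tf_s=0.50)] * 15, fs_hz=100)
events = fk.detect_jump_events(trace)
res = fk.bosco_summary(events, body)
print(f"jumps detected: {res.n_jumps}")
print(f"flight time   : {res.tf_s:.3f} s   contact time: {res.tc_s:.3f} s")
print(f"jump height   : {res.h_max_m:.3f} m")
print(f"mean power    : {res.mean_power_w:.1f} W")
print(f"RSI           : {res.rsi_ms:.3f} m/s")
print(f"leg stiffness : {res.stiffness_nm:.0f} N/m")

# a full 8-athlete, 4-week synthetic study, extracted and analysed
ds = fk.simulate_cohort(fk.CohortConfig(seed=11))
rep = fk.build_report(ds, make_figures=False)
wing = rep.weekly_prepost[rep.weekly_prepost.parameter == "wingate_mean_w"]
print(wing[["week", "pre_median", "post_median", "p_value", "cliffs_delta"]]
      .round(4).to_string(index=False))
```

prints

```
jumps detected: 15
flight time   : 0.500 s   contact time: 0.250 s
jump height   : 0.307 m
mean power    : 2969.8 W
RSI           : 1.226 m/s
leg stiffness : 15488 N/m

 week  pre_median  post_median  p_value  cliffs_delta
    1    413.6748     381.4435   0.0078        0.6562
    2    403.6402     326.8322   0.0078        0.9688
    3    412.7600     374.0596   0.0078        0.6250
    4    409.7187     406.6888   0.0391        0.2188
```

Every week shows a significant power loss after the fatigue protocol
(exact two-sided p = 2/256 = 0.0078 when all eight athletes decline), with
the largest effect size (Cliff's delta 0.97) in week 2 — the configured
nadir — and the smallest in week 4, as the cohort recovers.

## Command line

```sh
fatiguekit simulate --seed 7 --out study/        # synthetic study directory
fatiguekit extract  --study study/ --out params.csv
fatiguekit analyze  --table params.csv --study study/ --out report/
fatiguekit report   --study study/ --out report/  # end-to-end
fatiguekit fixtures --out tiny/                   # small demo dataset
```

A study directory holds a `manifest.csv` (one row per session, referencing
per-session trace CSVs), a long-form `questionnaire.csv`, and
`sessions/*.csv` traces with a unit-declaring comment header. The report
directory contains tidy CSV tables (pre/post contrasts, temporal tests,
post hoc pairs, subgroup splits, phase labels, questionnaire descriptives),
per-parameter figures and a `run_metadata.json` with the config hash and
seed.

## Documentation

See `docs/methods.md` for the modelling assumptions, the synthetic
generator's design, numerical conventions and known limitations.
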