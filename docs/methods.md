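# Methods

## The alarm mechanism

The baseline algorithm is a per-(vital, direction) streak state machine
over the 2-minute sample grid. A usable sample (value present and flagged
valid) is *abnormal-high* when it strictly exceeds the upper limit,
*abnormal-low* when strictly below the lower limit, and *in range*
otherwise; values exactly on a limit are normal (the normal ranges are
stated inclusively: HR 40–120 beats/min, RR 8–24 breaths/min, T ≤ 38.0 °C,
temperature having no lower limit). An alarm is annunciated at the
`n_abnormal`-th successive abnormal usable sample (default 7); after an
alarm, the same (vital, direction) type is suppressed until `n_rearm`
successive in-range usable samples have occurred (default 5). Unusable
samples are skipped entirely — they neither extend nor reset streaks, so
gaps lengthen the wall-clock annunciation delay but never cancel it. A
usable sample abnormal in the opposite direction breaks both the abnormal
streak and a re-arm run (it is not in the normal range).

Timestamp convention: an alarm's `trigger_time` is the timestamp of the
`n_abnormal`-th abnormal sample, so the default delay spans 12 min from
the first abnormal sample (7 samples = 6 inter-sample intervals). Counting
7 two-minute *intervals* instead would give 14 min; both readings use 7
samples and the sample-timestamp convention is used consistently here.

## Adaptive strategies

Thresholds may vary per sample:

* **I — individualization.** Per vital, lower/upper limits are the
  `cdf_low`/`cdf_high` empirical percentiles (linear interpolation between
  order statistics) of the usable samples in the patient's first 24 h;
  default limits apply during those 24 h, and temperature keeps no lower
  limit. A vital with < 30 usable first-24-h samples keeps its defaults
  (logged). A constant first-24-h signal legitimately collapses the
  normal range to a point.
* **II — postoperative elevation.** Upper limits ×(1 + PO_increase) while
  `surgery_end ≤ t < surgery_end + 96 h`.
* **III — annunciation delay.** `n_abnormal` replaced by `l_interval`.
* **IV / V — day/night.** Daytime is [08:00, 22:00) local clock, nighttime
  its complement. IV multiplies the upper HR/RR limits by (1 + DT_increase)
  during daytime; V multiplies the lower HR/RR limits by (1 − NT_decrease)
  during nighttime.
* **VI — slope trend.** At each grid point with ≥ 50 % usable samples in
  the trailing window of length `t_slope` (and nonzero regressor spread),
  an OLS line is fitted; the sample is abnormal when the fitted change
  over one window, slope × t_slope, exceeds the per-vital limit (±15 bpm,
  ±10 brpm, ±1 °C by default). Absolute levels are ignored. The same
  annunciation/re-arm machinery runs on this abnormality signal (no
  separate annunciation rule is defined for trends). VI cannot be combined
  with I–V, which act on absolute levels.

Modifiers compose multiplicatively on the base (default or individualized)
limits, applied in strategy order (II, then IV/V); since each modifier is a
scalar factor the order does not change the result, but it is fixed for
reproducibility.

## Classification and metrics

An alarm is TP for an AE iff it is in the same patient, its trigger time
lies in [confirmation − 24 h, treatment end], and its (vital, direction) is
in the event's `affected` set — the machine-readable surrogate for
"physiologically explained by the event". With several eligible events the
alarm goes to the one with the latest confirmation time only. TP alarms
strictly before confirmation are TP_early (an alarm exactly at
confirmation is not early). Sensitivities count distinct events; events
whose [confirmation, treatment-end] interval never overlaps the patient's
recording are excluded from denominators. With zero alarms the FDR is
absent, not zero. Metrics are computed unrounded; reports round
sensitivities to integers and rates to 2 decimals, half away from zero.

## Performance score

Sub-scores are integers in [−3, 3] from bands around the reference: 5
percentage points per band for S_early, 0.25 alarms/patient/day per band
for TAR, with exact equality scoring 0 and the outermost bands open. The
P-score is their sum. Band edges are evaluated on the difference to the
reference rounded to 1e-9 so that printed band-edge inputs land in the
band the table assigns regardless of binary float representation. One
published worked-example row (longer annunciation delay, S_early 33 %,
TAR 0.25, printed score 0) is inconsistent with a literal banding of its
rounded inputs (which gives −1, since 0.25 − 0.49 = −0.24 falls in the +1
TAR band); the discrepancy is consistent with an unrounded TAR ≤ 0.24, and
the implementation follows the band table literally rather than special-
casing the row.

Optimal-parameter selection maximizes the P-score, breaking ties by lower
FDR, then smaller modification magnitude (sum of fractional factors; for I
the distance of the percentile pair from the extremes; for III the delay
count; for VI the reciprocal window length, chosen here since no magnitude
is defined for trend windows), then candidate order. Combination
evaluation scores every non-empty subset of {I..V}; backward elimination
repeatedly removes the strategy whose removal yields the best resulting
P-score (ties: lower FDR, then lowest strategy index) down to a single
strategy.

### A note on threshold monotonicity

"Widening a threshold never increases the alarm count" is a theorem of the
pure annunciation mechanism (with re-arm disabled, alarms per maximal
abnormal run are ⌊len/n⌋, and pointwise shrinking of the abnormal set only
shortens or splits runs). With re-arm active it can fail: raising an upper
limit can split one long abnormal streak (one alarm, then suppression)
into two qualifying streaks separated by a re-arming normal run (two
alarms). The property suite therefore asserts strict monotonicity with
re-arm disabled, asserts delay (`n_abnormal`) monotonicity under the full
7/5 rules, and pins the re-arm inversion with an explicit counterexample.

## Synthetic cohort

Each patient's channel is
`baseline + circadian + postoperative elevation + noise (+ artifacts)`:

* baselines drawn from truncated normals (defaults HR 78 ± 8 bpm,
  RR 16 ± 2.5 brpm, T 36.8 ± 0.3 °C), truncation keeping traces inside
  hard physiological bounds;
* a single sinusoid per vital with nadir at 03:00 (inside the 22:00–08:00
  night window) and peak-to-trough amplitudes 8 bpm / 3 brpm / 0.5 °C —
  the minimal structure that makes the day/night strategies act;
* a postoperative elevation of 10 % (HR, RR) / 1 % (T) of baseline,
  decaying exponentially with time constant horizon/4 and cut to zero at
  the 4-day horizon, matching the window strategy II assumes;
* white noise (3 bpm / 1.5 brpm / 0.15 °C);
* Poisson artifact bursts (2/day, 1–5 samples ≤ 10 min, upward-biased,
  left flagged valid) to exercise false-alarm behaviour;
* independent per-vital missingness (10 %), stored as absent values with
  cleared validity flags on the fixed grid.

Recording durations are log-normal (median 94 h, log-sd 0.45) truncated to
[28, 279] h; recordings start at a random clock time (circadian phase
varies across patients) and surgery end coincides with recording start.
About half the patients draw one adverse event: confirmation uniform in
the recording after the first day, a 48-h treatment window, an affected
set of upward abnormalities (HR/RR/T with probabilities 0.8/0.55/0.45, at
least one), severity mix I/II/III = 6/8/4, and a linear drift ramping from
12 h before confirmation to full magnitude (HR +40 bpm, RR +10 brpm,
T +1.5 °C) at confirmation, sustained until treatment end. These defaults
are calibration choices in typical adult postoperative ranges — the source
population's vital-sign distribution is not available — made once and used
as the study conditions throughout.

All randomness derives from one integer seed via spawned child generators,
so a (spec, seed) pair reproduces the cohort byte for byte after
serialization.

### What the generator does not emulate

No physical-activity component: real daytime mobilization produces
sustained HR/RR elevations that dominate false alarms in practice, so the
synthetic baseline run shows an FDR near 0 % and an alarm rate well below
clinical reports, and strategy effects on FDR are muted. Artifact bursts
are shorter than the annunciation delay by construction, so they perturb
individualized percentiles and slope windows rather than firing alarms
directly. AEs here always produce drifts in their affected vitals; real
events may present without vital-sign changes, or in vitals outside the
monitored set. Passing tests therefore validate the *mechanisms*
(streak rules, threshold adaptation, classification, scoring) — not
clinical performance claims.

## Problem sizes and numerics

Default analyses use 39 patients (~160 patient-days); property tests use
ensembles of up to 200 random traces of ≤ 1,000 samples, 10-seed cohorts
of 8–20 patients, and a dense score-band grid — sizes chosen so the full
suite runs in minutes while each check has enough events to bite. Rolling
OLS uses cumulative sums (the regressor spans hundreds of hours at most,
well within double precision); windows with denominator < 1e-9 are
undefined. CSV timestamps are ISO-8601 local clock time without timezone,
because the day/night strategies are defined on clock time.
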