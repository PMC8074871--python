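# phenokit

Desk-scale analytics for **digital phenotyping** — the moment-by-moment
quantification of behavior from personal devices. `phenokit` re-implements
the computational backend of a smartphone + wearable sensing platform as an
importable Python library: it ingests per-day raw sensor stream files
(accelerometer, GPS, power state, call/SMS/messaging logs, taps, ambient
light, plus wearable heart-rate, step and sleep records), applies the
at-collection privacy transforms, engineers daily behavioral features,
accounts for data completeness, scores daily anomalies against empirical
forecast residuals, and runs a paired pre/post comparison around an abrupt
behavioral regime change. A seeded synthetic cohort generator with planted
ground truth makes every stage testable without any real participant data.

It is written for researchers and data scientists running passive-sensing
studies (mental health, behavioral medicine, quantified-self cohorts) who
need the backend pieces — not the phone apps or cloud plumbing — on a desk.

## The methods in brief

* **Daily features.** Per participant-day: accelerometer variability
  (SD of ‖a‖ and max |d‖a‖/dt|), ambient light (mean of hourly max
  log(1+lux)), screen-on rate, taps by 7-class app grouping, sociability
  counts (calls in/out, messages exchanged, calls > 1 min), GPS mobility
  (hometime, time away, significant locations visited, max distance from
  home), steps and walking minutes, heart-rate mean/min, and sleep totals
  with efficiency. Missing data is three-valued: a value, *no data*, or
  *device not worn* — the last inferred from nocturnal heart-rate coverage
  gaps exceeding an allowance, so an unworn night is never reported as zero
  sleep.
* **Completeness.** A stream-day counts as collected iff its daily file
  exists (empty files included); per-feature rates pool participant-days and
  the overall figure is their unweighted mean.
* **Anomaly scores.** Each feature series is re-fit daily on all past data
  (seasonal-naive, weekly autoregression, or periodic Gaussian process); the
  realized one-step error e is scored against the training residuals r as
  score = (#{|r|<|e|} + ½#{|r|=|e|}) / T ∈ [0,1], and a multivariate score
  refers Σ(eₖ/σₖ)² to a χ²_K CDF.
* **Regime comparison.** Per-participant feature means over inclusive day
  offsets [−45,−3] and [+3,+45] around the event, compared with a paired
  t test and an exact (≤ 12 pairs; sign-flip enumeration) Wilcoxon
  signed-rank test.

Details, defaults and design rationale: [`docs/methods.md`](docs/methods.md).

## Worked example

```python
import phenokit as pk

cfg = pk.default_cohort_config(n_participants=22, n_days=90, seed=1)  # level shift at day 45
cohort = pk.generate_cohort(cfg, seed=1)
daily = pk.build_daily_table(cohort)
table = pk.compare_table(daily, cfg.event_date)
print(table[["feature", "mean_before", "mean_after", "p_paired_t"]])
```

prints (abridged):

```
                 feature  mean_before  mean_after   p_paired_t
           daily_n_steps      6958.26     4077.20    7.712e-12
            hometime_min      1281.90     1355.68    1.046e-10
 n_taps_in_entertainment        88.42      115.88    1.981e-14
   sleep_mean_efficiency        91.63       90.26    5.898e-16
```

Read: after the planted stay-at-home shift, daily steps drop (≈ 6 958 →
4 077), minutes at home rise (≈ 1 282 → 1 356 of 1 440), entertainment-app
tapping rises, and sleep efficiency degrades slightly — each a paired
difference across the 22 participants' window means, with its two-sided
paired-t p value. Every direction matches the configured regime effect.

The `examples/` directory has one short narrative script per capability
(simulation and planted truth, feature extraction, mobility, completeness,
anomaly scoring, regime comparison). A thin CLI mirrors the library:

```bash
phenokit simulate --out data/ --seed 1
phenokit run-all --in data/ --out report/ --event 2020-04-07
```

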