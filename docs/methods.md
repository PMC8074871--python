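# Methods

`phenokit` is a desk-scale re-implementation of the computational backend of
a smartphone + wearable digital-phenotyping platform: raw per-day sensor
stream files go in, daily behavioral features, completeness accounting,
anomaly scores and a pre/post regime comparison come out. This note records
the models and procedures, the parameters that matter, what the synthetic
cohort generator does and does not emulate, and the numerical choices made
where the design was genuinely open.

## Data model and privacy transforms

Each raw stream lands as one UTF-8 CSV per participant, stream and local
calendar date (`<root>/<pid>/<stream>/<YYYY-MM-DD>.csv`), ISO-8601 UTC
millisecond timestamps in the first column. Thirteen stream kinds are
supported: ten phone streams (accelerometer, GPS, power state, call log, SMS
log, app-call log, app-message log, taps, accessibility events, ambient
light) and three wearable streams (heart rate epochs, step epochs, staged
sleep episodes). A header-only file is a real observation — "collected, but
no events" — and is deliberately distinct from an absent file; this
distinction drives both the completeness accounting and the feature
missingness semantics.

Privacy transforms happen before anything is serialized:

* **GPS obfuscation.** Every participant gets one random displacement
  (dlat, dlon), drawn once from a seeded generator and reused for all of
  their records. Translation preserves all within-participant spatial
  structure, so mobility metrics are unaffected.
* **Counterparty hashing.** Communication counterparties are replaced with
  HMAC-SHA256 tokens (128-bit, salt kept outside the data tree), prefixed so
  they can never pass a digits-only phone-number pattern.
* **Keystroke tokenization.** Raw keys are reduced to type tokens
  (alphabetic / numeric / punctuation / delete / backspace / enter / none);
  no character content is ever stored.

**Distance metric.** All spatial computation uses an equirectangular planar
approximation with the east–west scale fixed at a study reference latitude
(default 1.35°N, configurable). Fixing the reference latitude — rather than
using each point's own latitude — makes the metric depend only on coordinate
differences, so it is *exactly* invariant under the obfuscation translation;
at city scale the approximation error versus great-circle distance is
negligible (< 0.03% over 10 km at equatorial latitudes).

**Sleep day assignment.** A sleep episode is filed under its wake date, so a
sleep stream-day may legitimately contain timestamps from the previous
evening; every other stream's records lie within the local day.

## Daily features

One row per participant × enrolled date. Every feature is a value or an
explicit marker distinguishing `missing_no_data` (stream not collected) from
`missing_not_worn` (wearable off). Key definitions:

* `accel_L_std` — sample SD of the acceleration vector length
  L = sqrt(x²+y²+z²) over the day; `accel_ddt_max` — max |ΔL/Δt| over
  consecutive pairs no more than 1 s apart (the cutoff guards against
  duty-cycled sampling gaps; no smoothing).
* `ambient_hourly_max_log1p_lux` — mean over clock hours with data of the
  hourly max of ln(1+lux). Natural log.
* `hourly_n_screen_on` — total screen-on events / 24 (flat daily mean;
  configurable denominator).
* Taps: unique apps touched, per-class tap counts through the 7-class app
  grouper (social messenger, social media, entertainment, map navigation,
  utility tools, games, android systems; unmapped apps fall into the last),
  and the delete+backspace count.
* Sociability: incoming/outgoing call counts, messages exchanged across SMS
  and messaging-app channels, and calls strictly longer than 60 s. Missed
  calls count nowhere.
* Steps: daily total and walking minutes (minutes with ≥ `walk_threshold`
  steps after resampling to minute resolution; default 10 steps/min — the
  threshold is a design choice, there is no canonical definition).
* Heart: duration-weighted mean bpm and plain minimum.
* Sleep: total asleep hours (non-wake stage minutes) and mean efficiency,
  weighted by time in bed — algebraically, 100 × total asleep / total in
  bed.

**Wear disambiguation.** A night with no sleep records is ambiguous: no
sleep, or device off? Heart-rate epochs are recorded continually while the
device is worn, so the night window (default 22:00–08:00 local) is scanned
for heart coverage; if the uncovered time exceeds the allowance (default
120 min, boundary inclusive) the night is ruled not-worn and sleep features
are `missing_not_worn`, never zero. A worn night with no episodes yields
total 0 h with efficiency undefined. Daytime steps/heart use an analogous
day-worn rule (≥ 60 min of heart coverage).

## Mobility

Significant locations come from a greedy chronological density pass: each
GPS point joins the first cluster whose anchor is within `eps_m` (100 m),
else founds a new cluster; dwell is credited as the gap to the next point of
the day, capped at 30 min; clusters with ≥ 30 min total dwell are
significant. The procedure is deterministic given the input order — chosen
over k-means/DBSCAN precisely so tests can pin its output. Home is the
cluster with maximal nocturnal (00:00–06:00) dwell, falling back to maximal
total dwell (flagged low-confidence) when no nocturnal points exist.

Daily metrics classify each sample as at-home iff within `home_radius_m`
(200 m) of the home center. Hometime sums inter-sample intervals ≤ 30 min
whose *both* endpoints are at home; time away is the mirror image; mixed or
long intervals count toward neither, so the two never double-count and the
total never exceeds the day. No GPS imputation is performed anywhere.
"Radius of gyration" follows the clinician-dashboard usage — the maximum
distance from home that day; the classical RMS definition is available as
`rog_mode="rms"`.

## Completeness

A stream-day counts as collected iff its file is present (empty included).
Per-feature rates pool participant-days: 100 × days-with-data /
days-enrolled, reported to one decimal; the overall aggregate is the
unweighted mean of per-feature rates — the only aggregation consistent with
the reference deployment table shipped with the package. The completion
matrix reduces each participant-day to a phone row and a wearable row
(complete / partial / missing / not-enrolled), and upload recency is colored
green ≤ 24 h, orange ≤ 48 h, red beyond (invented thresholds, configurable —
the source platform defined only the color semantics).

## Anomaly scoring

Every day, for every feature series, a forecaster is fit on all past data
(expanding window, never touching the target day) and the realized absolute
one-step error is located in the empirical distribution of the model's
training residuals:

    score = (#{|r| < |e|} + ½·#{|r| = |e|}) / T

Scores live in [0,1]; higher is more anomalous; a day that cannot be scored
carries a NaN sentinel, never 0 or 1. Models: `seasonal_naive` (value 7 days
prior; residuals x_t − x_{t−7}), `ar_weekly` (least squares of x_t on
x_{t−1}, x_{t−7} and weekday indicators — an ARIMA-family stand-in), and an
optional `gp_periodic` (squared-exponential + 7-day periodic kernel). The
scorer interface is pluggable. `min_history` defaults to 21 observed days;
alert colors at 0.80/0.95. The multivariate score standardizes each
feature's error by its residual SD and refers Σ(e/σ)² to a χ²_K CDF
(diagonal standardization; cross-feature covariance is not modeled).

Numerical notes:

* `ar_weekly` in-sample residuals are rescaled by sqrt(m/(m−p)) so their
  spread matches the out-of-sample error scale; without this the high-alert
  rate on null data runs ~8.5% instead of ~5%. Early in the window
  (m barely above p = 9) scores still run slightly hot because parameter
  estimation error inflates true prediction error; `seasonal_naive` is the
  calibration reference.
* The empirical-tail transform is discrete: with T residuals the score lives
  on the lattice {0, 1/T, …, 1} and carries atoms of mass 1/(T+1) at the
  endpoints. Pooled over many short-history days this is detectable by a
  large-n uniformity test (a pooled KS test across ~7×10⁴ scores rejects
  with D ≈ 0.01 even though per-day calibration is correct and the
  high-alert fraction is nominal). The transform is kept as specified — its
  endpoint behavior (a record-breaking error scores exactly 1) is part of
  the alerting contract.

## Pre/post regime comparison

For an abrupt, externally-dated behavioral regime change, each participant
contributes a mean per feature over an inclusive window of day offsets
[−45, −3] before and [+3, +45] after the event (43 days each, a 5-day guard
band); a participant qualifies per feature with ≥ 7 non-missing days in each
window. Cohort-level paired t (t = mean(d)/(sd(d)/√n), df = n−1) and
Wilcoxon signed-rank tests are reported with across-participant mean (SD) of
the window means. The Wilcoxon p is exact — the W⁺ distribution under sign
flips is built by rank-polynomial convolution (ranks doubled so tie-averaged
half-ranks stay integral) — up to 12 nonzero differences, then a
tie-corrected, continuity-corrected normal approximation; two-sided p is
2·min(lower, upper tail), capped at 1. Zero differences are dropped;
all-zero and zero-variance cases yield flagged undefined p values, never 0.
P values are unadjusted by default (Benjamini–Hochberg available as an
opt-in column).

## Synthetic cohort generator

The generator is first-class code: it produces all 13 streams with the
statistical structure the pipeline assumes, plus a manifest of closed-form
planted expectations so recovery tests need no reference data.

Defaults define the study conditions: 22 participants × 90 days starting
2020-02-22 in UTC+8, with an instantaneous level shift at day 45 (an abrupt
stay-at-home order analogue; a step, not a ramp, matching the windowed
before/after design). Per day: a nightly sleep episode (Gaussian onset
~23:00 ± 40 min, Gaussian duration 7.5 ± 0.8 h, Beta-scaled efficiency in a
per-participant range) tiled with staged segments whose asleep fraction
equals the drawn efficiency exactly; heart epochs every 5 min while worn
with a cosine circadian waveform (peak 16:00); lognormal daily step totals
(weekend multiplier) decomposed into 100-step walking minutes (80% of the
total) and 5-step background minutes; GPS every 10 min at home or at one of
2–3 fixed places visited with per-place probabilities in grid-aligned time
slots; Poisson communication, tap (per app class), screen-on (hourly
profile) and accessibility events; lognormal day/night ambient light; and
hourly 10 Hz accelerometer bursts around gravity.

Missingness: whole-day phone silence (p=0.02), per-stream file absence
(p=0.03), non-wear days (p=0.10, removing heart/steps/sleep together so the
wear-coupling invariant holds by construction), and daytime non-wear blocks
of 1–3 h (p=0.25). Regime multipliers: steps ×0.6, place-visit probability
×0.5, incoming calls ×0.5, screen-on ×0.75, active app pool ×0.7,
entertainment taps ×1.3, daytime lux ×0.7, accelerometer SD ×0.7, sleep
efficiency ×0.985 — directions chosen to mirror the reference deployment's
observed lockdown effects, magnitudes chosen once to be comfortably
detectable with 22 participants.

Planted truth is exact where the model permits: steps (lognormal mean with
the realized weekday mix of the simulated span), walking minutes (with the
floor-rounding correction), sleep totals and efficiency, hometime/away (from
10-minute-grid interval bookkeeping: a visit of d minutes removes d+10 home
minutes and contributes d−10 away minutes), communication and tap rates,
unique apps (Poisson thinning: Σ k(1−e^{−λ/k})), and the heart-rate mean
(with a deterministic numeric correction for the circadian mass clipped by
daytime non-wear blocks). Ambient-light and accelerometer summaries have no
tractable closed form; the manifest declares their planted direction only.

What the generator does **not** emulate: map-matched trajectories,
physiological heart-rate dynamics beyond a smooth circadian trend,
autocorrelated day-to-day behavior within a regime, device clock drift, or
adversarial/malformed uploads (exercised separately with hand-written
fixtures). Passing recovery tests therefore demonstrates pipeline
correctness under the declared generative model, not robustness to every
pathology of field data.

## Validation experiments

`phenokit.experiments` (driven by `scripts/acceptance.py`) regenerates every
headline number from scratch: the reference completion-rate aggregate
(92.2% over 13 features); exact-Wilcoxon agreement with a 2ⁿ sign-flip
enumeration oracle and paired-t agreement with an independent implementation
on 1,000 random paired vectors; anomaly calibration on 200 stationary
Gaussian series of 365 days (high-alert fraction and pooled KS uniformity,
with the discreteness caveat above); median changepoint-day score for a 3σ
level shift at day 200 over 100 replicates for both forecasters; a 20-seed
regime-shift experiment (22 × 90) measuring direction recovery and paired-t
significance for all nine planted families; and moment recovery of steps,
sleep and hometime (plus completion rates) within Monte-Carlo standard
errors over 150-day simulations. Problem sizes were chosen to keep the full
validation run in the minutes range on a single CPU.

## Known limitations

* Hometime uses raw GPS coverage with no 24-hour normalization or
  imputation; days with sparse GPS under-report both hometime and time away
  (by design — gaps count toward neither).
* Window means weight every non-missing day equally; differential
  missingness between the pre and post windows can bias per-participant
  means for features with strong weekday structure.
* The multivariate score ignores cross-feature covariance and treats
  residual SDs as known.
* `ar_weekly` scores are mildly anticonservative right after `min_history`
  is reached (estimation noise); with 9 parameters it needs several weeks of
  history before its residual scale stabilizes.
* The 7-class app grouper ships as a static table; a real deployment would
  refresh it from an app-store crawl.
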