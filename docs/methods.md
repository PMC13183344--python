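# Methods

This note documents the models, algorithms and numerical choices behind
`stressjitai`: what each pipeline stage computes, which parameters matter,
what the synthetic-data generator does and does not emulate, and where the
design was genuinely open.

## 1. HRV features (`hrv_core`)

Input is a stream of timestamped RR intervals (ms) from a wrist PPG logger.
Artifact screening flags (never deletes) beats outside `[min_rr, max_rr]`
(defaults 300/2000 ms) or jumping more than `max_relative_jump` (default
20%) relative to the last accepted beat — standard plausibility screens for
optically derived beat series. The stream is tiled into non-overlapping
half-open 5-minute windows, left-aligned to the first valid sample; an
incomplete trailing window is dropped. A window needs at least `min_beats`
(default 100) valid beats to be usable (`quality="ok"`); below that, no
feature values are reported.

Per usable window:

* **SDRR** — population standard deviation (divide by *n*) of the RR values.
  The population convention is used because the quantity is a descriptive
  windowed statistic, not an estimator of a hypothetical larger sample.
* **RMSSD** — `sqrt(mean(diff^2))` over successive differences. A
  difference is taken only between *adjacent* beats: the timestamp spacing
  must agree with the later beat's RR value to within 100 ms. A removed
  artifact beat inflates the spacing by at least `min_rr` = 300 ms, and a
  sensor gap by far more, so differences never span holes.
* **LF/HF** — band powers of the RR tachogram integrated over LF
  (0.04–0.15 Hz) and HF (0.15–0.40 Hz); the bands are the conventional
  short-term HRV bands and are configurable. The default spectral
  estimator is the classical Lomb–Scargle periodogram, which natively
  handles unevenly sampled, gap-ridden beat series; a 4 Hz cubic-spline
  resampling + Welch estimator is selectable as an alternative. The
  periodogram is evaluated on a grid of 4 points per leakage linewidth
  (`df = 1/(4T)`) and scaled by `2/fs_mean` so that a sinusoid of amplitude
  *A* integrates to approximately `A^2/2` ms²; only the LF/HF *ratio*
  matters downstream, for which the normalization cancels. On an
  arithmetic frequency grid the periodogram is computed via a complex
  cumulative-product recurrence (O(*n*) transcendental calls instead of
  O(*n·m*)), which agrees with the direct evaluation to ~1e-12 relative
  error and is roughly an order of magnitude faster.

## 2. Trigger engine (`trigger_engine`)

Physiological triggering is personalized by clamped quantiles of the user's
own feature history:

```
theta_LFHF  = max( Q75(LF/HF history), 1.2 )      # trigger when LF/HF >= theta
theta_RMSSD = min( Q25(RMSSD history), 50 ms )    # trigger when RMSSD <= theta
```

Quantiles are sorted-order statistics with linear interpolation (the NumPy
`"linear"` definition), tested against a from-first-principles oracle. The
history is the expanding set of all prior ok-quality windows for that user,
recomputed before every new window, so thresholds are always "current". A
user with fewer than `min_history` windows (default 12, i.e. one hour of
data) falls back to the clamp values themselves.

A **stress event** is annotated when *both* conditions hold (LF/HF at or
above threshold and RMSSD at or below threshold) in **two consecutive**
windows. Design choices that the two-consecutive-windows rule leaves open,
all declared and tested:

* Boundary comparisons are inclusive (`>=`, `<=`).
* Windows are consecutive only when their starts differ by exactly one hop
  — a sensor gap breaks the run.
* After an event, a refractory period (default 30 minutes) suppresses
  re-annotation; without it every window pair inside a sustained episode
  would spawn an event.
* The pair that fired is consumed: its second window cannot seed the next
  pair.

Subjective triggering is unpersonalized: an EMA entry fires iff its
momentary valence is ≤ 3 on the 7-point scale (1 = negative).

## 3. Intervention engine (`intervention_engine`)

A delivery walks the decision tree to a leaf (the user's choice of stressor
branch), then samples one microintervention from the leaf with probability
proportional to its weight. Weights live in a table owned either by the
individual (*high* personalization) or by the whole cohort (*low*); the
update rule is multiplicative-exponential on the rated item only:

```
w_i <- max( floor, w_i * exp( eta * (r - 3) ) ),   r in 1..5
```

with weight floor 0.01 (every item stays reachable) and default learning
rate `eta = 1.0`. The rating scale (1–5, midpoint 3) and the rule itself
are package choices — they satisfy the stated behavioral contract (midpoint
ratings are no-ops, praise raises selection probability, criticism lowers
it, and scopes respect the high/low mode semantics). The learning rate was
calibrated against the preference-recovery requirement that a user rating
one CBT category 5 and everything else 1 concentrates >80% of selection
probability on that category within 50 feedback cycles over the 179-item
pool: per-item multiplicative updates move *category-level* mass only
through a rich-get-richer loop (a praised item is reselected, praised
again, and eventually dominates), which stalls below `eta ≈ 0.8` (measured
plateau ~0.34 at `eta = 0.3`) and saturates reliably from `eta ≈ 0.8`
upward; 1.0 is the default with margin. One 5-rating multiplies an item's
weight by `e^2 ≈ 7.4`.

The packaged default pool has exactly 179 items with synthetic metadata
(ids, CBT subarea — psychoeducation / training / relaxation / other-CBT —
and a presentation format, uniform initial weights); the therapeutic
content itself is out of scope. The default tree has four stressor
branches, each leaf spanning all four CBT categories, so the weighted
sampling — not the branching — carries the personalization.

## 4. Trial simulator (`trial_simulator`)

The simulator exists so the whole closed loop (windowing → triggering →
delivery → rating → weight update → physiological consequence) can be
exercised and calibrated without any real participants.

**Latent stress.** Each participant carries a calm/stressed regime process
on a 5-minute grid: episode onsets are Bernoulli per step (default 0.012
during 09:00–17:00 on weekdays, 0.002 otherwise), durations geometric
(mean 30 minutes), intensity drawn per episode from `U(0.8, 1.8)` times
the participant's stress reactivity. This is the standard two-state Markov
regime written as an episode overlay, which vectorizes per day.

**Physiology.** RR intervals are generated per window as a stress-shifted
mean (−80 ms per unit stress) plus two sinusoids — 0.10 Hz (inside LF) and
0.25 Hz (inside HF) — plus white beat-to-beat jitter. Calm-state
amplitudes are solved in closed form from two targets per participant
(windowed RMSSD ≈ 22 ± 5 ms; windowed LF/HF ≈ 0.88 ± 0.05): a sinusoid of
amplitude *A* at frequency *f*, sampled every `tau` seconds, contributes
`2 A^2 sin^2(pi f tau)` to the mean squared successive difference and
`A^2/2` to its band power, while jitter of variance `sigma^2` contributes
`2 sigma^2` and spreads uniformly to Nyquist. Under stress level *s* the HF
amplitude and jitter shrink by `1/(1 + 0.5 s)` and the LF amplitude grows
by `(1 + 0.5 s)`, so RMSSD falls and LF/HF rises several-fold — the exact
signature the trigger engine detects. The HF tone carries most of the
RMSSD budget (fraction 0.8), keeping the per-window LF/HF estimator CV
near 10%.

The calm LF/HF target deliberately sits *below* the 1.2 trigger floor: the
floor only functions as a guard against annotating unstressed users if
calm values cannot reach it. A consequence is that simulated weekly LF/HF
(~0.9–1.2) runs lower than the levels wearable cohorts typically report
(~1.5–1.8); those field levels mix postures, activity and measurement
artifacts the generator does not model.

**Behavior.** EMA valence/arousal are noisy monotone transforms of the
momentary latent stress clipped to 1–7 (calm means ≈ 5.6 / 3.1, matching
typical occupational EMA levels); during-day entries also rate the most
recent stress episode; morning/evening entries carry a daily chronic-stress
item. Entries are dropped with probability 1 − `ema_compliance` (drawn
0.85–1.0); the sensor is worn on a given day with probability
`sensor_compliance` (drawn 0.45–0.8, bracketing the 45–60% sensor yield
wearable pilots report), with a 1-hour off-wrist break every wear day.

**Intervention effect.** A delivered exercise subtracts
`effect_size * responsiveness * match` from latent stress (full credit for
a category match, `partial_match = 0.25` otherwise), decaying with a
15-minute half-life over 30 minutes, floored at zero. Ratings are a noisy
monotone function of the same match. Default `effect_size = 0.6` is a
moderate fraction of a typical episode intensity; the true effect of such
microinterventions is unknown, and the zero-effect configuration is the
reference point for all calibration claims.

**Randomness.** All draws descend from one seeded root. Each participant
owns two substreams: an *environment* stream (latent process, beat noise,
wear and EMA schedules) and a *policy* stream (weighted selection,
feedback). Two runs differing only in personalization policy therefore
share identical stress environments — the paired design used by the
arm-contrast property test — and phase-1 dynamics are bit-identical
regardless of the (separately drawn) phase-2 arm assignment.

**Study structure.** Two 3-week phases; phase 1 runs everyone on the shared
cohort table (low personalization); at the phase-2 boundary the cohort is
randomized 1:1, the high arm switching to private copies of the cohort
table at that moment (continuity of the user experience), the low arm
continuing on the shared table.

## 5. Evaluation (`evaluation`)

Raw streams are averaged into weekly means per participant (6 weeks). A
participant-variable series is excluded iff *more than* 75% of its data is
missing (strict inequality; exactly 75% is kept). Each outcome is fitted
with a linear mixed model — week and arm as categorical fixed factors,
random intercept per participant — delegated to statsmodels `MixedLM`
(REML). Each factor's F statistic is the Wald chi-square of its contrasts
divided by the contrast count; denominator degrees of freedom follow the
classical repeated-measures convention, `df_num * (N − 1)` for the time
factor and `N − 2` for the group factor. (Published mixed-model tables
sometimes show fractional denominator dfs from Satterthwaite-type
approximations; `MixedLM` does not provide one, and the convention used
here reproduces the balanced-design dfs exactly.) Effect sizes are partial
eta-squared, `F·df1 / (F·df1 + df2)`. Benjamini–Hochberg correction is
applied across the within-subject outcome family (and separately across the
between-subject family); Bonferroni (`min(1, p·m)`) is provided for post
hoc pairwise contrasts. The System Usability Scale is scored to 0–100
(odd items contribute `item − 1`, even items `5 − item`, total × 2.5);
satisfaction is a plain 1–5 scale mean. Significance level 0.05.

Monte-Carlo calibration (100 synthetic null panels): the harness's raw
time-effect p values are uniform (KS p ≈ 0.7) with rejection rate 0.05 at
`alpha = .05`, and power > 0.8 against a week-linear decline of 0.12/week
at N = 40.

## 6. Problem sizes used in the checks

Simulation-backed tests run scaled configurations chosen to keep the
stochastic assertions well-powered: the null-calibration suite uses 20
replicates of the full 46-participant, 6-week trial at 1 hour of sensor
wear and 2 during-day prompts per day; the arm-contrast property uses 8
paired 12-participant trials in a feedback-rich subjective-trigger regime
(6 prompts/day, guaranteed feedback, no partial credit for mismatches).
At the study's own delivery rate (~10 interventions per participant in 6
weeks) the ground-truth high-vs-low contrast is statistically
indistinguishable from episode noise even with paired environments — a
simulator-side reason why pilots of this size report null group effects.

## 7. Known limitations

* The physiological generator is a two-tone-plus-jitter model: no
  respiration coupling, posture, motion artifacts, circadian drift, or
  non-stationary spectra. Passing tests show the *pipeline* behaves as
  specified under controlled spectra, not that triggers would be accurate
  on field PPG data.
* Latent "stress" is a scalar with exchangeable weeks; real affect has
  trends, weekday/weekend structure beyond work-hour episode rates, and
  anticipation effects, so the null-calibration result speaks to the
  statistics pipeline, not to real-world type-I error.
* The intervention effect model is linear in match and responsiveness with
  a fixed decay; it exists to make preference learning recoverable, not to
  claim a dose-response shape.
* EMA responses are conditionally independent given latent stress; no
  response styles, anchoring or time-of-day item effects.
* The missingness mechanism (day-level Bernoulli wear, entry-level
  Bernoulli EMA) is missing-completely-at-random; the 75% exclusion rule is
  therefore never stress-tested against informative missingness.
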