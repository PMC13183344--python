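# stressjitai

A research toolkit for **just-in-time adaptive interventions (JITAI)**
against occupational stress: wearable heart-rate-variability (HRV) feature
extraction, personalized stress-event triggering, preference-weighted
microintervention selection with feedback learning, a two-phase micro-trial
simulator, and the matching statistical evaluation pipeline. It is aimed at
mHealth methodologists who want to stress-test a trigger-and-recommend
stack end to end on fully synthetic, ground-truth-known data before any
participant wears a sensor.

## The computational core

**HRV features.** RR-interval streams from wrist PPG are screened for
artifacts and tiled into 5-minute windows; each window yields SDRR
(population SD of RR), RMSSD (√mean squared successive difference, taken
only across truly adjacent beats) and the LF/HF ratio of band powers
(0.04–0.15 Hz vs 0.15–0.40 Hz) from a Lomb–Scargle periodogram of the
unevenly sampled tachogram.

**Personalized triggering.** Per user, running clamped-quantile thresholds

```
θ_LFHF  = max(Q75(LF/HF history), 1.2)        trigger when LF/HF ≥ θ_LFHF
θ_RMSSD = min(Q25(RMSSD history), 50 ms)      trigger when RMSSD ≤ θ_RMSSD
```

annotate a physiological stress event when both conditions hold in two
consecutive windows (30-minute refractory). A subjective event fires when
an EMA entry reports momentary valence ≤ 3 on the 7-point scale.

**Adaptive selection.** An event routes through a decision tree to an
eligible set within a 179-item microintervention pool (CBT subareas:
psychoeducation, training, relaxation, other-CBT); one item is sampled with
probability ∝ its weight, and the user's 1–5 rating updates that weight as
`w ← max(0.01, w·exp(η(r−3)))`. Under *high* personalization ratings
update the user's own table; under *low*, a single cohort-shared table.

**Trial simulation + evaluation.** Synthetic employees with latent
calm/stressed episode processes wear the sensor, answer EMA prompts, and
receive interventions through exactly the engines above, over two 3-week
phases with 1:1 high/low randomization at the phase boundary. The
evaluation module aggregates outcomes to weekly means, excludes series with
>75% missing data, fits linear mixed models (week + arm fixed factors,
random participant intercept, via statsmodels), reports partial η²
effect sizes and Benjamini–Hochberg-adjusted p values, and scores the
System Usability Scale to 0–100.

## Worked example

Simulate a 12-participant, 6-week trial and evaluate it:

```bash
cat > trial.yaml <<'YAML'
n_participants: 12
phase_weeks: 3
sensor_hours_per_day: 2.0
ema_during_day: 3
keep_rr: false
YAML
stressjitai simulate --config trial.yaml --seed 7 --out trial.json
stressjitai evaluate --trial trial.json --out results.csv
```

which prints

```
simulated 12 participants over 6 weeks; 116 stress events
            variable effect        F  df_num  df_den    p_raw  p_adjusted  eta_p_sq  n  significant
daily_chronic_stress   time 1.982350       5      55 0.095687    0.765494  0.152696 12        False
daily_chronic_stress  group 0.000799       1      10 0.978007    0.978007  0.000080 12        False
   valence_momentary   time 0.347046       5      55 0.881975    0.881975  0.030585 12        False
...
               lf_hf   time 0.746692       5      55 0.592002    0.881975  0.063566 12        False
               lf_hf  group 0.122571       1      10 0.733524    0.978007  0.012109 12        False
```

116 events over 12 participants is ~9.7 delivered interventions per
participant across the six weeks. Each row is one fixed-effect test from
the weekly mixed model of an outcome: `time` is the within-subject
week effect (5 numerator df over 6 weeks), `group` the high-vs-low arm
effect; `p_adjusted` is Benjamini–Hochberg across the outcome family and
`eta_p_sq` the partial η² effect size. With the default (small) simulated
effect sizes and n = 12, nothing survives correction — which is the
expected reading for a pilot-scale run.

Library use mirrors the CLI:

```python
from stressjitai import hrv_core, trigger_engine, io_formats

series = io_formats.read_rr("rr.csv", participant_id="P001")
features = hrv_core.compute_features(series)
events = trigger_engine.detect_physio_events(
    features,
    lambda i, f: trigger_engine.personal_thresholds(f[:i]),
    participant_id="P001",
)
```

## Layout

| Module                               | Role |
| ------------------------------------ | ---- |
| `stressjitai.io_formats`             | typed readers/writers: RR CSV, EMA CSV, pool/tree JSON, event logs, trial records |
| `stressjitai.hrv_core`               | artifact screening, windowing, SDRR / RMSSD / LF-HF |
| `stressjitai.trigger_engine`         | clamped-quantile thresholds, physiological + subjective event detection |
| `stressjitai.intervention_engine`    | decision-tree eligibility, weighted selection, feedback learning |
| `stressjitai.trial_simulator`        | synthetic cohort, latent stress process, closed-loop two-phase trial |
| `stressjitai.evaluation`             | weekly aggregation, missingness rule, mixed-model harness, η², BH/Bonferroni, SUS |

Design notes, model assumptions and known limitations are in
[`docs/methods.md`](docs/methods.md).
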