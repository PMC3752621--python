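# icualarms

Multi-sensor "smart alarm" definitions for ICU bedside monitors, with a
synthetic vital-sign simulator and a positive-predictive-value evaluation
pipeline.

## The problem

Conventional bedside-monitor alarms watch one sensor at a time and are tuned
for sensitivity, so 80–99 % of what they produce is false — motion artifact,
a flushed pressure line, a mis-leveled transducer — and caregivers learn to
ignore them (*alarm fatigue*). A practitioner at the bedside does not make
that mistake, because they cross-check: a heart rate of 190 with a normal
arterial waveform and a normal plethysmograph is artifact, not ventricular
tachycardia.

`icualarms` implements that cross-checking logic as a testable rule engine.
An alarm *definition* combines up to four single-parameter **triggers**,
each either

- a sustained absolute threshold violation — value strictly beyond a limit
  *L* continuously for *d* seconds (e.g. ARTsys < 78 mmHg for 300 s),
- a relative change — the smoothed value at time *t* differing from the
  smoothed baseline at *t − τ* by at least *p* % (or an absolute delta,
  e.g. +30 bpm) for some lag τ ∈ (0, W], or
- a rhythm-annotation flag held for *d* seconds,

and the definition fires only when **every** trigger slot has been active
within a co-occurrence window (default 60 s). After firing, the rule is
refractory (default 300 s). Evidence from independent sensors must agree
before any sound is made; a single corrupted channel cannot fire a
multi-sensor rule, which is the suppression mechanism the package exists to
study. The PPV of a definition is TP / (TP + FP) over adjudicated alarm
events.

Five clinically important definitions ship built in: hemodynamically
significant SVT (SVT+BP), ventricular tachycardia with hypotension
(Vtach+BP), left-ventricular shock, tamponade/obstructive shock, and
hypovolemia. Their limits and trigger times follow the configuration
deployed in a 10-bed cardiothoracic ICU study; user rules load from YAML.

Because no public dataset accompanies those definitions, the package
includes a seeded generator of synthetic patient records (1 Hz numerics,
lag-1 autoregressive baselines) in which clinical episodes and artifact
mechanisms are injected with analytic ground truth: an episode with
severity margin +10 % provably exceeds every relevant limit, one at −10 %
provably misses them all. The evaluation module matches alarms to truth
intervals and assigns the study's eight-way event classification (TPRE,
TP Predict, FP Artifact, FP Insufficient-Definition, FN threat / non-threat
/ sensor-off, TN time-interval), then tabulates per-scenario counts and PPV.

## Worked example

```python
from icualarms import (
    CohortSpec, PlanItem, builtin_scenarios, detect_cohort, evaluate_cohort,
    simulate_cohort,
)

spec = CohortSpec(
    n_patients=2,
    duration_s=43200,           # two 12 h records
    plan=[
        PlanItem("svt_bp", 4, margin_pct=10),       # detectable AF episodes
        PlanItem("lv_shock", 2, margin_pct=10),
        PlanItem("svt_bp", 2, margin_pct=-10),      # real but sub-threshold
        PlanItem("artifact_cvp_spike", 2),          # infusion artifacts
    ],
    seed=7,
)
records, truth = simulate_cohort(spec)
alarms, eligibility = detect_cohort(records, builtin_scenarios(),
                                    compatibility_mode=True)
classifications, summary = evaluate_cohort(alarms, truth, records=records)
print(summary.to_text())
```

```
   scenario  n_events  tp  fp_artifact  fp_insufficient_definition  ppv  fn
Hypovolemia         0   0            0                           0  NaN   0
   LV shock         2   2            0                           0  1.0   0
     SVT+BP         4   4            0                           0  1.0   2
  Tamponade         2   0            2                           0  0.0   0
   Vtach+BP         0   0            0                           0  NaN   0

overall FP fraction: 0.250
patient-days: 2
```

Every detectable episode was caught (4 SVT, 2 LV-shock true positives); the
two sub-threshold SVT episodes correctly produced no alarm and appear as
non-threat false negatives (`fn` column); and the two CVP infusion
artifacts — 200 mmHg readings placed in hemodynamically unstable context —
fired the tamponade definition, appearing as artifact false positives.
Re-running detection with `plausibility={ChannelId.CVPmean: (-5, 40)}`
instead of `compatibility_mode=True` screens those readings out and the FP
count drops to zero: `compatibility_mode` reproduces the historical
constraint that a definition may not examine the same parameter twice,
which is precisely what made such screening impossible.

The same pipeline is scriptable from the shell:

```sh
icualarms simulate --config cohort.yaml --seed 7 --out run/
icualarms detect   --records run/records --out run/alarms.csv --compatibility-mode
icualarms evaluate --alarms run/alarms.csv --truth run/truth.csv \
                   --records run/records --out run/cls.csv
icualarms report   --classifications run/cls.csv --out run/metrics.csv
```

or as one composite, manifest-stamped run: `icualarms run --config run.yaml
--seed 7 --out run/`.

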