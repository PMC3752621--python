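# Methods

## Trigger semantics

All evaluation happens on a uniform grid, 1 Hz by default. Bedside
monitors export their numerics at roughly this rate; the true update rate
of any given monitor is vendor-specific, so the rate is a configuration
knob (`rate` on the evaluators) rather than a constant.

Irregular input series are mapped to the grid by last-observation-carried-
forward with a bounded tolerance (default 10 s). Beyond the tolerance a
grid point is *missing*, not stale: a frozen pressure line that stopped
updating must not fabricate 300 s of "sustained hypotension" evidence.
Missing data never satisfies a condition and breaks the continuity of a
sustained violation.

**Sustained absolute triggers** ("< 78 mmHg for 300 sec") are strict
inequalities — the deployed configuration writes the limits with `<`/`>`
glyphs — and an activation interval begins at the first instant by which
the value has been continuously beyond the limit for the full persistence
time, ending when the violation ceases.

**Relative triggers** ("+40 % within 59 sec") compare a smoothed current
value with the smoothed value some lag τ ∈ (0, W] earlier, for every lag up
to the window W. The smoother is a trailing 10 s median: the deployed
software's internal reference is unspecified, and a single-sample reference
makes percent triggers fire on one noisy sample. The median (rather than a
mean) keeps a lone spike from polluting the reference. A raw-sample
comparison mode exists for sensitivity analysis (`relative_mode="raw"`).
Percent and absolute-delta thresholds ("+30 bpm") are both supported;
comparisons are inclusive (≥ the stated change).

Two of the printed trigger times name two durations. "−20 % within 3 min"
(tamponade perfusion) is a plain 180 s window. "−20 % within 120 sec/10
min" (hypovolemia perfusion) is genuinely ambiguous; it is encoded as a
120 s change window with a 600 s *scope*: once the fall has occurred, the
trigger remains active for 10 minutes, long enough to co-occur with the
300 s pressure conditions. Both numbers are ordinary config fields on the
trigger, so other readings are expressible.

**Rhythm flags** (the monitor's ventricular-tachycardia annotation) are
carried as a 0/1 channel and treated as a sustained trigger with a 5 s
persistence default. The monitor's internal arrhythmia detector is out of
scope; the flag stands in for its output. The PVC-rate parameter is carried
as a channel but unused by the built-in rules, since the deployed Vtach+BP
definition's corresponding cell is the rhythm annotation itself.

## Rule combination

A definition holds up to four triggers (the deployed software's cap, kept
as a schema invariant). The combinator is **AND over trigger slots** with a
co-occurrence window (default 60 s): the rule fires at the earliest instant
t at which every slot has an activation interval overlapping [t − 60 s, t].
The deployed configuration never states its combinator, but cross-sensor
confirmation is its entire rationale, and conjunction is the only reading
under which a lone corrupted channel cannot fire a multi-sensor rule.
Triggers may share a named slot, in which case they are alternatives within
the conjunction; the built-in hypovolemia rule uses this for its
arterial-line / cuff pressure pair ("either source" per the deployment's
description). After firing, the rule is silent for a refractory period
(default 300 s — no value is documented; 5 min matches common monitor
re-alarm behaviour) and re-fires if the conjunction still holds.

Fallback sources mirror the deployed parenthetical notation "HR (Pulse)": a
trigger uses its primary channel when present with < 50 % missing data,
otherwise its declared fallback. A rule is *eligible* on a patient only if
every slot has a usable source; ineligible (patient, rule) pairs produce no
alarms and are excluded from evaluation, reproducing the study's exclusion
of events whose requisite sensors were absent.

**Compatibility mode** reproduces a constraint of the studied software: no
parameter from a sensor may be examined more than once per definition.
Channel-reusing rules are rejected, and the plausibility pre-filter — which
blanks physically implausible values (e.g. CVP outside −5..40 mmHg) before
trigger evaluation, i.e. a second examination of the same parameter — is
disabled. Default mode allows both, quantifying the false positives that
the historical restriction caused.

## Synthetic cohorts

The generator emulates stable post-cardiac-surgery ICU monitoring, not
physiology. Channels are stationary lag-1 autoregressive processes around
typical baselines (HR 80 ± 4 bpm, ARTsys 120 ± 6, ARTmean 85 ± 5, CVP
8 ± 2, PAPdia 12 ± 2, perfusion index 2.0 ± 0.3, NIBPm 85 ± 5 mmHg;
φ = 0.95 at 1 Hz for minute-scale wander). Sampling is seeded and fully
deterministic; patient *i* draws from a stream seeded `[master_seed, i]`,
so record *i* is invariant to the cohort size.

Episodes are built so that their trigger outcome is provable by arithmetic
rather than measured empirically. The affected channels are pinned at their
running baseline for a lead-in covering the scenario's longest
relative-trigger lookback, ramp linearly (10–30 s) to hold targets, hold
past the longest persistence requirement plus 60 s, and recover over 120 s.
Hold targets are derived from the definition limits and one scalar severity
margin m: multiplicative on thresholds and percent triggers (limit ×
(1 ± m)), additive on deltas. A +10 % margin therefore guarantees every
relevant condition is met with a 10 % cushion relative to the *actual*
local baseline (not the nominal mean), and a −10 % margin guarantees every
condition fails — sub-threshold episodes are real-but-non-actionable
events, e.g. a ventricular-tachycardia run whose rhythm flag is on but
whose hemodynamics never cross the limits. Where one channel serves two
constraints (heart rate must both rise 40 % and exceed 110 bpm), the target
takes the most demanding constraint for positive margins and the least for
negative ones.

Artifact injectors reproduce the failure mechanisms reported from the
deployment: infusion-driven CVP readings of 200 mmHg, pulse-pressure
collapse of a damped arterial line (displayed systolic pressure decaying
below the hypotension limit while cuff pressure stays normal),
transducer-leveling offsets, motion interference (ECG rate spikes with the
rhythm flag flickering while the plethysmograph pulse stays quiet), and
sensor disconnects (channels go missing). A design point worth stating
explicitly: under AND semantics a lone corrupted channel cannot fire a
four-condition rule, so a *bare* CVP spike on normal vitals provokes
nothing — which is the suppression claim, and is tested as such. The
false positives observed clinically arose in unstable patients whose other
parameters already sat beyond the limits; the CVP-spike injector therefore
by default co-injects that borderline context (ARTsys ≈ 70 mmHg, perfusion
−25 %, PAPdia ≈ 17.6 mmHg) so the spike supplies exactly the one condition
(CVP > 16 mmHg) the patient does not meet. `context=False` yields the bare
spike.

What the generator does **not** emulate: waveform-level signal, real
pulse-pressure/mean-pressure coupling between channels, diurnal and
treatment-driven nonstationarity, intermittent NIBP cycling (the cuff
channel is continuous here), clustered artifact timing (infusions at
nursing shifts), or overlapping clinical episodes. Consequently, passing
detectability tests demonstrates that the engine implements the stated
semantics exactly — not that these definitions would achieve comparable
sensitivity or PPV on real ICU data, where baselines drift into trigger
range and artifact co-occurs with instability far more often.

## Adjudication and metrics

Alarms match ground truth by interval containment with a ±60 s tolerance
(one trend-screen unit; the original daily-review adjudication had no finer
granularity — configurable). Matching is greedy earliest-first and
one-to-many: several refractory-separated alarms inside one truth interval
count as one true-positive *event* by default (adjudication counts events),
with per-alarm counting behind a flag. An alarm matching an artifact
interval is an artifact false positive regardless of which rule fired. An
unmatched alarm overlapping a labeled confounder interval *or* a clinical
event of a different kind is an insufficient-definition false positive
(e.g. the SVT+BP definition firing during real ventricular tachycardia —
the definition cannot discriminate); any remaining unmatched alarm defaults
to artifact. Unmatched detectable truth becomes a false negative:
sensor-off when it overlaps a disconnect interval, otherwise definition
failure; unmatched sub-threshold truth is a non-threat false negative.
True negatives are tallied per (patient-day, scenario) with neither alarms
nor events.

Per-scenario PPV is TP/(TP + FP) over alarm-side events, undefined (None)
when no alarms fired; the cohort summary adds the overall FP fraction
Σ FP / Σ events using each row's stated event total. The event totals in a
published tabulation may disagree with their own breakdown (the studied
deployment's SVT row does); `MetricsRow.from_counts` therefore accepts an
explicit `n_events` so both the narrative arithmetic (PPV = 171/212 =
0.807) and the tabulated overall fraction (91/317 ≈ 29 %) are reproducible
as printed. Note 8/29 = 0.2759 truncates to the published 0.27 rather than
rounding.

## Numerical choices and problem sizes

Grid construction uses half-open float guards (1e-9…1e-12) so integer-
second inputs land exactly on grid points; persistence counts are computed
in grid steps (`ceil(duration × rate)`). Median smoothing uses pandas'
rolling median with `min_periods=1`, which skips missing values and equals
the direct median of the non-missing window. The trigger evaluators are
verified against brute-force per-sample scans (exhaustive sliding-window
and all-lag-pairs oracles) on ~1,200 random traces of up to 600 samples,
with exact interval equality.

Test and acceptance cohorts use 10 patients × 24 h (sensitivity, 200
episodes) and 5 patients × 12 h (PPV recovery, 25 events) — sizes at which
every scenario is exercised repeatedly while a full run of suite plus
acceptance script stays under a minute on one core. These were chosen as
the package's standard demonstration sizes; the generator scales linearly
in patients × duration.

## Known limitations

- The engine processes numerics only; no waveform analysis, no arrhythmia
  detection, no ST segments.
- The conjunction, refractory, smoothing and co-occurrence defaults are
  reasoned reconstructions where the deployed software's behaviour is
  undocumented; all are exposed in configuration precisely because they are
  assumptions.
- Insufficient-definition false positives require labeled confounder or
  cross-kind context in the truth log; the engine cannot infer clinical
  context (ventricular assist devices, open chests) from the signals.
- Synthetic PPV figures characterise the pipeline's bookkeeping, not
  expected clinical performance.
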