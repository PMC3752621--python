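"""Seeded generator of synthetic ICU patient records with known ground truth.

No public dataset accompanies the alarm definitions, so validation runs on
synthetic cohorts that emulate post-cardiac-surgery ICU monitoring at 1 Hz:
stationary lag-1 autoregressive baselines per channel, clinical episodes
shaped to the five scenario definitions, and the artifact mechanisms that
plague real sensors (infusion-driven CVP spikes, damped arterial lines,
transducer leveling errors, motion, disconnects).

Episodes are built so their trigger outcome is provable by arithmetic: the
affected channels are pinned to their running baseline for a lead-in (long
enough to cover every relative-trigger lookback), ramp linearly to targets
that exceed — or undershoot — every relevant limit by a stated severity
margin, hold past the longest persistence requirement, and recover.  A
``margin`` of +10 therefore guarantees detection with a 10 % cushion on
every limit, and −10 guarantees silence, making ground truth analytic
rather than empirical.
"""

from __future__ import annotations

import dataclasses
from typing import Any

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .channels import VALID_RANGE, ChannelId
from .vitals import PatientRecord, VitalTrace

#: truth-event kinds: the five clinical scenarios, five artifact mechanisms,
#: and an explicit confounder label for insufficient-definition accounting
#: (e.g. a ventricular-assist-device patient in whom tachyarrhythmia alarms
#: are clinically moot).
CLINICAL_KINDS = ("svt_bp", "vtach_bp", "lv_shock", "tamponade", "hypovolemia")
ARTIFACT_KINDS = (
    "artifact_cvp_spike",
    "artifact_damped_art",
    "artifact_level_error",
    "artifact_motion",
    "sensor_off",
)
CONFOUNDER_KIND = "confounder"
ALL_KINDS = CLINICAL_KINDS + ARTIFACT_KINDS + (CONFOUNDER_KIND,)

#: truth kind -> scenario rule name
KIND_TO_SCENARIO = {
    "svt_bp": "SVT+BP",
    "vtach_bp": "Vtach+BP",
    "lv_shock": "LV shock",
    "tamponade": "Tamponade",
    "hypovolemia": "Hypovolemia",
}
SCENARIO_TO_KIND = {v: k for k, v in KIND_TO_SCENARIO.items()}


class SchedulingError(ValueError):
    """Raised when a planned episode sequence cannot fit in the record."""


@dataclasses.dataclass(frozen=True)
class TruthEvent:
    """A labeled interval of ground truth in a synthetic record."""

    kind: str
    t_start: float
    t_end: float
    intended_detectable: bool
    patient_id: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ALL_KINDS:
            raise ValueError(f"unknown truth kind {self.kind!r}")
        if not self.t_start < self.t_end:
            raise ValueError("t_start must be < t_end")

    @property
    def scenario(self) -> str | None:
        return KIND_TO_SCENARIO.get(self.kind)


@dataclasses.dataclass(frozen=True)
class PlanItem:
    """One planned batch of identical truth events for a cohort."""

    kind: str
    count: int
    margin_pct: float = 10.0
    params: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ALL_KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.kind in CLINICAL_KINDS and self.margin_pct == 0:
            raise ValueError("clinical episodes need a nonzero severity margin")


#: per-channel stationary noise model: (mean, sd, lag-1 autocorrelation).
#: Means/sds are typical for a stable post-cardiac-surgery patient; the 0.95
#: lag-1 coefficient at 1 Hz gives minute-scale physiological wander.
DEFAULT_NOISE: dict[ChannelId, tuple[float, float, float]] = {
    ChannelId.HR: (80.0, 4.0, 0.95),
    ChannelId.Pulse: (80.0, 4.0, 0.95),
    ChannelId.ARTsys: (120.0, 6.0, 0.95),
    ChannelId.ARTmean: (85.0, 5.0, 0.95),
    ChannelId.CVPmean: (8.0, 2.0, 0.95),
    ChannelId.PAPdia: (12.0, 2.0, 0.95),
    ChannelId.Perf: (2.0, 0.3, 0.95),
    ChannelId.NIBPm: (85.0, 5.0, 0.95),
    ChannelId.PVC: (1.0, 0.5, 0.95),
}


@dataclasses.dataclass
class CohortSpec:
    """Plan for a simulated cohort: size, noise model, and episode plan."""

    n_patients: int = 10
    duration_s: float = 86400.0
    plan: list[PlanItem] = dataclasses.field(default_factory=list)
    noise: dict[ChannelId, tuple[float, float, float]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_NOISE)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.duration_s < 600:
            raise ValueError("duration_s must be >= 600 s")


# ---------------------------------------------------------------------------
# episode geometry
# ---------------------------------------------------------------------------

# lead_s pins affected channels at their running baseline long enough to
# cover the longest relative-trigger lookback of the scenario; hold_s
# exceeds the longest persistence requirement by >= 60 s.
_TIMING = {
    "svt_bp": dict(lead=80.0, ramp=30.0, hold=120.0, recover=120.0),
    "vtach_bp": dict(lead=40.0, ramp=10.0, hold=80.0, recover=120.0),
    "lv_shock": dict(lead=20.0, ramp=30.0, hold=360.0, recover=120.0),
    "tamponade": dict(lead=200.0, ramp=30.0, hold=240.0, recover=120.0),
    "hypovolemia": dict(lead=140.0, ramp=30.0, hold=360.0, recover=120.0),
    "artifact_cvp_spike": dict(lead=200.0, ramp=30.0, hold=240.0, recover=120.0),
    "artifact_damped_art": dict(lead=20.0, ramp=60.0, hold=400.0, recover=120.0),
    "artifact_level_error": dict(lead=0.0, ramp=0.0, hold=600.0, recover=0.0),
    "artifact_motion": dict(lead=0.0, ramp=0.0, hold=60.0, recover=0.0),
    "sensor_off": dict(lead=0.0, ramp=0.0, hold=600.0, recover=0.0),
    CONFOUNDER_KIND: dict(lead=0.0, ramp=0.0, hold=600.0, recover=0.0),
}


def episode_length_s(kind: str, params: dict[str, Any] | None = None) -> float:
    t = _TIMING[kind]
    hold = t["hold"]
    if params and "duration" in params:
        hold = float(params["duration"])
    return t["lead"] + t["ramp"] + hold + t["recover"]


def _signed(m: float, *candidates: float) -> float:
    """Combine per-trigger targets for one shared channel value.

    Positive margin: every constraint must be exceeded -> take the most
    extreme requirement (max for rises/upper limits).  Negative margin:
    every constraint must be undershot -> take the least extreme (min).
    """
    return max(candidates) if m > 0 else min(candidates)


def _episode_targets(
    kind: str, base: dict[ChannelId, float], margin_pct: float
) -> dict[ChannelId, float]:
    """Channel hold-targets that beat (or miss) every limit by the margin.

    Multiplicative on thresholds and percent triggers, additive on absolute
    deltas: one scalar controls the detectability of the whole episode.
    """
    m = margin_pct / 100.0
    C = ChannelId
    if kind == "svt_bp":
        rise = 1.0 + 0.40 * (1.0 + m)
        return {
            C.HR: _signed(m, base[C.HR] * rise, 110.0 * (1.0 + m)),
            C.Pulse: _signed(m, base[C.Pulse] * rise, 110.0 * (1.0 + m)),
            C.ARTsys: base[C.ARTsys] * (1.0 - 0.15 * (1.0 + m)),
        }
    if kind == "vtach_bp":
        delta = 30.0 * (1.0 + m)
        return {
            C.HR: _signed(m, base[C.HR] + delta, 110.0 * (1.0 + m)),
            C.Pulse: _signed(m, base[C.Pulse] + delta, 110.0 * (1.0 + m)),
            C.ARTsys: base[C.ARTsys] * (1.0 - 0.30 * (1.0 + m)),
            C.VtachFlag: 1.0,
        }
    if kind == "lv_shock":
        return {
            C.ARTsys: 78.0 * (1.0 - m),
            C.CVPmean: 16.0 * (1.0 - m),
            C.PAPdia: 16.0 * (1.0 + m),
            C.Perf: 1.2 * (1.0 - m),
        }
    if kind == "tamponade":
        return {
            C.ARTsys: 78.0 * (1.0 - m),
            C.CVPmean: 16.0 * (1.0 + m),
            C.Perf: base[C.Perf] * (1.0 - 0.20 * (1.0 + m)),
            C.PAPdia: 16.0 * (1.0 + m),
        }
    if kind == "hypovolemia":
        return {
            C.ARTmean: 50.0 * (1.0 - m),
            C.CVPmean: 5.0 * (1.0 - m),
            C.Perf: base[C.Perf] * (1.0 - 0.20 * (1.0 + m)),
            C.NIBPm: 55.0 * (1.0 - m),
        }
    raise ValueError(f"unknown clinical episode kind {kind!r}")


def _require_uniform(trace: VitalTrace) -> None:
    dt = np.diff(trace.times)
    if dt.size and not np.allclose(dt, 1.0):
        raise ValueError("injection requires 1 Hz uniform traces")


def _local_baseline(values: np.ndarray, i0: int, fallback: float) -> float:
    lo = max(0, i0 - 30)
    window = values[lo:i0]
    window = window[~np.isnan(window)]
    return float(np.median(window)) if window.size else fallback


def _write_profile(
    values: np.ndarray,
    i0: int,
    lead: int,
    ramp: int,
    hold: int,
    recover: int,
    base: float,
    target: float,
) -> None:
    """Pin / ramp / hold / recover one channel in place."""
    n = values.size
    a = i0
    b = min(n, i0 + lead)
    values[a:b] = base
    r0, r1 = i0 + lead, min(n, i0 + lead + ramp)
    if r1 > r0:
        values[r0:r1] = base + (target - base) * (
            np.arange(r1 - r0, dtype=float) + 1.0
        ) / max(ramp, 1)
    h0, h1 = i0 + lead + ramp, min(n, i0 + lead + ramp + hold)
    values[h0:h1] = target
    c0, c1 = h1, min(n, h1 + recover)
    if c1 > c0:
        end_value = values[c1 - 1] if c1 < n else base
        if np.isnan(end_value):
            end_value = base
        values[c0:c1] = target + (end_value - target) * (
            np.arange(c1 - c0, dtype=float) + 1.0
        ) / (c1 - c0)


def inject_episode(
    record: PatientRecord, kind: str, t0: float, margin_pct: float
) -> tuple[PatientRecord, TruthEvent]:
    """Embed one clinical episode starting at ``t0`` (modifies in place).

    The episode exceeds every relevant trigger limit by ``margin_pct`` %
    when the margin is positive, and undershoots every limit by that much
    when negative (a real but sub-threshold event).  Ventricular-tachycardia
    episodes keep the rhythm flag on in both cases: a sub-threshold run is a
    real arrhythmia without hemodynamic compromise.
    """
    if kind not in CLINICAL_KINDS:
        raise ValueError(f"unknown clinical episode kind {kind!r}")
    timing = _TIMING[kind]
    total = episode_length_s(kind)
    if t0 < 0 or t0 + total > record.duration_s:
        raise SchedulingError(
            f"{kind} episode at t0={t0:g} (length {total:g} s) does not fit "
            f"in a {record.duration_s:g} s record"
        )
    i0 = int(round(t0))
    bases: dict[ChannelId, float] = {}
    for ch in (ChannelId.HR, ChannelId.Pulse, ChannelId.ARTsys, ChannelId.ARTmean,
               ChannelId.CVPmean, ChannelId.PAPdia, ChannelId.Perf, ChannelId.NIBPm):
        if ch in record.traces:
            _require_uniform(record.traces[ch])
            mean = DEFAULT_NOISE.get(ch, (0.0, 0.0, 0.0))[0]
            bases[ch] = _local_baseline(record.traces[ch].values, i0, mean)
    targets = _episode_targets(kind, bases, margin_pct)
    lead, ramp, hold, recover = (
        int(timing["lead"]), int(timing["ramp"]), int(timing["hold"]), int(timing["recover"]),
    )
    for ch, target in targets.items():
        if ch not in record.traces:
            continue
        base = bases.get(ch, 0.0)
        if ch is ChannelId.VtachFlag:
            v = record.traces[ch].values
            v[i0 + lead : min(v.size, i0 + lead + ramp + hold)] = 1.0
        else:
            _write_profile(
                record.traces[ch].values, i0, lead, ramp, hold, recover, base, target
            )
    event = TruthEvent(
        kind=kind,
        t_start=float(t0),
        t_end=float(t0 + total),
        intended_detectable=margin_pct > 0,
        patient_id=record.patient_id,
    )
    return record, event


def inject_artifact(
    record: PatientRecord,
    kind: str,
    t0: float,
    params: dict[str, Any] | None = None,
) -> tuple[PatientRecord, TruthEvent]:
    """Embed one artifact mechanism starting at ``t0`` (modifies in place).

    ``artifact_cvp_spike``
        The CVP reads ``value`` (default 200 mmHg, the classic infusion
        artifact) for ``duration`` seconds.  By default (``context=True``)
        the spike is placed in the setting where such false positives arose
        clinically: a genuinely hypotensive, poorly perfused patient whose
        other parameters already satisfy the obstructive-shock definition —
        the spike supplies the one condition (elevated CVP) the patient
        does not actually meet.  ``context=False`` gives a bare spike on
        normal vitals, which a cross-sensor rule ignores.
    ``artifact_damped_art``
        Pulse-pressure collapse of a damped arterial line: displayed ARTsys
        decays to near the (lower) mean pressure, crossing the hypotension
        limit while the cuff pressure stays normal.
    ``artifact_level_error``
        Constant transducer-leveling offset (default +20 mmHg on CVPmean).
    ``artifact_motion``
        Motion interference: ECG heart rate spikes and the Vtach annotation
        flickers on while the plethysmograph pulse stays at baseline.
    ``sensor_off``
        The listed channels (default: the ECG-derived ones) go missing.
    """
    params = dict(params or {})
    if kind not in ARTIFACT_KINDS:
        raise ValueError(f"unknown artifact kind {kind!r}")
    timing = _TIMING[kind]
    hold = int(params.get("duration", timing["hold"]))
    lead, ramp, recover = int(timing["lead"]), int(timing["ramp"]), int(timing["recover"])
    total = lead + ramp + hold + recover
    if t0 < 0 or t0 + total > record.duration_s:
        raise SchedulingError(f"{kind} at t0={t0:g} does not fit in record")
    i0 = int(round(t0))
    C = ChannelId

    def bvals(ch: ChannelId) -> np.ndarray:
        _require_uniform(record.traces[ch])
        return record.traces[ch].values

    if kind == "artifact_cvp_spike":
        value = float(params.get("value", 200.0))
        if params.get("context", True):
            context = {
                C.ARTsys: 70.0,
                C.Perf: _local_baseline(bvals(C.Perf), i0, 2.0) * 0.75
                if C.Perf in record.traces
                else None,
                C.PAPdia: 17.6,
            }
            for ch, target in context.items():
                if target is None or ch not in record.traces:
                    continue
                base = _local_baseline(bvals(ch), i0, DEFAULT_NOISE[ch][0])
                _write_profile(bvals(ch), i0, lead, ramp, hold, recover, base, target)
        if C.CVPmean in record.traces:
            v = bvals(C.CVPmean)
            s0 = i0 + lead
            v[s0 : min(v.size, s0 + ramp + hold)] = value
    elif kind == "artifact_damped_art":
        floor = float(params.get("floor", 72.0))
        if C.ARTsys in record.traces:
            v = bvals(C.ARTsys)
            base = _local_baseline(v, i0, DEFAULT_NOISE[C.ARTsys][0])
            _write_profile(v, i0, lead, ramp, hold, recover, base, floor)
    elif kind == "artifact_level_error":
        ch = params.get("channel", C.CVPmean)
        if isinstance(ch, str):
            ch = ChannelId(ch)
        offset = float(params.get("offset", 20.0))
        if ch in record.traces:
            v = bvals(ch)
            lo, hi = VALID_RANGE[ch]
            seg = slice(i0, min(v.size, i0 + hold))
            v[seg] = np.clip(v[seg] + offset, lo, hi)
    elif kind == "artifact_motion":
        if C.HR in record.traces:
            v = bvals(C.HR)
            base = _local_baseline(v, i0, DEFAULT_NOISE[C.HR][0])
            v[i0 : min(v.size, i0 + hold)] = base + 45.0
        if C.VtachFlag in record.traces:
            v = bvals(C.VtachFlag)
            v[i0 : min(v.size, i0 + hold)] = 1.0
    elif kind == "sensor_off":
        channels = params.get("channels", (C.HR, C.PVC, C.VtachFlag))
        for ch in channels:
            if isinstance(ch, str):
                ch = ChannelId(ch)
            if ch in record.traces:
                v = bvals(ch)
                v[i0 : min(v.size, i0 + hold)] = np.nan
    event = TruthEvent(
        kind=kind,
        t_start=float(t0),
        t_end=float(t0 + total),
        intended_detectable=False,
        patient_id=record.patient_id,
    )
    return record, event


# ---------------------------------------------------------------------------
# whole-patient and whole-cohort simulation
# ---------------------------------------------------------------------------

def _ar1(rng: np.random.Generator, n: int, mean: float, sd: float, phi: float) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    innov_sd = sd * np.sqrt(max(1.0 - phi * phi, 0.0))
    e = rng.normal(0.0, innov_sd, size=n)
    e[0] = rng.normal(0.0, sd)
    x = lfilter([1.0], [1.0, -phi], e)
    return mean + x


def _baseline_record(
    spec: CohortSpec, rng: np.random.Generator, patient_id: str
) -> PatientRecord:
    n = int(spec.duration_s) + 1
    times = np.arange(n, dtype=float)
    traces: dict[ChannelId, VitalTrace] = {}
    for ch, (mean, sd, phi) in spec.noise.items():
        lo, hi = VALID_RANGE[ch]
        vals = np.clip(_ar1(rng, n, mean, sd, phi), lo, hi)
        traces[ch] = VitalTrace(channel=ch, times=times, values=vals, nominal_rate=1.0)
    flag = np.zeros(n)
    traces[ChannelId.VtachFlag] = VitalTrace(
        channel=ChannelId.VtachFlag, times=times.copy(), values=flag, nominal_rate=1.0
    )
    return PatientRecord(patient_id=patient_id, duration_s=spec.duration_s, traces=traces)


def _schedule(
    rng: np.random.Generator,
    items: list[PlanItem],
    duration_s: float,
) -> list[tuple[PlanItem, float]]:
    """Place episodes sequentially with randomized gaps, order shuffled.

    Gaps exceed the default refractory period so consecutive episodes of
    one scenario produce separable alarms.
    """
    order = list(rng.permutation(len(items)))
    t = 400.0 + float(rng.uniform(0, 120))
    placed: list[tuple[PlanItem, float]] = []
    for idx in order:
        item = items[idx]
        length = episode_length_s(item.kind, item.params)
        if t + length > duration_s - 60.0:
            raise SchedulingError(
                f"episode plan does not fit: {len(items)} episodes need more "
                f"than {duration_s:g} s"
            )
        placed.append((item, t))
        t += length + 320.0 + float(rng.uniform(0, 180))
    placed.sort(key=lambda p: p[1])
    return placed


def simulate_patient(
    spec: CohortSpec,
    seed: int | list[int],
    patient_id: str = "P000",
    items: list[PlanItem] | None = None,
) -> tuple[PatientRecord, list[TruthEvent]]:
    """Simulate one patient record with the given per-patient episode items.

    Deterministic given ``seed``: same seed, same record sample for sample.
    ``items`` defaults to one instance of every entry in ``spec.plan``.
    """
    rng = np.random.default_rng(seed)
    record = _baseline_record(spec, rng, patient_id)
    if items is None:
        items = [
            dataclasses.replace(p, count=1) for p in spec.plan for _ in range(p.count)
        ]
    truth: list[TruthEvent] = []
    for item, t0 in _schedule(rng, items, spec.duration_s):
        if item.kind in CLINICAL_KINDS:
            _, ev = inject_episode(record, item.kind, t0, item.margin_pct)
        elif item.kind in ARTIFACT_KINDS:
            _, ev = inject_artifact(record, item.kind, t0, item.params)
        else:  # confounder interval: labels context, alters no signal
            ev = TruthEvent(
                kind=item.kind,
                t_start=t0,
                t_end=t0 + episode_length_s(item.kind, item.params),
                intended_detectable=False,
                patient_id=patient_id,
            )
        truth.append(ev)
    truth.sort(key=lambda e: e.t_start)
    return record, truth


def simulate_cohort(spec: CohortSpec) -> tuple[list[PatientRecord], list[TruthEvent]]:
    """Simulate the whole cohort.

    Plan counts are dealt round-robin across patients; patient ``i`` draws
    from an independent stream seeded with ``[spec.seed, i]``, so cohorts
    are reproducible and patient ``i`` is unchanged by the patient count.
    """
    per_patient: list[list[PlanItem]] = [[] for _ in range(spec.n_patients)]
    cursor = 0
    for item in spec.plan:
        for _ in range(item.count):
            per_patient[cursor % spec.n_patients].append(
                dataclasses.replace(item, count=1)
            )
            cursor += 1
    records: list[PatientRecord] = []
    truth: list[TruthEvent] = []
    for i in range(spec.n_patients):
        pid = f"P{i:03d}"
        rec, tr = simulate_patient(spec, [spec.seed, i], pid, per_patient[i])
        records.append(rec)
        truth.extend(tr)
    return records, truth


# ---------------------------------------------------------------------------
# truth-log interface
# ---------------------------------------------------------------------------

def truth_to_frame(truth: list[TruthEvent]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": e.patient_id,
            "kind": e.kind,
            "t_start": e.t_start,
            "t_end": e.t_end,
            "intended_detectable": e.intended_detectable,
        }
        for e in sorted(truth, key=lambda e: (e.patient_id, e.t_start, e.kind))
    ]
    return pd.DataFrame(
        rows, columns=["patient_id", "kind", "t_start", "t_end", "intended_detectable"]
    )


def truth_from_frame(df: pd.DataFrame) -> list[TruthEvent]:
    return [
        TruthEvent(
            kind=str(r["kind"]),
            t_start=float(r["t_start"]),
            t_end=float(r["t_end"]),
            intended_detectable=bool(r["intended_detectable"]),
            patient_id=str(r["patient_id"]),
        )
        for _, r in df.iterrows()
    ]
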