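"""Alarm adjudication: match alarms to ground truth, classify, and score.

The daily expert review of a live deployment is replaced here by interval
matching against a ground-truth log.  Every fired alarm and every unmatched
truth event receives exactly one label from the study taxonomy:

========  ==========================================================
TPRE      true positive, real event
TP_PRED   true positive, predictive (alarm shortly before event onset)
FP_ART    false positive from sensor artifact (e.g. CVP reading 200 mmHg)
FP_INS    false positive from an insufficient definition (e.g. a
          ventricular-assist-device patient in arrhythmia)
FN_TH     false negative with threat: the definition failed
FN_NO_TH  false negative without threat: real but sub-threshold event
FN_SENS   false negative because the required sensor was disconnected
TN_INT    a (patient-day, scenario) with neither alarms nor events
========  ==========================================================

Per-scenario counts and the positive predictive value
``PPV = TP / (TP + FP)`` follow, with an overall false-positive fraction
across scenarios.
"""

from __future__ import annotations

import dataclasses
import enum
import math

import numpy as np
import pandas as pd

from .synthetic import (
    ARTIFACT_KINDS,
    CLINICAL_KINDS,
    CONFOUNDER_KIND,
    KIND_TO_SCENARIO,
    TruthEvent,
)
from .triggers import AlarmEvent
from .vitals import PatientRecord

DEFAULT_TOLERANCE_S = 60.0
DAY_S = 86400.0


class EventClassification(str, enum.Enum):
    TPRE = "TPRE"
    TP_PREDICT = "TP_PREDICT"
    FP_ART = "FP_ART"
    FP_INS_DEF = "FP_INS_DEF"
    FN_TH = "FN_TH"
    FN_NO_TH = "FN_NO_TH"
    FN_SENS_OFF = "FN_SENS_OFF"
    TN_TIME_INT = "TN_TIME_INT"


_TP_LABELS = (EventClassification.TPRE, EventClassification.TP_PREDICT)
_FP_LABELS = (EventClassification.FP_ART, EventClassification.FP_INS_DEF)
_FN_LABELS = (
    EventClassification.FN_TH,
    EventClassification.FN_NO_TH,
    EventClassification.FN_SENS_OFF,
)


@dataclasses.dataclass(frozen=True)
class ClassifiedEvent:
    """One labeled event with provenance."""

    label: EventClassification
    scenario: str
    patient_id: str
    t: float
    rationale: str = ""


@dataclasses.dataclass
class MatchResult:
    alarms: list[AlarmEvent]
    truth: list[TruthEvent]
    #: per alarm: index into ``truth`` or None
    alarm_match: list[int | None]
    tolerance_s: float

    def matched_truth_indices(self) -> set[int]:
        return {i for i in self.alarm_match if i is not None}


def _in_window(t: float, ev: TruthEvent, tol: float) -> bool:
    return ev.t_start - tol <= t <= ev.t_end + tol


def match_alarms(
    alarms: list[AlarmEvent],
    truth: list[TruthEvent],
    tolerance_s: float = DEFAULT_TOLERANCE_S,
) -> MatchResult:
    """Greedy earliest-first matching of alarms to truth intervals.

    An alarm matches a clinical truth event of its own scenario (same
    patient, fire time within the event interval padded by ``tolerance_s``);
    failing that, it matches any overlapping artifact interval.  One truth
    event may absorb several refractory-separated alarms (one-to-many).
    """
    alarms = sorted(alarms, key=lambda a: (a.patient_id or "", a.t_fire, a.scenario))
    truth = sorted(truth, key=lambda e: (e.patient_id, e.t_start, e.kind))
    alarm_match: list[int | None] = []
    for a in alarms:
        hit: int | None = None
        for i, ev in enumerate(truth):
            if ev.patient_id != (a.patient_id or ev.patient_id):
                continue
            if (
                ev.kind in CLINICAL_KINDS
                and KIND_TO_SCENARIO[ev.kind] == a.scenario
                and _in_window(a.t_fire, ev, tolerance_s)
            ):
                hit = i
                break
        if hit is None:
            for i, ev in enumerate(truth):
                if ev.patient_id != (a.patient_id or ev.patient_id):
                    continue
                if (
                    ev.kind in ARTIFACT_KINDS
                    and ev.kind != "sensor_off"
                    and _in_window(a.t_fire, ev, tolerance_s)
                ):
                    hit = i
                    break
        alarm_match.append(hit)
    return MatchResult(
        alarms=alarms, truth=truth, alarm_match=alarm_match, tolerance_s=tolerance_s
    )


def classify_events(
    matches: MatchResult,
    records: list[PatientRecord] | None = None,
    day_s: float = DAY_S,
    count_each_alarm: bool = False,
) -> list[ClassifiedEvent]:
    """Apply the classification taxonomy to a match result.

    By default several alarms absorbed by one truth event count as one
    true-positive *event* (the adjudication counts events, not alarm
    repetitions); ``count_each_alarm=True`` counts every alarm.  Unmatched
    detectable truth becomes a false negative — attributed to a sensor
    disconnect when it overlaps a ``sensor_off`` interval, otherwise to
    definition failure.  Unmatched alarms overlapping a confounder interval
    or a clinical event of a different kind are insufficient-definition
    false positives; any remaining unmatched alarm is counted as artifact.
    True negatives are tallied per (patient-day, scenario) with no alarm
    and no event.
    """
    tol = matches.tolerance_s
    out: list[ClassifiedEvent] = []
    counted_truth: set[int] = set()
    for a, hit in zip(matches.alarms, matches.alarm_match):
        pid = a.patient_id or ""
        if hit is not None:
            ev = matches.truth[hit]
            if ev.kind in CLINICAL_KINDS:
                if hit in counted_truth and not count_each_alarm:
                    continue
                counted_truth.add(hit)
                if a.t_fire < ev.t_start:
                    out.append(
                        ClassifiedEvent(
                            EventClassification.TP_PREDICT, a.scenario, pid, a.t_fire,
                            f"alarm {ev.t_start - a.t_fire:.0f} s before {ev.kind} onset",
                        )
                    )
                else:
                    out.append(
                        ClassifiedEvent(
                            EventClassification.TPRE, a.scenario, pid, a.t_fire,
                            f"alarm inside {ev.kind} event",
                        )
                    )
            else:
                out.append(
                    ClassifiedEvent(
                        EventClassification.FP_ART, a.scenario, pid, a.t_fire,
                        f"alarm caused by {ev.kind}",
                    )
                )
        else:
            confounded = any(
                ev.patient_id == pid
                and _in_window(a.t_fire, ev, tol)
                and (ev.kind == CONFOUNDER_KIND or ev.kind in CLINICAL_KINDS)
                for ev in matches.truth
            )
            if confounded:
                out.append(
                    ClassifiedEvent(
                        EventClassification.FP_INS_DEF, a.scenario, pid, a.t_fire,
                        "definition satisfied by a clinically different condition",
                    )
                )
            else:
                out.append(
                    ClassifiedEvent(
                        EventClassification.FP_ART, a.scenario, pid, a.t_fire,
                        "no corresponding event; presumed artifact",
                    )
                )

    matched = matches.matched_truth_indices()
    sensor_off = [e for e in matches.truth if e.kind == "sensor_off"]
    for i, ev in enumerate(matches.truth):
        if ev.kind not in CLINICAL_KINDS or i in matched:
            continue
        scenario = KIND_TO_SCENARIO[ev.kind]
        if not ev.intended_detectable:
            out.append(
                ClassifiedEvent(
                    EventClassification.FN_NO_TH, scenario, ev.patient_id, ev.t_start,
                    "sub-threshold event; no alarm expected",
                )
            )
        elif any(
            s.patient_id == ev.patient_id
            and s.t_start <= ev.t_end
            and s.t_end >= ev.t_start
            for s in sensor_off
        ):
            out.append(
                ClassifiedEvent(
                    EventClassification.FN_SENS_OFF, scenario, ev.patient_id, ev.t_start,
                    "required sensor disconnected during event",
                )
            )
        else:
            out.append(
                ClassifiedEvent(
                    EventClassification.FN_TH, scenario, ev.patient_id, ev.t_start,
                    "detectable event produced no alarm",
                )
            )

    if records is not None:
        busy: set[tuple[str, int, str]] = set()
        for a in matches.alarms:
            busy.add((a.patient_id or "", int(a.t_fire // day_s), a.scenario))
        for ev in matches.truth:
            if ev.kind in CLINICAL_KINDS:
                scen = KIND_TO_SCENARIO[ev.kind]
                for d in range(int(ev.t_start // day_s), int(ev.t_end // day_s) + 1):
                    busy.add((ev.patient_id, d, scen))
        scenarios = sorted({KIND_TO_SCENARIO[k] for k in CLINICAL_KINDS})
        for rec in records:
            n_days = max(1, math.ceil(rec.duration_s / day_s))
            for d in range(n_days):
                for scen in scenarios:
                    if (rec.patient_id, d, scen) not in busy:
                        out.append(
                            ClassifiedEvent(
                                EventClassification.TN_TIME_INT, scen,
                                rec.patient_id, d * day_s,
                                "no alarms and no events in this patient-day",
                            )
                        )
    return out


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class MetricsRow:
    """Per-scenario event counts and positive predictive value."""

    scenario: str
    n_events: int
    tp: int
    fp_art: int
    fp_ins_def: int
    fn: int
    ppv: float | None

    @classmethod
    def from_counts(
        cls,
        scenario: str,
        tp: int,
        fp_art: int,
        fp_ins_def: int = 0,
        fn: int = 0,
        n_events: int | None = None,
    ) -> "MetricsRow":
        """Build a row from raw counts; PPV = TP / (TP + FP).

        ``n_events`` defaults to the alarm-side total ``tp + fp``; it may be
        given explicitly when the source tabulation reports a different
        event total than its own count breakdown.
        """
        denom = tp + fp_art + fp_ins_def
        ppv = tp / denom if denom > 0 else None
        if n_events is None:
            n_events = denom
        return cls(
            scenario=scenario, n_events=n_events, tp=tp, fp_art=fp_art,
            fp_ins_def=fp_ins_def, fn=fn, ppv=ppv,
        )


def compute_metrics(
    classifications: list[ClassifiedEvent], scenario: str
) -> MetricsRow:
    """Aggregate one scenario's classifications into a metrics row."""
    labels = [c.label for c in classifications if c.scenario == scenario]
    tp = sum(1 for x in labels if x in _TP_LABELS)
    fp_art = sum(1 for x in labels if x is EventClassification.FP_ART)
    fp_ins = sum(1 for x in labels if x is EventClassification.FP_INS_DEF)
    fn = sum(1 for x in labels if x in _FN_LABELS)
    return MetricsRow.from_counts(scenario, tp, fp_art, fp_ins, fn)


@dataclasses.dataclass(frozen=True)
class CohortSummary:
    table: pd.DataFrame
    overall_fp_fraction: float
    patient_days: int | None = None

    def to_text(self) -> str:
        lines = [self.table.to_string(index=False)]
        lines.append("")
        lines.append(f"overall FP fraction: {self.overall_fp_fraction:.3f}")
        if self.patient_days is not None:
            lines.append(f"patient-days: {self.patient_days}")
        return "\n".join(lines) + "\n"


def summarize_cohort(
    rows: list[MetricsRow],
    truth: list[TruthEvent] | None = None,
    records: list[PatientRecord] | None = None,
    day_s: float = DAY_S,
) -> CohortSummary:
    """Cohort-level report: one row per scenario plus the overall FP fraction.

    The overall false-positive fraction is the FP total over the event
    total, ``sum(fp_art + fp_ins_def) / sum(n_events)``, using each row's
    stated event count.
    """
    table = pd.DataFrame(
        [
            {
                "scenario": r.scenario,
                "n_events": r.n_events,
                "tp": r.tp,
                "fp_artifact": r.fp_art,
                "fp_insufficient_definition": r.fp_ins_def,
                "ppv": round(r.ppv, 4) if r.ppv is not None else None,
                "fn": r.fn,
            }
            for r in rows
        ],
        columns=[
            "scenario", "n_events", "tp", "fp_artifact",
            "fp_insufficient_definition", "ppv", "fn",
        ],
    )
    fp_total = sum(r.fp_art + r.fp_ins_def for r in rows)
    ev_total = sum(r.n_events for r in rows)
    fraction = fp_total / ev_total if ev_total else 0.0
    patient_days = None
    if records is not None:
        patient_days = sum(max(1, math.ceil(r.duration_s / day_s)) for r in records)
    return CohortSummary(
        table=table, overall_fp_fraction=fraction, patient_days=patient_days
    )


def classifications_to_frame(classifications: list[ClassifiedEvent]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": c.patient_id,
            "scenario": c.scenario,
            "label": c.label.value,
            "t": c.t,
            "rationale": c.rationale,
        }
        for c in sorted(
            classifications, key=lambda c: (c.patient_id, c.t, c.scenario, c.label.value)
        )
    ]
    return pd.DataFrame(
        rows, columns=["patient_id", "scenario", "label", "t", "rationale"]
    )


def evaluate_cohort(
    alarms: list[AlarmEvent],
    truth: list[TruthEvent],
    records: list[PatientRecord] | None = None,
    tolerance_s: float = DEFAULT_TOLERANCE_S,
    day_s: float = DAY_S,
    count_each_alarm: bool = False,
) -> tuple[list[ClassifiedEvent], CohortSummary]:
    """Convenience pipeline: match, classify, and summarise in one call."""
    matches = match_alarms(alarms, truth, tolerance_s)
    classifications = classify_events(
        matches, records=records, day_s=day_s, count_each_alarm=count_each_alarm
    )
    scenarios = sorted({KIND_TO_SCENARIO[k] for k in CLINICAL_KINDS})
    rows = [compute_metrics(classifications, s) for s in scenarios]
    summary = summarize_cohort(rows, truth, records, day_s=day_s)
    return classifications, summary
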