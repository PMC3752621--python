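"""Single-parameter triggers and multi-sensor scenario evaluation.

A *trigger* is one condition on one channel: a sustained absolute threshold
violation ("ARTsys < 78 mmHg for 300 s"), a relative change against a recent
baseline ("HR +40 % within 59 s"), or the presence of a monitor rhythm flag.
A *scenario rule* combines up to four triggers; the alarm fires only when
every trigger slot has been active within a short co-occurrence window, so
that evidence from independent sensors must agree — the mechanism by which
cross-sensor correlation suppresses single-sensor artifact.

All evaluation happens on a uniform grid (1 Hz default).  Missing data
breaks the continuity of a sustained violation and never satisfies a
condition.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import TYPE_CHECKING, Literal

import numpy as np
import pandas as pd

from .channels import ChannelId
from .vitals import (
    DEFAULT_SMOOTHING_S,
    PatientRecord,
    VitalTrace,
    resample_uniform,
    rolling_baseline,
)

if TYPE_CHECKING:  # pragma: no cover
    from .scenarios import ScenarioRule

TriggerKind = Literal["absolute_sustained", "relative_change", "flag_present"]
Direction = Literal["above", "below", "rise", "fall"]
ThresholdUnit = Literal["native", "percent"]

#: a channel counts as usable when less than this fraction of it is missing
MAX_MISSING_FRACTION = 0.5


class ConfigurationError(ValueError):
    """Raised when a trigger or rule is applied to incompatible inputs."""


@dataclasses.dataclass(frozen=True)
class TriggerSpec:
    """One alarm condition on one channel.

    Parameters
    ----------
    channel : ChannelId
        Primary source parameter.
    kind : str
        ``absolute_sustained`` (threshold held for ``duration_s``),
        ``relative_change`` (change vs baseline within ``window_s``), or
        ``flag_present`` (boolean annotation held for ``duration_s``).
    direction : str or None
        ``above``/``below`` for absolute triggers, ``rise``/``fall`` for
        relative ones; irrelevant for ``flag_present``.
    threshold : float
        Threshold in channel units (absolute), or percent / absolute delta
        (relative, per ``threshold_unit``); unused for ``flag_present``.
    threshold_unit : str
        ``percent`` for relative-percent thresholds, ``native`` for
        channel-unit thresholds and deltas (e.g. "+30 bpm").
    duration_s : float or None
        Persistence requirement for absolute/flag triggers.
    window_s : float or None
        Lookback for relative triggers: the change must complete within
        some lag in ``(0, window_s]``.
    scope_s : float or None
        Optional wider evaluation scope for relative triggers: the trigger
        stays active for ``scope_s`` after the change occurred (used by the
        hypovolemia perfusion condition, quoted as "within 120 sec/10 min").
    fallback_channel : ChannelId or None
        Substitute source when the primary is absent or mostly missing,
        e.g. pulse rate standing in for ECG heart rate.
    slot : str or None
        Triggers sharing a slot name are alternatives (OR) within the AND
        combination — e.g. arterial-line vs cuff pressure in hypovolemia.
        Default: each trigger is its own slot.
    """

    channel: ChannelId
    kind: TriggerKind
    direction: Direction | None = None
    threshold: float = 0.0
    threshold_unit: ThresholdUnit = "native"
    duration_s: float | None = None
    window_s: float | None = None
    scope_s: float | None = None
    fallback_channel: ChannelId | None = None
    slot: str | None = None

    def __post_init__(self) -> None:
        if self.kind in ("absolute_sustained", "flag_present"):
            if self.duration_s is None or self.duration_s <= 0:
                raise ValueError(f"{self.kind} trigger requires duration_s > 0")
            if self.window_s is not None:
                raise ValueError(f"{self.kind} trigger must not set window_s")
            if self.kind == "absolute_sustained" and self.direction not in (
                "above",
                "below",
            ):
                raise ValueError("absolute trigger direction must be above/below")
        elif self.kind == "relative_change":
            if self.window_s is None or self.window_s <= 0:
                raise ValueError("relative trigger requires window_s > 0")
            if self.duration_s is not None:
                raise ValueError("relative trigger must not set duration_s")
            if self.direction not in ("rise", "fall"):
                raise ValueError("relative trigger direction must be rise/fall")
            if self.threshold == 0:
                raise ValueError("relative threshold must be nonzero")
        else:
            raise ValueError(f"unknown trigger kind {self.kind!r}")

    @property
    def slot_key(self) -> str:
        return self.slot if self.slot is not None else f"__{self.channel.value}"

    def describe(self) -> str:
        if self.kind == "flag_present":
            return f"{self.channel} flag for {self.duration_s:g} s"
        if self.kind == "absolute_sustained":
            op = ">" if self.direction == "above" else "<"
            return f"{self.channel} {op}{self.threshold:g} for {self.duration_s:g} s"
        sign = "+" if self.direction == "rise" else "-"
        unit = "%" if self.threshold_unit == "percent" else ""
        return f"{self.channel} {sign}{self.threshold:g}{unit} within {self.window_s:g} s"


@dataclasses.dataclass(frozen=True)
class ActiveInterval:
    """Maximal interval during which one trigger's condition is satisfied."""

    trigger: TriggerSpec
    t_on: float
    t_off: float

    def __post_init__(self) -> None:
        if self.t_on > self.t_off:
            raise ValueError("t_on must be <= t_off")

    def overlaps(self, lo: float, hi: float) -> bool:
        return self.t_on <= hi and self.t_off >= lo


@dataclasses.dataclass(frozen=True)
class AlarmEvent:
    """A fired scenario alarm with its contributing trigger activations."""

    scenario: str
    t_fire: float
    contributing: tuple[ActiveInterval, ...] = ()
    patient_id: str | None = None


# ---------------------------------------------------------------------------
# grid helpers
# ---------------------------------------------------------------------------

def _grid(trace: VitalTrace, rate: float) -> tuple[np.ndarray, np.ndarray]:
    g = resample_uniform(trace, rate)
    return g.times, g.values


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Index pairs (first, last) of maximal True runs."""
    if mask.size == 0:
        return []
    m = mask.astype(np.int8)
    d = np.diff(m)
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1))
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        ends.append(mask.size - 1)
    return list(zip(starts, ends))


def _trailing_any(mask: np.ndarray, n_back: int) -> np.ndarray:
    """mask[t] OR-ed over the previous ``n_back`` grid steps (inclusive window)."""
    if n_back <= 0:
        return mask
    s = pd.Series(mask.astype(float))
    return s.rolling(window=n_back + 1, min_periods=1).max().to_numpy() >= 0.5


def _resolve_channel_match(trace: VitalTrace, spec: TriggerSpec) -> None:
    if trace.channel is not spec.channel and trace.channel is not spec.fallback_channel:
        raise ConfigurationError(
            f"trace channel {trace.channel} does not match trigger on "
            f"{spec.channel}"
            + (f" (fallback {spec.fallback_channel})" if spec.fallback_channel else "")
        )


# ---------------------------------------------------------------------------
# single-trigger evaluators
# ---------------------------------------------------------------------------

def _absolute_active(
    values: np.ndarray, spec: TriggerSpec, rate: float
) -> np.ndarray:
    if spec.kind == "flag_present":
        viol = values >= 0.5
    elif spec.direction == "above":
        viol = values > spec.threshold
    else:
        viol = values < spec.threshold
    viol &= ~np.isnan(values)
    need = int(np.ceil(spec.duration_s * rate - 1e-9))
    active = np.zeros(values.size, dtype=bool)
    for a, b in _runs(viol):
        if b - a >= need:
            active[a + need : b + 1] = True
    return active


def eval_absolute_trigger(
    trace: VitalTrace, spec: TriggerSpec, rate: float = 1.0
) -> list[ActiveInterval]:
    """Sustained-threshold trigger: "lower & upper violation for x seconds".

    The condition is strict (a ">110 bpm" trigger does not fire at exactly
    110).  An interval begins at the first instant by which the value has
    been continuously beyond the threshold for ``duration_s`` and ends when
    the violation ceases; missing data breaks continuity.
    """
    if spec.kind not in ("absolute_sustained", "flag_present"):
        raise ConfigurationError("eval_absolute_trigger requires a sustained trigger")
    _resolve_channel_match(trace, spec)
    times, values = _grid(trace, rate)
    active = _absolute_active(values, spec, rate)
    return [
        ActiveInterval(trigger=spec, t_on=float(times[a]), t_off=float(times[b]))
        for a, b in _runs(active)
    ]


def _relative_active(
    values: np.ndarray,
    spec: TriggerSpec,
    rate: float,
    smoothing_s: float,
    mode: str,
) -> np.ndarray:
    ref = values if mode == "raw" else rolling_baseline(values, rate, smoothing_s)
    cur = values if mode == "raw" else ref
    n = values.size
    n_lag = int(np.floor(spec.window_s * rate + 1e-9))
    active = np.zeros(n, dtype=bool)
    p = spec.threshold
    for lag in range(1, n_lag + 1):
        if lag >= n:
            break
        b = ref[:-lag]
        s = cur[lag:]
        with np.errstate(invalid="ignore"):
            if spec.direction == "rise":
                if spec.threshold_unit == "percent":
                    cond = s >= b * (1.0 + p / 100.0)
                else:
                    cond = s >= b + p
            else:
                if spec.threshold_unit == "percent":
                    cond = s <= b * (1.0 - p / 100.0)
                else:
                    cond = s <= b - p
        active[lag:] |= cond & ~np.isnan(b) & ~np.isnan(s)
    if spec.scope_s:
        active = _trailing_any(active, int(round(spec.scope_s * rate)))
    return active


def eval_relative_trigger(
    trace: VitalTrace,
    spec: TriggerSpec,
    rate: float = 1.0,
    smoothing_s: float = DEFAULT_SMOOTHING_S,
    mode: str = "smoothed",
) -> list[ActiveInterval]:
    """Relative-change trigger: "relative triggers in % over a defined time".

    Satisfied at instant ``t`` when, for some lag in ``(0, window_s]``, the
    current reference value differs from the reference at ``t - lag`` by at
    least the stated percent (or absolute delta, e.g. "+30 bpm") in the
    trigger's direction.  The reference is a trailing-median smoothed value
    (``mode='smoothed'``, default) or the raw samples (``mode='raw'``).
    A ``scope_s`` keeps the trigger active for that long after the change.
    """
    if spec.kind != "relative_change":
        raise ConfigurationError("eval_relative_trigger requires a relative trigger")
    _resolve_channel_match(trace, spec)
    t0, t1 = trace.span
    if spec.window_s >= (t1 - t0):
        warnings.warn(
            f"relative window {spec.window_s:g} s is not shorter than the trace "
            f"span {t1 - t0:g} s; no evaluation possible",
            stacklevel=2,
        )
        return []
    times, values = _grid(trace, rate)
    active = _relative_active(values, spec, rate, smoothing_s, mode)
    return [
        ActiveInterval(trigger=spec, t_on=float(times[a]), t_off=float(times[b]))
        for a, b in _runs(active)
    ]


def plausibility_filter(
    trace: VitalTrace, limits: tuple[float, float]
) -> tuple[VitalTrace, int]:
    """Blank physically implausible values (e.g. a CVP of 200 mmHg).

    Values outside ``[low, high]`` become missing; returns the filtered
    trace and the number of samples replaced.  This is the artifact screen
    that a parameter-reuse restriction would forbid: it examines the same
    parameter a second time before the alarm condition does.
    """
    lo, hi = limits
    if lo >= hi:
        raise ValueError("plausibility limits must satisfy low < high")
    v = trace.values.copy()
    bad = (~np.isnan(v)) & ((v < lo) | (v > hi))
    v[bad] = np.nan
    out = VitalTrace(
        channel=trace.channel,
        times=trace.times.copy(),
        values=v,
        nominal_rate=trace.nominal_rate,
    )
    return out, int(bad.sum())


# ---------------------------------------------------------------------------
# rule-level evaluation
# ---------------------------------------------------------------------------

def _usable(record: PatientRecord, channel: ChannelId | None) -> bool:
    if channel is None or channel not in record.traces:
        return False
    return record.traces[channel].missing_fraction() < MAX_MISSING_FRACTION


def _resolve_trace(record: PatientRecord, spec: TriggerSpec) -> VitalTrace | None:
    if _usable(record, spec.channel):
        return record.traces[spec.channel]
    if _usable(record, spec.fallback_channel):
        return record.traces[spec.fallback_channel]
    return None


def sensors_present(
    record: PatientRecord, rule: "ScenarioRule"
) -> tuple[bool, list[ChannelId]]:
    """Eligibility check: are the rule's required sensors on this patient?

    Each trigger slot must have at least one usable source — present in the
    record with under half of its samples missing, the primary channel or
    its declared fallback.  Records failing this are excluded from analysis
    for that rule rather than silently producing no alarms.
    """
    missing: list[ChannelId] = []
    slots: dict[str, bool] = {}
    slot_primary: dict[str, list[ChannelId]] = {}
    for spec in rule.triggers:
        ok = _resolve_trace(record, spec) is not None
        key = spec.slot_key
        slots[key] = slots.get(key, False) or ok
        slot_primary.setdefault(key, []).append(spec.channel)
    for key, ok in slots.items():
        if not ok:
            missing.extend(slot_primary[key])
    missing = sorted(set(missing), key=lambda c: c.value)
    return (len(missing) == 0), missing


def _check_compatibility(rule: "ScenarioRule") -> None:
    seen: set[ChannelId] = set()
    for spec in rule.triggers:
        if spec.channel in seen:
            raise ConfigurationError(
                f"rule {rule.name!r} uses parameter {spec.channel} more than "
                "once, which compatibility mode forbids"
            )
        seen.add(spec.channel)


def eval_scenario(
    record: PatientRecord,
    rule: "ScenarioRule",
    co_occurrence_s: float | None = None,
    refractory_s: float | None = None,
    rate: float = 1.0,
    smoothing_s: float = DEFAULT_SMOOTHING_S,
    relative_mode: str = "smoothed",
    compatibility_mode: bool = False,
    plausibility: dict[ChannelId, tuple[float, float]] | None = None,
) -> list[AlarmEvent]:
    """Evaluate one scenario rule over one record.

    An alarm fires at the earliest instant ``t`` at which every trigger slot
    of the rule has an active interval overlapping ``[t - co_occurrence_s,
    t]``; after firing, the rule is silent for ``refractory_s`` and re-fires
    if the conjunction still (or again) holds.  Returns alarms sorted by
    fire time.  If the required sensors are absent the result is empty
    (check :func:`sensors_present` for the eligibility flag).

    ``compatibility_mode`` reproduces the constraint of the original
    surveillance software that no parameter may be examined more than once
    per definition: channel-reusing rules are rejected and the plausibility
    pre-filter (a second examination of the same parameter) is disabled.
    """
    if len(rule.triggers) == 0:
        raise ConfigurationError("rule has no triggers")
    if compatibility_mode:
        _check_compatibility(rule)
        plausibility = None
    co = rule.co_occurrence_s if co_occurrence_s is None else co_occurrence_s
    refr = rule.refractory_s if refractory_s is None else refractory_s

    ok, _missing = sensors_present(record, rule)
    if not ok:
        return []

    n = int(np.floor(record.duration_s * rate + 1e-9)) + 1
    times = np.arange(n, dtype=float) / rate

    slot_active: dict[str, np.ndarray] = {}
    slot_intervals: dict[str, list[ActiveInterval]] = {}
    for spec in rule.triggers:
        trace = _resolve_trace(record, spec)
        if trace is None:
            continue
        if plausibility and trace.channel in plausibility:
            trace, _ = plausibility_filter(trace, plausibility[trace.channel])
        g = resample_uniform(trace, rate, t_start=0.0, t_end=record.duration_s)
        if spec.kind == "relative_change":
            if spec.window_s >= record.duration_s:
                warnings.warn(
                    f"{rule.name}: relative window {spec.window_s:g} s exceeds "
                    "record duration; trigger never satisfied",
                    stacklevel=2,
                )
                active = np.zeros(n, dtype=bool)
            else:
                active = _relative_active(g.values, spec, rate, smoothing_s, relative_mode)
        else:
            active = _absolute_active(g.values, spec, rate)
        key = spec.slot_key
        ivs = [
            ActiveInterval(trigger=spec, t_on=float(times[a]), t_off=float(times[b]))
            for a, b in _runs(active)
        ]
        if key in slot_active:
            slot_active[key] |= active
            slot_intervals[key].extend(ivs)
        else:
            slot_active[key] = active
            slot_intervals[key] = ivs

    n_back = int(round(co * rate))
    conj = np.ones(n, dtype=bool)
    for key in slot_active:
        conj &= _trailing_any(slot_active[key], n_back)

    alarms: list[AlarmEvent] = []
    next_allowed = -np.inf
    for idx in np.flatnonzero(conj):
        t = float(times[idx])
        if t < next_allowed:
            continue
        contributing = []
        for key in sorted(slot_intervals, key=_slot_order(rule)):
            for iv in sorted(slot_intervals[key], key=lambda i: i.t_on):
                if iv.overlaps(t - co, t):
                    contributing.append(iv)
                    break
        alarms.append(
            AlarmEvent(
                scenario=rule.name,
                t_fire=t,
                contributing=tuple(contributing),
                patient_id=record.patient_id,
            )
        )
        next_allowed = t + refr
    return alarms


def _slot_order(rule: "ScenarioRule"):
    order = {}
    for i, spec in enumerate(rule.triggers):
        order.setdefault(spec.slot_key, i)
    return lambda key: order.get(key, len(order))


# ---------------------------------------------------------------------------
# cohort-level detection and the alarm-log interface
# ---------------------------------------------------------------------------

def detect_record(
    record: PatientRecord, rules: list["ScenarioRule"], **opts
) -> tuple[list[AlarmEvent], dict[str, bool]]:
    """Run every rule on a record; returns (alarms, per-rule eligibility)."""
    alarms: list[AlarmEvent] = []
    eligible: dict[str, bool] = {}
    for rule in rules:
        ok, _ = sensors_present(record, rule)
        eligible[rule.name] = ok
        if ok:
            alarms.extend(eval_scenario(record, rule, **opts))
    alarms.sort(key=lambda a: (a.t_fire, a.scenario))
    return alarms, eligible


def detect_cohort(
    records: list[PatientRecord], rules: list["ScenarioRule"], **opts
) -> tuple[list[AlarmEvent], pd.DataFrame]:
    """Run the rules on every record.

    Returns the pooled alarm list and an eligibility table with one row per
    (patient, rule) stating whether the required sensors were present.
    """
    alarms: list[AlarmEvent] = []
    rows = []
    for record in records:
        a, elig = detect_record(record, rules, **opts)
        alarms.extend(a)
        for name, ok in elig.items():
            rows.append({"patient_id": record.patient_id, "scenario": name, "eligible": ok})
    alarms.sort(key=lambda a: (a.patient_id or "", a.t_fire, a.scenario))
    eligibility = pd.DataFrame(rows, columns=["patient_id", "scenario", "eligible"])
    return alarms, eligibility


def alarms_to_frame(alarms: list[AlarmEvent]) -> pd.DataFrame:
    """Alarm log as a table: patient, scenario, fire time, trigger onsets."""
    rows = []
    for a in sorted(alarms, key=lambda a: (a.patient_id or "", a.t_fire, a.scenario)):
        row: dict[str, object] = {
            "patient_id": a.patient_id or "",
            "scenario": a.scenario,
            "t_fire": a.t_fire,
        }
        for i in range(4):
            row[f"trigger_{i + 1}_on"] = (
                a.contributing[i].t_on if i < len(a.contributing) else np.nan
            )
        rows.append(row)
    cols = ["patient_id", "scenario", "t_fire"] + [f"trigger_{i}_on" for i in (1, 2, 3, 4)]
    return pd.DataFrame(rows, columns=cols)


def alarms_from_frame(df: pd.DataFrame) -> list[AlarmEvent]:
    """Rebuild alarm events (without trigger provenance) from an alarm log."""
    out = []
    for _, row in df.iterrows():
        out.append(
            AlarmEvent(
                scenario=str(row["scenario"]),
                t_fire=float(row["t_fire"]),
                patient_id=str(row["patient_id"]),
            )
        )
    return out
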