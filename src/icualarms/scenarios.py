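"""Declarative scenario rules: the five built-in definitions plus user rules.

The built-ins are the multi-sensor 'smart alarm' definitions programmed
into the bedside monitors of a cardiothoracic ICU: hemodynamically
significant supraventricular tachycardia (SVT+BP), ventricular tachycardia
with hypotension (Vtach+BP), left-ventricular (cardiogenic) shock,
tamponade/obstructive shock, and hypovolemia.  Each combines up to four
single-parameter triggers; the four-trigger cap is part of the rule schema.

Rules serialise to a small YAML document (``schema_version: 1``) and load
back to equal objects, so rule sets are diffable, versionable text.
"""

from __future__ import annotations

import dataclasses
from typing import Any

import yaml

from .channels import ChannelId, channel_from_name
from .triggers import TriggerSpec

MAX_TRIGGERS = 4  # "maximum of four" parameters per definition
SCHEMA_VERSION = 1

DEFAULT_CO_OCCURRENCE_S = 60.0
DEFAULT_REFRACTORY_S = 300.0


@dataclasses.dataclass(frozen=True)
class ScenarioRule:
    """A named alarm definition: 1-4 triggers AND-ed over a co-occurrence window.

    Triggers sharing a ``slot`` are alternatives within the conjunction
    (either source satisfies that slot); ``required_channels`` is derived
    from the triggers and their fallbacks.
    """

    name: str
    description: str
    triggers: tuple[TriggerSpec, ...]
    co_occurrence_s: float = DEFAULT_CO_OCCURRENCE_S
    refractory_s: float = DEFAULT_REFRACTORY_S

    def __post_init__(self) -> None:
        trig = tuple(self.triggers)
        if not 1 <= len(trig) <= MAX_TRIGGERS:
            raise ValueError(
                f"rule {self.name!r} has {len(trig)} triggers; a definition "
                f"takes a maximum of four"
            )
        if self.co_occurrence_s < 0 or self.refractory_s < 0:
            raise ValueError("co_occurrence_s and refractory_s must be >= 0")
        object.__setattr__(self, "triggers", trig)

    @property
    def required_channels(self) -> frozenset[ChannelId]:
        out: set[ChannelId] = set()
        for t in self.triggers:
            out.add(t.channel)
        return frozenset(out)


def builtin_scenarios() -> list[ScenarioRule]:
    """The five built-in multi-sensor alarm definitions.

    Thresholds and trigger times follow the deployed monitor configuration:
    parenthetical sources ("HR (Pulse)") are fallbacks, the hypovolemia
    arterial-line / cuff pressures form one either-or slot, and the
    ventricular-tachycardia rhythm condition is carried by the monitor's
    Vtach annotation flag.
    """
    svt_bp = ScenarioRule(
        name="SVT+BP",
        description=(
            "Supraventricular tachycardia with hypotension: abrupt heart-rate "
            "rise with arterial pressure fall and a sustained fast pulse, as "
            "in paroxysmal atrial fibrillation with rapid ventricular response."
        ),
        triggers=(
            TriggerSpec(
                channel=ChannelId.HR,
                fallback_channel=ChannelId.Pulse,
                kind="relative_change",
                direction="rise",
                threshold=40.0,
                threshold_unit="percent",
                window_s=59.0,
            ),
            TriggerSpec(
                channel=ChannelId.ARTsys,
                kind="relative_change",
                direction="fall",
                threshold=15.0,
                threshold_unit="percent",
                window_s=59.0,
            ),
            TriggerSpec(
                channel=ChannelId.Pulse,
                fallback_channel=ChannelId.HR,
                kind="absolute_sustained",
                direction="above",
                threshold=110.0,
                duration_s=20.0,
            ),
        ),
    )
    vtach_bp = ScenarioRule(
        name="Vtach+BP",
        description=(
            "Ventricular tachycardia with hypotension: rhythm annotation plus "
            "rate rise, arterial pressure fall and sustained fast pulse — far "
            "less motion-sensitive than a single-lead ECG alarm."
        ),
        triggers=(
            TriggerSpec(
                channel=ChannelId.HR,
                fallback_channel=ChannelId.Pulse,
                kind="relative_change",
                direction="rise",
                threshold=30.0,
                threshold_unit="native",
                window_s=20.0,
            ),
            TriggerSpec(
                channel=ChannelId.VtachFlag,
                kind="flag_present",
                duration_s=5.0,
            ),
            TriggerSpec(
                channel=ChannelId.ARTsys,
                kind="relative_change",
                direction="fall",
                threshold=30.0,
                threshold_unit="percent",
                window_s=20.0,
            ),
            TriggerSpec(
                channel=ChannelId.Pulse,
                fallback_channel=ChannelId.HR,
                kind="absolute_sustained",
                direction="above",
                threshold=110.0,
                duration_s=10.0,
            ),
        ),
    )
    lv_shock = ScenarioRule(
        name="LV shock",
        description=(
            "Left-ventricular (cardiogenic) shock: sustained arterial "
            "hypotension with low CVP, elevated diastolic pulmonary artery "
            "pressure and poor peripheral perfusion."
        ),
        triggers=(
            TriggerSpec(
                channel=ChannelId.ARTsys,
                kind="absolute_sustained",
                direction="below",
                threshold=78.0,
                duration_s=300.0,
            ),
            TriggerSpec(
                channel=ChannelId.CVPmean,
                kind="absolute_sustained",
                direction="below",
                threshold=16.0,
                duration_s=300.0,
            ),
            TriggerSpec(
                channel=ChannelId.PAPdia,
                kind="absolute_sustained",
                direction="above",
                threshold=16.0,
                duration_s=300.0,
            ),
            TriggerSpec(
                channel=ChannelId.Perf,
                kind="absolute_sustained",
                direction="below",
                threshold=1.2,
                duration_s=300.0,
            ),
        ),
    )
    tamponade = ScenarioRule(
        name="Tamponade",
        description=(
            "Tamponade / obstructive shock (incl. tension pneumothorax): "
            "hypotension with elevated CVP, falling perfusion and elevated "
            "diastolic pulmonary artery pressure."
        ),
        triggers=(
            TriggerSpec(
                channel=ChannelId.ARTsys,
                kind="absolute_sustained",
                direction="below",
                threshold=78.0,
                duration_s=180.0,
            ),
            TriggerSpec(
                channel=ChannelId.CVPmean,
                kind="absolute_sustained",
                direction="above",
                threshold=16.0,
                duration_s=180.0,
            ),
            TriggerSpec(
                channel=ChannelId.Perf,
                kind="relative_change",
                direction="fall",
                threshold=20.0,
                threshold_unit="percent",
                window_s=180.0,
            ),
            TriggerSpec(
                channel=ChannelId.PAPdia,
                kind="absolute_sustained",
                direction="above",
                threshold=16.0,
                duration_s=180.0,
            ),
        ),
    )
    hypovolemia = ScenarioRule(
        name="Hypovolemia",
        description=(
            "Hypovolemic hypotension: low mean pressure (arterial line or "
            "cuff — either source satisfies the pressure slot), low CVP and "
            "falling perfusion."
        ),
        triggers=(
            TriggerSpec(
                channel=ChannelId.ARTmean,
                kind="absolute_sustained",
                direction="below",
                threshold=50.0,
                duration_s=300.0,
                slot="pressure",
            ),
            TriggerSpec(
                channel=ChannelId.CVPmean,
                kind="absolute_sustained",
                direction="below",
                threshold=5.0,
                duration_s=300.0,
            ),
            TriggerSpec(
                channel=ChannelId.Perf,
                kind="relative_change",
                direction="fall",
                threshold=20.0,
                threshold_unit="percent",
                window_s=120.0,
                scope_s=600.0,
            ),
            TriggerSpec(
                channel=ChannelId.NIBPm,
                kind="absolute_sustained",
                direction="below",
                threshold=55.0,
                duration_s=300.0,
                slot="pressure",
            ),
        ),
    )
    return [svt_bp, vtach_bp, lv_shock, tamponade, hypovolemia]


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

_OPTIONAL_NUMBERS = ("duration_s", "window_s", "scope_s")


def _trigger_to_dict(t: TriggerSpec) -> dict[str, Any]:
    d: dict[str, Any] = {"channel": t.channel.value, "kind": t.kind}
    if t.direction is not None:
        d["direction"] = t.direction
    if t.kind != "flag_present":
        d["threshold"] = float(t.threshold)
        d["threshold_unit"] = t.threshold_unit
    for f in _OPTIONAL_NUMBERS:
        v = getattr(t, f)
        if v is not None:
            d[f] = float(v)
    if t.fallback_channel is not None:
        d["fallback"] = t.fallback_channel.value
    if t.slot is not None:
        d["slot"] = t.slot
    return d


def _trigger_from_dict(d: dict[str, Any]) -> TriggerSpec:
    known = {
        "channel", "kind", "direction", "threshold", "threshold_unit",
        "duration_s", "window_s", "scope_s", "fallback", "slot",
    }
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown trigger fields: {sorted(unknown)}")
    kwargs: dict[str, Any] = {
        "channel": channel_from_name(str(d["channel"])),
        "kind": d["kind"],
    }
    if "direction" in d:
        kwargs["direction"] = d["direction"]
    if "threshold" in d:
        kwargs["threshold"] = float(d["threshold"])
    if "threshold_unit" in d:
        kwargs["threshold_unit"] = d["threshold_unit"]
    for f in _OPTIONAL_NUMBERS:
        if d.get(f) is not None:
            kwargs[f] = float(d[f])
    if d.get("fallback") is not None:
        kwargs["fallback_channel"] = channel_from_name(str(d["fallback"]))
    if d.get("slot") is not None:
        kwargs["slot"] = str(d["slot"])
    return TriggerSpec(**kwargs)


def serialize_rules(rules: list[ScenarioRule]) -> str:
    """Deterministic YAML for a rule list; ``load_rules`` inverts it exactly."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "rules": [
            {
                "name": r.name,
                "description": r.description,
                "co_occurrence_s": float(r.co_occurrence_s),
                "refractory_s": float(r.refractory_s),
                "triggers": [_trigger_to_dict(t) for t in r.triggers],
            }
            for r in rules
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=False)


def load_rules(config_text: str) -> list[ScenarioRule]:
    """Parse and validate a rule document.

    Raises ``ValueError`` on unknown channels, malformed triggers, or rules
    exceeding the four-trigger cap ("maximum of four").
    """
    doc = yaml.safe_load(config_text)
    if doc is None:
        return []
    if not isinstance(doc, dict) or "rules" not in doc:
        raise ValueError("rule document must be a mapping with a 'rules' list")
    version = doc.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version {version}")
    out: list[ScenarioRule] = []
    for rd in doc["rules"] or []:
        triggers = tuple(_trigger_from_dict(td) for td in rd.get("triggers", []))
        out.append(
            ScenarioRule(
                name=str(rd["name"]),
                description=str(rd.get("description", "")),
                triggers=triggers,
                co_occurrence_s=float(rd.get("co_occurrence_s", DEFAULT_CO_OCCURRENCE_S)),
                refractory_s=float(rd.get("refractory_s", DEFAULT_REFRACTORY_S)),
            )
        )
    return out
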