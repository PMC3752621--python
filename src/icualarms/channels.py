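"""Channel vocabulary for multi-parameter bedside monitoring.

The engine works on the numeric parameters a patient monitor exports
(heart rate from ECG, pulse rate from the plethysmograph, invasive and
non-invasive pressures, perfusion index, ectopy counts and the monitor's
ventricular-tachycardia rhythm annotation).  The vocabulary is closed:
rules referencing any other channel name are rejected at load time.
"""

from __future__ import annotations

import enum


class ChannelId(str, enum.Enum):
    """Symbolic identifier of one monitored parameter."""

    HR = "HR"                # heart rate from ECG, beats/min
    Pulse = "Pulse"          # pulse rate from plethysmograph, beats/min
    ARTsys = "ARTsys"        # systolic arterial pressure, mmHg
    ARTmean = "ARTmean"      # mean arterial pressure, mmHg
    CVPmean = "CVPmean"      # mean central venous pressure, mmHg
    PAPdia = "PAPdia"        # diastolic pulmonary artery pressure, mmHg
    Perf = "Perf"            # perfusion index, dimensionless
    NIBPm = "NIBPm"          # mean non-invasive (cuff) pressure, mmHg
    PVC = "PVC"              # premature ventricular contractions, count/min
    VtachFlag = "VtachFlag"  # monitor rhythm annotation, 0/1

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: physical units per channel
UNITS: dict[ChannelId, str] = {
    ChannelId.HR: "beats/min",
    ChannelId.Pulse: "beats/min",
    ChannelId.ARTsys: "mmHg",
    ChannelId.ARTmean: "mmHg",
    ChannelId.CVPmean: "mmHg",
    ChannelId.PAPdia: "mmHg",
    ChannelId.Perf: "",
    ChannelId.NIBPm: "mmHg",
    ChannelId.PVC: "count/min",
    ChannelId.VtachFlag: "flag",
}

_PRESSURE_RANGE = (-50.0, 400.0)
_RATE_RANGE = (0.0, 350.0)

#: carrier range of representable values per channel.  These are wide
#: transducer ranges, not plausibility limits: a CVP reading of 200 mmHg or
#: an arterial pressure of -10 mmHg is a representable (artifactual) value
#: and must survive ingestion so that downstream screening can see it.
VALID_RANGE: dict[ChannelId, tuple[float, float]] = {
    ChannelId.HR: _RATE_RANGE,
    ChannelId.Pulse: _RATE_RANGE,
    ChannelId.ARTsys: _PRESSURE_RANGE,
    ChannelId.ARTmean: _PRESSURE_RANGE,
    ChannelId.CVPmean: _PRESSURE_RANGE,
    ChannelId.PAPdia: _PRESSURE_RANGE,
    ChannelId.Perf: (0.0, 25.0),
    ChannelId.NIBPm: _PRESSURE_RANGE,
    ChannelId.PVC: _RATE_RANGE,
    ChannelId.VtachFlag: (0.0, 1.0),
}


def channel_from_name(name: str) -> ChannelId:
    """Resolve a channel name, raising ``ValueError`` for unknown names."""
    try:
        return ChannelId(name)
    except ValueError:
        known = ", ".join(c.value for c in ChannelId)
        raise ValueError(f"unknown channel {name!r}; known channels: {known}") from None
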