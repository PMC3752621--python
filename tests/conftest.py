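import numpy as np
import pytest

from icualarms import ChannelId, PatientRecord, VitalTrace


def uniform_trace(channel, values, t0=0.0):
    """1 Hz uniform trace from a value sequence."""
    values = np.asarray(values, dtype=float)
    times = t0 + np.arange(values.size, dtype=float)
    return VitalTrace(channel=channel, times=times, values=values, nominal_rate=1.0)


def flat_record(duration_s=3600.0, patient_id="P000", overrides=None, skip=()):
    """Record with every channel flat at a typical stable baseline."""
    levels = {
        ChannelId.HR: 80.0,
        ChannelId.Pulse: 80.0,
        ChannelId.ARTsys: 120.0,
        ChannelId.ARTmean: 85.0,
        ChannelId.CVPmean: 8.0,
        ChannelId.PAPdia: 12.0,
        ChannelId.Perf: 2.0,
        ChannelId.NIBPm: 85.0,
        ChannelId.PVC: 1.0,
        ChannelId.VtachFlag: 0.0,
    }
    if overrides:
        levels.update(overrides)
    n = int(duration_s) + 1
    traces = {}
    for ch, level in levels.items():
        if ch in skip:
            continue
        traces[ch] = uniform_trace(ch, np.full(n, level))
    return PatientRecord(patient_id=patient_id, duration_s=duration_s, traces=traces)


@pytest.fixture
def rng():
    return np.random.default_rng(20121108)
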