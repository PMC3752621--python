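"""Vital-sign time-series containers and elementary operations.

A :class:`VitalTrace` holds one channel's timestamped numeric series for one
patient; a :class:`PatientRecord` bundles the traces of one monitored stay.
Missing data is first-class (``NaN``): bedside numerics drop out whenever a
sensor is disconnected or the monitor rejects a measurement, and alarm
semantics downstream depend on distinguishing "no data" from "normal data".

All trigger evaluation happens on a uniform grid (1 Hz by default, matching
the update rate of monitor numerics); :func:`resample_uniform` maps an
irregular series onto that grid with a bounded carry-forward so stale values
cannot masquerade as sustained evidence.
"""

from __future__ import annotations

import dataclasses
import io
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .channels import VALID_RANGE, ChannelId, channel_from_name

#: sentinel accepted in sample sequences for a missing value
MISSING = float("nan")

#: default carry-forward tolerance (seconds): beyond this a value is stale
DEFAULT_GAP_TOLERANCE_S = 10.0

#: default smoothing window (seconds) for baseline/reference values
DEFAULT_SMOOTHING_S = 10.0


@dataclasses.dataclass(frozen=True)
class VitalTrace:
    """One channel's ordered (time, value) series.

    Parameters
    ----------
    channel : ChannelId
        Which monitored parameter this series carries.
    times : ndarray of float
        Sample times in seconds from record start, strictly increasing.
    values : ndarray of float
        Sample values in the channel's units; ``NaN`` marks missing data.
    nominal_rate : float
        Nominal sampling rate (samples/second).
    """

    channel: ChannelId
    times: np.ndarray
    values: np.ndarray
    nominal_rate: float = 1.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if t.size == 0:
            raise ValueError("trace must contain at least one sample")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"{self.channel}: timestamps must be strictly increasing")
        lo, hi = VALID_RANGE[self.channel]
        finite = v[~np.isnan(v)]
        if finite.size and (finite.min() < lo or finite.max() > hi):
            bad = finite[(finite < lo) | (finite > hi)][0]
            raise ValueError(
                f"{self.channel}: value {bad} outside carrier range [{lo}, {hi}]"
            )
        if self.channel is ChannelId.VtachFlag and finite.size:
            if not np.all(np.isin(finite, (0.0, 1.0))):
                raise ValueError("VtachFlag values must be 0 or 1")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def missing_fraction(self) -> float:
        """Fraction of grid points that are missing after resampling."""
        g = resample_uniform(self, self.nominal_rate)
        return float(np.mean(np.isnan(g.values)))


def make_trace(
    channel: ChannelId | str,
    samples: Iterable[tuple[float, float]],
    nominal_rate: float = 1.0,
) -> VitalTrace:
    """Build a validated :class:`VitalTrace` from ``(t_seconds, value)`` pairs.

    ``None`` or ``NaN`` values mark missing samples and are preserved.
    Unsorted timestamps and out-of-range values raise ``ValueError``.
    """
    if isinstance(channel, str):
        channel = channel_from_name(channel)
    pairs = list(samples)
    if not pairs:
        raise ValueError("samples must be non-empty")
    t = np.array([p[0] for p in pairs], dtype=float)
    v = np.array(
        [MISSING if p[1] is None else float(p[1]) for p in pairs], dtype=float
    )
    return VitalTrace(channel=channel, times=t, values=v, nominal_rate=nominal_rate)


def resample_uniform(
    trace: VitalTrace,
    rate: float,
    gap_tolerance_s: float = DEFAULT_GAP_TOLERANCE_S,
    t_start: float | None = None,
    t_end: float | None = None,
) -> VitalTrace:
    """Map a trace onto a uniform grid by bounded last-observation-carry-forward.

    The grid covers ``[t_start, t_end]`` (the trace span by default) at
    ``rate`` samples/second.  Each grid point takes the most recent sample at
    or before it; if that sample is itself missing, or lies more than
    ``gap_tolerance_s`` in the past, the grid point is missing.  The bound
    keeps a frozen sensor from fabricating sustained-violation evidence.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    t0 = trace.times[0] if t_start is None else float(t_start)
    t1 = trace.times[-1] if t_end is None else float(t_end)
    if t1 < t0:
        raise ValueError("t_end must be >= t_start")
    n = int(np.floor((t1 - t0) * rate + 1e-9)) + 1
    grid = t0 + np.arange(n, dtype=float) / rate
    idx = np.searchsorted(trace.times, grid + 1e-12, side="right") - 1
    out = np.full(n, MISSING)
    has = idx >= 0
    taken = idx[has]
    vals = trace.values[taken]
    age = grid[has] - trace.times[taken]
    ok = (age <= gap_tolerance_s + 1e-12) & ~np.isnan(vals)
    out[np.flatnonzero(has)[ok]] = vals[ok]
    return VitalTrace(channel=trace.channel, times=grid, values=out, nominal_rate=rate)


def baseline_value(
    trace: VitalTrace, t: float, smoothing_s: float = DEFAULT_SMOOTHING_S
) -> float:
    """Median of the non-missing samples in ``[t - smoothing_s, t]``.

    Returns ``NaN`` when the window holds no data.  The median is the
    reference for relative-change triggers; it resists single-sample spikes
    that would make a mean-based reference fire on artifact.
    """
    if smoothing_s <= 0:
        raise ValueError("smoothing_s must be positive")
    sel = (trace.times >= t - smoothing_s - 1e-12) & (trace.times <= t + 1e-12)
    window = trace.values[sel]
    window = window[~np.isnan(window)]
    if window.size == 0:
        return MISSING
    return float(np.median(window))


def rolling_baseline(
    values: np.ndarray, rate: float, smoothing_s: float = DEFAULT_SMOOTHING_S
) -> np.ndarray:
    """Vectorised trailing-median of uniform-grid values.

    Equivalent to :func:`baseline_value` evaluated at every grid point of an
    already-uniform trace (window ``[t - smoothing_s, t]``, missing values
    skipped, ``NaN`` where the window is empty).
    """
    win = int(round(smoothing_s * rate)) + 1
    s = pd.Series(values)
    return s.rolling(window=win, min_periods=1).median().to_numpy()


def mask_gaps(
    trace: VitalTrace,
    rate: float | None = None,
    gap_tolerance_s: float = DEFAULT_GAP_TOLERANCE_S,
) -> list[tuple[float, float]]:
    """Maximal half-open intervals ``[t_start, t_end)`` of missing grid data.

    The trace is first mapped onto its uniform grid; a gap interval extends
    from the first missing grid time to one sample period past the last
    missing grid time of the run.  Intervals are sorted and disjoint.
    """
    r = trace.nominal_rate if rate is None else rate
    g = resample_uniform(trace, r, gap_tolerance_s=gap_tolerance_s)
    miss = np.isnan(g.values)
    out: list[tuple[float, float]] = []
    dt = 1.0 / r
    i = 0
    n = miss.size
    while i < n:
        if miss[i]:
            j = i
            while j + 1 < n and miss[j + 1]:
                j += 1
            out.append((float(g.times[i]), float(g.times[j] + dt)))
            i = j + 1
        else:
            i += 1
    return out


@dataclasses.dataclass
class PatientRecord:
    """All traces of one monitored patient stay.

    A channel may be absent (no such sensor attached); rule eligibility
    handles absence downstream.
    """

    patient_id: str
    duration_s: float
    traces: dict[ChannelId, VitalTrace] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for ch, tr in self.traces.items():
            if tr.channel is not ch:
                raise ValueError(f"trace stored under {ch} carries channel {tr.channel}")
            if tr.times[0] < -1e-9 or tr.times[-1] > self.duration_s + 1e-9:
                raise ValueError(
                    f"{ch}: trace timestamps outside [0, {self.duration_s}]"
                )

    def channels(self) -> set[ChannelId]:
        return set(self.traces)

    def __contains__(self, channel: ChannelId) -> bool:
        return channel in self.traces


# ---------------------------------------------------------------------------
# CSV interface: long format `t_seconds,channel,value`, one file per record.
# ---------------------------------------------------------------------------

def record_to_csv(record: PatientRecord, path_or_buf) -> None:
    """Write a record as long-format CSV (empty value field = missing).

    Values are printed with 6 significant digits; the reader round-trips
    such files bit-exactly.
    """
    frames = []
    for ch in sorted(record.traces, key=lambda c: c.value):
        tr = record.traces[ch]
        frames.append(
            pd.DataFrame(
                {"t_seconds": tr.times, "channel": ch.value, "value": tr.values}
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["t_seconds", "channel", "value"])
    )
    df.to_csv(path_or_buf, index=False, float_format="%.6g", na_rep="")


def record_from_csv(
    path_or_buf, patient_id: str, duration_s: float | None = None
) -> PatientRecord:
    """Read a long-format trace CSV back into a :class:`PatientRecord`."""
    df = pd.read_csv(path_or_buf)
    expected = {"t_seconds", "channel", "value"}
    if not expected.issubset(df.columns):
        raise ValueError(f"trace CSV must have columns {sorted(expected)}")
    traces: dict[ChannelId, VitalTrace] = {}
    t_max = 0.0
    for name, grp in df.groupby("channel", sort=True):
        ch = channel_from_name(str(name))
        tr = VitalTrace(
            channel=ch,
            times=grp["t_seconds"].to_numpy(dtype=float),
            values=grp["value"].to_numpy(dtype=float),
        )
        traces[ch] = tr
        t_max = max(t_max, tr.times[-1])
    if duration_s is None:
        duration_s = t_max
    return PatientRecord(patient_id=patient_id, duration_s=duration_s, traces=traces)


def record_to_csv_text(record: PatientRecord) -> str:
    buf = io.StringIO()
    record_to_csv(record, buf)
    return buf.getvalue()
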