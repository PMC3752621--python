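"""Independent brute-force oracles for trigger semantics.

Pure-Python per-sample scans over 1 Hz uniform traces, written directly
from the trigger definitions with no shared code with the engine: the
sustained oracle checks every window of ``duration_s`` samples, the
relative oracle checks every (t - lag, t) pair.  Used to cross-check the
vectorised evaluators on randomly generated traces.
"""

from __future__ import annotations

import math
import statistics


def _is_nan(x: float) -> bool:
    return x != x


def smoothed_series(values: list[float], smoothing: int) -> list[float]:
    """Trailing median over the last ``smoothing`` seconds (inclusive)."""
    out = []
    for i in range(len(values)):
        window = [v for v in values[max(0, i - smoothing) : i + 1] if not _is_nan(v)]
        out.append(statistics.median(window) if window else math.nan)
    return out


def _intervals(active: list[bool], times: list[float]) -> list[tuple[float, float]]:
    out = []
    i = 0
    while i < len(active):
        if active[i]:
            j = i
            while j + 1 < len(active) and active[j + 1]:
                j += 1
            out.append((times[i], times[j]))
            i = j + 1
        else:
            i += 1
    return out


def absolute_intervals(
    times: list[float],
    values: list[float],
    direction: str,
    threshold: float,
    duration: int,
) -> list[tuple[float, float]]:
    """Sliding-window scan: active at i iff every sample in [i-d, i] violates."""
    n = len(values)

    def viol(v: float) -> bool:
        if _is_nan(v):
            return False
        return v > threshold if direction == "above" else v < threshold

    active = [
        i >= duration and all(viol(values[j]) for j in range(i - duration, i + 1))
        for i in range(n)
    ]
    return _intervals(active, times)


def relative_intervals(
    times: list[float],
    values: list[float],
    direction: str,
    threshold: float,
    unit: str,
    window: int,
    scope: int = 0,
    smoothing: int = 10,
) -> list[tuple[float, float]]:
    """Pairwise scan over all lags in (0, window] of the smoothed series."""
    n = len(values)
    s = smoothed_series(values, smoothing)

    def cond(cur: float, base: float) -> bool:
        if _is_nan(cur) or _is_nan(base):
            return False
        if direction == "rise":
            if unit == "percent":
                return cur >= base * (1.0 + threshold / 100.0)
            return cur >= base + threshold
        if unit == "percent":
            return cur <= base * (1.0 - threshold / 100.0)
        return cur <= base - threshold

    active = [
        any(cond(s[i], s[i - lag]) for lag in range(1, min(window, i) + 1))
        for i in range(n)
    ]
    if scope:
        active = [any(active[max(0, i - scope) : i + 1]) for i in range(n)]
    return _intervals(active, times)
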