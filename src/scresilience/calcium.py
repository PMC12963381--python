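"""Calcium transient quantification: rolling-percentile dF/F0, threshold event
detection, and well-level event-rate summaries.

The baseline F0 is the 10th percentile of the raw trace over a centered
10-second window (truncated at the edges), matching fluorescence acquired at a
few Hz where transients are sparse and the low percentile tracks the resting
level.  Events are strict upward crossings of dF/F0 = 0.2, debounced by a
short refractory separation.  Rates are summarized as events per minute and
averaged at the well level, each well being one biological replicate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import CalciumTraceSet


def compute_dff(
    trace: np.ndarray, rate_hz: float, window_s: float = 10.0, percentile: float = 10.0
) -> np.ndarray:
    """dF/F0 with F0 the rolling percentile over a centered window.

    Raises if the baseline is non-positive anywhere (the ratio would be
    undefined) or if the window holds fewer than 2 samples.
    """
    trace = np.asarray(trace, dtype=float)
    window = int(round(window_s * rate_hz))
    if window < 2:
        raise ValueError("window must span at least 2 samples")
    if window > len(trace):
        raise ValueError("window longer than trace")
    f0 = (
        pd.Series(trace)
        .rolling(window=window, center=True, min_periods=1)
        .quantile(percentile / 100.0, interpolation="linear")
        .to_numpy()
    )
    if (f0 <= 0).any():
        raise ValueError("non-positive baseline; trace rejected")
    return (trace - f0) / f0


def detect_events(
    dff: np.ndarray,
    rate_hz: float,
    threshold: float = 0.2,
    min_separation_s: float = 0.4,
) -> np.ndarray:
    """Onset times (s) of strict upward threshold crossings, debounced.

    An event starts where dF/F0 goes from <= threshold to > threshold; a
    crossing within ``min_separation_s`` of the previous onset is merged into
    it.  A trace already above threshold at sample 0 counts as an event at
    t = 0.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    dff = np.asarray(dff, dtype=float)
    above = dff > threshold
    crossings = np.flatnonzero(above & ~np.concatenate([[False], above[:-1]]))
    onsets: list[float] = []
    for c in crossings:
        t = c / rate_hz
        if onsets and t - onsets[-1] < min_separation_s:
            continue
        onsets.append(t)
    return np.asarray(onsets)


def event_table(
    traces: CalciumTraceSet,
    window_s: float = 10.0,
    percentile: float = 10.0,
    threshold: float = 0.2,
    min_separation_s: float = 0.4,
) -> pd.DataFrame:
    """Per-trace event counts and rates (events/min) for a trace set."""
    rows = []
    for tid in traces.traces.columns:
        raw = traces.traces[tid].to_numpy()
        dff = compute_dff(raw, traces.rate_hz, window_s, percentile)
        onsets = detect_events(dff, traces.rate_hz, threshold, min_separation_s)
        duration = len(raw) / traces.rate_hz
        rows.append(
            {
                "trace_id": tid,
                "event_count": len(onsets),
                "duration_s": duration,
                "events_per_min": len(onsets) / (duration / 60.0),
                "onsets_s": list(onsets),
            }
        )
    table = pd.DataFrame(rows).set_index("trace_id")
    return table.join(traces.trace_meta)


def summarize_rates(events: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average event rates at the well level, then summarize per condition.

    The condition mean is the mean of well means (wells are the biological
    replicates), never a pooled mean over traces.
    """
    if events["well_id"].isna().any():
        raise ValueError("every trace must map to a well")
    wells = (
        events.groupby(["condition", "well_id"])["events_per_min"]
        .agg(["mean", "count"])
        .rename(columns={"mean": "events_per_min", "count": "n_traces"})
        .reset_index()
    )
    conditions = (
        wells.groupby("condition")["events_per_min"]
        .agg(["mean", "std", "count"])
        .rename(columns={"mean": "events_per_min", "count": "n_wells"})
    )
    return wells, conditions
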