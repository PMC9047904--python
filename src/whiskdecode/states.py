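"""UP/DOWN network-state detection from the cumulative instantaneous firing rate.

The instantaneous firing rate (IFR) per electrode is the spike count in a
10 ms sliding window stepped by 1 ms, expressed in Hz.  Summing over all
electrodes yields a network-level trace; epochs where it exceeds its global
mean are UP states.  A stimulus is labeled UP if an UP interval intersects
the 50 ms investigation window preceding its onset, DOWN otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import SpikeRaster

WINDOW_S = 0.010
STEP_S = 0.001
INVESTIGATION_S = 0.050


@dataclass
class StateTrace:
    times: np.ndarray  # window start times, s
    cum_ifr: np.ndarray  # Hz, summed over electrodes
    threshold: float  # global mean of cum_ifr
    up_intervals: list[tuple[float, float]]
    window: float = WINDOW_S
    step: float = STEP_S


def compute_ifr(
    raster: SpikeRaster, window: float = WINDOW_S, step: float = STEP_S
) -> StateTrace:
    """Cumulative IFR over electrodes and its above-mean (UP) intervals."""
    t0, t1 = raster.span
    if t1 <= t0:
        raise ValueError("recording span is empty")
    nbins = int(np.ceil((t1 - t0) / step))
    per_bin = np.zeros(nbins)
    for times in raster.spikes.values():
        if len(times):
            idx, _ = np.histogram(times, bins=nbins, range=(t0, t0 + nbins * step))
            per_bin += idx
    # moving sum over window/step consecutive 1 ms bins = count in each window
    k = max(int(round(window / step)), 1)
    counts = np.convolve(per_bin, np.ones(k), mode="valid")
    cum_ifr = counts / window  # Hz summed over electrodes
    # causal alignment: each window is attributed to its END time, so a burst
    # of activity can only influence timestamps at or after the burst —
    # post-stimulus responses never leak into the pre-stimulus window
    times = t0 + window + np.arange(counts.size) * step
    threshold = float(cum_ifr.mean()) if cum_ifr.size else 0.0
    up = _runs_above(times, cum_ifr, threshold, step, window)
    return StateTrace(times, cum_ifr, threshold, up, window, step)


def _runs_above(times, x, thr, step, window) -> list[tuple[float, float]]:
    """Maximal runs of window END times above threshold, as (start, end) s."""
    above = x > thr  # strict: zero-activity traces yield no UP intervals
    if not above.any():
        return []
    d = np.diff(above.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))
    return [
        (float(times[a]), float(times[b - 1] + step)) for a, b in zip(starts, ends)
    ]


def label_stimuli(
    trace: StateTrace, stim: pd.DataFrame, investigation: float = INVESTIGATION_S
) -> pd.DataFrame:
    """Append a ``state`` column: UP iff an UP interval meets [onset-50ms, onset)."""
    labels = []
    t_start = trace.times[0] if trace.times.size else 0.0
    for onset in stim["onset"]:
        w0, w1 = onset - investigation, onset  # half-open [w0, w1)
        if w0 < t_start:
            warnings.warn(
                f"stimulus at {onset:.3f}s within {investigation*1e3:.0f} ms of "
                "recording start; labeling from truncated window"
            )
            w0 = t_start
        hit = any(a < w1 and b > w0 for a, b in trace.up_intervals)
        labels.append("UP" if hit else "DOWN")
    out = stim.copy()
    out["state"] = labels
    return out
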