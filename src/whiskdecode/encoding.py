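"""Threshold-crossing encoding of analog LFP traces into sparse spike events.

N_thresh thresholds are spaced uniformly over the signal range; channel i
(1..N) fires when the signal rises above threshold i, channel N+i fires when
it falls below threshold i.  A crossing requires a strict inequality on the
new sample, and events are timestamped at the later sample of the crossing
pair.  The default range is the pooled min/max of the training split, fixed
at test time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_THRESH_DEFAULT = 50


@dataclass
class EncoderConfig:
    n_thresh: int = N_THRESH_DEFAULT
    thresholds: np.ndarray | None = None  # µV, strictly increasing
    range_source: str = "train"  # "train" | "per-trial"

    @property
    def n_channels(self) -> int:
        return 2 * self.n_thresh

    def fit_range(self, traces) -> "EncoderConfig":
        """Set thresholds from the pooled min/max of the given traces."""
        lo = min(float(np.min(t)) for t in traces)
        hi = max(float(np.max(t)) for t in traces)
        if hi <= lo:
            raise ValueError(
                "degenerate signal range; fit thresholds on the training set"
            )
        # uniformly spaced over the range, at the midpoints of n equal bins
        # (keeps the extreme thresholds strictly inside the range so a
        # full-range sweep crosses every threshold)
        step = (hi - lo) / self.n_thresh
        self.thresholds = lo + step * (np.arange(self.n_thresh) + 0.5)
        return self


@dataclass
class EventStream:
    """2·n_thresh channels of spike times (s); rising first, then falling."""

    events: list[np.ndarray]
    n_thresh: int

    @property
    def n_channels(self) -> int:
        return 2 * self.n_thresh


def encode(trace: np.ndarray, cfg: EncoderConfig, fs: float) -> EventStream:
    """Encode one analog trace; event times are sample_index / fs."""
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace must be finite")
    if cfg.thresholds is None:
        if cfg.range_source == "per-trial":
            cfg_local = EncoderConfig(cfg.n_thresh).fit_range([trace])
            thr = cfg_local.thresholds
        else:
            raise ValueError("thresholds unset; call fit_range on the train split")
    else:
        thr = cfg.thresholds
    x0, x1 = trace[:-1], trace[1:]
    events: list[np.ndarray] = []
    for th in thr:  # rising: x_t <= th < x_{t+1}
        idx = np.flatnonzero((x0 <= th) & (x1 > th)) + 1
        events.append(idx / fs)
    for th in thr:  # falling: x_t >= th > x_{t+1}
        idx = np.flatnonzero((x0 >= th) & (x1 < th)) + 1
        events.append(idx / fs)
    return EventStream(events, len(thr))


def total_event_count(stream: EventStream) -> int:
    return int(sum(len(e) for e in stream.events))


def reconstruct(stream: EventStream, cfg: EncoderConfig, n_samples: int, fs: float,
                start_level: float | None = None) -> np.ndarray:
    """Staircase reconstruction: cumulative signed events × threshold step.

    Diagnostic inverse of the encoder; accurate to within one threshold step
    for traces inside the encoded range.
    """
    thr = cfg.thresholds
    step = thr[1] - thr[0] if len(thr) > 1 else 1.0
    delta = np.zeros(n_samples)
    for ch, ev in enumerate(stream.events):
        sgn = 1.0 if ch < stream.n_thresh else -1.0
        for t in ev:
            delta[int(round(t * fs))] += sgn * step
    level0 = thr[0] if start_level is None else start_level
    return level0 + np.cumsum(delta)
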