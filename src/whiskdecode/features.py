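"""Per-trial, per-layer evoked-response features from LFP and MUA.

LFP features (from the layer-averaged 2500 Hz LFP):

* ROL — response onset latency: first instant within 20 ms of stimulus onset
  where |d(trace)/dt| exceeds mean(bas') + 3·sd(bas'), bas' being the
  derivative over a baseline window preceding the stimulus.
* RPA — response peak amplitude: the onset-to-trough voltage drop
  |trace(ROL) − RP|, RP being the most negative value within 50 ms of ROL.
* PR — positive rebound: maximum positive voltage within 100 ms after the
  main peak, absent when the window never goes positive.
* tLFP — time-normalized LFP: AUC/RD, where RD is the time from onset until
  the trace first returns to its onset-instant value after the main peak
  (capped at 300 ms) and AUC is the unsigned area between trace and
  onset-level over that span.

MUA features (from layer-pooled spike events): latency of the first evoked
MUA event within 100 ms of onset (t1 − onset), its duration (t2 − t1) and
its firing rate (spike count / duration).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import BandSignal, MuaEvent, SpikeRaster, group_mua

ROL_SEARCH_S = 0.020
RPA_SEARCH_S = 0.050
PR_SEARCH_S = 0.100
RD_CAP_S = 0.300
MUA_WINDOW_S = 0.100
BASELINE_S = 10.0


def layer_mean_lfp(sig: BandSignal, layer: str) -> np.ndarray:
    """Arithmetic mean LFP across the electrodes of one layer."""
    if sig.channels is None:
        raise ValueError("BandSignal carries no channel table")
    sel = sig.channels[sig.channels["layer"] == layer]["index"].to_numpy()
    if sel.size == 0:
        raise ValueError(f"unknown or empty layer {layer!r}")
    return sig.samples[sel].mean(axis=0)


def response_onset_latency(
    trace: np.ndarray,
    fs: float,
    onset: float,
    baseline_window: float = BASELINE_S,
    search: float = ROL_SEARCH_S,
) -> float:
    """ROL in ms after onset, or NaN when no derivative crossing is found."""
    dt_ms = 1000.0 / fs
    deriv = np.gradient(trace) / dt_ms  # µV/ms
    i_on = int(round(onset * fs))
    i_bas = max(i_on - int(round(baseline_window * fs)), 0)
    bas = deriv[i_bas:i_on]
    if bas.size < 2:
        return np.nan
    thr = float(np.mean(bas) + 3.0 * np.std(bas))
    i_end = min(i_on + int(round(search * fs)), trace.size - 1)
    seg = np.abs(deriv[i_on + 1 : i_end + 1])
    hits = np.flatnonzero(seg > thr)
    if hits.size == 0:
        return np.nan
    return float((hits[0] + 1) / fs * 1000.0)


def response_peak_amplitude(
    trace: np.ndarray, fs: float, onset: float, rol_ms: float
) -> tuple[float, float, float]:
    """(RP µV, RPA µV, peak time s).  RPA is the onset-to-trough drop."""
    if np.isnan(rol_ms):
        return np.nan, np.nan, np.nan
    i_rol = int(round((onset + rol_ms / 1000.0) * fs))
    i_end = min(i_rol + int(round(RPA_SEARCH_S * fs)), trace.size - 1)
    seg = trace[i_rol : i_end + 1]
    k = int(np.argmin(seg))
    rp = float(seg[k])
    rpa = float(abs(trace[i_rol] - rp))
    return rp, rpa, (i_rol + k) / fs


def positive_rebound(trace: np.ndarray, fs: float, peak_time: float) -> float:
    """Max positive voltage in the 100 ms after the main peak; NaN if none."""
    if np.isnan(peak_time):
        return np.nan
    i_pk = int(round(peak_time * fs))
    i_end = min(i_pk + int(round(PR_SEARCH_S * fs)), trace.size - 1)
    if i_end <= i_pk:
        return np.nan
    m = float(np.max(trace[i_pk + 1 : i_end + 1]))
    return m if m > 0 else np.nan


def time_normalized_lfp(
    trace: np.ndarray, fs: float, onset: float, rol_ms: float, peak_time: float
) -> float:
    """tLFP = AUC/RD relative to the onset-instant voltage level."""
    if np.isnan(rol_ms) or np.isnan(peak_time):
        return np.nan
    i_rol = int(round((onset + rol_ms / 1000.0) * fs))
    i_pk = int(round(peak_time * fs))
    level = trace[i_rol]
    i_cap = min(i_rol + int(round(RD_CAP_S * fs)), trace.size - 1)
    seg = trace[i_pk : i_cap + 1]
    sign0 = np.sign(seg[0] - level) if seg.size else 0.0
    ret = np.flatnonzero(np.sign(seg - level) != sign0)
    i_ret = i_pk + int(ret[0]) if ret.size else i_cap  # cap when never returning
    rd = (i_ret - i_rol) / fs
    if rd <= 0:
        return np.nan
    auc = float(np.trapezoid(np.abs(trace[i_rol : i_ret + 1] - level), dx=1.0 / fs))
    return auc / rd


def lfp_features_for_trial(
    trace: np.ndarray,
    fs: float,
    onset: float,
    baseline_window: float = BASELINE_S,
) -> dict:
    rol = response_onset_latency(trace, fs, onset, baseline_window)
    rp, rpa, pk_t = response_peak_amplitude(trace, fs, onset, rol)
    pr = positive_rebound(trace, fs, pk_t)
    tlfp = time_normalized_lfp(trace, fs, onset, rol, pk_t)
    return {"ROL": rol, "RPA": rpa, "PR": pr, "tLFP": tlfp}


def mua_features(events: list[MuaEvent], onset: float) -> dict:
    """Latency/duration/rate of the first evoked MUA within 100 ms of onset."""
    for ev in events:
        if onset < ev.t1 <= onset + MUA_WINDOW_S:
            lat = (ev.t1 - onset) * 1000.0
            dur = (ev.t2 - ev.t1) * 1000.0
            rate = ev.n_spikes / (ev.t2 - ev.t1) if ev.t2 > ev.t1 else np.nan
            return {"latency": lat, "duration": dur, "rate": rate}
    return {"latency": np.nan, "duration": np.nan, "rate": np.nan}


def extract_feature_table(
    lfp: BandSignal,
    raster: SpikeRaster,
    stim: pd.DataFrame,
    baseline_window: float = BASELINE_S,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-trial × per-layer LFP and MUA feature tables.

    ``stim`` must carry columns onset, amp_class and (after state labeling)
    state.  The baseline window shortens automatically for closely spaced
    stimuli (bounded by the available pre-stimulus signal).
    """
    layers = list(dict.fromkeys(lfp.channels["layer"]))
    lfp_rows, mua_rows = [], []
    layer_traces = {ly: layer_mean_lfp(lfp, ly) for ly in layers}
    layer_spikes = {
        ly: raster.merged(
            lfp.channels[lfp.channels["layer"] == ly]["index"].to_numpy()
        )
        for ly in layers
    }
    for trial, row in stim.iterrows():
        onset = float(row["onset"])
        meta = {
            "trial": trial,
            "amp_class": row.get("amp_class"),
            "state": row.get("state"),
        }
        for ly in layers:
            f = lfp_features_for_trial(
                layer_traces[ly], lfp.fs, onset, baseline_window
            )
            lfp_rows.append({**meta, "layer": ly, **f})
            sp = layer_spikes[ly]
            win = sp[(sp > onset) & (sp <= onset + MUA_WINDOW_S + 0.050)]
            events = group_mua(win, ly)
            mua_rows.append({**meta, "layer": ly, **mua_features(events, onset)})
    return pd.DataFrame(lfp_rows), pd.DataFrame(mua_rows)
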