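"""Synthetic multi-electrode barrel-cortex recordings with planted evoked responses.

The generator emulates the statistical structure of anesthetized-rat barrel
cortex recordings: ~1 Hz alternation of UP (active) and DOWN (quiescent)
network states, whisker stimuli of three intensities (large/medium/small,
driven by 2.8/2.0/1.6 V pulses), evoked LFP deflections with a negative peak
~25 ms post-stimulus whose magnitude scales with intensity, cortical layer
and network state, a positive rebound within 100 ms, and evoked multi-unit
bursts within 100 ms whose latency and spike count depend on intensity and
state.  Ground-truth annotations (state at stimulus time, planted peak) are
kept in a sidecar table that the analysis pipeline never reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

LAYERS = ("II", "III", "IV", "Va", "Vb", "VI")
AMP_CLASSES = ("large", "medium", "small")
DRIVE_VOLTS = {"large": 2.8, "medium": 2.0, "small": 1.6}

#: default partition of the 27 in-cortex channels over layers (sums to 27)
DEFAULT_LAYER_COUNTS = {"II": 4, "III": 5, "IV": 5, "Va": 4, "Vb": 4, "VI": 5}


def default_layer_map(counts: dict[str, int] | None = None) -> dict[int, str]:
    """Channel index -> layer label, superficial to deep along the probe."""
    counts = dict(counts or DEFAULT_LAYER_COUNTS)
    if set(counts) != set(LAYERS):
        raise ValueError(f"layer counts must cover exactly {LAYERS}")
    mapping: dict[int, str] = {}
    ch = 0
    for layer in LAYERS:
        for _ in range(counts[layer]):
            mapping[ch] = layer
            ch += 1
    return mapping


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic session.

    Defaults are the study conditions: 61/63/61 trials of large/medium/small
    stimuli, 27 cortical channels, ~1 Hz UP/DOWN alternation.  ``isi`` defaults
    to the desk-test value of 1.5 s; the in-vivo protocol value of 10 s is a
    plain config switch.
    """

    seed: int = 0
    fs: float = 10_000.0
    n_channels_cortex: int = 27
    layer_map: dict[int, str] = field(default_factory=default_layer_map)
    n_trials: dict[str, int] = field(
        default_factory=lambda: {"large": 61, "medium": 63, "small": 61}
    )
    isi: float = 1.5
    pulse_dur: float = 0.005
    updown_rate: float = 1.0
    up_mua_rate: float = 12.0
    down_mua_rate: float = 0.5
    evoked_gain: dict[str, float] = field(
        default_factory=lambda: {"large": 300.0, "medium": 220.0, "small": 150.0}
    )
    state_gain: float = 1.4
    layer_gain: dict[str, float] = field(
        default_factory=lambda: {
            "II": 0.6, "III": 1.0, "IV": 1.0, "Va": 0.7, "Vb": 0.5, "VI": 0.35,
        }
    )
    rol_shift_small: float = 3.0  # ms, extra onset latency for small stimuli
    noise_sd: float = 5.0  # µV broadband Gaussian noise
    lead_in: float = 1.2  # s of pre-first-stimulus baseline
    onset_delay: float = 0.008  # s, planted LFP response onset after stimulus
    neg_peak_time: float = 0.025  # s, planted negative-peak time after stimulus
    # evoked MUA burst: per-channel expected spike count by class (layer-scaled)
    mua_count_params: dict[str, float] = field(
        default_factory=lambda: {"large": 6.0, "medium": 4.5, "small": 3.0}
    )
    # evoked burst latency (ms): base + state and class shifts, Gaussian jitter
    mua_latency_params: dict[str, float] = field(
        default_factory=lambda: {
            "base_ms": 7.0, "down_shift_ms": 4.0, "small_shift_ms": 4.0,
            "jitter_ms": 1.5,
        }
    )

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if any(n < 1 for n in self.n_trials.values()):
            raise ValueError("per-class trial counts must be >= 1")
        g = self.evoked_gain
        if not (g["large"] > g["medium"] > g["small"]):
            raise ValueError("evoked_gain must be ordered large > medium > small")
        if self.layer_gain["IV"] < self.layer_gain["VI"]:
            raise ValueError("layer_gain(IV) must be >= layer_gain(VI)")
        missing = [c for c in range(self.n_channels_cortex) if c not in self.layer_map]
        if missing:
            raise ValueError(f"layer_map missing channels {missing}")

    @property
    def n_total_trials(self) -> int:
        return sum(self.n_trials.values())

    @property
    def session_length(self) -> float:
        return self.lead_in + self.n_total_trials * self.isi + 0.5


@dataclass
class Recording:
    """Multi-channel raw extracellular voltage (µV)."""

    samples: np.ndarray  # (n_channels, n_samples) float32 µV
    fs: float
    channels: pd.DataFrame  # columns: index, layer, in_cortex

    def layer_channels(self, layer: str) -> np.ndarray:
        sel = self.channels[(self.channels.layer == layer) & self.channels.in_cortex]
        if sel.empty:
            raise ValueError(f"no channels in layer {layer!r}")
        return sel.index.to_numpy()

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.fs


def generate_state_sequence(
    cfg: SynthConfig, session_length: float | None = None, rng=None
) -> pd.DataFrame:
    """Alternating UP/DOWN intervals tiling the session.

    Durations are gamma-distributed (shape 2) with mean 1/(2·updown_rate) per
    state, so a full UP+DOWN cycle takes ~1/updown_rate seconds.  With
    ``updown_rate`` ~ 0 a single interval of the initial state covers the whole
    session.  Returns a frame with columns start, end, state.
    """
    length = cfg.session_length if session_length is None else session_length
    if length <= 0:
        raise ValueError("session length must be positive")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    state = "DOWN" if rng.random() < 0.5 else "UP"
    rows = []
    t = 0.0
    mean_dur = np.inf if cfg.updown_rate <= 0 else 1.0 / (2.0 * cfg.updown_rate)
    while t < length:
        dur = length - t if not np.isfinite(mean_dur) else rng.gamma(2.0, mean_dur / 2.0)
        end = min(t + max(dur, 1e-3), length)
        rows.append((t, end, state))
        t = end
        state = "UP" if state == "DOWN" else "DOWN"
    return pd.DataFrame(rows, columns=["start", "end", "state"])


def _state_at(states: pd.DataFrame, t: float) -> str:
    idx = np.searchsorted(states["start"].to_numpy(), t, side="right") - 1
    return str(states["state"].iloc[max(idx, 0)])


def _state_context(states: pd.DataFrame, onset: float, window: float = 0.050) -> str:
    """UP iff an UP interval intersects [onset - window, onset).

    This mirrors the pipeline's labeling rule ("stimulus delivered during an
    UP state" means UP activity within the 50 ms investigation window), so
    the truth column measures detection quality rather than a semantic
    mismatch between instantaneous state and windowed context.
    """
    w0, w1 = onset - window, onset
    sel = states[(states.start < w1) & (states.end > w0) & (states.state == "UP")]
    return "UP" if len(sel) else "DOWN"


def evoked_lfp_template(
    cfg: SynthConfig, amp_class: str, state: str, layer: str, n_samples: int
) -> np.ndarray:
    """Planted evoked LFP: difference of alpha functions (µV).

    A fast negative lobe peaking at ``neg_peak_time`` after the stimulus
    (shifted later by ``rol_shift_small`` for small stimuli) followed by a
    slower positive rebound within 100 ms.  Peak magnitude is
    evoked_gain(class) · layer_gain(layer), multiplied by ``state_gain`` when
    the stimulus falls in a DOWN state.
    """
    t = np.arange(n_samples) / cfg.fs
    onset = cfg.onset_delay
    if amp_class == "small":
        onset = onset + cfg.rol_shift_small / 1000.0
    tau_neg = cfg.neg_peak_time - cfg.onset_delay  # alpha fn peaks at t = tau
    peak = cfg.evoked_gain[amp_class] * cfg.layer_gain[layer]
    if state == "DOWN":
        peak *= cfg.state_gain
    s = np.clip(t - onset, 0.0, None)
    neg = -(s / tau_neg) * np.exp(1.0 - s / tau_neg)
    tau_pos = 0.030
    delay_pos = 2.5 * tau_neg  # rebound lobe starts after the main trough
    sp = np.clip(s - delay_pos, 0.0, None)
    pos = (sp / tau_pos) * np.exp(1.0 - sp / tau_pos)
    return (peak * (neg + 0.35 * pos)).astype(np.float64)


def spike_waveform(fs: float, amplitude: float = -70.0) -> np.ndarray:
    """Biphasic extracellular spike (~1.2 ms) in the 300–3000 Hz band, µV."""
    t = np.arange(int(round(1.2e-3 * fs))) / fs
    w = np.sin(2 * np.pi * t / 1.2e-3) * np.exp(-t / 4e-4)
    return (amplitude * w / np.max(np.abs(w))).astype(np.float64)


def _render_spikes(trace: np.ndarray, times: np.ndarray, wave: np.ndarray, fs: float):
    n = trace.shape[0]
    for st in times:
        i = int(round(st * fs))
        if 0 <= i < n:
            j = min(i + wave.shape[0], n)
            trace[i:j] += wave[: j - i]


def generate_recording(
    cfg: SynthConfig,
    background_mua: bool = True,
) -> tuple[Recording, pd.DataFrame]:
    """Synthesize a full session.

    Returns the raw Recording and a StimulusTable with columns
    onset, amp_class, drive_voltage plus ground-truth sidecar columns
    truth_state and truth_peak (planted layer-IV negative-peak magnitude, µV).
    Evoked gains use the state at the stimulus onset itself; truth_state is
    the windowed UP/DOWN context the state labeler is defined to recover
    (UP activity within the 50 ms investigation window).
    Use :func:`split_truth` to separate the sidecar before feeding the table
    to the pipeline.
    """
    rng = np.random.default_rng(cfg.seed)
    states = generate_state_sequence(cfg, rng=rng)
    n_samples = int(round(cfg.session_length * cfg.fs))
    n_ch = cfg.n_channels_cortex

    # stimulus schedule: exact per-class counts, shuffled order, fixed ISI
    labels = np.concatenate(
        [np.full(cfg.n_trials[c], i) for i, c in enumerate(AMP_CLASSES)]
    )
    rng.shuffle(labels)
    onsets = cfg.lead_in + np.arange(labels.size) * cfg.isi

    raw = np.zeros((n_ch, n_samples), dtype=np.float64)
    wave = spike_waveform(cfg.fs)
    lat = cfg.mua_latency_params

    # background MUA: state-dependent Poisson per channel
    if background_mua:
        for ch in range(n_ch):
            times = []
            for _, iv in states.iterrows():
                rate = cfg.up_mua_rate if iv.state == "UP" else cfg.down_mua_rate
                n_sp = rng.poisson(rate * (iv.end - iv.start))
                if n_sp:
                    times.append(rng.uniform(iv.start, iv.end, n_sp))
            if times:
                _render_spikes(raw[ch], np.sort(np.concatenate(times)), wave, cfg.fs)

    tmpl_len = int(round(0.300 * cfg.fs))
    stim_rows = []
    for onset, li in zip(onsets, labels):
        amp_class = AMP_CLASSES[int(li)]
        state = _state_at(states, onset)  # physiological state at onset
        state_ctx = _state_context(states, onset)  # windowed label context
        i0 = int(round(onset * cfg.fs))
        truth_peak = np.nan
        for ch in range(n_ch):
            layer = cfg.layer_map[ch]
            tmpl = evoked_lfp_template(cfg, amp_class, state, layer, tmpl_len)
            j = min(i0 + tmpl_len, n_samples)
            raw[ch, i0:j] += tmpl[: j - i0]
            if layer == "IV" and np.isnan(truth_peak):
                truth_peak = float(np.abs(tmpl.min()))
            # evoked spike burst within 100 ms, count scaled by class and layer
            mean_count = cfg.mua_count_params[amp_class] * cfg.layer_gain[layer]
            n_sp = rng.poisson(mean_count)
            if n_sp:
                mu = lat["base_ms"]
                if state == "DOWN":
                    mu += lat["down_shift_ms"]
                if amp_class == "small":
                    mu += lat["small_shift_ms"]
                first = max(rng.normal(mu, lat["jitter_ms"]), 1.0) / 1000.0
                extra = np.sort(rng.exponential(0.006, max(n_sp - 1, 0)))
                sp = onset + first + np.concatenate([[0.0], extra.cumsum()])
                sp = sp[sp < onset + 0.100]
                _render_spikes(raw[ch], sp, wave, cfg.fs)
        stim_rows.append(
            (float(onset), amp_class, DRIVE_VOLTS[amp_class], state_ctx, truth_peak)
        )

    if cfg.noise_sd > 0:
        raw += rng.normal(0.0, cfg.noise_sd, size=raw.shape)

    channels = pd.DataFrame(
        {
            "index": np.arange(n_ch),
            "layer": [cfg.layer_map[c] for c in range(n_ch)],
            "in_cortex": True,
        }
    ).set_index("index", drop=False)
    stim = pd.DataFrame(
        stim_rows,
        columns=["onset", "amp_class", "drive_voltage", "truth_state", "truth_peak"],
    )
    return Recording(raw.astype(np.float32), cfg.fs, channels), stim


def split_truth(stim: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Separate the ground-truth sidecar from the pipeline-facing table."""
    truth_cols = [c for c in stim.columns if c.startswith("truth_")]
    return stim.drop(columns=truth_cols), stim[truth_cols].copy()


def desk_config(seed: int = 0, n_per_class: int = 20, **overrides) -> SynthConfig:
    """A reduced-size configuration for fast tests and examples."""
    base = SynthConfig(
        seed=seed,
        n_trials={"large": n_per_class, "medium": n_per_class, "small": n_per_class},
    )
    return replace(base, **overrides) if overrides else base
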