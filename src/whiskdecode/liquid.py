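"""Liquid state machine: LIF neurons, exponential PSCs, short-term plasticity.

The liquid is a recurrent network of leaky integrate-and-fire neurons with
exponentially decaying postsynaptic currents.  Each neuron receives exactly
two excitatory and one inhibitory recurrent connection chosen at random;
recurrent synapses are dynamic (Tsodyks–Markram depression/facilitation),
input and noise synapses are static.  The excitatory population's spike
trains are low-pass filtered with a 5 ms exponential kernel and read out
45 ms after stimulus onset; a linear SVM on these liquid states is the only
trained component.

A hardware profile emulating the DYNAP-SE mixed-signal processor can be
applied to a built network: fan-in capped at 64 connections per neuron,
synapses quantized to integer multiples of one shared magnitude per synapse
type, zero delays, and 20 % Gaussian mismatch (clipped at two standard
deviations) on membrane time constant, threshold, reset potential and
capacitance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Tsodyks–Markram (U, tau_rec s, tau_fac s) means per connection class,
#: following the Maass-2002 convention; each jittered ±50 % at build time.
STP_DEFAULTS = {
    "EE": (0.5, 1.1, 0.05),
    "EI": (0.05, 0.125, 1.2),
    "IE": (0.25, 0.7, 0.02),
    "II": (0.32, 0.144, 0.06),
}


@dataclass(frozen=True)
class LsmNeuronParams:
    v_rest: float = 0.0  # mV
    c_m: float = 30.0  # pF
    tau_m: float = 30.0  # ms
    tau_syn_e: float = 3.0  # ms
    tau_syn_i: float = 2.0  # ms
    t_ref: float = 2.0  # ms
    theta: float = 15.0  # mV
    v_reset: float = 13.8  # mV
    i_const: float = 7.0  # pA


@dataclass(frozen=True)
class LsmConfig:
    """LFP variant: 330 E / 80 I; MUA variant: 100 E / 25 I (see presets)."""

    n_exc: int = 100
    n_inh: int = 25
    k_exc_in: int = 2  # recurrent excitatory in-degree
    k_inh_in: int = 1  # recurrent inhibitory in-degree
    w_ee: tuple = (100.0, 70.0)  # pA, N(mean, sd)
    w_ei: tuple = (500.0, 350.0)
    w_ie: tuple = (-400.0, 280.0)
    w_ii: tuple = (-400.0, 280.0)
    w_noise: tuple = (2.0, 1.0)
    noise_rate: float = 100.0  # Hz Poisson generator per neuron
    delay_dist: tuple = (10.0, 20.0)  # ms, N(mean, sd)
    delay_clip: tuple = (3.0, 200.0)  # ms
    input_fanout: int = 4
    input_weight_range: tuple = (15.0, 45.0)  # pA, U(lo, hi); LFP preset 250..750
    n_inputs: int = 27
    scale_input: float = 1.0
    scale_exc: float = 1.0
    scale_inh: float = 1.0
    readout_tau: float = 0.005  # s
    readout_offset: float = 0.045  # s after stimulus onset
    warmup: float = 1.0  # s of pre-onset input
    dt: float = 0.1  # ms integration step
    neuron: LsmNeuronParams = field(default_factory=LsmNeuronParams)
    v_init: str = "uniform"  # "uniform" over [0, theta) or "fixed" (-70 mV)
    seed: int = 0


def mua_lsm_config(**kw) -> LsmConfig:
    return replace(LsmConfig(), **kw)


def lfp_lsm_config(**kw) -> LsmConfig:
    base = LsmConfig(
        n_exc=330, n_inh=80, n_inputs=100, input_weight_range=(250.0, 750.0)
    )
    return replace(base, **kw)


@dataclass
class LsmNetwork:
    cfg: LsmConfig
    # per-neuron parameter arrays (jitterable by the hardware profile)
    tau_m: np.ndarray
    theta: np.ndarray
    v_reset: np.ndarray
    c_m: np.ndarray
    is_exc: np.ndarray  # bool mask, first n_exc True
    # recurrent synapses
    syn_pre: np.ndarray
    syn_post: np.ndarray
    syn_w: np.ndarray  # pA, sign-constrained
    syn_delay: np.ndarray  # ms
    syn_class: np.ndarray  # "EE"|"EI"|"IE"|"II"
    syn_U: np.ndarray
    syn_tau_rec: np.ndarray  # s
    syn_tau_fac: np.ndarray  # s
    syn_static: bool  # True once hardware constraints are applied
    # input projections (static)
    in_chan: np.ndarray
    in_post: np.ndarray
    in_w: np.ndarray  # pA, >= 0
    in_delay: np.ndarray  # ms
    noise_w: np.ndarray  # pA per neuron
    hardware: bool = False

    @property
    def n(self) -> int:
        return self.tau_m.size

    def in_degree(self) -> np.ndarray:
        """Connection count per postsynaptic neuron (recurrent + input)."""
        deg = np.bincount(self.syn_post, minlength=self.n).astype(int)
        deg += np.bincount(self.in_post, minlength=self.n)
        return deg


def build_network(cfg: LsmConfig, seed: int | None = None) -> LsmNetwork:
    """Sample a liquid with exact in-degrees and sign-constrained weights."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_exc + cfg.n_inh
    if cfg.n_exc < cfg.k_exc_in + 1 or cfg.n_inh < cfg.k_inh_in:
        raise ValueError("population too small for the configured in-degree")
    p = cfg.neuron
    exc_ids = np.arange(cfg.n_exc)
    inh_ids = np.arange(cfg.n_exc, n)

    pre, post, wts, cls = [], [], [], []
    for j in range(n):
        pool_e = exc_ids[exc_ids != j]
        pool_i = inh_ids[inh_ids != j]
        if pool_e.size < cfg.k_exc_in:
            pool_e = exc_ids
        if pool_i.size < cfg.k_inh_in:
            pool_i = inh_ids
        for i in rng.choice(pool_e, size=cfg.k_exc_in, replace=False):
            pre.append(i)
            post.append(j)
            mean, sd = cfg.w_ee if j < cfg.n_exc else cfg.w_ei
            wts.append(max(rng.normal(mean, sd), 0.0))
            cls.append("EE" if j < cfg.n_exc else "EI")
        for i in rng.choice(pool_i, size=cfg.k_inh_in, replace=False):
            pre.append(i)
            post.append(j)
            mean, sd = cfg.w_ie if j < cfg.n_exc else cfg.w_ii
            wts.append(min(rng.normal(mean, sd), 0.0))
            cls.append("IE" if j < cfg.n_exc else "II")
    pre = np.asarray(pre)
    post = np.asarray(post)
    wts = np.asarray(wts)
    cls = np.asarray(cls)
    delays = np.clip(
        rng.normal(*cfg.delay_dist, size=pre.size), *cfg.delay_clip
    )
    # STP parameters per connection class, jittered ±50 %
    U = np.empty(pre.size)
    t_rec = np.empty(pre.size)
    t_fac = np.empty(pre.size)
    for k in range(pre.size):
        u0, d0, f0 = STP_DEFAULTS[cls[k]]
        jit = rng.uniform(0.5, 1.5, size=3)
        U[k] = float(np.clip(u0 * jit[0], 1e-3, 1.0))
        t_rec[k] = max(d0 * jit[1], 1e-4)
        t_fac[k] = max(f0 * jit[2], 1e-4)

    in_chan = np.repeat(np.arange(cfg.n_inputs), cfg.input_fanout)
    in_post = np.concatenate(
        [
            rng.choice(cfg.n_exc, size=cfg.input_fanout, replace=False)
            for _ in range(cfg.n_inputs)
        ]
    )
    in_w = rng.uniform(*cfg.input_weight_range, size=in_chan.size)
    in_delay = np.clip(
        rng.normal(*cfg.delay_dist, size=in_chan.size), *cfg.delay_clip
    )
    noise_w = rng.normal(*cfg.w_noise, size=n)

    is_exc = np.zeros(n, dtype=bool)
    is_exc[: cfg.n_exc] = True
    return LsmNetwork(
        cfg=cfg,
        tau_m=np.full(n, p.tau_m),
        theta=np.full(n, p.theta),
        v_reset=np.full(n, p.v_reset),
        c_m=np.full(n, p.c_m),
        is_exc=is_exc,
        syn_pre=pre,
        syn_post=post,
        syn_w=wts,
        syn_delay=delays,
        syn_class=cls,
        syn_U=U,
        syn_tau_rec=t_rec,
        syn_tau_fac=t_fac,
        syn_static=False,
        in_chan=in_chan,
        in_post=in_post,
        in_w=in_w,
        in_delay=in_delay,
        noise_w=noise_w,
    )


@dataclass
class SimResult:
    spikes: list[np.ndarray]  # per-neuron spike times, s (relative to t_start)
    stp_u_trace: np.ndarray | None = None
    stp_x_trace: np.ndarray | None = None

    def mean_rate(self, duration: float, neurons=None) -> float:
        idx = range(len(self.spikes)) if neurons is None else neurons
        counts = [len(self.spikes[i]) for i in idx]
        return float(np.sum(counts) / (len(counts) * duration))


def simulate(
    net: LsmNetwork,
    input_events: list[np.ndarray],
    duration: float,
    rng: np.random.Generator | None = None,
    record_stp: bool = False,
) -> SimResult:
    """Fixed-step integration over ``duration`` seconds.

    ``input_events`` holds one array of event times (s, in [0, duration])
    per input channel.  Delays are rounded to the step grid.  Raises on
    non-finite state.
    """
    cfg = net.cfg
    p = cfg.neuron
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    dt = cfg.dt  # ms
    n_steps = int(round(duration * 1000.0 / dt))
    n = net.n

    if len(input_events) != cfg.n_inputs:
        raise ValueError(
            f"expected {cfg.n_inputs} input channels, got {len(input_events)}"
        )

    # schedule static input deliveries (event time + synaptic delay)
    arr_steps, arr_post, arr_w = [], [], []
    for k in range(net.in_chan.size):
        ev = input_events[net.in_chan[k]]
        if len(ev) == 0:
            continue
        steps = np.round(np.asarray(ev) * 1000.0 / dt + net.in_delay[k] / dt).astype(int)
        keep = (steps >= 0) & (steps < n_steps)
        arr_steps.append(steps[keep])
        arr_post.append(np.full(keep.sum(), net.in_post[k]))
        arr_w.append(np.full(keep.sum(), net.in_w[k] * cfg.scale_input))
    if arr_steps:
        arr_steps = np.concatenate(arr_steps)
        order = np.argsort(arr_steps, kind="stable")
        arr_steps = arr_steps[order]
        arr_post = np.concatenate(arr_post)[order]
        arr_w = np.concatenate(arr_w)[order]
    else:
        arr_steps = np.empty(0, int)
        arr_post = np.empty(0, int)
        arr_w = np.empty(0)

    # outgoing adjacency for recurrent synapses
    out_syn = [np.flatnonzero(net.syn_pre == i) for i in range(n)]
    delay_steps = np.maximum(np.round(net.syn_delay / dt).astype(int), 0)
    max_delay = int(delay_steps.max()) + 1 if delay_steps.size else 1
    buf_e = np.zeros((max_delay, n))
    buf_i = np.zeros((max_delay, n))

    # sign-constrained effective recurrent weights
    w_eff_base = np.where(
        net.syn_w >= 0, net.syn_w * cfg.scale_exc, net.syn_w * cfg.scale_inh
    )

    # STP state (event-driven): u, x, last presynaptic spike time (s)
    u = net.syn_U.copy()
    x = np.ones(net.syn_w.size)
    t_last = np.full(net.syn_w.size, -np.inf)

    decay_e = np.exp(-dt / p.tau_syn_e)
    decay_i = np.exp(-dt / p.tau_syn_i)
    i_e = np.zeros(n)
    i_i = np.zeros(n)
    if cfg.v_init == "uniform":
        v = rng.uniform(0.0, 1.0, n) * net.theta
    else:
        v = np.full(n, -70.0)
    ref = np.zeros(n, dtype=int)
    ref_steps = max(int(round(p.t_ref / dt)), 1)
    spikes: list[list[float]] = [[] for _ in range(n)]
    noise_p = cfg.noise_rate * dt / 1000.0
    noise_w = np.maximum(net.noise_w, 0.0)
    stp_u_rec, stp_x_rec = ([], []) if record_stp else (None, None)

    ptr = 0
    for step in range(n_steps):
        slot = step % max_delay
        # synaptic current decay + buffered deliveries
        i_e *= decay_e
        i_i *= decay_i
        i_e += buf_e[slot]
        i_i += buf_i[slot]
        buf_e[slot] = 0.0
        buf_i[slot] = 0.0
        # scheduled input deliveries at this step
        while ptr < arr_steps.size and arr_steps[ptr] == step:
            i_e[arr_post[ptr]] += arr_w[ptr]
            ptr += 1
        # background noise generators
        hits = rng.random(n) < noise_p
        if hits.any():
            i_e[hits] += noise_w[hits]
        # membrane integration (pA / pF = mV / ms)
        active = ref == 0
        dv = dt * (
            (p.v_rest - v) / net.tau_m + (i_e + i_i + p.i_const) / net.c_m
        )
        v = np.where(active, v + dv, v)
        ref = np.maximum(ref - 1, 0)
        fired = np.flatnonzero(active & (v >= net.theta))
        if fired.size:
            t_now = step * dt / 1000.0
            v[fired] = net.v_reset[fired]
            ref[fired] = ref_steps
            for j in fired:
                spikes[j].append(t_now)
                sidx = out_syn[j]
                if sidx.size == 0:
                    continue
                if net.syn_static:
                    w_del = w_eff_base[sidx]
                else:
                    dt_s = t_now - t_last[sidx]
                    first = ~np.isfinite(dt_s)
                    uu = np.where(
                        first,
                        net.syn_U[sidx],
                        net.syn_U[sidx]
                        + u[sidx] * (1.0 - net.syn_U[sidx])
                        * np.exp(-dt_s / net.syn_tau_fac[sidx]),
                    )
                    xx = np.where(
                        first, 1.0, 1.0 + (x[sidx] - 1.0) * np.exp(-dt_s / net.syn_tau_rec[sidx])
                    )
                    release = uu * xx
                    u[sidx] = uu
                    x[sidx] = xx * (1.0 - uu)
                    t_last[sidx] = t_now
                    w_del = w_eff_base[sidx] * release
                tgt_step = (step + np.maximum(delay_steps[sidx], 1)) % max_delay
                for kk, s_i in enumerate(sidx):
                    if w_del[kk] >= 0:
                        buf_e[tgt_step[kk], net.syn_post[s_i]] += w_del[kk]
                    else:
                        buf_i[tgt_step[kk], net.syn_post[s_i]] += w_del[kk]
        if record_stp:
            stp_u_rec.append(u.copy())
            stp_x_rec.append(x.copy())
        if not np.all(np.isfinite(v)):
            raise FloatingPointError(
                f"non-finite membrane potential at step {step}"
            )

    return SimResult(
        [np.asarray(s) for s in spikes],
        np.asarray(stp_u_rec) if record_stp else None,
        np.asarray(stp_x_rec) if record_stp else None,
    )


def readout_state(
    spikes: list[np.ndarray], readout_time: float, tau: float = 0.005,
    neurons: np.ndarray | None = None,
) -> np.ndarray:
    """Exponentially filtered spike-count state at ``readout_time`` (s)."""
    if readout_time < 0:
        raise ValueError("readout before span start")
    idx = np.arange(len(spikes)) if neurons is None else np.asarray(neurons)
    out = np.zeros(idx.size)
    for k, j in enumerate(idx):
        t = spikes[j]
        t = t[t <= readout_time]
        if len(t):
            out[k] = np.exp(-(readout_time - t) / tau).sum()
    return out


@dataclass(frozen=True)
class HardwareProfile:
    fan_in_max: int = 64
    mismatch_cv: float = 0.20
    mismatch_clip: float = 2.0  # in standard deviations


def apply_hardware_constraints(
    net: LsmNetwork, profile: HardwareProfile = HardwareProfile(), seed: int = 0
) -> LsmNetwork:
    """Emulate DYNAP-SE limits on a built liquid.

    Synapses are grouped into types by sign and synaptic time constant; each
    type shares one base magnitude (the median |w| of the type) and every
    original synapse becomes round(|w|/base) parallel unit connections.
    Fan-in above 64 per neuron is truncated by trimming the largest
    multiplicities first.  Delays are zeroed, dynamics become static, and
    per-neuron parameters are jittered by N(1, 0.2) clipped to [0.6, 1.4].
    """
    rng = np.random.default_rng(seed)
    # type key per synapse: recurrent E and input share the excitatory type
    rec_type = np.where(net.syn_w >= 0, 0, 1)
    bases = {}
    for t, wsel in ((0, np.abs(net.syn_w[rec_type == 0])), (1, np.abs(net.syn_w[rec_type == 1]))):
        wsel = wsel[wsel > 0]
        if wsel.size == 0:
            continue
        bases[t] = float(np.median(wsel))
    base_in = float(np.median(net.in_w[net.in_w > 0])) if np.any(net.in_w > 0) else None
    if (0 in bases and bases[0] == 0) or (1 in bases and bases[1] == 0):
        raise ValueError("zero base magnitude for a synapse type")

    mult = np.zeros(net.syn_w.size, dtype=int)
    for t, b in bases.items():
        sel = rec_type == t
        mult[sel] = np.round(np.abs(net.syn_w[sel]) / b).astype(int)
    in_mult = (
        np.round(net.in_w / base_in).astype(int)
        if base_in
        else np.zeros(net.in_w.size, dtype=int)
    )

    # enforce fan-in <= limit per postsynaptic neuron (recurrent + input)
    for j in range(net.n):
        rec_idx = np.flatnonzero(net.syn_post == j)
        in_idx = np.flatnonzero(net.in_post == j)
        total = mult[rec_idx].sum() + in_mult[in_idx].sum()
        while total > profile.fan_in_max:
            # trim the largest multiplicity first (deterministic)
            cands = [(mult[i], ("r", i)) for i in rec_idx] + [
                (in_mult[i], ("i", i)) for i in in_idx
            ]
            m, (kind, i) = max(cands)
            if m == 0:
                break
            if kind == "r":
                mult[i] -= 1
            else:
                in_mult[i] -= 1
            total -= 1

    new_w = np.where(
        rec_type == 0,
        mult * bases.get(0, 0.0),
        -mult * bases.get(1, 0.0),
    ).astype(float)
    new_in_w = in_mult * (base_in or 0.0)

    jitter = lambda arr: arr * np.clip(
        rng.normal(1.0, profile.mismatch_cv, arr.size),
        1.0 - profile.mismatch_clip * profile.mismatch_cv,
        1.0 + profile.mismatch_clip * profile.mismatch_cv,
    )
    out = LsmNetwork(
        cfg=net.cfg,
        tau_m=jitter(net.tau_m),
        theta=jitter(net.theta),
        v_reset=jitter(net.v_reset),
        c_m=jitter(net.c_m),
        is_exc=net.is_exc.copy(),
        syn_pre=net.syn_pre.copy(),
        syn_post=net.syn_post.copy(),
        syn_w=new_w,
        syn_delay=np.zeros_like(net.syn_delay),
        syn_class=net.syn_class.copy(),
        syn_U=net.syn_U.copy(),
        syn_tau_rec=net.syn_tau_rec.copy(),
        syn_tau_fac=net.syn_tau_fac.copy(),
        syn_static=True,
        in_chan=net.in_chan.copy(),
        in_post=net.in_post.copy(),
        in_w=new_in_w,
        in_delay=np.zeros_like(net.in_delay),
        noise_w=net.noise_w.copy(),
        hardware=True,
    )
    out._multiplicity = mult  # type: ignore[attr-defined]
    out._in_multiplicity = in_mult  # type: ignore[attr-defined]
    return out


def hardware_in_degree(net: LsmNetwork) -> np.ndarray:
    """Per-neuron connection count, counting quantized parallel connections."""
    mult = getattr(net, "_multiplicity", np.ones(net.syn_post.size, dtype=int))
    in_mult = getattr(net, "_in_multiplicity", np.ones(net.in_post.size, dtype=int))
    deg = np.bincount(net.syn_post, weights=mult, minlength=net.n)
    deg += np.bincount(net.in_post, weights=in_mult, minlength=net.n)
    return deg.astype(int)


def liquid_states_for_trials(
    net: LsmNetwork,
    trial_inputs: list[list[np.ndarray]],
    seed: int = 0,
) -> np.ndarray:
    """Simulate one trial window per input set and collect liquid states.

    Each entry of ``trial_inputs`` holds per-channel event times relative to
    the window start; the window spans warmup + readout_offset seconds and
    the state is read ``readout_offset`` after the (warmup-aligned) onset.
    """
    cfg = net.cfg
    duration = cfg.warmup + cfg.readout_offset + 0.005
    t_read = cfg.warmup + cfg.readout_offset
    exc = np.flatnonzero(net.is_exc)
    states = np.zeros((len(trial_inputs), exc.size))
    for k, events in enumerate(trial_inputs):
        rng = np.random.default_rng((seed * 100003 + k) % (2**31))
        res = simulate(net, events, duration, rng=rng)
        states[k] = readout_state(res.spikes, t_read, cfg.readout_tau, neurons=exc)
    return states
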