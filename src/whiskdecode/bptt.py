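"""Recurrent spiking network trained with surrogate-gradient BPTT.

Discrete-time LIF neurons (step 1 ms) follow

    V_j(t+dt) = alpha_j V_j(t) + (1 - alpha_j) R_m I_j(t),
    alpha_j = exp(-dt / tau_j),

with reset by threshold subtraction after a spike and a short refractory
period during which the spike output is clamped to zero.  The derivative of
a spike with respect to the normalized potential v_j = (V_j - b_j)/b_j is
replaced by the dampened pseudo-derivative gamma * max(0, 1 - |v_j|).

The network structure matches the liquid: sign-constrained sparse recurrent
connectivity (2 excitatory + 1 inhibitory in-connection per neuron) and
input channels fanning out to 4 excitatory targets.  A Deep-Rewiring-style
rule keeps the live-connection count fixed at that scheme during training:
weights are parameterized as sign * magnitude, a connection whose magnitude
is driven below zero becomes dormant and a fresh connection is resampled in
an allowed slot of the same category.  Readouts are three leaky integrator
units with a softmax over their values at the end of the input window;
training minimizes categorical cross-entropy plus an L1 weight penalty with
plain stochastic gradient descent whose learning rate is halved when
validation accuracy stalls for more than 10 epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GAMMA = 0.3
DT_MS = 1.0
TAU_MEM_MS = 20.0
R_M = 1.0  # membrane resistance folded into the weight units
B_THRESH = 0.01  # firing threshold b_j (volts)
REFRACTORY_MS = 2.0


def surrogate_grad(v: np.ndarray | float, gamma: float = GAMMA):
    """Pseudo-derivative of the spike: gamma * max(0, 1 - |v|)."""
    return gamma * np.maximum(0.0, 1.0 - np.abs(v))


def lif_step(v, i_in, alpha: float, b: float = B_THRESH, refractory=None):
    """One discrete LIF update; returns (v_next_after_reset, spike 0/1)."""
    v_next = alpha * v + (1.0 - alpha) * R_M * i_in
    can_fire = np.ones_like(v_next, dtype=bool) if refractory is None else (refractory == 0)
    z = ((v_next > b) & can_fire).astype(float)
    return v_next - b * z, z


@dataclass
class BpttConfig:
    n_in: int = 27
    n_exc: int = 100
    n_inh: int = 25
    k_exc_in: int = 2
    k_inh_in: int = 1
    input_fanout: int = 4
    n_out: int = 3
    window_ms: int = 50
    tau_mem: float = TAU_MEM_MS
    tau_out: float = 20.0
    b: float = B_THRESH
    gamma: float = GAMMA
    refractory_ms: float = REFRACTORY_MS
    epochs: int = 500
    lr: float = 0.05
    lr_halve_patience: int = 10
    batch_size: int = 32
    l1: float = 1e-5
    rewire_noise: float = 0.0  # sd of the SGD weight noise (rewiring temperature)
    init_scale: float = 0.04
    seed: int = 0

    @property
    def n_rec(self) -> int:
        return self.n_exc + self.n_inh


@dataclass
class BpttNetwork:
    """Sparse sign-constrained weights stored as connection lists."""

    cfg: BpttConfig
    # recurrent connections: sign fixed by presynaptic type, magnitude >= 0
    rec_pre: np.ndarray
    rec_post: np.ndarray
    rec_sign: np.ndarray
    rec_mag: np.ndarray
    # input connections (excitatory)
    in_chan: np.ndarray
    in_post: np.ndarray
    in_mag: np.ndarray
    w_out: np.ndarray  # (n_out, n_rec), unconstrained
    b_out: np.ndarray

    def live_counts(self) -> tuple[int, int]:
        return int(self.rec_mag.size), int(self.in_mag.size)

    def dense_weights(self) -> tuple[np.ndarray, np.ndarray]:
        cfg = self.cfg
        w_rec = np.zeros((cfg.n_rec, cfg.n_rec))
        np.add.at(w_rec, (self.rec_post, self.rec_pre), self.rec_sign * self.rec_mag)
        w_in = np.zeros((cfg.n_rec, cfg.n_in))
        np.add.at(w_in, (self.in_post, self.in_chan), self.in_mag)
        return w_rec, w_in


def build_bptt_network(cfg: BpttConfig, seed: int | None = None) -> BpttNetwork:
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    exc = np.arange(cfg.n_exc)
    inh = np.arange(cfg.n_exc, cfg.n_rec)
    pre, post, sign = [], [], []

    def pool(ids, j, k):
        p = ids[ids != j]  # self-connections only when the pool is too small
        return p if p.size >= k else ids

    for j in range(cfg.n_rec):
        for i in rng.choice(pool(exc, j, cfg.k_exc_in), cfg.k_exc_in, replace=False):
            pre.append(i), post.append(j), sign.append(1.0)
        for i in rng.choice(pool(inh, j, cfg.k_inh_in), cfg.k_inh_in, replace=False):
            pre.append(i), post.append(j), sign.append(-1.0)
    in_chan = np.repeat(np.arange(cfg.n_in), cfg.input_fanout)
    in_post = np.concatenate(
        [rng.choice(cfg.n_exc, cfg.input_fanout, replace=False) for _ in range(cfg.n_in)]
    )
    return BpttNetwork(
        cfg=cfg,
        rec_pre=np.asarray(pre),
        rec_post=np.asarray(post),
        rec_sign=np.asarray(sign),
        rec_mag=rng.uniform(0, cfg.init_scale, len(pre)),
        in_chan=in_chan,
        in_post=in_post,
        in_mag=rng.uniform(0, cfg.init_scale, in_chan.size),
        w_out=rng.normal(0, 0.1, (cfg.n_out, cfg.n_rec)),
        b_out=np.zeros(cfg.n_out),
    )


def _soft_spike(vnorm: np.ndarray, gamma: float) -> np.ndarray:
    """Antiderivative of the pseudo-derivative: a smooth stand-in for the spike.

    d(_soft_spike)/dv equals ``surrogate_grad`` exactly, which makes
    :func:`backward` the exact gradient of the soft forward pass — the basis
    of the finite-difference check of the BPTT implementation.
    """
    v = np.clip(vnorm, -1.0, 1.0)
    return gamma * (v - v * np.abs(v) / 2.0 + 0.5)


def forward(net: BpttNetwork, x: np.ndarray, record: bool = False,
            soft: bool = False):
    """Unrolled forward pass.

    ``x``: (batch, T, n_in) input spikes.  Returns (softmax probs, cache).
    With ``soft=True`` the hard spike is replaced by the smooth surrogate
    antiderivative and the refractory gate is disabled (gradient-check mode).
    """
    cfg = net.cfg
    w_rec, w_in = net.dense_weights()
    alpha = np.exp(-DT_MS / cfg.tau_mem)
    kappa = np.exp(-DT_MS / cfg.tau_out)
    batch, T, _ = x.shape
    v = np.zeros((batch, cfg.n_rec))
    z = np.zeros((batch, cfg.n_rec))
    refr = np.zeros((batch, cfg.n_rec), dtype=int)
    y = np.zeros((batch, cfg.n_out))
    ref_steps = int(round(cfg.refractory_ms / DT_MS))
    zs = np.zeros((T, batch, cfg.n_rec))
    vs = np.zeros((T, batch, cfg.n_rec))
    refr_mask = np.zeros((T, batch, cfg.n_rec), dtype=bool)
    for t in range(T):
        i_in = x[:, t] @ w_in.T + z @ w_rec.T
        v_pre = alpha * v + (1.0 - alpha) * R_M * i_in
        can = refr == 0
        if soft:
            z = _soft_spike((v_pre - cfg.b) / cfg.b, cfg.gamma)
        else:
            z = ((v_pre > cfg.b) & can).astype(float)
            refr = np.where(z > 0, ref_steps, np.maximum(refr - 1, 0))
        v = v_pre - cfg.b * z  # reset by subtracting the threshold
        zs[t], vs[t], refr_mask[t] = z, v_pre, can
        y = kappa * y + zs[t] @ net.w_out.T + net.b_out
    logits = y
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs = e / e.sum(axis=1, keepdims=True)
    cache = (x, zs, vs, refr_mask, w_rec, w_in, alpha, kappa) if record else None
    return probs, cache


def backward(net: BpttNetwork, probs: np.ndarray, targets: np.ndarray, cache):
    """Gradients of mean cross-entropy w.r.t. dense W_in, W_rec, W_out, b_out."""
    cfg = net.cfg
    x, zs, vs, refr_mask, w_rec, w_in, alpha, kappa = cache
    T, batch, n = zs.shape
    dlogits = probs.copy()
    dlogits[np.arange(batch), targets] -= 1.0
    dlogits /= batch
    g_wout = np.zeros_like(net.w_out)
    g_bout = np.zeros_like(net.b_out)
    g_wrec = np.zeros_like(w_rec)
    g_win = np.zeros_like(w_in)
    dv_pre_next = np.zeros((batch, n))  # dL/dV^pre_{t+1}
    dy = dlogits  # dL/dy_t, propagated backwards with factor kappa
    for t in range(T - 1, -1, -1):
        g_wout += dy.T @ zs[t]
        g_bout += dy.sum(axis=0)
        # dL/dz_t: readout now, next-step input current, and the reset term
        dv_post = alpha * dv_pre_next
        dz = dy @ net.w_out + (1.0 - alpha) * (dv_pre_next @ w_rec) - cfg.b * dv_post
        vnorm = (vs[t] - cfg.b) / cfg.b
        psi = np.where(refr_mask[t], surrogate_grad(vnorm, cfg.gamma), 0.0)
        dv_pre = dz * psi / cfg.b + dv_post
        z_prev = zs[t - 1] if t > 0 else np.zeros((batch, n))
        g_wrec += (1.0 - alpha) * dv_pre.T @ z_prev
        g_win += (1.0 - alpha) * dv_pre.T @ x[:, t]
        dv_pre_next = dv_pre
        dy = kappa * dy
    return g_win, g_wrec, g_wout, g_bout


def _rewire(net: BpttNetwork, rng: np.random.Generator) -> None:
    """Resample dormant connections so live counts match the scheme exactly."""
    cfg = net.cfg
    dead = np.flatnonzero(net.rec_mag < 0)
    for k in dead:
        j = net.rec_post[k]
        sgn = net.rec_sign[k]
        pool = (
            np.arange(cfg.n_exc) if sgn > 0 else np.arange(cfg.n_exc, cfg.n_rec)
        )
        same = (net.rec_post == j) & (net.rec_sign == sgn)
        taken = set(net.rec_pre[same]) | {j}
        free = [i for i in pool if i not in taken]
        if free:
            net.rec_pre[k] = rng.choice(free)
        net.rec_mag[k] = 0.0
    dead_in = np.flatnonzero(net.in_mag < 0)
    for k in dead_in:
        ch = net.in_chan[k]
        taken = set(net.in_post[net.in_chan == ch])
        free = [i for i in range(cfg.n_exc) if i not in taken]
        if free:
            net.in_post[k] = rng.choice(free)
        net.in_mag[k] = 0.0


def sgd_step(net: BpttNetwork, grads, lr: float, rng) -> None:
    g_win, g_wrec, g_wout, g_bout = grads
    cfg = net.cfg
    # gather dense gradients at live slots; signed parameterization w = s * m
    g_rec = net.rec_sign * g_wrec[net.rec_post, net.rec_pre]
    g_in = g_win[net.in_post, net.in_chan]
    noise = cfg.rewire_noise
    net.rec_mag -= lr * (g_rec + cfg.l1)
    net.in_mag -= lr * (g_in + cfg.l1)
    if noise > 0:
        net.rec_mag += rng.normal(0, noise * np.sqrt(lr), net.rec_mag.size)
        net.in_mag += rng.normal(0, noise * np.sqrt(lr), net.in_mag.size)
    net.w_out -= lr * g_wout
    net.b_out -= lr * g_bout
    _rewire(net, rng)


def train_bptt(
    x_train, y_train, x_val, y_val, cfg: BpttConfig, seed: int = 0
) -> tuple[BpttNetwork, "pd.DataFrame"]:
    """Train on spike tensors (n, T, n_in); returns (best network, log)."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    net = build_bptt_network(cfg, seed=seed)
    lr = cfg.lr
    best_val, best_state, stall = -1.0, None, 0
    log = []
    n = x_train.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            probs, cache = forward(net, x_train[idx], record=True)
            loss = -np.mean(
                np.log(probs[np.arange(idx.size), y_train[idx]] + 1e-12)
            )
            if not np.isfinite(loss):
                raise FloatingPointError(f"loss diverged at epoch {epoch}")
            grads = backward(net, probs, y_train[idx], cache)
            sgd_step(net, grads, lr, rng)
            losses.append(loss)
        val_acc = accuracy(net, x_val, y_val) if len(x_val) else np.nan
        log.append(
            {"epoch": epoch, "loss": float(np.mean(losses)), "val_acc": val_acc,
             "lr": lr}
        )
        if len(x_val):
            if val_acc > best_val:
                best_val, stall = val_acc, 0
                best_state = _snapshot(net)
            else:
                stall += 1
                if stall > cfg.lr_halve_patience:
                    lr /= 2.0
                    stall = 0
    if best_state is not None:
        _restore(net, best_state)
    return net, pd.DataFrame(log)


def _snapshot(net):
    return (
        net.rec_pre.copy(), net.rec_mag.copy(), net.in_post.copy(),
        net.in_mag.copy(), net.w_out.copy(), net.b_out.copy(),
    )


def _restore(net, s):
    net.rec_pre, net.rec_mag, net.in_post, net.in_mag, net.w_out, net.b_out = (
        a.copy() for a in s
    )


def accuracy(net: BpttNetwork, x, y) -> float:
    probs, _ = forward(net, x)
    return float(np.mean(np.argmax(probs, axis=1) == y))
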