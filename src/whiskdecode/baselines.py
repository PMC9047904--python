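"""Non-spiking comparison classifiers.

* FF — single-hidden-layer (80 ReLU units) network on the 50-sample 1 kHz
  LFP window, trained with L-BFGS (lr 0.001, 50 epochs) with L2 penalty
  1e-3 and early stopping on validation accuracy.
* LSTM — 64-unit LSTM fed the same window sequentially through one input
  neuron; SGD lr 0.1, momentum 0.9, batch 32, 250 epochs, early stopping.
* HC+RF — random forest (100 trees) on hand-crafted LFP features
  {RPA, PR, ROL, tLFP, window mean, window sd}.
* RF (MUA) — random forest on exponentially filtered spike trains
  (tau 16 ms, read out 30 ms after onset).
* Linear SVM — the LSM readout (one-vs-one hinge loss).

Weight initialization for FF and LSTM is U(-k, k) with k = 1/sqrt(fan_in)
(the 1/fan_in variant is available by flag); biases start at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC


# ---------------------------------------------------------------- inputs

def make_ff_inputs(trace: np.ndarray, fs: float, onset: float,
                   n_samples: int = 50) -> np.ndarray:
    """50 consecutive 1 kHz LFP samples from stimulus onset."""
    if abs(fs - 1000.0) > 1e-6:
        raise ValueError("FF inputs are defined on the 1 kHz LFP")
    i0 = int(round(onset * fs))
    if i0 + n_samples > trace.size:
        raise ValueError("window exceeds recording span")
    return trace[i0 : i0 + n_samples].astype(float)


class Standardizer:
    """Per-feature zero-mean/unit-sd scaling, fit on the training split only."""

    def fit(self, x: np.ndarray) -> "Standardizer":
        self.mean_ = x.mean(axis=0)
        sd = x.std(axis=0)
        self.sd_ = np.where(sd > 0, sd, 1.0)  # degenerate columns guarded
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean_) / self.sd_


def filtered_spike_features(
    spike_trains: list[np.ndarray], readout_time: float, tau: float = 0.016
) -> np.ndarray:
    """Exponentially filtered spike counts at ``readout_time`` per channel."""
    out = np.zeros(len(spike_trains))
    for k, t in enumerate(spike_trains):
        t = np.asarray(t)
        t = t[t <= readout_time]
        if t.size:
            out[k] = np.exp(-(readout_time - t) / tau).sum()
    return out


def init_uniform(rng, fan_in: int, shape, convention: str = "sqrt") -> np.ndarray:
    k = 1.0 / np.sqrt(fan_in) if convention == "sqrt" else 1.0 / fan_in
    return rng.uniform(-k, k, shape)


# ---------------------------------------------------------------- FF (L-BFGS)

@dataclass
class FFConfig:
    n_hidden: int = 80
    epochs: int = 50
    lr: float = 0.001
    l2: float = 0.001
    n_classes: int = 3
    init: str = "sqrt"


class FeedForwardClassifier:
    """One-hidden-layer ReLU network trained with L-BFGS and early stopping."""

    def __init__(self, cfg: FFConfig = FFConfig(), seed: int = 0):
        self.cfg = cfg
        self.seed = seed

    def _unpack(self, theta, d):
        c = self.cfg
        s = 0
        w1 = theta[s : s + d * c.n_hidden].reshape(c.n_hidden, d)
        s += d * c.n_hidden
        b1 = theta[s : s + c.n_hidden]
        s += c.n_hidden
        w2 = theta[s : s + c.n_hidden * c.n_classes].reshape(c.n_classes, c.n_hidden)
        s += c.n_hidden * c.n_classes
        b2 = theta[s:]
        return w1, b1, w2, b2

    def _loss_grad(self, theta, x, y):
        c = self.cfg
        w1, b1, w2, b2 = self._unpack(theta, x.shape[1])
        h_pre = x @ w1.T + b1
        h = np.maximum(h_pre, 0.0)
        logits = h @ w2.T + b2
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        p = e / e.sum(axis=1, keepdims=True)
        n = x.shape[0]
        loss = -np.mean(np.log(p[np.arange(n), y] + 1e-12))
        loss += c.l2 * (np.sum(w1**2) + np.sum(w2**2))
        dl = p.copy()
        dl[np.arange(n), y] -= 1.0
        dl /= n
        gw2 = dl.T @ h + 2 * c.l2 * w2
        gb2 = dl.sum(axis=0)
        dh = (dl @ w2) * (h_pre > 0)
        gw1 = dh.T @ x + 2 * c.l2 * w1
        gb1 = dh.sum(axis=0)
        return loss, np.concatenate([gw1.ravel(), gb1, gw2.ravel(), gb2])

    def fit(self, x, y, x_val=None, y_val=None):
        c = self.cfg
        rng = np.random.default_rng(self.seed)
        d = x.shape[1]
        theta = np.concatenate(
            [
                init_uniform(rng, d, (c.n_hidden, d), c.init).ravel(),
                np.zeros(c.n_hidden),
                init_uniform(rng, c.n_hidden, (c.n_classes, c.n_hidden), c.init).ravel(),
                np.zeros(c.n_classes),
            ]
        )
        best = (-1.0, theta.copy())
        track_val = x_val is not None and len(x_val)

        def cb(tk):
            nonlocal best
            if track_val:
                acc = self._acc(tk, x_val, y_val)
                if acc > best[0]:
                    best = (acc, tk.copy())

        res = minimize(
            self._loss_grad, theta, args=(x, y), jac=True, method="L-BFGS-B",
            callback=cb,
            options={"maxiter": c.epochs, "eps": c.lr, "maxls": 50},
        )
        self.theta_ = best[1] if (track_val and best[0] >= 0) else res.x
        if track_val and self._acc(res.x, x_val, y_val) > best[0]:
            self.theta_ = res.x
        self.d_ = d
        return self

    def _acc(self, theta, x, y):
        w1, b1, w2, b2 = self._unpack(theta, x.shape[1])
        h = np.maximum(x @ w1.T + b1, 0.0)
        pred = np.argmax(h @ w2.T + b2, axis=1)
        return float(np.mean(pred == y))

    def predict(self, x):
        w1, b1, w2, b2 = self._unpack(self.theta_, x.shape[1])
        h = np.maximum(x @ w1.T + b1, 0.0)
        return np.argmax(h @ w2.T + b2, axis=1)

    def score(self, x, y):
        return float(np.mean(self.predict(x) == y))


# ---------------------------------------------------------------- LSTM (SGD)

@dataclass
class LstmConfig:
    n_units: int = 64
    n_in: int = 1
    n_classes: int = 3
    epochs: int = 250
    lr: float = 0.1
    momentum: float = 0.9
    batch_size: int = 32
    init: str = "sqrt"


class LstmClassifier:
    """Single-layer LSTM with a softmax on the final hidden state.

    Manual forward/backward (BPTT); plain SGD with momentum, early stopping
    on validation accuracy.
    """

    def __init__(self, cfg: LstmConfig = LstmConfig(), seed: int = 0):
        self.cfg = cfg
        self.seed = seed

    def _init_params(self, rng):
        c = self.cfg
        d = c.n_in + c.n_units
        p = {}
        for g in ("i", "f", "o", "g"):
            p["W" + g] = init_uniform(rng, d, (c.n_units, d), c.init)
            p["b" + g] = np.zeros(c.n_units)
        p["bf"] += 1.0  # forget-gate bias init keeps early memory open
        p["Wy"] = init_uniform(rng, c.n_units, (c.n_classes, c.n_units), c.init)
        p["by"] = np.zeros(c.n_classes)
        return p

    @staticmethod
    def _sigmoid(x):
        return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))

    def _forward(self, p, x):
        c = self.cfg
        batch, T, _ = x.shape
        h = np.zeros((batch, c.n_units))
        cc = np.zeros((batch, c.n_units))
        cache = []
        for t in range(T):
            z = np.concatenate([x[:, t], h], axis=1)
            i = self._sigmoid(z @ p["Wi"].T + p["bi"])
            f = self._sigmoid(z @ p["Wf"].T + p["bf"])
            o = self._sigmoid(z @ p["Wo"].T + p["bo"])
            g = np.tanh(z @ p["Wg"].T + p["bg"])
            cc_new = f * cc + i * g
            h_new = o * np.tanh(cc_new)
            cache.append((z, i, f, o, g, cc, cc_new))
            h, cc = h_new, cc_new
        logits = h @ p["Wy"].T + p["by"]
        return logits, h, cache

    def _loss_grads(self, p, x, y):
        c = self.cfg
        logits, h, cache = self._forward(p, x)
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs = e / e.sum(axis=1, keepdims=True)
        n = x.shape[0]
        loss = -np.mean(np.log(probs[np.arange(n), y] + 1e-12))
        dl = probs
        dl[np.arange(n), y] -= 1.0
        dl /= n
        g = {k: np.zeros_like(v) for k, v in p.items()}
        g["Wy"] = dl.T @ h
        g["by"] = dl.sum(axis=0)
        dh = dl @ p["Wy"]
        dc = np.zeros((n, c.n_units))
        for t in range(len(cache) - 1, -1, -1):
            z, i, f, o, gt, c_prev, c_new = cache[t]
            tanh_c = np.tanh(c_new)
            do = dh * tanh_c
            dc = dc + dh * o * (1 - tanh_c**2)
            di = dc * gt
            df = dc * c_prev
            dg = dc * i
            d_zi = di * i * (1 - i)
            d_zf = df * f * (1 - f)
            d_zo = do * o * (1 - o)
            d_zg = dg * (1 - gt**2)
            for name, dz_ in (("i", d_zi), ("f", d_zf), ("o", d_zo), ("g", d_zg)):
                g["W" + name] += dz_.T @ z
                g["b" + name] += dz_.sum(axis=0)
            dz_total = (
                d_zi @ p["Wi"] + d_zf @ p["Wf"] + d_zo @ p["Wo"] + d_zg @ p["Wg"]
            )
            dh = dz_total[:, c.n_in :]
            dc = dc * f
        return loss, g

    def fit(self, x, y, x_val=None, y_val=None):
        c = self.cfg
        rng = np.random.default_rng(self.seed)
        p = self._init_params(rng)
        vel = {k: np.zeros_like(v) for k, v in p.items()}
        best = (-1.0, {k: v.copy() for k, v in p.items()})
        n = x.shape[0]
        for _ in range(c.epochs):
            order = rng.permutation(n)
            for s in range(0, n, c.batch_size):
                idx = order[s : s + c.batch_size]
                loss, grads = self._loss_grads(p, x[idx], y[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError("LSTM loss diverged")
                for k in p:
                    vel[k] = c.momentum * vel[k] - c.lr * grads[k]
                    p[k] = p[k] + vel[k]
            if x_val is not None and len(x_val):
                acc = self._acc(p, x_val, y_val)
                if acc > best[0]:
                    best = (acc, {k: v.copy() for k, v in p.items()})
        self.p_ = best[1] if best[0] >= 0 else p
        return self

    def _acc(self, p, x, y):
        logits, _, _ = self._forward(p, x)
        return float(np.mean(np.argmax(logits, axis=1) == y))

    def predict(self, x):
        logits, _, _ = self._forward(self.p_, x)
        return np.argmax(logits, axis=1)

    def score(self, x, y):
        return float(np.mean(self.predict(x) == y))


# ---------------------------------------------------------------- forests / SVM

RF_GRID = {
    "max_features": ["sqrt", None],
    "min_samples_split": [2, 4],
    "criterion": ["gini", "entropy"],
}


def make_random_forest(seed: int = 0, **params) -> RandomForestClassifier:
    return RandomForestClassifier(n_estimators=100, random_state=seed, **params)


def make_linear_svm(C: float = 1.0, seed: int = 0) -> SVC:
    """One-vs-one linear-kernel SVM used as the LSM readout."""
    return SVC(kernel="linear", C=C, decision_function_shape="ovo",
               random_state=seed)
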