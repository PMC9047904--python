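"""Evaluation protocol: repeated stratified splits, grid search, breakdowns.

Every classifier is scored with the same protocol: 20 independent runs (the
count is configurable), each with a fresh 80/20 train/test split (20 % of
the training part held out for validation), a grid search selecting the
hyperparameters with the best validation accuracy, and a single test
evaluation; the reported figure is the mean ± sd of the per-run test
accuracies.  Splits are stratified by stimulus class so that the ~185-trial
scale never produces an empty class in a split (a flag restores plain
random splits).  State- and layer-conditioned variants split the test set
by UP/DOWN label or repeat the full LFP pipeline per cortical layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd

from . import liquid
from .baselines import make_linear_svm
from .encoding import EncoderConfig, encode

CLASS_ORDER = ("large", "medium", "small")


@dataclass(frozen=True)
class EvalProtocol:
    test_fraction: float = 0.20
    val_fraction: float = 0.20  # of the training part
    n_runs: int = 20
    stratified: bool = True
    seed: int = 0


def encode_labels(amp_classes) -> np.ndarray:
    lut = {c: i for i, c in enumerate(CLASS_ORDER)}
    return np.asarray([lut[c] for c in amp_classes])


def stratified_split(y: np.ndarray, test_fraction: float, rng,
                     stratified: bool = True):
    n = y.size
    if not stratified:
        idx = rng.permutation(n)
        n_test = max(int(round(test_fraction * n)), 1)
        return idx[n_test:], idx[:n_test]
    train, test = [], []
    for c in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == c))
        n_test = max(int(round(test_fraction * idx.size)), 1)
        test.append(idx[:n_test])
        train.append(idx[n_test:])
    return (
        rng.permutation(np.concatenate(train)),
        rng.permutation(np.concatenate(test)),
    )


def three_way_split(y, protocol: EvalProtocol, rng):
    trainval, test = stratified_split(y, protocol.test_fraction, rng,
                                      protocol.stratified)
    rel_train, rel_val = stratified_split(
        y[trainval], protocol.val_fraction, rng, protocol.stratified
    )
    return trainval[rel_train], trainval[rel_val], test


@dataclass
class RunResult:
    run: int
    test_acc: float
    best_params: dict
    test_idx: np.ndarray
    predictions: np.ndarray


def summarize(runs: list[RunResult], classifier: str, signal: str,
              condition: str = "all",
              condition_labels: np.ndarray | None = None) -> pd.DataFrame:
    """ResultTable rows (accuracy in %, sd over runs)."""
    rows = []
    accs = [r.test_acc for r in runs]
    rows.append(
        {
            "classifier": classifier, "signal": signal, "condition": condition,
            "mean_accuracy_pct": 100 * float(np.mean(accs)),
            "sd_pct": 100 * float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
            "n_runs": len(accs),
        }
    )
    if condition_labels is not None:
        for lab in ("UP", "DOWN"):
            sub_accs, n_used = [], 0
            for r in runs:
                sel = condition_labels[r.test_idx] == lab
                if sel.sum() == 0:
                    continue
                truth = r.predictions[sel, 1]
                pred = r.predictions[sel, 0]
                sub_accs.append(float(np.mean(pred == truth)))
                n_used += 1
            rows.append(
                {
                    "classifier": classifier, "signal": signal,
                    "condition": f"{lab}-test",
                    "mean_accuracy_pct": (
                        100 * float(np.mean(sub_accs)) if sub_accs else np.nan
                    ),
                    "sd_pct": (
                        100 * float(np.std(sub_accs, ddof=1))
                        if len(sub_accs) > 1 else 0.0
                    ),
                    "n_runs": n_used,
                }
            )
    return pd.DataFrame(rows)


def run_protocol(
    x: np.ndarray,
    y: np.ndarray,
    model_factory,
    protocol: EvalProtocol = EvalProtocol(),
    grid: dict | None = None,
) -> list[RunResult]:
    """Matrix-classifier protocol.

    ``model_factory(seed, **params)`` must return an object with
    ``fit(x, y, x_val, y_val)`` and ``predict(x)``.  Grid search picks the
    parameter combination with the best validation accuracy per run.
    """
    results = []
    for run in range(protocol.n_runs):
        rng = np.random.default_rng(protocol.seed * 7919 + run)
        tr, va, te = three_way_split(y, protocol, rng)
        run_seed = int(rng.integers(2**31))
        combos = (
            [dict(zip(grid, vals)) for vals in product(*grid.values())]
            if grid
            else [{}]
        )
        best = (-1.0, None, None)
        for params in combos:
            model = model_factory(run_seed, **params)
            model.fit(x[tr], y[tr], x[va], y[va])
            val_acc = float(np.mean(model.predict(x[va]) == y[va]))
            if val_acc > best[0]:
                best = (val_acc, model, params)
        _, model, params = best
        pred = model.predict(x[te])
        results.append(
            RunResult(
                run, float(np.mean(pred == y[te])), params, te,
                np.column_stack([pred, y[te]]),
            )
        )
    return results


# ---------------------------------------------------------------- LSM protocol

@dataclass
class LsmGrid:
    scale_input: tuple = (1.0,)
    scale_exc: tuple = (1.0,)
    scale_inh: tuple = (1.0,)
    svm_c: tuple = (0.1, 1.0, 10.0)


def lsm_run_protocol(
    trial_builder,
    y: np.ndarray,
    cfg: liquid.LsmConfig,
    protocol: EvalProtocol = EvalProtocol(),
    grid: LsmGrid = LsmGrid(),
    hardware: bool = False,
) -> list[RunResult]:
    """Full LSM protocol with per-run network resampling.

    ``trial_builder(train_idx)`` returns per-trial input event lists for all
    trials, with anything fit on data (e.g. encoder thresholds) derived from
    the given training indices only.
    """
    results = []
    scale_combos = list(product(grid.scale_input, grid.scale_exc, grid.scale_inh))
    for run in range(protocol.n_runs):
        rng = np.random.default_rng(protocol.seed * 7919 + run)
        tr, va, te = three_way_split(y, protocol, rng)
        net_seed = int(rng.integers(2**31))
        trials = trial_builder(tr)
        best = (-1.0, None, None)
        for s_in, s_e, s_i in scale_combos:
            run_cfg = replace(cfg, scale_input=s_in, scale_exc=s_e, scale_inh=s_i)
            net = liquid.build_network(run_cfg, seed=net_seed)
            if hardware:
                net = liquid.apply_hardware_constraints(net, seed=net_seed + 1)
            states = liquid.liquid_states_for_trials(net, trials, seed=net_seed)
            for c in grid.svm_c:
                svm = make_linear_svm(C=c, seed=net_seed)
                svm.fit(states[tr], y[tr])
                val_acc = float(svm.score(states[va], y[va]))
                if val_acc > best[0]:
                    best = (
                        val_acc, (states, c),
                        {"scales": (s_in, s_e, s_i), "C": c},
                    )
        _, (states, c), params = best
        svm = make_linear_svm(C=c, seed=net_seed)
        svm.fit(states[tr], y[tr])
        pred = svm.predict(states[te])
        results.append(
            RunResult(
                run, float(np.mean(pred == y[te])), params, te,
                np.column_stack([pred, y[te]]),
            )
        )
    return results


def mua_trial_builder(raster, stim: pd.DataFrame, cfg: liquid.LsmConfig):
    """Per-trial MUA inputs: spike times per channel in the trial window."""
    onsets = stim["onset"].to_numpy(float)
    n_ch = cfg.n_inputs
    windows = []
    for onset in onsets:
        t0 = onset - cfg.warmup
        t1 = onset + cfg.readout_offset + 0.005
        chans = []
        for ch in range(n_ch):
            sp = raster.spikes.get(ch, np.empty(0))
            chans.append(sp[(sp >= t0) & (sp < t1)] - t0)
        windows.append(chans)
    return lambda train_idx: windows


def lfp_trial_builder(trace: np.ndarray, fs: float, stim: pd.DataFrame,
                      cfg: liquid.LsmConfig, n_thresh: int = 50):
    """Threshold-encoded layer-mean-LFP inputs; encoder range from train split."""
    onsets = stim["onset"].to_numpy(float)
    n0 = int(round(cfg.warmup * fs))
    n1 = int(round((cfg.readout_offset + 0.005) * fs))
    slices = []
    for onset in onsets:
        i = int(round(onset * fs))
        lo, hi = i - n0, i + n1
        if lo < 0 or hi > trace.size:
            raise ValueError("trial window exceeds the recording span")
        slices.append(trace[lo:hi])

    def build(train_idx):
        enc = EncoderConfig(n_thresh=n_thresh).fit_range(
            [slices[i] for i in train_idx]
        )
        return [encode(s, enc, fs).events for s in slices]

    return build


def state_conditioned_eval(
    runs: list[RunResult], state_labels: np.ndarray, classifier: str,
    signal: str,
) -> pd.DataFrame:
    """UP-test / DOWN-test accuracy rows from completed protocol runs."""
    table = summarize(runs, classifier, signal,
                      condition_labels=np.asarray(state_labels))
    return table[table.condition.str.endswith("-test")].reset_index(drop=True)


def layer_conditioned_eval(
    lfp_sig,
    stim: pd.DataFrame,
    cfg: liquid.LsmConfig,
    protocol: EvalProtocol = EvalProtocol(),
    grid: LsmGrid = LsmGrid(),
    n_thresh: int = 50,
    layers=("II", "III", "IV", "Va", "Vb", "VI"),
) -> pd.DataFrame:
    """Repeat the LSM-LFP pipeline with each layer's mean LFP as input."""
    from .features import layer_mean_lfp

    y = encode_labels(stim["amp_class"])
    rows = []
    for layer in layers:
        trace = layer_mean_lfp(lfp_sig, layer)
        builder = lfp_trial_builder(trace, lfp_sig.fs, stim, cfg, n_thresh)
        runs = lsm_run_protocol(builder, y, cfg, protocol, grid)
        rows.append(
            summarize(runs, "lsm", "lfp", condition=f"layer-{layer}")
        )
    return pd.concat(rows, ignore_index=True)


def psth(
    trial_spikes: list[list[np.ndarray]],
    window: tuple[float, float],
    bin_s: float = 0.004,
) -> np.ndarray:
    """Trial-averaged binned spike counts aligned to stimulus onset.

    ``trial_spikes[trial][channel]`` holds onset-relative spike times.
    Returns (channels, bins) mean counts per trial.
    """
    t0, t1 = window
    edges = np.arange(t0, t1 + bin_s / 2, bin_s)
    if not trial_spikes:
        return np.zeros((0, max(edges.size - 1, 0)))
    n_ch = len(trial_spikes[0])
    out = np.zeros((n_ch, edges.size - 1))
    for trial in trial_spikes:
        for ch in range(n_ch):
            h, _ = np.histogram(trial[ch], bins=edges)
            out[ch] += h
    return out / len(trial_spikes)
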