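"""Evaluation protocol: splits, repeated runs, conditioned metrics, PSTH."""

import numpy as np
import pandas as pd
import pytest

from whiskdecode.evaluation import (
    EvalProtocol,
    encode_labels,
    psth,
    run_protocol,
    state_conditioned_eval,
    stratified_split,
    summarize,
    three_way_split,
)


class _PerfectModel:
    def __init__(self, seed, **kw):
        pass

    def fit(self, x, y, xv=None, yv=None):
        self.lut = {tuple(r): t for r, t in zip(x, y)}
        return self

    def predict(self, x):
        return np.array([self.lut.get(tuple(r), 0) for r in x])


class _RandomModel:
    def __init__(self, seed, **kw):
        self.rng = np.random.default_rng(seed)

    def fit(self, x, y, xv=None, yv=None):
        return self

    def predict(self, x):
        return self.rng.integers(0, 3, len(x))


def _toy_xy(rng, n_per=20):
    y = np.repeat([0, 1, 2], n_per)
    x = rng.normal(size=(y.size, 4)) + y[:, None]
    return x, y


class TestSplits:
    def test_partition_and_stratification(self, rng):
        y = np.repeat([0, 1, 2], [20, 22, 20])
        tr, te = stratified_split(y, 0.2, rng)
        assert sorted(np.concatenate([tr, te])) == list(range(62))
        for c in (0, 1, 2):
            assert np.sum(y[te] == c) >= 1

    def test_three_way_no_overlap(self, rng):
        y = np.repeat([0, 1, 2], 20)
        tr, va, te = three_way_split(y, EvalProtocol(), rng)
        all_idx = np.concatenate([tr, va, te])
        assert len(set(all_idx)) == 60


class TestRunProtocol:
    def test_perfect_classifier_scores_100(self, rng):
        x, y = _toy_xy(rng)
        # lookup-based stub: memorizes every trial it has seen
        class Oracle(_PerfectModel):
            def fit(self, xx, yy, xv=None, yv=None):
                return self

            def predict(self, xx):
                return np.array([all_y[tuple(r)] for r in xx])

        all_y = {tuple(r): t for r, t in zip(x, y)}
        runs = run_protocol(x, y, Oracle, EvalProtocol(n_runs=4))
        table = summarize(runs, "stub", "toy")
        assert table.mean_accuracy_pct.iloc[0] == 100.0
        assert table.sd_pct.iloc[0] == 0.0

    def test_random_classifier_near_chance(self, rng):
        x, y = _toy_xy(rng, n_per=25)
        runs = run_protocol(x, y, _RandomModel, EvalProtocol(n_runs=25, seed=3))
        accs = np.array([r.test_acc for r in runs])
        n_test = len(runs[0].test_idx)
        se = np.sqrt((1 / 3) * (2 / 3) / n_test) / np.sqrt(len(runs))
        assert abs(accs.mean() - 1 / 3) < 4 * se
        # per-run spread consistent with binomial(n_test, 1/3)
        assert accs.std() < 3 * np.sqrt((1 / 3) * (2 / 3) / n_test)

    def test_deterministic_under_master_seed(self, rng):
        x, y = _toy_xy(rng)
        r1 = run_protocol(x, y, _RandomModel, EvalProtocol(n_runs=3, seed=9))
        r2 = run_protocol(x, y, _RandomModel, EvalProtocol(n_runs=3, seed=9))
        assert [r.test_acc for r in r1] == [r.test_acc for r in r2]
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a.test_idx, b.test_idx)


class TestConditioned:
    def test_state_rows_from_runs(self, rng):
        x, y = _toy_xy(rng)
        states = np.array(["UP", "DOWN"] * 30)
        runs = run_protocol(x, y, _RandomModel, EvalProtocol(n_runs=4))
        table = state_conditioned_eval(runs, states, "stub", "toy")
        assert set(table.condition) == {"UP-test", "DOWN-test"}

    def test_degenerate_all_up_reports_missing_down(self, rng):
        x, y = _toy_xy(rng)
        states = np.array(["UP"] * 60)
        runs = run_protocol(x, y, _RandomModel, EvalProtocol(n_runs=3))
        table = state_conditioned_eval(runs, states, "stub", "toy")
        down = table[table.condition == "DOWN-test"].iloc[0]
        assert down.n_runs == 0 and np.isnan(down.mean_accuracy_pct)


class TestPsth:
    def test_single_spike_lands_in_its_bin(self):
        trials = [[np.array([0.010])] for _ in range(7)]
        m = psth(trials, window=(0.0, 0.1), bin_s=0.004)
        assert m.shape == (1, 25)
        hot = np.flatnonzero(m[0])
        assert hot.tolist() == [2]  # bin [0.008, 0.012)
        assert m[0, 2] == pytest.approx(1.0)

    def test_empty_data_zero_matrix(self):
        assert psth([], window=(0, 0.1)).size == 0

    def test_mass_conservation(self, rng):
        trials = [
            [np.sort(rng.uniform(0, 0.1, 5)) for _ in range(3)]
            for _ in range(11)
        ]
        m = psth(trials, window=(0.0, 0.1), bin_s=0.004)
        mean_count = np.mean(
            [[len(t[ch]) for ch in range(3)] for t in trials], axis=0
        )
        np.testing.assert_allclose(m.sum(axis=1), mean_count)


def test_encode_labels_order():
    y = encode_labels(["small", "large", "medium", "large"])
    np.testing.assert_array_equal(y, [2, 0, 1, 0])


class TestLsmProtocolPaths:
    def test_mua_protocol_deterministic_and_bounded(self, small_session,
                                                    small_raster):
        from whiskdecode import liquid
        from whiskdecode.evaluation import (
            LsmGrid, lsm_run_protocol, mua_trial_builder,
        )

        _, rec, stim, _ = small_session
        cfg = liquid.mua_lsm_config(n_exc=40, n_inh=10, warmup=0.3)
        builder = mua_trial_builder(small_raster, stim, cfg)
        y = encode_labels(stim["amp_class"])
        proto = EvalProtocol(n_runs=1, seed=4)
        grid = LsmGrid(svm_c=(1.0,))
        r1 = lsm_run_protocol(builder, y, cfg, proto, grid)
        r2 = lsm_run_protocol(builder, y, cfg, proto, grid)
        assert r1[0].test_acc == r2[0].test_acc
        assert 0.0 <= r1[0].test_acc <= 1.0

    def test_hardware_variant_runs(self, small_session, small_raster):
        from whiskdecode import liquid
        from whiskdecode.evaluation import (
            LsmGrid, lsm_run_protocol, mua_trial_builder,
        )

        _, rec, stim, _ = small_session
        cfg = liquid.mua_lsm_config(n_exc=40, n_inh=10, warmup=0.3)
        builder = mua_trial_builder(small_raster, stim, cfg)
        y = encode_labels(stim["amp_class"])
        runs = lsm_run_protocol(
            builder, y, cfg, EvalProtocol(n_runs=1, seed=5),
            LsmGrid(svm_c=(1.0,)), hardware=True,
        )
        assert 0.0 <= runs[0].test_acc <= 1.0

    def test_layer_conditioned_lfp_pipeline(self, small_session):
        import whiskdecode as wd
        from whiskdecode import liquid
        from whiskdecode.evaluation import LsmGrid, layer_conditioned_eval

        _, rec, stim, _ = small_session
        lfp = wd.preprocess.bandpass(rec, "LFP", target_fs=1000.0)
        n_thresh = 8
        cfg = liquid.lfp_lsm_config(
            n_exc=40, n_inh=10, n_inputs=2 * n_thresh, warmup=0.3,
        )
        table = layer_conditioned_eval(
            lfp, stim, cfg, EvalProtocol(n_runs=1, seed=6),
            LsmGrid(svm_c=(1.0,)), n_thresh=n_thresh, layers=("IV", "VI"),
        )
        assert list(table.condition) == ["layer-IV", "layer-VI"]
        assert table.mean_accuracy_pct.between(0, 100).all()
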