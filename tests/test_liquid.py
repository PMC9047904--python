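"""Liquid state machine: wiring, LIF dynamics, STP, readout, hardware limits."""

import numpy as np
import pytest

from whiskdecode import liquid
from whiskdecode.liquid import (
    HardwareProfile,
    apply_hardware_constraints,
    build_network,
    hardware_in_degree,
    lfp_lsm_config,
    mua_lsm_config,
    readout_state,
    simulate,
)


class TestBuildNetwork:
    def test_mua_network_size_and_synapse_count(self):
        net = build_network(mua_lsm_config(), seed=0)
        assert net.n == 125
        assert net.syn_pre.size == 125 * 3  # in-degree 2 E + 1 I per neuron

    def test_lfp_network_size(self):
        net = build_network(lfp_lsm_config(), seed=0)
        assert net.n == 410
        assert net.in_chan.max() == 99  # 100 encoded input channels

    def test_in_degree_exact(self):
        net = build_network(mua_lsm_config(), seed=1)
        for j in range(net.n):
            pre = net.syn_pre[net.syn_post == j]
            assert np.sum(net.is_exc[pre]) == 2
            assert np.sum(~net.is_exc[pre]) == 1

    def test_delays_clipped(self):
        net = build_network(mua_lsm_config(), seed=2)
        assert net.syn_delay.min() >= 3.0
        assert net.syn_delay.max() <= 200.0

    def test_dale_sign_constraints(self):
        net = build_network(mua_lsm_config(), seed=3)
        exc_syn = net.is_exc[net.syn_pre]
        assert np.all(net.syn_w[exc_syn] >= 0)
        assert np.all(net.syn_w[~exc_syn] <= 0)

    def test_input_fanout_four_excitatory_targets(self):
        net = build_network(mua_lsm_config(), seed=4)
        for ch in range(27):
            targets = net.in_post[net.in_chan == ch]
            assert targets.size == 4
            assert np.all(net.is_exc[targets])

    def test_same_seed_identical(self):
        a = build_network(mua_lsm_config(), seed=5)
        b = build_network(mua_lsm_config(), seed=5)
        np.testing.assert_array_equal(a.syn_w, b.syn_w)
        np.testing.assert_array_equal(a.syn_delay, b.syn_delay)
        np.testing.assert_array_equal(a.in_post, b.in_post)


class TestSimulate:
    def test_constant_current_steady_state_below_threshold(self):
        # R = tau_m / C_m = 1 GOhm; V_inf = R * I_const = 7 mV < theta = 15 mV
        cfg = mua_lsm_config(noise_rate=0.0)
        net = build_network(cfg, seed=0)
        res = simulate(net, [np.empty(0)] * 27, 0.5)
        assert sum(len(s) for s in res.spikes) == 0

    def test_strong_input_spike_fires_target_once(self):
        cfg = mua_lsm_config(noise_rate=0.0, input_weight_range=(5e4, 5e4 + 1))
        net = build_network(cfg, seed=1)
        # silence recurrence so only the direct input acts
        net.syn_w[:] = 0.0
        res = simulate(net, [np.array([0.05])] + [np.empty(0)] * 26, 0.12)
        targets = net.in_post[net.in_chan == 0]
        for j in targets:
            assert len(res.spikes[j]) >= 1
        fired = {j for j in range(net.n) if len(res.spikes[j])}
        assert fired == set(targets.tolist())

    def test_refractoriness(self, rng):
        cfg = mua_lsm_config()
        net = build_network(cfg, seed=2)
        events = [np.sort(rng.uniform(0, 0.5, 30)) for _ in range(27)]
        res = simulate(net, events, 0.5)
        t_ref_s = cfg.neuron.t_ref / 1000.0
        for s in res.spikes:
            if len(s) > 1:
                assert np.min(np.diff(s)) >= t_ref_s - 1e-9

    def test_stp_state_bounds(self, rng):
        cfg = mua_lsm_config()
        net = build_network(cfg, seed=3)
        events = [np.sort(rng.uniform(0, 0.3, 40)) for _ in range(27)]
        res = simulate(net, events, 0.3, record_stp=True)
        assert np.all(res.stp_u_trace >= 0) and np.all(res.stp_u_trace <= 1)
        assert np.all(res.stp_x_trace >= 0) and np.all(res.stp_x_trace <= 1)

    def test_wrong_channel_count_rejected(self):
        net = build_network(mua_lsm_config(), seed=0)
        with pytest.raises(ValueError, match="input channels"):
            simulate(net, [np.empty(0)] * 5, 0.1)


class TestReadout:
    def test_kernel_values(self):
        spikes = [np.array([0.100]), np.array([0.095]), np.empty(0)]
        state = readout_state(spikes, 0.100, tau=0.005)
        assert state[0] == pytest.approx(1.0)  # spike exactly at readout
        assert state[1] == pytest.approx(np.exp(-1.0))  # 5 ms before, tau 5 ms
        assert state[2] == 0.0  # silent neuron

    def test_matches_bruteforce_kernel_sum(self, rng):
        spikes = [np.sort(rng.uniform(0, 1.0, rng.integers(0, 20)))
                  for _ in range(30)]
        t_read, tau = 0.9, 0.005
        state = readout_state(spikes, t_read, tau)
        for j, s in enumerate(spikes):
            expected = sum(np.exp(-(t_read - t) / tau) for t in s if t <= t_read)
            assert state[j] == pytest.approx(expected)

    def test_future_spikes_ignored(self):
        state = readout_state([np.array([0.5])], 0.4, tau=0.005)
        assert state[0] == 0.0

    def test_negative_readout_time_rejected(self):
        with pytest.raises(ValueError):
            readout_state([np.empty(0)], -0.1)


class TestHardwareConstraints:
    def test_mismatch_clipped_at_two_sigma(self):
        cfg = mua_lsm_config()
        net = build_network(cfg, seed=0)
        net.tau_m[:] = 20.0
        hw = apply_hardware_constraints(net, seed=1)
        # CV 20 % of 20 ms = 4 ms sd, clipped to [12, 28] ms
        assert hw.tau_m.min() >= 12.0 - 1e-9
        assert hw.tau_m.max() <= 28.0 + 1e-9
        assert hw.tau_m.std() > 1.0  # jitter actually applied

    @pytest.mark.parametrize("seed", range(10))
    def test_invariants_on_random_networks(self, seed):
        rng = np.random.default_rng(seed)
        cfg = mua_lsm_config(
            n_exc=int(rng.integers(20, 60)),
            n_inh=int(rng.integers(8, 20)),
            n_inputs=int(rng.integers(5, 27)),
        )
        net = build_network(cfg, seed=seed)
        hw = apply_hardware_constraints(net, seed=seed + 100)
        assert hardware_in_degree(hw).max() <= 64
        assert np.all(hw.syn_delay == 0.0) and np.all(hw.in_delay == 0.0)
        # shared magnitudes: at most one unit magnitude per synapse type
        mags = set()
        for w in (hw.syn_w[hw.syn_w > 0], -hw.syn_w[hw.syn_w < 0],
                  hw.in_w[hw.in_w > 0]):
            if w.size:
                mult = getattr(hw, "_multiplicity", None)
                # every weight is an integer multiple of the type base
                base = np.min(w)
                ratio = w / base
                np.testing.assert_allclose(ratio, np.round(ratio), atol=1e-9)
        # Dale signs preserved
        exc_syn = hw.is_exc[hw.syn_pre]
        assert np.all(hw.syn_w[exc_syn] >= 0)
        assert np.all(hw.syn_w[~exc_syn] <= 0)

    def test_weight_equal_to_base_gives_one_connection(self):
        net = build_network(mua_lsm_config(), seed=7)
        base = float(np.median(np.abs(net.syn_w[net.syn_w > 0])))
        k = int(np.flatnonzero(net.syn_w > 0)[0])
        net.syn_w[k] = base
        hw = apply_hardware_constraints(net, seed=8)
        assert hw._multiplicity[k] == 1

    def test_simulation_runs_with_hardware_net(self, rng):
        net = build_network(mua_lsm_config(), seed=9)
        hw = apply_hardware_constraints(net, seed=10)
        events = [np.sort(rng.uniform(0, 0.2, 5)) for _ in range(27)]
        res = simulate(hw, events, 0.2)
        assert isinstance(res.spikes, list)
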