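"""Evoked LFP and MUA feature extraction."""

import numpy as np
import pandas as pd
import pytest

from whiskdecode.features import (
    layer_mean_lfp,
    lfp_features_for_trial,
    mua_features,
    positive_rebound,
    response_onset_latency,
    response_peak_amplitude,
    time_normalized_lfp,
)
from whiskdecode.preprocess import BandSignal, MuaEvent

FS = 2500.0


def _trace_with_template(onset_s=1.0, onset_lat_ms=8.0, depth=-120.0,
                         rebound=40.0, total_s=2.0):
    """Baseline-zero trace with a planted alpha-shaped deflection."""
    n = int(total_s * FS)
    t = np.arange(n) / FS
    s = np.clip(t - onset_s - onset_lat_ms / 1000.0, 0, None)
    tau = 0.017
    tr = depth * (s / tau) * np.exp(1 - s / tau) * (s > 0)
    sp = np.clip(s - 0.045, 0, None)
    tr += rebound * (sp / 0.03) * np.exp(1 - sp / 0.03) * (sp > 0)
    return tr


class TestROL:
    def test_flat_trace_has_no_onset(self):
        rol = response_onset_latency(np.zeros(int(2 * FS)), FS, 1.0, 0.5)
        assert np.isnan(rol)

    def test_threshold_formula(self, rng):
        # baseline derivative ~ N(0, sigma): threshold = mean + 3 sigma;
        # a post-onset slope just below it must not trigger, above must
        sigma_uv_ms = 2.0
        dt_ms = 1000.0 / FS
        n_bas = int(1.0 * FS)
        # central-difference derivative of a random walk averages two steps;
        # the sqrt(2) factor makes its sd come out at sigma_uv_ms
        steps = rng.normal(0.0, sigma_uv_ms * dt_ms * np.sqrt(2), n_bas)
        trace = np.concatenate([np.cumsum(steps), np.zeros(int(0.5 * FS))])
        onset = n_bas / FS
        i0 = int(onset * FS)
        deriv = np.gradient(trace[:i0]) / dt_ms
        thr = deriv.mean() + 3 * deriv.std()
        assert thr == pytest.approx(6.0, rel=0.15)  # ~ mean 0 + 3 * 2 µV/ms
        # plant a ramp crossing the threshold at 5 ms post-onset
        ramp = np.zeros(trace.size)
        j = i0 + int(0.005 * FS)
        ramp[j:] = (2.5 * thr) * dt_ms * np.arange(trace.size - j)
        rol = response_onset_latency(trace + ramp, FS, onset, 1.0)
        assert rol == pytest.approx(5.0, abs=2 * dt_ms)

    def test_planted_onset_recovered(self):
        tr = _trace_with_template(onset_lat_ms=8.0)
        rol = response_onset_latency(tr, FS, 1.0, baseline_window=0.9)
        assert rol == pytest.approx(8.0, abs=1000.0 / FS + 0.4)


class TestRPA:
    def test_onset_to_trough_drop(self):
        tr = _trace_with_template(depth=-120.0, rebound=0.0)
        rol = response_onset_latency(tr, FS, 1.0, 0.9)
        rp, rpa, pk_t = response_peak_amplitude(tr, FS, 1.0, rol)
        assert rp == pytest.approx(-120.0, rel=0.01)
        assert rpa == pytest.approx(120.0, rel=0.02)  # trace(ROL) ~ 0

    def test_constant_trace_zero_amplitude(self):
        tr = np.full(int(2 * FS), 5.0)
        rp, rpa, _ = response_peak_amplitude(tr, FS, 1.0, rol_ms=3.0)
        assert rp == 5.0 and rpa == 0.0

    def test_missing_rol_propagates(self):
        rp, rpa, pk = response_peak_amplitude(np.zeros(100), FS, 0.0, np.nan)
        assert np.isnan(rpa)


class TestPR:
    def test_planted_rebound_recovered(self):
        # piecewise-linear response: trough -120 µV at 25 ms, rebound peak
        # exactly +40 µV at 80 ms post-onset
        n = int(2 * FS)
        t = np.arange(n) / FS
        knots_t = [0.0, 1.008, 1.025, 1.050, 1.080, 1.110, 2.0]
        knots_v = [0.0, 0.0, -120.0, 0.0, 40.0, 0.0, 0.0]
        tr = np.interp(t, knots_t, knots_v)
        pr = positive_rebound(tr, FS, peak_time=1.025)
        assert pr == pytest.approx(40.0, rel=0.01)

    def test_all_negative_window_absent(self):
        tr = -np.ones(int(2 * FS))
        assert np.isnan(positive_rebound(tr, FS, 1.0))

    def test_monotone_decreasing_absent(self):
        tr = -np.linspace(0, 100, int(2 * FS))
        assert np.isnan(positive_rebound(tr, FS, 1.0))


class TestTLFP:
    def test_triangle_closed_form(self):
        # triangular dip of depth d over base RD: AUC = d*RD/2 -> tLFP = d/2
        d, rd_s = 100.0, 0.080
        n = int(2 * FS)
        tr = np.zeros(n)
        i0 = int(1.0 * FS)
        half = int(rd_s * FS / 2)
        tr[i0 : i0 + half] = -d * np.arange(half) / half
        tr[i0 + half : i0 + 2 * half] = -d * (1 - np.arange(half) / half)
        peak_time = (i0 + half) / FS
        tlfp = time_normalized_lfp(tr, FS, 1.0, 0.0, peak_time)
        assert tlfp == pytest.approx(d / 2, rel=0.03)

    def test_zero_trace_gives_zero(self):
        tlfp = time_normalized_lfp(np.zeros(int(2 * FS)), FS, 1.0, 0.0, 1.02)
        assert tlfp == 0.0

    def test_scales_linearly(self):
        tr = _trace_with_template()
        f1 = lfp_features_for_trial(tr, FS, 1.0, 0.9)
        f2 = lfp_features_for_trial(2 * tr, FS, 1.0, 0.9)
        assert f2["tLFP"] == pytest.approx(2 * f1["tLFP"], rel=0.01)
        assert f2["RPA"] == pytest.approx(2 * f1["RPA"], rel=0.01)
        # ROL is amplitude-invariant on noise-free templates
        assert f2["ROL"] == pytest.approx(f1["ROL"], abs=1000.0 / FS)


class TestMuaFeatures:
    def test_arithmetic_from_definitions(self):
        ev = [MuaEvent("IV", 1.012, 1.026, 3)]
        f = mua_features(ev, onset=1.0)
        assert f["latency"] == pytest.approx(12.0)
        assert f["duration"] == pytest.approx(14.0)
        assert f["rate"] == pytest.approx(3 / 0.014, rel=1e-6)

    def test_no_event_in_window_missing(self):
        f = mua_features([MuaEvent("IV", 1.500, 1.51, 2)], onset=1.0)
        assert np.isnan(f["latency"])

    def test_single_spike_event_rate_missing(self):
        f = mua_features([MuaEvent("IV", 1.02, 1.02, 1)], onset=1.0)
        assert f["duration"] == 0.0
        assert np.isnan(f["rate"])


class TestLayerMean:
    def test_symmetric_channels_cancel(self):
        x = np.sin(np.linspace(0, 10, 1000))
        ch = pd.DataFrame(
            {"index": [0, 1], "layer": ["IV", "IV"], "in_cortex": [True, True]}
        ).set_index("index", drop=False)
        sig = BandSignal(np.stack([x, -x]), FS, "LFP", channels=ch)
        np.testing.assert_allclose(layer_mean_lfp(sig, "IV"), 0.0, atol=1e-12)

    def test_single_channel_identity(self):
        x = np.arange(100.0)
        ch = pd.DataFrame(
            {"index": [0], "layer": ["Va"], "in_cortex": [True]}
        ).set_index("index", drop=False)
        sig = BandSignal(x[None], FS, "LFP", channels=ch)
        np.testing.assert_array_equal(layer_mean_lfp(sig, "Va"), x)

    def test_unknown_layer_raises(self):
        ch = pd.DataFrame(
            {"index": [0], "layer": ["Va"], "in_cortex": [True]}
        ).set_index("index", drop=False)
        sig = BandSignal(np.zeros((1, 10)), FS, "LFP", channels=ch)
        with pytest.raises(ValueError):
            layer_mean_lfp(sig, "IX")

    def test_translation_invariance(self):
        # shifting the recording shifts timestamps but not feature values
        tr = _trace_with_template(onset_s=0.6, total_s=1.6)
        f1 = lfp_features_for_trial(tr, FS, 0.6, 0.5)
        tr2 = np.concatenate([np.zeros(int(0.4 * FS)), tr])
        f2 = lfp_features_for_trial(tr2, FS, 1.0, 0.5)
        for k in ("ROL", "RPA", "tLFP"):
            assert f2[k] == pytest.approx(f1[k], rel=0.01, abs=1e-9)
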