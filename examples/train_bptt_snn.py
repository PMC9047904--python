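"""Train a recurrent spiking network end-to-end with surrogate-gradient BPTT.

Threshold-crossing encoded layer-IV LFP (50 ms post-onset window, 1 kHz)
drives a sparse sign-constrained LIF network whose structure matches the
liquid; all weights are trained by backpropagation through time with the
dampened pseudo-derivative, and rewiring keeps the connection count fixed.
"""

import numpy as np

import whiskdecode as wd
from whiskdecode import bptt
from whiskdecode.encoding import EncoderConfig, encode
from whiskdecode.evaluation import encode_labels
from whiskdecode.features import layer_mean_lfp

cfg = wd.synth.desk_config(seed=9, n_per_class=15)
rec, stim_full = wd.synth.generate_recording(cfg)
stim, _ = wd.synth.split_truth(stim_full)
lfp = wd.preprocess.bandpass(rec, "LFP", target_fs=1000.0)
trace = layer_mean_lfp(lfp, "IV")

# threshold-encode the 50 ms post-onset window into spike tensors
n_thresh, T = 20, 50
slices = [
    trace[int(o * 1000): int(o * 1000) + T] for o in stim.onset
]
enc = EncoderConfig(n_thresh=n_thresh).fit_range(slices)
x = np.zeros((len(slices), T, 2 * n_thresh))
for k, s in enumerate(slices):
    for ch, ev in enumerate(encode(s, enc, 1000.0).events):
        x[k, (ev * 1000).astype(int), ch] = 1.0
y = encode_labels(stim.amp_class)

rng = np.random.default_rng(0)
idx = rng.permutation(len(y))
tr, va = idx[:33], idx[33:]
net_cfg = bptt.BpttConfig(
    n_in=2 * n_thresh, n_exc=40, n_inh=10, epochs=60, lr=0.3,
    batch_size=16, l1=1e-5,
)
net, log = bptt.train_bptt(x[tr], y[tr], x[va], y[va], net_cfg, seed=2)
print(log.tail(3).to_string(index=False))
print(f"train accuracy {bptt.accuracy(net, x[tr], y[tr]):.2f}, "
      f"held-out accuracy {bptt.accuracy(net, x[va], y[va]):.2f} "
      f"(chance 0.33)")
print(f"live connections {net.live_counts()} (fixed by the rewiring rule)")
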