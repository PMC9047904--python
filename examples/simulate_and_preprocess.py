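"""Generate a synthetic barrel-cortex session and extract spikes and bands.

Builds a small labeled recording (27 cortical channels, 3 stimulus
intensities), splits it into LFP (0.1-300 Hz) and spike (300-3000 Hz)
bands, and detects multi-unit spikes with the 3-sigma robust threshold.
"""

import numpy as np

import whiskdecode as wd

cfg = wd.synth.desk_config(seed=1, n_per_class=10)
rec, stim_full = wd.synth.generate_recording(cfg)
stim, truth = wd.synth.split_truth(stim_full)
print(f"session: {rec.samples.shape[0]} channels x {rec.duration:.1f} s "
      f"at {rec.fs:.0f} Hz, {len(stim)} stimuli")

lfp = wd.preprocess.bandpass(rec, "LFP", target_fs=2500.0)
spk = wd.preprocess.bandpass(rec, "SPIKE")
raster = wd.preprocess.detect_spikes(spk)
n_spikes = sum(len(v) for v in raster.spikes.values())
print(f"LFP band: {lfp.samples.shape[1]} samples at {lfp.fs:.0f} Hz per channel")
print(f"detected {n_spikes} spikes "
      f"(threshold = 3 x sigma_n, e.g. ch0: {raster.threshold[0]:.1f} uV)")

# each stimulus evokes an MUA burst within 100 ms; look at layer IV around
# the first stimulus (pooling the whole session merges everything into one
# event because spontaneous UP activity rarely pauses for 20 ms)
first = stim.onset.iloc[0]
iv_chans = rec.layer_channels("IV")
sp = raster.merged(iv_chans)
events = wd.preprocess.group_mua(sp[(sp > first) & (sp <= first + 0.15)])
e = events[0]
print(f"first stimulus at {first:.2f} s -> layer-IV evoked MUA latency "
      f"{(e.t1 - first) * 1000:.1f} ms, duration {e.duration * 1000:.1f} ms, "
      f"{e.n_spikes} spikes")
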