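"""Label stimuli as UP or DOWN from network-level firing dynamics.

The cumulative instantaneous firing rate (10 ms windows, 1 ms step, summed
over electrodes) is thresholded at its global mean; a stimulus counts as UP
when an UP epoch intersects the 50 ms window before its onset.  The
synthetic ground truth lets us score the labeling.
"""

import numpy as np

import whiskdecode as wd

cfg = wd.synth.desk_config(
    seed=7, n_per_class=15, up_mua_rate=80.0, down_mua_rate=0.2, noise_sd=2.0
)
rec, stim_full = wd.synth.generate_recording(cfg)
stim, truth = wd.synth.split_truth(stim_full)

raster = wd.preprocess.detect_spikes(wd.preprocess.bandpass(rec, "SPIKE"))
trace = wd.states.compute_ifr(raster)
print(f"cumulative IFR: mean (= threshold) {trace.threshold:.0f} Hz, "
      f"{len(trace.up_intervals)} UP intervals")

labeled = wd.states.label_stimuli(trace, stim)
counts = labeled.state.value_counts().to_dict()
agree = np.mean(labeled.state.to_numpy() == truth.truth_state.to_numpy())
print(f"labels: {counts}")
print(f"agreement with planted states: {100 * agree:.1f} %")
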