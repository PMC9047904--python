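"""Extract evoked-response features and build the significance grid.

Per trial and cortical layer: LFP onset latency (ROL), onset-to-trough
amplitude (RPA), positive rebound (PR) and time-normalized LFP (tLFP),
plus MUA latency/duration/rate.  Rank-based tests compare UP vs DOWN and
the three stimulus intensities per layer.
"""

import whiskdecode as wd
from whiskdecode.stats import build_sig_table

cfg = wd.synth.desk_config(seed=3, n_per_class=20)
rec, stim_full = wd.synth.generate_recording(cfg)
stim, truth = wd.synth.split_truth(stim_full)

lfp = wd.preprocess.bandpass(rec, "LFP", target_fs=2500.0)
raster = wd.preprocess.detect_spikes(wd.preprocess.bandpass(rec, "SPIKE"))
labeled = wd.states.label_stimuli(wd.states.compute_ifr(raster), stim)

lfp_feats, mua_feats = wd.features.extract_feature_table(
    lfp, raster, labeled, baseline_window=1.0
)
print("median layer-IV RPA (uV) by intensity:")
iv = lfp_feats[lfp_feats.layer == "IV"]
print(iv.groupby("amp_class").RPA.median().round(1).to_string())

grid = build_sig_table(lfp_feats[["layer", "amp_class", "state", "RPA"]],
                       feature_cols=["RPA"])
off = grid[grid.comparison.str.contains("-vs-") & (grid.layer == "IV")]
print("\nlayer-IV RPA intensity comparisons (Dunn, gated by Kruskal-Wallis):")
print(off[["comparison", "p", "stars", "direction"]].to_string(index=False))
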