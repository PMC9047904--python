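"""HDF5 / CSV containers for recordings, stimulus tables and derived signals."""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .synth import Recording


def save_recording(path, rec: Recording) -> None:
    """Write `/raw` (channels × samples, float32 µV, attr fs) and `/channels`."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("raw", data=rec.samples.astype(np.float32))
        d.attrs["fs"] = float(rec.fs)
        g = f.create_group("channels")
        g.create_dataset("index", data=rec.channels["index"].to_numpy(np.int64))
        g.create_dataset(
            "layer",
            data=np.array([s.encode() for s in rec.channels["layer"]]),
        )
        g.create_dataset("in_cortex", data=rec.channels["in_cortex"].to_numpy(bool))


def load_recording(path) -> Recording:
    with h5py.File(path, "r") as f:
        raw = f["raw"][...]
        fs = float(f["raw"].attrs["fs"])
        channels = pd.DataFrame(
            {
                "index": f["channels/index"][...],
                "layer": [b.decode() for b in f["channels/layer"][...]],
                "in_cortex": f["channels/in_cortex"][...],
            }
        ).set_index("index", drop=False)
    return Recording(raw, fs, channels)


def save_band(path, name: str, samples: np.ndarray, fs: float) -> None:
    """Append a filtered band (`/lfp` or `/spikeband`) to a recording file."""
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        d = f.create_dataset(name, data=samples.astype(np.float32))
        d.attrs["fs"] = float(fs)


def save_stimulus_table(path, stim: pd.DataFrame) -> None:
    stim.to_csv(path, index=False)


def load_stimulus_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_spikes_csv(path, raster) -> None:
    """Spike raster as long-form CSV (channel, time_s)."""
    rows = [
        (ch, t) for ch, times in raster.spikes.items() for t in times
    ]
    pd.DataFrame(rows, columns=["channel", "time_s"]).to_csv(path, index=False)
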