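"""Containers on disk: HDF5 session files, CSV tables, heatmap images.

A session container holds /spikes, /stimuli (x, y, side, onset,
duration, onset_phase) and /respiration (peaks, troughs, optional raw
trace), so simulated and recorded data flow through the identical
analysis path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .receptive_field_mapping import STIM_COLUMNS, Heatmap, Session
from .respiration_phase import PhaseMap, RespirationTrace

__all__ = [
    "save_session",
    "load_session",
    "save_trace_csv",
    "load_trace_csv",
    "phase_map_to_csv",
    "heatmap_to_csv",
    "heatmap_to_image",
]


def save_session(path, session: Session, trace: RespirationTrace = None):
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("spikes", data=session.spikes)
        g = f.create_group("stimuli")
        for col in STIM_COLUMNS:
            g.create_dataset(col, data=session.stimuli[col].to_numpy())
        r = f.create_group("respiration")
        r.create_dataset("peaks", data=session.phase_map.peaks)
        r.create_dataset("troughs", data=session.phase_map.troughs)
        if trace is not None:
            d = r.create_dataset("trace", data=trace.samples)
            d.attrs["sample_rate"] = trace.sample_rate
        f.attrs["field_width"] = session.field_size[0]
        f.attrs["field_height"] = session.field_size[1]
        f.attrs["pixel"] = session.pixel


def load_session(path) -> Session:
    import h5py

    with h5py.File(path, "r") as f:
        spikes = f["spikes"][...]
        stim = pd.DataFrame({c: f["stimuli"][c][...] for c in STIM_COLUMNS})
        pmap = PhaseMap(f["respiration/peaks"][...], f["respiration/troughs"][...])
        return Session(spikes, stim, pmap,
                       (float(f.attrs["field_width"]), float(f.attrs["field_height"])),
                       float(f.attrs["pixel"]))


def save_trace_csv(path, trace: RespirationTrace):
    pd.DataFrame({"sample": trace.samples}).to_csv(path, index=False)
    # sample_rate carried in a header comment for the single-column format
    with open(path) as fh:
        body = fh.read()
    with open(path, "w") as fh:
        fh.write(f"# sample_rate_hz={trace.sample_rate}\n{body}")


def load_trace_csv(path) -> RespirationTrace:
    with open(path) as fh:
        first = fh.readline()
    rate = 1000.0
    if first.startswith("# sample_rate_hz="):
        rate = float(first.split("=", 1)[1])
    df = pd.read_csv(path, comment="#")
    return RespirationTrace(df["sample"].to_numpy(), rate)


def phase_map_to_csv(path, pmap: PhaseMap):
    pmap.to_frame().to_csv(path, index=False)


def heatmap_to_csv(path, hmap: Heatmap):
    hmap.to_frame().to_csv(path, index=False)


def heatmap_to_image(path, hmap: Heatmap):
    """16-bit grayscale export (TIFF or PNG by extension); NaN maps to 0."""
    import tifffile
    from PIL import Image

    grid = np.nan_to_num(hmap.grid, nan=np.nanmin(hmap.grid[hmap.covered])
                         if hmap.covered.any() else 0.0)
    lo, hi = float(grid.min()), float(grid.max())
    scale = 65535.0 / (hi - lo) if hi > lo else 0.0
    img = ((grid - lo) * scale).astype(np.uint16)
    if str(path).endswith((".tif", ".tiff")):
        tifffile.imwrite(path, img)
    else:
        Image.fromarray(img, mode="I;16").save(path)
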