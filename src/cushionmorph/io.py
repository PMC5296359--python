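"""File round-trips for the pipeline's inputs and outputs.

Formats: label volumes as multi-page TIFF (uint16) with a JSON spacing
sidecar; cushion slices as multi-channel TIFF plus an annotation JSON of
named polylines in µm; diameter traces and PSM tables as CSV with
documented headers; channel maps as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .band_tightness import DiameterTrace
from .confocal import CushionSlice
from .morphometry import LabelVolume

__all__ = [
    "write_label_volume",
    "read_label_volume",
    "write_cushion_slice",
    "read_cushion_slice",
    "write_trace_csv",
    "read_trace_csv",
    "write_psm_csv",
    "read_psm_csv",
    "write_channel_map",
    "read_channel_map",
]


def write_label_volume(vol: LabelVolume, tiff_path, spacing_path=None) -> None:
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, vol.labels.astype(np.uint16))
    spacing_path = spacing_path or tiff_path.with_suffix(".json")
    Path(spacing_path).write_text(json.dumps({"spacing_um": list(vol.spacing)}))


def read_label_volume(tiff_path, spacing_path=None) -> LabelVolume:
    tiff_path = Path(tiff_path)
    labels = tifffile.imread(tiff_path)
    if labels.ndim == 2:
        labels = labels[None]
    spacing_path = spacing_path or tiff_path.with_suffix(".json")
    meta = json.loads(Path(spacing_path).read_text())
    return LabelVolume(labels=labels.astype(np.int64), spacing=tuple(meta["spacing_um"]))


def write_cushion_slice(slc: CushionSlice, tiff_path, ann_path=None) -> None:
    """Channels as a (C, H, W) TIFF; polylines and metadata as JSON."""
    tiff_path = Path(tiff_path)
    names = sorted(slc.channels)
    stack = np.stack([slc.channels[n] for n in names]).astype(np.float32)
    tifffile.imwrite(tiff_path, stack, photometric="minisblack")
    ann = {
        "channel_names": names,
        "pixel_size_um": slc.pixel_size,
        "cushion_label": slc.cushion_label,
        "embryo_id": slc.embryo_id,
        "slice_index": slc.slice_index,
        "lumen_edge_um": np.asarray(slc.lumen_edge).tolist(),
        "myocardium_edge_um": np.asarray(slc.myocardium_edge).tolist(),
    }
    ann_path = ann_path or tiff_path.with_suffix(".json")
    Path(ann_path).write_text(json.dumps(ann))


def read_cushion_slice(tiff_path, ann_path=None) -> CushionSlice:
    tiff_path = Path(tiff_path)
    stack = tifffile.imread(tiff_path)
    ann = json.loads(Path(ann_path or tiff_path.with_suffix(".json")).read_text())
    channels = {n: stack[i] for i, n in enumerate(ann["channel_names"])}
    return CushionSlice(
        channels=channels,
        pixel_size=float(ann["pixel_size_um"]),
        lumen_edge=np.asarray(ann["lumen_edge_um"], dtype=float),
        myocardium_edge=np.asarray(ann["myocardium_edge_um"], dtype=float),
        cushion_label=ann.get("cushion_label", ""),
        embryo_id=ann.get("embryo_id", ""),
        slice_index=int(ann.get("slice_index", 0)),
    )


def write_trace_csv(trace: DiameterTrace, path) -> None:
    pd.DataFrame(
        {"frame": np.arange(trace.diameters.size), "diameter_um": trace.diameters}
    ).to_csv(path, index=False)


def read_trace_csv(path, fps: float = 140.0) -> DiameterTrace:
    df = pd.read_csv(path)
    if "diameter_um" not in df.columns:
        raise ValueError("trace CSV must have a 'diameter_um' column")
    return DiameterTrace(df["diameter_um"].to_numpy(dtype=float), fps=fps)


def write_psm_csv(psms: pd.DataFrame, path) -> None:
    psms.to_csv(path, index=False)


def read_psm_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_channel_map(channel_map: dict, path) -> None:
    Path(path).write_text(json.dumps(channel_map, indent=2))


def read_channel_map(path) -> dict:
    return json.loads(Path(path).read_text())
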