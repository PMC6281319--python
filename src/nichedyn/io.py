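"""File I/O: track/status CSV, parameter JSON/YAML, TIFF stacks with voxel
metadata."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .simulate import SceneParameters

TRACK_COLUMNS = ["cell_id", "frame", "x_um", "y_um", "z_um"]


def read_tracks_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track CSV missing columns {missing}")
    return df


def write_tracks_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_params(path) -> SceneParameters:
    """Scene parameters from JSON or YAML."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return SceneParameters.from_dict(data)


def write_params(params: SceneParameters, path) -> None:
    path = Path(path)
    d = params.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def write_stack(volume: np.ndarray, path,
                voxel_size=(1.0, 1.0, 3.0)) -> None:
    """Write a (z, y, x) volume as an ImageJ-style TIFF with voxel size
    metadata (``voxel_size`` given as (dx, dy, dz) µm)."""
    dx, dy, dz = voxel_size
    vol = np.asarray(volume)
    if vol.dtype == bool:
        vol = vol.astype(np.uint8)
    if vol.dtype == np.float64:
        vol = vol.astype(np.float32)
    tifffile.imwrite(str(path), vol, imagej=True,
                     resolution=(1.0 / dx, 1.0 / dy),
                     metadata={"spacing": dz, "unit": "um", "axes": "ZYX"})


def read_stack(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a TIFF stack, returning the (z, y, x) volume and the
    (dx, dy, dz) voxel size recovered from metadata (1 µm where absent)."""
    with tifffile.TiffFile(str(path)) as tf:
        vol = tf.asarray()
        dx = dy = dz = 1.0
        page = tf.pages[0]
        res = page.tags.get("XResolution")
        if res is not None and res.value[0]:
            dx = res.value[1] / res.value[0]
        res = page.tags.get("YResolution")
        if res is not None and res.value[0]:
            dy = res.value[1] / res.value[0]
        if tf.imagej_metadata and "spacing" in tf.imagej_metadata:
            dz = float(tf.imagej_metadata["spacing"])
    return vol, (dx, dy, dz)
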