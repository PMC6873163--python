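"""TIFF stack and table I/O.

Stacks are plain multi-page TIFF with ImageJ-style voxel-size metadata
(x/y resolution tags plus z spacing, unit um); the grid spec in a config
overrides file metadata when both are present.  Axis order in every
array and table is (z, y, x).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .grid import VoxelGridSpec, VoxelChannel


def write_stack(channel: VoxelChannel, path: str | Path) -> None:
    """Write one channel as an ImageJ-compatible multi-page TIFF (um units)."""
    dz, dy, dx = channel.grid.voxel_size
    tifffile.imwrite(
        str(path),
        channel.data.astype(np.float32),
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
    )


def read_stack(
    path: str | Path,
    role: str = "puncta",
    grid_override: VoxelGridSpec | None = None,
) -> VoxelChannel:
    """Read a 3D TIFF stack into a channel.

    Voxel size comes from ImageJ metadata / resolution tags unless a
    grid override is supplied; a stack with neither is an error, as is a
    2D file.
    """
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        if data.ndim != 3:
            raise ValueError(f"expected a 3D stack, got ndim={data.ndim} in {path}")
        if grid_override is not None:
            if tuple(grid_override.shape) != data.shape:
                raise ValueError(
                    f"override grid shape {grid_override.shape} != data {data.shape}"
                )
            return VoxelChannel(data=data, grid=grid_override, role=role)
        voxel = _voxel_size_from_tiff(tf)
        if voxel is None:
            raise ValueError(
                f"{path} carries no voxel-size metadata; pass a grid override"
            )
    grid = VoxelGridSpec(shape=data.shape, voxel_size=voxel)
    return VoxelChannel(data=data, grid=grid, role=role)


def _voxel_size_from_tiff(tf: tifffile.TiffFile) -> tuple[float, float, float] | None:
    dz = dy = dx = None
    if tf.imagej_metadata:
        dz = tf.imagej_metadata.get("spacing")
    page = tf.pages[0]
    xres = page.tags.get("XResolution")
    yres = page.tags.get("YResolution")
    if xres is not None:
        num, den = xres.value
        if num:
            dx = den / num
    if yres is not None:
        num, den = yres.value
        if num:
            dy = den / num
    if dz is None or dy is None or dx is None:
        return None
    return (float(dz), float(dy), float(dx))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))
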