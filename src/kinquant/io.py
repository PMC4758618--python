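"""Stack, table and configuration I/O.

Stacks travel as multi-page TIFF (one page per z-slice, z-ascending, 16-bit
little-endian, ImageJ-style metadata carrying the voxel dimensions); tables
as CSV with fixed headers; run configurations as YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import DataError
from .simulate import DEFAULT_PIXEL_SIZE_UM, DEFAULT_Z_STEP_UM, VoxelGrid

CANDIDATE_COLUMNS = ["focus_id", "z", "y", "x", "peak_value"]
MEASUREMENT_COLUMNS = ["focus_id", "mean_kin", "mean_bg", "corrected",
                       "normalized", "reference", "genotype", "channel"]
SIZE_COLUMNS = ["focus_id", "fwhm_px", "fwhm_um", "peak_height", "converged",
                "fwhm_normalized", "peak_height_normalized"]


def write_stack(grid: VoxelGrid, path: str | Path) -> Path:
    """Write a quantized stack as multi-page TIFF, one z-slice per page."""
    path = Path(path)
    values = grid.values
    if not np.issubdtype(values.dtype, np.integer):
        values = np.clip(np.rint(values), 0, 2 ** grid.bit_depth - 1).astype(np.uint16)
    tifffile.imwrite(
        path, values, imagej=True,
        resolution=(1.0 / grid.dx, 1.0 / grid.dy),
        metadata={"spacing": grid.dz, "unit": "um", "axes": "ZYX",
                  "channel": grid.channel},
    )
    return path


def read_stack(path: str | Path, dx: float | None = None, dy: float | None = None,
               dz: float | None = None, channel: str | None = None) -> VoxelGrid:
    """Read a multi-page TIFF as a :class:`VoxelGrid`.

    Voxel dimensions are recovered from ImageJ metadata when present;
    explicit arguments override, and the package defaults fill any gap.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"stack not found: {path}")
    with tifffile.TiffFile(path) as tif:
        values = tif.asarray()
        meta = tif.imagej_metadata or {}
        res_dx = res_dy = None
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        if xres is not None and xres.value[0]:
            res_dx = xres.value[1] / xres.value[0]
        if yres is not None and yres.value[0]:
            res_dy = yres.value[1] / yres.value[0]
    if values.ndim == 2:
        values = values[None, :, :]
    if values.ndim != 3:
        raise DataError(f"{path}: expected a 2D/3D stack, got shape {values.shape}")
    return VoxelGrid(
        values,
        dx=dx if dx is not None else (res_dx or DEFAULT_PIXEL_SIZE_UM),
        dy=dy if dy is not None else (res_dy or DEFAULT_PIXEL_SIZE_UM),
        dz=dz if dz is not None else float(meta.get("spacing", DEFAULT_Z_STEP_UM)),
        channel=channel if channel is not None else str(meta.get("channel", "GFP")),
    )


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"table not found: {path}")
    return pd.read_csv(path)


def write_config(config_dict: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config_dict, fh, sort_keys=False)
    return path


def read_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise DataError(f"config not found: {path}")
    with open(path) as fh:
        return yaml.safe_load(fh)
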