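"""TIFF stack I/O.

Grids are z-major (z, y, x), voxel-indexed and 0-based everywhere; physical
spacing only enters distances and volumes and is supplied by the caller
(CLI flag or config), never inferred silently.  Integer stacks round-trip
bit-exactly; level-set fields are written as 32-bit float TIFF.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

__all__ = ["read_stack", "write_stack", "split_channels"]

_SUPPORTED = (np.uint8, np.uint16, np.float32, np.float64, np.int32)


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF as a z-major array.

    Accepts 8/16-bit unsigned and 32-bit float data, single- or
    two-channel (use :func:`split_channels` for the latter).
    """
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except (FileNotFoundError, OSError, ValueError) as exc:
        raise OSError(f"cannot read TIFF stack {path}: {exc}") from exc
    if arr.dtype.type not in _SUPPORTED:
        raise TypeError(f"unsupported dtype {arr.dtype} in {path}")
    if arr.ndim not in (3, 4):
        raise ValueError(f"expected a 3D (or two-channel 4D) stack in {path}, got shape {arr.shape}")
    return arr


def write_stack(grid: np.ndarray, path: str | Path) -> None:
    """Write a grid as multi-page TIFF; float64 is narrowed to float32."""
    grid = np.asarray(grid)
    if grid.dtype == np.float64:
        grid = grid.astype(np.float32)
    if grid.dtype == bool:
        grid = grid.astype(np.uint8)
    if grid.dtype.type not in _SUPPORTED:
        raise TypeError(f"unsupported dtype {grid.dtype} for {path}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, grid)


def split_channels(arr: np.ndarray):
    """Split a two-channel stack into two equal-shape z-major grids."""
    if arr.ndim != 4:
        raise ValueError(f"expected a 4D two-channel stack, got shape {arr.shape}")
    for axis in range(2):
        if arr.shape[axis] == 2:
            a, b = np.moveaxis(arr, axis, 0)
            return a, b
    if arr.shape[1] <= 4:  # (z, c, y, x) with few channels
        parts = np.moveaxis(arr, 1, 0)
        return parts[0], parts[1]
    raise ValueError(f"cannot locate the channel axis in shape {arr.shape}")
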