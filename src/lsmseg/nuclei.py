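"""Nuclei segmentation in a nuclear-reporter channel, plus volume statistics.

Each cell's level-set field is initialised on the eroded cell (d = 1) and
evolved in the edge map of the nuclear channel with the accelerating and
smoothing terms off, so the contour is free to seek the nucleus within the
initial cell contour.  In cells without nuclear signal the contour collapses
to a residual object of a few voxels, which is filtered out by size — the
cell's existence is still tracked through its parent label.  The nucleus
label equals its parent cell label, and every nucleus voxel is clipped to
its parent cell (hard containment).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cells import evolve_multi, init_from_labels, labels_from_lsfs
from .core import EvolutionParams
from .edges import IndicatorSpec, edge_map

__all__ = [
    "segment_nuclei",
    "filter_small",
    "measure_volumes",
    "nucleus_cell_stats",
]


def segment_nuclei(
    nuclear_channel: np.ndarray,
    cell_labels: np.ndarray,
    d: int = 1,
    spec: IndicatorSpec | None = None,
    params: EvolutionParams | None = None,
    spacing=(1.0, 1.0, 1.0),
    margin: int = 4,
) -> np.ndarray:
    """Segment one nucleus per cell; nucleus labels equal cell labels.

    Defaults: erosion d=1 for initialisation, alpha=0, beta=0, gamma=0.8,
    s=1, gradient indicator.  Returns a label grid; apply
    :func:`filter_small` to drop the residual objects of nucleus-free cells.
    """
    nuclear_channel = np.asarray(nuclear_channel, dtype=np.float64)
    cell_labels = np.asarray(cell_labels)
    if nuclear_channel.shape != cell_labels.shape:
        raise ValueError("nuclear channel and cell labels have different shapes")
    if spec is None:
        spec = IndicatorSpec(kind="g", gamma=0.8, s=1.0)
    if params is None:
        params = EvolutionParams(alpha=0.0, beta=0.0, max_iter=150)
    g = edge_map(nuclear_channel, spec, spacing)
    phis = init_from_labels(cell_labels, d=d, spacing=spacing, margin=margin)
    phis = evolve_multi(phis, g, params, spacing)
    nuclei = labels_from_lsfs(phis)
    nuclei[nuclei != cell_labels] = 0  # hard containment in the parent cell
    return nuclei


def filter_small(L: np.ndarray, min_voxels: int = 10):
    """Remove labels smaller than ``min_voxels``; report what was removed."""
    if min_voxels < 0:
        raise ValueError("min_voxels must be >= 0")
    L = np.asarray(L)
    out = L.copy()
    counts = np.bincount(L.ravel().astype(np.int64))
    removed = [
        int(k) for k in range(1, counts.size) if 0 < counts[k] < min_voxels
    ]
    if removed:
        out[np.isin(out, removed)] = 0
    return out, removed


def measure_volumes(L: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> pd.DataFrame:
    """Per-label voxel counts and physical volumes.

    Volume is ``voxel_count * sz*sy*sx`` in cubic micrometres when the
    spacing is given in micrometres.  Empty grid gives an empty table.
    """
    if any(s <= 0 for s in spacing):
        raise ValueError("voxel spacing must be positive")
    L = np.asarray(L)
    counts = np.bincount(L.ravel().astype(np.int64))
    labels = np.nonzero(counts)[0]
    labels = labels[labels > 0]
    voxel_volume = float(np.prod(spacing))
    return pd.DataFrame(
        {
            "label": labels.astype(int),
            "voxel_count": counts[labels].astype(int),
            "volume": counts[labels] * voxel_volume,
        }
    )


def nucleus_cell_stats(nuclei: pd.DataFrame, cells: pd.DataFrame) -> dict:
    """Summary statistics linking nuclei to their parent cells.

    Nucleus labels are their parent cell labels.  Returns means and standard
    deviations of cell and nucleus volume, of the per-cell nucleus:cell
    volume ratio, the Pearson correlation of (cell volume, nucleus volume)
    over cells with a detected nucleus, and the detected fraction.  With
    fewer than two linked pairs the correlation is undefined (None).
    """
    nuc = nuclei.copy()
    nuc["parent_cell"] = nuc["label"]
    merged = nuc.merge(cells, on="label", suffixes=("_nuc", "_cell"))
    if len(merged) != len(nuc):
        raise ValueError("some nuclei link to no existing cell label")
    n_cells = len(cells)
    stats = {
        "n_cells": int(n_cells),
        "n_nuclei": int(len(merged)),
        "detected_fraction": float(len(merged) / n_cells) if n_cells else float("nan"),
        "cell_volume_mean": float(cells["volume"].mean()) if n_cells else float("nan"),
        "cell_volume_sd": float(cells["volume"].std(ddof=1)) if n_cells > 1 else 0.0,
    }
    if len(merged):
        ratio = merged["volume_nuc"] / merged["volume_cell"]
        stats.update(
            nucleus_volume_mean=float(merged["volume_nuc"].mean()),
            nucleus_volume_sd=float(merged["volume_nuc"].std(ddof=1)) if len(merged) > 1 else 0.0,
            ratio_mean=float(ratio.mean()),
            ratio_sd=float(ratio.std(ddof=1)) if len(merged) > 1 else 0.0,
        )
    else:
        stats.update(
            nucleus_volume_mean=float("nan"),
            nucleus_volume_sd=float("nan"),
            ratio_mean=float("nan"),
            ratio_sd=float("nan"),
        )
    if len(merged) >= 2 and merged["volume_cell"].std() > 0 and merged["volume_nuc"].std() > 0:
        stats["pearson_r"] = float(
            np.corrcoef(merged["volume_cell"], merged["volume_nuc"])[0, 1]
        )
    else:
        stats["pearson_r"] = None
    return stats
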