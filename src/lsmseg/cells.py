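"""Per-cell level-set segmentation: one field per cell, shared edge map.

Each cell carries its own level-set function, initialised inside the cell
(from a seed or an eroded pre-segmentation) and evolved *independently* in
the common edge map — there is no coupling term, so the per-cell evolutions
are embarrassingly parallel and overlaps are resolved only when the fields
are rasterised to a label image.  Remaining unlabelled tissue voxels are
attributed to the nearest segmented object.

Fields are stored on padded bounding-box patches (`LevelSetPatch`): outside
its patch a cell's field is treated as far positive (exterior), which is
exact as long as the patch margin exceeds the contour's travel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import EvolutionParams, evolve
from .surface import signed_distance

__all__ = [
    "LevelSetPatch",
    "init_from_seeds",
    "init_from_labels",
    "evolve_multi",
    "labels_from_lsfs",
    "fill_unassigned_nearest",
    "seeds_from_label_grid",
]


@dataclass
class LevelSetPatch:
    """A level-set field restricted to a box within a larger grid."""

    label: int
    phi: np.ndarray
    origin: tuple
    full_shape: tuple

    @property
    def slices(self):
        return tuple(
            slice(o, o + n) for o, n in zip(self.origin, self.phi.shape)
        )

    def dense(self, fill: float = np.inf) -> np.ndarray:
        out = np.full(self.full_shape, fill)
        out[self.slices] = self.phi
        return out


def _ball(radius: float) -> np.ndarray:
    r = int(np.floor(radius))
    if r < 1:
        return np.ones((1, 1, 1), dtype=bool)
    zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return zz**2 + yy**2 + xx**2 <= radius**2


def _patch_from_mask(label, mask, full_shape, margin, spacing):
    """Signed-distance patch around ``mask`` (negative inside)."""
    idx = np.nonzero(mask)
    lo = [max(0, int(i.min()) - margin) for i in idx]
    hi = [min(n, int(i.max()) + margin + 1) for i, n in zip(idx, full_shape)]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    phi = signed_distance(mask[sl], spacing)
    return LevelSetPatch(label=int(label), phi=phi, origin=tuple(lo), full_shape=tuple(full_shape))


def init_from_seeds(seeds, shape, r0: float = 3.0, spacing=(1.0, 1.0, 1.0), margin=None):
    """One level-set field per seed: signed distance to the seed voxels
    dilated by ``r0`` (negative inside).  ``seeds`` is a list of
    ``(label, coords)`` with coords an (n, 3) array of z, y, x indices;
    fields are returned in ascending label order.
    """
    if r0 < 1:
        raise ValueError("r0 must be >= 1 voxel")
    shape = tuple(shape)
    out = []
    for label, coords in sorted(seeds, key=lambda t: t[0]):
        coords = np.atleast_2d(np.asarray(coords, dtype=np.intp))
        if coords.shape[1] != 3:
            raise ValueError("seed coordinates must be (n, 3)")
        if np.any(coords < 0) or np.any(coords >= np.array(shape)):
            raise ValueError(f"seed {label} has out-of-bounds voxels")
        m = margin if margin is not None else None
        pad = int(np.ceil(r0)) + (m if m is not None else 0)
        if m is None:
            # dense field over the whole grid
            mask = np.zeros(shape, dtype=bool)
            mask[tuple(coords.T)] = True
            d = ndimage.distance_transform_edt(~mask, sampling=spacing)
            phi = d - r0
            out.append(LevelSetPatch(int(label), phi, (0, 0, 0), shape))
        else:
            lo = [max(0, int(coords[:, ax].min()) - pad) for ax in range(3)]
            hi = [min(n, int(coords[:, ax].max()) + pad + 1) for ax, n in zip(range(3), shape)]
            sl = tuple(slice(a, b) for a, b in zip(lo, hi))
            mask = np.zeros(tuple(b - a for a, b in zip(lo, hi)), dtype=bool)
            mask[tuple((coords - np.array(lo)).T)] = True
            d = ndimage.distance_transform_edt(~mask, sampling=spacing)
            out.append(LevelSetPatch(int(label), d - r0, tuple(lo), shape))
    return out


def init_from_labels(L, d: int = 1, spacing=(1.0, 1.0, 1.0), margin: int = 8):
    """One level-set field per label of ``L``, initialised on the label
    eroded by a Euclidean ball of radius ``d``.

    A label whose erosion would vanish keeps its single deepest voxel
    (maximum of the internal distance transform, lowest-coordinate
    tie-break) so the cell is not dropped.
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    L = np.asarray(L)
    if not np.any(L > 0):
        raise ValueError("label grid contains no cells")
    ball = _ball(d) if d > 0 else None
    out = []
    objects = ndimage.find_objects(L)
    for label, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        pad = d + 1
        grown = tuple(
            slice(max(0, s.start - pad), min(n, s.stop + pad))
            for s, n in zip(sl, L.shape)
        )
        mask = L[grown] == label
        if d > 0:
            eroded = ndimage.binary_erosion(mask, structure=ball)
        else:
            eroded = mask
        if not eroded.any():
            dist = ndimage.distance_transform_edt(mask, sampling=spacing)
            deepest = np.unravel_index(int(np.argmax(dist)), mask.shape)
            eroded = np.zeros_like(mask)
            eroded[deepest] = True
        full_mask = np.zeros(L.shape, dtype=bool)
        full_mask[grown] = eroded
        out.append(_patch_from_mask(label, full_mask, L.shape, margin, spacing))
    return out


def evolve_multi(phis, g, params: EvolutionParams, spacing=(1.0, 1.0, 1.0)):
    """Evolve each cell's field independently in the shared edge map.

    With ``direction='outward'`` the accelerating term inflates each seed
    until its contour reaches the cell wall.  Output order matches input;
    each output depends only on its own input field, ``g`` and ``params``.
    """
    g = np.asarray(g, dtype=np.float64)
    out = []
    for p in phis:
        if p.full_shape != g.shape:
            raise ValueError("field grid does not match edge map shape")
        g_crop = g[p.slices]
        phi, _ = evolve(p.phi, g_crop, params, spacing, track_energy=False)
        out.append(LevelSetPatch(p.label, phi, p.origin, p.full_shape))
    return out


def labels_from_lsfs(phis) -> np.ndarray:
    """Rasterise per-cell fields to a label grid.

    A voxel takes the label whose field is most negative there; exact ties
    go to the lowest label; voxels where no field is negative stay 0.
    """
    if not phis:
        raise ValueError("no level-set fields to rasterise")
    shape = phis[0].full_shape
    for p in phis:
        if p.full_shape != shape:
            raise ValueError("inconsistent field shapes")
    best = np.full(shape, np.inf)
    lab = np.zeros(shape, dtype=np.int32)
    for p in sorted(phis, key=lambda q: q.label):
        sl = p.slices
        neg = (p.phi < 0) & (p.phi < best[sl])
        best_sl = best[sl]
        lab_sl = lab[sl]
        best_sl[neg] = p.phi[neg]
        lab_sl[neg] = p.label
        best[sl] = best_sl
        lab[sl] = lab_sl
    return lab


def fill_unassigned_nearest(L, domain_mask, spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Attribute every unlabelled domain voxel to the closest labelled object.

    Distance is Euclidean in physical units; exact distance ties go to the
    lowest label.  Already-assigned voxels are untouched.  Idempotent.
    """
    L = np.asarray(L)
    domain = np.asarray(domain_mask, dtype=bool)
    labels = np.unique(L[(L > 0)])
    if labels.size == 0 or not np.any((L > 0) & domain):
        raise ValueError("no labelled objects inside the domain")
    out = L.copy()
    target = domain & (L == 0)
    if not target.any():
        return out
    best = np.full(L.shape, np.inf)
    chosen = np.zeros(L.shape, dtype=L.dtype)
    for k in labels:  # ascending: strict '<' keeps the lowest label on ties
        dk = ndimage.distance_transform_edt(L != k, sampling=spacing)
        closer = target & (dk < best)
        best[closer] = dk[closer]
        chosen[closer] = k
    out[target] = chosen[target]
    return out


def seeds_from_label_grid(seed_grid) -> list:
    """Convert a labelled seed image to the (label, coords) list format."""
    seed_grid = np.asarray(seed_grid)
    out = []
    for label in np.unique(seed_grid[seed_grid > 0]):
        coords = np.argwhere(seed_grid == label)
        out.append((int(label), coords))
    return out
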