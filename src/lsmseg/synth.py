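"""Synthetic 3D confocal-like fixtures with exact ground truth.

The generators emulate the imaging pathologies of membrane-marker confocal
stacks of plant tissue that the segmentation pipelines must cope with:

* bright anticlinal (cell-cell) walls but dim outer periclinal walls
  (controlled by ``rho_outer``),
* brightness attenuation descending along the acquisition (z) axis
  (``atten_k``),
* deep narrow surface creases between organs with a bright halo inside
  (the folded-tissue fixture),
* an optional nuclear-reporter channel with one blurred blob per cell and
  a controllable nucleus:cell volume ratio distribution and correlation.

All randomness is driven by an explicit seed; a generator called twice with
the same arguments returns bit-identical fixtures.  Intensities are float64
in an 8-bit-like range [0, 255].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "SyntheticTissue",
    "make_shell_sphere",
    "make_foam",
    "make_folded_tissue",
    "add_nuclei_channel",
]

_CLIP_MAX = 255.0


@dataclass
class SyntheticTissue:
    """A generated stack plus its ground truth.

    ``truth_labels`` partitions the tissue interior (0 = exterior);
    ``truth_surface_mask`` marks the outermost interior voxel layer.
    ``params`` records every generator argument including the seed.
    """

    image: np.ndarray
    truth_labels: np.ndarray
    truth_surface_mask: np.ndarray
    params: dict = field(default_factory=dict)
    spacing: tuple = (1.0, 1.0, 1.0)
    nuclear_channel: np.ndarray | None = None
    truth_nuclei: np.ndarray | None = None

    def save(self, prefix: str | Path) -> None:
        """Write image/labels/surface (and nuclei channel) TIFFs + params JSON."""
        import tifffile

        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(f"{prefix}_image.tif", self.image.astype(np.float32))
        tifffile.imwrite(f"{prefix}_labels.tif", self.truth_labels.astype(np.uint16))
        tifffile.imwrite(
            f"{prefix}_surface.tif", self.truth_surface_mask.astype(np.uint8)
        )
        if self.nuclear_channel is not None:
            tifffile.imwrite(
                f"{prefix}_nuclei.tif", self.nuclear_channel.astype(np.float32)
            )
            tifffile.imwrite(
                f"{prefix}_nuclei_labels.tif", self.truth_nuclei.astype(np.uint16)
            )
        meta = dict(self.params)
        meta["spacing"] = list(self.spacing)
        with open(f"{prefix}_params.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True, default=float)

    @classmethod
    def load(cls, prefix: str | Path) -> "SyntheticTissue":
        import tifffile

        prefix = Path(prefix)
        with open(f"{prefix}_params.json") as fh:
            meta = json.load(fh)
        spacing = tuple(meta.pop("spacing"))
        nuc = nuc_lab = None
        if Path(f"{prefix}_nuclei.tif").exists():
            nuc = tifffile.imread(f"{prefix}_nuclei.tif").astype(np.float64)
            nuc_lab = tifffile.imread(f"{prefix}_nuclei_labels.tif").astype(np.int32)
        return cls(
            image=tifffile.imread(f"{prefix}_image.tif").astype(np.float64),
            truth_labels=tifffile.imread(f"{prefix}_labels.tif").astype(np.int32),
            truth_surface_mask=tifffile.imread(f"{prefix}_surface.tif").astype(bool),
            params=meta,
            spacing=spacing,
            nuclear_channel=nuc,
            truth_nuclei=nuc_lab,
        )


def _coord_grids(shape):
    return np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")


def _z_attenuation(shape, atten_k):
    nz = shape[0]
    z = np.arange(nz, dtype=np.float64)
    factor = 1.0 - atten_k * (z / max(nz - 1, 1))
    return factor.reshape(-1, 1, 1)


def _finalize(intensity, noise_sigma, atten_k, shape, rng):
    intensity = intensity * _z_attenuation(shape, atten_k)
    if noise_sigma > 0:
        intensity = intensity + rng.normal(0.0, noise_sigma, size=shape)
    return np.clip(intensity, 0.0, _CLIP_MAX)


def _surface_layer(interior: np.ndarray) -> np.ndarray:
    """Outermost interior voxel layer (6-connected boundary)."""
    eroded = ndimage.binary_erosion(interior, structure=ndimage.generate_binary_structure(3, 1))
    return interior & ~eroded


def make_shell_sphere(
    shape=(96, 96, 96),
    R=20.0,
    wall_sigma=1.0,
    A_wall=200.0,
    noise_sigma=2.0,
    atten_k=0.0,
    seed=0,
    bump_amp=0.0,
    bump_freq=4,
) -> SyntheticTissue:
    """Hollow bright spherical shell: the tissue-surface detection fixture.

    Intensity ``A_wall * exp(-(r-R_loc)^2 / 2 wall_sigma^2)`` times the z
    attenuation, plus clipped Gaussian noise.  ``bump_amp`` (voxels) adds a
    cell-scale sinusoidal relief of ``bump_freq`` periods per axis to the
    local radius ``R_loc`` — the bumpy-sphere variant used to probe the
    smoothing term.  Truth surface is the (possibly bumpy) sphere about the
    grid centre.
    """
    shape = tuple(int(n) for n in shape)
    if R + bump_amp >= min(shape) / 2.0 - 3.0 * wall_sigma:
        raise ValueError("sphere radius too large for the grid: need R < min(shape)/2 - 3*wall_sigma")
    rng = np.random.default_rng(seed)
    zz, yy, xx = _coord_grids(shape)
    centre = [(n - 1) / 2.0 for n in shape]
    r = np.sqrt((zz - centre[0]) ** 2 + (yy - centre[1]) ** 2 + (xx - centre[2]) ** 2)
    r_loc = R
    if bump_amp > 0:
        w = [2.0 * np.pi * bump_freq / n for n in shape]
        r_loc = R + bump_amp * (
            np.sin(w[0] * zz) * np.sin(w[1] * yy) * np.sin(w[2] * xx)
        )
    intensity = A_wall * np.exp(-((r - r_loc) ** 2) / (2.0 * wall_sigma**2))
    image = _finalize(intensity, noise_sigma, atten_k, shape, rng)
    interior = r < r_loc
    labels = interior.astype(np.int32)
    return SyntheticTissue(
        image=image,
        truth_labels=labels,
        truth_surface_mask=_surface_layer(interior),
        params=dict(
            kind="shell_sphere",
            shape=list(shape),
            R=R,
            centre=centre,
            wall_sigma=wall_sigma,
            A_wall=A_wall,
            noise_sigma=noise_sigma,
            atten_k=atten_k,
            seed=seed,
            bump_amp=bump_amp,
            bump_freq=bump_freq,
        ),
    )


def _sample_foam_seeds(rng, n_cells, tissue_radius, centre, shape, min_cell_voxels):
    """Rejection-sample cell seed points until every cell is large enough.

    Returns the nearest-seed tessellation, the tissue mask, the seed points
    and the distance to the wall mid-plane (half the gap between first- and
    second-nearest seed), all computed in one streaming pass so memory stays
    at a few full grids.
    """
    zz, yy, xx = _coord_grids(shape)
    r2 = (zz - centre[0]) ** 2 + (yy - centre[1]) ** 2 + (xx - centre[2]) ** 2
    tissue = r2 < tissue_radius**2
    # Poisson-disc-style sampling: a minimum seed separation keeps the
    # tessellated cells roundish (inradius a usable fraction of the
    # equivalent radius), which real tissue resembles far more than a
    # bare Poisson Voronoi
    sep = 0.75 * (4.0 * np.pi * tissue_radius**3 / (3.0 * n_cells)) ** (1.0 / 3.0)
    for attempt in range(200):
        pts_list = []
        tries = 0
        dmin = sep * (0.97**attempt)
        while len(pts_list) < n_cells and tries < 20000:
            tries += 1
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            rad = (tissue_radius - 2.0) * rng.random() ** (1.0 / 3.0)
            p = np.asarray(centre) + u * rad
            if all(np.linalg.norm(p - q) >= dmin for q in pts_list):
                pts_list.append(p)
        if len(pts_list) < n_cells:
            continue
        pts = np.asarray(pts_list)
        best1 = np.full(shape, np.inf)
        best2 = np.full(shape, np.inf)
        lab = np.zeros(shape, dtype=np.int32)
        for k, p in enumerate(pts, start=1):
            d = np.sqrt((zz - p[0]) ** 2 + (yy - p[1]) ** 2 + (xx - p[2]) ** 2)
            closer = d < best1
            np.minimum(best2, d, out=best2, where=~closer)
            best2[closer] = best1[closer]
            best1[closer] = d[closer]
            lab[closer] = k
        lab[~tissue] = 0
        counts = np.bincount(lab.ravel(), minlength=n_cells + 1)[1:]
        if counts.min() >= min_cell_voxels:
            wall_dist = 0.5 * (best2 - best1)
            return lab, tissue, pts, wall_dist
    raise RuntimeError("could not sample a foam without undersized cells")


def make_foam(
    shape=(96, 96, 96),
    n_cells=8,
    wall_width=2.0,
    A_wall=200.0,
    rho_outer=0.3,
    noise_sigma=2.0,
    atten_k=0.0,
    seed=0,
    min_cell_voxels=100,
    A_lumen=40.0,
) -> SyntheticTissue:
    """Ball-shaped tissue tessellated into cells by nearest seed point.

    Inner (anticlinal) walls are rendered at ``A_wall``; the outer
    (periclinal) wall at ``rho_outer * A_wall``, emulating the dim outer
    membrane signal of real stacks.  Cell lumens carry a cytoplasmic base
    intensity ``A_lumen`` brighter than the dark exterior — the property
    that makes raw watershed pour the background flood through dim outer
    walls.  ``truth_labels`` is the tessellation.
    """
    shape = tuple(int(n) for n in shape)
    if n_cells < 2:
        raise ValueError("a foam needs n_cells >= 2")
    rng = np.random.default_rng(seed)
    centre = [(n - 1) / 2.0 for n in shape]
    tissue_radius = min(shape) / 2.0 - 4.0
    labels, tissue, pts, wall_dist = _sample_foam_seeds(
        rng, n_cells, tissue_radius, centre, shape, min_cell_voxels
    )

    zz, yy, xx = _coord_grids(shape)
    r = np.sqrt((zz - centre[0]) ** 2 + (yy - centre[1]) ** 2 + (xx - centre[2]) ** 2)
    sigma_w = wall_width / 2.0
    inner = A_wall * np.exp(-(wall_dist**2) / (2.0 * sigma_w**2))
    inner[r > tissue_radius + 2.0 * sigma_w] = 0.0
    outer = rho_outer * A_wall * np.exp(-((r - tissue_radius) ** 2) / (2.0 * sigma_w**2))
    intensity = np.maximum(inner, outer)
    intensity = np.where(tissue, np.maximum(intensity, A_lumen), intensity)
    image = _finalize(intensity, noise_sigma, atten_k, shape, rng)

    surface = _surface_layer(tissue)
    return SyntheticTissue(
        image=image,
        truth_labels=labels,
        truth_surface_mask=surface,
        params=dict(
            kind="foam",
            shape=list(shape),
            n_cells=n_cells,
            wall_width=wall_width,
            A_wall=A_wall,
            rho_outer=rho_outer,
            noise_sigma=noise_sigma,
            atten_k=atten_k,
            seed=seed,
            A_lumen=A_lumen,
            tissue_radius=tissue_radius,
            centre=centre,
            seed_points=pts.tolist(),
            min_cell_voxels=min_cell_voxels,
        ),
    )


def make_folded_tissue(
    shape=(96, 96, 96),
    crease_depth=10.0,
    crease_width=6.0,
    A_wall=150.0,
    wall_sigma=1.0,
    noise_sigma=2.0,
    atten_k=0.0,
    seed=0,
    A_lumen=40.0,
) -> SyntheticTissue:
    """Two tissue lobes meeting in a deep narrow surface crease.

    The surface is a height map ``z_surf(y, x)``: a gentle dome indented by
    a Gaussian groove of the stated depth and width along the mid-plane
    (the organ-boundary fold).  The wall layer follows the Euclidean
    distance to the tissue boundary, so the narrow crease is filled with a
    bright halo.  Truth surface is recorded as the depth map.
    """
    shape = tuple(int(n) for n in shape)
    if crease_width < 2:
        raise ValueError("crease_width must be >= 2 voxels")
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    # gentle dome: shallow paraboloid, apex a third of the way down the stack
    z_base = nz / 3.0 + ((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * max(ny, nx))
    # slot-shaped groove: two near-parallel walls crease_width apart, so the
    # channel stays resolvable down to the stated depth (a V-groove would
    # fill itself with halo below ~2 wall widths)
    slot = (np.abs(np.arange(nx) - cx) <= crease_width / 2.0).astype(np.float64)
    slot = ndimage.gaussian_filter1d(slot, 0.6) * crease_depth
    z_surf = z_base + slot[None, :]

    zz = np.arange(nz, dtype=np.float64).reshape(-1, 1, 1)
    tissue = zz >= z_surf[None, :, :]
    # wall: single bright sheet on the boundary (distance via EDT), scaled
    # so voxels hugging the wall — and hence the halo filling the narrow
    # crease, which is close to a wall on both sides — reach A_wall
    d_out = ndimage.distance_transform_edt(~tissue)
    d_in = ndimage.distance_transform_edt(tissue)
    dist = np.where(tissue, d_in, d_out) - 0.5
    intensity = 1.3 * A_wall * np.exp(-(dist**2) / (2.0 * wall_sigma**2))
    intensity[dist > 4.0 * wall_sigma] = 0.0
    intensity = np.where(tissue, np.maximum(intensity, A_lumen), intensity)
    image = _finalize(intensity, noise_sigma, atten_k, shape, rng)

    labels = tissue.astype(np.int32)
    out = SyntheticTissue(
        image=image,
        truth_labels=labels,
        truth_surface_mask=_surface_layer(tissue),
        params=dict(
            kind="folded_tissue",
            shape=list(shape),
            crease_depth=crease_depth,
            crease_width=crease_width,
            A_wall=A_wall,
            wall_sigma=wall_sigma,
            noise_sigma=noise_sigma,
            atten_k=atten_k,
            seed=seed,
            A_lumen=A_lumen,
        ),
    )
    out.params["depth_map"] = z_surf.tolist()
    return out


def _calibrated_ratios(volumes, ratio_mean, ratio_sd, target_corr, rng, render=None):
    """Per-cell nucleus:cell ratios with stated mean/sd such that the
    (cell volume, nucleus volume) sample correlation hits target_corr.

    The ratio is a mixture ``c*z + sqrt(1-c^2)*w`` of the standardised cell
    volume z and independent noise w; the mixing weight c is solved on the
    realised sample (deterministic given the seed).  ``render`` optionally
    maps imposed nucleus volumes to the volumes the renderer will actually
    produce, so the calibration anticipates rendering distortion.
    """
    v = np.asarray(volumes, dtype=np.float64)
    n = v.size
    if ratio_sd == 0:
        return np.full(n, ratio_mean)
    if render is None:
        render = lambda x: x  # noqa: E731
    z = (v - v.mean()) / max(v.std(), 1e-12)
    w = rng.normal(size=n)
    w = (w - w.mean()) / max(w.std(), 1e-12)

    def corr_at(c):
        ratios = ratio_mean + ratio_sd * (c * z + np.sqrt(max(1.0 - c * c, 0.0)) * w)
        nuc = render(v * np.clip(ratios, 0.02, 0.9))
        return np.corrcoef(v, nuc)[0, 1] - target_corr

    lo, hi = corr_at(-1.0), corr_at(1.0)
    if lo >= 0:
        c = -1.0
    elif hi <= 0:
        c = 1.0
    else:
        c = optimize.brentq(corr_at, -1.0, 1.0, xtol=1e-6)
    return ratio_mean + ratio_sd * (c * z + np.sqrt(max(1.0 - c * c, 0.0)) * w)


def add_nuclei_channel(
    tissue: SyntheticTissue,
    ratio_mean=0.17,
    ratio_sd=0.05,
    target_corr=0.6,
    missing_fraction=0.0,
    seed=0,
    A_nuc=150.0,
    edge_sigma=1.2,
    noise_sigma=2.0,
) -> SyntheticTissue:
    """Add a nuclear-reporter channel: one blurred blob per cell.

    Each nucleus is a solid ball convolved with a Gaussian of width
    ``edge_sigma`` (a blurred step edge, whose half-maximum surface and
    gradient-maximum surface coincide), centred at the deepest point of its
    cell.  Ball volumes are drawn so the nucleus:cell volume ratio has the
    stated mean/sd and the (cell, nucleus) volumes the stated Pearson
    correlation.  A ``missing_fraction`` of cells, chosen at random, gets
    no blob.  Truth nucleus masks are the half-maximum surfaces of the
    noise-free channel.
    """
    if not (0.0 < ratio_mean < 1.0):
        raise ValueError("ratio_mean must be in (0, 1)")
    if not (0.0 <= missing_fraction < 1.0):
        raise ValueError("missing_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    labels = tissue.truth_labels
    ids = np.arange(1, labels.max() + 1)
    counts = np.bincount(labels.ravel(), minlength=ids.size + 1)[1:]
    if np.any(counts == 0):
        raise ValueError("truth labels must be consecutive and non-empty")

    n_missing = int(round(missing_fraction * ids.size))
    missing = rng.choice(ids, size=n_missing, replace=False) if n_missing else np.array([], int)
    present = np.setdiff1d(ids, missing)

    # deepest voxel of each cell (w.r.t. the cell's own boundary, walls
    # included) hosts the nucleus centre; the depth also caps the nucleus
    objects = ndimage.find_objects(labels)
    centres, dmaxes = {}, {}
    for lab in present:
        sl = objects[lab - 1]
        mask = np.pad(labels[sl] == lab, 1)
        depth = ndimage.distance_transform_edt(mask)
        centre_local = np.unravel_index(int(np.argmax(depth)), depth.shape)
        dmaxes[lab] = float(depth[centre_local])
        centres[lab] = tuple(
            c - 1 + s.start for c, s in zip(centre_local, sl)
        )

    def _draw_radius(vol, dmax):
        # inflate slightly: blurring shrinks the half-maximum surface of a
        # curved edge by ~sigma^2/r, and the discrete ball undershoots;
        # cap so the half-maximum surface stays inside the cell
        r_t = (3.0 * np.asarray(vol) / (4.0 * np.pi)) ** (1.0 / 3.0)
        r_d = r_t + 0.7 * edge_sigma**2 / np.maximum(r_t, 1.0) + 0.2
        return np.minimum(r_d, dmax - 1.0)

    dmax_arr = np.array([dmaxes[lab] for lab in present])

    def _rendered_volume(vol):
        return (4.0 / 3.0) * np.pi * _draw_radius(vol, dmax_arr) ** 3

    ratios = np.zeros(ids.size)
    ratios[present - 1] = _calibrated_ratios(
        counts[present - 1], ratio_mean, ratio_sd, target_corr, rng,
        render=_rendered_volume,
    )
    ratios = np.clip(ratios, 0.02, 0.9)

    channel = np.zeros(labels.shape, dtype=np.float64)
    for lab in present:
        cz, cy, cx = centres[lab]
        vol = ratios[lab - 1] * counts[lab - 1]
        r_ball = float(_draw_radius(vol, dmaxes[lab]))
        lo = [max(0, int(np.floor(c - r_ball - 1))) for c in (cz, cy, cx)]
        hi = [
            min(n, int(np.ceil(c + r_ball + 2)))
            for c, n in zip((cz, cy, cx), labels.shape)
        ]
        box = tuple(slice(a, b) for a, b in zip(lo, hi))
        zz, yy, xx = np.meshgrid(
            *[np.arange(a, b, dtype=np.float64) for a, b in zip(lo, hi)],
            indexing="ij",
        )
        ball = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= r_ball**2
        channel[box][ball] = A_nuc

    clean = ndimage.gaussian_filter(channel, edge_sigma, mode="nearest")
    truth_nuclei = np.where(clean >= A_nuc / 2.0, labels, 0).astype(np.int32)
    noisy = clean + (rng.normal(0.0, noise_sigma, labels.shape) if noise_sigma > 0 else 0.0)
    noisy = np.clip(noisy, 0.0, _CLIP_MAX)

    out = SyntheticTissue(
        image=tissue.image,
        truth_labels=tissue.truth_labels,
        truth_surface_mask=tissue.truth_surface_mask,
        params=dict(tissue.params),
        spacing=tissue.spacing,
        nuclear_channel=noisy,
        truth_nuclei=truth_nuclei,
    )
    out.params.update(
        nuclei=dict(
            ratio_mean=ratio_mean,
            ratio_sd=ratio_sd,
            target_corr=target_corr,
            missing_fraction=missing_fraction,
            seed=seed,
            A_nuc=A_nuc,
            edge_sigma=edge_sigma,
            noise_sigma=noise_sigma,
            missing_labels=sorted(int(m) for m in missing),
        )
    )
    return out
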