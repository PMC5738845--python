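# lsmseg

Level-set segmentation of 3D confocal stacks of plant tissue: tissue-surface
detection, watershed enhancement of the outer cell layer, per-cell
segmentation with one level-set function per cell, and nuclei volumetry in
two-channel stacks.

## The problem

Membrane-marker confocal stacks of growing plant tissue (shoot meristems,
flower primordia) have three recurring pathologies that defeat standard
seeded-watershed pipelines: the outer periclinal walls image much dimmer
than the anticlinal and interior walls, brightness falls with imaging depth,
and organ boundaries form deep narrow surface creases filled with a bright
halo. The consequences are trimmed or entirely missing cells in the
outermost (L1) layer and unfaithful tissue contours at the creases.

## The method

A contour is the zero level of a field φ (negative inside) evolving by the
gradient flow of the geodesic energy

    E = λ L_g + β L_1 + α A_g + R_p,

i.e. edge-weighted contour area (image term), plain area (smoothing, whose
flow is motion by mean curvature), g-weighted enclosed volume (the
accelerating/balloon term, pushing the contour into creases or inflating
cell seeds), and a distance regulariser. The edge map is a Hill function
g = 1/(1 + |f/γ|²) of one of three indicators of the smoothed image Î:
|∇Î| (type `g`), Î itself (type `i`), or the wall indicator min(λ₃, 0)
built from the smallest Hessian eigenvalue (type `h`). A bright wall makes
*two* valleys of the gradient edge map but a *single*, wall-centred valley
of the Hessian one — which is why type `h` cell contours can meet at the
wall and why dim outer walls still pin a type-`h` surface.

The pipelines:

* **surface** — threshold varying linearly in z (dimmer at depth) gives a
  coarse outside initialisation; the contour then adheres to the tissue
  surface, entering creases when the balloon term is on.
* **enhance + cells-watershed** — the detected surface is painted white and
  the exterior set to the most frequent interior intensity; h-minima
  seeding and watershed on the modified image no longer trim or lose L1
  cells.
* **cells-lsm** — one level-set function per cell, initialised from seeds
  or eroded labels, inflated to the walls, rasterised, and the remaining
  wall voxels attributed to the nearest cell.
* **nuclei** — per-cell contours initialised on cells eroded by d=1 shrink
  onto the nuclei of a nuclear-reporter channel (α=β=0); signal-free cells
  collapse to a residue removed by a size filter; volumes, nucleus:cell
  ratios and the cell–nucleus volume correlation are tabulated.

Everything is testable without microscope data: `lsmseg.synth` generates
shells, foams (Voronoi-cell tissue balls with dim outer walls, depth
attenuation, cytoplasm background), creased tissue, and nuclear channels
with imposed volume statistics — all with exact ground truth and
bit-reproducible from a seed.

## Worked example

```
$ lsmseg synth --kind foam --shape 96,96,96 --n-cells 8 --rho-outer 1.0 \
      --seed 2 --out-prefix scratch/foam
INFO synth parameters: {"kind": "foam", "seed": 2, "shape": [96, 96, 96]}
INFO wrote fixture with 8 truth labels to scratch/foam_*

$ lsmseg cells-lsm --input scratch/foam_image.tif \
      --init-labels scratch/foam_labels.tif --d 2 --type h \
      --out-labels scratch/foam_cells.tif
INFO cells-lsm parameters: {"alpha": 1.0, "beta": 0.0, "d": 2, "fill": true,
  "gamma": 0.8, "kind": "h", "lam": 1.0}
INFO cells=8 labelled_voxels=367097

$ lsmseg cells-watershed --input scratch/foam_image.tif \
      --out-labels scratch/foam_ws.tif --truth scratch/foam_labels.tif
INFO h=20.7037 seeds=9 labels=9
metric,value
n_truth,8
lost_cells,0
agreement,0.9974
mean_volume_error,0.0009
```

The last block segments the same stack by seeded watershed and scores it
against the generator's truth: all 8 cells recovered, 99.7% of tissue voxels
carry the right label, and per-cell volumes are within a tenth of a percent. On a foam with
dim outer walls (`--rho-outer 0.3 --atten-k 0.4`) the same raw watershed
loses most surface cells — run `surface` and `enhance` first and it
recovers them all; that contrast is exactly what the package is for.

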