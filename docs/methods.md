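# Methods

## The model

A contour (in 3D, a surface) is represented implicitly as the zero level of
a scalar field φ, negative inside. The field evolves by the gradient flow
of a geodesic-active-contour energy

    E = λ L_g + β L_1 + α A_g + R_p

whose terms are, in order: the *image term* (the contour's length/area
weighted by an edge map g), a *smoothing term* (unweighted length/area,
whose flow is motion by mean curvature), an *accelerating or balloon term*
(the g-weighted enclosed volume, producing normal motion at speed αg,
signed inward or outward), and a *distance regulariser* that keeps |∇φ|
near 1. The realised flow is

    ∂φ/∂t = λ (g κ |∇φ| + ∇g · ∇φ) + β κ |∇φ| ± α g |∇φ| + μ R_p[φ]

with κ = div(∇φ/|∇φ|) the sum of principal curvatures. The image term is
the full geodesic flow: the advection part ∇g·∇φ attracts the contour to
valleys of g from both sides, and the g-weighted curvature part shrinks it
wherever the image offers no edge to hold on to. That second part matters:
it is what collapses the contour inside cells that have no nuclear signal,
leaving at most a few-voxel residue — observed behaviour of this family of
methods that a pure-advection image term cannot produce.

The edge map is a Hill function of an indicator f of the smoothed image Î:

    g = 1 / (1 + |f/γ|²)

with three indicator choices: `g` (gradient magnitude |∇Î|), `i` (the
intensity itself), and `h` (the wall indicator min(λ₃, 0), λ₃ the smallest
eigenvalue of the local Hessian). A bright thin wall produces *two* valleys
of the gradient edge map (one per side) but a *single* valley of the
Hessian one, centred on the wall — and the Hessian indicator keeps a deep
valley on dim outer walls where the gradient one fades. This is what makes
`h` the right choice for inflating cell contours that should meet at the
wall midplane, and for surfaces over weakly stained outer membranes.

## Parameters

| name | meaning | default | notes |
|------|---------|---------|-------|
| λ | image-term weight | 1 | sets the time scale; α, β are read relative to it |
| α | balloon weight | 0 | 1 for surface detection (inward) and cell inflation (outward) |
| β | smoothing weight | 0 | 1 when only tissue-scale shape is wanted |
| μ | regulariser weight | 0.1 | stability bound μ·dt < 0.25 enforced |
| dt | time step | 1.0 | internally split into CFL-stable sub-steps |
| γ | Hill scale | 8 / 60 / 0.8 per kind | must track the span of f values; e.g. the synthetic nuclear channel (amplitude 150, edge width ≈1.6 voxels, peak gradient ≈38) calls for γ ≈ 4 |
| s | Gaussian pre-smoothing | 1 voxel | |
| conv_tol, conv_window | stop criterion | 2·10⁻⁴, 10 | mean sign-change fraction over the window |

The stop criterion measures contour deceleration: the run ends when the
fraction of voxels whose sign of φ changed, averaged over `conv_window`
iterations, falls below `conv_tol`. The tolerance is a voxel fraction, so
on small grids (≲64³) a somewhat larger value (5·10⁻⁴) is appropriate.

Keeping α and β at or below λ matters. The balloon must not exceed the
image term's ability to pin the contour at a wall, and a seed of radius r
inflates only while α > λ·g·2/r, so very small seeds need the default λ=1
rather than a large image weight.

## Numerics

* Explicit time stepping; the user-facing `dt` is split into sub-steps
  satisfying an empirically validated CFL bound (advective Courant sum plus
  an advective-scale term for the clamped curvature and a parabolic term
  for the regulariser).
* The hyperbolic terms (advection + balloon) are discretised by a local
  Lax–Friedrichs scheme: central-difference Hamiltonian plus per-axis
  dissipation with the *local characteristic speed* |v_i + b·n_i| as
  coefficient. Two subtleties led to this choice. One-sided (Godunov/upwind)
  schemes carry a curvature-correlated O(hκ) bias on spherical fronts —
  the balloon samples the steepening side, the restoring advection the
  other — which can ratchet a pinned contour through its g-valley. And the
  plain Lax–Friedrichs coefficient |v_i|+|b| re-introduces the same bias
  as dissipation; the local characteristic speed vanishes exactly where
  balloon and attraction balance, so pinned fronts stay pinned.
* Curvature is computed from staggered (half-node) unit normals: compact
  (±1 voxel), accurate to ~1% at radius 5, and exactly invariant to the
  radial slope of φ, so a compressed profile at a pinned front cannot
  masquerade as curvature.
* The driving terms are confined to a raised-cosine band (half-width 6
  voxels, full weight through the first layers) around the zero level, and
  sign changes farther than 2.5 voxels from the front are rejected: remote
  voxels can neither drift nor nucleate new interface.
* φ is refreshed to a signed distance every `reinit_every` = 3 iterations:
  exact Euclidean EDT in the far field, linear-interpolated crossing
  distances in the two front layers (a mask-only EDT would quantise the
  front and bias curved contours outward by ~0.05 voxel per refresh).
* The regulariser is the double-well potential (wells at |∇φ| = 0 and 1),
  so the refresh cadence is a cheap insurance rather than a necessity.
* The distance regulariser acts on the full grid; everything else is
  banded. All updates are deterministic; two runs with identical inputs
  are bit-identical.
* Hessians for the wall indicator use fourth-order central stencils: the
  three-point second difference biases the curvature of a σ=2 ridge by
  ~5%, which would be the whole error budget of the analytic checks.
* The per-cell fields of the multi-contour stages live on padded bounding
  boxes (exact as long as the margin exceeds the contour's travel) and are
  evolved independently — no coupling term exists, matching the per-cell
  formulation; overlaps are resolved at rasterisation (most-negative φ
  wins, ties to the lowest label).

Measured behaviour of the flow oracles (64³ grid): shrinking-sphere
radius within ~2% of R(t)=√(R₀²−4βt) down to R=5; planar balloon front
speed within ~4% of αg·dt; balloon spheres within ~2–6% over 8–14 voxel
excursions.

## What the generators emulate

`make_shell_sphere` — a hollow bright shell (Gaussian cross-profile,
σ=1 voxel) with optional depth attenuation (brightness falls linearly in
z) and optional cell-scale sinusoidal relief (the "bumpy" variant used to
probe the smoothing term).

`make_foam` — a ball of tissue tessellated into cells by nearest seed
point, seeds drawn with a minimum-separation (Poisson-disc-like) rule so
cells are roundish as in real tissue. Anticlinal (cell–cell) walls at full
brightness, the outer periclinal wall dimmed by ρ_outer, cytoplasm at a
base intensity above the dark exterior. That last property is what breaks
raw watershed: the background flood pours through the dim outer wall into
the brighter lumens, trimming or swallowing outer-layer cells.

`make_folded_tissue` — two tissue lobes meeting in a slot-shaped groove of
stated depth and width; the wall layer follows the Euclidean distance to
the boundary, so the narrow crease fills with a bright halo. A V-shaped
groove narrower than about two wall widths is not resolvable — it renders
as a solid bright plug that no edge-based contour can enter — so the
default crease is 6 voxels wide with 1-voxel walls, and the wall amplitude
(150) is chosen so the halo does not saturate the 8-bit-like range.

`add_nuclei_channel` — one nucleus per cell (minus a random missing
fraction): a solid ball convolved with a Gaussian (edge width 1.2 voxels),
centred at the cell's deepest interior point. A blurred ball is used
rather than a Gaussian intensity blob deliberately: for a blurred step
edge the half-maximum surface and the gradient-maximum surface coincide,
so the generator's recorded truth (the half-maximum mask) is also the
fixed point any edge-seeking contour converges to. Ball radii are drawn so
the nucleus:cell volume ratio has the requested mean and spread and the
(cell, nucleus) volumes the requested Pearson correlation; the calibration
anticipates the rendering distortions (half-maximum shrink of a curved
blurred edge, the inradius cap) by solving for the mixing weight on the
predicted rendered volumes.

What the fixtures do *not* emulate: anisotropic PSFs, Poisson photon
statistics, wall-thickness variation, cell-shape anisotropy, touching
nuclei, and multi-angle fusion artefacts. Passing these tests shows the
pipelines implement the intended mechanisms; it does not certify
performance on any particular microscope's data.

## Pipeline choices

* Surface detection initialises from a z-linear threshold (thresholds may
  differ at the top and bottom of the stack because brightness falls with
  depth), keeps the largest connected component, fills internal cavities
  (the target is the *outer* surface), and takes the signed EDT. A
  pre-existing coarse mask may be supplied instead.
* For surfaces over dim outer walls (the foam rescue) and for creased
  tissue, the wall indicator `h` is the recommended and tested choice; the
  gradient indicator works on bright closed shells but its valley sits on
  the wall flank (≈1 voxel outside the wall centre), while the `h` valley
  is wall-centred — the interior volume then matches the enclosed ball to
  a few percent.
* Watershed enhancement paints the shell |φ| ≤ 1 white (dtype maximum) and
  sets the exterior to the most frequent interior intensity (exact counts
  for integer images, 256 equal-width bins for float, ties to the lowest
  value). Seeding takes connected components of the h-minima after a light
  1-voxel Gaussian pre-smoothing (sensor noise otherwise fringes each basin
  with satellite minima); h defaults to 10% of the dynamic range.
* Scoring against truth uses one-to-one label matching by maximum total
  overlap (Hungarian assignment); a truth cell with no matched partner
  covering the majority of its voxels counts as lost.
* Nuclei: initialise per-cell fields on cells eroded by a 1-voxel ball
  (cells whose erosion vanishes keep their deepest voxel), evolve with
  α=β=0 in the edge map of the nuclear channel, rasterise, clip each
  nucleus to its parent cell, and drop objects below `min_voxels` = 10.
  In signal-free cells the g-weighted curvature collapses the contour; the
  parent cell remains tracked through the cell table, and the statistics
  report such cells as undetected.

## Known limitations

* A balloon-driven contour pinned at a weak, narrow g-valley (valley width
  ≈1 voxel, g-contrast ≪ the balloon term) is metastable: over hundreds of
  iterations past convergence a local fluctuation can breach it. The stop
  criterion returns the pinned state long before that; for long runs,
  raise λ relative to α, as the parameter guidance says.
* The half-voxel rasterisation of a wall-midplane contour leaves a
  one-voxel film of wall voxels attributed to whichever neighbour claims
  them first; for a cell of radius r this is ~3/(2r) of its volume.
* γ is not auto-calibrated; it must be chosen per channel from the span of
  indicator values (the defaults assume 8-bit-like intensity ranges).
* Full-grid regularisation makes single-field memory O(grid); the
  problem sizes used throughout (96³–128³ stacks, up to 200 cells) run in
  minutes on one core. The per-cell stages scale with total cell bounding
  box volume, not with cell count times grid size.
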