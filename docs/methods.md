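# Methods

This note records the modelling assumptions, numerical choices and defaults
behind `lheart`, and what the synthetic test bed does and does not show.

## Coordinate conventions

Contours are 0-based pixel index pairs `(u, v)`; `u` advances along the
plane's row direction cosine with pitch `Δu`, `v` along the column
direction with `Δv`.  DICOM's `PixelSpacing` lists row spacing first, so
`Δu = PixelSpacing[1]` and `Δv = PixelSpacing[0]`; this choice is fixed
here because the attribute order is a perennial source of silent
transposition bugs and nothing else in the pipeline disambiguates it.  The
patient frame is DICOM LPS in mm.  Direction cosines are accepted within
1e-6 of unit/orthogonal and re-normalized; anything worse is rejected
rather than repaired.

## Registration

The SAX cloud is the reference and never moves.  For each LAX view the
filter tolerance is `ε = α·d_H(C_sax, C_lax)` with `α = 0.35`, the midpoint
of the empirically useful 0.2–0.5 band; `α` stays a config knob
(`registration.alpha`) because its ideal value depends on how much the
clouds actually overlap.  Mutual-subset filtering keeps `ε` fixed across
sweeps; each non-final sweep removes at least one point, so it terminates
in at most `|C_X| + |C_Y|` sweeps.

ICP is point-to-point with a closed-form orthogonal-Procrustes update,
identity initialization (all clouds already share the patient frame;
breath-hold motion is a few mm/deg), nearest-neighbour ties broken to the
lowest point index, and the standard determinant guard against
reflections.  Convergence: `|Δ RMS| < 1e-6 mm` or 100 sweeps.

**Correspondence trimming.**  Each update uses only the half of the moving
points with the smallest correspondence distances
(`registration.trim_fraction = 0.5`).  The reference cloud is sampled on
slices 8 mm apart, so moving points lying over the inter-slice gaps have no
true counterpart; matched anyway, they drag the fit toward the slices and
the recovered pose can be worse than the motion being corrected (measured
on the phantom: mean residual 6.6°/4.7 mm untrimmed vs 2.0°/1.4 mm trimmed
under 5 mm/5° motions).  The closest-half restriction concentrates the
update on the plane-crossing regions where genuine correspondences exist.
`trim_fraction = 1` recovers the classic iteration.

Two accuracy regimes should not be confused: with exact one-to-one
correspondences ICP recovers the transform to machine precision, but on
discretely sampled contours the objective's true minimum sits a sub-pixel
distance away from the ideal pose, so even a motion-free study registers
back with a drift of order 0.1–1° / a few tenths of a mm.  That is a
property of RMS point matching on sliced data, not an implementation
artifact.

## Densification

Orientation is defined about the SAX stack normal; every contour is made
counter-clockwise by sign of its shoelace area.  Intra-contour resampling
uses PCHIP on the cumulative chord-length parameter with three wrap-around
knots padded on each side, sampling only the central period — standard
PCHIP is not periodic and this is C¹ across the seam in practice, which is
sufficient for near-circular endocardial contours (a C² spline changes the
result negligibly).  At 12 knots on a circle the radial error is ≈ 0.8%,
at 24 knots ≈ 0.2%; clinical contours carry 100+ points.

Matching is sequential (each contour to its immediate lower neighbour),
the only construction consistent with column-wise correspondence tracks;
shift ties break to the smallest shift, and orientation is fixed before
matching, so only shifts are searched.  Inter-contour interpolation runs
against the physical position along the stack normal, not the slice index,
which keeps it correct when a slice is missing.  Defaults: `N = 64` points
per contour, `M` chosen so the level spacing matches the resampled
intra-contour point spacing (both tie the sheet density to the eventual
mesh density).  Interpolation never extrapolates beyond the group's level
range, and the bifurcation region between the LV top and the LA/AO bottoms
is never interpolated — point correspondence is undefined across the
branching, and the raw merged-contour points still shape the surface
through the distance term.

## Surface reconstruction

The auxiliary lattice has spacing `h`, covers the cloud bounding box
expanded 10% per side, and drops lattice points within `h/2` of a cloud
point.  A deterministic jitter of `1e-3·h` breaks the cospherical
degeneracy of a perfect lattice in the Delaunay construction.  Default
`h` ≈ 2.5 × the cloud's median nearest-neighbour spacing, clipped to
[2, 6] mm: reconstruction quality on the phantom is flat across h = 2–6 mm
while the tet count scales as `h⁻³`, so the default sits at the cheap end
of the flat region (≈ 150k tets, ≈ 3 s end-to-end).

The energy `E(S) = ∫ d(x, C_new) dx` is discretized per interior face as
`Area × (d(centroid) + 0.05·h)`.  The floor term is a small area
regularization: among surfaces at near-zero distance from the cloud it
prefers the least area, which breaks the discrete ties that otherwise
produce ragged, occasionally non-manifold cuts.  The distance uses the full
cloud including registered LAX and merged bifurcation points.

**Seeds.**  Exterior: every tet with a face on the convex hull.  Interior:
the per-level contour centroids (endocardial contours are star-shaped about
their centroid in practice) — but isolated anchor tets are not enough: the
global minimum of a discrete minimal-surface energy happily collapses into
a tiny box around each anchor (observed directly: a 100-tet interior).  The
anchors are therefore (a) bridged along their Euclidean minimum spanning
tree, sampled every `h/2`, which keeps the interior connected from apex
through the bifurcation into LA and AO, and (b) complemented by a grid fill
(spacing `h`) of each contour row's interior eroded by `h`, which
pre-labels the bulk of the delineated blood pool and leaves the cut free
only in the band near the data.  Anchors landing in hull-adjacent tets
raise a seed-conflict error (the grid is too coarse for the anatomy).

The max-flow problem is solved with integer capacities scaled into a 2^30
budget (relative quantization ≲ 1e-6 of the total energy); the reported cut
cost is re-accumulated from the exact float weights of the faces crossing
the returned cut, so the energy bookkeeping is exact for the labeling
found.  Node order is tet index order; runs are reproducible.  On meshes
small enough to enumerate, the cut equals the exhaustive minimum (tested
100/100).

Surface extraction takes faces whose incident tets disagree, oriented away
from the interior.  Labelings touching only along an edge yield a
non-manifold interface; the repair dilates the interior through the ring of
tets around each offending edge (monotone, hence terminating) and is
logged.  With the area floor the repair fires rarely.

A caveat on refinement: halving `h` does not monotonically improve the fit.
The continuum minimizer of `∫ d dA` chords slightly inward across the 8 mm
inter-slice gaps (the area factor), and a finer mesh approximates that
minimizer better — measured on the sphere test: mean cloud distance
2.7 → 3.1 mm when h goes 4 → 2 mm, radial error essentially unchanged.

## Post-processing

Taubin λ|μ smoothing with λ = 0.5, μ = −0.53, 10 iterations: the
alternating inflate/deflate steps act as a band-pass filter with volume
change < 2% at defaults (plain Laplacian smoothing would visibly thin the
aortic section).  Isotropic remeshing (split > 4/3·target, link-condition-
guarded collapse < 4/5·target, valence-driven flips, tangential relaxation
with re-projection onto a dense sampling of the input surface) is
implemented and exposed (`post.target_edge_mm`), but disabled by default:
the raw cut surface already has near-uniform Delaunay-scale edges, and
smoothing alone meets the geometric quality checks.  Both passes preserve
the Euler characteristic.

## Validation

Sections are computed by exact triangle/plane crossing and chained into
closed loops through shared mesh edges; vertices exactly on the plane are
nudged by 1e-12 so every crossing is a clean edge crossing.  In-plane
coordinates are mm along the plane's row/column axes.  Region overlap uses
exact polygon clipping (nested loops are holes, via even-odd symmetric
difference), never rasterization — a 0.25 mm rasterization survives in the
test suite as an independent cross-check oracle.  Hausdorff distances are
computed between boundary polylines resampled at 0.5 mm arc-length steps,
in 2D plane coordinates (equivalent to 3D for coplanar curves).  Reference
regions on multi-chamber planes are the union of all delineated chamber
regions, matched against the full mesh section.

## The phantom

The phantom blends three signed quasi-distance fields with a 5 mm
smooth-min: an LV ellipsoid (semiaxes 25 × 25 × 40 mm, apex down), a
laterally offset LA ellipsoid (16 × 16 × 18 mm) above the base, and a 9 mm
radius aortic tube along an 80 mm radius circular arc.  Sizes are ordinary
adult end-diastolic dimensions (LV cavity ≈ 130 ml).  The blend makes the
junction slices genuinely merge, so the virtual SAX stack exhibits all
three clinical delineation cases (LV-only / separate LA + AO / single
merged contour).  Acquisition geometry follows routine CMR: 8 mm SAX
spacing with no gap, 1.43 mm pixel spacing, three LAX planes orthogonal to
the stack.  The LAX angles are irregular (8°/63°/122°) and all plane
origins carry sub-pixel offsets: a perfectly centered, mirror-symmetric
layout puts one LAX plane exactly midway between SAX grid lines, creating
exact nearest-neighbour ties that registration resolves by index order — a
measure-zero artifact no real scan exhibits (it showed up as a systematic
half-pixel translation bias).

Breath-hold perturbation draws, per LAX plane, a uniformly distributed
rotation (axis uniform on the sphere, angle ≤ bound) about the plane's
contour centroid plus a uniform translation (≤ bound), deterministically
per seed, and returns the ground-truth transforms.

What the phantom does *not* emulate: papillary muscles and trabeculae
(excluded from delineation in practice anyway), valve leaflets, wall
motion/temporal coherence, observer variability in the contours, and
through-plane slice thickness (contours are ideal zero-level sets sampled
at pixel resolution).  Passing tests therefore demonstrate the geometric
correctness of the pipeline, not robustness to delineation noise.

## Problem sizes in the shipped tests

The test suite and the acceptance script use the default phantom
(≈ 5000 contour points, ≈ 150k tets) for single end-to-end runs, `h = 4 mm`
for the repeated ablation/perturbation runs, and 100-trial batches for the
registration, min-cut and metric oracles.

## Known limitations

- Rotational near-symmetry of the anatomy leaves the registration weakly
  constrained about the long axis; residuals of 1–3° remain under 5°
  motions, and occasional cases exceed the applied motion.
- The minimal-surface energy slightly under-shoots convex regions between
  slices (chording); the effect is ≲ 1 mm at 8 mm spacing.
- Multi-label (per-chamber) segmentation, adaptive meshing and non-rigid
  or temporal registration are out of scope.
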