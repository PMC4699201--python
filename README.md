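# lheart — left-heart surface reconstruction from planar CMR contours

`lheart` reconstructs a watertight triangulated surface of the left cardiac
blood pool — left ventricle (LV), left atrium (LA) and aorta (AO) — from the
sparse planar endocardial contours drawn during routine cardiovascular MR
examinations: a parallel short-axis (SAX) stack sliced every 8 mm plus two-,
three- and four-chamber long-axis (LAX) views.  It is aimed at researchers
who have expert 2D delineations and need a complete patient-specific 3D
model (including the inflow/outflow junctions) for hemodynamic simulation,
curvature analysis or anatomy atlases.

## Method

1. **Projection.**  Every contour, an ordered list of pixel coordinates
   `(u, v)`, is mapped into the patient coordinate system using its plane's
   DICOM geometry (position `P`, orientation `U, V`, pixel spacing
   `Δu, Δv`):  `p = P + u·Δu·U + v·Δv·V`.
2. **Registration.**  Breath-hold motion misaligns each LAX acquisition
   rigidly.  Each LAX cloud is aligned to the fixed SAX cloud by *mutual
   subset filtering* — iteratively discarding points farther than
   `ε = α·d_H` from the other cloud (`d_H` = Hausdorff distance,
   `α ∈ [0.2, 0.5]`) — followed by trimmed point-to-point ICP with a
   closed-form Kabsch update.
3. **Densification.**  Each parallel SAX group (LV, LA, AO) is re-oriented
   counter-clockwise, resampled to `N` points on a periodic shape-preserving
   PCHIP curve, matched across neighbouring slices by the mean-distance-
   minimizing circular shift, and interpolated to `M` levels with PCHIP
   along the stack — turning `L` sparse contours into an `M × N` point
   sheet.  The merged bifurcation contours are never interpolated.
4. **Variational reconstruction.**  The joint cloud `C_new` (densified SAX
   sheets + registered LAX points + raw bifurcation points) is embedded in
   a Delaunay tetrahedralization together with an auxiliary lattice, and the
   surface is found as the minimizer of the distance-weighted minimal
   surface energy

   &nbsp;&nbsp;&nbsp;&nbsp;`E(S) = ∫_S d(x, C_new) dx`

   discretized per face as `Area × d(centroid)` and solved globally as an
   s-t min-cut on the tet adjacency graph (interior seeds: the delineated
   blood pool; exterior seeds: the convex hull).  The interior/exterior
   interface is the watertight surface, finished with Taubin smoothing
   (and optional isotropic remeshing).
5. **Validation.**  The surface is cut with each imaging plane and the
   closed section polygons are scored against the reference contours with
   the Hausdorff distance `H`, Dice `D = 2|Re∩Tr|/(|Re|+|Tr|)` and Jaccard
   `J = |Re∩Tr|/|Re∪Tr|` (so `J = D/(2−D)`); an overlap of 0.7 or more is
   conventionally adequate.

No patient data ships with the package: a fully analytic phantom (blended
ellipsoids + bent tube) emulates the acquisition, including the three SAX
delineation cases and seed-controlled breath-hold misalignment with known
ground truth.

## Worked example

```bash
python examples/04_reconstruct_surface.py
```

prints (default phantom, one CPU):

```
cloud: 5174 contour points + 17688 auxiliary grid points
tetrahedral mesh: 152141 tets, h = 3.45 mm
min-cut: 33132 interior tets, energy = 24468 mm^3
surface: 5271 vertices, volume = 133 ml, genus 0: True
runtime: 2.7 s

validation against the long-axis reference contours
(Dice/Jaccard in [0,1], overlap >= 0.7 is conventionally adequate):
  2ch: Hausdorff =  0.93 mm, Dice = 0.995, Jaccard = 0.990
  3ch: Hausdorff =  4.31 mm, Dice = 0.983, Jaccard = 0.966
  4ch: Hausdorff =  1.59 mm, Dice = 0.994, Jaccard = 0.988
  mean: H = 2.28 mm, D = 0.991, J = 0.981
```

i.e. the reconstructed 133 ml blood pool re-sections onto the three
long-axis planes with ≥ 0.98 Dice overlap against the reference contours,
and the largest curve deviation (4.3 mm on the 3-chamber view, which cuts
the narrow aortic root) stays well under the 8 mm slice spacing.  The other
examples demonstrate phantom generation, registration recovery,
densification and the section metrics individually.

The same pipeline is available as a CLI:

```bash
lheart phantom --out study.json --seed 0
lheart reconstruct --study study.json --out-mesh heart.ply --report report.csv
lheart validate --study study.json --mesh heart.ply
```

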