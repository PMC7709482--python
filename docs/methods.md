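# Methods

## Scope and model

`genstereo` quantifies a monopodially branching tubular tree embedded in a
3D grayscale volume, per branching generation. The anatomical model is the
small-mammal pulmonary arterial tree: a single longitudinal trunk
(generation 1) spanning the organ along its vertical (apex-to-base) axis,
with lateral daughters of strictly smaller calibre branching off at a
fixed angle (generation 2), recursively. Each vessel is modelled as a
circular cylinder: a lumen of radius r surrounded by a concentric wall
annulus of thickness t, embedded in parenchyma. Generations are counted
from the hilum outward; a lateral daughter starts generation g+1, the
continuation of the parent keeps generation g, and proximal vs distal
position within a generation is not distinguished. Horsfield/Strahler
ordering from the periphery is out of scope.

## Phantom generator

The synthetic-data module is first-class: it defines the study conditions
under which every downstream stage is validated.

* **Geometry.** The trunk runs along the vertical (y) axis. Daughters
  attach at equispaced stations over the proximal `station_span` fraction
  of the parent, alternate azimuth side-to-side with a slow progressive
  twist (so daughter pairs do not share one plane), leave at
  `branch_angle` from the parent axis, and their own cylinder starts at
  the parent's luminal surface. Defaults: 3 generations, 2 daughters per
  parent, trunk 1900 µm, daughter lengths 532/176 µm, lumen radii
  70/40/28 µm, walls 18/12/8 µm, branch angle 75°, station span 0.45.
  These proportions are desk-scale (a whole organ would not fit a test
  budget) but preserve the defining features: an organ-length trunk,
  short proximal laterals, strictly decreasing calibre.
* **Ground truth.** Per-generation lumen/wall volumes and luminal surface
  areas are plain sums of cylinder closed forms (πr²L, π((r+t)²−r²)L,
  2πrL). Junction overlap is *not* subtracted: with daughters starting at
  the parent surface at 75°, the residual overlap is the cylindrical-hoof
  volume ≈ (2/3)r³/tan(angle) per junction, ≲ 1 % of any generation's
  volume at the defaults — absorbed by the rasterisation tolerance.
* **Monopodial dominance.** `build_tree` rejects specifications for which
  a length-based continuation rule could not recover the generator's
  labels. The margin is skeleton-aware: the continuation's downstream
  length must exceed 1.1 × the lateral subtree length **plus 4 parent
  radii**, because a voxel skeleton systematically (i) grows an in-parent
  connector of ≈ 1 parent radius on the lateral side, (ii) erodes
  terminal centerlines by ≈ 1 tube radius, and (iii) displaces junction
  nodes into the parent. An analytically comfortable margin without the
  radius term was demonstrably insufficient.
* **Rasterisation.** Branches are finite *open* cylinders (no end caps;
  caps would inflate short fat branches by tens of percent relative to
  πr²L). Compartment ties resolve innermost-first (lumen > wall >
  parenchyma); voxels covered by several branches belong to the branch
  with the nearest axis. The raster grid is anchored a quarter voxel off
  the trunk axis: a perfectly voxel-symmetric tube end can be retracted
  end-to-junction by parallel thinning without ever forming a curve
  endpoint, and the quarter-voxel offset breaks that degeneracy for the
  one axis-aligned tube (oblique daughters are generically asymmetric).
* **µCT appearance.** Class intensities follow the inverted convention of
  plastic-embedded specimens: embedding-medium-filled spaces bright
  (lumen 200), tissue dark (wall 40), parenchyma intermediate (130) with
  an optional smooth speckle emulating the alveolar air/septa mix (the
  speckle also gives registration algorithms realistic texture). Gaussian
  blur and additive Gaussian noise follow; everything is seeded.
* **Serial-section simulation.** Sections are extracted per SURS plan and
  deformed by a per-section random affine (rotation, anisotropic scale,
  shear, translation) plus a smooth low-frequency displacement field. The
  deformation is stored as the pull-back map W (deformed → undeformed
  coordinates), rescaled so the maximum landmark displacement is bounded
  by the requested amplitude; registration-recovery tests compare against
  W directly. Real magnitudes of cutting deformations are not known
  quantitatively, so the amplitude is a free parameter, not a calibrated
  one.

What the phantom does **not** emulate: capillary-scale vasculature, veins
and airways as separate interleaved trees (only optionally as disjoint
tubes), section loss/folds, stain variability, supernumerary laterals,
and dichotomous (human-type) branching. Passing tests therefore establish
the correctness of the estimators and the label-recovery machinery under
clean monopodial geometry, not robustness to every histological artefact.

## Segmentation

Anisotropic gradient diffusion (10 iterations, conductance 2.0, time step
0.0625 — the 3D stability bound for the explicit scheme; diffusion runs
in index space so the bound is spacing-independent) is followed by a
morphological watershed of the gradient magnitude. The flooding level is
expressed as a fraction of the gradient dynamic range (default 0.05;
0.02 in the demo configuration whose textured parenchyma raises the
gradient range). Lids — voxel caps sealing cut vessel openings at the
volume boundary — are painted with tissue intensity (or the wall label)
so flooding cannot leak out of an opened vessel; the operation is
idempotent.

Watershed segments are merged into anatomical classes either from an
explicit assignment table or by seeded flooding through the
segment-adjacency graph restricted to *bright* (plastic-filled) segments.
The bright threshold defaults to Otsu over per-segment mean intensities
but should be pinned by the operator when textured parenchyma dominates
the histogram (the demo uses 165, midway between tissue and embedding
medium) — this mirrors the inherently semi-manual character of the
original joining step. Conflicting double assignment of a segment is an
error naming the segment.

Note: independent watershed runs at two flooding levels agree with strict
hierarchical nesting only up to plateau ties (~10⁻³ of voxels); the
coarsening property is therefore guaranteed for segment *counts* and
tested at the 99.5 % voxel level.

## Generation analysis

1. **Skeletonization.** The artery mask is lightly smoothed (Gaussian,
   0.8 voxels, re-thresholded and intersected with the mask) so staircase
   terraces on oblique tube surfaces do not seed shallow ridge spurs,
   then thinned (topology-preserving, 26-connectivity). Node radii come
   from the Euclidean distance transform in physical units. The
   26-adjacency of the thinned voxel set still contains spurious short
   cycles; it is reduced to the minimum-total-length spanning tree
   (orthogonal links beat diagonals). Terminal branches shorter than
   3 × the local tube radius (the largest distance-transform value on the
   branch or immediately around its junction) are pruned iteratively;
   2 × proved too weak against junction-crevice spurs. Declared anchor
   points (the vessel entry used as the root) are guaranteed centerline
   coverage: if thinning retracted the tube end, a path is carved from
   the anchor's tube centre to the nearest skeleton voxel along the
   distance-transform ridge (Dijkstra with inverse-squared-EDT weights).
2. **Generation assignment.** Branches are traversed from the root; at
   every junction the daughter with the maximal total downstream length
   continues the parent's generation (ties: larger mean radius, then
   smaller branch id); all other daughters start generation + 1. The rule
   operationalises "the longitudinal trunk is generation 1": in a
   monopodial tree the trunk is by far the longest downstream path. A
   manual override table (branch id → generation) is honoured verbatim.
   Cyclic branch graphs are rejected.
3. **Label spreading.** Skeleton voxels act as markers for a watershed on
   the inverted distance transform restricted to the mask, so branch
   labels grow from the centerlines to the full vessel calibre; mask
   components unreached by any marker are assigned to the nearest label.
   The result partitions the mask exactly, and branch → generation
   mapping yields the per-voxel generation map.

## Virtual sectioning (SURS)

Sections of thickness 2 µm are cut orthogonally to one volume axis,
parallel to the vertical axis. Blocks of 20 consecutive sections are
collected, the next 50 skipped (period 140 µm, sampled fraction 2/7); the
first collected section is drawn uniformly from 1..period, which is what
makes the design unbiased. Each collected block is a *substack*.
Grayscale sections are interpolated linearly, label sections
nearest-neighbour (no invented label values). The Cavalieri estimator
weights each collected section by period/n_collected, so the estimate is
exactly unbiased over the offset ensemble and reduces to the plain
section-wise sum under exhaustive collection. Substack projections
(min/mean/max; min by default, since stained structure is dark on bright)
condense a substack for visual checks.

## Registration

Two-stage transforms (affine: translation/rotation/scale/shear, then
B-spline free-form deformation) behind SimpleITK's registration
framework. The similarity metric defaults to mean squares for
mono-modality pairs and Mattes mutual information across modalities;
multi-resolution (3 levels), regular-step gradient descent with physical
-shift scaling, L-BFGS-B for the B-spline stage. The 3D reference volume
is registered **to** each substack, so one flat resampled volume slice
corresponds to each physical section; the opposite direction would mix
material from different physical sections in one output slice. Labels are
always transported nearest-neighbour. Every deformable chain reports a
Jacobian-determinant summary (min/mean/max area change) in the run log,
because deformable corrections rescale structures and hence bias
measurements made on the warped material. A registration whose metric
ends worse than it started raises an error with the metric values.

## Stereological counting

* **Point grids.** 16 fine points (4×4 lattice) and 2 coarse points (an
  evenly spread subset of the fine lattice; factor = 16/2 = 8 fine per
  coarse). Point hits resolve to the nearest pixel centre — the raster is
  the ground truth, no sub-pixel adjudication.
* **Cycloids.** 36 half-cycloid arcs (6×6 lattice, alternating mirroring)
  of generating-circle radius 26 µm; each arc has length 4r and two end
  points, so the test-line length per end point is 2r = 52 µm. The minor
  axis (2r span) is parallel to the vertical axis, giving the
  sine-weighted orientation density required on vertical sections. All
  probes share one uniform random offset per field; systematic field
  tiling keeps border-straddling fields (probes falling outside the
  section count nothing) — discarding them would over-sample the interior.
* **Intersections.** I counts sign changes of the *bilinearly
  interpolated* lumen-class indicator (threshold 0.5) along each arc,
  sampled at one-pixel arc-length steps, censored where the arc leaves
  the image. Tangential grazes contribute nothing by construction. The
  interpolation and step size act as boundary anti-aliasing: sampling a
  nearest-pixel indicator at sub-pixel steps measures the staircase
  perimeter of the digitised boundary, which exceeds the smooth surface
  by up to 4/π (measured +25 % on a digitised sphere); bilinear
  membership at one-pixel steps reduces the residual to ≈ +4 % at a tube
  radius of 21 px and < 1 % at 43 px.
* **Guard bands.** Probe patterns are positioned by one random offset
  modulo the field, so an arc can protrude past the far field edge. A
  cropped field window therefore carries a guard band (one arc span) on
  its far sides: without guard tissue, a partially visible arc
  contributes intersections but no end points, which measurably deflates
  the wall-thickness estimate.
* **Pooling.** All estimators are ratios of summed counts (counts pooled
  over fields before dividing), the standard stereological practice;
  per-field reference counts enter the denominator once per field.
  Undefined quantities (zero wall hits, zero intersections) are reported
  as missing, never silently zero.
* **Finite-tube end faces.** The luminal surface of a rasterised *finite*
  cylinder includes its two end disks — they are real boundary of the
  digital object even though the closed form 2πrL ignores them (a 7.5 %
  surface difference at r/L = 0.075, visible as a T(wall) deficit).
  Validation phantoms for surface-based quantities therefore use tubes
  spanning the whole volume, and users measuring vessels cut off inside
  the volume should cap them (lids) or accept the corresponding surface
  contribution.

## Numerical choices and degenerate inputs

* Seeds: every stochastic operation takes an explicit seed; the pipeline
  derives per-stage streams from one run seed.
* Time step for diffusion > 1/2^(d+1) raises; empty masks, empty plans,
  empty stacks, zero reference counts raise with specific messages.
* Tolerances used by the validation suite: rasterised vs analytic volume
  2 % (cylinder at ≥ 6-voxel radius), spread labels vs analytic 5 %
  (junction territory), wall thickness 5 % at 200 fields, Cavalieri mean
  1 % over the exhaustive offset sweep, affine landmark recovery 1 px.
* Problem sizes: the default phantom rasterises to ≈ 12 M voxels at
  7 µm; the pipeline demo uses 9 µm (≈ 5.6 M voxels); random-tree
  experiments choose spacing = min(radius)/3 so the thinnest tube spans
  ≥ 3 voxels.

## Known limitations

* The skeleton-based generation recovery assumes the monopodial dominance
  margin; trees violating it (a lateral subtree longer than the remaining
  trunk, conceivable near an organ base) would need the manual override
  table, exactly as the semi-manual original procedure would.
* Thinning of tubes at < 3 voxel radius is unreliable; choose finer
  spacing rather than trusting pruning to clean up.
* The intersection counter's residual digitisation bias (few percent at
  small tube radii) is inherent to counting on rasters; it shrinks with
  resolution.
* Volume-to-substack registration is validated for moderate
  misalignments (≤ 10° rotation, 10 % scale/shear); gross initial
  misalignment needs a manual initial transform.
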