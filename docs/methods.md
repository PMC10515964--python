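# Methods

`devatlas` re-implements, at desk scale, the computational machinery used to
build a developmental mouse brain common coordinate framework: stitching of
light-sheet tile stacks, symmetric multi-contrast template construction,
landmark/mask-assisted multimodal registration, reconstruction of sparse 2-D
in situ hybridization (ISH) section series into template space, hierarchical
anatomical ontologies with annotation volumes, and regional quantification.
All pipelines run on synthetic phantoms produced by `devatlas.synthetic`;
this note states the models, the parameters that matter, the numerical
choices, and what the synthetic fixtures do and do not establish.

## Coordinate conventions

Voxel indices are 0-based and node-centered: the world coordinate of index
`i` is `origin + i * spacing`. The canonical internal orientation is RAS
(axis 0 left→right), chosen because midsagittal reflection needs an
unambiguous left–right axis; loaders reorient NIfTI inputs on entry and an
`orientation` override exists for headerless formats. The internal length
unit is mm; µm inputs are converted at load and the original tag is kept in
a JSON sidecar so round-trips are lossless.

A `Transform` is the standard pull-back map `m(x) = A x + u(x)` from fixed-
world to moving-world coordinates, with the displacement field `u` stored in
world units on the fixed grid so that it survives grid resampling. Inverses
of displacement fields are computed by damped fixed-point iteration;
`compose_transforms` chains point mappings in list order (matrix `B @ A` for
`[A, B]`), evaluating nonlinear compositions numerically on a reference
grid.

## Registration engine

The built-in engine is deliberately small and fully deterministic:

* **Linear stage** — multiresolution (default shrink factors 4, 2, each
  level smoothed and resampled onto a *centered* coarse grid, which keeps
  downsampling equivariant under grid reflection — the symmetric-template
  property depends on this). Translation is initialized by phase
  correlation, then Powell descent runs on up to 12 parameters
  (translation, rotation, log-scale, shear) of the selected metric. A final
  full-resolution phase-correlation polish removes the fraction-of-a-voxel
  bias that double interpolation at coarse levels can leave.
* **Nonlinear stage** — vector-valued demons: per iteration the update is
  `-(Σ w_c d_c ∇f_c) / (Σ w_c (|∇f_c|² + d_c²/s²))` summed over channels,
  Gaussian-regularized both as a fluid (update smoothing, σ = 1.0 voxel)
  and as a diffusion (field smoothing, σ = 1.2). The shared normalization
  means the stated channel weights weight the *metric*, not per-channel
  step sizes — a channel with no local signal exerts no pull. Out-of-field
  samples use nearest-edge extension; zero fill would fabricate strong
  gradients for channels whose background is not zero (distance maps).
* **Metrics** — mean squared error; mutual information from a 32-bin joint
  histogram with Parzen smoothing (cross-modality pairs are first remapped
  through the histogram's conditional-mean transfer function so demons
  operates on matched intensities); cross-correlation, implemented for the
  nonlinear stage as demons on locally normalized images.
* **Guarantee** — if the optimized transform scores worse than identity
  under the requested metric, identity is returned, so registration can
  never actively harm an aligned pair.

Iteration counts and convergence thresholds are configuration, not claims;
the defaults (levels 4/2/1 with 60/40/20 demons iterations) were chosen for
64³-scale volumes. An external backend can be plugged in wherever a
`(fixed, moving, spec) -> Transform` callable is accepted; a SimpleITK
wrapper in the test suite checks that the built-in engine and the external
one pass the same recovery thresholds.

## Tile stitching

Tiles are read exactly twice, and a counting reader makes that testable.
Pass 1 collects, per tile and z-block (default 32 slices), maximum-intensity
projections of the four outer edge strips plus a per-slice strip profile
(mean across the strip width, kept per in-plane position). Alignment then
proceeds without touching raw data:

1. **In-plane offsets** first: whole-stack strip MIPs — invariant to the
   still-unknown z offsets — are matched by direct normalized
   cross-correlation over a shift window (FFT correlation is avoided: thin
   strips alias the shift modulo their width). Per-block estimates may only
   deviate from the whole-stack answer on clear evidence. Pairwise offsets
   are reconciled by weighted least squares over the tile graph with
   iterative outlier down-weighting; the (0,0) tile anchors the gauge.
2. **z offsets** per column: facing strip profiles are differenced along z
   and correlated with the in-plane shift fixed from step 1; the top/bottom
   seam profiles of the same tile pair are pooled in as additional rows.
   Scores are Fisher-z transformed before pooling so widely-overlapping
   (hence always-high-NCC) rows do not drown out the discriminating ones.
   Because a slow drift makes the relative shift a step function, the shift
   path is solved by dynamic programming over short windows with a
   transition penalty; windows whose comparison region is clipped by the
   stack boundary are flagged and left to the curve fit.
3. **Curve fitting**: per-slice offsets come from a fit through the block
   offsets, with model complexity (constant … cubic, interpolating spline)
   chosen by leave-one-out error and a 20 % improvement hurdle — an
   interpolating curve through noisy constant offsets oscillates, and its
   extrapolated tails are clamped. A Hampel filter removes isolated block
   outliers first.

Fusion places tiles at integer offsets (linear feathering across overlaps,
width 8 voxels); voxels covered by exactly one tile are written directly
from their source so single-coverage regions are bit-identical to it.
Iteration order is fixed, making fusion independent of tile-list order.

If the nominal overlap exceeds the collected edge width, jittered facing
strips can share *no* physical content and no estimator can recover their
offset; `stitch` therefore widens the default edge fraction to the overlap
plus the jitter search margin (the classic 10 % default is kept when it
suffices, and remains available explicitly).

## Symmetric template construction

Starting from the voxel-wise mean of the (intensity-rescaled) inputs, each
iteration registers every input to the current template, averages the
warped images, and applies the inverse of the average transform — averaged
in the displacement domain, with the affine part averaged in the matrix-log
domain — to the intensity average, which removes the cohort-mean shape bias
from the template. Symmetry comes from construction: every subject is
duplicated and reflected across the grid's x-center plane before building.

Two details matter in practice:

* The returned per-subject transforms are composed with the final inverse
  average, so they map the *returned* template to each subject. This also
  makes the voxel-wise mean of the final displacement fields vanish
  identically — the property the average-transform update exists to
  enforce — and it is required for contrast propagation to be consistent.
* An unsharp-masking step (strength scaled by the measured warp scatter)
  counteracts the blur that averaging residually-misaligned images
  introduces; a perfectly aligned cohort receives none. The per-iteration
  mean-update record can plateau at the level of the registration
  estimator's profile-shape bias rather than decaying to zero; the
  composition above absorbs that bias into the template/transform pair
  rather than leaving it in the fields.

Sibling contrasts are never re-registered: the final warps are reused and
the warped contrasts averaged, so propagation is exactly linear in contrast
intensity. The staged multiresolution build (e.g. spacings 4 → 2 → 1)
initializes each stage from the upsampled previous template. Default
iteration count is 4 with an early stop when the mean update falls below
0.1 voxel.

## Mask-assisted multimodal alignment

The initial cross-modality registration uses mutual information, linear
then nonlinear. When internal structures remain misaligned although the
outer surface matches, region masks covering them (their identification is
a manual inspection step; the masks are inputs) are subtracted from the
whole-brain masks. Stage 1 registers the modified masks linearly — on
signed Euclidean distance maps by default, saturated at a 6-voxel capture
radius so forces concentrate in a band around the carved boundaries; a flag
switches to raw-mask MI. Stage 2 runs the nonlinear engine on two equally
weighted channels, the image and the modified-mask distance map, with a
generous coarse-level schedule (the carved boundary must close the
structure gap at coarse scale before the image term starts assisting); the
result composes both stages.

The stereotaxic frame is rigid only: bregma maps to the origin and the
bregma→lambda direction to −AP; the dorsoventral zero sits at the supplied
bregma point since only brain volumes, not skulls, are handled. Annotation
backprojection applies the inverse transform with nearest-neighbor
interpolation.

## ISH section-to-volume mapping

The seven-step chain: (1) intensity-invert each section and resample to a
square working resolution (512² by default; smaller sizes for desk-scale
runs), padding to preserve aspect, with one intensity scale for the whole
series — per-section stretching would fabricate signal on empty sections;
(2) stack the sections and fill missing ones by a spline along z fitted per
pixel column through the present sections (cubic by default, hence C²
along z; a full 3-D scattered fit stays out of scope because the per-column
fit is the minimal reading of slice infill); (3) align the reference
template to the reconstruction linearly; (4) register each section to its
reference plane in 2-D under mutual information — short and heavily
regularized, because the cross-contrast signal away from boundaries is
weak and the step exists to undo sectioning jitter, not to morph expression
patterns into the reference; if the stack's adjacent-section correlation
would drop, the refinement is rejected; (5) register the template to the
corrected reconstruction nonlinearly; (6) carry the sample into template
space with the inverse; (7) split by gene, re-infill each gene's sections,
and warp with the step-6 transform. Coronal vs sagittal series are a plane-
axis parameter; mixed series are rejected.

## Ontology and annotation volumes

Regions form a tree with 16-bit labels. Ids below 18000 are legacy labels
kept verbatim; 18000–19999 is reserved for new structures (the allocator
refuses to exceed it); legacy 32-bit ids that do not fit in 16 bits map to
`20000 + id32 mod 10000` — the exact arithmetic form of taking the last
four decimal digits and prefixing a 2, preserving leading zeros. Collisions
raise rather than renumber silently. The validator reports exhaustiveness
violations (mask voxels labeled 0), labels missing from the ontology, and
labels outside the mask. Aggregation replaces labels by their ancestor at a
target depth and conserves labeled-voxel counts exactly; cross-atlas label
comparison is an integer contingency table whose marginals equal region
volumes by construction, exportable in long form for Sankey renderers (log
scaling is the renderer's business).

## Quantification

Classified binary volumes are reduced by exact block summation (each coarse
voxel holds its block's positive count; totals conserved). Relative
occupancy per region is `positives / (region voxels x per-bin capacity)`,
so 1.0 means fully occupied at classification resolution — the convention
fixes the mixed-resolution ratio explicitly. Count volumes warped to a
template use linear interpolation scaled by the warp's Jacobian determinant
when conservation matters; a flag disables it. Cells are assigned to
regions by flooring world coordinates (deterministic tie-break); the
proportion matrix divides per-region counts by subclass totals, with an
exact-`Fraction` mode in which columns sum to one identically. The
magnetization transfer ratio is the closed form `MTR = 1 − MT/M0`, with
non-positive `M0` masked.

## Synthetic fixtures

Every generator is a pure function of its parameters and an explicit seed.
The phantoms are gaussian-blob "brains": an ellipsoidal envelope with
structures generated in mirror pairs, a small `asymmetry` parameter
(default a few percent of the grid) jittering one member of each pair —
brains are near-mirror-symmetric, and a strongly asymmetric phantom makes
symmetrized template construction chase mirror ghosts that no real cohort
contains. Stitching fixtures use a texture phantom with many small blobs
(3–12 voxels) because strip correlation locks onto fine structure, not
gross anatomy. Cohorts are made by warping a phantom with centered,
Gaussian-smoothed random fields whose true values are returned for recovery
scoring; tile grids are cut with integer per-tile jitter and per-column
rounded linear z-drift (column 0 and tile (0,0) stay clean — inter-tile
alignment can only observe offsets relative to an anchor, so the truth is
expressed in the same gauge); ISH series are sampled, dropped, jittered and
inverted; ontologies are nested Voronoi parcellations in which children
tile their parent exactly, with an option to punch seeded holes for
validator tests.

What passing these tests shows: the algorithms recover known ground truth
under controlled noise, drift and sparsity at the stated scales. What they
do not show: behavior under real microscope artifacts (illumination
gradients, refraction, tissue tearing), real cross-modality intensity
relationships, or real anatomical variability; the phantom deformation
model is smooth and small-strain, and phantom structures are simpler than
tissue.

## Problem sizes and defaults

The shipped configuration targets a desk-scale study: stitching on a 3×3
grid of 128³-voxel tiles (15 % overlap, jitter ≤ 5 voxels, linear z-drift
up to 3 slices), template construction on 6-member cohorts at 64³
symmetrized to 12, mask-assisted alignment and registration recovery at
48³, and the ISH chain at 64×64 working resolution with 20 % dropped
sections and ±4 px jitter. These sizes exercise every code path the
full-scale pipelines use; only the grids are smaller.
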