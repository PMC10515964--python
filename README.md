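# devatlas

A desk-scale toolkit for the computational side of developmental mouse
brain atlas construction. Building a common coordinate framework (CCF) for
the developing brain takes a chain of image-processing machinery that is
usually buried in cluster pipelines; `devatlas` implements that chain as a
tested Python library small enough to run — and verify against ground
truth — on a laptop:

* **Tile stitching** — light-sheet acquisitions arrive as overlapping tile
  stacks; a two-pass algorithm (edge-strip maximum-intensity projections
  and per-slice profiles, then curve-fitted per-slice offsets) reassembles
  them while reading the raw data exactly twice.
* **Symmetric template construction** — the groupwise loop
  `register → average → apply the inverse average transform`, with every
  subject duplicated and mirrored across the midsagittal plane so the
  fixed point is left–right symmetric; per-subject warps are reused to
  build templates for sibling MRI contrasts (T2w, FA, DWI, ADC, …).
* **Mask-assisted multimodal registration** — when mutual-information
  registration between modalities leaves internal structures misaligned,
  region masks covering them are subtracted from the brain masks and the
  carved masks join the nonlinear alignment as an equally weighted channel.
  Includes stereotaxic (bregma/lambda) frames and inverse-warp label
  backprojection.
* **2-D section → 3-D template mapping** — sparse, jittered in situ
  hybridization section series are inverted, stacked, spline-infilled
  along z, corrected slice-by-slice against a reference, and carried into
  template space by the inverse of a template→sample registration, per
  gene.
* **Ontology & quantification** — hierarchical region trees with a 16-bit
  label scheme (legacy 32-bit ids map to `20000 + id mod 10000`),
  annotation validation (mutually exclusive, exhaustive), level
  aggregation, cross-atlas label crosstabs, count-preserving downsampling
  of classified voxels, per-region relative occupancy, cell-type
  proportion matrices, and the magnetization transfer ratio
  `MTR = 1 − MT/M0`.
* **Synthetic fixtures** — every pipeline is exercised by seeded phantom
  generators that return their ground truth, so recovery is measured, not
  assumed.

The registration engine underneath is self-contained (multiresolution
affine + vector-valued demons with MSE / mutual-information /
local-correlation behavior) and exposed behind a one-callable contract, so
an external toolkit can be plugged in where desired.

## Worked example

`examples/` holds one short script per capability. Mask-assisted
registration, the method's centerpiece:

```bash
$ python examples/03_align_multimodal.py
structure centroid error, image-only:    5.28 voxels
structure centroid error, mask-assisted: 0.02 voxels
improvement factor: 328.0x
whole-brain Dice: 0.8819 -> 0.9919
```

The fixture is a pair of phantom brains whose outer surfaces match (up to a
scale difference) while an internal, low-contrast structure sits 6 voxels
apart — the situation in which whole-image registration quietly fails.
Image-only alignment leaves the structure 5.3 voxels off target; after
carving the structure's region out of both brain masks and registering
image + modified mask as equally weighted channels, the residual is 0.02
voxels, and the whole-brain Dice overlap improves rather than degrades.

Template construction, on a 6-subject cohort symmetrized to 12:

```bash
$ python examples/02_build_template.py
cohort size after symmetrization: 12
template mirror asymmetry: 0.0000 %
|mean final displacement|_inf: 0.0001 voxels
mean update per iteration: [0.171, 0.868, 0.95]
```

Zero asymmetry is by construction (reflection-equivariant processing of a
mirrored cohort); the vanishing mean displacement says the returned
template sits at the cohort's mean shape, with the mean component of the
per-subject warps absorbed into the template by the average-transform
update.

The same stages are available as `devatlas <stitch|build-template|
align-multimodal|stereotaxic|ish-map|ontology|occupancy|celltypes|synth|
convert|resample|run>` subcommands, each writing a YAML run manifest and a
JSON-lines log next to its outputs; `devatlas run manifest.yaml` replays a
stage from its manifest.

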