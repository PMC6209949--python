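# Methods

`weedmap` implements a site-specific weed management (SSWM) pipeline for
paddy rice: per-pixel classification of high-resolution aerial imagery into
{others, rice, weeds}, assembly of a whole-field weed cover map, and
derivation of a grid-based prescription map for a variable-rate sprayer.
This note records the models, the synthetic study conditions, and the
numerical and design choices a maintainer would want to know.

## Field mapping workflows

Two workflows produce the whole-field weed cover map:

1. **mosaic-then-label** — the field raster (an ortho-mosaic or the
   assembled synthetic master scene) is decomposed into square patches
   (1000×1000 px at full field scale; the desk-scale default is 256 px),
   each patch is scored by the network, and the predicted label tiles are
   stitched back. The decomposition is a pure partition (row-major,
   0-based, top-left origin, half-open windows), so stitch∘split is the
   identity; label padding uses the ignore code 255 and image padding the
   nodata value, so partial edge tiles never fabricate class pixels.
2. **label-then-mosaic** — each collected image is scored in place and the
   per-image *score maps* are mosaicked using their geotransforms. The
   merge rule is the mean of per-class scores over all covering images,
   then argmax, with ties broken toward the lowest class code. The rule is
   deterministic and permutation-invariant, and with a zero-overlap flight
   set whose images coincide with the tile grid the two workflows are
   pixel-identical by construction (asserted in the tests).

Geometry is pure translation at a shared ground sampling distance (GSD);
there is no resampling, bundle adjustment or orthorectification — synthetic
flight images are axis-aligned crops of one master scene, which is what
makes the workflow-equivalence check exact.

## Segmentation models

Both architectures share a VGG-16-style backbone with fully connected
layers converted to convolutions (fc6 a 7×7 convolution, fc7/fc8 1×1), so
an H×W image maps end-to-end to an H×W×K score map.

* **FCN-8s** (baseline): five 2×2 max-pooling stages, fc8 at output
  stride 32, skip fusion of fc8 with 1×1-scored copies of pool5 and pool4
  (the fusion taps are configurable), then upsampling back to input
  resolution.
* **FCN-4s** (modified): the fifth pooling operation and all skip fusions
  are removed, so the backbone stops at stride 16 and a single ×16
  transposed convolution restores input resolution; fc6/fc7 carry 2048
  feature maps instead of 4096. The name is kept for continuity with the
  source architecture family even though the coarsest stride is 16. fc6
  stays a 7×7 convolution — the minimal-change reading of "remove pool5".
  At equal width scale FCN-4s has strictly fewer parameters than FCN-8s
  (narrower head, no skip heads); this is asserted numerically.

Upsampling layers are transposed convolutions initialised to the exact
bilinear interpolation kernel; by default they stay learnable
(`learned_bilinear`), with `fixed_bilinear` available for exactness tests.
Non-divisible input sizes are reflect-padded to the output stride and the
scores cropped back, avoiding edge-class artefacts from zero padding.

A `backbone_scale` knob multiplies every channel width (`max(1,
round(w·scale))`), so the full architecture (scale 1) and a CPU-sized
replica (scale 1/8: widths 8…64, fc 256) share one code path and one set of
contracts. Pretrained backbone weights are an optional input accepted only
at scale 1; nothing in the package depends on them.

### The compute engine

No deep-learning framework is part of the dependency set; the models run on
a compact numpy engine (`weedmap.nn`) implementing exactly the required
operations — im2col convolution, 2×2 max pooling, ReLU, strided transposed
convolution, softmax cross-entropy with an ignore index, SGD with momentum
and Adam — with hand-derived backward passes. Every layer and the composed
models are validated against central finite differences in the test suite.
All computation is float32, NCHW, and deterministic: two forwards with the
same weights and input are bit-identical, which the checkpoint round-trip
and workflow-equivalence contracts rely on. Checkpoints are `.npz` weight
archives with a JSON architecture sidecar.

## Training regime

Training minimises mean per-pixel softmax cross-entropy over non-ignore
pixels (adding ignore-labelled pixels to a batch provably leaves the loss
unchanged). Defaults, chosen for *from-scratch* training on synthetic
scenes:

| parameter | default | why |
|---|---|---|
| optimizer | Adam, lr 2e-3 | from-scratch plateau escape (below) |
| weight decay | 5e-4, decoupled, weights only | standard VGG-era value |
| SGD alternative | momentum 0.9 | available via `optimizer="sgd"` for fine-tuning setups |
| batch size | 1 | maximises update count on small patch sets |
| epochs | 10 | benchmark budget; best epoch selected by validation mean IU |
| augmentation | horizontal/vertical flips | rotations would break row-structure cues |
| class weighting | none | exposed but off |

Two choices matter for trainability and were selected after diagnosing a
persistent failure mode: with random He initialisation, a deep untrained
VGG stack *destroys* the colour signal (a linear probe on random stride-16
features reaches ~0.83 versus ~0.998 on raw block mean colours), and both
SGD and Adam then sit at the class-prior solution for hundreds of updates.
The backbone therefore defaults to **Dirac (identity-preserving)
initialisation** — each 3×3 kernel is a centre-tap identity on channel
`o mod in_ch` plus 0.3×He noise — which passes the input colours through to
depth at initialisation while leaving the network free to learn texture.
With this init plus Adam, the reference benchmark converges in a few
epochs; with He+SGD it does not move off the prior within the epoch budget.
He initialisation remains available (`backbone_init="he"`).

Validation selection: the per-epoch log records training loss, validation
overall accuracy and validation mean IU; the returned checkpoint is the
epoch with the highest validation mean IU.

## Evaluation

All metrics derive from a 3×3 confusion matrix (rows = ground truth,
columns = prediction); ground-truth ignore pixels contribute to no cell.
Overall accuracy is trace/total. Mean IU averages `c_ii/(row_i+col_i−c_ii)`
over classes with `row_i+col_i > 0` — classes absent from both ground truth
and prediction are excluded, which keeps two-class synthetic checks
meaningful. The row-normalised matrix reproduces per-class recognition
rates. All three are cross-checked against brute-force per-pixel loops on
random maps.

## Prescription maps

The weed cover map is partitioned into square cells of `cell_size_m`
(default 0.5 m — the common sprayer resolution; at 0.5 cm GSD each cell is
100×100 px). Cell coverage = weed pixels / non-ignore pixels in the cell;
cells with no non-ignore pixel are invalid and excluded everywhere. A cell
is treated iff coverage is **strictly greater** than the threshold, so
τ = 0 treats every cell containing a single weed pixel — the conservative
reading that minimises missed infestations. Consequences that are proven
as properties: treated fraction is non-increasing in the threshold, and
`herbicide saving = 1 − P_treatment` exactly. Prescription-map accuracy is
the fraction of jointly valid cells whose treatment decision matches the
reference map derived from ground truth. The default sweep evaluates
τ ∈ {0.00, 0.05, 0.10, 0.15, 0.20, 0.25}. Edge cells of maps that do not
divide evenly are included with coverage over their actual pixels.

## Synthetic study conditions

The generator emulates what the method needs from a real paddy scene, not
its radiometry:

* **geometry** — 0.5 cm/pixel GSD; the reference benchmark uses a
  2000×2000 px field (10×10 m) and 256×256 px training patches;
* **weed patches** — Gaussian noise smoothed at a characteristic patch
  radius (default 40 px ≈ 20 cm; a free parameter, not a claim about any
  particular field) and thresholded at the exact pixel count matching the
  target coverage, so realized coverage equals the target up to integer
  rounding;
* **non-vegetation** — margins plus scattered gaps from a border-biased
  smoothed noise field, again count-exact (default 5%);
* **appearance** — per-class mean colours, a smooth illumination field,
  and per-pixel texture noise (σ = 9 DN); the **between-date shift** is a
  deterministic channel-wise gain/offset plus re-drawn texture noise.
  Class mean colours stay pairwise separated by ≥30 DN, which is what makes
  the ten-epoch training benchmark feasible;
* **flight sets** — overlapping crops of the master scene with exact
  geotransforms, so overlap pixels are byte-identical across images.

Everything is a pure function of the `FieldSpec` (one seeded generator
passed down; no global random state): identical specs give bit-identical
scenes.

What passing on these scenes does *not* show: robustness to photogrammetric
blur and seam artefacts, radiometric variation, rolling-shutter/lens
distortion, or weeds that resemble rice in colour — the synthetic classes
are separable by construction, so the benchmark validates the pipeline's
mechanics and learnability, not field-condition performance.

## Reference benchmark

`weedmap.experiments.cross_date_benchmark` trains FCN-4s (backbone scale
1/8) on the 64 patches of a date-1 scene and evaluates on the full date-2
field (different seed, appearance shift 0.5), then derives the prescription
sweep from the predicted map. The problem sizes (2000×2000 field, 256 px
patches, ≤10 epochs, 1/8-width backbone) are the package's desk-scale
reference conditions; a full-scale run only changes the configuration.

## Known limitations

* Overlap blending in the label-then-mosaic workflow is the package's own
  mean-score rule; commercial photogrammetry suites do not document theirs,
  so no equivalence with them is claimed.
* No dropout: the original VGG-era heads used it, but it would break the
  bit-determinism contracts and matters little at desk scale.
* The engine is single-process CPU; full-scale (scale-1) training is
  architecturally supported but not practical without hardware
  acceleration.
* GeoTIFF is not read or written; geo I/O is PNG + ESRI world file, which
  preserves the needed affine information for axis-aligned north-up
  rasters but no CRS metadata.
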