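# Methods

## Problem and pipeline

Histology images from the 10x Visium platform carry a printed square frame
of small circular fiducial markers used for spot alignment.  For image
analysis (registration, cell segmentation, visualization) those markers are
artifacts: they sit on the background, frequently overlap the tissue
section, and confuse downstream tools.  `slideprep` cleans such images in
four stages run in fixed order:

1. **Marker detection.**  A customized encoder-decoder segmentation
   network predicts a per-pixel marker probability map, binarized at 0.5.
2. **Restoration.**  The masked marker pixels are filled by inpainting
   from surrounding context; unmasked pixels are never modified.
3. **Tissue detection.**  A lightweight saliency network separates tissue
   from background, producing a probability mask and an RGBA blend.
4. **Segregation.**  The tissue probability mask is binarized at 0.8,
   8-connected components are labeled, and components under 20 px are
   discarded.

Stages 1-2 can be switched off for platforms without fiducial markers.

## The marker-detection network

The architecture is a U-Net variant tuned for small, globally distributed
circular structures.  Encoder channel widths are 3 → 32 → 64 → 128 → 256
(four 4×4 stride-2 downsampling convolutions); decoder widths are
256 → 128 → 64 → 32 → 16 (four 4×4 stride-2 transposed convolutions).
Deviations from a plain U-Net, all load-bearing for this task:

* the first encoder block adds a 3×3 refinement convolution and uses
  neither normalization nor dropout, preserving the fine detail that tiny
  rings depend on;
* the deepest encoder block adds a 3×3 refinement convolution and the
  bottleneck stacks two further 3×3 convolutions, widening the receptive
  field so the global square-frame prior can be captured;
* skip connections are *additive* (the deepest one through a learned 1×1
  projection so channel counts match); the final decoder output (16
  channels) is concatenated with the 3 input channels, because a 19-channel
  pre-head map cannot arise from addition;
* the head is a learnable 4×4 stride-1 convolution plus sigmoid, giving a
  full-resolution probability map.

Other fixed conventions: instance normalization without learned affine
parameters; dropout rate 0.5 in the blocks that use it (off at inference);
inputs scaled to [0, 1]; reflect-padding when dims are not divisible by 16.
The network and its backward pass are implemented directly in numpy
(im2col convolutions over BLAS matmuls); tests verify every layer and the
whole network against finite-difference gradients.

### Loss

Training minimizes `λ·L_dice + (1−λ)·L_focal` with λ = 0.9,
Dice smoothing ε = 1.0, focal class weight α = 0.95 and focusing exponent
γ = 3.  The Dice definition binarizes the prediction at 0.5; because that
step has no gradient, optimization uses the soft relaxation (probabilities
in place of the binarized mask) while reported Dice values keep the
binarized form.  Both traces are recorded during training
(`loss_trace_`, `hard_loss_trace_`).

### Difficulty-weighted sampling

Each slide's *marker overlap factor* is the fraction of its markers whose
centre lies in tissue.  Slides are classed hard (> 0.8), moderate
((0.3, 0.8]) or easy (< 0.3); a factor of exactly 0.3 falls to easy, the
complement of the strict "> 0.3" moderate bound.  Per epoch, hard slides
are drawn 3×, moderate 2×, easy 1×, in seeded shuffled order.

### Optimization and augmentation

Adam with learning rate 1e-4, β₁ = 0.5, β₂ = 0.999, batch size 1.
Augmentation per draw: left-right/up-down flips (p = 0.5 each), scaling in
[0.8, 1.0], rotation in [−10°, +10°] (image bilinear, mask
nearest-neighbour, shared transform), brightness in [0.5, 1.2] and
Gaussian blur with σ in [0, 1] (image only).

### Desk-scale profile

The full-scale recipe trains for 800 epochs on high-resolution sub-images
(`TrainConfig.paper_preset()`).  The package's defaults are a desk-scale
profile chosen so that training on synthetic corpora completes in minutes
on one CPU core: 200 epochs by default, and the end-to-end evaluation runs
train for 20 epochs on random 128-px crops (biased to contain at least one
marker pixel) of 256-px slides.  These sizes are the package's study
conditions, stated here once; they were fixed before the evaluation runs
and are not tuned per dataset.

## Restoration

The backend registry ships two classical, weight-free inpainters:
biharmonic-equation filling (scikit-image) as the default, and an
iterative harmonic (Laplacian relaxation) fill.  A learned model can be
registered as a drop-in backend.  The working mask is the detector output
dilated by 2 px so anti-aliased ring rims do not leak.  Large slides are
processed per mask component inside its bounding box plus a 64-px halo
(capped at a 1024-px patch); a component too large for the patch is
processed at full resolution with a warning.  A final compositing step
copies every unmasked pixel from the input, making the no-touch guarantee
unconditional.

## Tissue detection

The saliency backend reuses the marker network's block library at
shallower widths: the standard variant has encoder widths (16, 32, 64,
128), the compact variant (8, 16, 32, 64).  Images are resized to the
320×320 working size for inference and the saliency map is upsampled back
(bilinear).  If the first pass finds a tissue bounding box smaller than
100×100 px (original scale, from thresholding the probability at 0.5), the
image is re-run at a 1000×1000 working size with the compact variant; when
no foreground at all is found the second pass is skipped.  The backend is
*trained at its inference working size* (320 px) — training at a smaller
size leaves small stain speckles out of scale at inference and costs
component-count accuracy.  Training uses the same loop as the marker
network with class-balanced loss settings (α = 0.5, γ = 2), learning rate
1e-3 and 20 epochs; tissue-vs-background is a much easier task and
converges quickly.

## Segregation

Probability ≥ 0.8 is foreground (the threshold comparison is inclusive);
components are labeled with 8-connectivity, components under 20 px are
removed, and surviving labels are compacted to 1..K in raster-scan
first-encounter order (deterministic for tests).  Filtering happens before
compaction; the two orders are observationally equivalent.

## Synthetic slides

The generator (see `slideprep.synthetic`) renders, per seeded spec: a
light background with a smooth intensity field; one main tissue blob whose
radius is set from the quantile of marker-centre distances so that a
requested overlap factor is realized, plus optional disjoint extra blobs
(irregular Fourier-wobbled boundaries, pink/purple band-limited texture);
a square frame of dark anti-aliased marker rings (default 13 per side,
radius 4 px) with per-marker jitter and a smooth global elastic
deformation (coarse 4×4 random displacement grid, default amplitude 4 px);
and sparse purple stain speckles that act as circle-detector decoys.
Markers over tissue are drawn at reduced contrast — the feature that makes
high-overlap slides genuinely hard.  Ground truth (circles with in-tissue
flags, marker mask, tissue mask, component count) is emitted with each
sample, and a marker-free re-render of the identical scene provides an
exact oracle for restoration quality.

What the generator does **not** emulate: nuclei-level texture, scanner
illumination, slide-version-specific frame geometry, or the size of real
microscope scans.  Passing the synthetic evaluations demonstrates that the
machinery (architecture, losses, sampling, training loop, stitching,
thresholds) works end-to-end; it does not certify accuracy numbers on real
Visium images.

Difficulty strata draw target overlap factors from (0.85, 0.97) for hard,
(0.40, 0.72) for moderate and (0.0, 0.20) for easy — comfortably inside
the class boundaries so that rendering noise cannot flip a sample's
stratum; the corpus builder re-draws a sample (new sub-seed) if its
realized factor still lands outside the requested stratum.

## Evaluation suite

IoU (empty/empty defined as 1.0), boundary Hausdorff distance, perimeter
ratio, component-count difference, per-channel-averaged SSIM (11×11
Gaussian windows, σ = 1.5, standard constants), grayscale mutual
information (64 bins, natural log), multi-class Dice (classes absent from
both masks skipped), adjusted Rand index, nine morphology descriptors with
a mean-0/sd-1 standardization helper, centroid-rule cells-outside-tissue
counting, and extraction of vendor-overlay markers by red thresholding
(R > 180, G < 30, B < 30) plus circle detection.  Every discrete metric is
validated against an independent brute-force oracle (pixel loops,
recursive flood fill, contingency-table arithmetic) to 1e-9 on random
masks; the Hausdorff metric is the literal sup-inf form, not the
95th-percentile variant.

## Numerical and degenerate-input choices

* Hausdorff and perimeter ratio are NaN when a boundary is empty; callers
  decide how to aggregate.
* Mutual information of a constant image is exactly 0 (single occupied
  bin).
* The Hough baseline returns an empty annotation set on blank images.
* Otsu on a constant image returns an empty mask with a warning.
* A tile size exceeding the image extent degrades to a single full-image
  tile with a warning; overlapping tile predictions are averaged.
* Training aborts with a diagnostic if the loss becomes non-finite.
* All randomness flows from explicit integer seeds (`numpy` PCG64);
  repeated runs are bit-identical on one machine.

## Known limitations

* No GPU path; the numpy implementation is single-core and sized for
  thumbnail-scale slides, not microscope-scale scans.
* The classical inpainting backends produce smooth fills, not texture
  synthesis; behind heavy texture the fill is visibly blurred.
* The saliency backend is trained per corpus; no pretrained weights ship
  with the package.
* The small-tissue second pass relies on the first pass finding *some*
  foreground; a tissue region missed entirely at 320 px is not recovered.
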