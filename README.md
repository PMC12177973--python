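# slideprep

Cleaning pipeline for spatial-transcriptomics histology images.

10x Visium slides surround the tissue capture area with a printed square
frame of circular **fiducial markers**.  On the H&E image these markers
are artifacts: they litter the background, often overlap the tissue
section, and degrade downstream image analysis (registration, cell
segmentation, tissue-based imputation).  `slideprep` removes them and
prepares the image in four stages:

| stage | class | what it does |
|---|---|---|
| marker detection | `MarkerSegmenter` | encoder-decoder network predicts the marker mask M̂ |
| restoration | `Inpainter` | fills the masked pixels from surrounding context |
| tissue detection | `TissueDetector` | saliency network separates tissue from background (M̂ₜ) |
| segregation | `TissueSegregator` | labels disconnected tissue pieces (M̂ₛ) |

A seeded synthetic-slide generator (`slideprep.synthetic`) renders
Visium-like images with full ground truth — marker circles with in-tissue
flags, tissue masks, component counts — so every stage can be trained and
evaluated without external data, and `slideprep.metrics` implements the
evaluation suite (IoU, Hausdorff, perimeter ratio, component difference,
SSIM, mutual information, multi-class Dice, adjusted Rand index,
morphology features).

## The model

The detector is a U-Net-style network with encoder widths
3→32→64→128→256 and decoder widths 256→128→64→32→16, modified for small
globally-distributed circular structures: extra 3×3 refinement
convolutions in the first and deepest encoder blocks, a two-layer 3×3
bottleneck, additive skip connections (the deepest through a 1×1
projection), and concatenation of the input image onto the 16 decoder
channels so a learnable 4×4 head sees a 19-channel full-resolution map.
Training minimizes

    L = λ·L_dice + (1−λ)·L_focal,   λ = 0.9, ε = 1.0, α = 0.95, γ = 3

with Adam (lr 1e-4, β₁ = 0.5, β₂ = 0.999) and difficulty-weighted
sampling: slides whose marker *overlap factor* (fraction of markers inside
tissue) exceeds 0.8 appear 3× per epoch, factors in (0.3, 0.8] appear 2×.
The network and its backprop are implemented in numpy and gradient-checked
in the test suite.  See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from slideprep import (SyntheticSpec, generate_corpus, MarkerSegmenter,
                       Inpainter, TissueDetector, TissueSegregator)
from slideprep.marker import TrainConfig
from slideprep.metrics import iou

mix = {"hard": 0.25, "moderate": 0.25, "easy": 0.5}
train = generate_corpus(40, SyntheticSpec(), mix, seed=11)
test = generate_corpus(10, SyntheticSpec(), mix, seed=12)

det = MarkerSegmenter(train_config=TrainConfig(epochs=20, crop_size=128))
det.fit(train)
ious = [iou(det.predict(s.image), s.markers.mask) for s in test]
print("median marker IoU", np.median(ious))

s = test[0]
restored = Inpainter().inpaint_patched(s.image, det.predict(s.image))
tissue = TissueDetector(train_compact=False).fit(
    [(t.image, t.tissue_mask) for t in train[:20]])
labels = TissueSegregator().transform(tissue.predict_proba(restored))
print("tissue components", labels.max(), "true", s.n_tissue_components)
```

Output from this exact script (seeds as shown):

```
median marker IoU 0.8910318564395251
tissue components 1 true 1
```

i.e. the detector recovers ~89% pixel overlap with the gold marker masks
on held-out slides (the classical Hough-transform baseline reaches ~0.39
on the same slides), and the tissue stage recovers the generator's
disconnected-component count.

The same flow is available from the shell:

```bash
slideprep simulate --n 20 --seed 0 --out corpus/
slideprep train --corpus corpus/ --seed 0 --epochs 20 --out marker.npz
slideprep detect --image slide.png --checkpoint marker.npz --out mask.png
slideprep restore --image slide.png --mask mask.png --out clean.png
slideprep run --image slide.png --config cfg.yaml --out outdir/
```

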