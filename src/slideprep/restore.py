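"""Mask-conditioned image restoration (inpainting of marker regions).

Given the original image and the binary marker mask from the detection
stage, the masked pixels are replaced with content synthesized from the
surrounding context while every unmasked pixel is left bit-identical (a
final compositing step enforces this regardless of backend behaviour).

Backends are pluggable via a registry; the defaults are classical,
weight-free methods: ``"biharmonic"`` (scikit-image's biharmonic
equation solver) and ``"diffusion"`` (iterative Laplacian relaxation).
Large slides are handled patch-wise: each connected mask component is
inpainted inside its bounding box plus a surrounding halo of context.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.restoration import inpaint_biharmonic
from sklearn.base import BaseEstimator, TransformerMixin

from slideprep.io import InputError
from slideprep.synthetic import ConfigError

logger = logging.getLogger(__name__)

_EIGHT = np.ones((3, 3), dtype=int)

BACKENDS = {}


def register_backend(name):
    def deco(fn):
        BACKENDS[name] = fn
        return fn
    return deco


@register_backend("biharmonic")
def _biharmonic_fill(img_f: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = inpaint_biharmonic(img_f, mask.astype(bool), channel_axis=-1)
    return out


@register_backend("diffusion")
def _diffusion_fill(img_f: np.ndarray, mask: np.ndarray,
                    max_iter: int = 500, tol: float = 1e-3) -> np.ndarray:
    """Harmonic fill: Jacobi iteration of the Laplace equation on the hole."""
    out = img_f.copy()
    m = mask.astype(bool)
    if not m.any():
        return out
    # initialize hole pixels with the nearest outside value
    _, (ir, ic) = ndimage.distance_transform_edt(m, return_indices=True)
    out[m] = out[ir[m], ic[m]]
    for _ in range(max_iter):
        avg = (np.roll(out, 1, 0) + np.roll(out, -1, 0)
               + np.roll(out, 1, 1) + np.roll(out, -1, 1)) / 4.0
        delta = np.abs(avg[m] - out[m]).max()
        out[m] = avg[m]
        if delta < tol:
            break
    return out


@dataclass
class InpaintingRequest:
    image: np.ndarray           # uint8 (H, W, 3)
    mask: np.ndarray            # uint8 {0,1}, same H x W
    patch_size: int = 1024
    backend: str = "biharmonic"


class Inpainter(BaseEstimator, TransformerMixin):
    """Restoration stage as a stateless transformer.

    Parameters
    ----------
    backend : str
        Registered backend id ("biharmonic" or "diffusion").
    dilate : int
        Pixels of mask dilation before filling, so anti-aliased marker
        rims do not leak into the result.
    patch_size, halo : int
        Patch-based processing bounds for large images: each mask
        component is filled inside its bounding box plus ``halo`` px of
        context, capped at ``patch_size``.
    """

    def __init__(self, backend="biharmonic", dilate=2, patch_size=1024,
                 halo=64):
        self.backend = backend
        self.dilate = dilate
        self.patch_size = patch_size
        self.halo = halo

    def fit(self, X=None, y=None):
        return self

    def _backend_fn(self):
        if self.backend not in BACKENDS:
            raise ConfigError(f"unknown inpainting backend {self.backend!r}; "
                              f"registered: {sorted(BACKENDS)}")
        return BACKENDS[self.backend]

    def _prep(self, image, mask):
        image = np.asarray(image)
        mask = np.asarray(mask)
        if mask.shape != image.shape[:2]:
            raise InputError("mask dims must equal image dims")
        work = (mask > 0).astype(np.uint8)
        if work.all():
            raise InputError("mask covers the entire image; nothing to "
                             "borrow context from")
        if self.dilate > 0 and work.any():
            work = ndimage.binary_dilation(work, _EIGHT,
                                           iterations=self.dilate)
            work = work.astype(np.uint8)
        return image, (mask > 0), work

    def inpaint(self, image: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """Whole-image restoration; unmasked pixels stay bit-identical."""
        image, raw, work = self._prep(image, mask)
        if not raw.any():
            return image.copy()
        fn = self._backend_fn()
        filled = fn(image.astype(np.float64) / 255.0, work)
        out = image.copy()
        fill8 = np.clip(filled * 255.0, 0, 255).astype(np.uint8)
        out[work > 0] = fill8[work > 0]
        out[~(work > 0)] = image[~(work > 0)]  # compositing guarantee
        return out

    def inpaint_patched(self, image: np.ndarray, mask: np.ndarray,
                        patch_size: int | None = None,
                        halo: int | None = None) -> np.ndarray:
        """Component-wise restoration with a context halo.

        Equivalent to whole-image processing when the backend's support
        radius is below the halo; components too large for the patch are
        processed at full resolution (with a warning).
        """
        patch = patch_size or self.patch_size
        halo = self.halo if halo is None else halo
        if patch <= 2 * halo:
            raise ConfigError("patch size must exceed twice the halo")
        image, raw, work = self._prep(image, mask)
        if not raw.any():
            return image.copy()
        fn = self._backend_fn()
        h, w = work.shape
        labels, n = ndimage.label(work, structure=_EIGHT)
        out = image.copy()
        for sl in ndimage.find_objects(labels):
            comp_h = sl[0].stop - sl[0].start
            comp_w = sl[1].stop - sl[1].start
            if comp_h + 2 * halo > patch or comp_w + 2 * halo > patch:
                logger.warning("mask component larger than patch; "
                               "processing at full resolution")
                r0, r1, c0, c1 = 0, h, 0, w
            else:
                r0 = max(sl[0].start - halo, 0)
                r1 = min(sl[0].stop + halo, h)
                c0 = max(sl[1].start - halo, 0)
                c1 = min(sl[1].stop + halo, w)
            sub_mask = work[r0:r1, c0:c1]
            filled = fn(image[r0:r1, c0:c1].astype(np.float64) / 255.0,
                        sub_mask)
            fill8 = np.clip(filled * 255.0, 0, 255).astype(np.uint8)
            sel = sub_mask > 0
            out[r0:r1, c0:c1][sel] = fill8[sel]
        out[~(work > 0)] = image[~(work > 0)]
        return out

    def transform(self, X):
        """Transform (image, mask) pairs -> restored images."""
        return [self.inpaint_patched(img, mask) for img, mask in X]


def inpaint(request: InpaintingRequest) -> np.ndarray:
    """Functional entry point mirroring the stage contract."""
    inp = Inpainter(backend=request.backend, patch_size=request.patch_size)
    return inp.inpaint_patched(request.image, request.mask)
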