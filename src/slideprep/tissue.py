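"""Tissue detection: separate tissue from background on the restored image.

A lightweight trainable saliency network (the same encoder-decoder block
library as the marker detector, with shallower widths) predicts a tissue
probability mask.  Images are resized to a small working size (default
320 x 320) for the network and the saliency map is upsampled back to the
original resolution.  When the first pass finds only a small tissue extent
(bounding box under 100 x 100 px at original scale) the image is re-run at
a 1000 x 1000 working size with the compact model variant, which resolves
thin or tiny tissue structures better.

Two classical helpers complete the stage: Otsu thresholding as an
unsupervised baseline, and RGBA blending that encodes the tissue
probability in the alpha channel for visualization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.base import BaseEstimator

from slideprep.io import resize_image, resize_probability
from slideprep.nn import NetConfig
from slideprep.marker import (AugmentConfig, LossConfig, MarkerSegmenter,
                              TrainConfig)

logger = logging.getLogger(__name__)

VARIANT_WIDTHS = {
    "standard": {"encoder_widths": (16, 32, 64, 128),
                 "decoder_widths": (64, 32, 16, 8)},
    "compact": {"encoder_widths": (8, 16, 32, 64),
                "decoder_widths": (32, 16, 8, 8)},
}


@dataclass
class TissueDetectConfig:
    working_size: int = 320        # default network input resolution
    small_working_size: int = 1000  # second-pass resolution
    small_trigger_px: int = 100    # bbox side (original scale) under which
    # the second pass with the compact variant is taken
    variant: str = "standard"

    def dump(self) -> dict:
        return asdict(self)


@dataclass
class TissueResult:
    prob: np.ndarray    # (H, W) float in [0, 1], original resolution
    blend: np.ndarray   # (H, W, 4) uint8, alpha = round(255 * prob)
    second_pass: bool = False


def blend_rgba(img: np.ndarray, prob: np.ndarray) -> np.ndarray:
    """RGBA blend: RGB copied, alpha proportional to tissue probability."""
    if prob.shape != img.shape[:2]:
        raise ValueError("probability mask dims must match image dims")
    alpha = np.round(255.0 * np.clip(prob, 0, 1)).astype(np.uint8)
    return np.dstack([img, alpha])


def otsu_baseline(img: np.ndarray) -> np.ndarray:
    """Otsu thresholding baseline.

    Exhaustively searches the 0..255 threshold maximizing inter-class
    variance on the grayscale image; the darker (stained) class is
    foreground.  Constant images yield an empty mask with a warning.
    """
    gray = np.round(img[..., 0] * 0.299 + img[..., 1] * 0.587
                    + img[..., 2] * 0.114).astype(np.uint8) \
        if img.ndim == 3 else img.astype(np.uint8)
    hist = np.bincount(gray.ravel(), minlength=256).astype(np.float64)
    total = hist.sum()
    if np.count_nonzero(hist) < 2:
        warnings.warn("constant image: Otsu threshold undefined, "
                      "returning empty mask", stacklevel=2)
        return np.zeros(gray.shape, dtype=np.uint8)
    levels = np.arange(256, dtype=np.float64)
    best_t, best_var = 0, -1.0
    cum_n = np.cumsum(hist)
    cum_s = np.cumsum(hist * levels)
    mean_all = cum_s[-1] / total
    for t in range(255):
        n0 = cum_n[t]
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            continue
        mu0 = cum_s[t] / n0
        mu1 = (cum_s[-1] - cum_s[t]) / n1
        var = n0 * n1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return (gray <= best_t).astype(np.uint8)


class TissueDetector(BaseEstimator):
    """Salient-tissue detector, scikit-learn style.

    ``fit(images, masks)`` trains the saliency backend(s) on synthetic (or
    annotated) slides; ``predict_proba(img)`` returns the tissue
    probability mask at original resolution with the small-tissue
    second-pass rule applied; ``detect(img)`` additionally returns the
    RGBA blend.
    """

    def __init__(self, config=None, train_size=320, epochs=20,
                 learning_rate=1e-3, seed=0, train_compact=True):
        self.config = config
        self.train_size = train_size
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.seed = seed
        self.train_compact = train_compact

    def _cfg(self) -> TissueDetectConfig:
        return self.config or TissueDetectConfig()

    def config_dump(self) -> dict:
        return self._cfg().dump()

    def _make_backend(self, variant: str) -> MarkerSegmenter:
        widths = VARIANT_WIDTHS[variant]
        offset = {"standard": 0, "compact": 7}[variant]
        # tissue is roughly class-balanced, so no extreme focal weighting
        return MarkerSegmenter(
            net_config=NetConfig(seed=self.seed + offset, **widths),
            loss_config=LossConfig(alpha=0.5, gamma=2.0),
            train_config=TrainConfig(learning_rate=self.learning_rate,
                                     epochs=self.epochs, seed=self.seed,
                                     tile_size=self.train_size),
            augment_config=AugmentConfig(scale_range=(0.9, 1.0),
                                         rotation_range=(-5.0, 5.0),
                                         brightness_range=(0.8, 1.1),
                                         blur_sigma_range=(0.0, 0.5)),
        )

    def fit(self, X, y=None):
        """Train on slides.  ``X``: list of RGB images; ``y``: tissue masks."""
        if y is None:  # allow a list of (image, mask) pairs
            pairs = list(X)
        else:
            pairs = list(zip(X, y))
        corpus = [(resize_image(img, (self.train_size, self.train_size)),
                   _resize_binary(mask, self.train_size)) for img, mask in pairs]
        self.backend_ = self._make_backend("standard").fit(corpus)
        if self.train_compact:
            self.backend_compact_ = self._make_backend("compact").fit(corpus)
        else:
            self.backend_compact_ = None
        return self

    def _run_pass(self, img, working_size, backend):
        h, w = img.shape[:2]
        small = resize_image(img, (working_size, working_size))
        prob = backend.predict_proba(small, tile_size=working_size)
        return resize_probability(prob, (h, w))

    def predict_proba(self, img: np.ndarray) -> np.ndarray:
        result = self.detect(img)
        return result.prob

    def detect(self, img: np.ndarray) -> TissueResult:
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "backend_")
        cfg = self._cfg()
        prob = self._run_pass(img, cfg.working_size, self.backend_)
        second = False
        fg = prob > 0.5
        if fg.any():
            rows = np.flatnonzero(fg.any(axis=1))
            cols = np.flatnonzero(fg.any(axis=0))
            extent = (rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1)
            if (extent[0] < cfg.small_trigger_px
                    and extent[1] < cfg.small_trigger_px):
                backend = self.backend_compact_ or self.backend_
                which = "compact" if self.backend_compact_ else "standard"
                logger.info(
                    "tissue extent %sx%s px below %d px: second pass at "
                    "%d px working size (%s variant)", extent[0], extent[1],
                    cfg.small_trigger_px, cfg.small_working_size, which)
                prob = self._run_pass(img, cfg.small_working_size, backend)
                second = True
        return TissueResult(prob=prob, blend=blend_rgba(img, prob),
                            second_pass=second)

    def predict(self, img: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(img) >= threshold).astype(np.uint8)

    def save(self, path):
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "backend_")
        path = str(path)
        self.backend_.save(path)
        if self.backend_compact_ is not None:
            self.backend_compact_.save(_compact_path(path))

    @classmethod
    def load(cls, path) -> "TissueDetector":
        import os
        path = str(path)
        det = cls()
        det.backend_ = MarkerSegmenter.load(path)
        cpath = _compact_path(path)
        det.backend_compact_ = (MarkerSegmenter.load(cpath)
                                if os.path.exists(cpath) else None)
        return det


def _compact_path(path: str) -> str:
    root, ext = (path[:-4], path[-4:]) if path.endswith(".npz") else (path, "")
    return f"{root}.compact{ext}"


def _resize_binary(mask: np.ndarray, size: int) -> np.ndarray:
    from slideprep.io import resize_mask
    return resize_mask(mask.astype(np.uint8), (size, size))


def detect_tissue(img: np.ndarray, detector: TissueDetector,
                  cfg: TissueDetectConfig | None = None) -> TissueResult:
    """Functional wrapper around :meth:`TissueDetector.detect`."""
    if cfg is not None:
        detector = detector.set_params(config=cfg) if detector.config is not cfg \
            else detector
    return detector.detect(img)
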