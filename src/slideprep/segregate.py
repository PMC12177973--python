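"""Disconnected-tissue segregation.

Binarizes the tissue probability mask (default threshold 0.8), labels
8-connected components, removes components smaller than a preset area
(default 20 px) and compacts the surviving labels to 1..K in raster-scan
first-encounter order.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

_STRUCTS = {4: ndimage.generate_binary_structure(2, 1),
            8: ndimage.generate_binary_structure(2, 2)}


@dataclass
class SegregationConfig:
    threshold: float = 0.8
    min_area: int = 20
    connectivity: int = 8

    def dump(self) -> dict:
        return asdict(self)


def count_components(mask: np.ndarray, connectivity: int = 8) -> int:
    """Number of connected components in a binary mask."""
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be 4 or 8")
    return int(ndimage.label(mask > 0, structure=_STRUCTS[connectivity])[1])


def segregate(prob: np.ndarray, cfg: SegregationConfig | None = None) -> np.ndarray:
    """Labeled tissue mask from a probability mask.

    Pixels with probability >= threshold are foreground; components below
    the area floor are dropped; labels are renumbered 1..K in raster-scan
    order of first encounter.
    """
    cfg = cfg or SegregationConfig()
    fg = np.asarray(prob) >= cfg.threshold
    labels, n = ndimage.label(fg, structure=_STRUCTS[cfg.connectivity])
    if n == 0:
        return labels.astype(np.int32)
    areas = np.bincount(labels.ravel(), minlength=n + 1)
    keep = np.flatnonzero(areas >= cfg.min_area)
    keep = keep[keep > 0]
    remap = np.zeros(n + 1, dtype=np.int32)
    # scipy labels components in raster-scan first-encounter order already;
    # compacting in ascending label order preserves that order
    remap[keep] = np.arange(1, len(keep) + 1, dtype=np.int32)
    return remap[labels]


class TissueSegregator(BaseEstimator, TransformerMixin):
    """Segregation stage as a stateless transformer over probability masks."""

    def __init__(self, threshold=0.8, min_area=20, connectivity=8):
        self.threshold = threshold
        self.min_area = min_area
        self.connectivity = connectivity

    def _cfg(self):
        return SegregationConfig(threshold=self.threshold,
                                 min_area=self.min_area,
                                 connectivity=self.connectivity)

    def config_dump(self) -> dict:
        return self._cfg().dump()

    def fit(self, X=None, y=None):
        return self

    def transform(self, X):
        if isinstance(X, np.ndarray) and X.ndim == 2:
            return segregate(X, self._cfg())
        return [segregate(p, self._cfg()) for p in X]
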