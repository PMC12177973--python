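"""Segmentation evaluation metrics and morphology features.

Binary-mask metrics: IoU, Hausdorff distance between mask boundaries,
perimeter ratio, connected-component-count difference.  Image metrics:
per-channel-averaged SSIM and histogram mutual information.  Labeling
metrics: multi-class Dice and the adjusted Rand index.  Plus per-object
morphology descriptors with a standardization helper and the
cells-outside-tissue count.

Conventions (fixed because discretization is otherwise ambiguous):
boundary pixels are foreground pixels with at least one background
4-neighbour, and the boundary "length" is the count of such pixels; both
Hausdorff and the perimeter ratio use these same boundary sets.
``iou`` of two empty masks is 1.0 (both methods found nothing — perfect
agreement).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.measure import regionprops
from skimage.metrics import structural_similarity as _sk_ssim

from slideprep.io import InputError
from slideprep.segregate import count_components


@dataclass
class MetricReport:
    """The evaluation statistics for one prediction/gold pair."""

    iou: float | None = None
    hausdorff: float | None = None
    perim_ratio: float | None = None
    comp_diff: int | None = None
    ssim: float | None = None
    mutual_information: float | None = None
    dice: float | None = None
    ari: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}


def _check_shapes(p, g):
    if p.shape != g.shape:
        raise InputError(f"mask shapes differ: {p.shape} vs {g.shape}")


def iou(P: np.ndarray, G: np.ndarray) -> float:
    """Intersection over union of two binary masks; 1.0 when both empty."""
    _check_shapes(P, G)
    p = P > 0
    g = G > 0
    union = np.logical_or(p, g).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(p, g).sum() / union)


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """(n, 2) coordinates of foreground pixels with a background 4-neighbour."""
    m = np.asarray(mask) > 0
    if not m.any():
        return np.empty((0, 2), dtype=np.int64)
    er = ndimage.binary_erosion(m, structure=ndimage.generate_binary_structure(2, 1),
                                border_value=0)
    return np.argwhere(m & ~er)


def hausdorff(P: np.ndarray, G: np.ndarray) -> float:
    """Symmetric Hausdorff distance between the two mask boundaries."""
    _check_shapes(P, G)
    bp = boundary_pixels(P)
    bg = boundary_pixels(G)
    if len(bp) == 0 or len(bg) == 0:
        return math.nan
    d1 = cKDTree(bg).query(bp)[0].max()
    d2 = cKDTree(bp).query(bg)[0].max()
    return float(max(d1, d2))


def perimeter_ratio(P: np.ndarray, G: np.ndarray) -> float:
    """|boundary(P)| / |boundary(G)| in boundary-pixel counts."""
    _check_shapes(P, G)
    nb_g = len(boundary_pixels(G))
    if nb_g == 0:
        return math.nan
    return len(boundary_pixels(P)) / nb_g


def comp_diff(P: np.ndarray, G: np.ndarray, connectivity: int = 8) -> int:
    """Absolute difference in connected-component counts."""
    _check_shapes(P, G)
    return abs(count_components(P, connectivity) - count_components(G, connectivity))


def ssim(Ix: np.ndarray, Iy: np.ndarray) -> float:
    """Structural similarity, per channel, averaged over the 3 channels.

    Windows are 11 x 11 Gaussian-weighted (sigma 1.5) with the standard
    stability constants c1 = (0.01 L)^2, c2 = (0.03 L)^2, L = 255.
    """
    if Ix.shape != Iy.shape:
        raise InputError("images must share dimensions for SSIM")
    if Ix.ndim == 2:
        Ix = Ix[..., None]
        Iy = Iy[..., None]
    scores = [
        _sk_ssim(Ix[..., c].astype(np.float64), Iy[..., c].astype(np.float64),
                 data_range=255.0, gaussian_weights=True, sigma=1.5,
                 use_sample_covariance=False)
        for c in range(Ix.shape[2])
    ]
    return float(np.mean(scores))


def _to_gray(img: np.ndarray) -> np.ndarray:
    if img.ndim == 3:
        return img[..., 0] * 0.299 + img[..., 1] * 0.587 + img[..., 2] * 0.114
    return img.astype(np.float64)


def mutual_information(Ix: np.ndarray, Iy: np.ndarray, n_bins: int = 64) -> float:
    """Histogram mutual information (natural log) between two images.

    Intensities are converted to grayscale and binned into an
    ``n_bins`` x ``n_bins`` joint histogram normalized to a joint
    distribution.
    """
    if Ix.shape[:2] != Iy.shape[:2]:
        raise InputError("images must share dimensions for MI")
    x = _to_gray(Ix).ravel()
    y = _to_gray(Iy).ravel()
    joint, _, _ = np.histogram2d(x, y, bins=n_bins, range=[[0, 255], [0, 255]])
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float((pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])).sum())


def multiclass_dice(Ix: np.ndarray, Iy: np.ndarray, classes=None,
                    skip_absent: bool = True) -> float:
    """Mean per-class Dice overlap between two labelings.

    Classes absent from both masks are skipped by default (configurable);
    a class present in exactly one mask scores 0 for that class.
    """
    _check_shapes(np.asarray(Ix), np.asarray(Iy))
    Ix = np.asarray(Ix)
    Iy = np.asarray(Iy)
    if classes is None:
        classes = sorted(set(np.unique(Ix)) | set(np.unique(Iy)) - {0})
        classes = [c for c in classes if c != 0]
    classes = list(classes)
    if not classes:
        raise InputError("no classes to evaluate")
    scores = []
    for c in classes:
        a = Ix == c
        b = Iy == c
        na, nb = a.sum(), b.sum()
        if na == 0 and nb == 0:
            if skip_absent:
                continue
            scores.append(1.0)
            continue
        scores.append(2.0 * np.logical_and(a, b).sum() / (na + nb))
    return float(np.mean(scores)) if scores else math.nan


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand index from the contingency table of two labelings."""
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.shape != b.shape:
        raise InputError("labelings must have equal length")
    if a.size < 2:
        raise InputError("need at least two elements")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    n_a = ai.max() + 1
    n_b = bi.max() + 1
    table = np.zeros((n_a, n_b), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    n = a.size
    expected = sum_a * sum_b / comb2(n)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # e.g. both labelings trivial
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

MORPHOLOGY_FEATURES = ("area", "perimeter", "elongation", "eccentricity",
                       "circularity", "solidity", "extent", "aspect_ratio",
                       "compactness")


@dataclass
class MorphologyFeatures:
    label: int
    area: float
    perimeter: float
    elongation: float
    eccentricity: float
    circularity: float
    solidity: float
    extent: float
    aspect_ratio: float
    compactness: float
    centroid: tuple = (0.0, 0.0)

    def vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in MORPHOLOGY_FEATURES])


def morphology_features(labels: np.ndarray) -> list:
    """One feature vector per labeled object.

    Definitions: circularity = 4*pi*A/P^2; compactness = P^2/A;
    extent = A / bounding-box area; elongation = 1 - minor/major axis
    (ellipse fit); aspect ratio = long/short bounding-box side (>= 1);
    eccentricity from the ellipse of second moments.
    """
    out = []
    for rp in regionprops(np.asarray(labels).astype(np.int64)):
        area = float(rp.area)
        perim = float(rp.perimeter) or 1.0
        major = float(rp.axis_major_length) or 1.0
        minor = float(rp.axis_minor_length)
        r0, c0, r1, c1 = rp.bbox
        bh, bw = r1 - r0, c1 - c0
        out.append(MorphologyFeatures(
            label=int(rp.label),
            area=area,
            perimeter=perim,
            elongation=1.0 - minor / major,
            eccentricity=float(rp.eccentricity),
            circularity=4.0 * math.pi * area / perim ** 2,
            solidity=float(rp.solidity),
            extent=float(rp.extent),
            aspect_ratio=max(bh, bw) / max(min(bh, bw), 1),
            compactness=perim ** 2 / area,
            centroid=tuple(map(float, rp.centroid)),
        ))
    return out


def standardize_features(features: list) -> np.ndarray:
    """Stack feature vectors and scale each to mean 0, sd 1 across objects."""
    mat = np.stack([f.vector() for f in features])
    mu = mat.mean(axis=0)
    sd = mat.std(axis=0)
    sd[sd == 0] = 1.0
    return (mat - mu) / sd


def cells_outside_tissue(cell_labels: np.ndarray, tissue: np.ndarray) -> int:
    """Count labeled objects whose centroid lies outside the tissue mask."""
    if cell_labels.shape != tissue.shape:
        raise InputError("cell labels and tissue mask must share dimensions")
    t = tissue > 0
    n = 0
    for rp in regionprops(np.asarray(cell_labels).astype(np.int64)):
        r, c = (int(round(v)) for v in rp.centroid)
        r = min(max(r, 0), t.shape[0] - 1)
        c = min(max(c, 0), t.shape[1] - 1)
        if not t[r, c]:
            n += 1
    return n


# ---------------------------------------------------------------------------
# vendor-overlay marker extraction
# ---------------------------------------------------------------------------

def extract_overlay_markers(layered: np.ndarray, radius_range=(3, 10),
                            sensitivity: float = 0.3) -> np.ndarray:
    """Binary marker mask from a vendor layered image with red circles.

    Pixels with R > 180, G < 30, B < 30 are the overlay's red fiducial
    rings; circles detected on that mask are filled to produce a marker
    mask comparable to segmentation outputs.
    """
    from skimage.transform import hough_circle, hough_circle_peaks

    red = ((layered[..., 0] > 180) & (layered[..., 1] < 30)
           & (layered[..., 2] < 30))
    out = np.zeros(red.shape, dtype=np.uint8)
    if not red.any():
        return out
    radii = np.arange(int(radius_range[0]), int(radius_range[1]) + 1)
    accum = hough_circle(red, radii)
    accums, cx, cy, rad = hough_circle_peaks(
        accum, radii, min_xdistance=int(radii.min()),
        min_ydistance=int(radii.min()), total_num_peaks=500)
    h, w = red.shape
    for a, x, y, r in zip(accums, cx, cy, rad):
        if a < sensitivity:
            continue
        rr, cc = np.mgrid[max(y - r, 0):min(y + r + 1, h),
                          max(x - r, 0):min(x + r + 1, w)]
        inside = (rr - y) ** 2 + (cc - x) ** 2 <= r * r
        out[rr[inside], cc[inside]] = 1
    return out


def red_threshold(layered: np.ndarray) -> np.ndarray:
    """The raw R>180, G<30, B<30 overlay threshold as a binary mask."""
    return (((layered[..., 0] > 180) & (layered[..., 1] < 30)
             & (layered[..., 2] < 30))).astype(np.uint8)


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def evaluate_masks(pred: np.ndarray, gold: np.ndarray,
                   connectivity: int = 8) -> MetricReport:
    """IoU / Hausdorff / perimeter ratio / component difference report."""
    return MetricReport(
        iou=iou(pred, gold),
        hausdorff=hausdorff(pred, gold),
        perim_ratio=perimeter_ratio(pred, gold),
        comp_diff=comp_diff(pred, gold, connectivity),
    )
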