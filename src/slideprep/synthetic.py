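"""Seeded generator of Visium-like synthetic slides with full ground truth.

A real Visium capture area is surrounded by a printed square frame of small
circular fiducial markers; the tissue section, stained pink/purple by H&E,
may overlap an arbitrary fraction of that frame and may consist of several
disconnected pieces.  The generator emulates exactly the features the
cleaning pipeline has to cope with:

* a square frame of dark marker rings along the image border, with
  per-marker jitter and a smooth global (elastic) deformation of the frame;
* one or more textured tissue blobs with irregular boundaries; the main
  blob's extent is chosen so that a requested fraction of markers falls
  inside tissue (the *overlap factor* that drives training difficulty);
* markers overlapping tissue are rendered with reduced contrast, which is
  what makes them hard to detect on real slides;
* sparse background stain speckles that act as circle-detector decoys.

Every sample carries its ground truth (marker circles and mask, tissue
mask, connected-component count), and a spec plus seed fully determines the
rendered image bit-for-bit.

What the generator does **not** emulate: nuclei-level histology texture,
scanner illumination fields, or the exact marker geometry of any slide
version — results on synthetic slides demonstrate that the pipeline's
machinery works, not field performance on real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from skimage.draw import polygon as _sk_polygon
from skimage.transform import resize as _sk_resize

from slideprep.io import write_image, write_mask


class ConfigError(ValueError):
    """Raised for infeasible generator or training configurations."""


@dataclass
class CircleAnnotation:
    """A single gold-standard fiducial marker."""

    center: tuple  # (row, col), fractional px
    radius: float
    in_tissue: bool = False


@dataclass
class MarkerAnnotationSet:
    circles: list
    mask: np.ndarray  # uint8 {0,1}, union of rasterized circles
    overlap_factor: float  # in-tissue markers / total markers, 0 if none

    def recompute_overlap_factor(self, tissue_mask: np.ndarray) -> float:
        if not self.circles:
            return 0.0
        h, w = tissue_mask.shape
        hits = 0
        for c in self.circles:
            r = min(max(int(round(c.center[0])), 0), h - 1)
            col = min(max(int(round(c.center[1])), 0), w - 1)
            hits += bool(tissue_mask[r, col])
        return hits / len(self.circles)


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic slide.

    Defaults describe a 256 px thumbnail-scale slide: 13 markers per frame
    side (52 rings, the thumbnail-scale analogue of the dense printed
    frame), 4 px marker radius, moderate frame deformation and one tissue
    blob that stays inside the frame (overlap factor ~0).
    """

    size: int = 256
    markers_per_side: int = 13
    marker_radius: float = 4.0
    radius_jitter: float = 0.4
    center_jitter: float = 0.7
    deform_amplitude: float = 4.0
    n_tissue_blobs: int = 1
    target_overlap: float = 0.0
    stain_noise_density: float = 8e-5
    frame_margin_frac: float = 0.11
    seed: int = 0


@dataclass
class SyntheticSample:
    image: np.ndarray  # uint8 (H, W, 3)
    markers: MarkerAnnotationSet
    tissue_mask: np.ndarray  # uint8 {0,1}
    n_tissue_components: int
    spec: SyntheticSpec | None = None


_EIGHT = np.ones((3, 3), dtype=int)


def frame_positions(spec: SyntheticSpec) -> np.ndarray:
    """Ideal (undeformed, unjittered) marker centers, shape (4*mps, 2)."""
    s, m = spec.size, spec.frame_margin_frac * spec.size
    n = spec.markers_per_side
    t = np.linspace(m, s - m, n, endpoint=False)
    top = np.stack([np.full(n, m), t], axis=1)
    right = np.stack([t, np.full(n, s - m)], axis=1)
    bottom = np.stack([np.full(n, s - m), (s - m) - (t - m)], axis=1)
    left = np.stack([(s - m) - (t - m), np.full(n, m)], axis=1)
    return np.concatenate([top, right, bottom, left], axis=0)


def _elastic_field(size: int, amplitude: float, rng) -> RegularGridInterpolator:
    """Smooth global displacement field from a coarse 4x4 random grid."""
    grid = rng.uniform(-amplitude, amplitude, size=(4, 4, 2))
    knots = np.linspace(0, size - 1, 4)
    return RegularGridInterpolator((knots, knots), grid, method="linear",
                                   bounds_error=False, fill_value=None)


def _smooth_field(shape, coarse: int, rng) -> np.ndarray:
    """Band-limited noise in [0, 1] used for tissue texture/background."""
    f = rng.standard_normal((coarse, coarse))
    f = _sk_resize(f, shape, order=3, mode="reflect", anti_aliasing=False)
    f -= f.min()
    rngspan = f.max() or 1.0
    return f / rngspan


def _blob_mask(size, center, radius, rng, n_theta=256) -> np.ndarray:
    """Rasterize one irregular blob: a disc with Fourier boundary wobble."""
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    wobble = np.zeros(n_theta)
    for k in range(2, 6):
        wobble += rng.uniform(0.0, 0.09) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    r = radius * (1.0 + wobble)
    rows = center[0] + r * np.sin(theta)
    cols = center[1] + r * np.cos(theta)
    rr, cc = _sk_polygon(rows, cols, shape=(size, size))
    mask = np.zeros((size, size), dtype=np.uint8)
    mask[rr, cc] = 1
    return mask


def _render_circle(img_f, center, radius, color, opacity, ring_width=1.3):
    """Anti-aliased dark ring with a faint interior fill, drawn in place."""
    h, w = img_f.shape[:2]
    pad = int(np.ceil(radius + 3 * ring_width))
    r0 = max(int(np.floor(center[0])) - pad, 0)
    r1 = min(int(np.ceil(center[0])) + pad + 1, h)
    c0 = max(int(np.floor(center[1])) - pad, 0)
    c1 = min(int(np.ceil(center[1])) + pad + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d = np.hypot(rr - center[0], cc - center[1])
    ink = np.exp(-((d - radius) / ring_width) ** 2)
    ink = np.maximum(ink, 0.25 * (d < radius))  # faint interior tint
    alpha = (opacity * ink)[..., None]
    img_f[r0:r1, c0:c1] = (1 - alpha) * img_f[r0:r1, c0:c1] + alpha * np.asarray(color, float)


def _circle_mask(size, center, radius) -> tuple:
    """Pixel (row, col) indices inside the circle (subpixel-centre rule)."""
    pad = int(np.ceil(radius)) + 1
    r0 = max(int(np.floor(center[0])) - pad, 0)
    r1 = min(int(np.ceil(center[0])) + pad + 1, size)
    c0 = max(int(np.floor(center[1])) - pad, 0)
    c1 = min(int(np.ceil(center[1])) + pad + 1, size)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    inside = np.hypot(rr - center[0], cc - center[1]) <= radius
    return rr[inside], cc[inside]


def generate_sample(spec: SyntheticSpec) -> SyntheticSample:
    """Render one synthetic slide with all ground truths.

    The same spec (including its seed) always produces a bit-identical
    sample.
    """
    return _render_scene(spec, draw_markers=True)


def render_marker_free(spec: SyntheticSpec) -> np.ndarray:
    """Re-render the identical scene without marker rings.

    Drawing the rings consumes no random draws, so skipping them leaves
    background, tissue and speckles bit-identical — this is the oracle
    image for judging marker restoration.
    """
    return _render_scene(spec, draw_markers=False).image


def _render_scene(spec: SyntheticSpec, draw_markers: bool) -> SyntheticSample:
    if spec.size < 128:
        raise ConfigError("synthetic slide size must be >= 128 px")
    if spec.target_overlap > 0 and spec.n_tissue_blobs == 0:
        raise ConfigError("target_overlap > 0 requires at least one tissue blob")
    rng = np.random.default_rng(spec.seed)
    s = spec.size

    # --- background: light off-white with a gentle smooth field -----------
    bg = 236.0 + 8.0 * (_smooth_field((s, s), 6, rng) - 0.5)
    img = np.stack([bg, bg - 2.0, bg + 2.0], axis=-1)

    # --- marker centers: frame + jitter + global elastic warp -------------
    centers = frame_positions(spec)
    centers = centers + rng.normal(0.0, spec.center_jitter, centers.shape)
    if spec.deform_amplitude > 0:
        warp = _elastic_field(s, spec.deform_amplitude, rng)
        centers = centers + warp(centers)
    radii = np.maximum(spec.marker_radius
                       + rng.normal(0.0, spec.radius_jitter, len(centers)), 1.0)

    # --- tissue blobs ------------------------------------------------------
    tissue = np.zeros((s, s), dtype=np.uint8)
    if spec.n_tissue_blobs > 0:
        blob_center = np.array([s / 2, s / 2]) + rng.uniform(-0.04 * s, 0.04 * s, 2)
        d_marker = np.hypot(*(centers - blob_center).T)
        if spec.target_overlap > 0:
            # choose the main blob radius so that ~target fraction of the
            # (wobbly) blob boundary encloses that fraction of marker centers
            q = min(spec.target_overlap, 0.999)
            rho = float(np.quantile(d_marker, q)) + spec.marker_radius
        else:
            rho = min(0.30 * s, 0.9 * float(d_marker.min()))
            rho = max(rho, 0.12 * s)
        tissue |= _blob_mask(s, blob_center, rho, rng)
        # extra disconnected blobs, placed away from existing tissue
        placed = 1
        attempts = 0
        dil = ndimage.binary_dilation(tissue, _EIGHT, iterations=4)
        while placed < spec.n_tissue_blobs and attempts < 60:
            attempts += 1
            r_extra = rng.uniform(0.05, 0.09) * s
            c_extra = rng.uniform(0.1 * s, 0.9 * s, 2)
            cand = _blob_mask(s, c_extra, r_extra, rng)
            grow = ndimage.binary_dilation(cand, _EIGHT, iterations=4)
            if not (grow & dil).any():
                tissue |= cand
                dil |= ndimage.binary_dilation(cand, _EIGHT, iterations=4)
                placed += 1

    # --- render tissue over background -------------------------------------
    if tissue.any():
        tex = _smooth_field((s, s), max(s // 16, 4), rng)
        light = np.array([228.0, 178.0, 208.0])
        deep = np.array([168.0, 104.0, 158.0])
        color = light[None, None] + tex[..., None] * (deep - light)[None, None]
        soft = ndimage.gaussian_filter(tissue.astype(float), 1.0)
        alpha = np.clip(soft, 0, 1)[..., None] * 0.92
        img = (1 - alpha) * img + alpha * color

    # --- stain speckles (decoys, not tissue) --------------------------------
    n_speck = rng.poisson(spec.stain_noise_density * s * s)
    for _ in range(n_speck):
        c = rng.uniform(0, s, 2)
        r = rng.uniform(1.0, 3.0)
        _render_circle(img, c, r, (190, 120, 175), 0.45, ring_width=r)

    # --- markers -------------------------------------------------------------
    marker_mask = np.zeros((s, s), dtype=np.uint8)
    circles = []
    for (cy, cx), rad in zip(centers, radii):
        in_t = bool(tissue[min(max(int(round(cy)), 0), s - 1),
                           min(max(int(round(cx)), 0), s - 1)])
        opacity = 0.55 if in_t else 0.92
        if draw_markers:
            _render_circle(img, (cy, cx), rad, (45, 42, 60), opacity)
        rr, cc = _circle_mask(s, (cy, cx), rad)
        marker_mask[rr, cc] = 1
        circles.append(CircleAnnotation(center=(float(cy), float(cx)),
                                        radius=float(rad), in_tissue=in_t))

    n_comp = int(ndimage.label(tissue, structure=_EIGHT)[1])
    overlap = (sum(c.in_tissue for c in circles) / len(circles)) if circles else 0.0
    markers = MarkerAnnotationSet(circles=circles, mask=marker_mask,
                                  overlap_factor=overlap)
    image = np.clip(img, 0, 255).astype(np.uint8)
    return SyntheticSample(image=image, markers=markers, tissue_mask=tissue,
                           n_tissue_components=n_comp, spec=spec)


# ---------------------------------------------------------------------------
# difficulty strata and corpora
# ---------------------------------------------------------------------------

STRATA = ("hard", "moderate", "easy")
# target-overlap sampling ranges per stratum; chosen inside the class
# boundaries (hard > 0.8, 0.3 < moderate <= 0.8, easy < 0.3)
_STRATUM_RANGES = {"hard": (0.85, 0.97), "moderate": (0.40, 0.72),
                   "easy": (0.0, 0.20)}


def classify_overlap(factor: float) -> str:
    """Difficulty class of a slide from its marker overlap factor."""
    if factor > 0.8:
        return "hard"
    if factor > 0.3:  # 0.3 itself falls through to easy
        return "moderate"
    return "easy"


def _stratum_counts(n: int, mix: dict) -> dict:
    """Largest-remainder apportionment of n samples to the strata."""
    total = sum(mix.get(k, 0.0) for k in STRATA)
    if n > 0 and not np.isclose(total, 1.0):
        raise ConfigError("difficulty mix proportions must sum to 1")
    raw = {k: n * mix.get(k, 0.0) for k in STRATA}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    rem = n - sum(counts.values())
    order = sorted(STRATA, key=lambda k: raw[k] - counts[k], reverse=True)
    for k in order[:rem]:
        counts[k] += 1
    return counts


def generate_corpus(n: int, template: SyntheticSpec | None = None,
                    mix: dict | None = None, seed: int | None = None,
                    max_tries: int = 12) -> list:
    """Generate ``n`` samples with a requested difficulty mix.

    ``mix`` maps "hard"/"moderate"/"easy" to proportions summing to 1.
    Each sample re-draws its target overlap inside the stratum's range and
    is re-generated (with a fresh sub-seed) until its realized overlap
    factor lands in the stratum, so the empirical mix matches the request.
    """
    template = template or SyntheticSpec()
    mix = mix or {"hard": 0.25, "moderate": 0.25, "easy": 0.5}
    if seed is None:
        seed = template.seed
    counts = _stratum_counts(n, mix)
    ss = np.random.SeedSequence(seed)
    child_rng = np.random.default_rng(ss)
    samples = []
    for stratum in STRATA:
        lo, hi = _STRATUM_RANGES[stratum]
        for _ in range(counts[stratum]):
            for _try in range(max_tries):
                sub_seed = int(child_rng.integers(0, 2**31 - 1))
                target = float(child_rng.uniform(lo, hi))
                spec = replace(template, seed=sub_seed, target_overlap=target)
                sample = generate_sample(spec)
                if classify_overlap(sample.markers.overlap_factor) == stratum:
                    break
            samples.append(sample)
    order = child_rng.permutation(len(samples))
    return [samples[i] for i in order]


# ---------------------------------------------------------------------------
# corpus persistence
# ---------------------------------------------------------------------------

def save_corpus(samples: list, outdir) -> None:
    """Persist a corpus: PNG images/masks, JSON circles, YAML manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"n": len(samples), "samples": []}
    for i, s in enumerate(samples):
        stem = f"sample_{i:04d}"
        write_image(s.image, outdir / f"{stem}.png")
        write_mask(s.markers.mask, outdir / f"{stem}_markers.png")
        write_mask(s.tissue_mask, outdir / f"{stem}_tissue.png")
        circles = [{"center": list(c.center), "radius": c.radius,
                    "in_tissue": c.in_tissue} for c in s.markers.circles]
        (outdir / f"{stem}_circles.json").write_text(json.dumps({
            "circles": circles,
            "overlap_factor": s.markers.overlap_factor,
            "n_tissue_components": s.n_tissue_components,
        }))
        manifest["samples"].append({
            "stem": stem,
            "spec": asdict(s.spec) if s.spec else None,
            "overlap_factor": s.markers.overlap_factor,
        })
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest))


def load_corpus(indir) -> list:
    """Load a corpus saved by :func:`save_corpus`."""
    from slideprep.io import read_image, read_mask

    indir = Path(indir)
    manifest = yaml.safe_load((indir / "manifest.yaml").read_text())
    samples = []
    for entry in manifest["samples"]:
        stem = entry["stem"]
        image = read_image(indir / f"{stem}.png")
        mmask = read_mask(indir / f"{stem}_markers.png").astype(np.uint8)
        tissue = read_mask(indir / f"{stem}_tissue.png").astype(np.uint8)
        meta = json.loads((indir / f"{stem}_circles.json").read_text())
        circles = [CircleAnnotation(center=tuple(c["center"]), radius=c["radius"],
                                    in_tissue=c["in_tissue"])
                   for c in meta["circles"]]
        spec = SyntheticSpec(**entry["spec"]) if entry.get("spec") else None
        samples.append(SyntheticSample(
            image=image,
            markers=MarkerAnnotationSet(circles=circles, mask=mmask,
                                        overlap_factor=meta["overlap_factor"]),
            tissue_mask=tissue,
            n_tissue_components=meta["n_tissue_components"],
            spec=spec,
        ))
    return samples
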