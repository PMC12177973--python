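"""Raster/mask I/O, tiling and stitching shared by all pipeline stages.

Conventions used throughout the package: arrays are row-major with the
origin at the top-left pixel, indices are 0-based and given in (row, col)
order.  RGB images are ``uint8`` arrays of shape (H, W, 3); probability
masks are ``float32``/``float64`` in [0, 1]; binary masks are ``uint8`` in
{0, 1}; labeled masks are non-negative integer arrays whose labels form a
gap-free range 1..K.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image, UnidentifiedImageError
from skimage.transform import resize as _sk_resize

logger = logging.getLogger(__name__)


class InputError(ValueError):
    """Raised for unreadable or inconsistent user-supplied inputs."""


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG raster as an 8-bit RGB array of shape (H, W, 3).

    Grayscale inputs are replicated across the three channels; an alpha
    channel, if present, is dropped.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise InputError(f"cannot read image: {path} is missing or empty")
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(str(path))
        else:
            with Image.open(path) as im:
                im.load()
                arr = np.asarray(im)
    except (UnidentifiedImageError, OSError, ValueError) as exc:
        raise InputError(f"cannot read image {path}: {exc}") from exc
    return _to_rgb8(arr, path)


def _to_rgb8(arr: np.ndarray, origin="array") -> np.ndarray:
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim == 3 and arr.shape[2] == 3:
        pass
    else:
        raise InputError(f"unsupported raster shape {arr.shape} from {origin}")
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return np.ascontiguousarray(arr)


def write_image(img: np.ndarray, path) -> None:
    """Write an RGB(A) uint8 image as PNG/JPEG/TIFF depending on suffix."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(str(path), img)
    else:
        Image.fromarray(img).save(path)


def write_mask(mask: np.ndarray, path) -> None:
    """Write a mask so that ``read_mask`` round-trips it losslessly.

    Binary masks ({0,1}) are stored as 0/255 8-bit PNG, labeled masks as
    16-bit PNG, probability masks as 32-bit float TIFF.
    """
    path = Path(path)
    mask = np.asarray(mask)
    try:
        if np.issubdtype(mask.dtype, np.floating):
            if mask.min() < 0 or mask.max() > 1:
                raise InputError("probability mask values must lie in [0, 1]")
            tifffile.imwrite(str(path), mask.astype(np.float32))
        elif set(np.unique(mask)) <= {0, 1}:
            Image.fromarray((mask.astype(np.uint8) * 255)).save(path)
        else:
            if mask.max() > np.iinfo(np.uint16).max:
                raise InputError("labeled mask exceeds 16-bit label range")
            Image.fromarray(mask.astype(np.uint16)).save(path)
    except OSError as exc:
        raise OSError(f"cannot write mask to {path}: {exc}") from exc


def read_mask(path) -> np.ndarray:
    """Read a mask written by :func:`write_mask` back to its native dtype."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"mask file not found: {path}")
    if path.suffix.lower() in {".tif", ".tiff"}:
        return tifffile.imread(str(path))
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.dtype == np.uint8:
        return (arr > 127).astype(np.uint8)
    return arr.astype(np.int32)


@dataclass
class TileGrid:
    """Origins of overlapping square tiles covering an image."""

    tile_size: int
    overlap: int
    origins: list = field(default_factory=list)
    image_shape: tuple = (0, 0)

    def __iter__(self):
        return iter(self.origins)

    def __len__(self):
        return len(self.origins)


def _axis_origins(extent: int, tile: int, stride: int) -> list[int]:
    if extent <= tile:
        return [0]
    starts = list(range(0, extent - tile, stride))
    starts.append(extent - tile)  # clamp last tile to the image bound
    # remove duplicates introduced by the clamp while keeping order
    seen, out = set(), []
    for s in starts:
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


def tile_image(img: np.ndarray, tile_size: int, overlap: int = 0) -> TileGrid:
    """Cover an image with square tiles of ``tile_size`` px.

    Tiles start every ``tile_size - overlap`` px; the last row/column of
    tiles is clamped to the image bounds so every pixel is covered.  If the
    image is smaller than the tile in either dimension a single full-image
    tile is returned (with a warning).
    """
    if tile_size < 32:
        raise InputError("tile_size must be >= 32")
    if overlap >= tile_size:
        raise InputError("overlap must be smaller than tile_size")
    h, w = img.shape[:2]
    if tile_size > min(h, w):
        warnings.warn(
            f"tile_size {tile_size} exceeds image extent {h}x{w}; "
            "using a single full-image tile",
            stacklevel=2,
        )
        return TileGrid(tile_size=tile_size, overlap=overlap,
                        origins=[(0, 0)], image_shape=(h, w))
    stride = tile_size - overlap
    origins = [(r, c) for r in _axis_origins(h, tile_size, stride)
               for c in _axis_origins(w, tile_size, stride)]
    return TileGrid(tile_size=tile_size, overlap=overlap,
                    origins=origins, image_shape=(h, w))


def extract_tile(img: np.ndarray, origin: tuple, tile_size: int) -> np.ndarray:
    r, c = origin
    h, w = img.shape[:2]
    return img[r:min(r + tile_size, h), c:min(c + tile_size, w)]


def stitch_probability(tiles, shape) -> np.ndarray:
    """Merge per-tile probability masks into one mask of the given shape.

    Pixels covered by several tiles receive the arithmetic mean of the
    contributing values, which keeps agreeing tiles seamless.
    """
    h, w = shape
    acc = np.zeros((h, w), dtype=np.float64)
    cnt = np.zeros((h, w), dtype=np.float64)
    for (r, c), mask in tiles:
        th, tw = mask.shape[:2]
        acc[r:r + th, c:c + tw] += mask
        cnt[r:r + th, c:c + tw] += 1.0
    if (cnt == 0).any():
        raise RuntimeError("stitch_probability: tiles do not cover the image")
    out = acc / cnt
    return np.clip(out, 0.0, 1.0)


def resize_image(img: np.ndarray, shape) -> np.ndarray:
    """Bilinear resize of an RGB image to ``shape`` = (H, W), uint8 out."""
    out = _sk_resize(img, shape, order=1, preserve_range=True,
                     anti_aliasing=False)
    return np.clip(out, 0, 255).astype(np.uint8)


def resize_mask(mask: np.ndarray, shape) -> np.ndarray:
    """Nearest-neighbour resize for binary/labeled masks (no label mixing)."""
    out = _sk_resize(mask, shape, order=0, preserve_range=True,
                     anti_aliasing=False)
    return out.astype(mask.dtype)


def resize_probability(prob: np.ndarray, shape) -> np.ndarray:
    """Bilinear resize for probability masks, clipped back to [0, 1]."""
    out = _sk_resize(prob.astype(np.float64), shape, order=1,
                     preserve_range=True, anti_aliasing=False)
    return np.clip(out, 0.0, 1.0)
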