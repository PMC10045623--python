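"""Impulse-noise removal and tile-based adaptive histogram equalization.

Inputs are 8-bit grayscale images (`numpy` uint8 arrays).  The noise filter
is a conditional mean: only pixels at the intensity extremes 0/255 are
replaced, by the mean of the non-extreme pixels in their window.  Contrast
enhancement is classical rank/CDF equalization computed per tile and blended
bilinearly between tile centers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "remove_impulse_noise",
    "adaptive_hist_eq",
    "read_image",
    "write_image",
]


def _as_gray(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def remove_impulse_noise(img: np.ndarray, window: int = 3) -> np.ndarray:
    """Replace 0/255 pixels by the rounded mean of their non-extreme neighbours.

    If every pixel in the window is extreme, the rounded full-window mean is
    used instead.  Non-extreme pixels pass through untouched, so the filter
    is idempotent once its output is free of extremes.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    arr = _as_gray(img)
    extreme = (arr == 0) | (arr == 255)
    if not extreme.any():
        return arr.copy()

    values = arr.astype(np.float64)
    good = ~extreme
    size = (window, window)

    def window_sum(a: np.ndarray) -> np.ndarray:
        # zero padding -> sums run over in-image pixels only
        return np.rint(ndimage.uniform_filter(a, size=size, mode="constant", cval=0.0) * window**2)

    good_sum = window_sum(values * good)
    good_cnt = window_sum(good.astype(np.float64))
    full_sum = window_sum(values)
    full_cnt = window_sum(np.ones_like(values))

    out = arr.copy()
    cond_mean = np.where(good_cnt > 0, good_sum / np.maximum(good_cnt, 1), full_sum / full_cnt)
    out[extreme] = np.rint(cond_mean[extreme]).astype(np.uint8)
    return out


def _tile_lut(tile: np.ndarray) -> np.ndarray:
    """Rank/CDF lookup table for one tile: v -> floor(rank(v)/n * 255).

    A tile with a single unique value maps to itself — plain equalization
    would jump a flat tile straight to 255.
    """
    hist = np.bincount(tile.ravel(), minlength=256)
    if np.count_nonzero(hist) <= 1:
        return np.arange(256, dtype=np.uint8)
    cdf = np.cumsum(hist)
    lut = np.floor(cdf / tile.size * 255.0)
    return lut.astype(np.uint8)


def adaptive_hist_eq(img: np.ndarray, tiles: tuple[int, int] = (8, 8)) -> np.ndarray:
    """Per-tile rank equalization with bilinear blending between tile centers."""
    arr = _as_gray(img)
    rows, cols = tiles
    h, w = arr.shape
    if rows < 1 or cols < 1:
        raise ValueError("tile grid must be at least 1x1")
    if h < rows or w < cols:
        raise ValueError(f"image {arr.shape} smaller than tile grid {tiles}")

    row_edges = np.linspace(0, h, rows + 1).astype(int)
    col_edges = np.linspace(0, w, cols + 1).astype(int)
    luts = np.empty((rows, cols, 256), dtype=np.float64)
    for i in range(rows):
        for j in range(cols):
            tile = arr[row_edges[i] : row_edges[i + 1], col_edges[j] : col_edges[j + 1]]
            luts[i, j] = _tile_lut(tile)

    if rows == 1 and cols == 1:
        return luts[0, 0].astype(np.uint8)[arr]

    centers_y = (row_edges[:-1] + row_edges[1:]) / 2.0
    centers_x = (col_edges[:-1] + col_edges[1:]) / 2.0

    yy = np.arange(h, dtype=np.float64)
    xx = np.arange(w, dtype=np.float64)
    # fractional tile coordinates, clamped so border pixels reuse edge tiles
    ty = np.interp(yy, centers_y, np.arange(rows, dtype=np.float64))
    tx = np.interp(xx, centers_x, np.arange(cols, dtype=np.float64))
    y0 = np.clip(np.floor(ty).astype(int), 0, rows - 1)
    x0 = np.clip(np.floor(tx).astype(int), 0, cols - 1)
    y1 = np.minimum(y0 + 1, rows - 1)
    x1 = np.minimum(x0 + 1, cols - 1)
    fy = (ty - y0)[:, None]
    fx = (tx - x0)[None, :]

    Y0 = y0[:, None]
    Y1 = y1[:, None]
    X0 = x0[None, :]
    X1 = x1[None, :]
    v = arr
    m00 = luts[Y0, X0, v]
    m01 = luts[Y0, X1, v]
    m10 = luts[Y1, X0, v]
    m11 = luts[Y1, X1, v]
    blended = (
        m00 * (1 - fy) * (1 - fx)
        + m01 * (1 - fy) * fx
        + m10 * fy * (1 - fx)
        + m11 * fy * fx
    )
    return np.clip(np.rint(blended), 0, 255).astype(np.uint8)


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale image; DICOM handled if pydicom is available."""
    path = Path(path)
    if path.suffix.lower() in {".dcm", ".dicom"}:
        try:
            import pydicom  # optional dependency
        except ImportError as exc:  # pragma: no cover - environment dependent
            raise ImportError("reading DICOM requires the optional pydicom package") from exc
        ds = pydicom.dcmread(str(path))
        pixels = ds.pixel_array.astype(np.float64)
        lo, hi = pixels.min(), pixels.max()
        scale = 255.0 / (hi - lo) if hi > lo else 0.0
        return np.rint((pixels - lo) * scale).astype(np.uint8)
    with Image.open(path) as im:
        return np.asarray(im.convert("L"))


def write_image(path: str | Path, img: np.ndarray) -> None:
    Image.fromarray(_as_gray(img), mode="L").save(str(path))
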