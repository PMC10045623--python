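"""Fourteen-value feature vector: Haar sub-band means, five co-occurrence
texture features, five first-order histogram statistics.

The gray-level co-occurrence matrix (GLCM) is accumulated symmetrically at
unit distance over four angles and normalized to probabilities; the five
Haralick-style summaries (contrast, correlation, homogeneity, entropy,
energy) are averaged across angles.  The wavelet features are the mean
absolute coefficient of each sub-band of a single-level orthonormal 2-D
Haar transform.  Histogram statistics use population moments with excess
(Fisher) kurtosis.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FeatureConfig",
    "FeatureVector",
    "FEATURE_NAMES",
    "quantize_image",
    "compute_glcm",
    "glcm_features",
    "haar2d",
    "inverse_haar2d",
    "dwt_subband_features",
    "histogram_stats",
    "extract_feature_vector",
    "write_feature_table",
]

FEATURE_NAMES = (
    "wav_LL",
    "wav_LH",
    "wav_HL",
    "wav_HH",
    "glcm_contrast",
    "glcm_correlation",
    "glcm_homogeneity",
    "glcm_entropy",
    "glcm_energy",
    "hist_mean",
    "hist_variance",
    "hist_sd",
    "hist_skewness",
    "hist_kurtosis",
)

# (dy, dx) displacements for angles 0, 45, 90, 135 degrees at unit distance
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class FeatureConfig:
    glcm_levels: int = 8
    glcm_distance: int = 1
    glcm_angles: tuple[int, ...] = (0, 45, 90, 135)
    histogram_bins: int = 256

    def __post_init__(self) -> None:
        if self.glcm_levels < 2:
            raise ValueError("glcm_levels must be >= 2")
        if self.glcm_distance < 1:
            raise ValueError("glcm_distance must be >= 1")
        unknown = set(self.glcm_angles) - set(_ANGLE_OFFSETS)
        if unknown:
            raise ValueError(f"unsupported angles: {sorted(unknown)}")

    @property
    def offsets(self) -> list[tuple[int, int]]:
        d = self.glcm_distance
        return [(dy * d, dx * d) for dy, dx in (_ANGLE_OFFSETS[a] for a in self.glcm_angles)]


@dataclass(frozen=True)
class FeatureVector:
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(FEATURE_NAMES):
            raise ValueError(f"expected {len(FEATURE_NAMES)} features, got {len(self.values)}")
        if not all(math.isfinite(v) for v in self.values):
            raise ValueError("all features must be finite")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def quantize_image(img: np.ndarray, levels: int) -> np.ndarray:
    """Map 8-bit intensities onto ``levels`` bins: v -> floor(v * L / 256)."""
    if levels < 2:
        raise ValueError("levels must be >= 2")
    arr = np.asarray(img)
    return (arr.astype(np.int64) * levels // 256).astype(np.int64)


def compute_glcm(level_img: np.ndarray, config: FeatureConfig | None = None) -> np.ndarray:
    """Symmetric normalized co-occurrence matrices, one per configured angle.

    Returns an array of shape ``(n_angles, L, L)``; each matrix counts level
    pairs at its offset in both orderings and is normalized to sum to 1.
    """
    config = config or FeatureConfig()
    arr = np.asarray(level_img, dtype=np.int64)
    L = config.glcm_levels
    if arr.max(initial=0) >= L:
        raise ValueError("level image holds values >= configured level count")
    matrices = np.zeros((len(config.offsets), L, L), dtype=np.float64)
    h, w = arr.shape
    for k, (dy, dx) in enumerate(config.offsets):
        if abs(dy) >= h or abs(dx) >= w:
            raise ValueError(f"image {arr.shape} smaller than offset ({dy}, {dx})")
        ys = slice(max(0, -dy), min(h, h - dy))
        xs = slice(max(0, -dx), min(w, w - dx))
        a = arr[ys, xs].ravel()
        b = arr[max(0, dy) : min(h, h + dy), max(0, dx) : min(w, w + dx)].ravel()
        counts = np.zeros((L, L), dtype=np.float64)
        np.add.at(counts, (a, b), 1.0)
        counts += counts.T  # symmetric accumulation: both pair orderings
        matrices[k] = counts / counts.sum()
    return matrices


def _single_glcm_features(p: np.ndarray) -> tuple[float, float, float, float, float]:
    L = p.shape[0]
    i = np.arange(L, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    contrast = float(np.sum(p * (ii - jj) ** 2))
    homogeneity = float(np.sum(p / (1.0 + (ii - jj) ** 2)))
    energy = float(np.sum(p**2))
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    mu_i = float(np.sum(p * ii))
    mu_j = float(np.sum(p * jj))
    var_i = float(np.sum(p * (ii - mu_i) ** 2))
    var_j = float(np.sum(p * (jj - mu_j) ** 2))
    if var_i <= 0 or var_j <= 0:
        correlation = 1.0  # constant field: perfectly self-correlated
    else:
        correlation = float(np.sum(p * (ii - mu_i) * (jj - mu_j)) / math.sqrt(var_i * var_j))
    return contrast, correlation, homogeneity, entropy, energy


def glcm_features(matrices: np.ndarray) -> tuple[float, float, float, float, float]:
    """Contrast, correlation, homogeneity, entropy, energy — averaged over angles."""
    matrices = np.asarray(matrices, dtype=np.float64)
    if matrices.ndim == 2:
        matrices = matrices[None]
    if np.any(np.abs(matrices.sum(axis=(1, 2)) - 1.0) > 1e-9):
        raise ValueError("co-occurrence matrices must be normalized to sum to 1")
    per_angle = np.array([_single_glcm_features(m) for m in matrices])
    return tuple(per_angle.mean(axis=0))  # type: ignore[return-value]


def haar2d(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Single-level orthonormal 2-D Haar transform: (LL, LH, HL, HH).

    Odd extents are padded by edge replication first.  LH holds horizontal
    detail (column-direction high pass), HL vertical detail.
    """
    x = np.asarray(img, dtype=np.float64)
    pad_h = x.shape[0] % 2
    pad_w = x.shape[1] % 2
    if pad_h or pad_w:
        x = np.pad(x, ((0, pad_h), (0, pad_w)), mode="edge")
    s = math.sqrt(2.0)
    lo_r = (x[:, 0::2] + x[:, 1::2]) / s
    hi_r = (x[:, 0::2] - x[:, 1::2]) / s
    LL = (lo_r[0::2] + lo_r[1::2]) / s
    HL = (lo_r[0::2] - lo_r[1::2]) / s
    LH = (hi_r[0::2] + hi_r[1::2]) / s
    HH = (hi_r[0::2] - hi_r[1::2]) / s
    return LL, LH, HL, HH


def inverse_haar2d(
    LL: np.ndarray, LH: np.ndarray, HL: np.ndarray, HH: np.ndarray
) -> np.ndarray:
    """Exact inverse of :func:`haar2d` (up to the replication padding)."""
    s = math.sqrt(2.0)
    lo_r = np.empty((LL.shape[0] * 2, LL.shape[1]))
    hi_r = np.empty_like(lo_r)
    lo_r[0::2] = (LL + HL) / s
    lo_r[1::2] = (LL - HL) / s
    hi_r[0::2] = (LH + HH) / s
    hi_r[1::2] = (LH - HH) / s
    out = np.empty((lo_r.shape[0], lo_r.shape[1] * 2))
    out[:, 0::2] = (lo_r + hi_r) / s
    out[:, 1::2] = (lo_r - hi_r) / s
    return out


def dwt_subband_features(img: np.ndarray) -> tuple[float, float, float, float]:
    """Mean absolute coefficient of each Haar sub-band (LL, LH, HL, HH)."""
    LL, LH, HL, HH = haar2d(img)
    return tuple(float(np.mean(np.abs(b))) for b in (LL, LH, HL, HH))  # type: ignore[return-value]


def histogram_stats(img: np.ndarray) -> tuple[float, float, float, float, float]:
    """Mean, population variance, sd, skewness, excess kurtosis.

    A constant image returns skewness = kurtosis = 0 by convention.
    """
    arr = np.asarray(img, dtype=np.float64).ravel()
    if arr.size == 0:
        raise ValueError("empty image")
    mean = float(arr.mean())
    centered = arr - mean
    m2 = float(np.mean(centered**2))
    sd = math.sqrt(m2)
    if m2 <= 0:
        return mean, 0.0, 0.0, 0.0, 0.0
    m3 = float(np.mean(centered**3))
    m4 = float(np.mean(centered**4))
    return mean, m2, sd, m3 / m2**1.5, m4 / m2**2 - 3.0


def extract_feature_vector(img: np.ndarray, config: FeatureConfig | None = None) -> FeatureVector:
    """Concatenate wavelet, texture and histogram features in fixed order."""
    config = config or FeatureConfig()
    wav = dwt_subband_features(img)
    glcm = glcm_features(compute_glcm(quantize_image(img, config.glcm_levels), config))
    hist = histogram_stats(img)
    return FeatureVector(values=tuple(wav) + tuple(glcm) + tuple(hist))


def write_feature_table(
    path: str | Path,
    rows: Iterable[tuple[str, int, FeatureVector]],
) -> int:
    """Write `path,label,<14 features>` CSV rows; returns the row count."""
    path = Path(path)
    n = 0
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(("path", "label") + FEATURE_NAMES)
        for img_path, label, vec in rows:
            writer.writerow((img_path, label) + tuple(repr(float(v)) for v in vec.values))
            n += 1
    return n
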