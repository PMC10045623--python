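"""Reproducible 4-class CT-like grayscale phantoms.

Each image is a smooth low-frequency background field plus class-specific
bright elliptical blobs; the "Normal" class has none.  Optional
salt-and-pepper corruption exercises the noise filter.  The generator is a
pure function of its seed so every test and the end-to-end run are
reproducible without any downloads.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .cnn import LabeledDataset
from .preprocess import write_image

__all__ = ["CLASS_NAMES", "ClassSignal", "SynthConfig", "generate_image", "generate_dataset", "add_impulse_noise", "write_dataset"]

CLASS_NAMES = ("adenocarcinoma", "large_cell_carcinoma", "normal", "squamous_cell_carcinoma")


@dataclass(frozen=True)
class ClassSignal:
    """Blob population of one class.

    ``orientation`` fixes the ellipse angle (radians) instead of drawing it
    per blob, giving a class a directional texture signature that survives
    contrast equalization.
    """

    n_blobs: int
    radius: float
    intensity: float
    eccentricity: float = 0.6
    orientation: float | None = None


# tuned so classes separate on texture (equalization flattens intensity cues):
# horizontal vs vertical elongated blobs split on the directional wavelet
# detail bands, many tiny blobs on the diagonal band and co-occurrence
# contrast, and the blob-free class on all of them
DEFAULT_SIGNALS: dict[str, ClassSignal] = {
    "adenocarcinoma": ClassSignal(n_blobs=5, radius=7.0, intensity=80.0, eccentricity=0.85, orientation=0.0),
    "large_cell_carcinoma": ClassSignal(n_blobs=5, radius=7.0, intensity=80.0, eccentricity=0.85, orientation=np.pi / 2),
    "normal": ClassSignal(n_blobs=0, radius=0.0, intensity=0.0),
    "squamous_cell_carcinoma": ClassSignal(n_blobs=25, radius=1.6, intensity=90.0),
}


@dataclass(frozen=True)
class SynthConfig:
    images_per_class: int = 100
    size: int = 64
    seed: int = 0
    noise_fraction: float = 0.02
    signals: dict[str, ClassSignal] = field(default_factory=lambda: dict(DEFAULT_SIGNALS))

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_fraction < 1.0:
            raise ValueError("noise_fraction must lie in [0, 1)")
        if self.size < 16:
            raise ValueError("image size must be >= 16")
        if set(self.signals) != set(CLASS_NAMES):
            raise ValueError(f"signals must cover exactly the classes {CLASS_NAMES}")


def _background(size: int, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency random field in [40, 180]: coarse noise, smoothly zoomed."""
    coarse = rng.uniform(0.0, 1.0, size=(6, 6))
    smooth = ndimage.zoom(coarse, size / 6.0, order=3)[:size, :size]
    lo, hi = smooth.min(), smooth.max()
    smooth = (smooth - lo) / (hi - lo) if hi > lo else np.zeros_like(smooth)
    return 40.0 + smooth * 140.0


def generate_image(signal: ClassSignal, size: int, rng: np.random.Generator) -> np.ndarray:
    img = _background(size, rng)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    for _ in range(signal.n_blobs):
        cy, cx = rng.uniform(0.15 * size, 0.85 * size, size=2)
        r = max(signal.radius * rng.uniform(0.7, 1.3), 1.0)
        ecc = min(signal.eccentricity * rng.uniform(0.8, 1.2), 0.95)
        if signal.orientation is None:
            theta = rng.uniform(0.0, np.pi)
        else:
            theta = signal.orientation + rng.normal(scale=0.1)
        a, b = r, max(r * (1.0 - ecc), 0.8)
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        dist2 = (u / a) ** 2 + (v / b) ** 2
        img += signal.intensity * np.exp(-dist2 * 2.0)
    return np.clip(np.rint(img), 1, 254).astype(np.uint8)  # keep 0/255 free for noise


def add_impulse_noise(img: np.ndarray, p: float, seed: int | np.random.Generator) -> np.ndarray:
    """Independently flip each pixel to 0 or 255 (fair coin) with probability p."""
    if not 0.0 <= p < 1.0:
        raise ValueError("noise fraction must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.asarray(img).copy()
    if p == 0.0:
        return out
    hit = rng.uniform(size=out.shape) < p
    salt = rng.uniform(size=out.shape) < 0.5
    out[hit & salt] = 255
    out[hit & ~salt] = 0
    return out


def generate_dataset(config: SynthConfig | None = None) -> LabeledDataset:
    """Images (N x size x size uint8-valued floats) with labels 0..3."""
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    images = []
    labels = []
    for label, name in enumerate(CLASS_NAMES):
        signal = config.signals[name]
        for _ in range(config.images_per_class):
            img = generate_image(signal, config.size, rng)
            if config.noise_fraction > 0:
                img = add_impulse_noise(img, config.noise_fraction, rng)
            images.append(img)
            labels.append(label)
    return LabeledDataset(np.asarray(images, dtype=float), np.asarray(labels), split="all")


def write_dataset(root: str | Path, config: SynthConfig | None = None) -> Path:
    """Write `root/<class>/img_####.png` plus a manifest.csv; returns root."""
    config = config or SynthConfig()
    root = Path(root)
    data = generate_dataset(config)
    manifest = []
    counters = {name: 0 for name in CLASS_NAMES}
    for img, label in zip(data.items, data.labels):
        name = CLASS_NAMES[label]
        class_dir = root / name
        class_dir.mkdir(parents=True, exist_ok=True)
        path = class_dir / f"img_{counters[name]:04d}.png"
        counters[name] += 1
        write_image(path, img.astype(np.uint8))
        manifest.append((str(path.relative_to(root)), label, config.seed))
    with open(root / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(("path", "label", "seed"))
        writer.writerows(manifest)
    return root
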