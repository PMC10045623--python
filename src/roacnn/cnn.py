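"""Genome-driven small convolutional classifier, trained by plain SGD.

A candidate network is described by two integer genomes: a *structure*
triple (number of conv / pool / fully-connected layers, each 1-5) and a
*layer* vector of 8 shared parameters (FC width, pooling padding / stride /
filter size, conv stride / padding / filter size / filter count).  The
decoder floors real-valued search positions and clamps them into range, so
any real position yields a valid genome.

Networks are assembled as alternating conv->pool pairs, surplus convs, then
surplus pools, then the FC stack and a final K-way softmax.  Layers that
would shrink a spatial extent below one pixel are skipped.  Everything runs
on numpy; feature-vector inputs are handled as 1 x D single-channel images
so the same conv/pool machinery serves both input modes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

logger = logging.getLogger(__name__)

__all__ = [
    "STRUCTURE_RANGES",
    "LAYER_RANGES",
    "StructureGenome",
    "LayerGenome",
    "TrainSettings",
    "LabeledDataset",
    "CNNConfig",
    "DivergenceError",
    "decode_genome",
    "decode_structure",
    "decode_layers",
    "assemble_architecture",
    "train_network",
    "predict",
]

# hyperparameter ranges (inclusive integer bounds)
STRUCTURE_RANGES: tuple[tuple[int, int], ...] = ((1, 5), (1, 5), (1, 5))  # nc, np, nf
LAYER_RANGES: tuple[tuple[int, int], ...] = (
    (4, 128),  # op: FC output neurons
    (0, 1),    # p_pp: pooling padding (0 valid / 1 same)
    (1, 5),    # p_ss: pooling stride
    (1, 13),   # p_fs: pooling filter size
    (1, 5),    # c_ss: conv stride
    (0, 1),    # c_pp: conv padding (0 valid / 1 same)
    (1, 13),   # c_fs: conv filter size
    (1, 64),   # c_nf: conv filter count
)

_PAD_NEG = -1.0e30  # pooling pad value; never selected over real pixels


class DivergenceError(RuntimeError):
    """Raised when training produces a non-finite loss."""


@dataclass(frozen=True)
class StructureGenome:
    nc: int
    np_: int
    nf: int

    def __post_init__(self) -> None:
        for value, (lo, hi) in zip((self.nc, self.np_, self.nf), STRUCTURE_RANGES):
            if not lo <= value <= hi:
                raise ValueError(f"structure value {value} outside [{lo}, {hi}]")

    def as_array(self) -> np.ndarray:
        return np.array([self.nc, self.np_, self.nf], dtype=int)


@dataclass(frozen=True)
class LayerGenome:
    op: int
    p_pp: int
    p_ss: int
    p_fs: int
    c_ss: int
    c_pp: int
    c_fs: int
    c_nf: int

    def __post_init__(self) -> None:
        for value, (lo, hi) in zip(self.as_tuple(), LAYER_RANGES):
            if not lo <= value <= hi:
                raise ValueError(f"layer value {value} outside [{lo}, {hi}]")

    def as_tuple(self) -> tuple[int, ...]:
        return (self.op, self.p_pp, self.p_ss, self.p_fs, self.c_ss, self.c_pp, self.c_fs, self.c_nf)

    def as_array(self) -> np.ndarray:
        return np.array(self.as_tuple(), dtype=int)

    @classmethod
    def midpoint(cls) -> "LayerGenome":
        """Integer midpoints of the ranges; the phase-1 default layer genome."""
        return cls(*((lo + hi) // 2 for lo, hi in LAYER_RANGES))


@dataclass(frozen=True)
class TrainSettings:
    learning_rate: float = 0.01
    epochs: int = 5
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("learning_rate and batch_size must be positive, epochs >= 0")


@dataclass
class LabeledDataset:
    """Feature vectors (N x D) or images (N x H x W) with integer labels."""

    items: np.ndarray
    labels: np.ndarray
    split: str = "train"
    n_classes: int = 4

    def __post_init__(self) -> None:
        self.items = np.asarray(self.items, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.items) != len(self.labels):
            raise ValueError("items and labels length mismatch")
        if len(self.labels) and (self.labels.min() < 0 or self.labels.max() >= self.n_classes):
            raise ValueError("labels outside declared class range")

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx: np.ndarray, split: str | None = None) -> "LabeledDataset":
        return LabeledDataset(self.items[idx], self.labels[idx], split or self.split, self.n_classes)


def decode_genome(position: Sequence[float], ranges: Sequence[tuple[int, int]]) -> np.ndarray:
    """Floor each coordinate, then clamp into its integer range."""
    position = np.asarray(position, dtype=float)
    if len(position) != len(ranges):
        raise ValueError("position length does not match range list")
    lo = np.array([r[0] for r in ranges])
    hi = np.array([r[1] for r in ranges])
    return np.clip(np.floor(position).astype(int), lo, hi)


def decode_structure(position: Sequence[float]) -> StructureGenome:
    return StructureGenome(*map(int, decode_genome(position, STRUCTURE_RANGES)))


def decode_layers(position: Sequence[float]) -> LayerGenome:
    return LayerGenome(*map(int, decode_genome(position, LAYER_RANGES)))


# ---------------------------------------------------------------------------
# architecture assembly


@dataclass(frozen=True)
class ConvSpec:
    filters: int
    size: int
    stride: int
    same_padding: bool


@dataclass(frozen=True)
class PoolSpec:
    size: int
    stride: int
    same_padding: bool


@dataclass(frozen=True)
class DenseSpec:
    units: int


@dataclass(frozen=True)
class CNNConfig:
    input_shape: tuple[int, int]  # (H, W); feature vectors are (1, D)
    layers: tuple[object, ...]
    n_classes: int = 4
    skipped: tuple[str, ...] = ()


def _out_extent(n: int, size: int, stride: int, same: bool) -> int:
    if same:
        return math.ceil(n / stride)
    return (n - size) // stride + 1


def _spatial_after(shape: tuple[int, int], size: int, stride: int, same: bool) -> tuple[int, int]:
    # unit-height (1-D) inputs keep their height; filters collapse to 1 there
    h = 1 if shape[0] == 1 else _out_extent(shape[0], size, stride, same)
    w = _out_extent(shape[1], size, stride, same)
    return h, w


def assemble_architecture(
    structure: StructureGenome,
    layers: LayerGenome,
    input_shape: tuple[int, ...],
    n_classes: int = 4,
) -> CNNConfig:
    """Order: conv->pool pairs, surplus convs, surplus pools, FC stack, softmax.

    All conv layers share (c_fs, c_nf, c_ss, c_pp); all pools share
    (p_fs, p_ss, p_pp).  Any conv/pool whose output extent would drop below
    1 is skipped and recorded in ``skipped``.
    """
    if not input_shape:
        raise ValueError("empty input shape")
    if len(input_shape) == 1:
        shape: tuple[int, int] = (1, int(input_shape[0]))
    elif len(input_shape) == 2:
        shape = (int(input_shape[0]), int(input_shape[1]))
    else:
        raise ValueError(f"input shape must be 1-D or 2-D, got {input_shape}")
    if min(shape) < 1:
        raise ValueError("input extents must be positive")

    conv = ConvSpec(layers.c_nf, layers.c_fs, layers.c_ss, bool(layers.c_pp))
    pool = PoolSpec(layers.p_fs, layers.p_ss, bool(layers.p_pp))
    plan: list[tuple[str, object]] = []
    n_pairs = min(structure.nc, structure.np_)
    for _ in range(n_pairs):
        plan.append(("conv", conv))
        plan.append(("pool", pool))
    plan.extend(("conv", conv) for _ in range(structure.nc - n_pairs))
    plan.extend(("pool", pool) for _ in range(structure.np_ - n_pairs))

    built: list[object] = []
    skipped: list[str] = []
    cur = shape
    for idx, (kind, spec) in enumerate(plan):
        size, stride, same = (
            (spec.size, spec.stride, spec.same_padding)
            if isinstance(spec, (ConvSpec, PoolSpec))
            else (1, 1, False)
        )
        nxt = _spatial_after(cur, size, stride, same)
        if min(nxt) < 1:
            skipped.append(f"{kind}@{idx}")
            logger.warning("skipping %s layer %d: output extent %s below 1", kind, idx, nxt)
            continue
        built.append(spec)
        cur = nxt
    built.extend(DenseSpec(layers.op) for _ in range(structure.nf))
    built.append(DenseSpec(n_classes))
    return CNNConfig(input_shape=shape, layers=tuple(built), n_classes=n_classes, skipped=tuple(skipped))


# ---------------------------------------------------------------------------
# numpy layers


def _pad_amount(n: int, size: int, stride: int) -> tuple[int, int]:
    out = math.ceil(n / stride)
    total = max((out - 1) * stride + size - n, 0)
    return total // 2, total - total // 2


class _Conv:
    def __init__(self, spec: ConvSpec, in_channels: int, in_shape: tuple[int, int], rng: np.random.Generator):
        self.stride = spec.stride
        self.same = spec.same_padding
        self.fh = min(spec.size, in_shape[0]) if in_shape[0] == 1 else spec.size
        self.fw = spec.size
        self.stride_h = spec.stride if in_shape[0] > 1 else 1
        fan_in = in_channels * self.fh * self.fw
        self.W = rng.standard_normal((spec.filters, in_channels, self.fh, self.fw)) * math.sqrt(2.0 / fan_in)
        self.b = np.zeros(spec.filters)
        self.out_shape = _spatial_after(in_shape, spec.size, spec.stride, spec.same_padding)
        self.out_channels = spec.filters

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.same:
            ph = _pad_amount(x.shape[2], self.fh, self.stride_h)
            pw = _pad_amount(x.shape[3], self.fw, self.stride)
            x = np.pad(x, ((0, 0), (0, 0), ph, pw))
        self._x_padded_shape = x.shape
        win = sliding_window_view(x, (self.fh, self.fw), axis=(2, 3))
        self._cols = win[:, :, :: self.stride_h, :: self.stride, :, :]
        y = np.einsum("nchwij,fcij->nfhw", self._cols, self.W, optimize=True)
        return y + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray, lr: float) -> np.ndarray:
        dW = np.einsum("nfhw,nchwij->fcij", dy, self._cols, optimize=True)
        db = dy.sum(axis=(0, 2, 3))
        dcols = np.einsum("nfhw,fcij->nchwij", dy, self.W, optimize=True)
        dx_pad = np.zeros(self._x_padded_shape)
        Ho, Wo = dy.shape[2], dy.shape[3]
        for i in range(self.fh):
            for j in range(self.fw):
                dx_pad[:, :, i : i + self.stride_h * Ho : self.stride_h, j : j + self.stride * Wo : self.stride] += dcols[:, :, :, :, i, j]
        if self.same:
            h, w = self._in_hw
            ph = _pad_amount(h, self.fh, self.stride_h)
            pw = _pad_amount(w, self.fw, self.stride)
            dx_pad = dx_pad[:, :, ph[0] : ph[0] + h, pw[0] : pw[0] + w]
        self.W -= lr * dW
        self.b -= lr * db
        return dx_pad

    def __call__(self, x: np.ndarray) -> np.ndarray:
        self._in_hw = (x.shape[2], x.shape[3])
        return self.forward(x)


class _MaxPool:
    def __init__(self, spec: PoolSpec, in_shape: tuple[int, int]):
        self.fh = min(spec.size, in_shape[0]) if in_shape[0] == 1 else spec.size
        self.fw = spec.size
        self.stride_h = spec.stride if in_shape[0] > 1 else 1
        self.stride = spec.stride
        self.same = spec.same_padding
        self.out_shape = _spatial_after(in_shape, spec.size, spec.stride, spec.same_padding)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        self._in_hw = (x.shape[2], x.shape[3])
        if self.same:
            ph = _pad_amount(x.shape[2], self.fh, self.stride_h)
            pw = _pad_amount(x.shape[3], self.fw, self.stride)
            x = np.pad(x, ((0, 0), (0, 0), ph, pw), constant_values=_PAD_NEG)
        self._x_padded_shape = x.shape
        win = sliding_window_view(x, (self.fh, self.fw), axis=(2, 3))
        win = win[:, :, :: self.stride_h, :: self.stride, :, :]
        flat = win.reshape(win.shape[:4] + (self.fh * self.fw,))
        self._argmax = flat.argmax(axis=-1)
        return flat.max(axis=-1)

    def backward(self, dy: np.ndarray, lr: float) -> np.ndarray:
        dx_pad = np.zeros(self._x_padded_shape)
        Ho, Wo = dy.shape[2], dy.shape[3]
        for i in range(self.fh):
            for j in range(self.fw):
                mask = self._argmax == i * self.fw + j
                dx_pad[:, :, i : i + self.stride_h * Ho : self.stride_h, j : j + self.stride * Wo : self.stride] += dy * mask
        if self.same:
            h, w = self._in_hw
            ph = _pad_amount(h, self.fh, self.stride_h)
            pw = _pad_amount(w, self.fw, self.stride)
            dx_pad = dx_pad[:, :, ph[0] : ph[0] + h, pw[0] : pw[0] + w]
        return dx_pad


class _ReLU:
    def __call__(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray, lr: float) -> np.ndarray:
        return dy * self._mask


class _Flatten:
    def __call__(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray, lr: float) -> np.ndarray:
        return dy.reshape(self._shape)


class _Dense:
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, final: bool = False):
        scale = 0.01 if final else math.sqrt(2.0 / in_dim)
        self.W = rng.standard_normal((in_dim, out_dim)) * scale
        self.b = np.zeros(out_dim)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray, lr: float) -> np.ndarray:
        dW = self._x.T @ dy
        db = dy.sum(axis=0)
        dx = dy @ self.W.T
        self.W -= lr * dW
        self.b -= lr * db
        return dx


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class CNNModel:
    """Assembled network plus input standardization statistics."""

    def __init__(self, config: CNNConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        self._layers: list[object] = []
        shape = config.input_shape
        channels = 1
        dense_started = False
        flat_dim = None
        specs = list(config.layers)
        for i, spec in enumerate(specs):
            if isinstance(spec, ConvSpec):
                layer = _Conv(spec, channels, shape, rng)
                self._layers.append(layer)
                self._layers.append(_ReLU())
                shape = layer.out_shape
                channels = layer.out_channels
            elif isinstance(spec, PoolSpec):
                layer = _MaxPool(spec, shape)
                self._layers.append(layer)
                shape = layer.out_shape
            elif isinstance(spec, DenseSpec):
                if not dense_started:
                    self._layers.append(_Flatten())
                    flat_dim = channels * shape[0] * shape[1]
                    dense_started = True
                final = i == len(specs) - 1
                self._layers.append(_Dense(flat_dim, spec.units, rng, final=final))
                if not final:
                    self._layers.append(_ReLU())
                flat_dim = spec.units
        self.feat_mean: np.ndarray | float = 0.0
        self.feat_std: np.ndarray | float = 1.0
        self.final_loss: float | None = None

    # -- input plumbing -----------------------------------------------------
    def _prepare(self, items: np.ndarray) -> np.ndarray:
        x = np.asarray(items, dtype=float)
        if x.ndim == 2:  # feature vectors -> 1 x D single-channel images
            x = x[:, None, None, :]
        elif x.ndim == 3:
            x = x[:, None, :, :]
        else:
            raise ValueError(f"items must be N x D or N x H x W, got shape {x.shape}")
        expected = self.config.input_shape
        if x.shape[2:] != expected:
            raise ValueError(f"item shape {x.shape[2:]} does not match model input {expected}")
        return (x - self.feat_mean) / self.feat_std

    def fit_standardizer(self, items: np.ndarray) -> None:
        x = np.asarray(items, dtype=float)
        if x.ndim == 2:
            mean = x.mean(axis=0)
            std = x.std(axis=0)
            std[std == 0] = 1.0
            self.feat_mean = mean[None, None, None, :]
            self.feat_std = std[None, None, None, :]
        else:
            std = float(x.std())
            self.feat_mean = float(x.mean())
            self.feat_std = std if std > 0 else 1.0

    # -- forward / backward -------------------------------------------------
    def forward(self, items: np.ndarray) -> np.ndarray:
        h = self._prepare(items)
        for layer in self._layers:
            h = layer(h)
        return h

    def train_step(self, items: np.ndarray, labels: np.ndarray, lr: float) -> float:
        logits = self.forward(items)
        probs = _softmax(logits)
        n = len(labels)
        loss = float(-np.mean(np.log(probs[np.arange(n), labels] + 1e-12)))
        grad = probs.copy()
        grad[np.arange(n), labels] -= 1.0
        grad /= n
        for layer in reversed(self._layers):
            grad = layer.backward(grad, lr)
        return loss

    def loss(self, items: np.ndarray, labels: np.ndarray) -> float:
        probs = _softmax(self.forward(items))
        return float(-np.mean(np.log(probs[np.arange(len(labels)), labels] + 1e-12)))


def train_network(
    config: CNNConfig, data: LabeledDataset, settings: TrainSettings
) -> tuple[CNNModel, float]:
    """Mini-batch SGD on softmax cross-entropy; returns (model, final loss)."""
    if len(data) == 0:
        raise ValueError("training data is empty")
    model = CNNModel(config, seed=settings.seed)
    model.fit_standardizer(data.items)
    if settings.epochs == 0:
        loss = model.loss(data.items, data.labels)
        model.final_loss = loss
        return model, loss
    rng = np.random.default_rng(settings.seed)
    loss = math.nan
    for _ in range(settings.epochs):
        order = rng.permutation(len(data))
        epoch_losses = []
        for start in range(0, len(data), settings.batch_size):
            idx = order[start : start + settings.batch_size]
            batch_loss = model.train_step(data.items[idx], data.labels[idx], settings.learning_rate)
            if not math.isfinite(batch_loss):
                raise DivergenceError(f"non-finite loss {batch_loss} during training")
            epoch_losses.append(batch_loss)
        loss = float(np.mean(epoch_losses))
    model.final_loss = loss
    return model, loss


def predict(model: CNNModel, items: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities (rows sum to 1) and argmax labels (ties -> lowest)."""
    probs = _softmax(model.forward(items))
    return probs, probs.argmax(axis=1)
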