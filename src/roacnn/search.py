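"""Two-phase swarm search over CNN hyperparameters.

Phase 1 optimizes the 3-value structure genome (conv/pool/FC layer counts)
with a 5-agent swarm while the 8 layer parameters sit at their range
midpoints; phase 2 freezes the winning structure and optimizes the 8-value
layer genome with a 10-agent swarm, half seeded near the phase-1 defaults
and half uniform.  Fitness is negated validation accuracy of the assembled
classifier on an inner split of the training data — the optimizer
minimizes.  Eleven hyperparameters are searched in total (3 + 8).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np

from . import cnn, metrics, roa
from .cnn import (
    LAYER_RANGES,
    STRUCTURE_RANGES,
    LabeledDataset,
    LayerGenome,
    StructureGenome,
    TrainSettings,
    decode_layers,
    decode_structure,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SearchSpecification",
    "SearchResult",
    "stratified_split",
    "fitness_of",
    "phase1_search",
    "phase2_search",
    "train_and_evaluate",
    "run_mproh",
]

PHASE1_DIMENSIONS = 3
PHASE2_DIMENSIONS = 8


def _genome_box(ranges: tuple[tuple[int, int], ...]) -> roa.SearchSpace:
    # decoder floors, so [lo, hi + 1] makes every integer equally reachable
    lower = np.array([lo for lo, _ in ranges], dtype=float)
    upper = np.array([hi + 1 for _, hi in ranges], dtype=float)
    return roa.SearchSpace(lower, upper)


@dataclass(frozen=True)
class SearchSpecification:
    phase1: roa.ROAConfig = field(default_factory=lambda: roa.ROAConfig(population=5, max_iter=10))
    phase2: roa.ROAConfig = field(default_factory=lambda: roa.ROAConfig(population=10, max_iter=10))
    train_settings: TrainSettings = field(default_factory=TrainSettings)
    final_epochs: int = 15
    inner_val_fraction: float = 0.2
    test_fraction: float = 0.2
    n_classes: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.inner_val_fraction < 1.0:
            raise ValueError("inner_val_fraction must lie in (0, 1)")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")

    @property
    def total_hyperparameters(self) -> int:
        return PHASE1_DIMENSIONS + PHASE2_DIMENSIONS

    def reseeded(self, seed: int) -> "SearchSpecification":
        return replace(
            self,
            seed=seed,
            phase1=replace(self.phase1, seed=seed),
            phase2=replace(self.phase2, seed=seed + 1),
            train_settings=replace(self.train_settings, seed=seed),
        )


@dataclass
class SearchResult:
    structure: StructureGenome
    layers: LayerGenome
    phase1_trace: roa.OptimizationTrace
    phase2_trace: roa.OptimizationTrace
    best_fitness: float
    report: metrics.MetricsReport | None
    seed: int

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "seed": self.seed,
            "structure": {"nc": self.structure.nc, "np": self.structure.np_, "nf": self.structure.nf},
            "layers": dict(zip(("op", "p_pp", "p_ss", "p_fs", "c_ss", "c_pp", "c_fs", "c_nf"), self.layers.as_tuple())),
            "best_fitness": self.best_fitness,
            "phase1_best_fitness": [float(v) for v in self.phase1_trace.best_fitness],
            "phase2_best_fitness": [float(v) for v in self.phase2_trace.best_fitness],
            "metrics": self.report.as_dict() if self.report is not None else None,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def stratified_split(
    labels: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class shuffled split; returns (large_part, held_out) index arrays."""
    labels = np.asarray(labels)
    held, kept = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_held = max(1, round(len(idx) * fraction))
        held.append(idx[:n_held])
        kept.append(idx[n_held:])
    return np.sort(np.concatenate(kept)), np.sort(np.concatenate(held))


def _genome_seed(base_seed: int, genome: tuple[int, ...]) -> int:
    return int(np.random.SeedSequence((base_seed,) + genome).generate_state(1)[0])


def fitness_of(
    structure: StructureGenome,
    layers: LayerGenome,
    data: LabeledDataset,
    spec: SearchSpecification,
) -> float:
    """Negated inner-validation accuracy of the assembled, trained classifier.

    Deterministic per (genome, seed): the training seed and the inner split
    are both derived from the spec seed and the genome, so evaluation order
    does not matter.  Training divergence scores as accuracy 0 (worst).
    """
    genome = tuple(structure.as_array()) + structure_layers_key(layers)
    eval_seed = _genome_seed(spec.seed, genome)
    rng = np.random.default_rng(eval_seed)
    train_idx, val_idx = stratified_split(data.labels, spec.inner_val_fraction, rng)
    inner_train = data.subset(train_idx, "inner-train")
    inner_val = data.subset(val_idx, "inner-val")
    item_shape = data.items.shape[1:]
    config = cnn.assemble_architecture(structure, layers, item_shape, spec.n_classes)
    settings = replace(spec.train_settings, seed=eval_seed)
    try:
        model, _ = cnn.train_network(config, inner_train, settings)
    except cnn.DivergenceError:
        logger.warning("training diverged for genome %s; scoring accuracy 0", genome)
        return 0.0
    _, pred = cnn.predict(model, inner_val.items)
    accuracy = float(np.mean(pred == inner_val.labels))
    return -accuracy


def structure_layers_key(layers: LayerGenome) -> tuple[int, ...]:
    return layers.as_tuple()


def _cached(fn: Callable[[tuple[int, ...]], float]) -> Callable[[tuple[int, ...]], float]:
    cache: dict[tuple[int, ...], float] = {}

    def wrapped(key: tuple[int, ...]) -> float:
        if key not in cache:
            cache[key] = fn(key)
        return cache[key]

    return wrapped


def phase1_search(
    spec: SearchSpecification,
    data: LabeledDataset | None = None,
    fitness_fn: Callable[[StructureGenome], float] | None = None,
) -> tuple[StructureGenome, roa.OptimizationTrace]:
    """Swarm of 5 over the 3-dim structure box, layer genome at midpoints."""
    if fitness_fn is None:
        if data is None:
            raise ValueError("either data or fitness_fn must be provided")
        default_layers = LayerGenome.midpoint()

        def fitness_fn(s: StructureGenome) -> float:  # noqa: F811
            return fitness_of(s, default_layers, data, spec)

    evaluate = _cached(lambda key: fitness_fn(StructureGenome(*key)))

    def objective(position: np.ndarray) -> float:
        return evaluate(tuple(int(v) for v in cnn.decode_genome(position, STRUCTURE_RANGES)))

    trace = roa.optimize(objective, _genome_box(STRUCTURE_RANGES), spec.phase1)
    return decode_structure(trace.best_position), trace


def phase2_search(
    spec: SearchSpecification,
    data: LabeledDataset | None = None,
    structure: StructureGenome | None = None,
    fitness_fn: Callable[[LayerGenome], float] | None = None,
) -> tuple[LayerGenome, roa.OptimizationTrace]:
    """Swarm of 10 over the 8-dim layer box with the structure frozen.

    Five agents start near the phase-1 layer defaults (midpoints, jittered),
    five start uniform in the box.
    """
    if fitness_fn is None:
        if data is None or structure is None:
            raise ValueError("either (data, structure) or fitness_fn must be provided")

        def fitness_fn(l: LayerGenome) -> float:  # noqa: F811
            return fitness_of(structure, l, data, spec)

    evaluate = _cached(lambda key: fitness_fn(LayerGenome(*key)))

    def objective(position: np.ndarray) -> float:
        return evaluate(tuple(int(v) for v in cnn.decode_genome(position, LAYER_RANGES)))

    space = _genome_box(LAYER_RANGES)
    rng = np.random.default_rng(spec.phase2.seed)
    midpoints = LayerGenome.midpoint().as_array().astype(float) + 0.5
    n_seeded = min(5, spec.phase2.population)
    widths = space.upper - space.lower
    seeded = midpoints[None, :] + rng.normal(scale=0.05 * widths, size=(n_seeded, space.dimension))
    trace = roa.optimize(objective, space, spec.phase2, initial_positions=seeded)
    return decode_layers(trace.best_position), trace


def train_and_evaluate(
    structure: StructureGenome,
    layers: LayerGenome,
    train: LabeledDataset,
    test: LabeledDataset,
    spec: SearchSpecification,
) -> metrics.MetricsReport:
    """Train the given genome on the full training split, report on the test split."""
    config = cnn.assemble_architecture(structure, layers, train.items.shape[1:], spec.n_classes)
    settings = replace(spec.train_settings, epochs=spec.final_epochs, seed=spec.seed)
    model, _ = cnn.train_network(config, train, settings)
    _, pred = cnn.predict(model, test.items)
    cm = metrics.confusion_matrix(test.labels, pred, spec.n_classes)
    return metrics.compute_metrics(cm)


def run_mproh(spec: SearchSpecification, dataset: LabeledDataset) -> SearchResult:
    """Full search: 80/20 split, phase 1, phase 2, retrain, test metrics.

    The test split is created first and never seen by any fitness call.
    """
    labels = dataset.labels
    counts = np.bincount(labels, minlength=spec.n_classes)
    if np.any(counts < 5):
        raise ValueError(f"every class needs at least 5 items, got counts {counts.tolist()}")
    rng = np.random.default_rng(spec.seed)
    train_idx, test_idx = stratified_split(labels, spec.test_fraction, rng)
    train = dataset.subset(train_idx, "train")
    test = dataset.subset(test_idx, "test")

    structure, trace1 = phase1_search(spec, train)
    layers, trace2 = phase2_search(spec, train, structure)
    best_fitness = float(trace2.best_fitness[-1])
    report = train_and_evaluate(structure, layers, train, test, spec)
    return SearchResult(
        structure=structure,
        layers=layers,
        phase1_trace=trace1,
        phase2_trace=trace2,
        best_fitness=best_fitness,
        report=report,
        seed=spec.seed,
    )


def run_two_fold(spec: SearchSpecification, dataset: LabeledDataset) -> tuple[SearchResult, SearchResult]:
    """Two-fold variant: split in half, search on each fold, test on the other."""
    rng = np.random.default_rng(spec.seed)
    fold_a, fold_b = stratified_split(dataset.labels, 0.5, rng)
    results = []
    for train_idx, test_idx in ((fold_a, fold_b), (fold_b, fold_a)):
        train = dataset.subset(train_idx, "train")
        test = dataset.subset(test_idx, "test")
        structure, trace1 = phase1_search(spec, train)
        layers, trace2 = phase2_search(spec, train, structure)
        report = train_and_evaluate(structure, layers, train, test, spec)
        results.append(
            SearchResult(
                structure=structure,
                layers=layers,
                phase1_trace=trace1,
                phase2_trace=trace2,
                best_fitness=float(trace2.best_fitness[-1]),
                report=report,
                seed=spec.seed,
            )
        )
    return tuple(results)  # type: ignore[return-value]
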