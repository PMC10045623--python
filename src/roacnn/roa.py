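"""Bound-constrained remora swarm optimizer (minimizer).

A population of "remoras" rides a host: agents with host flag ``H == 0``
exploit with a whale-style exponential spiral toward the elite, agents with
``H == 1`` explore with a sailfish-style elite-following jump.  After each
move an *experience attack* probes one step along the agent's recent
displacement; an improving probe triggers a host change (the probe is
adopted and ``H`` is redrawn), otherwise the agent performs a small
host-feeding step inside a linearly shrinking volume, damped by a two-stage
inertia weight.

The optimizer is a general minimizer over a rectangular box and is reused by
:mod:`roacnn.search` with CNN validation accuracy (negated) as objective.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SearchSpace",
    "ROAConfig",
    "RemoraState",
    "OptimizationTrace",
    "initialize_population",
    "inertia_weight",
    "sfo_move",
    "experience_attack",
    "woa_move",
    "host_feeding_move",
    "clip_to_bounds",
    "optimize",
]

Objective = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class SearchSpace:
    """Rectangular feasible box: ``lower[i] < upper[i]`` for every axis."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        if lower.ndim != 1 or lower.shape != upper.shape:
            raise ValueError("lower and upper must be 1-D vectors of equal length")
        if lower.size == 0:
            raise ValueError("search space must have at least one dimension")
        if not np.all(lower < upper):
            raise ValueError("every lower bound must be strictly below its upper bound")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @property
    def dimension(self) -> int:
        return self.lower.size

    @classmethod
    def box(cls, dimension: int, lower: float = -10.0, upper: float = 10.0) -> "SearchSpace":
        """Symmetric box; defaults match the reference optimizer settings (±10)."""
        if dimension < 1:
            raise ValueError("dimension must be positive")
        return cls(np.full(dimension, lower), np.full(dimension, upper))


@dataclass(frozen=True)
class ROAConfig:
    population: int = 50
    max_iter: int = 100
    remora_factor: float = 0.1
    inertia_switch: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 1:
            raise ValueError("population must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.remora_factor <= 0:
            raise ValueError("remora_factor must be > 0")
        if not 0.0 < self.inertia_switch < 1.0:
            raise ValueError("inertia_switch must lie in (0, 1)")


@dataclass
class RemoraState:
    """One candidate: position, its previous position, fitness, host flag."""

    position: np.ndarray
    prev_position: np.ndarray
    fitness: float
    host_flag: int

    def __post_init__(self) -> None:
        if self.host_flag not in (0, 1):
            raise ValueError("host_flag must be 0 or 1")


@dataclass
class OptimizationTrace:
    """Elitist per-iteration record; ``best_fitness`` has ``max_iter + 1`` entries."""

    best_fitness: np.ndarray
    best_position: np.ndarray
    evaluations: int
    seed: int
    config: ROAConfig = field(repr=False, default=None)  # type: ignore[assignment]

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "evaluations": self.evaluations,
            "best_fitness": [float(v) for v in self.best_fitness],
            "best_position": [float(v) for v in self.best_position],
            "config": {
                "population": self.config.population,
                "max_iter": self.config.max_iter,
                "remora_factor": self.config.remora_factor,
                "inertia_switch": self.config.inertia_switch,
                "seed": self.config.seed,
            }
            if self.config is not None
            else None,
        }
        return json.dumps(payload, indent=2)


def initialize_population(
    space: SearchSpace, config: ROAConfig, rng: np.random.Generator | None = None
) -> list[RemoraState]:
    """Uniform positions in the box, prev == current, host flag a fair coin."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    states = []
    for _ in range(config.population):
        pos = rng.uniform(space.lower, space.upper)
        states.append(
            RemoraState(
                position=pos,
                prev_position=pos.copy(),
                fitness=math.inf,
                host_flag=int(rng.integers(0, 2)),
            )
        )
    return states


def inertia_weight(t: int, config: ROAConfig) -> float:
    """Two-stage schedule: flat 0.9 early, sigmoid decay after the switch point.

    Returns 0.9 while ``t < inertia_switch * max_iter``, afterwards
    ``1 / (1 + exp(10 t / max_iter - 2))``; always in (0, 0.9].
    """
    if not 0 <= t <= config.max_iter:
        raise ValueError(f"iteration index {t} outside [0, {config.max_iter}]")
    if t < config.inertia_switch * config.max_iter:
        return 0.9
    return 1.0 / (1.0 + math.exp(10.0 * t / config.max_iter - 2.0))


def _check_same_shape(*vectors: np.ndarray) -> None:
    shapes = {np.asarray(v).shape for v in vectors}
    if len(shapes) != 1:
        raise ValueError(f"position vectors must share one shape, got {shapes}")


def sfo_move(r_best: np.ndarray, r_rand: np.ndarray, uniform_draw: float) -> np.ndarray:
    """Elite-following exploration jump toward the historical best position."""
    r_best = np.asarray(r_best, dtype=float)
    r_rand = np.asarray(r_rand, dtype=float)
    _check_same_shape(r_best, r_rand)
    return r_best - (uniform_draw * (r_best + r_rand) / 2.0 - r_rand)


def experience_attack(r_I: np.ndarray, r_pre: np.ndarray, normal_draw: float) -> np.ndarray:
    """Probe one step along the agent's own recent displacement."""
    r_I = np.asarray(r_I, dtype=float)
    r_pre = np.asarray(r_pre, dtype=float)
    _check_same_shape(r_I, r_pre)
    return r_I + (r_I - r_pre) * normal_draw


def woa_scale(t: int, max_iter: int) -> float:
    """Spiral scale a(t) = -(1 + t/Tmax), linearly from -1 down to -2."""
    if not 0 <= t <= max_iter:
        raise ValueError(f"iteration index {t} outside [0, {max_iter}]")
    return -(1.0 + t / max_iter)


def woa_move(
    r_I: np.ndarray,
    r_best: np.ndarray,
    t: int,
    max_iter: int,
    uniform_draw: float,
) -> np.ndarray:
    """Whale-style exponential spiral around the elite.

    With ``a = -(1 + t/Tmax)`` and ``alpha = u (a - 1) + 1`` the step is
    ``|r_best - r_I| * exp(alpha) * cos(2 pi alpha)`` added to the current
    position; the spiral tightens as the schedule advances.
    """
    r_I = np.asarray(r_I, dtype=float)
    r_best = np.asarray(r_best, dtype=float)
    _check_same_shape(r_I, r_best)
    a = woa_scale(t, max_iter)
    alpha = uniform_draw * (a - 1.0) + 1.0
    d = np.abs(r_best - r_I)
    return d * math.exp(alpha) * math.cos(2.0 * math.pi * alpha) + r_I


def host_volume(t: int, max_iter: int) -> float:
    """Host volume V(t) = 2 (1 - t/Tmax), shrinking linearly from 2 to 0."""
    if not 0 <= t <= max_iter:
        raise ValueError(f"iteration index {t} outside [0, {max_iter}]")
    return 2.0 * (1.0 - t / max_iter)


def host_feeding_move(
    r_I: np.ndarray,
    r_best: np.ndarray,
    t: int,
    config: ROAConfig,
    uniform_draw: float,
) -> np.ndarray:
    """Small feeding step inside the shrinking host volume, inertia-damped.

    ``B`` is uniform on [-V, V]; the raw step ``A = B (r_I - C r_best)`` is
    scaled by the inertia weight before being applied.
    """
    r_I = np.asarray(r_I, dtype=float)
    r_best = np.asarray(r_best, dtype=float)
    _check_same_shape(r_I, r_best)
    V = host_volume(t, config.max_iter)
    B = 2.0 * V * uniform_draw - V
    A = B * (r_I - config.remora_factor * r_best)
    return r_I + inertia_weight(t, config) * A


def clip_to_bounds(position: np.ndarray, space: SearchSpace) -> np.ndarray:
    position = np.asarray(position, dtype=float)
    if position.shape != (space.dimension,):
        raise ValueError("position length does not match search space dimension")
    return np.clip(position, space.lower, space.upper)


def _evaluate(objective: Objective, position: np.ndarray) -> float:
    value = float(objective(position))
    if not math.isfinite(value):
        raise ValueError(f"objective returned non-finite value {value!r} at {position!r}")
    return value


def optimize(
    objective: Objective,
    space: SearchSpace,
    config: ROAConfig,
    initial_positions: np.ndarray | None = None,
) -> OptimizationTrace:
    """Run the full swarm loop and return the elitist trace.

    Per iteration and per agent: move by the spiral (H=0) or the elite jump
    (H=1), probe with an experience attack, adopt the probe and redraw H if
    it strictly improves the agent, otherwise host-feed; every visited
    position is clipped into the box before evaluation.  Deterministic for a
    given ``config.seed``.

    ``initial_positions`` (M x D, M <= population) overrides the uniformly
    drawn start positions of the first M agents; the rest stay random.
    """
    rng = np.random.default_rng(config.seed)
    swarm = initialize_population(space, config, rng)
    if initial_positions is not None:
        seeds = np.atleast_2d(np.asarray(initial_positions, dtype=float))
        if seeds.shape[0] > config.population or seeds.shape[1] != space.dimension:
            raise ValueError("initial_positions must be at most population x dimension")
        for state, pos in zip(swarm, seeds):
            clipped = clip_to_bounds(pos, space)
            state.position = clipped
            state.prev_position = clipped.copy()
    evaluations = 0
    for state in swarm:
        state.fitness = _evaluate(objective, state.position)
        evaluations += 1

    best_idx = int(np.argmin([s.fitness for s in swarm]))
    best_position = swarm[best_idx].position.copy()
    best_fitness = swarm[best_idx].fitness
    trace = np.empty(config.max_iter + 1)
    trace[0] = best_fitness

    for t in range(1, config.max_iter + 1):
        for state in swarm:
            old_position = state.position
            u_move = float(rng.uniform())
            if state.host_flag == 0:
                moved = woa_move(old_position, best_position, t, config.max_iter, u_move)
            else:
                r_rand = rng.uniform(space.lower, space.upper)
                moved = sfo_move(best_position, r_rand, u_move)
            moved = clip_to_bounds(moved, space)

            probe = experience_attack(moved, state.prev_position, float(rng.standard_normal()))
            probe = clip_to_bounds(probe, space)
            probe_fitness = _evaluate(objective, probe)
            evaluations += 1

            state.prev_position = old_position
            if probe_fitness < state.fitness:
                # host change: adopt the probe and pick a new host at random
                state.position = probe
                state.fitness = probe_fitness
                state.host_flag = int(rng.integers(0, 2))
            else:
                fed = host_feeding_move(moved, best_position, t, config, float(rng.uniform()))
                state.position = clip_to_bounds(fed, space)
                state.fitness = _evaluate(objective, state.position)
                evaluations += 1

            if state.fitness < best_fitness:  # ties keep the incumbent
                best_fitness = state.fitness
                best_position = state.position.copy()
        trace[t] = best_fitness

    return OptimizationTrace(
        best_fitness=trace,
        best_position=best_position,
        evaluations=evaluations,
        seed=config.seed,
        config=config,
    )
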