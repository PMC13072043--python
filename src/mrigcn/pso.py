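"""Particle-swarm search over (hidden_dim, learning_rate, dropout).

Standard inertia/cognitive/social velocity update with hard clipping to
the bounds, integer rounding of the hidden dimension, zero initial
velocities, and stagnation-based early stopping. Fitness is validation
accuracy after a short training run; each evaluation uses a seed derived
from the global seed and the particle index so the search is fully
deterministic and the global-best trace is exactly non-decreasing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from mrigcn.graph import GraphDataset
from mrigcn.model import DivergenceError, GcnParams, TrainConfig, init_params
from mrigcn.model import train as train_gcn

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchBounds:
    hid: tuple[int, int] = (128, 768)
    lr: tuple[float, float] = (1e-4, 1e-2)
    p: tuple[float, float] = (0.0, 0.5)

    def __post_init__(self) -> None:
        for lo, hi in (self.hid, self.lr, self.p):
            if not lo < hi:
                raise ValueError("each bound must satisfy lower < upper")

    @property
    def lower(self) -> np.ndarray:
        return np.array([self.hid[0], self.lr[0], self.p[0]], dtype=np.float64)

    @property
    def upper(self) -> np.ndarray:
        return np.array([self.hid[1], self.lr[1], self.p[1]], dtype=np.float64)


@dataclass
class SwarmConfig:
    n_particles: int = 30
    max_iters: int = 50
    inertia: float = 0.7
    cognitive: float = 1.5
    social: float = 1.5
    stagnation_delta: float = 1e-4
    stagnation_iters: int = 5
    fitness_epochs: int = 5  # E_short
    fitness_mode: str = "best"  # "best" or "last" epoch of the short run
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        if not 0 < self.inertia < 1:
            raise ValueError("inertia must lie in (0, 1)")
        if self.cognitive <= 0 or self.social <= 0:
            raise ValueError("cognitive and social coefficients must be positive")


@dataclass
class Particle:
    position: np.ndarray  # (hid, lr, p)
    velocity: np.ndarray
    pbest: np.ndarray
    pbest_val: float


@dataclass
class SwarmState:
    particles: list[Particle]
    gbest: np.ndarray
    gbest_val: float
    rng: np.random.Generator


def _project(x: np.ndarray, bounds: SearchBounds) -> np.ndarray:
    x = np.clip(x, bounds.lower, bounds.upper)
    x[0] = np.round(x[0])  # hid is integral
    return x


def init_swarm(
    bounds: SearchBounds,
    cfg: SwarmConfig,
    fitness: Callable[[np.ndarray, int], float],
) -> SwarmState:
    """Uniform positions within bounds, zero velocities, pbest = position."""
    rng = np.random.default_rng(cfg.seed)
    particles = []
    gbest, gbest_val = None, -np.inf
    for i in range(cfg.n_particles):
        x = bounds.lower + rng.random(3) * (bounds.upper - bounds.lower)
        x = _project(x, bounds)
        val = fitness(x, i)
        particles.append(
            Particle(position=x.copy(), velocity=np.zeros(3), pbest=x.copy(), pbest_val=val)
        )
        if val > gbest_val:
            gbest, gbest_val = x.copy(), val
    return SwarmState(particles=particles, gbest=gbest, gbest_val=gbest_val, rng=rng)


def update_particle(
    p: Particle,
    gbest: np.ndarray,
    bounds: SearchBounds,
    cfg: SwarmConfig,
    rng: np.random.Generator,
) -> None:
    """In-place velocity/position update with element-wise r1, r2 draws."""
    r1 = rng.random(3)
    r2 = rng.random(3)
    p.velocity = (
        cfg.inertia * p.velocity
        + cfg.cognitive * r1 * (p.pbest - p.position)
        + cfg.social * r2 * (gbest - p.position)
    )
    p.position = _project(p.position + p.velocity, bounds)


def evaluate_fitness(
    position: np.ndarray,
    data: GraphDataset,
    cfg: SwarmConfig,
    eval_seed: int = 0,
) -> float:
    """Validation accuracy of a short GCN training run at this position.

    Divergent candidates are penalized with fitness 0 so the search
    continues.
    """
    hid, lr, p = int(round(position[0])), float(position[1]), float(position[2])
    n_classes = int(data.labels[data.labels >= 0].max()) + 1
    params = init_params(data.X.shape[1], hid, n_classes, seed=eval_seed, dropout_p=p)
    tc = TrainConfig(
        learning_rate=lr,
        max_epochs=cfg.fitness_epochs,
        patience=cfg.fitness_epochs,
        seed=eval_seed,
    )
    try:
        _, hist = train_gcn(data, params, tc)
    except DivergenceError:
        logger.warning("training diverged at position %s; fitness 0", position)
        return 0.0
    if cfg.fitness_mode == "last":
        return float(hist.val_acc[-1])
    return float(hist.best_val_acc)


def optimize(
    bounds: SearchBounds,
    cfg: SwarmConfig,
    data: GraphDataset | None = None,
    fitness_fn: Callable[[np.ndarray], float] | None = None,
    trace_path: str | Path | None = None,
) -> tuple[np.ndarray, float, list[dict]]:
    """Run the swarm; returns (best position, best fitness, trace).

    Early-stops once the global best has improved by less than
    ``stagnation_delta`` for ``stagnation_iters`` consecutive iterations
    (the first in-loop iteration sets the stagnation baseline). The
    global-best trace is non-decreasing by construction.
    """
    if fitness_fn is not None:
        user_fn = fitness_fn

        def _fitness(x: np.ndarray, _pid: int) -> float:
            return user_fn(x)

    else:
        if data is None:
            raise ValueError("either data or fitness_fn is required")

        def _fitness(x: np.ndarray, pid: int) -> float:
            # per-evaluation seed derived from global seed + particle id
            return evaluate_fitness(x, data, cfg, eval_seed=cfg.seed * 100003 + pid)

    state = init_swarm(bounds, cfg, _fitness)
    trace: list[dict] = []
    stagnant = 0
    baseline = None
    for t in range(1, cfg.max_iters + 1):
        for pid, p in enumerate(state.particles):
            update_particle(p, state.gbest, bounds, cfg, state.rng)
            val = _fitness(p.position, pid)
            if val > p.pbest_val:
                p.pbest, p.pbest_val = p.position.copy(), val
            if val > state.gbest_val:
                state.gbest, state.gbest_val = p.position.copy(), val
        trace.append(
            {
                "iteration": t,
                "gbest_position": [float(v) for v in state.gbest],
                "gbest_value": float(state.gbest_val),
            }
        )
        if baseline is None:
            baseline = state.gbest_val
        else:
            if state.gbest_val - baseline < cfg.stagnation_delta:
                stagnant += 1
            else:
                stagnant = 0
            baseline = state.gbest_val
            if stagnant >= cfg.stagnation_iters:
                logger.info("PSO stagnation stop at iteration %d", t)
                break
    if trace_path is not None:
        with open(trace_path, "w") as f:
            for rec in trace:
                f.write(json.dumps(rec) + "\n")
    return state.gbest.copy(), float(state.gbest_val), trace
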