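"""Chaotic accelerated particle swarm optimization (CAPSO).

A velocity-free swarm minimizer.  Each particle carries a chaotic variable
advanced by the fully chaotic logistic map d <- 4 d (1 - d); its current
value is the mixing coefficient C2, and every coordinate updates as

    x <- (1 - C2) * x + C2 * p_g + C2 * r

with p_g the global best position and r a symmetric uniform perturbation
drawn per coordinate.  There is no velocity and no personal-best term: the
update is a chaotic contraction toward the global best plus exploration
noise.  The perturbation scale decays geometrically per iteration by
default, annealing from coarse exploration to fine local search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SwarmConfig",
    "SwarmState",
    "OptimizeResult",
    "logistic_step",
    "capso_step",
    "optimize",
]

log = logging.getLogger(__name__)

#: logistic-map seeds on degenerate orbits (fixed points or collapse to 0)
DEGENERATE_CHAOS_SEEDS = (0.25, 0.5, 0.75)


def logistic_step(d: float) -> float:
    """One step of the logistic map at full chaos parameter: 4 d (1 - d)."""
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"chaotic variable {d!r} outside [0, 1]")
    return 4.0 * d * (1.0 - d)


@dataclass(frozen=True)
class SwarmConfig:
    """Swarm hyperparameters.

    ``init_range`` bounds the uniform initialization (+-init_range);
    ``r_scale`` is the half-width of the uniform perturbation, decayed by
    ``r_decay`` per iteration.  ``chaos_seeds`` (one per particle, each in
    (0,1) and off the degenerate orbits {0.25, 0.5, 0.75}) default to draws
    from a stream derived from ``rng_seed``.
    """

    n_particles: int = 30
    n_iterations: int = 200
    init_range: float = 0.5
    r_scale: float = 0.5
    r_decay: float = 0.99
    chaos_seeds: tuple[float, ...] | None = None
    rng_seed: int = 0
    fitness_budget: int | None = None

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        if self.n_iterations < 1:
            raise ValueError("need at least 1 iteration")
        if self.init_range <= 0 or self.r_scale < 0:
            raise ValueError("init_range must be > 0 and r_scale >= 0")
        if not 0.0 < self.r_decay <= 1.0:
            raise ValueError("r_decay must lie in (0, 1]")
        if self.chaos_seeds is not None:
            if len(self.chaos_seeds) != self.n_particles:
                raise ValueError("need one chaos seed per particle")
            for d in self.chaos_seeds:
                if not 0.0 < d < 1.0 or any(
                    abs(d - bad) < 1e-12 for bad in DEGENERATE_CHAOS_SEEDS
                ):
                    raise ValueError(
                        f"chaos seed {d!r} must lie in (0,1) away from "
                        f"{DEGENERATE_CHAOS_SEEDS}"
                    )


@dataclass
class SwarmState:
    """Mutable swarm state: positions, chaotic variables, global best, trace."""

    positions: np.ndarray  # (n_particles, dim)
    chaos: np.ndarray  # (n_particles,)
    c2: np.ndarray  # (n_particles,) mixing coefficients of the last step
    best_position: np.ndarray  # (dim,)
    best_fitness: float
    iteration: int = 0
    trace: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class OptimizeResult:
    """Outcome of an optimization run.

    ``improvements`` holds (iteration, fitness, position) checkpoints at every
    strict improvement of the global best (including initialization), so a
    caller can re-select among incumbents by an external criterion.
    """

    best_position: np.ndarray
    best_fitness: float
    trace: list[float]
    improvements: list[tuple[int, float, np.ndarray]]
    n_evaluations: int

    def __iter__(self):
        return iter((self.best_position, self.best_fitness, self.trace))


def _draw_chaos_seeds(n: int, rng: np.random.Generator) -> np.ndarray:
    seeds = np.empty(n)
    for i in range(n):
        d = rng.uniform(0.05, 0.95)
        while any(abs(d - bad) < 1e-6 for bad in DEGENERATE_CHAOS_SEEDS):
            d = rng.uniform(0.05, 0.95)
        seeds[i] = d
    return seeds


def capso_step(
    state: SwarmState,
    fitness,
    rng: np.random.Generator,
    r_scale: float = 0.5,
    init_range: float = 0.5,
) -> SwarmState:
    """Advance the swarm one iteration in place.

    Each particle's chaotic variable moves one logistic step and becomes its
    C2; every coordinate contracts toward the global best with a fresh
    uniform(-r_scale, r_scale) perturbation; fitness is re-evaluated and the
    global best updated on strict improvement.  A particle whose fitness is
    non-finite is re-drawn uniformly within +-init_range.
    """
    n, dim = state.positions.shape
    for i in range(n):
        state.chaos[i] = logistic_step(state.chaos[i])
        c2 = state.chaos[i]
        state.c2[i] = c2
        r = rng.uniform(-r_scale, r_scale, size=dim)
        state.positions[i] = (
            (1.0 - c2) * state.positions[i] + c2 * state.best_position + c2 * r
        )
        value = float(fitness(state.positions[i]))
        if not np.isfinite(value):
            log.warning("non-finite fitness for particle %d; re-drawing", i)
            state.positions[i] = rng.uniform(-init_range, init_range, size=dim)
            value = float(fitness(state.positions[i]))
            if not np.isfinite(value):
                value = np.inf
        if value < state.best_fitness:
            state.best_fitness = value
            state.best_position = state.positions[i].copy()
    state.iteration += 1
    state.trace.append(state.best_fitness)
    return state


def optimize(fitness, dim: int, config: SwarmConfig) -> OptimizeResult:
    """Minimize ``fitness`` over R^dim with the chaotic accelerated swarm.

    Fully reproducible: the result is a pure function of (fitness, dim,
    config).  Stops after ``n_iterations`` iterations or once
    ``fitness_budget`` evaluations have been spent.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = np.random.default_rng(config.rng_seed)
    if config.chaos_seeds is not None:
        chaos = np.array(config.chaos_seeds, dtype=float)
    else:
        chaos = _draw_chaos_seeds(config.n_particles, rng)

    evaluations = 0

    def counted(x: np.ndarray) -> float:
        nonlocal evaluations
        evaluations += 1
        return float(fitness(x))

    positions = rng.uniform(-config.init_range, config.init_range,
                            size=(config.n_particles, dim))
    best_fitness = np.inf
    best_position = positions[0].copy()
    improvements: list[tuple[int, float, np.ndarray]] = []
    for i in range(config.n_particles):
        value = counted(positions[i])
        if not np.isfinite(value):
            value = np.inf
        if value < best_fitness:
            best_fitness = value
            best_position = positions[i].copy()
    improvements.append((0, best_fitness, best_position.copy()))

    state = SwarmState(
        positions=positions,
        chaos=chaos,
        c2=np.zeros(config.n_particles),
        best_position=best_position,
        best_fitness=best_fitness,
        trace=[best_fitness],
    )
    r_scale = config.r_scale
    for _ in range(config.n_iterations):
        if config.fitness_budget is not None and evaluations >= config.fitness_budget:
            break
        previous_best = state.best_fitness
        capso_step(state, counted, rng, r_scale=r_scale, init_range=config.init_range)
        if state.best_fitness < previous_best:
            improvements.append(
                (state.iteration, state.best_fitness, state.best_position.copy())
            )
        r_scale *= config.r_decay
    return OptimizeResult(
        best_position=state.best_position.copy(),
        best_fitness=state.best_fitness,
        trace=list(state.trace),
        improvements=improvements,
        n_evaluations=evaluations,
    )
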