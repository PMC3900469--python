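"""Hybrid GA-PSO optimizer for one decoupled gene sub-problem.

Each iteration ranks the population by fitness (minimization) and splits it:
the best fraction p are *elites*, kept and enhanced by a constriction-factor
PSO velocity/position update; the worst 1-p fraction is discarded and
replaced by offspring of a parent pool made of a fraction r of freshly
randomized individuals plus draws from the PSO-enhanced elites.  Offspring
are produced by tournament selection, a velocity-aware arithmetic crossover

    new1 = (old1.x + old2.x)/2 - phi1 * old2.v
    new2 = (old1.x + old2.x)/2 - phi2 * old1.v      (phi1, phi2 ~ U[0,1])

and Michalewicz non-uniform mutation, whose step Delta(t, y) =
y * (1 - u^{(1 - t/T)^b}) shrinks toward zero as the run progresses.

The PSO update uses the Clerc-Kennedy constriction factor

    chi = 2 / |2 - phi - sqrt(phi^2 - 4 phi)|,   phi = c1 + c2 > 4,

which with the default c1 = c2 = 2.05 gives chi ~ 0.7298.

All randomness flows through counter-keyed streams (`RngStream`): a draw is
identified by (run seed, operator tag, iteration, gene, island, particle
slot), which makes every trajectory reproducible bit-for-bit regardless of
execution order or backend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ssystem import (
    DEFAULT_SUBSTEPS,
    PENALTY_FITNESS,
    ExpressionDataset,
    GeneParameterVector,
    default_bounds,
)

__all__ = [
    "OP_INIT",
    "OP_PSO",
    "OP_GA",
    "OP_MIGRATE",
    "RngStream",
    "GAPSOConfig",
    "Particle",
    "SwarmState",
    "constriction_factor",
    "pso_update",
    "rank_and_partition",
    "tournament_select",
    "crossover",
    "nonuniform_mutate",
    "run_gapso",
]

# Operator tags used as part of RNG stream keys.
OP_INIT = 1
OP_PSO = 2
OP_GA = 3
OP_MIGRATE = 4

_MASK31 = 0x7FFFFFFF


class RngStream:
    """Deterministic random stream keyed by a tuple of integers.

    Identical key material yields an identical sequence of variates, no
    matter where or when the stream is instantiated.  This is the only
    randomness primitive used by the optimizer.
    """

    def __init__(self, *key: int) -> None:
        self.key = tuple(int(k) & _MASK31 for k in key)
        self._rng = np.random.default_rng(np.random.SeedSequence(self.key))

    def uniform(self, low: float = 0.0, high: float = 1.0, size=None):
        return self._rng.uniform(low, high, size)

    def integers(self, low: int, high: int, size=None):
        return self._rng.integers(low, high, size)

    def choice(self, n: int, size: int, replace: bool = True) -> np.ndarray:
        return self._rng.choice(n, size=size, replace=replace)


@dataclass
class GAPSOConfig:
    """Settings of the hybrid optimizer.

    pop_size         particles per (sub)population.
    max_iterations   number of generations T.
    p_elite          fraction p kept and PSO-enhanced each generation (0.7).
    r_random         fraction r of the parent pool that is freshly
                     randomized (0.1); with `r_final` set, r ramps linearly
                     from r_random to r_final over the run.
    c1, c2           PSO acceleration constants; phi = c1 + c2 must be > 4.
    inertia_w        inertia weight w inside the constricted update (1.0, so
                     the constriction factor alone governs momentum).
    mutation_b       shape exponent b of the non-uniform mutation (5).
    mutation_prob    per-parameter mutation probability (0.1).
    tournament_size  entrants per tournament, sampled with replacement (2).
    substeps         RK4 substeps per sampling interval in the fitness.
    seed             root seed of all random streams.
    """

    pop_size: int
    max_iterations: int
    p_elite: float = 0.7
    r_random: float = 0.1
    r_final: float | None = None
    c1: float = 2.05
    c2: float = 2.05
    inertia_w: float = 1.0
    mutation_b: float = 5.0
    mutation_prob: float = 0.1
    tournament_size: int = 2
    lower_bounds: np.ndarray | None = None
    upper_bounds: np.ndarray | None = None
    penalty_fitness: float = PENALTY_FITNESS
    substeps: int = DEFAULT_SUBSTEPS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 4:
            raise ValueError("pop_size must be >= 4")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not 0.0 < self.p_elite < 1.0:
            raise ValueError("p_elite must lie in (0, 1)")
        for r in (self.r_random,) + (() if self.r_final is None else (self.r_final,)):
            if not 0.0 <= r <= 1.0 - self.p_elite:
                raise ValueError("randomness rate must lie in [0, 1 - p_elite]")
        if self.phi <= 4.0:
            raise ValueError("c1 + c2 must exceed 4 for the constriction factor")
        if self.tournament_size < 1:
            raise ValueError("tournament_size must be >= 1")
        if self.lower_bounds is not None:
            self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        if self.upper_bounds is not None:
            self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)

    @property
    def phi(self) -> float:
        return self.c1 + self.c2

    def resolved_bounds(self, n_genes: int) -> tuple[np.ndarray, np.ndarray]:
        """Configured box bounds, defaulting to the standard search space."""
        if self.lower_bounds is not None and self.upper_bounds is not None:
            return self.lower_bounds, self.upper_bounds
        return default_bounds(n_genes)

    def randomness_rate(self, t: int) -> float:
        """The (possibly scheduled) fraction r at iteration t (1-based)."""
        if self.r_final is None:
            return self.r_random
        return self.r_random + (self.r_final - self.r_random) * t / self.max_iterations


@dataclass(eq=False)
class Particle:
    """One candidate parameter vector with PSO state and personal-best memory."""

    particle_id: int
    position: np.ndarray
    velocity: np.ndarray
    fitness: float = math.nan
    pbest_position: np.ndarray | None = None
    pbest_fitness: float = math.inf

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.position.shape != self.velocity.shape:
            raise ValueError("position and velocity must have the same shape")
        if self.pbest_position is not None:
            self.pbest_position = np.asarray(self.pbest_position, dtype=float)

    @property
    def stale(self) -> bool:
        return math.isnan(self.fitness)


@dataclass
class SwarmState:
    """A population plus its global-best memory.

    `gbest` is the best solution *ever* observed by the swarm; it survives
    even if its holder is later discarded, so the best-so-far trace is
    non-increasing by construction.
    """

    particles: list[Particle]
    gbest_position: np.ndarray | None = None
    gbest_fitness: float = math.inf
    iteration: int = 0

    def refresh_gbest(self) -> None:
        for p in self.particles:
            if p.pbest_fitness < self.gbest_fitness:
                self.gbest_fitness = p.pbest_fitness
                self.gbest_position = np.array(p.pbest_position)


# ---------------------------------------------------------------------------
# operators


def constriction_factor(phi: float) -> float:
    """Clerc-Kennedy constriction chi = 2/|2 - phi - sqrt(phi^2 - 4 phi)|."""
    phi = float(phi)
    if phi <= 4.0:
        raise ValueError("phi must be larger than 4")
    return 2.0 / abs(2.0 - phi - math.sqrt(phi * phi - 4.0 * phi))


def _pso_step(
    position: np.ndarray,
    velocity: np.ndarray,
    pbest: np.ndarray,
    gbest: np.ndarray,
    cfg: GAPSOConfig,
    rng: RngStream,
    lb: np.ndarray,
    ub: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    chi = constriction_factor(cfg.phi)
    d = position.size
    r1 = rng.uniform(size=d)
    r2 = rng.uniform(size=d)
    v = chi * (
        cfg.inertia_w * velocity
        + cfg.c1 * r1 * (pbest - position)
        + cfg.c2 * r2 * (gbest - position)
    )
    vmax = ub - lb
    v = np.clip(v, -vmax, vmax)
    x = np.clip(position + v, lb, ub)
    return x, v


def pso_update(
    particle: Particle,
    gbest_position: np.ndarray,
    cfg: GAPSOConfig,
    rng: RngStream,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> Particle:
    """Constricted velocity/position update; the new fitness is stale (NaN)."""
    if bounds is None:
        n_genes = particle.position.size // 2 - 1
        bounds = cfg.resolved_bounds(n_genes)
    lb, ub = bounds
    pbest = particle.pbest_position
    if pbest is None:
        pbest = particle.position
    x, v = _pso_step(particle.position, particle.velocity, pbest,
                     np.asarray(gbest_position, dtype=float), cfg, rng, lb, ub)
    return Particle(
        particle_id=particle.particle_id,
        position=x,
        velocity=v,
        fitness=math.nan,
        pbest_position=particle.pbest_position,
        pbest_fitness=particle.pbest_fitness,
    )


def partition_counts(pop_size: int, p_elite: float, r_random: float) -> tuple[int, int, int]:
    """(n_elites, n_random, n_from_elites) under the floor-then-remainder rule."""
    n_e = int(math.floor(p_elite * pop_size))
    n_new = pop_size - n_e
    n_rand = min(int(math.floor(r_random * pop_size)), n_new)
    return n_e, n_rand, n_new - n_rand


def rank_and_partition(
    swarm: SwarmState,
    cfg: GAPSOConfig,
    rng: RngStream,
    t: int = 1,
) -> tuple[list[Particle], list[Particle]]:
    """Split a fully evaluated swarm into elites and the GA parent pool.

    Particles are sorted ascending by fitness (ties broken by particle_id);
    the best floor(p*pop) become elites, the rest are discarded.  The parent
    pool of size pop - n_elites holds floor(r*pop) freshly randomized
    particles (stale fitness) plus uniform draws from the elites, sampled
    without replacement when the elite count allows.
    """
    if any(p.stale for p in swarm.particles):
        raise RuntimeError("all particles must be evaluated before ranking")
    pop = len(swarm.particles)
    ranked = sorted(swarm.particles, key=lambda p: (p.fitness, p.particle_id))
    n_e, n_rand, n_par = partition_counts(pop, cfg.p_elite, cfg.randomness_rate(t))
    elites = ranked[:n_e]
    d = ranked[0].position.size
    lb, ub = cfg.resolved_bounds(d // 2 - 1)
    pool: list[Particle] = []
    for j in range(n_rand):
        pos = lb + rng.uniform(size=d) * (ub - lb)
        pool.append(Particle(particle_id=pop + j, position=pos, velocity=np.zeros(d)))
    if n_par > 0 and elites:
        idx = rng.choice(len(elites), size=n_par, replace=n_par > len(elites))
        pool.extend(elites[int(i)] for i in idx)
    return elites, pool


def tournament_select(pool: Sequence[Particle], k: int, rng: RngStream) -> Particle:
    """Best of k entrants drawn uniformly with replacement (ties by entry index)."""
    if not pool:
        raise RuntimeError("tournament pool is empty")
    idx = rng.integers(0, len(pool), size=int(k))
    best = min(idx, key=lambda i: (pool[int(i)].fitness, int(i)))
    return pool[int(best)]


def _crossover_positions(
    x1: np.ndarray, v1: np.ndarray, x2: np.ndarray, v2: np.ndarray,
    rng: RngStream, lb: np.ndarray, ub: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    d = x1.size
    phi1 = rng.uniform(size=d)
    phi2 = rng.uniform(size=d)
    mid = 0.5 * (x1 + x2)
    c1 = np.clip(mid - phi1 * v2, lb, ub)
    c2 = np.clip(mid - phi2 * v1, lb, ub)
    return c1, c2


def crossover(
    old1: Particle,
    old2: Particle,
    rng: RngStream,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    cfg: GAPSOConfig | None = None,
) -> tuple[Particle, Particle]:
    """Velocity-aware midpoint crossover producing two children.

    Out-of-range coordinates are set to the violated bound; children carry
    zero velocity and stale fitness.
    """
    if old1.position.shape != old2.position.shape:
        raise ValueError("parents differ in dimensionality")
    d = old1.position.size
    if bounds is None:
        if cfg is not None:
            bounds = cfg.resolved_bounds(d // 2 - 1)
        else:
            bounds = default_bounds(d // 2 - 1)
    lb, ub = bounds
    c1, c2 = _crossover_positions(
        old1.position, old1.velocity, old2.position, old2.velocity, rng, lb, ub
    )
    z = np.zeros(d)
    return (
        Particle(particle_id=old1.particle_id, position=c1, velocity=z.copy()),
        Particle(particle_id=old2.particle_id, position=c2, velocity=z.copy()),
    )


def _mutate_position(
    x: np.ndarray, t: int, cfg: GAPSOConfig, rng: RngStream,
    lb: np.ndarray, ub: np.ndarray,
) -> np.ndarray:
    d = x.size
    hit = rng.uniform(size=d) < cfg.mutation_prob
    upward = rng.uniform(size=d) < 0.5
    u = rng.uniform(size=d)
    expo = (1.0 - t / cfg.max_iterations) ** cfg.mutation_b
    shrink = 1.0 - u ** expo
    up = x + (ub - x) * shrink
    down = x - (x - lb) * shrink
    out = np.where(hit, np.where(upward, up, down), x)
    return np.clip(out, lb, ub)


def nonuniform_mutate(
    particle: Particle,
    t: int,
    cfg: GAPSOConfig,
    rng: RngStream,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> Particle:
    """Per-parameter non-uniform mutation; the step decays to 0 as t -> T."""
    if t > cfg.max_iterations:
        raise ValueError("iteration exceeds max_iterations")
    if bounds is None:
        bounds = cfg.resolved_bounds(particle.position.size // 2 - 1)
    lb, ub = bounds
    x = _mutate_position(particle.position, t, cfg, rng, lb, ub)
    return Particle(
        particle_id=particle.particle_id,
        position=x,
        velocity=particle.velocity.copy(),
        fitness=math.nan,
        pbest_position=particle.pbest_position,
        pbest_fitness=particle.pbest_fitness,
    )


# ---------------------------------------------------------------------------
# driver


def run_gapso(
    dataset: ExpressionDataset,
    gene_index: int,
    cfg: GAPSOConfig,
) -> tuple[GeneParameterVector, np.ndarray]:
    """Optimize one gene's decoupled sub-problem with a single population.

    Returns the best parameter vector found and the per-iteration best-so-far
    fitness trace (length max_iterations).  Equivalent to the island variant
    with a single island.
    """
    from . import _engine
    from .island import IslandConfig

    island_cfg = IslandConfig(
        n_islands=1,
        subpop_size=cfg.pop_size,
        migration_interval=cfg.max_iterations + 1,
        migration_fraction=0.0,
    )
    result = _engine.evolve(dataset, gene_index, cfg, island_cfg)
    return result.best_vector, result.traces[0]
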