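"""Array-based core loop of the (island) hybrid GA-PSO.

Both execution backends — the in-process driver in `island`/`gapso` and the
map/reduce-style driver in `parallel` — are thin schedulers over the staged
functions defined here, so they produce bit-identical results by
construction.  Per-particle operations (initialization, PSO moves) draw from
random streams keyed by (seed, operator, iteration, gene, island, slot);
grouped operations (reproduction, migration) draw from one stream per
(seed, operator, iteration, gene, island).  Nothing depends on the order or
placement of per-particle work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .gapso import (
    OP_GA,
    OP_INIT,
    OP_MIGRATE,
    OP_PSO,
    GAPSOConfig,
    RngStream,
    _crossover_positions,
    _mutate_position,
    _pso_step,
    partition_counts,
)
from .island import IslandConfig, hypercube_neighbors, migration_count
from .ssystem import DecoupledProblem, ExpressionDataset, GeneParameterVector

__all__ = ["IslandArrays", "EngineResult", "evolve"]


@dataclass
class IslandArrays:
    """One island's population as flat arrays (rows are rank slots)."""

    island_id: int
    pos: np.ndarray  # (S, D)
    vel: np.ndarray  # (S, D)
    fit: np.ndarray  # (S,)
    pbest_pos: np.ndarray  # (S, D)
    pbest_fit: np.ndarray  # (S,)
    gbest_pos: np.ndarray | None = None
    gbest_fit: float = math.inf

    @property
    def size(self) -> int:
        return self.pos.shape[0]

    def reorder(self, order: np.ndarray) -> None:
        self.pos = self.pos[order]
        self.vel = self.vel[order]
        self.fit = self.fit[order]
        self.pbest_pos = self.pbest_pos[order]
        self.pbest_fit = self.pbest_fit[order]

    def rank(self) -> None:
        """Sort ascending by fitness, stable in the current slot order."""
        self.reorder(np.lexsort((np.arange(self.size), self.fit)))

    def refresh_gbest(self) -> None:
        m = int(np.argmin(self.pbest_fit))
        if self.pbest_fit[m] < self.gbest_fit:
            self.gbest_fit = float(self.pbest_fit[m])
            self.gbest_pos = self.pbest_pos[m].copy()


@dataclass
class EngineResult:
    best_vector: GeneParameterVector
    best_fitness: float
    traces: np.ndarray  # (n_islands, max_iterations)


def init_island(
    problem: DecoupledProblem,
    cfg: GAPSOConfig,
    island_id: int,
    subpop_size: int,
    lb: np.ndarray,
    ub: np.ndarray,
) -> IslandArrays:
    """Random in-bounds initial population with zero velocities."""
    d = problem.dim
    pos = np.empty((subpop_size, d))
    for pid in range(subpop_size):
        rng = RngStream(cfg.seed, OP_INIT, 0, problem.gene_index, island_id, pid)
        pos[pid] = lb + rng.uniform(size=d) * (ub - lb)
    fit = problem.fitness(pos)
    state = IslandArrays(
        island_id=island_id,
        pos=pos,
        vel=np.zeros((subpop_size, d)),
        fit=fit,
        pbest_pos=pos.copy(),
        pbest_fit=fit.copy(),
    )
    state.refresh_gbest()
    return state


def pso_move(
    state: IslandArrays,
    slot: int,
    t: int,
    gene_index: int,
    cfg: GAPSOConfig,
    lb: np.ndarray,
    ub: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Constricted PSO update of one elite slot (pure; no state mutation)."""
    rng = RngStream(cfg.seed, OP_PSO, t, gene_index, state.island_id, slot)
    return _pso_step(
        state.pos[slot], state.vel[slot], state.pbest_pos[slot],
        state.gbest_pos, cfg, rng, lb, ub,
    )


def update_pbest(state: IslandArrays, slots: np.ndarray | slice) -> None:
    idx = np.arange(state.size)[slots]
    improved = idx[state.fit[idx] < state.pbest_fit[idx]]
    state.pbest_pos[improved] = state.pos[improved]
    state.pbest_fit[improved] = state.fit[improved]


def _tournament_index(fit: np.ndarray, k: int, rng: RngStream) -> int:
    idx = rng.integers(0, fit.size, size=k)
    return int(min(idx, key=lambda i: (fit[int(i)], int(i))))


def ga_reproduce(
    state: IslandArrays,
    n_elites: int,
    n_rand: int,
    n_new: int,
    t: int,
    gene_index: int,
    cfg: GAPSOConfig,
    problem: DecoupledProblem,
    lb: np.ndarray,
    ub: np.ndarray,
) -> np.ndarray:
    """Create n_new offspring positions from the PSO-enhanced elites.

    The parent pool holds n_rand freshly randomized (and evaluated)
    candidates plus n_new - n_rand elites drawn uniformly, without
    replacement when possible.  Pairs are picked by tournament, crossed
    over, and each child is mutated.  Returns the stacked child positions
    (velocities start at zero, fitness stale).
    """
    d = problem.dim
    grng = RngStream(cfg.seed, OP_GA, t, gene_index, state.island_id)
    rand_pos = lb + grng.uniform(size=(n_rand, d)) * (ub - lb) if n_rand else np.empty((0, d))
    rand_fit = problem.fitness(rand_pos) if n_rand else np.empty(0)
    n_par = n_new - n_rand
    if n_par > 0:
        idx = grng.choice(n_elites, size=n_par, replace=n_par > n_elites)
        par_pos = state.pos[idx]
        par_vel = state.vel[idx]
        par_fit = state.fit[idx]
    else:
        par_pos = np.empty((0, d))
        par_vel = np.empty((0, d))
        par_fit = np.empty(0)
    pool_pos = np.vstack((rand_pos, par_pos))
    pool_vel = np.vstack((np.zeros((n_rand, d)), par_vel))
    pool_fit = np.concatenate((rand_fit, par_fit))
    children: list[np.ndarray] = []
    for _ in range((n_new + 1) // 2):
        i1 = _tournament_index(pool_fit, cfg.tournament_size, grng)
        i2 = _tournament_index(pool_fit, cfg.tournament_size, grng)
        c1, c2 = _crossover_positions(
            pool_pos[i1], pool_vel[i1], pool_pos[i2], pool_vel[i2], grng, lb, ub
        )
        children.append(_mutate_position(c1, t, cfg, grng, lb, ub))
        children.append(_mutate_position(c2, t, cfg, grng, lb, ub))
    return np.array(children[:n_new])


def merge_generation(
    state: IslandArrays,
    n_elites: int,
    child_pos: np.ndarray,
    child_fit: np.ndarray,
) -> None:
    """Replace the discarded tail with the offspring; offspring pbest = self."""
    d = state.pos.shape[1]
    n_new = child_pos.shape[0]
    state.pos = np.vstack((state.pos[:n_elites], child_pos))
    state.vel = np.vstack((state.vel[:n_elites], np.zeros((n_new, d))))
    state.fit = np.concatenate((state.fit[:n_elites], child_fit))
    state.pbest_pos = np.vstack((state.pbest_pos[:n_elites], child_pos.copy()))
    state.pbest_fit = np.concatenate((state.pbest_fit[:n_elites], child_fit.copy()))
    state.refresh_gbest()


def migrate_arrays(
    states: list[IslandArrays],
    island_cfg: IslandConfig,
    t: int,
    gene_index: int,
    seed: int,
) -> None:
    """Synchronized migration between immediate neighbors (copies, not moves).

    Donors are drawn from each island's top `donor_fraction`; copies replace
    the worst k slots of every neighbor, k = round(migration_fraction *
    subpop_size).  Incoming batches are applied in ascending donor-id order
    over the worst slots of the pre-migration ranking.
    """
    n = len(states)
    k = migration_count(island_cfg)
    if n < 2 or k == 0:
        return
    outgoing = []
    worst_slots = []
    for state in states:
        order = np.lexsort((np.arange(state.size), state.fit))
        n_top = max(1, int(math.floor(island_cfg.donor_fraction * state.size)))
        rng = RngStream(seed, OP_MIGRATE, t, gene_index, state.island_id)
        picked = rng.choice(n_top, size=k, replace=k > n_top)
        donor_idx = order[picked]
        outgoing.append(
            (
                state.pos[donor_idx].copy(),
                state.vel[donor_idx].copy(),
                state.fit[donor_idx].copy(),
                state.pbest_pos[donor_idx].copy(),
                state.pbest_fit[donor_idx].copy(),
            )
        )
        worst_slots.append(order[::-1][:k])
    for receiver in range(n):
        slots = worst_slots[receiver]
        st = states[receiver]
        for donor in sorted(hypercube_neighbors(receiver, n)):
            pos, vel, fit, ppos, pfit = outgoing[donor]
            st.pos[slots] = pos
            st.vel[slots] = vel
            st.fit[slots] = fit
            st.pbest_pos[slots] = ppos
            st.pbest_fit[slots] = pfit
        st.refresh_gbest()


def iterate_islands(
    states: list[IslandArrays],
    problem: DecoupledProblem,
    cfg: GAPSOConfig,
    island_cfg: IslandConfig,
    t: int,
    traces: np.ndarray,
) -> None:
    """One full generation for every island, plus migration at epoch ends."""
    gene = problem.gene_index
    lb, ub = cfg.resolved_bounds(problem.dataset.n_genes)
    for j, state in enumerate(states):
        state.rank()
        n_e, n_rand, n_par = partition_counts(
            state.size, cfg.p_elite, cfg.randomness_rate(t)
        )
        for s in range(n_e):
            state.pos[s], state.vel[s] = pso_move(state, s, t, gene, cfg, lb, ub)
        state.fit[:n_e] = problem.fitness(state.pos[:n_e])
        update_pbest(state, slice(0, n_e))
        child_pos = ga_reproduce(
            state, n_e, n_rand, n_rand + n_par, t, gene, cfg, problem, lb, ub
        )
        child_fit = problem.fitness(child_pos)
        merge_generation(state, n_e, child_pos, child_fit)
        traces[j, t - 1] = state.gbest_fit
    if (
        len(states) > 1
        and island_cfg.migration_fraction > 0.0
        and t % island_cfg.migration_interval == 0
        and t < cfg.max_iterations
    ):
        migrate_arrays(states, island_cfg, t, gene, cfg.seed)


def evolve(
    dataset: ExpressionDataset,
    gene_index: int,
    cfg: GAPSOConfig,
    island_cfg: IslandConfig,
    island_ids: list[int] | None = None,
) -> EngineResult:
    """Run the full (island) GA-PSO for one gene and return the best solution."""
    problem = DecoupledProblem(
        dataset, gene_index, substeps=cfg.substeps, penalty=cfg.penalty_fitness
    )
    lb, ub = cfg.resolved_bounds(dataset.n_genes)
    if island_ids is None:
        island_ids = list(range(island_cfg.n_islands))
    states = [
        init_island(problem, cfg, isl, island_cfg.subpop_size, lb, ub)
        for isl in island_ids
    ]
    traces = np.empty((len(states), cfg.max_iterations))
    for t in range(1, cfg.max_iterations + 1):
        iterate_islands(states, problem, cfg, island_cfg, t, traces)
    best = min(states, key=lambda s: s.gbest_fit)
    vec = GeneParameterVector(gene_index=gene_index, values=best.gbest_pos.copy())
    return EngineResult(best_vector=vec, best_fitness=best.gbest_fit, traces=traces)
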