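"""Map/reduce-style execution backend for the island GA-PSO.

The optimizer splits naturally into *map* operations that touch one particle
at a time (PSO velocity/position update, fitness evaluation, personal-best
update) and *reduce* operations that need a whole group (ranking/partition,
selection, crossover, mutation, migration, global-best determination),
grouped by the gene a particle works on.  This module realizes that
contract on a local worker pool: particles travel between phases as plain
text records carrying (gene-id, island-id, particle-id) plus the numeric
state, and the grouped steps run under a synchronization barrier.

Because every random draw is keyed by (seed, operator, iteration, gene,
island, particle slot), the backend is an execution strategy only: for any
worker count it reproduces the in-process driver bit for bit.  A port to an
actual cluster framework is mechanical — the record format and phase split
are exactly what a mapper/reducer pair would consume and emit.  One
generation needs two map barriers (move+evaluate the elites, then evaluate
the offspring) with grouped steps between them; per-iteration scheduling
overhead of a real cluster is represented only as a constant in the cost
model, not simulated here.
"""

from __future__ import annotations

import math
import os
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from . import _engine
from .gapso import OP_PSO, GAPSOConfig, RngStream, partition_counts, _pso_step
from .island import IslandConfig
from .ssystem import DecoupledProblem, ExpressionDataset, GeneParameterVector

__all__ = [
    "RECORD_VERSION",
    "ParticleRecord",
    "PhasePlan",
    "DEFAULT_PHASE_PLAN",
    "record_header",
    "serialize_record",
    "parse_record",
    "map_phase",
    "reduce_phase",
    "run_mapreduce",
]

RECORD_VERSION = 1


class RecordFormatError(ValueError):
    """A particle record line could not be parsed."""


@dataclass
class ParticleRecord:
    """One particle's state as it travels between map and reduce phases.

    `particle_id` is the rank slot inside its island for the current
    iteration; a NaN fitness marks a freshly created particle that still
    needs evaluation (and whose personal best is itself).
    """

    gene_id: int
    island_id: int
    particle_id: int
    position: np.ndarray
    velocity: np.ndarray
    fitness: float
    pbest_position: np.ndarray
    pbest_fitness: float
    gbest_position: np.ndarray
    gbest_fitness: float

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.pbest_position = np.asarray(self.pbest_position, dtype=float)
        self.gbest_position = np.asarray(self.gbest_position, dtype=float)

    @property
    def stale(self) -> bool:
        return math.isnan(self.fitness)


@dataclass(frozen=True)
class PhasePlan:
    """Declares which operations run per particle vs per gene group."""

    map_ops: tuple[str, ...]
    reduce_ops: tuple[str, ...]
    grouping_key: str = "gene_id"


DEFAULT_PHASE_PLAN = PhasePlan(
    map_ops=("pso_velocity_position_update", "fitness_evaluation", "pbest_update"),
    reduce_ops=(
        "ranking_partition",
        "tournament_selection",
        "crossover",
        "mutation",
        "migration",
        "gbest_determination",
    ),
)


# ---------------------------------------------------------------------------
# record serialization (one tab-separated line per particle)

_FIELDS = "gene_id island_id particle_id position[D] velocity[D] fitness pbest_position[D] pbest_fitness gbest_position[D] gbest_fitness"


def record_header(dim: int) -> str:
    """Self-describing header naming the record version and field order."""
    return f"#ssgrn-particle-record\tv{RECORD_VERSION}\tD={dim}\t{_FIELDS}"


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def serialize_record(rec: ParticleRecord) -> str:
    """One tab-separated line; numeric state at 17 significant digits.

    Positions, velocities and bests must be finite (a NaN fitness is the
    legitimate 'stale' marker and is allowed).
    """
    for name, arr in (
        ("position", rec.position),
        ("velocity", rec.velocity),
        ("pbest_position", rec.pbest_position),
        ("gbest_position", rec.gbest_position),
    ):
        if not np.isfinite(arr).all():
            raise ValueError(f"non-finite {name} cannot be serialized")
    parts = [str(int(rec.gene_id)), str(int(rec.island_id)), str(int(rec.particle_id))]
    parts += [_fmt(v) for v in rec.position]
    parts += [_fmt(v) for v in rec.velocity]
    parts.append(_fmt(rec.fitness))
    parts += [_fmt(v) for v in rec.pbest_position]
    parts.append(_fmt(rec.pbest_fitness))
    parts += [_fmt(v) for v in rec.gbest_position]
    parts.append(_fmt(rec.gbest_fitness))
    return "\t".join(parts)


def parse_record(line: str) -> ParticleRecord:
    """Inverse of `serialize_record`; raises RecordFormatError on bad lines."""
    fields = line.rstrip("\n").split("\t")
    n = len(fields)
    # 3 identifiers + 4D numeric vectors + 3 scalars
    if n < 10 or (n - 6) % 4 != 0:
        raise RecordFormatError(
            f"expected 6 + 4*D fields, got {n}: cannot infer the dimension"
        )
    dim = (n - 6) // 4
    vals: list[float] = []
    for i, tok in enumerate(fields):
        try:
            if i < 3:
                vals.append(int(tok))
            else:
                vals.append(float(tok))
        except ValueError as exc:
            raise RecordFormatError(f"field {i} ({tok!r}) is not numeric") from exc
    o = 3
    return ParticleRecord(
        gene_id=int(vals[0]),
        island_id=int(vals[1]),
        particle_id=int(vals[2]),
        position=np.array(vals[o : o + dim]),
        velocity=np.array(vals[o + dim : o + 2 * dim]),
        fitness=vals[o + 2 * dim],
        pbest_position=np.array(vals[o + 2 * dim + 1 : o + 3 * dim + 1]),
        pbest_fitness=vals[o + 3 * dim + 1],
        gbest_position=np.array(vals[o + 3 * dim + 2 : o + 4 * dim + 2]),
        gbest_fitness=vals[o + 4 * dim + 2],
    )


def _spill(records: list[ParticleRecord], spill_dir: str, tag: str) -> None:
    if not records:
        return
    path = os.path.join(spill_dir, f"{tag}.records.txt")
    with open(path, "w") as fh:
        fh.write(record_header(records[0].position.size) + "\n")
        for rec in records:
            fh.write(serialize_record(rec) + "\n")


# ---------------------------------------------------------------------------
# phases


def _process_record(
    rec: ParticleRecord,
    problem: DecoupledProblem,
    cfg: GAPSOConfig,
    t: int,
    lb: np.ndarray,
    ub: np.ndarray,
) -> ParticleRecord:
    """The per-particle map operation.

    Records with a valid fitness are due a PSO move (then re-evaluation and
    personal-best update); stale records are newly created offspring that
    only need evaluation, with the personal best initialized to themselves.
    """
    pos, vel = rec.position, rec.velocity
    if not rec.stale:
        rng = RngStream(cfg.seed, OP_PSO, t, rec.gene_id, rec.island_id, rec.particle_id)
        pos, vel = _pso_step(pos, vel, rec.pbest_position, rec.gbest_position,
                             cfg, rng, lb, ub)
    fit = float(problem.fitness(pos[None, :])[0])
    if rec.stale or fit < rec.pbest_fitness:
        pbest_pos, pbest_fit = pos.copy(), fit
    else:
        pbest_pos, pbest_fit = rec.pbest_position, rec.pbest_fitness
    return ParticleRecord(
        gene_id=rec.gene_id,
        island_id=rec.island_id,
        particle_id=rec.particle_id,
        position=pos,
        velocity=vel,
        fitness=fit,
        pbest_position=pbest_pos,
        pbest_fitness=pbest_fit,
        gbest_position=rec.gbest_position,
        gbest_fitness=rec.gbest_fitness,
    )


def map_phase(
    records: list[ParticleRecord],
    dataset: ExpressionDataset,
    cfg: GAPSOConfig,
    t: int,
    worker_count: int = 1,
    spill_dir: str | None = None,
    problems: dict[int, DecoupledProblem] | None = None,
) -> list[ParticleRecord]:
    """Apply the per-particle operations to every record independently.

    The output is identical for any `worker_count`: all randomness is keyed
    by record identity, not by scheduling.  A failing worker chunk is
    retried once before the error is surfaced.
    """
    if problems is None:
        problems = {}
    lb, ub = cfg.resolved_bounds(dataset.n_genes)
    for rec in records:
        if rec.gene_id not in problems:
            problems[rec.gene_id] = DecoupledProblem(
                dataset, rec.gene_id, substeps=cfg.substeps,
                penalty=cfg.penalty_fitness,
            )

    def work(chunk: list[ParticleRecord]) -> list[ParticleRecord]:
        return [
            _process_record(r, problems[r.gene_id], cfg, t, lb, ub) for r in chunk
        ]

    if worker_count <= 1 or len(records) < 2:
        out = work(records)
    else:
        n_chunks = min(worker_count * 4, len(records))
        chunks = [list(c) for c in np.array_split(np.array(records, dtype=object), n_chunks)]
        out_chunks: list[list[ParticleRecord]] = [None] * len(chunks)  # type: ignore
        with ThreadPoolExecutor(max_workers=worker_count) as pool:
            futures = {pool.submit(work, c): i for i, c in enumerate(chunks)}
            retried: list[tuple[int, list[ParticleRecord]]] = []
            for fut, i in futures.items():
                try:
                    out_chunks[i] = fut.result()
                except Exception:
                    retried.append((i, chunks[i]))
            for i, c in retried:  # fault-tolerance contract: one retry
                out_chunks[i] = work(c)
        out = [r for c in out_chunks for r in c]
    if spill_dir is not None:
        _spill(out, spill_dir, f"iter{t:04d}.map")
    return out


def _records_to_arrays(
    recs: list[ParticleRecord], island_id: int
) -> _engine.IslandArrays:
    recs = sorted(recs, key=lambda r: r.particle_id)
    state = _engine.IslandArrays(
        island_id=island_id,
        pos=np.array([r.position for r in recs]),
        vel=np.array([r.velocity for r in recs]),
        fit=np.array([r.fitness for r in recs]),
        pbest_pos=np.array([r.pbest_position for r in recs]),
        pbest_fit=np.array([r.pbest_fitness for r in recs]),
        gbest_pos=recs[0].gbest_position.copy(),
        gbest_fit=recs[0].gbest_fitness,
    )
    return state


def _arrays_to_records(state: _engine.IslandArrays, gene_id: int) -> list[ParticleRecord]:
    return [
        ParticleRecord(
            gene_id=gene_id,
            island_id=state.island_id,
            particle_id=s,
            position=state.pos[s].copy(),
            velocity=state.vel[s].copy(),
            fitness=float(state.fit[s]),
            pbest_position=state.pbest_pos[s].copy(),
            pbest_fitness=float(state.pbest_fit[s]),
            gbest_position=state.gbest_pos.copy(),
            gbest_fitness=float(state.gbest_fit),
        )
        for s in range(state.size)
    ]


def reduce_phase(
    records: list[ParticleRecord],
    dataset: ExpressionDataset,
    cfg: GAPSOConfig,
    island_cfg: IslandConfig,
    t: int,
    stage: str,
    problems: dict[int, DecoupledProblem] | None = None,
    spill_dir: str | None = None,
) -> list[ParticleRecord]:
    """Grouped operations, keyed by gene_id (then island within each group).

    stage="partition"  rank each island ascending by fitness, reassign
                       particle ids as rank slots, keep the best
                       floor(p * size) elites and discard the rest.
    stage="reproduce"  run tournament/crossover/mutation on the
                       (PSO-enhanced) elites of each island and emit the
                       stale offspring records alongside them.
    stage="finalize"   refresh each island's global best from the personal
                       bests, broadcast it to every record, and at epoch
                       boundaries perform the synchronized migration.

    Every output record of a group carries that island's current global
    best; group sizes are conserved across a full generation.
    """
    if stage not in ("partition", "reproduce", "finalize"):
        raise ValueError(f"unknown reduce stage {stage!r}")
    if any(r.stale for r in records):
        raise RuntimeError("reduce phase observed a stale fitness")
    by_gene: dict[int, dict[int, list[ParticleRecord]]] = {}
    for r in records:
        by_gene.setdefault(r.gene_id, {}).setdefault(r.island_id, []).append(r)
    out: list[ParticleRecord] = []
    for gene_id in sorted(by_gene):
        islands = by_gene[gene_id]
        if stage == "finalize":
            states = [
                _records_to_arrays(islands[isl], isl) for isl in sorted(islands)
            ]
            for st in states:
                st.refresh_gbest()
            if (
                len(states) > 1
                and island_cfg.migration_fraction > 0.0
                and t % island_cfg.migration_interval == 0
                and t < cfg.max_iterations
            ):
                _engine.migrate_arrays(states, island_cfg, t, gene_id, cfg.seed)
            for st in states:
                out.extend(_arrays_to_records(st, gene_id))
            continue
        for isl in sorted(islands):
            state = _records_to_arrays(islands[isl], isl)
            if stage == "partition":
                state.rank()
                n_e, _, _ = partition_counts(
                    state.size, cfg.p_elite, cfg.randomness_rate(t)
                )
                state.reorder(np.arange(n_e))
                out.extend(_arrays_to_records(state, gene_id))
            else:  # reproduce
                if problems is None or gene_id not in problems:
                    raise RuntimeError("reproduce stage needs the fitness problems")
                problem = problems[gene_id]
                lb, ub = cfg.resolved_bounds(dataset.n_genes)
                n_e = state.size
                sub = island_cfg.subpop_size
                _, n_rand, n_par = partition_counts(
                    sub, cfg.p_elite, cfg.randomness_rate(t)
                )
                child_pos = _engine.ga_reproduce(
                    state, n_e, n_rand, n_rand + n_par, t, gene_id, cfg,
                    problem, lb, ub,
                )
                elite_recs = _arrays_to_records(state, gene_id)
                out.extend(elite_recs)
                ref = elite_recs[0]
                for j in range(child_pos.shape[0]):
                    out.append(
                        ParticleRecord(
                            gene_id=gene_id,
                            island_id=isl,
                            particle_id=n_e + j,
                            position=child_pos[j],
                            velocity=np.zeros_like(child_pos[j]),
                            fitness=math.nan,
                            pbest_position=child_pos[j].copy(),
                            pbest_fitness=math.inf,
                            gbest_position=ref.gbest_position.copy(),
                            gbest_fitness=ref.gbest_fitness,
                        )
                    )
    if spill_dir is not None and stage == "finalize":
        _spill(out, spill_dir, f"iter{t:04d}.reduce")
    return out


# ---------------------------------------------------------------------------
# driver


def run_mapreduce(
    dataset: ExpressionDataset,
    gene_indices: list[int],
    cfg: GAPSOConfig,
    island_cfg: IslandConfig,
    worker_count: int = 1,
    spill_dir: str | None = None,
) -> dict[int, tuple[GeneParameterVector, np.ndarray]]:
    """Run the island GA-PSO for several genes through the map/reduce contract.

    Returns, per gene, the best parameter vector and the per-island
    best-so-far traces — bit-identical to `island.run_igapso` for the same
    seed and configuration, for any worker count.
    """
    problems = {
        g: DecoupledProblem(dataset, g, substeps=cfg.substeps,
                            penalty=cfg.penalty_fitness)
        for g in gene_indices
    }
    lb, ub = cfg.resolved_bounds(dataset.n_genes)
    records: list[ParticleRecord] = []
    traces = {
        g: np.empty((island_cfg.n_islands, cfg.max_iterations)) for g in gene_indices
    }
    for g in gene_indices:
        for isl in range(island_cfg.n_islands):
            state = _engine.init_island(
                problems[g], cfg, isl, island_cfg.subpop_size, lb, ub
            )
            records.extend(_arrays_to_records(state, g))
    for t in range(1, cfg.max_iterations + 1):
        elites = reduce_phase(records, dataset, cfg, island_cfg, t, "partition")
        elites = map_phase(elites, dataset, cfg, t, worker_count, spill_dir, problems)
        mixed = reduce_phase(
            elites, dataset, cfg, island_cfg, t, "reproduce", problems
        )
        done = [r for r in mixed if not r.stale]
        fresh = [r for r in mixed if r.stale]
        fresh = map_phase(fresh, dataset, cfg, t, worker_count, spill_dir, problems)
        pre = done + fresh
        # per-island gbest must be refreshed before the trace is taken
        by_key: dict[tuple[int, int], list[ParticleRecord]] = {}
        for r in pre:
            by_key.setdefault((r.gene_id, r.island_id), []).append(r)
        for (g, isl), recs in by_key.items():
            best = min(
                min(r.pbest_fitness for r in recs), recs[0].gbest_fitness
            )
            traces[g][isl, t - 1] = best
        records = reduce_phase(
            pre, dataset, cfg, island_cfg, t, "finalize", problems,
            spill_dir=spill_dir,
        )
    result: dict[int, tuple[GeneParameterVector, np.ndarray]] = {}
    for g in gene_indices:
        recs = [r for r in records if r.gene_id == g]
        best = min(recs, key=lambda r: r.gbest_fitness)
        result[g] = (
            GeneParameterVector(gene_index=g, values=best.gbest_position.copy()),
            traces[g],
        )
    return result
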