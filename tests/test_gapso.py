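import numpy as np
import pytest

from ssgrn.gapso import (
    GAPSOConfig,
    Particle,
    RngStream,
    SwarmState,
    constriction_factor,
    crossover,
    nonuniform_mutate,
    partition_counts,
    pso_update,
    rank_and_partition,
    run_gapso,
    tournament_select,
)


def _cfg(**kw):
    base = dict(pop_size=10, max_iterations=10, seed=1)
    base.update(kw)
    return GAPSOConfig(**base)


class TestConstriction:
    def test_reference_value(self):
        assert constriction_factor(4.1) == pytest.approx(0.729844, abs=1e-6)

    def test_domain_boundary(self):
        with pytest.raises(ValueError):
            constriction_factor(4.0)

    def test_strictly_decreasing(self):
        grid = np.linspace(4.001, 10.0, 200)
        chis = [constriction_factor(p) for p in grid]
        assert all(0 < c < 1 for c in chis)
        assert all(a > b for a, b in zip(chis, chis[1:]))


class TestPsoUpdate:
    def test_fixed_point(self):
        x = np.array([1.0, 2.0])
        p = Particle(0, x.copy(), np.zeros(2), fitness=0.5,
                     pbest_position=x.copy(), pbest_fitness=0.5)
        rng = RngStream(0, 1, 2)
        out = pso_update(p, x, _cfg(), rng,
                         bounds=(np.full(2, -10.0), np.full(2, 10.0)))
        assert np.array_equal(out.position, x)
        assert np.array_equal(out.velocity, np.zeros(2))
        assert out.stale

    def test_pinned_hand_value(self, pinned_rng):
        # 1-D, x=0, v=0, pbest=gbest=1, r1=r2=1:
        # v' = chi(4.1) * 4.1 ~ 2.99236
        p = Particle(0, np.zeros(1), np.zeros(1), fitness=1.0,
                     pbest_position=np.ones(1), pbest_fitness=1.0)
        out = pso_update(p, np.ones(1), _cfg(), pinned_rng(1.0),
                         bounds=(np.full(1, -10.0), np.full(1, 10.0)))
        assert out.position[0] == pytest.approx(2.99236, abs=1e-4)

    def test_clamped_to_bounds(self, pinned_rng):
        p = Particle(0, np.zeros(1), np.zeros(1), fitness=1.0,
                     pbest_position=np.ones(1), pbest_fitness=1.0)
        out = pso_update(p, np.ones(1), _cfg(), pinned_rng(1.0),
                         bounds=(np.zeros(1), np.ones(1)))
        assert out.position[0] == 1.0  # clamped to the violated bound


class TestCrossover:
    def test_identical_parents_zero_velocity(self):
        x = np.array([0.3, -1.0, 2.0, 0.1])
        a = Particle(0, x.copy(), np.zeros(4))
        b = Particle(1, x.copy(), np.zeros(4))
        c1, c2 = crossover(a, b, RngStream(9))
        assert np.array_equal(c1.position, x)
        assert np.array_equal(c2.position, x)
        assert np.array_equal(c1.velocity, np.zeros(4))

    def test_pinned_hand_value(self, pinned_rng):
        # midpoint (0+2)/2 = 1 minus 0.5 * velocity 1 -> 0.5 for both children
        a = Particle(0, np.zeros(1), np.ones(1))
        b = Particle(1, np.full(1, 2.0), np.ones(1))
        c1, c2 = crossover(a, b, pinned_rng(0.5),
                           bounds=(np.full(1, -10.0), np.full(1, 10.0)))
        assert c1.position[0] == pytest.approx(0.5)
        assert c2.position[0] == pytest.approx(0.5)

    def test_out_of_range_set_to_bound(self, pinned_rng):
        a = Particle(0, np.zeros(1), np.full(1, 100.0))
        b = Particle(1, np.full(1, 2.0), np.full(1, -100.0))
        c1, c2 = crossover(a, b, pinned_rng(1.0),
                           bounds=(np.zeros(1), np.full(1, 3.0)))
        assert c1.position[0] == 3.0  # 1 + 100 clamped up
        assert c2.position[0] == 0.0  # 1 - 100 clamped down

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            crossover(Particle(0, np.zeros(2), np.zeros(2)),
                      Particle(1, np.zeros(3), np.zeros(3)), RngStream(0))

    def test_zero_velocity_children_in_convex_hull(self):
        rng = RngStream(3)
        lb, ub = np.full(4, -3.0), np.full(4, 3.0)
        for trial in range(50):
            xa = np.asarray(rng.uniform(-3, 3, 4))
            xb = np.asarray(rng.uniform(-3, 3, 4))
            a = Particle(0, xa, np.zeros(4))
            b = Particle(1, xb, np.zeros(4))
            c1, c2 = crossover(a, b, rng, bounds=(lb, ub))
            lo, hi = np.minimum(xa, xb), np.maximum(xa, xb)
            for c in (c1, c2):
                assert np.all(c.position >= lo - 1e-12)
                assert np.all(c.position <= hi + 1e-12)


class TestMutation:
    def test_unit_draw_is_identity(self, pinned_rng):
        # u = 1 gives Delta = 0 (probability draw < 1 also triggers mutation)
        cfg = _cfg(mutation_prob=1.0)
        p = Particle(0, np.array([0.5, -1.0]), np.zeros(2))
        out = nonuniform_mutate(p, 1, cfg, pinned_rng(1.0),
                                bounds=(np.full(2, -3.0), np.full(2, 3.0)))
        assert np.allclose(out.position, p.position)

    def test_final_iteration_is_identity(self):
        cfg = _cfg(mutation_prob=1.0)
        p = Particle(0, np.array([0.5, -1.0]), np.zeros(2))
        out = nonuniform_mutate(p, cfg.max_iterations, cfg, RngStream(4),
                                bounds=(np.full(2, -3.0), np.full(2, 3.0)))
        assert np.allclose(out.position, p.position)

    def test_always_within_bounds_and_step_bounded(self):
        cfg = _cfg(mutation_prob=1.0)
        lb, ub = np.full(3, -3.0), np.full(3, 3.0)
        rng = RngStream(11)
        x = np.array([-2.9, 0.0, 2.9])
        for t in (1, 3, 9):
            for _ in range(300):
                out = nonuniform_mutate(Particle(0, x, np.zeros(3)), t, cfg,
                                        rng, bounds=(lb, ub))
                assert np.all(out.position >= lb) and np.all(out.position <= ub)
                # |Delta| never exceeds the distance to the moved-toward bound
                assert np.all(np.abs(out.position - x) <= np.maximum(ub - x, x - lb) + 1e-12)

    def test_iteration_overflow_rejected(self):
        with pytest.raises(ValueError):
            nonuniform_mutate(Particle(0, np.zeros(2), np.zeros(2)), 11,
                              _cfg(), RngStream(0))


class TestSelectionAndPartition:
    def _pool(self, fits):
        return [
            Particle(i, np.full(2, float(i)), np.zeros(2), fitness=f)
            for i, f in enumerate(fits)
        ]

    def test_tournament_favors_best(self):
        pool = self._pool([5.0, 1.0, 3.0, 4.0, 2.0])
        rng = RngStream(21)
        wins = np.zeros(5)
        for _ in range(10_000):
            wins[tournament_select(pool, 5, rng).particle_id] += 1
        assert wins[1] == wins.max()
        # exact P(best of 5 draws with replacement hits the minimum)
        expect = 1 - (4 / 5) ** 5
        assert wins[1] / 10_000 == pytest.approx(expect, abs=0.02)

    def test_tournament_k1_is_uniform(self):
        pool = self._pool([5.0, 1.0, 3.0])
        rng = RngStream(22)
        counts = np.zeros(3)
        for _ in range(6000):
            counts[tournament_select(pool, 1, rng).particle_id] += 1
        assert np.all(counts / 6000 > 0.25)

    def test_tournament_ties_deterministic(self):
        pool = self._pool([2.0, 2.0, 2.0])
        a = tournament_select(pool, 3, RngStream(7))
        b = tournament_select(pool, 3, RngStream(7))
        assert a.particle_id == b.particle_id
        with pytest.raises(RuntimeError):
            tournament_select([], 2, RngStream(0))

    @pytest.mark.parametrize(
        "pop,p,r,expected",
        [(10, 0.7, 0.1, (7, 1, 2)), (9, 0.7, 0.1, (6, 0, 3)), (40, 0.7, 0.1, (28, 4, 8))],
    )
    def test_partition_counts(self, pop, p, r, expected):
        assert partition_counts(pop, p, r) == expected

    def test_rank_and_partition(self):
        cfg = _cfg(pop_size=10)
        particles = [
            Particle(i, np.zeros(8), np.zeros(8), fitness=float(10 - i))
            for i in range(10)
        ]
        swarm = SwarmState(particles=particles)
        elites, pool = rank_and_partition(swarm, cfg, RngStream(3))
        assert len(elites) == 7 and len(pool) == 3
        assert [p.fitness for p in elites] == sorted(p.fitness for p in elites)
        assert max(p.fitness for p in elites) < 10 - 2  # worst 3 discarded
        # one randomized pool member (stale), two drawn from the elites
        stale = [p for p in pool if p.stale]
        assert len(stale) == 1
        assert all(any(p is e for e in elites) for p in pool if not p.stale)

    def test_rank_requires_evaluated_population(self):
        swarm = SwarmState(particles=[Particle(0, np.zeros(8), np.zeros(8))])
        with pytest.raises(RuntimeError):
            rank_and_partition(swarm, _cfg(), RngStream(0))


class TestConfigValidation:
    def test_phi_must_exceed_four(self):
        with pytest.raises(ValueError):
            _cfg(c1=2.0, c2=2.0)

    def test_fraction_invariants(self):
        with pytest.raises(ValueError):
            _cfg(p_elite=1.0)
        with pytest.raises(ValueError):
            _cfg(p_elite=0.7, r_random=0.4)
        with pytest.raises(ValueError):
            _cfg(pop_size=3)

    def test_randomness_schedule(self):
        cfg = _cfg(r_random=0.0, r_final=0.3, p_elite=0.7)
        assert cfg.randomness_rate(0) == 0.0
        assert cfg.randomness_rate(10) == pytest.approx(0.3)
        assert _cfg().randomness_rate(5) == 0.1


class TestRunGapso:
    def test_trace_monotone_deterministic_in_bounds(self, bench3):
        _, ds = bench3
        cfg = GAPSOConfig(pop_size=24, max_iterations=10, seed=3)
        vec, trace = run_gapso(ds, 0, cfg)
        assert trace.shape == (10,)
        assert np.all(np.diff(trace) <= 0)
        lb = np.concatenate(([0], np.full(3, -3), [0], np.full(3, -3)))
        ub = np.concatenate(([10], np.full(3, 3), [10], np.full(3, 3)))
        assert np.all(vec.values >= lb) and np.all(vec.values <= ub)
        vec2, trace2 = run_gapso(ds, 0, cfg)
        assert np.array_equal(trace, trace2)
        assert np.array_equal(vec.values, vec2.values)

    def test_different_seeds_differ(self, bench3):
        _, ds = bench3
        a = run_gapso(ds, 0, GAPSOConfig(pop_size=24, max_iterations=5, seed=1))[1]
        b = run_gapso(ds, 0, GAPSOConfig(pop_size=24, max_iterations=5, seed=2))[1]
        assert not np.array_equal(a, b)
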