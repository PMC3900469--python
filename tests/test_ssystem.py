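import numpy as np
import pytest

from ssgrn.ssystem import (
    DivergenceError,
    ExpressionDataset,
    GeneParameterVector,
    SSystemError,
    SSystemModel,
    default_bounds,
    fitness_mse,
    parameter_counts,
    simulate_coupled,
    simulate_decoupled_gene,
)


def _random_in_bounds_model(n, seed):
    rng = np.random.default_rng(seed)
    return SSystemModel(
        alpha=rng.uniform(1, 4, n),
        beta=rng.uniform(1, 4, n),
        g=rng.uniform(-0.8, 0.8, (n, n)),
        h=rng.uniform(0.2, 1.0, (n, n)),
    )


class TestCoupledSimulation:
    def test_zero_exponents_reduce_to_linear_growth(self):
        # dx/dt = alpha - beta = 1, so x(1) = 2 exactly
        model = SSystemModel(alpha=[2.0], beta=[1.0], g=[[0.0]], h=[[0.0]])
        ds = simulate_coupled(model, np.array([1.0]), np.array([0.0, 1.0]))
        assert ds.values[-1, 0] == pytest.approx(2.0, abs=1e-12)

    def test_symmetric_model_is_stationary(self):
        rng = np.random.default_rng(0)
        g = rng.uniform(-1, 1, (2, 2))
        model = SSystemModel(alpha=[1.5, 2.5], beta=[1.5, 2.5], g=g, h=g.copy())
        x0 = np.array([0.7, 1.9])
        ds = simulate_coupled(model, x0, np.linspace(0, 2, 5))
        assert np.allclose(ds.values, x0[None, :], atol=1e-12)

    def test_matches_refined_step_oracle(self):
        model = _random_in_bounds_model(2, seed=3)
        x0 = np.array([0.8, 1.2])
        times = np.linspace(0, 2, 21)
        coarse = simulate_coupled(model, x0, times, substeps=10)
        fine = simulate_coupled(model, x0, times, substeps=1000)
        assert np.max(np.abs(coarse.values - fine.values)) < 1e-6

    def test_fourth_order_convergence(self):
        # halving the step size shrinks the error against a refined
        # reference by at least 8x (4th-order behavior)
        model = _random_in_bounds_model(2, seed=4)
        x0 = np.array([1.1, 0.6])
        times = np.linspace(0, 1.5, 4)
        ref = simulate_coupled(model, x0, times, substeps=512).values
        e2 = np.max(np.abs(simulate_coupled(model, x0, times, substeps=2).values - ref))
        e4 = np.max(np.abs(simulate_coupled(model, x0, times, substeps=4).values - ref))
        assert e2 / e4 >= 8.0

    def test_divergent_model_raises(self):
        # strong mutual activation with weak degradation blows up
        model = SSystemModel(
            alpha=[8.0, 8.0], beta=[0.1, 0.1],
            g=[[0.0, 3.0], [3.0, 0.0]], h=[[0.1, 0.0], [0.0, 0.1]],
        )
        with pytest.raises(DivergenceError):
            simulate_coupled(model, np.array([5.0, 5.0]), np.linspace(0, 50, 11))

    def test_invalid_inputs(self):
        model = _random_in_bounds_model(2, seed=5)
        with pytest.raises(SSystemError):
            simulate_coupled(model, np.array([1.0, -1.0]), np.array([0.0, 1.0]))
        with pytest.raises(SSystemError):
            simulate_coupled(model, np.array([1.0, 1.0]), np.array([1.0, 0.5]))
        with pytest.raises(SSystemError):
            SSystemModel(alpha=[np.nan], beta=[1.0], g=[[0.0]], h=[[0.0]])


class TestDecoupledSimulation:
    def test_single_gene_equals_coupled(self):
        model = _random_in_bounds_model(1, seed=6)
        times = np.linspace(0, 2, 7)
        coupled = simulate_coupled(model, np.array([1.3]), times)
        pred = simulate_decoupled_gene(model.gene_parameters(0), coupled)
        assert np.allclose(pred, coupled.values[:, 0], atol=1e-12)

    def test_zero_rates_give_constant_profile(self, bench3):
        _, ds = bench3
        n = ds.n_genes
        params = GeneParameterVector(1, np.zeros(2 * (n + 1)))
        pred = simulate_decoupled_gene(params, ds)
        assert np.allclose(pred, ds.values[0, 1])

    def test_true_parameters_reproduce_observations(self, bench3):
        # the decoupling device interpolates the other genes linearly, so it
        # is exact only up to O(dt^2); sample densely enough to see < 1e-4
        model, _ = bench3
        times = np.linspace(0.0, 3.0, 201)
        ds = simulate_coupled(model, np.array([1.2, 0.7, 1.6]), times)
        for i in range(ds.n_genes):
            pred = simulate_decoupled_gene(model.gene_parameters(i), ds)
            assert np.max(np.abs(pred - ds.values[:, i])) < 1e-4

    def test_ignores_unconnected_genes(self):
        # gene 0 is regulated by gene 1 only; rescaling gene 2's observed
        # profile must not change gene 0's decoupled prediction
        model = SSystemModel(
            alpha=[2.0, 1.5, 2.5], beta=[1.0, 2.0, 1.5],
            g=[[0.0, 0.8, 0.0], [0.0, 0.0, 0.5], [0.6, 0.0, 0.0]],
            h=[[0.7, 0.0, 0.0], [0.0, 0.9, 0.0], [0.0, 0.0, 0.8]],
        )
        ds = simulate_coupled(model, np.array([1.0, 1.4, 0.8]),
                              np.linspace(0, 2, 11))
        params = model.gene_parameters(0)
        base = simulate_decoupled_gene(params, ds)
        perturbed = ds.values.copy()
        perturbed[:, 2] *= 3.7
        ds2 = ExpressionDataset(times=ds.times, values=perturbed)
        assert np.array_equal(simulate_decoupled_gene(params, ds2), base)

    def test_dimension_mismatch(self, bench3):
        _, ds = bench3
        params = GeneParameterVector(0, np.zeros(2 * (5 + 1)))
        with pytest.raises(SSystemError):
            simulate_decoupled_gene(params, ds)


class TestFitness:
    def test_identity_is_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert fitness_mse(x, x) == 0.0

    def test_hand_value(self):
        # four points, desired 2, predicted 3: 4 * ((3-2)/2)^2 = 1
        assert fitness_mse(np.full(4, 3.0), np.full(4, 2.0)) == pytest.approx(1.0)
        assert fitness_mse(
            np.full(4, 3.0), np.full(4, 2.0), normalize=True
        ) == pytest.approx(0.25)

    def test_guards_and_penalty(self):
        with pytest.raises(SSystemError):
            fitness_mse(np.ones(2), np.array([1.0, 0.0]))
        assert fitness_mse(np.array([np.nan, 1.0]), np.ones(2)) == 1e9

    def test_nonnegative_and_zero_iff_equal(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(0.5, 2, 10)
        p = d + rng.normal(0, 0.1, 10)
        val = fitness_mse(p, d)
        assert val > 0


class TestBookkeeping:
    @pytest.mark.parametrize(
        "n,expected", [(25, (1300, 52)), (1, (4, 4)), (50, (5100, 102))]
    )
    def test_parameter_counts(self, n, expected):
        assert parameter_counts(n) == expected

    def test_per_gene_times_n_equals_total(self):
        for n in range(1, 30):
            total, per = parameter_counts(n)
            assert per * n == total
        with pytest.raises(SSystemError):
            parameter_counts(0)

    def test_model_vector_roundtrip(self):
        model = _random_in_bounds_model(4, seed=9)
        vectors = [model.gene_parameters(i) for i in range(4)]
        assert len(vectors[0].values) == parameter_counts(4)[1]
        back = SSystemModel.from_gene_parameters(vectors)
        assert np.array_equal(back.alpha, model.alpha)
        assert np.array_equal(back.beta, model.beta)
        assert np.array_equal(back.g, model.g)
        assert np.array_equal(back.h, model.h)

    def test_default_bounds_layout(self):
        lb, ub = default_bounds(3)
        assert lb.size == ub.size == 8
        assert lb[0] == 0.0 and ub[0] == 10.0  # alpha
        assert lb[1] == -3.0 and ub[3] == 3.0  # kinetic orders
        assert lb[4] == 0.0 and ub[4] == 10.0  # beta

    def test_dataset_validation(self):
        with pytest.raises(SSystemError):
            ExpressionDataset(times=[0.0, 1.0], values=[[1.0], [-1.0]])
        with pytest.raises(SSystemError):
            ExpressionDataset(times=[0.0], values=[[1.0]])
        with pytest.raises(SSystemError):
            ExpressionDataset(times=[0.0, 0.0], values=[[1.0], [1.0]])
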