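"""Synthetic S-system benchmarks with perturbed, noisy time series.

Emulates the role of in-silico benchmark generators for network-inference
studies: draw a sparse random regulatory network, then simulate perturbed
time-series "experiments" with microarray-like multiplicative noise and
optional per-gene normalization.  Data are generated *from* S-systems, so
ground-truth parameter recovery is well-posed and every other module can be
exercised without external downloads.

Defaults follow the benchmark conditions used throughout the package's
tests: 31 time points per series, sparse regulation (mean in-degree 2),
nonzero kinetic orders bounded away from zero so that every edge is
identifiable, and guaranteed self-degradation (h_ii > 0) so trajectories
stay bounded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ssystem import (
    STATE_FLOOR,
    DivergenceError,
    ExpressionDataset,
    SSystemModel,
    simulate_coupled,
)

__all__ = ["BenchmarkSpec", "generate_network", "generate_dataset", "generate_benchmark"]

_NETWORK_TAG = 11
_DATA_TAG = 12


@dataclass
class BenchmarkSpec:
    """Conditions of one synthetic benchmark.

    n_genes          network size N.
    mean_in_degree   expected number of production regulators per gene
                     (must be < n_genes).
    time_points      samples per series (31).
    duration         simulated time span; with rate constants in [1, 5] the
                     relaxation timescales are 0.2-1 time units, so 3.0
                     captures the transient and the approach to steady state.
    n_perturbations  independent initial-condition perturbations (series).
    noise_sd         sigma of the multiplicative log-normal measurement
                     noise ("lognormal"), or the sd of additive Gaussian
                     noise ("additive"); 0 disables noise.
    normalize        scale each gene to (0, 1] by its per-series maximum.
    seed             root seed; identical specs give identical benchmarks.
    """

    n_genes: int
    mean_in_degree: float = 2.0
    time_points: int = 31
    duration: float = 3.0
    n_perturbations: int = 1
    noise_sd: float = 0.05
    noise_model: str = "lognormal"
    normalize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0 <= self.mean_in_degree < self.n_genes:
            raise ValueError("mean_in_degree must lie in [0, n_genes)")
        if self.time_points < 2:
            raise ValueError("time_points must be >= 2")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.n_perturbations < 1:
            raise ValueError("n_perturbations must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_model not in ("lognormal", "additive"):
            raise ValueError("noise_model must be 'lognormal' or 'additive'")


def _draw_kinetic_orders(rng: np.random.Generator, size: int) -> np.ndarray:
    """Uniform on [-3, -0.5] U [0.5, 3]: edges bounded away from zero."""
    mag = rng.uniform(0.5, 3.0, size)
    sign = np.where(rng.uniform(size=size) < 0.5, -1.0, 1.0)
    return sign * mag


def _stable(model: SSystemModel, spec: BenchmarkSpec) -> bool:
    """Probe boundedness from a few spread-out initial states."""
    times = np.linspace(0.0, spec.duration, spec.time_points)
    for scale in (0.5, 1.0, 2.0):
        try:
            simulate_coupled(model, np.full(model.n_genes, scale), times)
        except DivergenceError:
            return False
    return True


def generate_network(spec: BenchmarkSpec, max_retries: int = 200) -> SSystemModel:
    """Sample a sparse, bounded, in-bounds S-system.

    Each off-diagonal production edge j -> i exists independently with
    probability mean_in_degree / (N - 1), giving the requested expected
    in-degree.  Degradation is first-order in the gene itself
    (h_ii in [0.5, 3], other h entries zero) and rate constants are drawn
    from [1, 5].  Because strong mutual activation can still make power-law
    production outrun the degradation, candidate networks are screened by
    simulation from a few probe states and unstable draws are rejected
    (as benchmark generators for inference studies normally do).
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, _NETWORK_TAG]))
    n = spec.n_genes
    for _attempt in range(max_retries):
        g = np.zeros((n, n))
        if n > 1 and spec.mean_in_degree > 0:
            p_edge = spec.mean_in_degree / (n - 1)
            mask = rng.uniform(size=(n, n)) < p_edge
            np.fill_diagonal(mask, False)
            g[mask] = _draw_kinetic_orders(rng, int(mask.sum()))
        h = np.zeros((n, n))
        np.fill_diagonal(h, rng.uniform(0.5, 3.0, n))
        alpha = rng.uniform(1.0, 5.0, n)
        beta = rng.uniform(1.0, 5.0, n)
        model = SSystemModel(alpha=alpha, beta=beta, g=g, h=h)
        if _stable(model, spec):
            return model
    raise DivergenceError(
        f"no bounded network found in {max_retries} draws for {spec!r}"
    )


def generate_dataset(
    model: SSystemModel,
    spec: BenchmarkSpec,
    max_retries: int = 20,
) -> list[ExpressionDataset]:
    """Perturbed time series from a model, one dataset per perturbation.

    For each perturbation a positive initial state is drawn in [0.5, 2.0]
    per gene and the coupled system is integrated over `time_points`
    equally spaced samples; a diverging initial state is redrawn up to
    `max_retries` times before an error is raised.  Noise and normalization
    are applied per `spec`; all returned values remain strictly positive.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, _DATA_TAG]))
    times = np.linspace(0.0, spec.duration, spec.time_points)
    datasets: list[ExpressionDataset] = []
    for _ in range(spec.n_perturbations):
        clean = None
        for _attempt in range(max_retries):
            x0 = rng.uniform(0.5, 2.0, model.n_genes)
            try:
                clean = simulate_coupled(model, x0, times)
                break
            except DivergenceError:
                continue
        if clean is None:
            raise DivergenceError(
                f"model diverged for {max_retries} perturbation draws"
            )
        values = clean.values.copy()
        if spec.noise_sd > 0:
            if spec.noise_model == "lognormal":
                values = values * np.exp(
                    rng.normal(0.0, spec.noise_sd, values.shape)
                )
            else:
                values = values + rng.normal(0.0, spec.noise_sd, values.shape)
            values = np.maximum(values, STATE_FLOOR)
        if spec.normalize:
            values = values / values.max(axis=0, keepdims=True)
            values = np.maximum(values, STATE_FLOOR)
        datasets.append(
            ExpressionDataset(
                times=times.copy(), values=values, gene_names=clean.gene_names
            )
        )
    return datasets


def generate_benchmark(spec: BenchmarkSpec) -> tuple[SSystemModel, list[ExpressionDataset]]:
    """Network plus its perturbed time series in one call."""
    model = generate_network(spec)
    return model, generate_dataset(model, spec)
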