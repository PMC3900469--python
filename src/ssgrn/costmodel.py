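"""Expected computational cost of try-until-success runs, and Amdahl bounds.

A stochastic optimizer is re-run independently until one run reaches a
success threshold.  If a single run costs C and succeeds with probability
P, the expected total cost x satisfies x = C*P + (C + x)(1 - P), i.e.
x = C/P.  Observing M successes and N failures and placing the flat prior
on P gives the Beta(M+1, N+1) posterior

    f(P) = P^M (1-P)^N / B(M+1, N+1),

The estimator counts the terminating successful run as one more observed
success, so the expectation of C/P is taken under Beta(M+2, N+1) and
collapses to the closed form

    E[x] = C * (M + N + 2) / (M + 1),       (M >= 1)

which is what `expected_cost` returns.  `expected_cost_mc` evaluates the
same expectation by adaptive quadrature or Monte-Carlo sampling and serves
as an independent cross-check on the closed form.

The module also carries the standard Amdahl speed-up accounting for the
parallel backend: a parallel fraction f on S processors is bounded by
1 / ((1-f) + f/S), hence by 1/(1-f) no matter how many processors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

__all__ = [
    "RunOutcome",
    "CostEstimate",
    "classify_runs",
    "expected_cost",
    "estimate_cost",
    "success_posterior_density",
    "expected_cost_mc",
    "amdahl_speedup",
    "parallel_fraction",
]


@dataclass
class RunOutcome:
    """Tally of independent optimization runs against a success threshold."""

    successes: int
    failures: int
    single_run_cost: float = 1.0
    success_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.successes < 0 or self.failures < 0:
            raise ValueError("success/failure counts must be non-negative")
        if self.single_run_cost <= 0:
            raise ValueError("single_run_cost must be positive")

    @property
    def n_runs(self) -> int:
        return self.successes + self.failures


@dataclass
class CostEstimate:
    """Posterior expected cost together with the Beta posterior on P."""

    expected_cost: float
    posterior_alpha: float  # M + 1
    posterior_beta: float  # N + 1


def classify_runs(
    final_fitness: np.ndarray,
    threshold: float,
    single_run_cost: float = 1.0,
) -> RunOutcome:
    """Count runs whose final fitness fell below the success threshold."""
    fit = np.asarray(final_fitness, dtype=float)
    succ = int(np.sum(fit < threshold))
    return RunOutcome(
        successes=succ,
        failures=int(fit.size - succ),
        single_run_cost=single_run_cost,
        success_threshold=threshold,
    )


def expected_cost(outcome: RunOutcome) -> float:
    """Closed-form posterior expected cost C*(M+N+2)/(M+1); requires M >= 1."""
    m, n = outcome.successes, outcome.failures
    if m < 1:
        raise ValueError(
            "expected cost is undefined without at least one success"
        )
    return outcome.single_run_cost * (m + n + 2) / (m + 1)


def estimate_cost(outcome: RunOutcome) -> CostEstimate:
    return CostEstimate(
        expected_cost=expected_cost(outcome),
        posterior_alpha=outcome.successes + 1,
        posterior_beta=outcome.failures + 1,
    )


def success_posterior_density(p: float | np.ndarray, m: int, n: int):
    """Beta(M+1, N+1) posterior density of the success probability."""
    if m < 0 or n < 0:
        raise ValueError("M and N must be non-negative")
    return stats.beta.pdf(p, m + 1, n + 1)


def expected_cost_mc(
    outcome: RunOutcome,
    n_samples: int = 100_000,
    rng: np.random.Generator | None = None,
    method: str = "quadrature",
) -> float:
    """Brute-force posterior expectation of C/P (oracle for `expected_cost`).

    The closed form C*(M+N+2)/(M+1) is the expectation of C/P when the
    success that terminates the try-until-success sequence is itself counted
    as an observation, i.e. under the Beta(M+2, N+1) posterior; that is the
    density integrated here.  (Under Beta(M+1, N+1) — the density reported
    by `success_posterior_density` — the same expectation would instead be
    C*(M+N+1)/M.)

    method="quadrature"  adaptive quadrature of (C/P) f(P) dP over (0, 1).
    method="mc"          Monte-Carlo average of C/P over Beta posterior
                         samples (needs `rng`).
    """
    m, n = outcome.successes, outcome.failures
    c = outcome.single_run_cost
    if m < 1:
        raise ValueError(
            "expected cost is undefined without at least one success"
        )
    if method == "quadrature":
        val, _err = integrate.quad(
            lambda p: c / p * stats.beta.pdf(p, m + 2, n + 1), 0.0, 1.0,
            limit=200,
        )
        return float(val)
    if method == "mc":
        if rng is None:
            raise ValueError("Monte-Carlo estimation needs an rng")
        p = rng.beta(m + 2, n + 1, size=int(n_samples))
        return float(np.mean(c / p))
    raise ValueError(f"unknown method {method!r}")


def amdahl_speedup(f: float, s: float | None = None) -> float:
    """Amdahl's bound 1/((1-f) + f/S); S=None (or inf) gives the limit 1/(1-f)."""
    if not 0.0 <= f <= 1.0:
        raise ValueError("parallel fraction must lie in [0, 1]")
    if s is None or math.isinf(s):
        if f == 1.0:
            return math.inf
        return 1.0 / (1.0 - f)
    if s < 1:
        raise ValueError("processor count must be >= 1")
    return 1.0 / ((1.0 - f) + f / s)


def parallel_fraction(sequential_time: float, parallel_time: float) -> float:
    """Realized parallel fraction 1 - t_parallel / t_sequential.

    If the parallel time exceeds the sequential time (no speed-up), 0 is
    returned with a warning.
    """
    if sequential_time <= 0 or parallel_time <= 0:
        raise ValueError("times must be positive")
    if parallel_time > sequential_time:
        warnings.warn(
            "parallel time exceeds sequential time; reporting fraction 0",
            stacklevel=2,
        )
        return 0.0
    return 1.0 - parallel_time / sequential_time
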