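"""S-system models of gene regulatory networks and their simulation.

An S-system describes the concentration x_i of each of N genes by a pair of
power laws,

    dx_i/dt = alpha_i * prod_j x_j^{g_ij}  -  beta_i * prod_j x_j^{h_ij},

where alpha_i, beta_i >= 0 are rate constants and the kinetic orders g_ij,
h_ij encode the sign and strength of gene j's influence on gene i's
production and degradation.  Fitting the full coupled system means searching
a 2N(N+1)-dimensional space; the *decoupled* formulation instead fits each
gene independently against measured profiles, substituting the observed
time courses of all other genes into gene i's right-hand side.  Each
sub-problem then has only 2(N+1) free parameters.

This module holds the model containers, coupled and decoupled simulation
(classical fixed-step RK4; the decoupled path is compiled with numba because
it is the fitness hot loop of the optimizer), and the relative mean-squared
error used as the optimization objective,

    f_i = sum_t ((x_i^a(t) - x_i^d(t)) / x_i^d(t))^2 ,

a sum over the T measured time points of squared relative deviations between
the simulated (a) and desired (d) profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

__all__ = [
    "RATE_CONSTANT_RANGE",
    "KINETIC_ORDER_RANGE",
    "STATE_FLOOR",
    "STATE_CAP",
    "DEFAULT_SUBSTEPS",
    "PENALTY_FITNESS",
    "SSystemError",
    "DivergenceError",
    "SSystemModel",
    "GeneParameterVector",
    "ExpressionDataset",
    "DecoupledProblem",
    "parameter_counts",
    "default_bounds",
    "simulate_coupled",
    "simulate_decoupled_gene",
    "fitness_mse",
]

#: Default search range for the rate constants alpha_i, beta_i.
RATE_CONSTANT_RANGE = (0.0, 10.0)
#: Default search range for the kinetic orders g_ij, h_ij.
KINETIC_ORDER_RANGE = (-3.0, 3.0)
#: Concentrations are floored here after every integration substep so that
#: negative-exponent power laws stay defined.
STATE_FLOOR = 1e-6
#: Any state exceeding this (or going non-finite) aborts the integration and
#: is reported as divergence.
STATE_CAP = 1e6
#: RK4 substeps per observed sampling interval.
DEFAULT_SUBSTEPS = 10
#: Fitness assigned to diverged candidates so that ranking stays total.
PENALTY_FITNESS = 1e9


class SSystemError(ValueError):
    """Invalid model, parameter vector, or dataset."""


class DivergenceError(RuntimeError):
    """The ODE trajectory exceeded the state cap or went non-finite."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class SSystemModel:
    """Full parameter set (alpha, beta, g, h) of an N-gene S-system."""

    alpha: np.ndarray
    beta: np.ndarray
    g: np.ndarray
    h: np.ndarray
    gene_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        n = self.alpha.shape[0] if self.alpha.ndim == 1 else -1
        if n < 1:
            raise SSystemError("alpha must be a 1-d array with at least one gene")
        for name, arr, shape in (
            ("beta", self.beta, (n,)),
            ("g", self.g, (n, n)),
            ("h", self.h, (n, n)),
        ):
            if arr.shape != shape:
                raise SSystemError(f"{name} has shape {arr.shape}, expected {shape}")
        if not all(np.isfinite(a).all() for a in (self.alpha, self.beta, self.g, self.h)):
            raise SSystemError("model parameters must be finite")
        if self.gene_names is not None and len(self.gene_names) != n:
            raise SSystemError("gene_names length does not match the model size")

    @property
    def n_genes(self) -> int:
        return self.alpha.shape[0]

    def in_bounds(self) -> bool:
        """Whether all parameters lie in the default search ranges."""
        lo, hi = RATE_CONSTANT_RANGE
        klo, khi = KINETIC_ORDER_RANGE
        return bool(
            (self.alpha >= lo).all()
            and (self.alpha <= hi).all()
            and (self.beta >= lo).all()
            and (self.beta <= hi).all()
            and (self.g >= klo).all()
            and (self.g <= khi).all()
            and (self.h >= klo).all()
            and (self.h <= khi).all()
        )

    def gene_parameters(self, gene_index: int) -> "GeneParameterVector":
        """The 2(N+1)-vector (alpha_i, g_i., beta_i, h_i.) of one sub-problem."""
        i = int(gene_index)
        if not 0 <= i < self.n_genes:
            raise SSystemError(f"gene index {i} out of range for N={self.n_genes}")
        values = np.concatenate(
            ([self.alpha[i]], self.g[i], [self.beta[i]], self.h[i])
        )
        return GeneParameterVector(gene_index=i, values=values)

    @classmethod
    def from_gene_parameters(
        cls, vectors: Sequence["GeneParameterVector"],
        gene_names: list[str] | None = None,
    ) -> "SSystemModel":
        """Assemble a full model from the N decoupled solutions (round-trip exact)."""
        n = len(vectors)
        by_gene = {v.gene_index: v for v in vectors}
        if sorted(by_gene) != list(range(n)):
            raise SSystemError("need exactly one parameter vector per gene 0..N-1")
        alpha = np.empty(n)
        beta = np.empty(n)
        g = np.empty((n, n))
        h = np.empty((n, n))
        for i in range(n):
            v = by_gene[i]
            if v.n_genes != n:
                raise SSystemError(
                    f"gene {i} vector implies N={v.n_genes}, expected {n}"
                )
            alpha[i], beta[i] = v.alpha, v.beta
            g[i], h[i] = v.g, v.h
        return cls(alpha=alpha, beta=beta, g=g, h=h, gene_names=gene_names)


@dataclass
class GeneParameterVector:
    """Parameters of one decoupled sub-problem, ordered (alpha, g_1..N, beta, h_1..N)."""

    gene_index: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 4 or self.values.size % 2:
            raise SSystemError(
                "parameter vector must have length 2(N+1) for some N >= 1"
            )
        if self.gene_index < 0 or self.gene_index >= self.n_genes:
            raise SSystemError("gene_index out of range for the implied N")

    @property
    def n_genes(self) -> int:
        return self.values.size // 2 - 1

    @property
    def alpha(self) -> float:
        return float(self.values[0])

    @property
    def g(self) -> np.ndarray:
        return self.values[1 : 1 + self.n_genes]

    @property
    def beta(self) -> float:
        return float(self.values[1 + self.n_genes])

    @property
    def h(self) -> np.ndarray:
        return self.values[2 + self.n_genes :]


@dataclass
class ExpressionDataset:
    """T time points by N genes of strictly positive concentrations."""

    times: np.ndarray
    values: np.ndarray
    gene_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise SSystemError("need at least two time points")
        if np.any(np.diff(self.times) <= 0):
            raise SSystemError("time points must be strictly increasing")
        if self.values.ndim != 2 or self.values.shape[0] != self.times.size:
            raise SSystemError(
                f"values shape {self.values.shape} does not match {self.times.size} times"
            )
        if not np.isfinite(self.values).all() or np.any(self.values <= 0):
            raise SSystemError("concentrations must be finite and strictly positive")
        if self.gene_names is not None and len(self.gene_names) != self.n_genes:
            raise SSystemError("gene_names length does not match the data")

    @property
    def n_times(self) -> int:
        return self.times.size

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def labels(self) -> list[str]:
        if self.gene_names is not None:
            return list(self.gene_names)
        return [f"G{i + 1}" for i in range(self.n_genes)]


# ---------------------------------------------------------------------------
# bookkeeping helpers


def parameter_counts(n_genes: int) -> tuple[int, int]:
    """(total parameters of the coupled problem, parameters per decoupled gene).

    The coupled system has 2N(N+1) parameters; each decoupled sub-problem has
    2(N+1).
    """
    n = int(n_genes)
    if n < 1:
        raise SSystemError("n_genes must be >= 1")
    return 2 * n * (n + 1), 2 * (n + 1)


def default_bounds(n_genes: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-dimension search bounds for one gene's 2(N+1) parameter vector."""
    n = int(n_genes)
    if n < 1:
        raise SSystemError("n_genes must be >= 1")
    rlo, rhi = RATE_CONSTANT_RANGE
    klo, khi = KINETIC_ORDER_RANGE
    lb = np.concatenate(([rlo], np.full(n, klo), [rlo], np.full(n, klo)))
    ub = np.concatenate(([rhi], np.full(n, khi), [rhi], np.full(n, khi)))
    return lb, ub


# ---------------------------------------------------------------------------
# coupled simulation


def _coupled_rate(model: SSystemModel, x: np.ndarray) -> np.ndarray:
    xe = np.maximum(x, STATE_FLOOR)
    lx = np.log(xe)
    return model.alpha * np.exp(model.g @ lx) - model.beta * np.exp(model.h @ lx)


def simulate_coupled(
    model: SSystemModel,
    x0: np.ndarray,
    times: np.ndarray,
    substeps: int = DEFAULT_SUBSTEPS,
) -> ExpressionDataset:
    """Integrate the coupled system through the requested time points.

    Classical fixed-step RK4 with `substeps` internal steps per sampling
    interval; states are floored at STATE_FLOOR after every substep.  Raises
    DivergenceError when any state exceeds STATE_CAP or goes non-finite.
    """
    x0 = np.asarray(x0, dtype=float)
    times = np.asarray(times, dtype=float)
    if x0.shape != (model.n_genes,) or np.any(x0 <= 0):
        raise SSystemError("x0 must be strictly positive with one entry per gene")
    if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
        raise SSystemError("times must be strictly increasing with at least 2 points")
    if substeps < 1:
        raise SSystemError("substeps must be >= 1")

    out = np.empty((times.size, model.n_genes))
    x = x0.copy()
    out[0] = x
    with np.errstate(over="ignore", invalid="ignore"):
        for k in range(times.size - 1):
            h = (times[k + 1] - times[k]) / substeps
            for _ in range(substeps):
                k1 = _coupled_rate(model, x)
                k2 = _coupled_rate(model, x + 0.5 * h * k1)
                k3 = _coupled_rate(model, x + 0.5 * h * k2)
                k4 = _coupled_rate(model, x + h * k3)
                x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
                x = np.maximum(x, STATE_FLOOR)
                if not np.isfinite(x).all() or np.any(x > STATE_CAP):
                    raise DivergenceError(
                        f"trajectory diverged in interval {k} (state cap {STATE_CAP:g})"
                    )
            out[k + 1] = x
    return ExpressionDataset(times=times.copy(), values=out,
                             gene_names=model.gene_names)


# ---------------------------------------------------------------------------
# decoupled simulation (fitness hot loop, numba-compiled)


@njit(cache=True, inline="always")
def _decoupled_rate(a, b, g, h, p, own, x, lx, floor):  # pragma: no cover - jit
    xe = x if x > floor else floor
    sg = 0.0
    sh = 0.0
    for j in range(g.shape[1]):
        if j != own:
            sg += g[p, j] * lx[j]
            sh += h[p, j] * lx[j]
    l = np.log(xe)
    return a * np.exp(sg + g[p, own] * l) - b * np.exp(sh + h[p, own] * l)


@njit(cache=True, nogil=True)
def _rk4_decoupled(alpha, beta, g, h, own, x0, times, lx, substeps, floor, cap):
    """RK4 integration of one gene's ODE for a batch of parameter vectors.

    `lx` holds, per sampling interval, the log observed concentrations of all
    genes at the 2*substeps+1 stage times (own-gene column included but
    ignored; the integrated state supplies the own-gene factor).  Every
    particle is handled by an independent scalar loop, so results are
    bit-identical for any batch size or batch split.
    """
    n_part = alpha.shape[0]
    n_t = times.shape[0]
    traj = np.full((n_part, n_t), np.nan)
    diverged = np.zeros(n_part, dtype=np.bool_)
    for p in range(n_part):
        a = alpha[p]
        b = beta[p]
        x = x0
        traj[p, 0] = x
        dead = False
        for k in range(n_t - 1):
            hh = (times[k + 1] - times[k]) / substeps
            for j in range(substeps):
                s0 = 2 * j
                k1 = _decoupled_rate(a, b, g, h, p, own, x, lx[k, s0], floor)
                k2 = _decoupled_rate(a, b, g, h, p, own, x + 0.5 * hh * k1, lx[k, s0 + 1], floor)
                k3 = _decoupled_rate(a, b, g, h, p, own, x + 0.5 * hh * k2, lx[k, s0 + 1], floor)
                k4 = _decoupled_rate(a, b, g, h, p, own, x + hh * k3, lx[k, s0 + 2], floor)
                x = x + (hh / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
                if x < floor:
                    x = floor
                if not np.isfinite(x) or x > cap:
                    dead = True
                    break
            if dead:
                break
            traj[p, k + 1] = x
        if dead:
            diverged[p] = True
    return traj, diverged


class DecoupledProblem:
    """One gene's decoupled fitting problem against a measured dataset.

    Precomputes the linearly interpolated log-profiles of all genes at the
    RK4 stage times, then evaluates trajectories/fitness for whole batches of
    candidate parameter vectors at once.
    """

    def __init__(
        self,
        dataset: ExpressionDataset,
        gene_index: int,
        substeps: int = DEFAULT_SUBSTEPS,
        penalty: float = PENALTY_FITNESS,
    ) -> None:
        if not 0 <= gene_index < dataset.n_genes:
            raise SSystemError(
                f"gene index {gene_index} out of range for N={dataset.n_genes}"
            )
        if substeps < 1:
            raise SSystemError("substeps must be >= 1")
        self.dataset = dataset
        self.gene_index = int(gene_index)
        self.substeps = int(substeps)
        self.penalty = float(penalty)
        t = dataset.times
        n_int = t.size - 1
        # stage times: 2*substeps+1 evenly spaced points per sampling interval
        frac = np.arange(2 * substeps + 1) / (2.0 * substeps)
        stage_t = t[:-1, None] + np.diff(t)[:, None] * frac[None, :]
        flat = stage_t.ravel()
        interp = np.empty((flat.size, dataset.n_genes))
        for j in range(dataset.n_genes):
            interp[:, j] = np.interp(flat, t, dataset.values[:, j])
        self._log_stages = np.ascontiguousarray(
            np.log(np.maximum(interp, STATE_FLOOR)).reshape(
                n_int, 2 * substeps + 1, dataset.n_genes
            )
        )
        self._x0 = float(dataset.values[0, self.gene_index])
        self._desired = dataset.values[:, self.gene_index].copy()

    @property
    def dim(self) -> int:
        return 2 * (self.dataset.n_genes + 1)

    def _split(self, positions: np.ndarray):
        pos = np.ascontiguousarray(np.atleast_2d(np.asarray(positions, dtype=float)))
        n = self.dataset.n_genes
        if pos.shape[1] != self.dim:
            raise SSystemError(
                f"parameter vectors have dimension {pos.shape[1]}, expected {self.dim}"
            )
        alpha = np.ascontiguousarray(pos[:, 0])
        g = np.ascontiguousarray(pos[:, 1 : 1 + n])
        beta = np.ascontiguousarray(pos[:, 1 + n])
        h = np.ascontiguousarray(pos[:, 2 + n :])
        return alpha, beta, g, h

    def trajectories(self, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Predicted own-gene profiles for a (P, 2(N+1)) batch.

        Returns (traj, diverged); diverged rows are NaN beyond the point of
        failure.
        """
        alpha, beta, g, h = self._split(positions)
        return _rk4_decoupled(
            alpha, beta, g, h, self.gene_index, self._x0, self.dataset.times,
            self._log_stages, self.substeps, STATE_FLOOR, STATE_CAP,
        )

    def fitness(self, positions: np.ndarray) -> np.ndarray:
        """Relative-MSE fitness of a batch; diverged candidates get the penalty."""
        traj, diverged = self.trajectories(positions)
        with np.errstate(invalid="ignore", over="ignore"):
            err = (traj - self._desired[None, :]) / self._desired[None, :]
            fit = np.einsum("pt,pt->p", err, err)
        bad = diverged | ~np.isfinite(fit)
        fit[bad] = self.penalty
        return fit


def simulate_decoupled_gene(
    params: GeneParameterVector,
    dataset: ExpressionDataset,
    substeps: int = DEFAULT_SUBSTEPS,
) -> np.ndarray:
    """Predicted profile of gene i with all other genes pinned to the data.

    The other genes' concentrations are linearly interpolated between the
    measured time points; integration starts at the observed x_i(t_1).
    """
    if params.n_genes != dataset.n_genes:
        raise SSystemError(
            f"parameter vector implies N={params.n_genes}, dataset has N={dataset.n_genes}"
        )
    problem = DecoupledProblem(dataset, params.gene_index, substeps=substeps)
    traj, diverged = problem.trajectories(params.values[None, :])
    if diverged[0]:
        raise DivergenceError(
            f"decoupled trajectory of gene {params.gene_index} diverged"
        )
    return traj[0]


def fitness_mse(
    predicted: np.ndarray,
    desired: np.ndarray,
    normalize: bool = False,
    penalty: float = PENALTY_FITNESS,
) -> float:
    """Sum over time points of squared relative errors ((x^a-x^d)/x^d)^2.

    Despite the customary name, the quantity is a plain sum over the T
    points; `normalize=True` divides by T for a true mean.  Non-finite
    predictions return `penalty`; non-positive desired values are a domain
    error.
    """
    predicted = np.asarray(predicted, dtype=float)
    desired = np.asarray(desired, dtype=float)
    if predicted.shape != desired.shape:
        raise SSystemError("predicted and desired profiles differ in length")
    if np.any(desired <= 0) or not np.isfinite(desired).all():
        raise SSystemError("desired concentrations must be finite and > 0")
    if not np.isfinite(predicted).all():
        return float(penalty)
    val = float(np.sum(((predicted - desired) / desired) ** 2))
    if normalize:
        val /= desired.size
    return val
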