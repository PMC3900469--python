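# Methods

## The model

An S-system describes an N-gene regulatory network by power-law kinetics:

    dx_i/dt = alpha_i * prod_j x_j^{g_ij} - beta_i * prod_j x_j^{h_ij}

with rate constants alpha_i, beta_i >= 0 and real kinetic orders g_ij, h_ij
whose sign and magnitude encode activation/repression strength of gene j on
gene i's production and degradation.  The default search space is the one
customary for evolutionary S-system fitting: alpha, beta in [0, 10] and
g, h in [-3, 3].  Fitting the coupled system means estimating 2N(N+1)
parameters jointly; this package uses the *decoupled* formulation instead:
gene i's ODE is integrated with every other gene's concentration pinned to
its measured profile, so each sub-problem has 2(N+1) parameters and the N
sub-problems are independent.  The other genes' profiles are linearly
interpolated between measured time points (the standard decoupling device);
the decoupled trajectory therefore agrees with the coupled one only up to
O(dt^2) in the sampling interval, which is far below the optimization
tolerance at the 31-point sampling used here.

The objective per gene is the sum over measured time points of squared
relative errors, sum_t ((x_i^a(t) - x_i^d(t)) / x_i^d(t))^2 (a sum, not a
mean, despite the customary "MSE" name — the reported "fitness per gene"
is this per-gene quantity; a normalized variant is available via
`fitness_mse(..., normalize=True)`).  Desired concentrations must be
strictly positive, both for this ratio and for the power laws.

### Numerics

Integration is classical fixed-step RK4 with 10 substeps per sampling
interval (configurable).  States are floored at 1e-6 after every substep so
negative exponents stay defined; any state above 1e6 or non-finite aborts
the integration and the candidate receives the penalty fitness 1e9, keeping
the ranking total.  The decoupled evaluator is compiled (numba) and handles
whole particle batches; each particle is an independent scalar loop, so
results are bit-identical for any batch size or batch split — the property
the parallel backend's determinism rests on.

## The hybrid GA-PSO optimizer

Each generation, the population of `pop_size` particles is ranked ascending
by fitness and split: the best fraction p (default 0.7) are elites, the
rest are discarded.  Elites are enhanced by one constricted PSO step

    v' = chi * (w v + c1 r1 (pbest - x) + c2 r2 (gbest - x)),   x' = x + v'

with the Clerc-Kennedy constriction chi = 2/|2 - phi - sqrt(phi^2 - 4 phi)|,
phi = c1 + c2 > 4 (defaults c1 = c2 = 2.05, so chi ~ 0.7298).  The inertia
weight w defaults to 1 so the constriction alone governs momentum (the
chi * w product would otherwise damp twice); positions are clamped to the
box bounds and velocities to +/-(UB - LB).  The discarded slots are refilled
by a GA: a parent pool of floor(r * pop) freshly randomized candidates
(r = 0.1 by default, optionally ramping linearly over the run) plus draws
from the PSO-enhanced elites (without replacement when the elite count
allows); binary tournaments (k = 2, with replacement) pick parent pairs; the
velocity-aware crossover places children at the parents' midpoint pushed by
the other parent's velocity (out-of-range coordinates are set to the violated
bound, children start with zero velocity); and Michalewicz non-uniform
mutation perturbs each coordinate with probability 0.1 by
Delta(t, y) = y (1 - u^{(1 - t/T)^b}), b = 5, shrinking to zero by the final
iteration.  Fractional partition counts are floored, with the remainder
assigned to elite-drawn parents; ranking ties break by particle id, so runs
are fully deterministic given the seed.

The swarm-level best (`gbest`) is the best solution ever observed, retained
even if its holder is later discarded.  This makes the best-so-far trace
non-increasing by construction; at any instant gbest is <= the minimum
current personal best (equality can break when a personal-best holder is
discarded by the fitness ranking).

## Island model

For coarse-grained parallelism the population splits into `n_islands`
subpopulations evolving independently.  Every `migration_interval`
iterations (10 by default) the islands synchronize and exchange individuals
along a binary n-cube: islands are labeled by n-bit ids and are neighbors
iff the ids differ in one bit (non-power-of-two counts fall back to a
bidirectional ring).  Each island draws round(0.05 * subpop) migrants — at
least one — uniformly from its top 20% and *copies* of them (position,
velocity, fitness, personal best) replace the worst slots of every
neighbor, batches applied in ascending donor id over the pre-migration
ranking, so a later batch may overwrite an earlier one.  Migration happens
strictly between generations, after the receiving islands' own selection.
A single island reduces exactly to the plain optimizer.

## Map/reduce-style backend

Per-particle work (PSO move, fitness evaluation, personal-best update) is
the map side; grouped work (ranking/partition, selection, crossover,
mutation, migration, global-best determination) is the reduce side, grouped
by gene id.  Particles travel between phases as tab-separated text records
(gene-id, island-id, particle-id, then position/velocity/fitness/
personal-best/global-best at 17 significant digits; the field order is
declared in a versioned header line).  Because the flow requires the GA
parent pool to be drawn from elites *after* their PSO enhancement, one
generation runs two map barriers (move+evaluate elites; evaluate offspring)
with reduce stages between; on a cluster this is two chained jobs per
generation.  The randomized parent-pool candidates are ephemeral parents,
not population records, and are evaluated inside the reduce stage that
creates them.

Every random draw is keyed by (seed, operator, iteration, gene, island,
particle slot), so the backend's output is bit-identical to the in-process
driver for any worker count — it is an execution strategy, not an algorithm
change.  The local pool uses threads (the fitness kernel releases the GIL);
a failed chunk is retried once.  Cluster job latency and distributed-storage
overheads are not simulated; they belong to the cost model as a constant.

## Synthetic benchmarks

`synthetic` plays the role of an in-silico benchmark generator, but draws
the data *from* S-systems so that ground truth is well-posed.  Networks
have expected production in-degree `mean_in_degree` (default 2; each
off-diagonal edge present with probability m/(N-1)), nonzero kinetic orders
uniform on [-3, -0.5] u [0.5, 3] (edges bounded away from unidentifiable
zero), first-order-like self-degradation (h_ii in [0.5, 3], off-diagonal h
zero), and rate constants in [1, 5].  Guaranteed self-degradation alone
does not bound power-law mutual activation, so candidate networks are
screened by simulation from three probe states and unstable draws are
rejected — deterministic given the seed, as real benchmark suites also
select for stable modules.  Series default to 31 time points over a
duration of 3.0 (relaxation timescales are 0.2-1 for the rate-constant
range, so the transient and the approach to steady state are both
sampled); initial states are uniform on [0.5, 2] per gene, redrawn on
divergence.  Measurement noise is multiplicative log-normal with sd
`noise_sd` (default 0.05; additive Gaussian behind a flag) and per-gene
max-normalization to (0, 1] is optional.

What this emulates — sparse regulation, perturbed series, multiplicative
microarray-like noise, optional normalization.  What it does not — kinetics
other than S-systems, module extraction from real interactomes, or any
specific published noise pipeline.  Passing tests therefore demonstrate
correct and effective optimization on data a matched S-system can fit
exactly; they do not certify accuracy on data generated by other kinetics.

## Cost model

Re-running an optimizer until one run beats a success threshold has
expected total cost x = C/P for per-run cost C and success probability P.
Observing M successes and N failures and counting the terminating
successful run as one more observation gives the Beta(M+2, N+1) posterior
for P, under which E[C/P] collapses to C (M+N+2)/(M+1) — the closed form
used throughout (undefined at M = 0; the code raises).  The posterior
*density* reported for (M, N) alone is Beta(M+1, N+1); under that density
E[C/P] would be C (M+N+1)/M — the distinction is documented where it
matters, and the quadrature/Monte-Carlo oracle integrates the density
consistent with the closed form.  The success threshold is a configuration
value, so success tallies are inputs, not outputs.  Amdahl accounting is
standard: speed-up(f, S) = 1/((1-f) + f/S), with the S -> inf bound
1/(1-f), and the realized parallel fraction of a measured pair of times is
1 - t_par/t_seq (clamped to 0 with a warning when there is no speed-up).

## Reference problem sizes

The test suite exercises the optimizer at two scales, chosen as the
package's reference conditions: structural/property tests use 3-gene
benchmarks with populations of 16-40 and up to 15 generations, and the
end-to-end checks use a noise-free 5-gene benchmark (generator seed 11)
with 500 particles per gene and 200 generations — at which the median
per-gene fitness over seeds 1-5 is well below 1e-2 and the assembled
network re-simulates the data with pooled R^2 above 0.99 (squared Pearson
correlation over all gene x time point pairs, reported as 0 with a warning
for degenerate constant profiles).  The island comparison pairs one
population of 500 against 4 islands x 125 with migration every 10
generations over seeds 1-10 on the same benchmark sub-problem.

## Known limitations

- Fitting quality certifies data reproduction, not structural recovery;
  distinct S-system parameterizations can fit the same profiles (the
  classical identifiability caveat of decoupled fitting).
- The fixed-step integrator targets the small, screened-stable systems of
  the benchmark generator; stiff or near-singular models need the substep
  count raised.
- The assembled network is the direct union of decoupled solutions; no
  recoupled refinement step is performed.
- The map/reduce backend demonstrates the contract locally; wall-clock
  speed-ups are hardware questions outside its scope.
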