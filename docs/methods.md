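# Methods

## Model

The generative model is a Boolean network with perturbation (BNp) over
`d` genes. The state `X_k ∈ {0,1}^d` evolves as `X_k = f(X_{k−1}) ⊕ n_k`,
where `⊕` is component-wise XOR and each component of `n_k` is an
independent Bernoulli(`p`) flip, `0 ≤ p < 0.5`. The network function
thresholds a signed linear form: gene `i` switches on exactly when
`Σ_j c_ij x(j) + b_i > 0`, with ternary regulation types
`c_ij ∈ {−1, 0, +1}` and tie-breaking biases `b_i = ±1/2`. Validation is
strict: entries outside these sets are rejected rather than coerced,
because the topology space and the kernel distances below presuppose
ternary connectivity.

States are enumerated `1..2^d` with gene 1 as the least-significant bit,
`index(x) = 1 + Σ_j x(j) 2^{j−1}`. Any fixed enumeration gives identical
probabilities; this one is cheap and bijective.

## Exact likelihood with missing steps

Data enter as a state-index sequence `I_{1:T}` with `I_k = 0` marking a
fully missing time step. The missingness mechanism is assumed ignorable
(missing completely at random): masking which steps are hidden carries no
information about the hidden states.

The transition matrix has entries `M_ij = p^h (1−p)^{d−h}` where `h` is
the Hamming distance between `f(x^j)` and `x^i`. The belief over states
is filtered forward: predict `Π_{k|k−1} = M Π_{k−1|k−1}`; at a missing
step the posterior equals the predictive and the step contributes
probability 1; at an observed step the posterior is a point mass at `I_k`
and the step contributes `Π_{k|k−1}(I_k)`. The log-likelihood is the sum
of step log-probabilities, starting from a uniform prior `Π_{0|0} = 1/2^d`
(the simulator also draws its initial state uniformly when none is
given). Tests verify this filter against brute-force marginalization over
all assignments of the missing states for small networks.

Numerics: for `p > 0` every step probability is at least
`min(p, 1−p)^d > 0`, so plain logarithms are taken per step and no
log-sum-exp is needed. For `p = 0` a zero-probability observation returns
a `−inf` sentinel rather than raising. One evaluation performs `T` dense
matrix–vector products of size `2^d` (about 0.1 s for `d = 10`,
`T = 100`); the transition matrix is rebuilt per candidate and not cached
across candidates. The noise probability `p` is treated as known during
inference; an override argument allows likelihood evaluation under a
mis-specified `p` for robustness studies, but `p` is never estimated.

## Topology space

With `L` unknown connectivity entries (ordered 1-based `(target, source)`
positions), a candidate is a ternary vector `θ ∈ {−1, 0, +1}^L` and the
space holds `3^L` candidates. Enumeration is mixed-radix with digit order
(−1, 0, +1) and is capped at 10^6 candidates; beyond the cap the
GA-based acquisition optimizer must be used instead of exhaustive
scoring. The connectivity error between two candidates is the L1 distance
between their embedded matrices, which reduces to `Σ_r |θ(r) − θ′(r)|`
because known entries coincide.

## GP surrogate

The log-likelihood over candidates is modeled as a GP with constant mean
and the connectivity-matrix kernel

```
k(θ, θ′) = σ_f² exp(−‖C^θ − C^θ′‖² / l),
```

`‖·‖²` being the sum of squared element-wise differences. Known entries
cancel, so the distance is computed on the θ vectors directly (O(L) per
pair). In the shipped two-gene example the squared distances from θ¹ to
θ², θ³, θ⁴ are 1, 4 and 8, giving the strict kernel ordering
`σ_f² > k(θ¹,θ²) > k(θ¹,θ³) > k(θ¹,θ⁴)`.

Log-likelihood observations are deterministic, so no observation-noise
hyperparameter exists; a fixed jitter `δ = 10⁻⁸ σ_f²` stabilizes the
Cholesky factorization. Posterior mean and variance follow the standard
GP regression formulas; variances are clipped at zero after round-off.

Hyperparameters `(σ_f², l, mean constant)` are fitted each iteration by
maximizing the Gaussian log marginal likelihood with multi-start (5
seeded starts) L-BFGS-B on log-parameters, bounded by `l ∈ [10⁻², 10³]`
and `σ_f² ∈ [10⁻⁶, 10⁸] · var(L_{1:t})`; the mean constant is initialized
at the sample mean. A refit-interval switch trades fit freshness for
speed; the default refits every iteration.

## Sequential search

Expected improvement over the incumbent `L_max` is used in its standard
form `(μ−L_max)Φ(z) + s·φ(z)` with `z = (μ−L_max)/s` and `s` the posterior
*standard deviation* (the posterior second moment is a variance, so its
square root enters the normal arguments; at `s = 0` EI degenerates to
`max(μ−L_max, 0)`). The search evaluates `init_n = 5` uniformly drawn
distinct candidates (the initial design counts against the evaluation
budget), then loops: refit hyperparameters, score EI over all unevaluated
candidates (exhaustively by default; by ternary GA above the enumeration
cap), evaluate the maximizer's exact likelihood, update the surrogate.
Ties break by enumeration order. The run stops at the budget; an optional
plateau rule (best value improved by less than a tolerance over a fixed
number of consecutive evaluations) is available but off by default. The
reported topology is the argmax over all evaluated candidates, so the
best-so-far curve is non-decreasing by construction.

The GA baseline is a standard elitist genetic algorithm on ternary
strings (population 20, tournament size 2, uniform crossover rate 0.9,
per-gene mutation rate 0.1, elitism 1) with the exact log-likelihood as
fitness; an evaluation cache makes the budget count unique likelihood
evaluations only.

## Synthetic data and the benchmark

The built-in simulator is the generative model itself: uniform initial
state, `T` noisy Boolean updates, then an exact-count uniform random
subset of `round(fraction·T)` time steps hidden (so the realized sparsity
matches the configured percentage exactly). Every stochastic operation
takes an explicit seed; experiment replicate `r` derives its seeds from
`base_seed + r`.

The benchmark masks ten regulations of the 10-gene mammalian cell-cycle
network and uses `T = 100`, `p = 0.1`, 50% missing data, a 100-evaluation
budget. The headline convergence run (`headline_benchmark`, also used by
`scripts/acceptance.py`) simulates **one** masked trajectory and runs
three independently seeded optimizer replicates on that shared data set —
the setting in which a single "optimal log-likelihood" reference value
and a replicate-averaged convergence curve are both well-defined.
`run_experiment` instead defaults to a fresh trajectory per replicate
(with a `shared_trajectory` switch), which is the right design when the
quantity of interest is robustness across data realizations, as in the
missing-data and noise sweeps.

What the simulator emulates — and what it does not: the data are exactly
BNp-distributed, so passing tests certify the estimator under its own
model assumptions (known `p`, ignorable missingness, synchronous updates,
whole-state observations). Real expression data violate all of these to
some degree (asynchronous updates, gene-wise dropout, binarization error,
unknown noise), and nothing here measures robustness to such
misspecification.

## Identifiability at benchmark scale

With 50 observed steps, not every masked regulation is resolvable.
Computing the per-step Kullback–Leibler separation between the true
network and its one-entry perturbations (under the true chain's
stationary distribution) shows two near-degenerate directions: zeroing
the CycB→p27 entry costs only ≈ 0.007 nats/step and zeroing Cdc20→CycA
≈ 0.02 nats/step, so distinguishing these entries reliably needs
trajectories several times longer than `T = 100`. Consequently the
maximum-likelihood topology equals the truth only on a minority of data
realizations (about 1 in 5 in a 24-realization audit); on the others it
differs in one such weak entry while exceeding the truth's likelihood.
The likelihood-convergence result (best value reaches the true topology's
likelihood, typically within 30–40 evaluations) is therefore robust,
while exact recovery (connectivity error 0) is a property of the data
realization, not of the search. The sweeps make the same point
qualitatively: recovery degrades monotonically with missing data, and is
U-shaped in `p` — tiny noise traps the dynamics in attractors (few states
visited, non-identifiable), large noise approaches coin-flipping.

## Problem sizes used in tests

Exhaustive-oracle comparisons use `d ≤ 3`, `T ≤ 6` (likelihood) and
`L ≤ 3` (search). The headline benchmark runs 3 replicates of 100
evaluations; the robustness sweeps use a 4-entry subproblem (the first
four masked regulations) with a 30-evaluation budget and 3 replicates.
These sizes keep a full run on one CPU in the minutes range while leaving
every qualitative conclusion intact; the constants live at the top of
`scripts/acceptance.py` and in the test fixtures.

## Known limitations

- Exact filtering scales as `O(2^{2d} T)` memory/time per evaluation:
  fine for `d ≲ 12`, impossible beyond; no approximate filtering is
  provided.
- Bias entries are part of the model but not of the searchable parameter
  vector (the data model leaves this as an extension hook).
- Only expected improvement is implemented as acquisition; only
  exhaustive scoring and a ternary GA as its optimizers.
- The GP treats duplicate candidates with conflicting observations as a
  conditioning error; deduplication is the caller's responsibility (the
  BO loop never proposes duplicates).
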