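"""Sequential topology search: expected-improvement BO and a GA baseline.

The searcher treats the exact log-likelihood as an expensive black box.
A GP surrogate with the connectivity-matrix kernel is conditioned on the
candidates evaluated so far; the next candidate maximises the expected
improvement (EI)

    alpha(theta) = (mu - L_max) Phi(z) + s phi(z),   z = (mu - L_max) / s,

over the unevaluated candidates, where (mu, s^2) is the GP posterior at
theta and L_max the best log-likelihood observed so far.  After the
evaluation budget is spent, the reported topology is the argmax of the
evaluated log-likelihoods.

A standard elitist genetic algorithm over ternary strings, with the
log-likelihood itself as fitness and a cache so the budget counts unique
evaluations, serves as the comparison baseline.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .gp import KernelHyperparams, SurrogateState
from .likelihood import log_likelihood
from .topology import TopologySpace, theta_to_string

__all__ = [
    "expected_improvement",
    "select_next",
    "run_inference",
    "ga_baseline",
    "BORunResult",
    "GASettings",
]

TRACE_COLUMNS = [
    "iteration",
    "theta",
    "loglik",
    "best_loglik",
    "connectivity_error",
    "sigma_f2",
    "length_scale",
    "mean_const",
    "elapsed_s",
]


@dataclass
class BORunResult:
    """Trace and outcome of one sequential search run."""

    trace: pd.DataFrame
    best_theta: np.ndarray
    best_loglik: float
    method: str = "bo"

    @property
    def n_evaluations(self) -> int:
        return len(self.trace)

    def best_so_far(self) -> np.ndarray:
        return self.trace["best_loglik"].to_numpy()

    def to_csv(self, path) -> None:
        self.trace.to_csv(path, index=False)


def expected_improvement(
    mean: np.ndarray | float, variance: np.ndarray | float, L_max: float
) -> np.ndarray | float:
    """Closed-form EI of a Gaussian posterior over the incumbent ``L_max``.

    At zero posterior variance the EI degenerates to ``max(mean - L_max, 0)``.
    Accepts scalars or arrays (vectorized over candidates).
    """
    mean = np.asarray(mean, dtype=np.float64)
    variance = np.asarray(variance, dtype=np.float64)
    s = np.sqrt(np.clip(variance, 0.0, None))
    gap = mean - L_max
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(s > 0, gap / np.where(s > 0, s, 1.0), 0.0)
    ei = np.where(s > 0, gap * norm.cdf(z) + s * norm.pdf(z), np.clip(gap, 0.0, None))
    ei = np.clip(ei, 0.0, None)
    return float(ei) if ei.ndim == 0 else ei


@dataclass(frozen=True)
class GASettings:
    """Elitist GA defaults; logged with every run."""

    population: int = 20
    tournament: int = 2
    crossover_rate: float = 0.9
    mutation_rate: float = 0.1
    elitism: int = 1


def _ei_over(s: SurrogateState, thetas: np.ndarray) -> np.ndarray:
    mean, var = s.predict(thetas)
    L_max = float(s.loglik.max())
    return np.asarray(expected_improvement(mean, var, L_max))


def _ga_maximize(
    fitness: Callable[[np.ndarray], float],
    L: int,
    rng: np.random.Generator,
    n_generations: int,
    settings: GASettings,
    exclude: set[bytes] | None = None,
) -> np.ndarray | None:
    """Generic ternary-string GA; returns the best individual not in ``exclude``."""
    exclude = exclude or set()
    pop = rng.integers(-1, 2, size=(settings.population, L), dtype=np.int8)
    fit = np.array([fitness(ind) for ind in pop])
    best_key: bytes | None = None
    best_val = -np.inf
    best_ind: np.ndarray | None = None

    def consider(ind: np.ndarray, val: float) -> None:
        nonlocal best_key, best_val, best_ind
        key = ind.tobytes()
        if key not in exclude and val > best_val:
            best_key, best_val, best_ind = key, val, ind.copy()

    for ind, val in zip(pop, fit):
        consider(ind, val)
    for _ in range(n_generations):
        order = np.argsort(fit)[::-1]
        new_pop = [pop[i].copy() for i in order[: settings.elitism]]
        while len(new_pop) < settings.population:
            picks = rng.integers(0, settings.population, size=settings.tournament)
            pa = pop[picks[np.argmax(fit[picks])]]
            picks = rng.integers(0, settings.population, size=settings.tournament)
            pb = pop[picks[np.argmax(fit[picks])]]
            child = pa.copy()
            if rng.random() < settings.crossover_rate:
                swap = rng.random(L) < 0.5
                child[swap] = pb[swap]
            mutate = rng.random(L) < settings.mutation_rate
            if mutate.any():
                child[mutate] = rng.integers(-1, 2, size=int(mutate.sum()), dtype=np.int8)
            new_pop.append(child)
        pop = np.array(new_pop, dtype=np.int8)
        fit = np.array([fitness(ind) for ind in pop])
        for ind, val in zip(pop, fit):
            consider(ind, val)
    return best_ind


def select_next(
    s: SurrogateState,
    space: TopologySpace,
    optimizer: Literal["exhaustive", "ga"] = "exhaustive",
    rng: np.random.Generator | None = None,
    ga_generations: int = 50,
    ga_settings: GASettings = GASettings(),
) -> np.ndarray:
    """Candidate with maximal EI among the unevaluated topologies.

    Exhaustive mode scores every candidate (ties broken by enumeration
    order); GA mode optimises EI heuristically for spaces too large to
    enumerate and never returns an already-evaluated candidate.
    """
    evaluated = {row.tobytes() for row in s.thetas}
    if len(evaluated) >= space.size:
        raise RuntimeError("topology space exhausted: every candidate is evaluated")
    if optimizer == "exhaustive":
        cands = space.all_thetas()
        fresh = np.array([row.tobytes() not in evaluated for row in cands])
        cands = cands[fresh]
        ei = _ei_over(s, cands)
        return cands[int(np.argmax(ei))].copy()
    if optimizer == "ga":
        rng = rng if rng is not None else np.random.default_rng()

        def fitness(ind: np.ndarray) -> float:
            return float(_ei_over(s, ind[None, :])[0])

        best = _ga_maximize(fitness, space.L, rng, ga_generations, ga_settings, exclude=evaluated)
        if best is None:  # GA never left the evaluated set; fall back to random
            best = space.random_thetas(1, rng)[0]
            while best.tobytes() in evaluated:
                best = space.random_thetas(1, rng)[0]
        return best
    raise ValueError(f"unknown acquisition optimizer {optimizer!r}")


class _TraceRecorder:
    """Accumulates per-evaluation records and tracks the incumbent."""

    def __init__(self, space: TopologySpace, truth: np.ndarray | None) -> None:
        self.space = space
        self.truth = truth
        self.records: list[dict] = []
        self.best_value = -np.inf
        self.best_theta: np.ndarray | None = None
        self.t0 = time.perf_counter()

    def __len__(self) -> int:
        return len(self.records)

    def add(self, theta: np.ndarray, value: float, hp: KernelHyperparams | None = None) -> None:
        if value > self.best_value:
            self.best_value = value
            self.best_theta = np.asarray(theta, dtype=np.int8).copy()
        err = (
            self.space.connectivity_error(self.truth, self.best_theta)
            if self.truth is not None
            else np.nan
        )
        self.records.append(
            {
                "iteration": len(self.records) + 1,
                "theta": theta_to_string(theta),
                "loglik": value,
                "best_loglik": self.best_value,
                "connectivity_error": err,
                "sigma_f2": hp.sigma_f2 if hp else np.nan,
                "length_scale": hp.length_scale if hp else np.nan,
                "mean_const": hp.mean_const if hp else np.nan,
                "elapsed_s": time.perf_counter() - self.t0,
            }
        )

    def result(self, method: str) -> BORunResult:
        trace = pd.DataFrame.from_records(self.records, columns=TRACE_COLUMNS)
        assert self.best_theta is not None
        return BORunResult(
            trace=trace, best_theta=self.best_theta, best_loglik=self.best_value, method=method
        )


def run_inference(
    space: TopologySpace,
    I: Sequence[int] | np.ndarray,
    budget: int,
    init_n: int = 5,
    seed: int | None = 0,
    prior: np.ndarray | None = None,
    truth: np.ndarray | None = None,
    optimizer: Literal["exhaustive", "ga"] = "exhaustive",
    refit_every: int = 1,
    plateau: tuple[float, int] | None = None,
) -> BORunResult:
    """Bayesian-optimization topology inference (sequential selection).

    Evaluates ``init_n`` distinct uniformly drawn candidates, then loops
    EI-selection -> likelihood evaluation -> surrogate refit until the
    evaluation budget is spent (the budget counts every likelihood
    evaluation, initial design included) or, when ``plateau=(tol, n)`` is
    given, the best value has improved by less than ``tol`` over ``n``
    consecutive evaluations.  ``truth`` enables per-iteration connectivity
    error in the trace.
    """
    if budget < init_n or init_n < 1:
        raise ValueError(f"need budget >= init_n >= 1, got budget={budget}, init_n={init_n}")
    budget = min(budget, space.size)
    init_n = min(init_n, budget)
    rng = np.random.default_rng(seed)
    rec = _TraceRecorder(space, truth)

    design = space.random_thetas(init_n, rng)
    values = [log_likelihood(space, th, I, prior) for th in design]
    for th, v in zip(design, values):
        rec.add(th, v)

    surrogate = SurrogateState(design, np.array(values))
    stall = 0
    while len(rec) < budget:
        t = len(rec)
        if surrogate.t >= 2 and (t == init_n or (t - init_n) % refit_every == 0):
            surrogate.fit_hyperparams(seed=int(rng.integers(2**31)))
        theta = select_next(surrogate, space, optimizer=optimizer, rng=rng)
        value = log_likelihood(space, theta, I, prior)
        surrogate.add(theta, value)
        rec.add(theta, value, surrogate.hp)
        if plateau is not None:
            tol, n_stall = plateau
            improved = rec.records[-1]["best_loglik"] - rec.records[-2]["best_loglik"] > tol
            stall = 0 if improved else stall + 1
            if stall >= n_stall:
                break
    return rec.result("bo")


def ga_baseline(
    space: TopologySpace,
    I: Sequence[int] | np.ndarray,
    budget: int,
    seed: int | None = 0,
    prior: np.ndarray | None = None,
    truth: np.ndarray | None = None,
    settings: GASettings = GASettings(),
) -> BORunResult:
    """Genetic-algorithm search with the log-likelihood as fitness.

    Repeated individuals hit an evaluation cache and consume no budget, so
    the trace length equals the number of unique likelihood evaluations.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    budget = min(budget, space.size)
    rng = np.random.default_rng(seed)
    rec = _TraceRecorder(space, truth)
    cache: dict[bytes, float] = {}

    class _BudgetExhausted(Exception):
        pass

    def fitness(ind: np.ndarray) -> float:
        key = ind.tobytes()
        if key in cache:
            return cache[key]
        if len(rec) >= budget:
            raise _BudgetExhausted
        value = log_likelihood(space, ind, I, prior)
        cache[key] = value
        rec.add(ind, value)
        return value

    try:
        # generations bounded by the budget; the cache stops double spending
        _ga_maximize(fitness, space.L, rng, n_generations=10 * budget, settings=settings)
        while len(rec) < budget:  # top up with random unseen candidates
            cand = space.random_thetas(1, rng)[0]
            if cand.tobytes() not in cache:
                fitness(cand)
    except _BudgetExhausted:
        pass
    return rec.result("ga")
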