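"""Exact log-likelihood of a candidate topology via belief filtering.

The observed data are summarised by a state-index sequence ``I_1..I_T``
(0 marks a missing step).  A belief vector over the 2^d states is pushed
through the transition matrix each step; at observed steps the belief
collapses to a point mass and the predictive probability of the observed
index contributes to the log-likelihood:

    L(theta) = sum_k log P(I_k | I_{1:k-1}, theta),

where the step probability is the predictive belief at the observed index
and 1 at missing steps.  One evaluation costs T dense matrix-vector
products of size 2^d.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .model import BNPModel, Trajectory, state_to_index, transition_matrix
from .topology import TopologySpace

__all__ = [
    "encode_observations",
    "uniform_prior",
    "filter_step",
    "log_likelihood",
    "log_likelihood_model",
]

_NORM_TOL = 1e-6


def encode_observations(traj: Trajectory) -> np.ndarray:
    """State-index sequence for a trajectory: I_k in 1..2^d, 0 if missing."""
    I = np.zeros(traj.T, dtype=np.int64)
    for k in np.flatnonzero(traj.observed):
        I[k] = state_to_index(traj.states[k])
    return I


def uniform_prior(d: int) -> np.ndarray:
    """Uniform initial belief over the 2^d states."""
    n = 1 << d
    return np.full(n, 1.0 / n)


def filter_step(
    M: np.ndarray, prev_posterior: np.ndarray, I_k: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """One predict/update cycle of the belief recursion.

    Returns ``(predictive, posterior, step_prob)`` where the predictive
    belief is ``M @ prev_posterior``; at a missing step (``I_k == 0``) the
    posterior equals the predictive and the step probability is 1, at an
    observed step the posterior is the point mass at ``I_k`` and the step
    probability is the predictive mass there.
    """
    prev_posterior = np.asarray(prev_posterior, dtype=np.float64)
    total = prev_posterior.sum()
    if abs(total - 1.0) > _NORM_TOL:
        raise ValueError(f"input belief is not normalized (sums to {total!r})")
    predictive = M @ prev_posterior
    if I_k == 0:
        return predictive, predictive, 1.0
    if not 1 <= I_k <= predictive.size:
        raise ValueError(f"state index {I_k} outside 1..{predictive.size}")
    posterior = np.zeros_like(predictive)
    posterior[I_k - 1] = 1.0
    return predictive, posterior, float(predictive[I_k - 1])


def log_likelihood_model(
    model: BNPModel,
    I: Sequence[int] | np.ndarray,
    prior: np.ndarray | None = None,
) -> float:
    """Log-likelihood of an index sequence under a concrete BNp model.

    Returns ``-inf`` when a zero-probability observation occurs (possible
    only for ``p = 0``); for ``p > 0`` every step probability is at least
    ``min(p, 1-p)^d > 0`` so the result is finite.
    """
    I = np.asarray(I, dtype=np.int64)
    if I.ndim != 1 or I.size < 1:
        raise ValueError("index sequence must be a non-empty 1-D vector")
    if I.min() < 0 or I.max() > model.n_states:
        raise ValueError(f"state indices must lie in 0..{model.n_states}")
    if not I.any():
        return 0.0  # every step contributes log 1
    M = transition_matrix(model)
    belief = uniform_prior(model.d) if prior is None else np.asarray(prior, dtype=np.float64)
    total = 0.0
    for I_k in I:
        _, belief, step_prob = filter_step(M, belief, int(I_k))
        if step_prob == 0.0:
            return float("-inf")
        total += np.log(step_prob)
    return float(total)


def log_likelihood(
    space: TopologySpace,
    theta: Sequence[int] | np.ndarray,
    I: Sequence[int] | np.ndarray,
    prior: np.ndarray | None = None,
    p: float | None = None,
) -> float:
    """Log-likelihood of candidate ``theta`` given the index sequence ``I``.

    ``p`` optionally overrides the noise probability of the embedded model
    (the noise rate is otherwise treated as known); the prior defaults to
    uniform over the 2^d states.
    """
    model = space.embed(theta)
    if p is not None:
        model = model.with_noise(p)
    return log_likelihood_model(model, I, prior)
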