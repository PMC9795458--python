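"""Boolean network with perturbation (BNp): model, dynamics, simulation.

A BNp over ``d`` genes evolves as ``X_k = f(X_{k-1}) XOR n_k`` where the
network function thresholds a signed linear form,

    f_i(x) = 1  if  sum_j c_ij x(j) + b_i > 0,  else 0,

``C`` is a ternary connectivity matrix (+1 activation, -1 suppression,
0 no regulation), ``b`` a +/-1/2 tie-breaking bias, and each component of
the perturbation ``n_k`` is an independent Bernoulli(p) flip.

States are enumerated 1..2^d with gene 1 as the least-significant bit:
``index(x) = 1 + sum_j x(j) * 2**(j-1)``.  All probabilistic machinery
(transition matrix, belief filtering) uses this fixed enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "BNPModel",
    "Trajectory",
    "state_to_index",
    "index_to_state",
    "all_states",
    "network_function",
    "transition_matrix",
    "simulate",
    "mask_missing",
]


@dataclass(frozen=True)
class BNPModel:
    """A Boolean network with perturbation.

    Parameters
    ----------
    C : (d, d) array-like
        Connectivity matrix; entry ``C[i, j]`` is the regulation type from
        gene ``j`` to gene ``i``, one of {-1, 0, +1}.
    b : (d,) array-like
        Bias (tie-breaking) vector, entries +1/2 or -1/2.
    p : float
        Per-gene Bernoulli perturbation probability, ``0 <= p < 0.5``.
    genes : sequence of str, optional
        Gene names; defaults to ``g1..gd``.
    """

    C: np.ndarray
    b: np.ndarray
    p: float
    genes: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=np.int8)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError(f"C must be square, got shape {C.shape}")
        if not np.isin(C, (-1, 0, 1)).all():
            raise ValueError("connectivity entries must be in {-1, 0, +1}")
        b = np.asarray(self.b, dtype=np.float64)
        if b.shape != (C.shape[0],):
            raise ValueError(f"b has shape {b.shape}, expected ({C.shape[0]},)")
        if not np.isin(b, (-0.5, 0.5)).all():
            raise ValueError("bias entries must be +1/2 or -1/2")
        if not 0.0 <= self.p < 0.5:
            raise ValueError(f"noise probability must satisfy 0 <= p < 0.5, got {self.p}")
        genes = tuple(self.genes) or tuple(f"g{i + 1}" for i in range(C.shape[0]))
        if len(genes) != C.shape[0]:
            raise ValueError("number of gene names must equal d")
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "genes", genes)

    @property
    def d(self) -> int:
        return self.C.shape[0]

    @property
    def n_states(self) -> int:
        return 1 << self.d

    def with_noise(self, p: float) -> "BNPModel":
        """Return a copy with a different perturbation probability."""
        return BNPModel(self.C, self.b, p, self.genes)


@dataclass
class Trajectory:
    """A time-indexed Boolean state sequence with per-step missingness.

    ``states[k]`` is meaningful only where ``observed[k]`` is True; missing
    rows are stored as zeros and never read.
    """

    states: np.ndarray  # (T, d) int8 in {0, 1}
    observed: np.ndarray  # (T,) bool

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.states.ndim != 2:
            raise ValueError("states must be a (T, d) array")
        if self.observed.shape != (self.states.shape[0],):
            raise ValueError("observed mask length must equal T")
        if self.states.shape[0] < 1:
            raise ValueError("trajectory must contain at least one time step")
        if not np.isin(self.states[self.observed], (0, 1)).all():
            raise ValueError("observed states must be binary")

    @property
    def T(self) -> int:
        return self.states.shape[0]

    @property
    def d(self) -> int:
        return self.states.shape[1]

    def __len__(self) -> int:
        return self.T

    def __getitem__(self, k: int) -> np.ndarray | None:
        """State at step ``k`` (0-based), or None if missing."""
        return self.states[k] if self.observed[k] else None

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())


def _validate_state(x: Sequence[int] | np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim != 1:
        raise ValueError("state must be a 1-D vector")
    if not np.isin(x, (0, 1)).all():
        raise ValueError(f"state entries must be 0 or 1, got {x!r}")
    return x.astype(np.int8)


def state_to_index(x: Sequence[int] | np.ndarray) -> int:
    """Map a binary state vector to its 1-based index.

    Gene 1 is the least-significant bit: ``i = 1 + sum_j x(j) 2^(j-1)``.
    """
    x = _validate_state(x)
    weights = 1 << np.arange(x.size, dtype=np.int64)
    return int(1 + x @ weights)


def index_to_state(i: int, d: int) -> np.ndarray:
    """Inverse of :func:`state_to_index` for a network of ``d`` genes."""
    if not 1 <= i <= (1 << d):
        raise ValueError(f"state index must lie in 1..2^{d}, got {i}")
    bits = (i - 1) >> np.arange(d, dtype=np.int64)
    return (bits & 1).astype(np.int8)


def all_states(d: int) -> np.ndarray:
    """All 2^d states as a (2^d, d) matrix; row k is ``index_to_state(k+1, d)``."""
    idx = np.arange(1 << d, dtype=np.int64)
    return ((idx[:, None] >> np.arange(d)) & 1).astype(np.int8)


def network_function(model: BNPModel, x: Sequence[int] | np.ndarray) -> np.ndarray:
    """Deterministic next state ``f(x)``: threshold of ``C x + b``."""
    x = _validate_state(x)
    if x.size != model.d:
        raise ValueError(f"state length {x.size} does not match d={model.d}")
    return (model.C @ x.astype(np.float64) + model.b > 0).astype(np.int8)


def _successor_indices(model: BNPModel) -> np.ndarray:
    """0-based index of f(x) for every state x, in enumeration order."""
    S = all_states(model.d).astype(np.float64)
    F = (S @ model.C.T.astype(np.float64) + model.b > 0).astype(np.int64)
    weights = 1 << np.arange(model.d, dtype=np.int64)
    return F @ weights


def transition_matrix(model: BNPModel) -> np.ndarray:
    """Exact 2^d x 2^d state-transition matrix.

    Entry ``(i, j)`` is ``P(X_k = x^i | X_{k-1} = x^j) = p^h (1-p)^(d-h)``
    with ``h`` the Hamming distance between ``f(x^j)`` and ``x^i``.  Columns
    sum to one; for ``p = 0`` each column is a unit vector selecting
    ``f(x^j)``.
    """
    d = model.d
    succ = _successor_indices(model)
    idx = np.arange(1 << d, dtype=np.uint64)
    ham = np.bitwise_count(idx[:, None] ^ succ.astype(np.uint64)[None, :]).astype(np.int64)
    # p^h (1-p)^(d-h) via a lookup over h = 0..d avoids 4^d float powers
    table = model.p ** np.arange(d + 1) * (1.0 - model.p) ** np.arange(d, -1, -1)
    return table[ham]


def simulate(
    model: BNPModel,
    T: int,
    x0: Sequence[int] | np.ndarray | None = None,
    seed: int | np.random.Generator | None = None,
) -> Trajectory:
    """Simulate ``T`` steps of the BNp dynamics.

    The initial state ``x0`` (the state at time 0, not part of the returned
    trajectory) is drawn uniformly over the 2^d states when omitted,
    matching the uniform prior used by the likelihood filter.
    """
    if T < 1:
        raise ValueError(f"horizon must be >= 1, got {T}")
    rng = np.random.default_rng(seed)
    if x0 is None:
        x = all_states(model.d)[rng.integers(model.n_states)].copy()
    else:
        x = _validate_state(x0)
        if x.size != model.d:
            raise ValueError("x0 length does not match model dimension")
    states = np.empty((T, model.d), dtype=np.int8)
    for k in range(T):
        noise = rng.random(model.d) < model.p
        x = network_function(model, x) ^ noise.astype(np.int8)
        states[k] = x
    return Trajectory(states, np.ones(T, dtype=bool))


def mask_missing(
    traj: Trajectory,
    fraction: float,
    seed: int | np.random.Generator | None = None,
) -> Trajectory:
    """Hide ``round(fraction * T)`` uniformly chosen time steps.

    An exact-count subset (rather than i.i.d. per-step dropout) makes the
    realized sparsity equal the configured percentage.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"missing fraction must lie in [0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    n_missing = int(round(fraction * traj.T))
    observed = traj.observed.copy()
    if n_missing:
        drop = rng.choice(traj.T, size=n_missing, replace=False)
        observed[drop] = False
    states = traj.states.copy()
    states[~observed] = 0
    return Trajectory(states, observed)
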