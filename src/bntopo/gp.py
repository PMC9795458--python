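"""Gaussian-process surrogate over the discrete topology space.

The covariance between two candidate topologies is the connectivity-matrix
kernel

    k(theta, theta') = sigma_f^2 * exp(-||C^theta - C^theta'||^2 / l),

where ``||.||^2`` is the sum of squared element-wise differences.  Known
entries are identical across candidates and cancel, so the squared
distance is computed on the ternary parameter vectors directly.  Together
with a constant mean this gives a standard GP regression whose
hyperparameters (sigma_f^2, l, mean constant) are fitted by maximising the
Gaussian log marginal likelihood of the evaluated candidates.

Log-likelihood observations are deterministic, so no observation-noise
hyperparameter exists; a small jitter proportional to sigma_f^2 keeps the
Cholesky factorisation stable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

__all__ = [
    "KernelHyperparams",
    "SurrogateState",
    "GPPrediction",
    "kernel",
    "kernel_matrix",
    "gp_posterior",
    "fit_hyperparams",
]

#: relative jitter added to the kernel diagonal
JITTER_REL = 1e-8

#: bounds for the length-scale during marginal-likelihood fitting
LENGTH_SCALE_BOUNDS = (1e-2, 1e3)
#: bounds for sigma_f^2, relative to the sample variance of the observations
SIGMA_F2_REL_BOUNDS = (1e-6, 1e8)


@dataclass(frozen=True)
class KernelHyperparams:
    """Kernel scale ``sigma_f2``, length-scale ``length_scale``, constant mean."""

    sigma_f2: float = 1.0
    length_scale: float = 1.0
    mean_const: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_f2 <= 0:
            raise ValueError("sigma_f2 must be positive")
        if self.length_scale <= 0:
            raise ValueError("length_scale must be positive")


@dataclass(frozen=True)
class GPPrediction:
    mean: float
    variance: float  # clipped to >= 0 after round-off


def _sqdist(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    A = np.atleast_2d(np.asarray(A, dtype=np.float64))
    B = np.atleast_2d(np.asarray(B, dtype=np.float64))
    return cdist(A, B, metric="sqeuclidean")


def kernel_matrix(A: np.ndarray, B: np.ndarray, hp: KernelHyperparams) -> np.ndarray:
    """Kernel Gram block between candidate sets ``A`` (n, L) and ``B`` (m, L)."""
    return hp.sigma_f2 * np.exp(-_sqdist(A, B) / hp.length_scale)


def kernel(
    theta_a: Sequence[int] | np.ndarray,
    theta_b: Sequence[int] | np.ndarray,
    hp: KernelHyperparams,
) -> float:
    """Connectivity-matrix kernel between two candidates."""
    return float(kernel_matrix(np.asarray(theta_a), np.asarray(theta_b), hp)[0, 0])


class SurrogateState:
    """Evaluated candidates, their log-likelihoods, and the fitted GP.

    The kernel Cholesky factor is cached and refreshed whenever points are
    added or hyperparameters change.
    """

    def __init__(
        self,
        thetas: np.ndarray,
        loglik: np.ndarray,
        hp: KernelHyperparams | None = None,
    ) -> None:
        self.thetas = np.atleast_2d(np.asarray(thetas, dtype=np.int8))
        self.loglik = np.atleast_1d(np.asarray(loglik, dtype=np.float64))
        if self.thetas.shape[0] != self.loglik.shape[0]:
            raise ValueError("number of candidates and observations must match")
        if hp is None:
            hp = KernelHyperparams(mean_const=float(self.loglik.mean()))
        self.hp = hp
        self._chol: tuple[np.ndarray, bool] | None = None

    @property
    def t(self) -> int:
        return self.loglik.size

    @property
    def jitter(self) -> float:
        return JITTER_REL * self.hp.sigma_f2

    def add(self, theta: np.ndarray, value: float) -> None:
        self.thetas = np.vstack([self.thetas, np.asarray(theta, dtype=np.int8)])
        self.loglik = np.append(self.loglik, value)
        self._chol = None

    def set_hyperparams(self, hp: KernelHyperparams) -> None:
        self.hp = hp
        self._chol = None

    def _factorization(self) -> tuple[np.ndarray, bool]:
        if self._chol is None:
            K = kernel_matrix(self.thetas, self.thetas, self.hp)
            K[np.diag_indices_from(K)] += self.jitter
            try:
                self._chol = cho_factor(K, lower=True)
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise np.linalg.LinAlgError(
                    "kernel matrix is singular even with jitter; check for duplicate "
                    "candidates with conflicting observations"
                ) from exc
        return self._chol

    def predict(self, thetas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and variance at each row of ``thetas`` (m, L)."""
        thetas = np.atleast_2d(np.asarray(thetas))
        c, lower = self._factorization()
        Ks = kernel_matrix(thetas, self.thetas, self.hp)  # (m, t)
        alpha = cho_solve((c, lower), self.loglik - self.hp.mean_const)
        mean = self.hp.mean_const + Ks @ alpha
        # variance via the triangular solve L^-1 k*; diag(Ks K^-1 Ks^T)
        V = solve_triangular(c, Ks.T, lower=lower)
        var = self.hp.sigma_f2 - np.einsum("ij,ij->j", V, V)
        return mean, np.clip(var, 0.0, None)

    # -- marginal likelihood -------------------------------------------------

    def log_marginal_likelihood(self, hp: KernelHyperparams) -> float:
        """Gaussian log marginal likelihood of the observations under ``hp``."""
        K = kernel_matrix(self.thetas, self.thetas, hp)
        K[np.diag_indices_from(K)] += JITTER_REL * hp.sigma_f2
        try:
            c, lower = cho_factor(K, lower=True)
        except np.linalg.LinAlgError:
            return float("-inf")
        resid = self.loglik - hp.mean_const
        alpha = cho_solve((c, lower), resid)
        logdet = 2.0 * np.log(np.diag(c)).sum()
        return float(-0.5 * resid @ alpha - 0.5 * logdet - 0.5 * self.t * np.log(2.0 * np.pi))

    def fit_hyperparams(self, seed: int | None = 0, n_starts: int = 5) -> KernelHyperparams:
        """Fit (mean_const, sigma_f2, length_scale) by multi-start quasi-Newton.

        Positive parameters are optimised in log-space within fixed bounds;
        the first start is the current hyperparameter triple, further starts
        are drawn uniformly in the log-bound box.  Falls back to the current
        hyperparameters (with a warning) if every start fails.
        """
        if self.t < 2:
            raise ValueError("hyperparameter fitting needs at least two evaluations")
        rng = np.random.default_rng(seed)
        var_l = max(float(self.loglik.var()), 1e-12)
        lo = np.log([SIGMA_F2_REL_BOUNDS[0] * var_l, LENGTH_SCALE_BOUNDS[0]])
        hi = np.log([SIGMA_F2_REL_BOUNDS[1] * var_l, LENGTH_SCALE_BOUNDS[1]])
        mean0 = float(self.loglik.mean())

        def unpack(z: np.ndarray) -> KernelHyperparams:
            return KernelHyperparams(
                sigma_f2=float(np.exp(z[0])), length_scale=float(np.exp(z[1])), mean_const=float(z[2])
            )

        def objective(z: np.ndarray) -> float:
            return -self.log_marginal_likelihood(unpack(z))

        starts = [
            np.array(
                [
                    np.clip(np.log(self.hp.sigma_f2), lo[0], hi[0]),
                    np.clip(np.log(self.hp.length_scale), lo[1], hi[1]),
                    mean0,
                ]
            )
        ]
        for _ in range(n_starts - 1):
            z = rng.uniform(lo, hi)
            starts.append(np.array([z[0], z[1], mean0 + rng.normal(scale=max(1.0, np.sqrt(var_l)))]))

        best: tuple[float, KernelHyperparams] | None = None
        bounds = [(lo[0], hi[0]), (lo[1], hi[1]), (None, None)]
        for z0 in starts:
            res = minimize(objective, z0, method="L-BFGS-B", bounds=bounds)
            if not np.isfinite(res.fun):
                continue
            cand = (float(res.fun), unpack(res.x))
            if best is None or cand[0] < best[0]:
                best = cand
        if best is None:  # pragma: no cover - requires pathological data
            warnings.warn("hyperparameter optimisation failed on all starts; keeping previous values")
            return self.hp
        self.set_hyperparams(best[1])
        return best[1]

    # -- checkpointing -------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "thetas": self.thetas.astype(int).tolist(),
            "loglik": self.loglik.tolist(),
            "hyperparams": {
                "sigma_f2": self.hp.sigma_f2,
                "length_scale": self.hp.length_scale,
                "mean_const": self.hp.mean_const,
            },
        }
        Path(path).write_text(json.dumps(payload) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SurrogateState":
        payload = json.loads(Path(path).read_text())
        hp = KernelHyperparams(**payload["hyperparams"])
        return cls(np.array(payload["thetas"]), np.array(payload["loglik"]), hp)


def gp_posterior(s: SurrogateState, theta: Sequence[int] | np.ndarray) -> GPPrediction:
    """Posterior mean/variance of the log-likelihood at a single candidate."""
    mean, var = s.predict(np.asarray(theta))
    return GPPrediction(mean=float(mean[0]), variance=float(var[0]))


def fit_hyperparams(s: SurrogateState, seed: int | None = 0, n_starts: int = 5) -> KernelHyperparams:
    """Module-level convenience wrapper around :meth:`SurrogateState.fit_hyperparams`."""
    return s.fit_hyperparams(seed=seed, n_starts=n_starts)
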