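"""The combinatorial space of candidate topologies.

When ``L`` entries of the connectivity matrix are unknown, each candidate
topology is a ternary parameter vector theta in {-1, 0, +1}^L assigning a
regulation type to every unknown entry; the space holds 3^L candidates.
Embedding a theta into the base model yields a concrete BNp whose
likelihood can be evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .model import BNPModel

__all__ = [
    "UnknownEntrySet",
    "TopologySpace",
    "theta_to_string",
    "string_to_theta",
]

#: default upper bound on exhaustive enumeration (3^L candidates)
ENUMERATION_CAP = 10**6

_DIGITS = (-1, 0, 1)  # mixed-radix digit order per position


def _validate_theta(theta: Sequence[int] | np.ndarray, L: int) -> np.ndarray:
    theta = np.asarray(theta, dtype=np.int8)
    if theta.shape != (L,):
        raise ValueError(f"parameter vector must have length {L}, got shape {theta.shape}")
    if not np.isin(theta, (-1, 0, 1)).all():
        raise ValueError("parameter entries must be in {-1, 0, +1}")
    return theta


def theta_to_string(theta: Sequence[int] | np.ndarray) -> str:
    """Compact ternary string, one of ``-``, ``0``, ``+`` per entry."""
    return "".join("-0+"[int(v) + 1] for v in np.asarray(theta, dtype=int))


def string_to_theta(s: str) -> np.ndarray:
    return np.array(["-0+".index(ch) - 1 for ch in s], dtype=np.int8)


@dataclass(frozen=True)
class UnknownEntrySet:
    """Ordered list of unknown connectivity-matrix positions.

    Positions are 1-based ``(target_row, source_col)`` pairs, i.e. the
    entry ``c_ij`` regulating gene ``i`` by gene ``j``.
    """

    entries: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        entries = tuple((int(r), int(c)) for r, c in self.entries)
        if len(entries) < 1:
            raise ValueError("at least one unknown entry is required")
        if len(set(entries)) != len(entries):
            raise ValueError("unknown entry positions must be distinct")
        for r, c in entries:
            if r < 1 or c < 1:
                raise ValueError("positions are 1-based gene indices")
        object.__setattr__(self, "entries", entries)

    @property
    def L(self) -> int:
        return len(self.entries)

    def rows_cols(self) -> tuple[np.ndarray, np.ndarray]:
        """0-based row/column index arrays for vectorized matrix patching."""
        arr = np.asarray(self.entries, dtype=np.int64) - 1
        return arr[:, 0], arr[:, 1]


@dataclass(frozen=True)
class TopologySpace:
    """Candidate space over the unknown entries of a base model.

    ``base_model`` carries the known connectivity truth with every unknown
    position zeroed; ``embed`` overwrites those positions with a candidate
    theta.
    """

    base_model: BNPModel
    unknowns: UnknownEntrySet

    def __post_init__(self) -> None:
        d = self.base_model.d
        for r, c in self.unknowns.entries:
            if r > d or c > d:
                raise ValueError(f"unknown position ({r},{c}) outside a {d}-gene network")
        rows, cols = self.unknowns.rows_cols()
        if self.base_model.C[rows, cols].any():
            C = self.base_model.C.copy()
            C[rows, cols] = 0
            object.__setattr__(
                self, "base_model", BNPModel(C, self.base_model.b, self.base_model.p, self.base_model.genes)
            )

    @property
    def L(self) -> int:
        return self.unknowns.L

    @property
    def size(self) -> int:
        return 3**self.L

    def embed(self, theta: Sequence[int] | np.ndarray) -> BNPModel:
        """Concrete BNp with the unknown entries set to ``theta``."""
        theta = _validate_theta(theta, self.L)
        C = self.base_model.C.copy()
        rows, cols = self.unknowns.rows_cols()
        C[rows, cols] = theta
        return BNPModel(C, self.base_model.b, self.base_model.p, self.base_model.genes)

    def extract(self, model: BNPModel) -> np.ndarray:
        """Read the unknown positions out of a connectivity matrix."""
        rows, cols = self.unknowns.rows_cols()
        return model.C[rows, cols].astype(np.int8)

    def enumerate(self, cap: int = ENUMERATION_CAP) -> Iterator[np.ndarray]:
        """Yield every candidate once, in mixed-radix order (-1, 0, +1)."""
        for row in self.all_thetas(cap):
            yield row

    def all_thetas(self, cap: int = ENUMERATION_CAP) -> np.ndarray:
        """All 3^L candidates as a (3^L, L) int8 array in enumeration order.

        Raises if the space exceeds ``cap``; very large spaces must go
        through the GA acquisition optimizer instead of exhaustive scoring.
        """
        if self.size > cap:
            raise ValueError(
                f"3^{self.L} = {self.size} candidates exceed the enumeration cap {cap}; "
                "use the genetic-algorithm acquisition optimizer for spaces this large"
            )
        idx = np.arange(self.size, dtype=np.int64)
        digits = (idx[:, None] // 3 ** np.arange(self.L, dtype=np.int64)[None, ::-1]) % 3
        return (digits - 1).astype(np.int8)

    def connectivity_error(
        self, theta_true: Sequence[int] | np.ndarray, theta_hat: Sequence[int] | np.ndarray
    ) -> float:
        """L1 distance between the two embedded connectivity matrices.

        Known entries are shared by construction, so the distance reduces
        to ``sum_r |theta_true(r) - theta_hat(r)|``; zero means exact
        topology recovery.
        """
        a = _validate_theta(theta_true, self.L).astype(np.int64)
        b = _validate_theta(theta_hat, self.L).astype(np.int64)
        return float(np.abs(a - b).sum())

    def random_thetas(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """``n`` distinct uniformly drawn candidates (requires n <= 3^L)."""
        if n > self.size:
            raise ValueError(f"cannot draw {n} distinct candidates from a space of {self.size}")
        if self.size <= ENUMERATION_CAP:
            pick = rng.choice(self.size, size=n, replace=False)
            base = 3 ** np.arange(self.L, dtype=np.int64)[::-1]
            return ((pick[:, None] // base) % 3 - 1).astype(np.int8)
        seen: set[bytes] = set()
        out = np.empty((n, self.L), dtype=np.int8)
        k = 0
        while k < n:
            cand = rng.integers(-1, 2, size=self.L, dtype=np.int8)
            key = cand.tobytes()
            if key not in seen:
                seen.add(key)
                out[k] = cand
                k += 1
        return out
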