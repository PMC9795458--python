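"""Built-in networks: the mammalian cell-cycle BNp and a two-gene example.

The cell-cycle network couples ten regulators of mammalian cell division
(CycD, Rb, p27, E2F, CycE, CycA, Cdc20, Cdh1, UbcH10, CycB).  Growth
signals activate cyclin D, which drives the Rb/E2F restriction-point
switch; the remaining cyclins and the APC regulators (Cdc20, Cdh1,
UbcH10) sequence progression through the cycle.  The threshold form used
here encodes each regulation as +1 (activation) or -1 (suppression) with
a uniform -1/2 bias, which reproduces the published Boolean update rules.

The benchmark masks ten of these regulations and asks the inference
machinery to recover them from a noisy, temporally sparse trajectory.
"""

from __future__ import annotations

import numpy as np

from .model import BNPModel
from .topology import TopologySpace, UnknownEntrySet

__all__ = [
    "CELL_CYCLE_GENES",
    "cell_cycle_model",
    "cell_cycle_unknowns",
    "cell_cycle_space",
    "two_gene_space",
    "two_gene_example_thetas",
]

CELL_CYCLE_GENES = ("CycD", "Rb", "p27", "E2F", "CycE", "CycA", "Cdc20", "Cdh1", "UbcH10", "CycB")

# Rows are targets, columns are sources, in the gene order above.
_CELL_CYCLE_C = np.array(
    [
        [+1, 0, 0, 0, 0, 0, 0, 0, 0, 0],
        [-1, 0, +1, 0, -1, -1, 0, 0, 0, -1],
        [-1, 0, +1, 0, -1, -1, 0, 0, 0, -1],
        [0, -1, +1, 0, 0, -1, 0, 0, 0, -1],
        [0, -1, +1, +1, -1, -1, 0, 0, 0, 0],
        [0, -1, 0, +1, 0, +1, -1, -1, -1, 0],
        [0, 0, 0, 0, 0, 0, -1, 0, 0, +1],
        [0, 0, +1, 0, 0, -1, +1, 0, 0, -1],
        [0, 0, 0, 0, 0, +1, +1, -1, +1, +1],
        [0, 0, 0, 0, 0, 0, -1, -1, 0, 0],
    ],
    dtype=np.int8,
)

# The ten masked regulations of the benchmark, as 1-based (target, source)
# positions c_ij with their true signs.
_UNKNOWN_TRUTH = (
    ((2, 1), -1),
    ((3, 5), -1),
    ((3, 10), -1),
    ((4, 2), -1),
    ((5, 4), +1),
    ((6, 7), -1),
    ((6, 9), -1),
    ((8, 3), +1),
    ((9, 6), +1),
    ((9, 8), -1),
)


def cell_cycle_model(p: float = 0.1) -> BNPModel:
    """The 10-gene mammalian cell-cycle BNp with noise probability ``p``."""
    return BNPModel(
        C=_CELL_CYCLE_C.copy(),
        b=np.full(10, -0.5),
        p=p,
        genes=CELL_CYCLE_GENES,
    )


def cell_cycle_unknowns() -> tuple[UnknownEntrySet, np.ndarray]:
    """The benchmark's ten unknown positions and their true ternary values."""
    entries = tuple(pos for pos, _ in _UNKNOWN_TRUTH)
    truth = np.array([v for _, v in _UNKNOWN_TRUTH], dtype=np.int8)
    return UnknownEntrySet(entries), truth


def cell_cycle_space(p: float = 0.1) -> tuple[TopologySpace, np.ndarray]:
    """Cell-cycle topology space (3^10 candidates) and the true theta."""
    unknowns, truth = cell_cycle_unknowns()
    return TopologySpace(cell_cycle_model(p), unknowns), truth


def two_gene_space(p: float = 0.1) -> TopologySpace:
    """Two-gene space with both cross-regulations (c12, c21) unknown."""
    base = BNPModel(C=np.zeros((2, 2), dtype=np.int8), b=np.array([-0.5, -0.5]), p=p)
    return TopologySpace(base, UnknownEntrySet(((1, 2), (2, 1))))


def two_gene_example_thetas() -> dict[str, np.ndarray]:
    """The four worked-example topologies over the two-gene space.

    theta = (c12, c21); squared connectivity distances from theta1 are
    1 (theta2), 4 (theta3) and 8 (theta4), which fixes the kernel ordering
    k(t1,t1) > k(t1,t2) > k(t1,t3) > k(t1,t4).
    """
    return {
        "theta1": np.array([-1, +1], dtype=np.int8),
        "theta2": np.array([0, +1], dtype=np.int8),
        "theta3": np.array([+1, +1], dtype=np.int8),
        "theta4": np.array([+1, -1], dtype=np.int8),
    }
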