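"""Reading and writing networks and trajectories.

Formats
-------
Network JSON
    ``{"genes": [...], "C": row-major int matrix, "b": list of +/-0.5,
    "p": float}``.
SIF-style TSV
    One signed interaction per line: ``source<TAB>sign<TAB>target`` with
    sign in {+1, -1}; pairs not listed have no regulation.  Gene names,
    bias and noise live in a companion JSON ("bias file").
Trajectory CSV
    Header row of gene names, then one row per time step with 0/1 entries;
    a missing step is a fully blank row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import BNPModel, Trajectory

__all__ = [
    "read_network_json",
    "write_network_json",
    "read_sif",
    "write_sif",
    "read_trajectory_csv",
    "write_trajectory_csv",
]


def write_network_json(model: BNPModel, path: str | Path) -> None:
    payload = {
        "genes": list(model.genes),
        "C": model.C.astype(int).tolist(),
        "b": model.b.tolist(),
        "p": model.p,
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_network_json(path: str | Path) -> BNPModel:
    payload = json.loads(Path(path).read_text())
    return BNPModel(
        C=np.array(payload["C"]),
        b=np.array(payload["b"]),
        p=float(payload["p"]),
        genes=tuple(payload.get("genes", ())),
    )


def write_sif(model: BNPModel, sif_path: str | Path, bias_path: str | Path) -> None:
    """Write the signed interaction list plus a companion bias/noise file."""
    lines = []
    for i in range(model.d):  # i = target row
        for j in range(model.d):
            if model.C[i, j] != 0:
                lines.append(f"{model.genes[j]}\t{int(model.C[i, j]):+d}\t{model.genes[i]}")
    Path(sif_path).write_text("\n".join(lines) + ("\n" if lines else ""))
    companion = {"genes": list(model.genes), "b": model.b.tolist(), "p": model.p}
    Path(bias_path).write_text(json.dumps(companion, indent=1) + "\n")


def read_sif(sif_path: str | Path, bias_path: str | Path) -> BNPModel:
    companion = json.loads(Path(bias_path).read_text())
    genes = list(companion["genes"])
    index = {g: i for i, g in enumerate(genes)}
    C = np.zeros((len(genes), len(genes)), dtype=np.int8)
    for line in Path(sif_path).read_text().splitlines():
        if not line.strip():
            continue
        source, sign, target = line.split("\t")
        C[index[target], index[source]] = int(sign)
    return BNPModel(C=C, b=np.array(companion["b"]), p=float(companion["p"]), genes=tuple(genes))


def write_trajectory_csv(traj: Trajectory, path: str | Path, genes: tuple[str, ...] | None = None) -> None:
    genes = genes or tuple(f"g{i + 1}" for i in range(traj.d))
    frame = pd.DataFrame(traj.states.astype("float64"), columns=list(genes))
    frame[~traj.observed] = np.nan
    frame.to_csv(path, index=False, float_format="%.0f")


def read_trajectory_csv(path: str | Path) -> Trajectory:
    frame = pd.read_csv(path)
    observed = ~frame.isna().any(axis=1).to_numpy()
    states = frame.fillna(0).to_numpy().astype(np.int8)
    return Trajectory(states, observed)
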