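"""HDF5 / JSON serialization of fitted artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .distributions import ReturnTable, SupportGrid
from .simulator import EmpiricalMDP
from .state_repr import Representation, StandardizationParams

__all__ = [
    "save_return_table",
    "load_return_table",
    "save_empirical_mdp",
    "load_empirical_mdp",
    "save_representation",
    "load_representation",
]


def save_return_table(table: ReturnTable, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("atoms", data=table.grid.atoms)
        fh.create_dataset("keys", data=np.array(table.keys, dtype=np.int64))
        fh.create_dataset("weights", data=table.weights)
        fh.attrs["signed"] = table.signed


def load_return_table(path) -> ReturnTable:
    with h5py.File(path, "r") as fh:
        grid = SupportGrid(fh["atoms"][:])
        keys = [tuple(k) for k in fh["keys"][:]]
        return ReturnTable(grid, keys, fh["weights"][:], signed=bool(fh.attrs["signed"]))


def save_empirical_mdp(mdp: EmpiricalMDP, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("counts", data=mdp.counts)
        fh.create_dataset("initial_counts", data=mdp.initial_counts)


def load_empirical_mdp(path) -> EmpiricalMDP:
    with h5py.File(path, "r") as fh:
        return EmpiricalMDP(fh["counts"][:], fh["initial_counts"][:])


def save_representation(rep: Representation, path) -> None:
    """Representation as plain JSON (centers as nested lists)."""
    payload = {
        "centers": rep.centers.tolist(),
        "seed": rep.seed,
    }
    if rep.standardization is not None:
        payload["standardization"] = {
            "mean": rep.standardization.mean.tolist(),
            "sd": rep.standardization.sd.tolist(),
        }
    Path(path).write_text(json.dumps(payload))


def load_representation(path) -> Representation:
    payload = json.loads(Path(path).read_text())
    std = None
    if "standardization" in payload:
        std = StandardizationParams(
            mean=np.asarray(payload["standardization"]["mean"]),
            sd=np.asarray(payload["standardization"]["sd"]),
        )
    return Representation(
        centers=np.asarray(payload["centers"]),
        seed=int(payload["seed"]),
        standardization=std,
    )
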