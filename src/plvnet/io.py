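"""Readers and writers for intermediate pipeline artifacts.

Epoch arrays go to HDF5 with a JSON sidecar carrying sampling metadata;
connectivity matrices to tab-delimited text with a label header (plus an
HDF5 batch container for whole runs); metric tables to CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .simulate import EpochArray

__all__ = [
    "save_epochs",
    "load_epochs",
    "save_matrix_tsv",
    "load_matrix_tsv",
    "save_matrices_h5",
    "load_matrices_h5",
    "save_metric_table",
    "load_metric_table",
]


def save_epochs(epochs: EpochArray, path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
    sidecar = {
        "fs_hz": epochs.fs_hz,
        "t0_s": epochs.t0_s,
        "node_labels": epochs.node_labels,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_epochs(path) -> EpochArray:
    path = Path(path)
    with h5py.File(path, "r") as f:
        data = f["data"][()]
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return EpochArray(
        data=data,
        fs_hz=meta["fs_hz"],
        t0_s=meta["t0_s"],
        node_labels=meta["node_labels"],
    )


def save_matrix_tsv(mat: ConnectivityMatrix, path) -> None:
    """Plain n x n tab-delimited matrix with a label header row."""
    with open(path, "w") as fh:
        fh.write("\t".join(mat.node_labels) + "\n")
        np.savetxt(fh, mat.plv, delimiter="\t", fmt="%.10g")


def load_matrix_tsv(path) -> ConnectivityMatrix:
    with open(path) as fh:
        labels = fh.readline().rstrip("\n").split("\t")
        data = np.loadtxt(fh, delimiter="\t")
    return ConnectivityMatrix(plv=data, node_labels=labels)


def _cell_key(cell: tuple[str, str, str]) -> str:
    return "/".join(cell)


def save_matrices_h5(matrices: dict, path) -> None:
    """Batch container: one dataset per (subject, condition, emotion)."""
    with h5py.File(path, "w") as f:
        for cell, mat in matrices.items():
            d = f.create_dataset(_cell_key(cell), data=mat.plv)
            d.attrs["node_labels"] = [s.encode() for s in mat.node_labels]


def load_matrices_h5(path) -> dict:
    out = {}
    with h5py.File(path, "r") as f:

        def visit(name, obj):
            if isinstance(obj, h5py.Dataset):
                labels = [b.decode() for b in obj.attrs["node_labels"]]
                cell = tuple(name.split("/"))
                out[cell] = ConnectivityMatrix(
                    plv=obj[()], node_labels=labels, cell=cell
                )

        f.visititems(visit)
    return out


def save_metric_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def load_metric_table(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"subject": str})
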