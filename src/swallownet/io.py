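"""Plain-text serialization: TSV matrices, edge lists, series and motion files.

Everything the pipeline writes is a flat text table or JSON so any stage can
be inspected or re-entered independently.  Matrices round-trip losslessly at
15 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .construction import Network
from .preprocess import DEFAULT_TR_SECONDS, RegionalTimeSeriesSet
from .synthetic import MotionTrace

__all__ = [
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_edge_list_tsv",
    "read_edge_list_tsv",
    "read_series_tsv",
    "read_motion_tsv",
    "write_json",
]

_FLOAT_FMT = "%.15g"


def write_matrix_tsv(path: str | Path, matrix: np.ndarray, labels=None) -> Path:
    """Write a square matrix as TSV with an optional label header/index column."""
    path = Path(path)
    matrix = np.asarray(matrix, dtype=float)
    if labels is None:
        labels = [f"N{i:03d}" for i in range(matrix.shape[0])]
    df = pd.DataFrame(matrix, index=list(labels), columns=list(labels))
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    return path


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_edge_list_tsv(path: str | Path, net: Network) -> Path:
    """Write ``node_i<TAB>node_j<TAB>weight`` rows (upper triangle only)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# n_nodes={net.n_nodes}\tmode={net.mode}\n")
        fh.write("node_i\tnode_j\tweight\n")
        for i, j, w in net.edge_list():
            fh.write(f"{i}\t{j}\t{_FLOAT_FMT % w}\n")
    return path


def read_edge_list_tsv(path: str | Path) -> Network:
    path = Path(path)
    with path.open() as fh:
        meta = fh.readline().strip().lstrip("# ").split("\t")
        kv = dict(part.split("=", 1) for part in meta)
        n = int(kv["n_nodes"])
        mode = kv["mode"]
        fh.readline()  # column header
        adj = np.zeros((n, n))
        for line in fh:
            i_s, j_s, w_s = line.split("\t")
            i, j, w = int(i_s), int(j_s), float(w_s)
            adj[i, j] = adj[j, i] = w
    return Network(adj, mode)


def read_series_tsv(
    path: str | Path,
    subject_id: str | None = None,
    tr_seconds: float = DEFAULT_TR_SECONDS,
) -> RegionalTimeSeriesSet:
    """Read a volumes x regions TSV (as written by the cohort generator)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    return RegionalTimeSeriesSet(
        subject_id=subject_id or path.stem.replace("_series", ""),
        series=df.to_numpy(dtype=float).T,
        tr_seconds=tr_seconds,
    )


def read_motion_tsv(path: str | Path) -> MotionTrace:
    """Read a six-column motion TSV (tx, ty, tz in mm; rx, ry, rz in degrees)."""
    arr = pd.read_csv(path, sep="\t").to_numpy(dtype=float)
    if arr.shape[1] != 6:
        raise ValueError(f"motion file must have 6 columns, found {arr.shape[1]}")
    return MotionTrace(translations=arr[:, :3], rotations=arr[:, 3:])


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_json(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")
    return path
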