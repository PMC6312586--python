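"""Readers and writers for all pipeline artifacts.

Everything is delimited text or JSON: recordings as one TSV matrix per
subject (rows = regions, columns = samples) with a JSON sidecar (fs, labels,
epoch boundaries); connectivity matrices as square TSVs with a label header;
trees as edge lists; metric and comparison tables as tidy TSVs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .errors import InvalidInputError
from .mst import TreeGraph
from .recording import Recording


def write_recording(rec: Recording, path: str | Path, epoch_seconds: float | None = None) -> None:
    """Write data to ``path`` (TSV) and metadata to ``path + '.json'``."""
    path = Path(path)
    np.savetxt(path, rec.data, delimiter="\t", fmt="%.10g")
    meta = {"fs": rec.fs, "labels": list(rec.labels)}
    if epoch_seconds is not None:
        win = int(round(epoch_seconds * rec.fs))
        meta["epoch_boundaries"] = list(range(0, rec.n_samples - win + 1, win))
        meta["epoch_seconds"] = epoch_seconds
    Path(str(path) + ".json").write_text(json.dumps(meta) + "\n")


def read_recording(path: str | Path) -> Recording:
    path = Path(path)
    sidecar = Path(str(path) + ".json")
    if not sidecar.exists():
        raise InvalidInputError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    return Recording(data=data, fs=float(meta["fs"]), labels=tuple(meta["labels"]))


def write_matrix(mat: ConnectivityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(mat.values, columns=list(mat.labels))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_matrix(path: str | Path) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t")
    return ConnectivityMatrix(values=df.values, labels=tuple(df.columns))


def write_tree(tree: TreeGraph, path: str | Path) -> None:
    rows = [
        {"node_i": tree.labels[i], "node_j": tree.labels[j], "weight": w}
        for i, j, w in tree.edges
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_tree(path: str | Path, labels: tuple[str, ...]) -> TreeGraph:
    df = pd.read_csv(path, sep="\t")
    index = {lab: i for i, lab in enumerate(labels)}
    edges = [
        (index[r.node_i], index[r.node_j], float(r.weight))
        for r in df.itertuples(index=False)
    ]
    return TreeGraph(n_nodes=len(labels), edges=edges, labels=labels)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
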