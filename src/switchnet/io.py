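"""Delimited-text readers and writers for pipeline artifacts.

All on-disk formats are plain TSV so runs are diffable and portable:

* node x time series — first column ``node_id``, then one column per
  frame index;
* label matrices (latent memberships, multilayer partitions) — same
  layout with integer entries; partitions carry a ``#`` header line
  recording gamma, omega, seed and the achieved Q;
* cohort covariate / metric tables — pandas TSV round-trips.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import NodeTimeSeries

__all__ = [
    "write_timeseries", "read_timeseries",
    "write_label_matrix", "read_label_matrix",
    "write_table", "read_table",
    "write_manifest", "read_manifest",
]


def write_timeseries(path: str | Path, ts: NodeTimeSeries) -> Path:
    path = Path(path)
    frame = pd.DataFrame(ts.values, index=list(ts.node_ids),
                         columns=[str(t) for t in range(ts.n_frames)])
    frame.index.name = "node_id"
    frame.to_csv(path, sep="\t", float_format="%.10g")
    return path


def read_timeseries(path: str | Path, tr_seconds: float = 2.0) -> NodeTimeSeries:
    frame = pd.read_csv(path, sep="\t", index_col="node_id")
    return NodeTimeSeries(values=frame.to_numpy(dtype=float),
                          tr_seconds=tr_seconds,
                          node_ids=tuple(str(i) for i in frame.index))


def write_label_matrix(path: str | Path, labels: np.ndarray,
                       node_ids: tuple[str, ...] | None = None,
                       header: dict | None = None) -> Path:
    """Write an integer node x column label matrix, optionally with a
    ``# key=value ...`` provenance line (used for partitions)."""
    path = Path(path)
    labels = np.asarray(labels)
    n_nodes, n_cols = labels.shape
    if node_ids is None:
        width = len(str(n_nodes - 1))
        node_ids = tuple(f"node_{i:0{width}d}" for i in range(n_nodes))
    with open(path, "w") as fh:
        if header:
            fh.write("# " + " ".join(f"{k}={v}" for k, v in header.items()) + "\n")
        fh.write("node_id\t" + "\t".join(str(t) for t in range(n_cols)) + "\n")
        for nid, row in zip(node_ids, labels):
            fh.write(str(nid) + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
    return path


def read_label_matrix(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    meta: dict = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for item in first[1:].split():
                if "=" in item:
                    key, val = item.split("=", 1)
                    meta[key] = val
            skip = 1
        else:
            skip = 0
    frame = pd.read_csv(path, sep="\t", index_col="node_id", skiprows=skip)
    return frame.to_numpy(dtype=int), meta


def write_table(path: str | Path, table: pd.DataFrame) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_manifest(path: str | Path, manifest: dict) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
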