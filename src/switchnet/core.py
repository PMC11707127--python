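"""Shared containers for node-level brain activity data.

The pipeline's entry point is a node-by-time real matrix: one row per
network node (e.g. an independent-component time course), one column per
acquired frame, with a fixed sampling interval (the repetition time, TR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NodeTimeSeries"]


@dataclass
class NodeTimeSeries:
    """A node x frame activity matrix with its sampling interval.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_nodes, n_frames)``; no missing values.
    tr_seconds
        Sampling interval between frames, in seconds.
    node_ids
        Unique node identifiers; their order defines the row order of
        every matrix downstream (connectivity layers, partitions, rates).
    """

    values: np.ndarray
    tr_seconds: float = 2.0
    node_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D node x frame matrix")
        n_nodes, n_frames = self.values.shape
        if n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if n_frames < 3:
            raise ValueError("need at least 3 frames")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not self.node_ids:
            width = len(str(n_nodes - 1))
            self.node_ids = tuple(f"node_{i:0{width}d}" for i in range(n_nodes))
        else:
            self.node_ids = tuple(str(n) for n in self.node_ids)
        if len(self.node_ids) != n_nodes:
            raise ValueError("node_ids length must equal the number of rows")
        if len(set(self.node_ids)) != n_nodes:
            raise ValueError("node_ids must be unique")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def copy_with(self, values: np.ndarray) -> "NodeTimeSeries":
        """Return a new series with the same metadata and new values."""
        return NodeTimeSeries(values=np.asarray(values, dtype=float),
                              tr_seconds=self.tr_seconds,
                              node_ids=self.node_ids)
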