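"""Sliding-window connectivity stacks and the coupled multilayer form.

A node x time series is segmented into overlapping windows (default
width 20 frames, step 1); within each window the Pearson correlation of
every node pair is computed, negatives are truncated to zero and the
diagonal zeroed, giving one nonnegative symmetric layer per window.  A
229-frame series with the default window therefore yields 210 layers.

The layers are coupled into a single super-adjacency matrix of order
``n_nodes * n_layers``: intra-layer weights on the block diagonal, and
uniform ordinal couplings (weight omega) linking each node to itself in
adjacent layers.  The flattening convention is layer-major: node ``i``
in layer ``t`` maps to row ``t * n_nodes + i``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .core import NodeTimeSeries

__all__ = [
    "WindowSpec", "LayerStack", "SuperAdjacency",
    "make_windows", "window_connectivity", "build_layer_stack",
    "build_super_adjacency", "n_windows",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in frames."""

    width_frames: int = 20
    step_frames: int = 1

    def __post_init__(self) -> None:
        if self.width_frames < 3:
            raise ValueError("width_frames must be >= 3 (correlation needs >= 3 samples)")
        if self.step_frames < 1:
            raise ValueError("step_frames must be >= 1")


def n_windows(n_frames: int, spec: WindowSpec) -> int:
    """Window count: ``floor((n_frames - width) / step) + 1``."""
    if n_frames < spec.width_frames:
        raise ValueError(
            f"series of {n_frames} frames is shorter than one "
            f"{spec.width_frames}-frame window")
    return (n_frames - spec.width_frames) // spec.step_frames + 1


def make_windows(ts_or_frames: NodeTimeSeries | int,
                 spec: WindowSpec) -> list[tuple[int, int]]:
    """Half-open frame ranges ``[k*step, k*step + width)``."""
    n_frames = (ts_or_frames.n_frames if isinstance(ts_or_frames, NodeTimeSeries)
                else int(ts_or_frames))
    count = n_windows(n_frames, spec)
    return [(k * spec.step_frames, k * spec.step_frames + spec.width_frames)
            for k in range(count)]


def window_connectivity(ts: NodeTimeSeries,
                        window: tuple[int, int],
                        window_index: int | None = None) -> np.ndarray:
    """Pearson correlation of every node pair within one window, with
    negatives truncated to zero and a zero diagonal.

    A node with zero variance inside the window gets zero correlations
    (with a warning naming the window) rather than aborting the run.
    """
    start, stop = window
    if start < 0 or stop > ts.n_frames or stop - start < 3:
        raise ValueError(f"window {window} invalid for {ts.n_frames} frames")
    seg = ts.values[:, start:stop]
    sd = seg.std(axis=1)
    flat = sd == 0
    if flat.any():
        logger.warning(
            "window %s: %d zero-variance node(s); correlations set to 0",
            window_index if window_index is not None else window, int(flat.sum()))
        seg = seg.copy()
        # give flat rows unit variance noise-free placeholders; zero later
        seg[flat] += np.arange(seg.shape[1])
    corr = np.corrcoef(seg)
    if flat.any():
        corr[flat, :] = 0.0
        corr[:, flat] = 0.0
    np.fill_diagonal(corr, 0.0)
    np.clip(corr, 0.0, 1.0, out=corr)
    return corr


@dataclass
class LayerStack:
    """Ordered per-window connectivity matrices, shape ``(L, n, n)``."""

    layers: np.ndarray
    window_spec: WindowSpec | None = None
    node_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.layers = np.asarray(self.layers, dtype=float)
        if self.layers.ndim != 3 or self.layers.shape[1] != self.layers.shape[2]:
            raise ValueError("layers must have shape (n_layers, n_nodes, n_nodes)")
        if (self.layers < 0).any():
            raise ValueError("layer entries must be nonnegative")
        if not np.allclose(self.layers, self.layers.transpose(0, 2, 1)):
            raise ValueError("layers must be symmetric")
        if not self.node_ids:
            width = len(str(self.n_nodes - 1))
            self.node_ids = tuple(f"node_{i:0{width}d}" for i in range(self.n_nodes))

    @property
    def n_layers(self) -> int:
        return self.layers.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.layers.shape[1]


def build_layer_stack(ts: NodeTimeSeries,
                      spec: WindowSpec | None = None) -> LayerStack:
    """One truncated-correlation layer per sliding window, in order."""
    spec = spec or WindowSpec()
    windows = make_windows(ts, spec)
    layers = np.stack([window_connectivity(ts, win, window_index=k)
                       for k, win in enumerate(windows)])
    return LayerStack(layers=layers, window_spec=spec, node_ids=ts.node_ids)


@dataclass
class SuperAdjacency:
    """Coupled multilayer matrix of order ``n_nodes * n_layers``.

    Layer-major layout: slot ``t * n_nodes + i`` is node ``i`` in layer
    ``t``.  Off-diagonal blocks hold only the ordinal self-couplings
    ``(i, t) <-> (i, t+1)`` with weight ``omega``.
    """

    matrix: sparse.csr_matrix
    omega: float
    n_nodes: int
    n_layers: int

    def slot(self, node: int, layer: int) -> int:
        return layer * self.n_nodes + node

    def layer_block(self, t: int) -> np.ndarray:
        a = t * self.n_nodes
        return self.matrix[a:a + self.n_nodes, a:a + self.n_nodes].toarray()

    def to_layer_stack(self) -> LayerStack:
        """Round-trip: extract the block diagonal back into a stack."""
        layers = np.stack([self.layer_block(t) for t in range(self.n_layers)])
        return LayerStack(layers=layers)


def build_super_adjacency(stack: LayerStack, omega: float = 0.75) -> SuperAdjacency:
    """Assemble intra-layer blocks plus ordinal interlayer couplings."""
    if omega < 0:
        raise ValueError("omega must be >= 0")
    L, n = stack.n_layers, stack.n_nodes
    blocks = sparse.block_diag([sparse.csr_matrix(stack.layers[t])
                                for t in range(L)], format="lil")
    if L > 1 and omega > 0:
        idx = np.arange((L - 1) * n)
        blocks[idx, idx + n] = omega
        blocks[idx + n, idx] = omega
    return SuperAdjacency(matrix=blocks.tocsr(), omega=float(omega),
                          n_nodes=n, n_layers=L)
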