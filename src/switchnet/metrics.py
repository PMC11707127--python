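"""Node, subnetwork, and global switching rates from multilayer partitions.

A node's switching rate is the fraction of layer-to-layer transitions
at which its module assignment changes:

    rate_i = #{ t : g[i, t] != g[i, t+1] } / (L - 1)

The transitions denominator (L - 1, not L) makes the rate a proper
proportion with range exactly [0, 1]; a frames denominator is available
for sensitivity analyses.  Because the interlayer coupling carries
module labels through time, raw label changes are meaningful without
any relabel matching across layers.

Rates are first averaged per node over repeated optimizations, then
over a subnetwork's member nodes (subnetwork rate) or all nodes
(global rate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .community import MultilayerPartition

__all__ = [
    "SubnetworkMap", "SwitchingProfile",
    "node_switching_rate", "aggregate_rates", "switching_profile",
]

logger = logging.getLogger(__name__)


@dataclass
class SubnetworkMap:
    """Node id -> subnetwork label; every node has exactly one label."""

    assignment: dict[str, str]

    @classmethod
    def from_labels(cls, node_ids: Sequence[str],
                    labels: Sequence[str]) -> "SubnetworkMap":
        if len(node_ids) != len(labels):
            raise ValueError("node_ids and labels must align")
        return cls(assignment=dict(zip(map(str, node_ids), map(str, labels))))

    def labels_for(self, node_ids: Sequence[str]) -> list[str]:
        missing = [n for n in node_ids if n not in self.assignment]
        if missing:
            raise KeyError(f"nodes without a subnetwork label: {missing[:5]}")
        return [self.assignment[n] for n in node_ids]

    @property
    def subnetworks(self) -> list[str]:
        """Subnetwork names in first-appearance order."""
        seen: dict[str, None] = {}
        for label in self.assignment.values():
            seen.setdefault(label, None)
        return list(seen)


@dataclass
class SwitchingProfile:
    """Per-node / per-subnetwork / global switching rates for one
    subject, averaged over repetitions, plus the mean modularity."""

    node_rates: np.ndarray                 # (n_nodes,)
    subnetwork_rates: dict[str, float]
    global_rate: float
    q_mean: float
    n_repetitions_used: int
    node_ids: tuple[str, ...] = field(default=())


def node_switching_rate(partition: MultilayerPartition | np.ndarray,
                        denominator: str = "transitions") -> np.ndarray:
    """Per-node fraction of transitions with a module change.

    ``denominator='frames'`` divides by L instead of L - 1 (sensitivity
    option; the resulting rates cannot reach 1).
    """
    labels = (partition.labels if isinstance(partition, MultilayerPartition)
              else np.asarray(partition))
    if labels.ndim != 2 or labels.shape[1] < 2:
        raise ValueError("partition needs at least 2 layers")
    changes = (labels[:, 1:] != labels[:, :-1]).sum(axis=1)
    if denominator == "transitions":
        denom = labels.shape[1] - 1
    elif denominator == "frames":
        denom = labels.shape[1]
    else:
        raise ValueError("denominator must be 'transitions' or 'frames'")
    return changes / denom


def aggregate_rates(node_rates_per_rep: Iterable[np.ndarray],
                    subnet_map: SubnetworkMap | Mapping[str, str],
                    node_ids: Sequence[str],
                    q_values: Sequence[float] | None = None) -> SwitchingProfile:
    """Average per-node rates over repetitions, then form subnetwork and
    global means.  Subnetworks with no member nodes are omitted with a
    warning."""
    if isinstance(subnet_map, Mapping) and not isinstance(subnet_map, SubnetworkMap):
        subnet_map = SubnetworkMap(assignment=dict(subnet_map))
    rates = np.stack([np.asarray(r, dtype=float) for r in node_rates_per_rep])
    if rates.ndim != 2 or rates.shape[1] != len(node_ids):
        raise ValueError("all repetitions must share the node set")
    node_mean = rates.mean(axis=0)
    labels = subnet_map.labels_for(list(node_ids))
    subnet_rates: dict[str, float] = {}
    for name in subnet_map.subnetworks:
        mask = np.array([lab == name for lab in labels])
        if not mask.any():
            logger.warning("subnetwork %s has no member nodes; omitted", name)
            continue
        subnet_rates[name] = float(node_mean[mask].mean())
    q_values = list(q_values) if q_values is not None else []
    return SwitchingProfile(
        node_rates=node_mean,
        subnetwork_rates=subnet_rates,
        global_rate=float(node_mean.mean()),
        q_mean=float(np.mean(q_values)) if q_values else float("nan"),
        n_repetitions_used=rates.shape[0],
        node_ids=tuple(map(str, node_ids)),
    )


def switching_profile(partitions: Sequence[MultilayerPartition],
                      subnet_map: SubnetworkMap | Mapping[str, str],
                      node_ids: Sequence[str],
                      denominator: str = "transitions") -> SwitchingProfile:
    """Full per-subject profile from repeated optimization runs."""
    rates = [node_switching_rate(p, denominator=denominator) for p in partitions]
    qs = [p.q_value for p in partitions]
    return aggregate_rates(rates, subnet_map, node_ids, q_values=qs)
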