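"""Multilayer modularity: quality function, generalized Louvain, and the
exact enumeration oracle."""

import numpy as np
import pytest

from switchnet.community import (MultilayerParams, enumerate_oracle,
                                 louvain_optimize, multilayer_quality,
                                 run_repetitions, canonical_relabel,
                                 ModularityOperator)
from switchnet.network import LayerStack
from conftest import random_stack


def two_clique_stack(weight=1.0):
    """Single layer: two disconnected 3-cliques of equal weight."""
    A = np.zeros((6, 6))
    A[:3, :3] = weight
    A[3:, 3:] = weight
    np.fill_diagonal(A, 0.0)
    return LayerStack(layers=A[None])


class TestQuality:
    def test_all_in_one_partition_zero(self):
        stack = two_clique_stack()
        labels = np.ones((6, 1), dtype=int)
        assert multilayer_quality(stack, labels, gamma=1.0) == pytest.approx(
            0.0, abs=1e-12)

    def test_two_clique_partition_half(self):
        # Newman-Girvan value for two equal disconnected communities
        stack = two_clique_stack()
        labels = np.array([[1], [1], [1], [2], [2], [2]])
        assert multilayer_quality(stack, labels, gamma=1.0) == pytest.approx(
            0.5, abs=1e-12)

    def test_coupling_contribution_hand_computed(self, rng):
        # 2 nodes, 2 identical layers: constant labels gain the coupling
        # reward 2*omega relative to layer-split labels
        layers = random_stack(rng, 2, 1).layers
        stack = LayerStack(layers=np.repeat(layers, 2, axis=0))
        omega = 0.75
        op = ModularityOperator(stack, gamma=1.0, omega=omega)
        constant = np.array([[1, 1], [2, 2]])
        split = np.array([[1, 3], [2, 4]])
        gap = op.quality(constant) - op.quality(split)
        assert gap == pytest.approx(2 * 2 * omega / op.two_mu, abs=1e-12)

    def test_relabeling_invariance(self, rng):
        stack = random_stack(rng, 5, 3)
        labels = rng.integers(1, 4, size=(5, 3))
        q0 = multilayer_quality(stack, labels)
        for _ in range(10):
            perm = rng.permutation(3) + 1
            q1 = multilayer_quality(stack, perm[labels - 1])
            assert abs(q1 - q0) < 1e-12

    def test_zero_weight_layer_defined(self, rng):
        layers = np.zeros((2, 3, 3))
        layers[1] = random_stack(rng, 3, 1).layers[0]
        stack = LayerStack(layers=layers)
        labels = np.ones((3, 2), dtype=int)
        q = multilayer_quality(stack, labels, gamma=1.0, omega=0.5)
        assert np.isfinite(q)


class TestLouvain:
    def test_planted_blocks_recovered(self, planted_stack):
        params = MultilayerParams(gamma=1.0, omega=0.75, seed=4)
        part = louvain_optimize(planted_stack, params)
        labels = part.labels
        # constant across layers
        assert (labels == labels[:, [0]]).all()
        # exactly the two planted blocks (up to relabeling)
        assert (labels[:6] == labels[0, 0]).all()
        assert (labels[6:] == labels[6, 0]).all()
        assert labels[0, 0] != labels[6, 0]

    def test_q_self_consistent_and_beats_baselines(self, rng):
        stack = random_stack(rng, 6, 4)
        params = MultilayerParams(seed=0)
        part = louvain_optimize(stack, params)
        recomputed = multilayer_quality(stack, part.labels,
                                        params.gamma, params.omega)
        assert part.q_value == pytest.approx(recomputed, abs=1e-12)
        n, L = 6, 4
        singles = np.arange(1, n * L + 1).reshape(L, n).T
        allone = np.ones((n, L), dtype=int)
        for baseline in (singles, allone):
            assert part.q_value >= multilayer_quality(
                stack, baseline, params.gamma, params.omega) - 1e-12

    def test_labels_canonical(self, rng):
        stack = random_stack(rng, 5, 3)
        part = louvain_optimize(stack, MultilayerParams(seed=1))
        flat = part.labels.T.ravel()
        seen = []
        for lab in flat:
            if lab not in seen:
                seen.append(lab)
        assert seen == list(range(1, len(set(flat)) + 1))

    def test_strong_coupling_freezes_labels_in_time(self, rng):
        stack = random_stack(rng, 6, 5)
        part = louvain_optimize(stack,
                                MultilayerParams(omega=100.0, seed=2))
        assert (part.labels == part.labels[:, [0]]).all()

    def test_zero_coupling_decomposes_over_layers(self, planted_stack):
        # with omega=0 the optimum is layerwise; Q should equal the
        # strength-weighted combination of single-layer optima
        params = MultilayerParams(gamma=1.0, omega=0.0, seed=0)
        part = louvain_optimize(planted_stack, params)
        per_layer = []
        weights = []
        for t in range(planted_stack.n_layers):
            sub = LayerStack(layers=planted_stack.layers[[t]])
            p = louvain_optimize(sub, MultilayerParams(gamma=1.0, omega=0.0,
                                                       seed=t))
            per_layer.append(p.q_value)
            weights.append(sub.layers.sum())
        expected = np.average(per_layer, weights=weights)
        assert part.q_value == pytest.approx(expected, abs=1e-9)

    def test_repetitions_deterministic_and_consistent(self, planted_stack):
        params = MultilayerParams(n_repetitions=3, seed=11)
        first = run_repetitions(planted_stack, params)
        second = run_repetitions(planted_stack, params)
        assert len(first) == 3
        for a, b in zip(first, second):
            np.testing.assert_array_equal(a.labels, b.labels)
            assert a.q_value == b.q_value
        # planted instance: between-repetition label agreement is perfect
        for p in first[1:]:
            agreement = (p.labels == first[0].labels).mean()
            assert agreement > 0.95

    def test_single_repetition(self, rng):
        stack = random_stack(rng, 4, 2)
        parts = run_repetitions(stack, MultilayerParams(n_repetitions=1, seed=0))
        assert len(parts) == 1


class TestOracle:
    def test_single_node_stays_in_one_module(self):
        # 1 real node cannot form a stack (needs >= 2); use 2 nodes with
        # zero intra-layer weight: coupling alone keeps each node's
        # labels constant in time
        stack = LayerStack(layers=np.zeros((3, 2, 2)))
        labels, _ = enumerate_oracle(stack, gamma=1.0, omega=0.5)
        assert (labels == labels[:, [0]]).all()

    def test_two_node_single_layer_merge_decision(self):
        # one edge of weight 1, gamma=1: merged Q = (1/2m)*2*(A - k^2/2m)
        # evaluated by hand over both partitions
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        stack = LayerStack(layers=A[None])
        labels, q = enumerate_oracle(stack, gamma=1.0, omega=0.0)
        # merged: (1/2)[(0-.5)+(1-.5)+(1-.5)+(0-.5)] = 0
        # split: (1/2)[(0-.5)+(0-.5)] = -0.5 -> merged wins
        assert (labels == labels[0, 0]).all()
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_oracle_never_below_louvain(self, rng):
        for i in range(8):
            stack = random_stack(rng, 3, 3)
            _, q_oracle = enumerate_oracle(stack)
            best = max(louvain_optimize(stack, MultilayerParams(seed=s)).q_value
                       for s in range(10))
            assert q_oracle >= best - 1e-9

    def test_large_instance_rejected(self, rng):
        with pytest.raises(ValueError, match="slots"):
            enumerate_oracle(random_stack(rng, 5, 3))


def test_canonical_relabel_first_appearance():
    labels = np.array([[7, 2], [7, 9]])
    out = canonical_relabel(labels)
    # layer-major scan: 7, 7, 2, 9 -> 1, 1, 2, 3
    np.testing.assert_array_equal(out, [[1, 2], [1, 3]])


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        MultilayerParams(gamma=0.0)
    with pytest.raises(ValueError):
        MultilayerParams(omega=-1.0)
    with pytest.raises(ValueError):
        MultilayerParams(n_repetitions=0)
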