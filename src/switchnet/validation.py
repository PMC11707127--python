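"""Self-validation studies: parameter recovery, calibration, and
oracle agreement.

These are the package's own Monte-Carlo checks that the estimator chain
recovers what the synthetic generator plants.  They run at a desk-scale
geometry (see docs/methods.md): a reduced node count, and — for
hazard-recovery studies — a short window with a coarse step whose
temporal resolution covers per-frame switching hazards up to 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community import (MultilayerParams, enumerate_oracle, louvain_optimize,
                        run_repetitions)
from .metrics import node_switching_rate
from .network import LayerStack, WindowSpec, build_layer_stack
from .pipeline import RunConfig, analyze_cohort, compute_cohort_metrics
from .synthetic import SimulationConfig, simulate_cohort, simulate_membership, \
    simulate_timeseries

__all__ = [
    "RecoveryGeometry", "recovered_global_rate", "hazard_rank_order_study",
    "q_range_study", "oracle_agreement_study", "null_cohort_study",
    "planted_effect_study",
]


@dataclass(frozen=True)
class RecoveryGeometry:
    """Desk-scale geometry for hazard-recovery runs.

    The 6-frame window with step 3 resolves module dwell times down to
    ~5 frames (hazard 0.2); omega 0.5 — one of the coupling values in
    the robustness grid — anchors labels weakly enough that recovered
    rates track the planted hazard over the whole band.  Eight
    repetitions damp optimizer stochasticity (the full-scale analysis
    uses 50).
    """

    n_nodes: int = 20
    n_frames: int = 300
    width_frames: int = 6
    step_frames: int = 3
    gamma: float = 0.9
    omega: float = 0.5
    n_repetitions: int = 8
    n_modules: int = 4
    within_module_corr: float = 0.9
    smoothing_kernel: int = 1


def recovered_global_rate(hazard: float, seed: int,
                          geom: RecoveryGeometry = RecoveryGeometry()) -> float:
    """Simulate one subject at a planted hazard and run it through
    windows -> communities -> switching metrics."""
    cfg = SimulationConfig(
        n_nodes=geom.n_nodes, n_frames=geom.n_frames, n_per_group=2,
        n_subnetworks=4, n_modules=geom.n_modules,
        within_module_corr=geom.within_module_corr,
        smoothing_kernel=geom.smoothing_kernel,
        switch_hazard_control=hazard, switch_hazard_patient=hazard,
        seed=seed)
    rng = np.random.default_rng(seed)
    membership = simulate_membership(cfg, "control", rng)
    ts = simulate_timeseries(membership, cfg, rng)
    stack = build_layer_stack(ts, WindowSpec(geom.width_frames,
                                             geom.step_frames))
    parts = run_repetitions(stack, MultilayerParams(
        gamma=geom.gamma, omega=geom.omega,
        n_repetitions=geom.n_repetitions, seed=seed))
    return float(np.mean([node_switching_rate(p).mean() for p in parts]))


def hazard_rank_order_study(n_replicates: int, seed: int,
                            hazards: tuple[float, ...] = (0.05, 0.10, 0.20),
                            geom: RecoveryGeometry = RecoveryGeometry()) -> float:
    """Fraction of replicates whose recovered global rates are strictly
    ordered by the planted hazard.

    Each replicate simulates one subject per hazard from a common
    stream, so the latent chains are coupled (nested switch sets)."""
    ordered = 0
    for r in range(n_replicates):
        rep_seed = seed + r
        rates = [recovered_global_rate(h, rep_seed, geom) for h in hazards]
        ordered += all(a < b for a, b in zip(rates, rates[1:]))
    return ordered / n_replicates


def q_range_study(n_instances: int, seed: int) -> tuple[float, float]:
    """(min, max) of optimizer-returned Q over seeded synthetic stacks
    with nonnegative weights."""
    qs = []
    for i in range(n_instances):
        inst_seed = seed + i
        cfg = SimulationConfig(
            n_nodes=8, n_frames=40, n_per_group=2, n_subnetworks=4,
            n_modules=3, within_module_corr=0.85, smoothing_kernel=1,
            switch_hazard_control=0.02 + 0.15 * (i % 5) / 4,
            switch_hazard_patient=0.2, seed=inst_seed)
        rng = np.random.default_rng(inst_seed)
        membership = simulate_membership(cfg, "control", rng)
        ts = simulate_timeseries(membership, cfg, rng)
        stack = build_layer_stack(ts, WindowSpec(8, 4))
        part = louvain_optimize(stack, MultilayerParams(seed=inst_seed))
        qs.append(part.q_value)
    return float(np.min(qs)), float(np.max(qs))


def _random_small_stack(rng: np.random.Generator) -> LayerStack:
    """Random nonnegative instance with n_nodes * n_layers <= 10."""
    shapes = [(5, 2), (2, 5), (3, 3), (4, 2), (2, 4), (2, 3), (3, 2)]
    n, L = shapes[rng.integers(len(shapes))]
    layers = rng.random((L, n, n))
    layers = (layers + layers.transpose(0, 2, 1)) / 2
    for layer in layers:
        np.fill_diagonal(layer, 0.0)
    return LayerStack(layers=layers)


def oracle_agreement_study(n_instances: int, seed: int,
                           n_restarts: int = 20,
                           gamma: float = 0.9,
                           omega: float = 0.75) -> tuple[float, int]:
    """(fraction of instances where best-of-restarts Louvain attains the
    exact enumeration maximum within 1e-9, count of instances where it
    exceeded it — which must be zero)."""
    rng = np.random.default_rng(seed)
    agree = 0
    exceed = 0
    for _ in range(n_instances):
        stack = _random_small_stack(rng)
        _, q_exact = enumerate_oracle(stack, gamma=gamma, omega=omega)
        best = max(
            louvain_optimize(stack, MultilayerParams(
                gamma=gamma, omega=omega,
                seed=int(rng.integers(2 ** 31 - 1)))).q_value
            for _ in range(n_restarts))
        if best > q_exact + 1e-9:
            exceed += 1
        elif abs(best - q_exact) <= 1e-9:
            agree += 1
    return agree / n_instances, exceed


def _reduced_cohort_config(seed: int, control_hazard: float,
                           patient_hazard: float, n_per_group: int,
                           geom: RecoveryGeometry) -> SimulationConfig:
    return SimulationConfig(
        n_nodes=12, n_frames=183,  # 60 layers at window 6, step 3
        n_per_group=n_per_group, n_subnetworks=9, n_affected=3,
        n_modules=geom.n_modules,
        within_module_corr=geom.within_module_corr,
        smoothing_kernel=geom.smoothing_kernel,
        switch_hazard_control=control_hazard,
        switch_hazard_patient=patient_hazard,
        seed=seed)


def _cohort_tests(cfg: SimulationConfig, geom: RecoveryGeometry,
                  n_repetitions: int, seed: int):
    cohort = simulate_cohort(cfg)
    window = WindowSpec(geom.width_frames, geom.step_frames)
    community = MultilayerParams(gamma=geom.gamma, omega=geom.omega,
                                 n_repetitions=n_repetitions, seed=seed)
    table = compute_cohort_metrics(cohort, window, community,
                                   master_seed=seed)
    return analyze_cohort(table)


def null_cohort_study(n_cohorts: int, seed: int, n_per_group: int = 10,
                      hazard: float = 0.05,
                      geom: RecoveryGeometry = RecoveryGeometry()) -> dict:
    """Type-I calibration on cohorts with equal hazards in both groups.

    Returns the pooled fraction of node-level raw p < 0.05 and the
    fraction of cohorts with any subnetwork-level BH-FDR discovery."""
    node_hits = 0
    node_total = 0
    subnet_cohort_hits = 0
    for c in range(n_cohorts):
        cohort_seed = seed + c
        cfg = _reduced_cohort_config(cohort_seed, hazard, hazard, n_per_group,
                                     geom)
        res = _cohort_tests(cfg, geom, n_repetitions=2, seed=cohort_seed)
        node = res["group_node"]
        node_hits += int((node["p_raw"] < 0.05).sum())
        node_total += len(node)
        subnet = res["group_subnetwork"]
        subnet_cohort_hits += int((subnet["p_fdr"] < 0.05).any())
    return {"node_typeI_rate": node_hits / node_total,
            "subnet_family_fp_rate": subnet_cohort_hits / n_cohorts}


def planted_effect_study(n_cohorts: int, seed: int, n_per_group: int = 20,
                         control_hazard: float = 0.05,
                         hazard_ratio: float = 3.0,
                         geom: RecoveryGeometry = RecoveryGeometry()) -> dict:
    """Power to report the planted pattern: elevated patient switching in
    every affected subnetwork (BH-FDR < 0.05) and globally (p < 0.05)."""
    full_pattern = 0
    global_hits = 0
    for c in range(n_cohorts):
        cohort_seed = seed + c
        cfg = _reduced_cohort_config(cohort_seed, control_hazard,
                                     control_hazard * hazard_ratio,
                                     n_per_group, geom)
        res = _cohort_tests(cfg, geom, n_repetitions=2, seed=cohort_seed)
        affected = {f"subnet_{name}" for name in cfg.affected_subnetworks}
        subnet = res["group_subnetwork"]
        hits = subnet[(subnet["metric"].isin(affected))
                      & (subnet["p_fdr"] < 0.05)
                      & (subnet["direction"] == "patient>control")]
        glob = res["group_global"].iloc[0]
        global_ok = (glob["p_raw"] < 0.05
                     and glob["direction"] == "patient>control")
        global_hits += int(global_ok)
        full_pattern += int(len(hits) == len(affected) and global_ok)
    return {"pattern_power": full_pattern / n_cohorts,
            "global_power": global_hits / n_cohorts}
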