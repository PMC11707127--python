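"""End-to-end orchestration: simulate -> prep -> networks -> communities
-> switching metrics -> group statistics, plus the parameter-robustness
sweep over window width, gamma and omega.

A run is fully determined by its :class:`RunConfig` (which embeds the
simulation, conditioning, window and community-detection parameters and
the master seed): the same config and seed reproduce every output file
byte-identically.  All stage outputs land under one run directory with
a manifest recording the config and the files written.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as snio
from .community import MultilayerParams, run_repetitions
from .core import NodeTimeSeries
from .metrics import SubnetworkMap, switching_profile
from .network import WindowSpec, build_layer_stack
from .prep import PrepConfig, preprocess
from .stats import (demographics_table, fit_prediction_models, group_compare,
                    correlate, regression_table)
from .synthetic import SimulationConfig, simulate_cohort

__all__ = ["RunConfig", "SweepSpec", "run_pipeline", "run_sweep",
           "subject_metrics", "analyze_cohort"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    prep: PrepConfig = field(default_factory=lambda: PrepConfig(enabled=False))
    window: WindowSpec = field(default_factory=WindowSpec)
    community: MultilayerParams = field(default_factory=MultilayerParams)
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        # the master seed drives both simulation and community detection
        if self.simulation.seed != self.seed:
            self.simulation = SimulationConfig(
                **{**self.simulation.to_dict(), "seed": self.seed})

    def to_dict(self) -> dict:
        return {"simulation": self.simulation.to_dict(),
                "prep": asdict(self.prep),
                "window": asdict(self.window),
                "community": asdict(self.community),
                "out_dir": self.out_dir, "seed": self.seed}


@dataclass
class SweepSpec:
    """Grid of analysis settings for the robustness check."""

    window_widths: tuple[int, ...] = (20, 50)
    gammas: tuple[float, ...] = (0.9, 1.0, 1.1)
    omegas: tuple[float, ...] = (0.5, 0.75, 1.0)

    def cells(self) -> list[tuple[int, float, float]]:
        grid = list(product(self.window_widths, self.gammas, self.omegas))
        if not grid:
            raise ValueError("sweep grid is empty")
        return grid


def _community_seed(master_seed: int, subject_index: int) -> int:
    """Per-subject community-detection seed, stable under cohort growth."""
    ss = np.random.SeedSequence(entropy=master_seed,
                                spawn_key=(1000 + subject_index,))
    return int(ss.generate_state(1)[0] % (2 ** 31 - 1))


def subject_metrics(ts: NodeTimeSeries, subnet_map: SubnetworkMap,
                    window: WindowSpec, community: MultilayerParams,
                    prep_cfg: PrepConfig | None = None):
    """Run one subject through prep, networks, communities and metrics."""
    if prep_cfg is not None:
        ts = preprocess(ts, prep_cfg)
    stack = build_layer_stack(ts, window)
    partitions = run_repetitions(stack, community)
    return switching_profile(partitions, subnet_map, ts.node_ids)


def _profile_row(subject_id: str, profile) -> dict:
    row = {"subject_id": subject_id, "global_rate": profile.global_rate,
           "q_mean": profile.q_mean}
    for name, rate in profile.subnetwork_rates.items():
        row[f"subnet_{name}"] = rate
    for nid, rate in zip(profile.node_ids, profile.node_rates):
        row[f"node_{nid}"] = rate
    return row


def compute_cohort_metrics(cohort, window: WindowSpec,
                           community: MultilayerParams,
                           prep_cfg: PrepConfig | None = None,
                           master_seed: int = 0) -> pd.DataFrame:
    """Switching profiles for every subject, joined to the covariates."""
    cfg = cohort.config
    subnet_map = SubnetworkMap.from_labels(cohort.subjects[0].node_ids,
                                           cfg.node_subnetworks)
    rows = []
    for i, ts in enumerate(cohort.subjects):
        params = MultilayerParams(
            gamma=community.gamma, omega=community.omega,
            n_repetitions=community.n_repetitions,
            seed=_community_seed(master_seed, i),
            max_passes=community.max_passes, tolerance=community.tolerance)
        profile = subject_metrics(ts, subnet_map, window, params,
                                  prep_cfg=prep_cfg)
        rows.append(_profile_row(cohort.table.iloc[i]["subject_id"], profile))
    metrics = pd.DataFrame(rows)
    return cohort.table.merge(metrics, on="subject_id", validate="1:1")


def analyze_cohort(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Group tests (node/subnetwork FDR families, global uncorrected),
    behavioral correlations, demographics, and the prediction models."""
    node_cols = [c for c in table.columns if c.startswith("node_")]
    subnet_cols = [c for c in table.columns if c.startswith("subnet_")]
    results = {
        "group_node": group_compare(table, node_cols, family="node"),
        "group_subnetwork": group_compare(table, subnet_cols,
                                          family="subnetwork"),
        "group_global": group_compare(table, ["global_rate"], family="global"),
        "group_q": group_compare(table, ["q_mean"], family="global"),
        "demographics": demographics_table(table),
    }
    corr_rows = []
    for metric in subnet_cols + ["global_rate"]:
        for score in ("baseline_score", "change_score"):
            try:
                r, p, n = correlate(table, metric, score)
            except ValueError:
                continue
            corr_rows.append({"metric": metric, "score": score,
                              "r": r, "p": p, "n": n,
                              "correction": "uncorrected"})
    results["correlations"] = pd.DataFrame(corr_rows)
    try:
        results["regression"] = regression_table(fit_prediction_models(table))
    except ValueError as exc:
        logger.warning("prediction models skipped: %s", exc)
        results["regression"] = pd.DataFrame(
            columns=["model", "variable", "B", "beta", "p", "R2", "RMSE",
                     "AIC", "n"])
    return results


def run_pipeline(config: RunConfig) -> dict:
    """Full run; writes all stage outputs when ``config.out_dir`` is set.

    Returns a bundle with the metrics table, the stats tables, and the
    manifest."""
    t0 = time.time()
    cohort = simulate_cohort(config.simulation)
    logger.info("simulated %d subjects", len(cohort.subjects))
    table = compute_cohort_metrics(
        cohort, config.window, config.community,
        prep_cfg=config.prep if config.prep.enabled else None,
        master_seed=config.seed)
    results = analyze_cohort(table)
    manifest = {"config": config.to_dict(), "seed": config.seed,
                "n_subjects": len(cohort.subjects),
                "elapsed_seconds": round(time.time() - t0, 2),
                "files": []}
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        snio.write_table(out / "cohort_metrics.tsv", table)
        manifest["files"].append("cohort_metrics.tsv")
        for name, frame in results.items():
            path = out / f"{name}.tsv"
            snio.write_table(path, frame)
            manifest["files"].append(path.name)
        manifest["config_hash"] = _config_hash(config)
        snio.write_manifest(out / "manifest.json", manifest)
    return {"metrics": table, "results": results, "manifest": manifest,
            "cohort": cohort}


def _config_hash(config: RunConfig) -> str:
    import hashlib
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_sweep(sweep: SweepSpec, base: RunConfig) -> pd.DataFrame:
    """Re-analyze one simulated cohort under every grid cell.

    The cohort is simulated once from the base config; each cell
    rebuilds networks, communities and group tests with its window
    width, gamma and omega.  The concordance column reports whether the
    cell finds the same significant metrics, in the same direction, as
    the base cell (base = base config's own settings, evaluated first).
    """
    cells = sweep.cells()
    cohort = simulate_cohort(base.simulation)
    max_width = max(w for w, _, _ in cells)
    if cohort.config.n_frames < max_width:
        raise ValueError("cohort shorter than the widest sweep window")

    def cell_result(width: int, gamma: float, omega: float) -> dict:
        window = WindowSpec(width_frames=width,
                            step_frames=base.window.step_frames)
        community = MultilayerParams(
            gamma=gamma, omega=omega,
            n_repetitions=base.community.n_repetitions,
            seed=base.community.seed,
            max_passes=base.community.max_passes,
            tolerance=base.community.tolerance)
        table = compute_cohort_metrics(cohort, window, community,
                                       master_seed=base.seed)
        res = analyze_cohort(table)
        sig_subnets = frozenset(
            res["group_subnetwork"].query("p_fdr < 0.05")
            .apply(lambda r: (r["metric"], r["direction"]), axis=1))
        glob = res["group_global"].iloc[0]
        patients = table[table["group"] == "patient"]["global_rate"]
        controls = table[table["group"] == "control"]["global_rate"]
        return {"width": width, "gamma": gamma, "omega": omega,
                "global_p": float(glob["p_raw"]),
                "global_direction": glob["direction"],
                "global_significant": bool(glob["p_raw"] < 0.05),
                "mean_rate_patient": float(patients.mean()),
                "mean_rate_control": float(controls.mean()),
                "significant_subnetworks": sig_subnets}

    base_cell = cell_result(base.window.width_frames, base.community.gamma,
                            base.community.omega)
    rows = []
    for width, gamma, omega in cells:
        if (width, gamma, omega) == (base.window.width_frames,
                                     base.community.gamma,
                                     base.community.omega):
            cell = base_cell
        else:
            cell = cell_result(width, gamma, omega)
        concordant = (cell["significant_subnetworks"]
                      == base_cell["significant_subnetworks"]
                      and cell["global_direction"] == base_cell["global_direction"])
        row = dict(cell)
        row["significant_subnetworks"] = ";".join(
            sorted(f"{m}:{d}" for m, d in cell["significant_subnetworks"]))
        row["concordant_with_base"] = concordant
        rows.append(row)
    report = pd.DataFrame(rows)
    if base.out_dir is not None:
        out = Path(base.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        snio.write_table(out / "sweep_report.tsv", report)
    return report
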