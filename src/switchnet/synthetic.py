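"""Synthetic two-group cohorts with planted time-varying modular structure.

The generator plants, for every node, an independent Markov chain over
latent module labels: at each frame after the first the node resamples a
uniformly random *different* module with a per-node hazard, otherwise it
keeps its label.  Nodes sharing a module at a frame receive a common
module signal plus idiosyncratic noise, so windowed correlation can see
the planted structure, and a short moving-average kernel gives the
series the temporal smoothness that sliding-window estimators need.

The "patient" group's elevated hazard is restricted to the nodes of a
configurable set of affected subnetworks, so that subnetwork-level group
differences have an unambiguous ground truth.  Behavioral change scores
are an affine function of each subject's realized global switch rate
plus Gaussian noise, which makes the downstream correlation and
regression stages testable by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import NodeTimeSeries
from . import io as snio

__all__ = [
    "SimulationConfig", "LatentMembership", "Cohort",
    "simulate_membership", "simulate_timeseries", "simulate_subject",
    "simulate_cohort", "write_cohort", "default_subnetwork_sizes",
]

# The nine canonical resting-state systems with the node counts of the
# 43-component parcellation this pipeline defaults to.
STUDY_SUBNETWORK_SIZES: dict[str, int] = {
    "VIS": 6, "SMN": 5, "DAN": 7, "VAN": 4, "LIM": 3,
    "FPN": 3, "DMN": 11, "SCN": 2, "CBN": 2,
}
STUDY_AFFECTED: tuple[str, ...] = ("FPN", "DMN", "CBN")

# Cohort demographics the generator emulates (means/SDs in years and FMA
# points; males/females as counts out of 20).
_AGE_CONTROL = (56.10, 8.93)
_AGE_PATIENT = (59.15, 13.46)
_P_MALE = {"control": 0.5, "patient": 0.6}
_BASELINE_FMA = (15.80, 4.91)


@dataclass
class SimulationConfig:
    """Parameters of the planted-membership cohort generator.

    ``switch_hazard_*`` are per-frame probabilities that a node leaves
    its current module; the patient hazard applies only to nodes in
    ``affected_subnetworks`` (patients' other nodes switch at the
    control hazard).  ``within_module_corr`` is the instantaneous
    correlation between two nodes sharing a module (exact at the
    default ``noise_sd`` of 1, which scales the idiosyncratic
    component).  Behavioral change scores follow
    ``behav_intercept + behav_slope * global_switch_rate + N(0, behav_noise_sd)``.
    """

    n_nodes: int = 43
    n_frames: int = 229
    tr_seconds: float = 2.0
    n_modules: int = 4
    switch_hazard_control: float = 0.05
    switch_hazard_patient: float = 0.15
    within_module_corr: float = 0.8
    noise_sd: float = 1.0
    n_per_group: int = 20
    behav_intercept: float = 5.0
    behav_slope: float = 150.0
    behav_noise_sd: float = 8.0
    smoothing_kernel: int = 3
    n_subnetworks: int = 9
    n_affected: int = 3
    subnetwork_sizes: dict[str, int] | None = None
    affected_subnetworks: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("switch_hazard_control", "switch_hazard_patient"):
            hazard = getattr(self, name)
            if not 0.0 <= hazard <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {hazard}")
        if not 0.0 <= self.within_module_corr < 1.0:
            raise ValueError("within_module_corr must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.behav_noise_sd < 0:
            raise ValueError("behav_noise_sd must be >= 0")
        if self.smoothing_kernel < 1:
            raise ValueError("smoothing_kernel must be >= 1")
        if self.subnetwork_sizes is None:
            self.subnetwork_sizes = default_subnetwork_sizes(
                self.n_nodes, self.n_subnetworks)
        if sum(self.subnetwork_sizes.values()) != self.n_nodes:
            raise ValueError("subnetwork sizes must sum to n_nodes")
        if self.affected_subnetworks is None:
            if self.subnetwork_sizes == STUDY_SUBNETWORK_SIZES:
                self.affected_subnetworks = STUDY_AFFECTED
            else:
                names = list(self.subnetwork_sizes)
                self.affected_subnetworks = tuple(names[: self.n_affected])
        unknown = set(self.affected_subnetworks) - set(self.subnetwork_sizes)
        if unknown:
            raise ValueError(f"affected subnetworks not in map: {sorted(unknown)}")

    @property
    def node_subnetworks(self) -> tuple[str, ...]:
        """Subnetwork label of each node, in node order."""
        out: list[str] = []
        for name, size in self.subnetwork_sizes.items():
            out.extend([name] * size)
        return tuple(out)

    def node_hazards(self, group: str) -> np.ndarray:
        """Per-node switching hazard for the given group."""
        _check_group(group)
        hazards = np.full(self.n_nodes, self.switch_hazard_control)
        if group == "patient":
            affected = set(self.affected_subnetworks)
            mask = np.array([s in affected for s in self.node_subnetworks])
            hazards[mask] = self.switch_hazard_patient
        return hazards

    def to_dict(self) -> dict:
        return asdict(self)


def default_subnetwork_sizes(n_nodes: int, n_subnetworks: int = 9) -> dict[str, int]:
    """Node counts per subnetwork: the study's nine-system layout at 43
    nodes, otherwise an even split into generic ``SN*`` labels."""
    if n_nodes == 43 and n_subnetworks == 9:
        return dict(STUDY_SUBNETWORK_SIZES)
    n_subnetworks = min(n_subnetworks, n_nodes)
    sizes = [len(chunk) for chunk in np.array_split(np.arange(n_nodes), n_subnetworks)]
    return {f"SN{k + 1}": s for k, s in enumerate(sizes)}


@dataclass
class LatentMembership:
    """Ground-truth module label of each node at each frame."""

    labels: np.ndarray                 # (n_nodes, n_frames), values 1..n_modules
    realized_switch_rate: np.ndarray   # (n_nodes,) in [0, 1]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.realized_switch_rate = np.asarray(self.realized_switch_rate, dtype=float)
        if self.labels.min() < 1:
            raise ValueError("module labels must be positive")
        if ((self.realized_switch_rate < 0) | (self.realized_switch_rate > 1)).any():
            raise ValueError("realized switch rates must lie in [0, 1]")

    @property
    def global_rate(self) -> float:
        return float(self.realized_switch_rate.mean())


def _check_group(group: str) -> None:
    if group not in ("control", "patient"):
        raise ValueError(f"group must be 'control' or 'patient', got {group!r}")


def simulate_membership(cfg: SimulationConfig, group: str,
                        rng: np.random.Generator,
                        node_hazards: np.ndarray | None = None) -> LatentMembership:
    """Plant independent per-node Markov chains over module labels.

    At each frame after the first, a node resamples a uniformly random
    different module with its hazard, else keeps its label.  The hazard
    vector defaults to ``cfg.node_hazards(group)``.
    """
    _check_group(group)
    if node_hazards is None:
        node_hazards = cfg.node_hazards(group)
    node_hazards = np.asarray(node_hazards, dtype=float)
    if ((node_hazards < 0) | (node_hazards > 1)).any():
        raise ValueError("hazards must lie in [0, 1]")

    n, T, M = cfg.n_nodes, cfg.n_frames, cfg.n_modules
    labels = np.empty((n, T), dtype=int)
    labels[:, 0] = rng.integers(1, M + 1, size=n)
    # all randomness drawn up front: with a shared stream, chains at two
    # hazards are coupled (the lower hazard's switch set is nested in the
    # higher's), which pairs simulations in hazard-recovery studies
    switch = rng.random((n, T - 1)) < node_hazards[:, None]
    draws = rng.integers(1, M, size=(n, T - 1)) if M > 1 else None
    if M == 1:
        switch[:] = False  # nowhere to go
    for t in range(1, T):
        labels[:, t] = labels[:, t - 1]
        movers = np.flatnonzero(switch[:, t - 1])
        if movers.size:
            # uniform over the M-1 other modules
            draw = draws[movers, t - 1]
            cur = labels[movers, t - 1]
            new = np.where(draw >= cur, draw + 1, draw)
            labels[movers, t] = new
    changed = labels[:, 1:] != labels[:, :-1]
    rate = changed.mean(axis=1) if T > 1 else np.zeros(n)
    return LatentMembership(labels=labels, realized_switch_rate=rate)


def _check_block_covariance(rho: float, max_block: int) -> None:
    """Abort unless the equicorrelation block (1-rho)I + rho*J is PD."""
    block = np.full((max_block, max_block), rho)
    np.fill_diagonal(block, 1.0)
    try:
        np.linalg.cholesky(block)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by config
        raise ValueError(
            f"within_module_corr={rho} gives a non-positive-definite "
            f"block covariance at block size {max_block}") from exc


def simulate_timeseries(membership: LatentMembership, cfg: SimulationConfig,
                        rng: np.random.Generator) -> NodeTimeSeries:
    """Emit node signals from the planted memberships.

    ``x_it = sqrt(rho) * z_{m(i,t),t} + sqrt(1-rho) * noise_sd * eps_it``
    with shared per-module signals ``z`` and i.i.d. ``eps``, followed by
    a short moving-average kernel so 20-frame windows see
    quasi-stationary structure.
    """
    if cfg.noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rho = cfg.within_module_corr
    labels = membership.labels
    n, T = labels.shape
    # largest number of nodes sharing a module at any single frame sets
    # the equicorrelation block whose positive-definiteness matters
    occupancy = max(int(np.bincount(labels[:, t]).max()) for t in range(T))
    _check_block_covariance(rho, max(2, occupancy))

    z = rng.standard_normal((cfg.n_modules + 1, T))  # row 0 unused
    eps = rng.standard_normal((n, T))
    frames = np.arange(T)
    values = np.sqrt(rho) * z[labels, frames] + np.sqrt(1.0 - rho) * cfg.noise_sd * eps
    k = cfg.smoothing_kernel
    if k > 1:
        kernel = np.ones(k) / k
        values = np.apply_along_axis(
            lambda row: np.convolve(row, kernel, mode="same"), 1, values)
    return NodeTimeSeries(values=values, tr_seconds=cfg.tr_seconds)


def simulate_subject(cfg: SimulationConfig, group: str,
                     rng: np.random.Generator) -> tuple[NodeTimeSeries, LatentMembership]:
    """One subject: membership chain, then the series conditioned on it."""
    membership = simulate_membership(cfg, group, rng)
    ts = simulate_timeseries(membership, cfg, rng)
    return ts, membership


@dataclass
class Cohort:
    """A simulated two-group cohort bundle."""

    config: SimulationConfig
    subjects: list[NodeTimeSeries] = field(default_factory=list)
    memberships: list[LatentMembership] = field(default_factory=list)
    table: pd.DataFrame = field(default_factory=pd.DataFrame)


def subject_rng(seed: int, index: int) -> np.random.Generator:
    """One named pseudo-random stream per subject, derived from the
    master seed so adding subjects never perturbs existing ones."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(index,)))


def simulate_cohort(cfg: SimulationConfig) -> Cohort:
    """Simulate controls then patients with per-subject streams and a
    covariate table (age, sex, baseline/change scores, ground truth)."""
    cohort = Cohort(config=cfg)
    rows = []
    index = 0
    for group in ("control", "patient"):
        age_mu, age_sd = _AGE_CONTROL if group == "control" else _AGE_PATIENT
        for _ in range(cfg.n_per_group):
            rng = subject_rng(cfg.seed, index)
            ts, membership = simulate_subject(cfg, group, rng)
            age = float(np.clip(rng.normal(age_mu, age_sd), 18, 90))
            sex = "male" if rng.random() < _P_MALE[group] else "female"
            if group == "patient":
                baseline = float(np.clip(rng.normal(*_BASELINE_FMA), 0, 100))
                noise = rng.normal(0.0, cfg.behav_noise_sd) if cfg.behav_noise_sd > 0 else 0.0
                change = float(cfg.behav_intercept
                               + cfg.behav_slope * membership.global_rate
                               + noise)
            else:
                baseline = np.nan
                change = np.nan
            rows.append({
                "subject_id": f"sub-{index:03d}",
                "group": group,
                "age": round(age, 1),
                "sex": sex,
                "baseline_score": baseline,
                "change_score": change,
                "true_global_rate": membership.global_rate,
            })
            cohort.subjects.append(ts)
            cohort.memberships.append(membership)
            index += 1
    cohort.table = pd.DataFrame(rows)
    return cohort


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict:
    """Write per-subject series and labels, the covariate table, and a
    manifest recording every path plus the full config."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = cohort.config
    paths: dict[str, list[str] | str] = {"timeseries": [], "labels": []}
    for i, (ts, mem) in enumerate(zip(cohort.subjects, cohort.memberships)):
        ts_path = out_dir / f"sub-{i:03d}_timeseries.tsv"
        lab_path = out_dir / f"sub-{i:03d}_truth_labels.tsv"
        snio.write_timeseries(ts_path, ts)
        snio.write_label_matrix(lab_path, mem.labels, node_ids=ts.node_ids)
        paths["timeseries"].append(ts_path.name)
        paths["labels"].append(lab_path.name)
    table_path = out_dir / "cohort.tsv"
    snio.write_table(table_path, cohort.table)
    paths["cohort_table"] = table_path.name
    subnet_path = out_dir / "subnetworks.tsv"
    subnet = pd.DataFrame({"node_id": cohort.subjects[0].node_ids,
                           "subnetwork": cfg.node_subnetworks})
    snio.write_table(subnet_path, subnet)
    paths["subnetwork_map"] = subnet_path.name
    manifest = {"config": cfg.to_dict(), "paths": paths,
                "n_subjects": len(cohort.subjects)}
    snio.write_manifest(out_dir / "manifest.json", manifest)
    return manifest
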