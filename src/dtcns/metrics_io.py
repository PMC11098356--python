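"""Summary statistics, distribution comparisons and file I/O.

Per-iteration metrics cover the infection occurrence (fraction of nodes
infected), interaction counts stratified by the endpoints' health, total
and cumulative interaction utility, and mean degree / local clustering /
shortest path length by health stratum.  Whole-network statistics are
summarised as fixed-bin histograms (degree over the integers 0..n-1,
local clustering over ten equal bins on [0, 1], geodesic lengths over the
integers 1..n-1 plus a separate disconnected-pair bin) which are compared
by the Euclidean distance between count vectors.

Shortest-path averages are taken over connected pairs only; the count of
disconnected pairs is reported alongside rather than folded into the
mean.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field, fields
from statistics import pstdev

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .model_core import (
    BackboneSpec,
    ConfigurationError,
    EpidemicParams,
    Health,
    InteractionGraph,
    SimulationConfig,
    Trajectory,
    UtilityParams,
)

__all__ = [
    "MetricRecord",
    "DistributionHistogram",
    "infection_occurrence",
    "interactions_by_status",
    "statistic_distribution",
    "distribution_distance",
    "compute_metrics",
    "summarise_replicates",
    "trajectory_frame",
    "write_timeseries",
    "write_snapshots",
    "read_config",
    "write_config",
]

CLUSTERING_BINS = 10


@dataclass
class MetricRecord:
    """Scalar metrics for one iteration snapshot."""

    iteration: int
    infection_occurrence: float
    n_interactions: int
    interactions_hh: int
    interactions_hi: int
    interactions_ii: int
    total_utility: float
    cumulative_total_utility: float
    mean_degree_healthy: float
    mean_degree_infected: float
    mean_clustering_healthy: float
    mean_clustering_infected: float
    mean_shortest_path_healthy: float
    mean_shortest_path_infected: float
    disconnected_pairs: int


@dataclass
class DistributionHistogram:
    """Fixed-bin histogram of one network statistic."""

    kind: str
    bin_edges: np.ndarray
    counts: np.ndarray
    disconnected: int = 0

    def total(self) -> int:
        return int(self.counts.sum()) + self.disconnected


def infection_occurrence(health: np.ndarray) -> float:
    """Fraction of nodes currently infected."""
    health = np.asarray(health)
    if health.size == 0:
        raise ValueError("health vector is empty")
    return float((health == Health.INFECTED).mean())


def interactions_by_status(
    graph: InteractionGraph, health: np.ndarray
) -> tuple[int, int, int]:
    """Edge counts partitioned by endpoint health: (HH, HI, II)."""
    hh = hi = ii = 0
    for i, j in graph.intensity:
        k = int(health[i] == Health.INFECTED) + int(health[j] == Health.INFECTED)
        if k == 0:
            hh += 1
        elif k == 1:
            hi += 1
        else:
            ii += 1
    return hh, hi, ii


def statistic_distribution(graph: InteractionGraph, kind: str) -> DistributionHistogram:
    """Histogram of per-node degree or clustering, or per-pair geodesics."""
    n = graph.n
    g = graph.to_networkx()
    if kind == "degree":
        deg = graph.degrees()
        counts = np.bincount(deg, minlength=n)[:n]
        return DistributionHistogram(kind, np.arange(n + 1) - 0.5, counts)
    if kind == "clustering":
        cc = np.array(list(nx.clustering(g).values()))
        edges = np.linspace(0.0, 1.0, CLUSTERING_BINS + 1)
        counts, _ = np.histogram(cc, bins=edges)
        # np.histogram puts 1.0 in the last bin already
        return DistributionHistogram(kind, edges, counts)
    if kind == "shortest_path":
        counts = np.zeros(n - 1, dtype=int)
        reached = 0
        for src, dists in nx.all_pairs_shortest_path_length(g):
            for dst, d in dists.items():
                if dst > src:
                    counts[d - 1] += 1
                    reached += 1
        disconnected = n * (n - 1) // 2 - reached
        return DistributionHistogram(
            kind, np.arange(1, n + 1) - 0.5, counts, disconnected=disconnected
        )
    raise ValueError(f"unknown statistic kind {kind!r}")


def distribution_distance(a: DistributionHistogram, b: DistributionHistogram) -> float:
    """Euclidean distance between histogram count vectors (the
    disconnected-pair bin participates for geodesic histograms)."""
    if a.kind != b.kind or a.counts.shape != b.counts.shape or not np.allclose(
        a.bin_edges, b.bin_edges
    ):
        raise ValueError("histograms must share kind and bin structure")
    va = np.append(a.counts, a.disconnected).astype(float)
    vb = np.append(b.counts, b.disconnected).astype(float)
    return float(np.linalg.norm(va - vb))


def _stratum_mean(values: np.ndarray, mask: np.ndarray) -> float:
    return float(values[mask].mean()) if mask.any() else float("nan")


def compute_metrics(
    graph: InteractionGraph,
    health: np.ndarray,
    iteration: int,
    total_utility: float,
    cumulative_total_utility: float,
) -> MetricRecord:
    """All scalar metrics for one snapshot."""
    health = np.asarray(health)
    g = graph.to_networkx()
    deg = graph.degrees().astype(float)
    cc = np.array([nx.clustering(g, i) for i in range(graph.n)], dtype=float)
    infected = health == Health.INFECTED
    healthy = ~infected
    hh, hi, ii = interactions_by_status(graph, health)

    # geodesics over connected pairs, stratified by endpoint health
    sp_h: list[int] = []
    sp_i: list[int] = []
    reached = 0
    for src, dists in nx.all_pairs_shortest_path_length(g):
        for dst, d in dists.items():
            if dst > src:
                reached += 1
                if healthy[src] and healthy[dst]:
                    sp_h.append(d)
                elif infected[src] and infected[dst]:
                    sp_i.append(d)
    return MetricRecord(
        iteration=iteration,
        infection_occurrence=infection_occurrence(health),
        n_interactions=graph.n_edges(),
        interactions_hh=hh,
        interactions_hi=hi,
        interactions_ii=ii,
        total_utility=total_utility,
        cumulative_total_utility=cumulative_total_utility,
        mean_degree_healthy=_stratum_mean(deg, healthy),
        mean_degree_infected=_stratum_mean(deg, infected),
        mean_clustering_healthy=_stratum_mean(cc, healthy),
        mean_clustering_infected=_stratum_mean(cc, infected),
        mean_shortest_path_healthy=float(np.mean(sp_h)) if sp_h else float("nan"),
        mean_shortest_path_infected=float(np.mean(sp_i)) if sp_i else float("nan"),
        disconnected_pairs=graph.n * (graph.n - 1) // 2 - reached,
    )


_METRIC_COLUMNS = [f.name for f in fields(MetricRecord) if f.name != "iteration"]


def trajectory_frame(traj: Trajectory, replicate: int = 0) -> pd.DataFrame:
    """Tidy frame: one row per iteration with all scalar metrics."""
    rows = []
    for rec in traj:
        row = {"replicate": replicate, "iteration": rec.iteration}
        row.update({k: getattr(rec.metrics, k) for k in _METRIC_COLUMNS})
        rows.append(row)
    return pd.DataFrame(rows)


def summarise_replicates(trajectories: list[Trajectory]) -> pd.DataFrame:
    """Per-iteration mean and population standard deviation of every
    metric across replicates."""
    if not trajectories:
        raise ValueError("at least one trajectory is required")
    lengths = {len(t) for t in trajectories}
    if len(lengths) != 1:
        raise ValueError("trajectories must have equal length")
    frames = [trajectory_frame(t, r) for r, t in enumerate(trajectories)]
    stacked = pd.concat(frames, ignore_index=True)
    grouped = stacked.groupby("iteration")[_METRIC_COLUMNS]
    mean = grouped.mean().add_suffix("_mean")
    sd = grouped.std(ddof=0).fillna(0.0).add_suffix("_sd")
    return pd.concat([mean, sd], axis=1).reset_index()


def write_timeseries(trajectories: list[Trajectory], path: str) -> None:
    """Tidy CSV: one row per replicate x iteration."""
    frames = [trajectory_frame(t, r) for r, t in enumerate(trajectories)]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_snapshots(traj: Trajectory, directory: str) -> None:
    """Per-iteration edge lists (i, j, intensity) plus a health CSV."""
    os.makedirs(directory, exist_ok=True)
    health_rows = []
    for rec in traj:
        fname = os.path.join(directory, f"edges_{rec.iteration:04d}.csv")
        with open(fname, "w") as fh:
            fh.write("i,j,intensity\n")
            for (i, j), w in sorted(rec.graph.intensity.items()):
                fh.write(f"{i},{j},{w:.6f}\n")
        for i, h in enumerate(rec.health):
            health_rows.append((rec.iteration, i, int(h)))
    with open(os.path.join(directory, "health.csv"), "w") as fh:
        fh.write("iteration,node,infected\n")
        for t, i, h in health_rows:
            fh.write(f"{t},{i},{h}\n")


# ---------------------------------------------------------------------------
# Configuration files

_SUBSECTIONS = {"backbone": BackboneSpec, "epidemic": EpidemicParams, "utility": UtilityParams}


def _build(cls, data: dict, context: str):
    valid = {f.name for f in fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigurationError(
            f"unknown field(s) {sorted(unknown)} in {context}"
        )
    return cls(**data)


def read_config(path: str) -> SimulationConfig:
    """Load a JSON or YAML simulation configuration."""
    with open(path) as fh:
        text = fh.read()
    if path.endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError("config file must contain a mapping")
    data = dict(data)
    kwargs = {}
    for name, cls in _SUBSECTIONS.items():
        if name in data:
            sub = data.pop(name)
            if not isinstance(sub, dict):
                raise ConfigurationError(f"config section {name!r} must be a mapping")
            kwargs[name] = _build(cls, sub, f"section {name!r}")
    config = _build(SimulationConfig, {**data, **kwargs}, "config")
    config.validate()
    return config


def write_config(config: SimulationConfig, path: str) -> None:
    """Write a configuration back to JSON or YAML (round-trips)."""
    data = asdict(config)
    with open(path, "w") as fh:
        if path.endswith(".json"):
            json.dump(data, fh, indent=2)
        else:
            yaml.safe_dump(data, fh, sort_keys=False)
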