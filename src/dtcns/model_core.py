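"""Domain types, configuration, population initialisation and backbones.

The simulator models a population of nodes, each carrying a fixed feature
vector in [0, 1]^l and a mutable *preference genome*: signed preferences
(-1 / 0 / +1) with weights in (0, 1] for partner features (preferential
attachment), feature differences (homophily) and common friends (triadic
closure).  Nodes interact each iteration under a per-node social-capital
budget while an epidemic spreads over the realised interactions.

This module owns the value types shared by the rest of the package, the
initialisation of populations and backbone networks, and seed selection
for the epidemic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Health",
    "ConfigurationError",
    "PreferenceGenome",
    "NodeState",
    "InteractionGraph",
    "EpidemicParams",
    "UtilityParams",
    "BackboneSpec",
    "SimulationConfig",
    "IterationRecord",
    "Trajectory",
    "STYLES",
    "init_population",
    "generate_backbone",
    "select_seeds",
]


class Health(enum.IntEnum):
    """Binary health status; the epidemic has no immune compartment."""

    HEALTHY = 0
    INFECTED = 1


class ConfigurationError(ValueError):
    """Raised for invalid simulation configuration values."""


STYLES = ("inactive", "ignorant", "egocentric", "cooperative", "collaborative")


@dataclass
class PreferenceGenome:
    """A node's connection preferences.

    ``p``/``w_p`` score the partner's raw feature values, ``h``/``w_h``
    score absolute feature differences (homophily/heterophily), and the
    scalar ``c``/``w_c`` scores the fraction of shared neighbours.
    Preference entries take values in {-1, 0, 1}; weights lie in (0, 1].
    """

    p: np.ndarray
    w_p: np.ndarray
    h: np.ndarray
    w_h: np.ndarray
    c: int
    w_c: float

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=int)
        self.h = np.asarray(self.h, dtype=int)
        self.w_p = np.asarray(self.w_p, dtype=float)
        self.w_h = np.asarray(self.w_h, dtype=float)
        if self.p.shape != self.h.shape or self.p.shape != self.w_p.shape:
            raise ValueError("preference and weight vectors must share length")
        for vec in (self.p, self.h, np.array([self.c])):
            if not np.isin(vec, (-1, 0, 1)).all():
                raise ValueError("preference entries must be in {-1, 0, 1}")
        for w in (self.w_p, self.w_h, np.array([self.w_c])):
            if not ((np.asarray(w) > 0) & (np.asarray(w) <= 1)).all():
                raise ValueError("preference weights must lie in (0, 1]")

    @classmethod
    def zero(cls, n_features: int) -> "PreferenceGenome":
        """The neutral genome: all preferences 0, all weights 1."""
        return cls(
            p=np.zeros(n_features, dtype=int),
            w_p=np.ones(n_features),
            h=np.zeros(n_features, dtype=int),
            w_h=np.ones(n_features),
            c=0,
            w_c=1.0,
        )

    @classmethod
    def random(cls, n_features: int, rng: np.random.Generator) -> "PreferenceGenome":
        """Uniform-random signed preferences; weights stay at 1."""
        return cls(
            p=rng.integers(-1, 2, size=n_features),
            w_p=np.ones(n_features),
            h=rng.integers(-1, 2, size=n_features),
            w_h=np.ones(n_features),
            c=int(rng.integers(-1, 2)),
            w_c=1.0,
        )


@dataclass
class NodeState:
    """Full per-node state at one simulation instant."""

    id: int
    features: np.ndarray
    genome: PreferenceGenome
    health: Health = Health.HEALTHY
    capital_limit: int = 0
    capital_spent: int = 0
    reward: float = 0.0
    risk_healthy: float = 0.0
    risk_infected: float = 0.0
    utility: float = 0.0


def _norm_edge(i: int, j: int) -> tuple[int, int]:
    if i == j:
        raise ValueError("self-edges are not allowed")
    return (i, j) if i < j else (j, i)


@dataclass
class InteractionGraph:
    """A symmetric interaction set with per-edge intensities in [0, 1]."""

    n: int
    intensity: dict[tuple[int, int], float] = field(default_factory=dict)

    @property
    def edges(self) -> set[tuple[int, int]]:
        return set(self.intensity)

    def add_edge(self, i: int, j: int, intensity: float = 1.0) -> None:
        self.intensity[_norm_edge(i, j)] = float(intensity)

    def has_edge(self, i: int, j: int) -> bool:
        return _norm_edge(i, j) in self.intensity

    def n_edges(self) -> int:
        return len(self.intensity)

    def degree(self, i: int) -> int:
        return sum(1 for e in self.intensity if i in e)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=int)
        for i, j in self.intensity:
            deg[i] += 1
            deg[j] += 1
        return deg

    def neighbors(self, i: int) -> set[int]:
        out: set[int] = set()
        for a, b in self.intensity:
            if a == i:
                out.add(b)
            elif b == i:
                out.add(a)
        return out

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix."""
        a = np.zeros((self.n, self.n))
        for i, j in self.intensity:
            a[i, j] = a[j, i] = 1.0
        return a

    def intensity_matrix(self) -> np.ndarray:
        w = np.zeros((self.n, self.n))
        for (i, j), val in self.intensity.items():
            w[i, j] = w[j, i] = val
        return w

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        for (i, j), w in self.intensity.items():
            g.add_edge(i, j, intensity=w)
        return g

    @classmethod
    def from_edges(
        cls, n: int, edges: Iterable[tuple[int, int]], intensity: float = 1.0
    ) -> "InteractionGraph":
        g = cls(n=n)
        for i, j in edges:
            g.add_edge(i, j, intensity)
        return g

    @classmethod
    def from_matrices(cls, adj: np.ndarray, weights: np.ndarray) -> "InteractionGraph":
        n = adj.shape[0]
        g = cls(n=n)
        ii, jj = np.nonzero(np.triu(adj, 1))
        for i, j in zip(ii.tolist(), jj.tolist()):
            g.intensity[(i, j)] = float(weights[i, j])
        return g


@dataclass
class EpidemicParams:
    """Transmission/recovery rates (per interaction, per iteration)."""

    transmissibility: float = 0.20
    recovery: float = 0.20
    n_seeds: int = 1

    def validate(self) -> None:
        if not 0.0 <= self.transmissibility <= 1.0:
            raise ConfigurationError("epidemic.transmissibility must be in [0, 1]")
        if not 0.0 <= self.recovery <= 1.0:
            raise ConfigurationError("epidemic.recovery must be in [0, 1]")
        if self.n_seeds < 1:
            raise ConfigurationError("epidemic.n_seeds must be a positive integer")


@dataclass
class UtilityParams:
    """Reward/utility parameters.

    ``reward_scale`` (epsilon) scales the interaction score into reward
    units; ``infection_penalty`` (psi) multiplies the base interaction
    cost for infected nodes (0.40 -> 0.60 at defaults); ``utility_discount``
    (delta) depreciates an infected node's utility; ``interference_sd`` is
    the standard deviation of the Gaussian noise added to each unilateral
    evaluation.
    """

    reward_scale: float = 1.0
    infection_penalty: float = 1.5
    base_cost: float = 0.40
    utility_discount: float = 0.01
    interference_sd: float = 0.01

    def validate(self) -> None:
        if self.reward_scale <= 0:
            raise ConfigurationError("utility.reward_scale must be positive")
        if not 1.0 < self.infection_penalty <= 2.0:
            raise ConfigurationError("utility.infection_penalty must lie in (1, 2]")
        if self.interference_sd < 0:
            raise ConfigurationError("utility.interference_sd must be non-negative")


@dataclass
class BackboneSpec:
    """Initial-network specification.

    ``kind`` is one of ``unconnected``, ``random`` (G(n, m), exactly
    ``n_edges`` uniform edges), ``scale_free`` (preferential-attachment
    growth, ``m_attach`` edges per arriving node) or ``file`` (two-column
    edge list at ``path``).  ``metadata`` carries free-form provenance
    (e.g. a connection probability quoted for a pre-built network) and is
    not used by the generator.
    """

    kind: str = "unconnected"
    n_edges: Optional[int] = None
    m_attach: int = 2
    path: Optional[str] = None
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.kind not in ("unconnected", "random", "scale_free", "file"):
            raise ConfigurationError(f"backbone.kind {self.kind!r} is not recognised")
        if self.kind == "random" and self.n_edges is None:
            raise ConfigurationError("backbone.n_edges is required for kind 'random'")
        if self.kind == "file" and self.path is None:
            raise ConfigurationError("backbone.path is required for kind 'file'")


@dataclass
class SimulationConfig:
    """All scalar parameters of one simulation scenario.

    Defaults mirror the reference scenario: 30 nodes with a single
    uniform feature, full encounter rate, action-space size 2, 100
    iterations, 8 replicates, transmissibility and recovery 0.2.
    """

    n_nodes: int = 30
    n_features: int = 1
    encounter_rate: float = 1.0
    n_candidates: int = 2
    iterations: int = 100
    replicates: int = 8
    style: str = "inactive"
    capital_limit: int = 10
    backbone: BackboneSpec = field(default_factory=BackboneSpec)
    epidemic: EpidemicParams = field(default_factory=EpidemicParams)
    utility: UtilityParams = field(default_factory=UtilityParams)
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_nodes < 2:
            raise ConfigurationError("n_nodes must be at least 2")
        if self.n_features < 1:
            raise ConfigurationError("n_features must be at least 1")
        if not 0.0 <= self.encounter_rate <= 1.0:
            raise ConfigurationError("encounter_rate must be in [0, 1]")
        if self.n_candidates < 1:
            raise ConfigurationError("n_candidates must be at least 1")
        if self.iterations < 0:
            raise ConfigurationError("iterations must be non-negative")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be at least 1")
        if self.style not in STYLES:
            raise ConfigurationError(
                f"style {self.style!r} is not one of {', '.join(STYLES)}"
            )
        if self.capital_limit < 0:
            raise ConfigurationError("capital_limit must be non-negative")
        if self.epidemic.n_seeds > self.n_nodes:
            raise ConfigurationError("epidemic.n_seeds cannot exceed n_nodes")
        self.backbone.validate()
        self.epidemic.validate()
        self.utility.validate()

    def with_overrides(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class IterationRecord:
    """State snapshot after one iteration (index 0 = pre-dynamics state)."""

    iteration: int
    graph: InteractionGraph
    health: np.ndarray
    reward: np.ndarray
    utility: np.ndarray
    metrics: "object" = None  # MetricRecord; typed loosely to avoid a cycle


@dataclass
class Trajectory:
    """Per-iteration history of one replicate run."""

    config: SimulationConfig
    records: list[IterationRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, idx):
        return self.records[idx]

    def __iter__(self):
        return iter(self.records)


# ---------------------------------------------------------------------------
# Operations


def init_population(
    config: SimulationConfig, rng: np.random.Generator
) -> list[NodeState]:
    """Create the initial population.

    Features are i.i.d. uniform on [0, 1]; every genome is neutral
    (zero preferences, unit weights); everyone starts healthy.
    """
    if config.n_nodes < 2:
        raise ConfigurationError("n_nodes must be at least 2")
    feats = rng.uniform(0.0, 1.0, size=(config.n_nodes, config.n_features))
    return [
        NodeState(
            id=i,
            features=feats[i],
            genome=PreferenceGenome.zero(config.n_features),
            health=Health.HEALTHY,
            capital_limit=config.capital_limit,
        )
        for i in range(config.n_nodes)
    ]


def _read_edge_list(path: str) -> list[tuple[int, int]]:
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ConfigurationError(f"malformed edge-list line: {line!r}")
            edges.append((int(parts[0]), int(parts[1])))
    return edges


def generate_backbone(
    spec: BackboneSpec, n: int, rng: np.random.Generator
) -> InteractionGraph:
    """Generate the initial network; all backbone intensities are 1."""
    if n < 2:
        raise ConfigurationError("backbone requires at least 2 nodes")
    spec.validate()
    max_edges = n * (n - 1) // 2
    if spec.kind == "unconnected":
        return InteractionGraph(n=n)
    if spec.kind == "random":
        if not 0 <= spec.n_edges <= max_edges:
            raise ConfigurationError(
                f"backbone.n_edges must be in [0, {max_edges}] for n={n}"
            )
        g = nx.gnm_random_graph(n, spec.n_edges, seed=rng)
        return InteractionGraph.from_edges(n, g.edges())
    if spec.kind == "scale_free":
        g = nx.barabasi_albert_graph(n, spec.m_attach, seed=rng)
        return InteractionGraph.from_edges(n, g.edges())
    # file kind
    edges = _read_edge_list(spec.path)
    for i, j in edges:
        if not (0 <= i < n and 0 <= j < n):
            raise ConfigurationError(f"edge ({i}, {j}) out of range for n={n}")
    return InteractionGraph.from_edges(n, edges)


def select_seeds(
    graph: InteractionGraph, k: int, rng: np.random.Generator
) -> set[int]:
    """Pick the k highest-degree nodes; ties (and the all-isolated case)
    are broken uniformly at random."""
    n = graph.n
    if not 1 <= k <= n:
        raise ConfigurationError(f"seed count must be in [1, {n}]")
    deg = graph.degrees()
    # Random keys make equal-degree order uniform; on an empty graph this
    # reduces to a uniform random subset.
    keys = rng.random(n)
    order = np.lexsort((keys, -deg))
    return set(int(i) for i in order[:k])
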