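"""Network-epidemic co-evolution: the per-iteration simulation loop.

Each iteration proceeds in a fixed order:

1. preference mutation (one of five styles, below);
2. encounter sampling (each unordered pair independently, rate eta);
3. pairwise scoring with fresh evaluation interference, closure drawn
   from the previous iteration's realised graph;
4. capital-constrained interaction formation (greedy by mutual score);
5. per-node rewards, risks and utilities on the realised graph;
6. synchronous epidemic transmission/recovery;
7. metric recording.

Mutation styles: *inactive* nodes keep their genome; *ignorant* nodes
adopt a fresh random genome each iteration without evaluation;
*egocentric* nodes each test gamma random genomes (plus the status quo)
in independent what-if rollouts and keep the one maximising their own
expected utility, all updating simultaneously and unaware of each other;
*cooperative* nodes evaluate gamma joint random assignments against the
joint status quo and adopt the one maximising the population's total
expected utility; *collaborative* nodes do the same but pool their
social-capital budgets during formation.

What-if rollouts resample encounters and draw their own interference, so
group decisions degrade when noise is large relative to utility gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import metrics_io
from .epidemic import risk_vectors, transmit_and_recover
from .model_core import (
    ConfigurationError,
    Health,
    InteractionGraph,
    IterationRecord,
    NodeState,
    PreferenceGenome,
    SimulationConfig,
    Trajectory,
    UtilityParams,
    generate_backbone,
    init_population,
    select_seeds,
)
from .scoring import ScoreMatrix, interaction_cost, score_matrices
from .utility import utility_vectors

__all__ = [
    "GenomeArrays",
    "CandidateSet",
    "FormationResult",
    "SimState",
    "sample_encounters",
    "form_interactions",
    "propose_candidates",
    "evaluate_candidates",
    "initial_state",
    "step",
    "run",
    "run_replicates",
]


@dataclass
class GenomeArrays:
    """Population genomes as stacked arrays (one row per node)."""

    P: np.ndarray
    WP: np.ndarray
    H: np.ndarray
    WH: np.ndarray
    C: np.ndarray
    WC: np.ndarray

    @classmethod
    def zero(cls, n: int, l: int) -> "GenomeArrays":
        return cls(
            P=np.zeros((n, l), dtype=int),
            WP=np.ones((n, l)),
            H=np.zeros((n, l), dtype=int),
            WH=np.ones((n, l)),
            C=np.zeros(n, dtype=int),
            WC=np.ones(n),
        )

    @classmethod
    def from_nodes(cls, nodes: list[NodeState]) -> "GenomeArrays":
        return cls(
            P=np.stack([nd.genome.p for nd in nodes]),
            WP=np.stack([nd.genome.w_p for nd in nodes]),
            H=np.stack([nd.genome.h for nd in nodes]),
            WH=np.stack([nd.genome.w_h for nd in nodes]),
            C=np.array([nd.genome.c for nd in nodes]),
            WC=np.array([nd.genome.w_c for nd in nodes]),
        )

    def copy(self) -> "GenomeArrays":
        return GenomeArrays(
            self.P.copy(), self.WP.copy(), self.H.copy(),
            self.WH.copy(), self.C.copy(), self.WC.copy(),
        )

    def row(self, i: int) -> PreferenceGenome:
        return PreferenceGenome(
            p=self.P[i], w_p=self.WP[i], h=self.H[i], w_h=self.WH[i],
            c=int(self.C[i]), w_c=float(self.WC[i]),
        )

    def set_row(self, i: int, genome: PreferenceGenome) -> None:
        self.P[i] = genome.p
        self.H[i] = genome.h
        self.C[i] = genome.c
        # weights are never mutated

    def n_nodes(self) -> int:
        return self.C.shape[0]


@dataclass
class CandidateSet:
    """Mutation proposals for one iteration.

    ``per_node[i]`` lists node i's candidate genomes (status quo first for
    evaluated styles); for group styles ``joint`` lists whole-population
    assignments (joint status quo first).
    """

    style: str
    per_node: list[list[PreferenceGenome]] | None = None
    joint: list[GenomeArrays] | None = None


@dataclass
class FormationResult:
    """Outcome of one interaction-formation round."""

    graph: InteractionGraph
    capital_spent: np.ndarray
    pair_rewards: dict[tuple[int, int], tuple[float, float]]


@dataclass
class SimState:
    """Mutable simulation state between iterations."""

    features: np.ndarray
    genomes: GenomeArrays
    health: np.ndarray
    capital_limits: np.ndarray
    graph: InteractionGraph          # previous realised graph (closure source)
    prev_risk_healthy: np.ndarray
    cumulative_utility: float = 0.0


def sample_encounters(n: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Symmetric boolean encounter matrix; each unordered pair meets
    independently with probability ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ConfigurationError("encounter rate must be in [0, 1]")
    enc = np.zeros((n, n), dtype=bool)
    iu, ju = np.triu_indices(n, 1)
    hits = rng.random(iu.size) < rate
    enc[iu, ju] = hits
    enc[ju, iu] = hits
    return enc


def _greedy_formation(
    scores: ScoreMatrix,
    health: np.ndarray,
    limits: np.ndarray,
    pooled: bool,
    params: UtilityParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, dict[tuple[int, int], tuple[float, float]]]:
    """Greedy admission of encountered pairs by descending mutual score.

    A pair is admissible when both endpoint rewards (score minus the
    endpoint's own health-dependent cost) are non-negative; it is admitted
    when capacity allows: spare individual capital for both endpoints, or,
    with a pooled budget, two units of total capital remaining.  Greedy
    maximality holds: after the pass no admissible pair is left out.
    """
    n = health.shape[0]
    cost = np.array([interaction_cost(Health(int(b)), params) for b in health])
    iu, ju = np.triu_indices(n, 1)
    pi = scores.mutual[iu, ju]
    r_i = params.reward_scale * pi - cost[iu]
    r_j = params.reward_scale * pi - cost[ju]
    ok = scores.encounter[iu, ju] & (r_i >= 0.0) & (r_j >= 0.0)
    idx = np.nonzero(ok)[0]
    tie = rng.random(idx.size)
    order = idx[np.lexsort((tie, -pi[idx]))]

    adj = np.zeros((n, n))
    spent = np.zeros(n, dtype=int)
    rewards: dict[tuple[int, int], tuple[float, float]] = {}
    budget = int(limits.sum())
    total = 0
    for k in order.tolist():
        i, j = int(iu[k]), int(ju[k])
        if pooled:
            if total + 2 > budget:
                continue
        else:
            if spent[i] >= limits[i] or spent[j] >= limits[j]:
                continue
        adj[i, j] = adj[j, i] = 1.0
        spent[i] += 1
        spent[j] += 1
        total += 2
        rewards[(i, j)] = (float(r_i[k]), float(r_j[k]))
    return adj, spent, rewards


def form_interactions(
    scores: ScoreMatrix,
    nodes: list[NodeState],
    pooled: bool,
    params: UtilityParams,
    rng: np.random.Generator,
) -> FormationResult:
    """Public formation API over a node list; intensity = mutual score."""
    health = np.array([int(nd.health) for nd in nodes])
    limits = np.array([nd.capital_limit for nd in nodes])
    adj, spent, rewards = _greedy_formation(scores, health, limits, pooled, params, rng)
    graph = InteractionGraph.from_matrices(adj, scores.mutual)
    return FormationResult(graph=graph, capital_spent=spent, pair_rewards=rewards)


def propose_candidates(
    style: str, genomes: GenomeArrays, gamma: int, rng: np.random.Generator
) -> CandidateSet:
    """Draw mutation proposals for one iteration (see module docstring)."""
    if gamma < 1:
        raise ConfigurationError("n_candidates must be at least 1")
    n = genomes.n_nodes()
    l = genomes.P.shape[1]
    if style == "inactive":
        return CandidateSet(style=style, per_node=[[genomes.row(i)] for i in range(n)])
    if style == "ignorant":
        return CandidateSet(
            style=style,
            per_node=[[PreferenceGenome.random(l, rng)] for i in range(n)],
        )
    if style == "egocentric":
        per = [
            [genomes.row(i)] + [PreferenceGenome.random(l, rng) for _ in range(gamma)]
            for i in range(n)
        ]
        return CandidateSet(style=style, per_node=per)
    if style in ("cooperative", "collaborative"):
        joint = [genomes.copy()]
        for _ in range(gamma):
            g = genomes.copy()
            g.P = rng.integers(-1, 2, size=(n, l))
            g.H = rng.integers(-1, 2, size=(n, l))
            g.C = rng.integers(-1, 2, size=n)
            joint.append(g)
        return CandidateSet(style=style, joint=joint)
    raise ConfigurationError(f"unknown mutation style {style!r}")


def _whatif_expected_utility(
    features: np.ndarray,
    genomes: GenomeArrays,
    health: np.ndarray,
    adj_prev: np.ndarray,
    prev_risk_healthy: np.ndarray,
    limits: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    pooled: bool,
) -> np.ndarray:
    """One hypothetical rollout: encounters, scoring with fresh
    interference, formation, risks and per-node expected utility."""
    n = features.shape[0]
    up, ep = config.utility, config.epidemic
    enc = sample_encounters(n, config.encounter_rate, rng)
    noise = rng.normal(0.0, up.interference_sd, (n, n)) if up.interference_sd > 0 else None
    sm = score_matrices(
        features, genomes.P, genomes.WP, genomes.H, genomes.WH,
        genomes.C, genomes.WC, adj_prev, enc, noise,
    )
    adj, _, _ = _greedy_formation(sm, health, limits, pooled, up, rng)
    deg = adj.sum(axis=1)
    score_sum = (adj * sm.mutual).sum(axis=1)
    # hypothetical rewards with the node's own health forced to each state
    r_h = up.reward_scale * score_sum - deg * up.base_cost
    r_i = up.reward_scale * score_sum - deg * up.infection_penalty * up.base_cost
    risk_h, risk_i = risk_vectors(adj, health, ep.transmissibility)
    u_h, u_i = utility_vectors(r_h, r_i, risk_h, risk_i, up.utility_discount)
    healthy = health == Health.HEALTHY
    return np.where(
        healthy,
        u_h * (1.0 - prev_risk_healthy) + u_i * prev_risk_healthy,
        u_i * (1.0 - ep.recovery) + u_h * ep.recovery,
    )


def _pick(values: list[float], rng: np.random.Generator) -> int:
    """Argmax with status-quo-first (index 0), then uniform tie-break."""
    best = max(values)
    winners = [k for k, v in enumerate(values) if v == best]
    if 0 in winners:
        return 0
    if len(winners) == 1:
        return winners[0]
    return winners[int(rng.integers(len(winners)))]


def evaluate_candidates(
    candidates: CandidateSet,
    state: SimState,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> GenomeArrays:
    """Resolve the iteration's mutation decision and return the adopted
    genomes (see module docstring for the per-style decision rules)."""
    style = candidates.style
    if style == "inactive":
        return state.genomes
    if style == "ignorant":
        new = state.genomes.copy()
        for i, cands in enumerate(candidates.per_node):
            new.set_row(i, cands[0])
        return new

    adj_prev = state.graph.adjacency()
    args = (state.features, state.health, adj_prev, state.prev_risk_healthy,
            state.capital_limits)

    def rollout(genomes: GenomeArrays, pooled: bool) -> np.ndarray:
        feats, health, ap, prh, lim = args
        return _whatif_expected_utility(
            feats, genomes, health, ap, prh, lim, config, rng, pooled
        )

    if style == "egocentric":
        eu_quo = rollout(state.genomes, pooled=False)
        new = state.genomes.copy()
        for i, cands in enumerate(candidates.per_node):
            values = [float(eu_quo[i])]
            for genome in cands[1:]:
                trial = state.genomes.copy()
                trial.set_row(i, genome)
                values.append(float(rollout(trial, pooled=False)[i]))
            choice = _pick(values, rng)
            if choice > 0:
                new.set_row(i, cands[choice])
        return new

    pooled = style == "collaborative"
    totals = [float(rollout(g, pooled).sum()) for g in candidates.joint]
    return candidates.joint[_pick(totals, rng)]


def initial_state(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[SimState, IterationRecord]:
    """Build the pre-dynamics state: population, backbone and seeds."""
    config.validate()
    nodes = init_population(config, rng)
    backbone = generate_backbone(config.backbone, config.n_nodes, rng)
    seeds = select_seeds(backbone, config.epidemic.n_seeds, rng)
    n = config.n_nodes
    health = np.zeros(n, dtype=int)
    health[list(seeds)] = Health.INFECTED
    risk_h, _ = risk_vectors(backbone.adjacency(), health, config.epidemic.transmissibility)
    state = SimState(
        features=np.stack([nd.features for nd in nodes]),
        genomes=GenomeArrays.from_nodes(nodes),
        health=health,
        capital_limits=np.full(n, config.capital_limit, dtype=int),
        graph=backbone,
        prev_risk_healthy=risk_h,
    )
    zeros = np.zeros(n)
    record = IterationRecord(
        iteration=0,
        graph=backbone,
        health=health.copy(),
        reward=zeros.copy(),
        utility=zeros.copy(),
        metrics=metrics_io.compute_metrics(backbone, health, 0, 0.0, 0.0),
    )
    return state, record


def step(
    state: SimState, config: SimulationConfig, rng: np.random.Generator, iteration: int
) -> IterationRecord:
    """Advance the simulation one iteration in place."""
    n = state.features.shape[0]
    up, ep = config.utility, config.epidemic

    # (1) preference mutation
    candidates = propose_candidates(config.style, state.genomes, config.n_candidates, rng)
    state.genomes = evaluate_candidates(candidates, state, config, rng)

    # (2)-(4) encounters, scoring, formation
    enc = sample_encounters(n, config.encounter_rate, rng)
    noise = rng.normal(0.0, up.interference_sd, (n, n)) if up.interference_sd > 0 else None
    sm = score_matrices(
        state.features, state.genomes.P, state.genomes.WP, state.genomes.H,
        state.genomes.WH, state.genomes.C, state.genomes.WC,
        state.graph.adjacency(), enc, noise,
    )
    pooled = config.style == "collaborative"
    adj, spent, _ = _greedy_formation(sm, state.health, state.capital_limits, pooled, up, rng)
    if pooled:
        assert spent.sum() <= state.capital_limits.sum()
    else:
        assert (spent <= state.capital_limits).all()
    graph = InteractionGraph.from_matrices(adj, sm.mutual)

    # (5) rewards, risks, utilities on the realised graph
    deg = adj.sum(axis=1)
    score_sum = (adj * sm.mutual).sum(axis=1)
    cost = np.where(
        state.health == Health.INFECTED, up.infection_penalty * up.base_cost, up.base_cost
    )
    reward = up.reward_scale * score_sum - deg * cost
    risk_h, risk_i = risk_vectors(adj, state.health, ep.transmissibility)
    healthy = state.health == Health.HEALTHY
    util = np.where(
        healthy,
        reward * (1.0 - risk_h),
        up.utility_discount * reward * (1.0 - risk_i),
    )
    state.cumulative_utility += float(util.sum())

    # (6) epidemic update (synchronous, on the pre-step health vector)
    new_health = transmit_and_recover(graph, state.health, ep, rng)

    # (7) record; the snapshot carries the post-update health vector
    record = IterationRecord(
        iteration=iteration,
        graph=graph,
        health=new_health.copy(),
        reward=reward,
        utility=util,
        metrics=metrics_io.compute_metrics(
            graph, new_health, iteration, float(util.sum()), state.cumulative_utility
        ),
    )
    state.graph = graph
    state.prev_risk_healthy = risk_h
    state.health = new_health
    return record


def run(config: SimulationConfig, rng_seed: int | None = None) -> Trajectory:
    """Run one replicate; returns a trajectory of ``iterations + 1`` records."""
    seed = config.rng_seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    state, record0 = initial_state(config, rng)
    traj = Trajectory(config=config, records=[record0])
    for t in range(1, config.iterations + 1):
        traj.records.append(step(state, config, rng, t))
    return traj


def run_replicates(config: SimulationConfig) -> list[Trajectory]:
    """Run ``config.replicates`` independent replicates with derived seeds."""
    return [run(config, rng_seed=config.rng_seed + r) for r in range(config.replicates)]
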