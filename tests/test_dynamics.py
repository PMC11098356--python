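"""Encounters, capital-constrained formation, mutation strategies and the loop."""

import itertools

import numpy as np
import pytest

from dtcns import (
    EpidemicParams,
    Health,
    InteractionGraph,
    PreferenceGenome,
    ScoreMatrix,
    SimulationConfig,
    UtilityParams,
    expected_utility,
    interaction_utility,
    pair_reward,
    run,
    run_replicates,
    sample_encounters,
)
from dtcns.dynamics import (
    CandidateSet,
    GenomeArrays,
    SimState,
    _greedy_formation,
    evaluate_candidates,
    form_interactions,
    propose_candidates,
)
from dtcns.epidemic import risk_vectors
from dtcns.model_core import NodeState


def _full_encounter(n):
    enc = np.ones((n, n), dtype=bool)
    np.fill_diagonal(enc, False)
    return enc


def _score_matrix(mutual, enc=None):
    mutual = np.asarray(mutual, dtype=float)
    n = mutual.shape[0]
    if enc is None:
        enc = _full_encounter(n)
    return ScoreMatrix(mutual=mutual, unilateral=mutual.copy(), encounter=enc)


# ---------------------------------------------------------------------------
# encounters


def test_encounters_rate_extremes():
    rng = np.random.default_rng(0)
    full = sample_encounters(5, 1.0, rng)
    assert full.sum() == 5 * 4  # both triangle halves
    assert not full.diagonal().any()
    assert (full == full.T).all()
    assert sample_encounters(5, 0.0, rng).sum() == 0


def test_encounters_binomial_mean():
    """Pair count at rate 0.5 on 30 nodes: mean 435/2 over 10^3 draws."""
    rng = np.random.default_rng(1)
    n_reps = 1000
    counts = [sample_encounters(30, 0.5, rng).sum() // 2 for _ in range(n_reps)]
    se = np.sqrt(435 * 0.25 / n_reps)
    assert abs(np.mean(counts) - 217.5) < 3 * se


# ---------------------------------------------------------------------------
# formation


def test_formation_capital_one_takes_best_pair():
    """Three mutually positive pairs, one unit of capital each: only the
    top-scoring pair forms."""
    mutual = np.array([[0, 0.8, 0.7], [0.8, 0, 0.6], [0.7, 0.6, 0]])
    health = np.zeros(3, dtype=int)
    adj, spent, rewards = _greedy_formation(
        _score_matrix(mutual), health, np.array([1, 1, 1]), False,
        UtilityParams(), np.random.default_rng(0),
    )
    assert adj.sum() == 2
    assert adj[0, 1] == 1
    assert spent.tolist() == [1, 1, 0]
    assert list(rewards) == [(0, 1)]


def test_formation_rejects_negative_endpoint_reward():
    """An infected endpoint turns score 0.5 into reward -0.1: never admitted."""
    mutual = np.array([[0, 0.5], [0.5, 0]])
    health = np.array([Health.INFECTED, Health.HEALTHY])
    adj, _, _ = _greedy_formation(
        _score_matrix(mutual), health, np.array([5, 5]), False,
        UtilityParams(), np.random.default_rng(0),
    )
    assert adj.sum() == 0
    # the same pair forms when both are healthy
    adj, _, _ = _greedy_formation(
        _score_matrix(mutual), np.zeros(2, dtype=int), np.array([5, 5]), False,
        UtilityParams(), np.random.default_rng(0),
    )
    assert adj.sum() == 2


def test_formation_pooled_budget_allows_transfer():
    """A node may exceed its own limit under a pooled budget, but the total
    budget still binds."""
    mutual = np.array([
        [0, 0.9, 0.8],
        [0.9, 0, 0.1],
        [0.8, 0.1, 0],
    ])
    health = np.zeros(3, dtype=int)
    limits = np.array([1, 3, 0])  # pooled budget 4
    adj_ind, spent_ind, _ = _greedy_formation(
        _score_matrix(mutual), health, limits, False, UtilityParams(),
        np.random.default_rng(0),
    )
    # individually, node 0 can afford only its best edge and node 2 none
    assert spent_ind.tolist() == [1, 1, 0]
    adj_pool, spent_pool, _ = _greedy_formation(
        _score_matrix(mutual), health, limits, True, UtilityParams(),
        np.random.default_rng(0),
    )
    assert spent_pool.tolist() == [2, 1, 1]  # node 0 over its own limit
    assert spent_pool.sum() <= limits.sum()


def test_formation_greedy_maximality_brute_force():
    """On every random <=6-node instance, no admissible pair is left out."""
    rng = np.random.default_rng(5)
    params = UtilityParams()
    for trial in range(40):
        n = int(rng.integers(3, 7))
        raw = rng.uniform(0.0, 1.0, (n, n))
        mutual = (raw + raw.T) / 2
        np.fill_diagonal(mutual, 0.0)
        enc = sample_encounters(n, 0.8, rng)
        health = rng.integers(0, 2, n)
        limits = rng.integers(0, 4, n)
        adj, spent, _ = _greedy_formation(
            _score_matrix(mutual, enc), health, limits, False, params, rng
        )
        assert (spent <= limits).all()
        for i, j in itertools.combinations(range(n), 2):
            if adj[i, j]:
                continue
            admissible = (
                enc[i, j]
                and pair_reward(mutual[i, j], Health(int(health[i])), params) >= 0
                and pair_reward(mutual[i, j], Health(int(health[j])), params) >= 0
            )
            if admissible:
                # must be blocked by capacity somewhere
                assert spent[i] >= limits[i] or spent[j] >= limits[j]


def test_form_interactions_public_api_sets_intensity_to_score():
    nodes = [
        NodeState(id=i, features=np.array([0.5]), genome=PreferenceGenome.zero(1),
                  capital_limit=2)
        for i in range(3)
    ]
    mutual = np.array([[0, 0.9, 0.45], [0.9, 0, 0.41], [0.45, 0.41, 0]])
    result = form_interactions(
        _score_matrix(mutual), nodes, False, UtilityParams(), np.random.default_rng(0)
    )
    assert result.graph.intensity[(0, 1)] == pytest.approx(0.9)
    assert result.capital_spent.tolist() == list(result.graph.degrees())
    for (i, j), (ri, rj) in result.pair_rewards.items():
        assert ri >= 0 and rj >= 0


# ---------------------------------------------------------------------------
# candidate proposal and evaluation


def test_propose_candidates_shapes():
    rng = np.random.default_rng(0)
    genomes = GenomeArrays.zero(4, 1)
    inactive = propose_candidates("inactive", genomes, 2, rng)
    assert all(len(c) == 1 for c in inactive.per_node)
    assert inactive.per_node[0][0].p.tolist() == [0]

    ego = propose_candidates("egocentric", genomes, 2, rng)
    assert all(len(c) == 3 for c in ego.per_node)  # status quo + gamma proposals

    coop = propose_candidates("cooperative", genomes, 2, rng)
    assert len(coop.joint) == 3
    assert (coop.joint[0].P == 0).all()  # joint status quo first
    assert (coop.joint[1].WP == 1).all()  # weights never mutate


def test_ignorant_proposals_deterministic_under_seed():
    genomes = GenomeArrays.zero(5, 1)
    a = propose_candidates("ignorant", genomes, 2, np.random.default_rng(3))
    b = propose_candidates("ignorant", genomes, 2, np.random.default_rng(3))
    for ca, cb in zip(a.per_node, b.per_node):
        assert ca[0].p.tolist() == cb[0].p.tolist()
        assert ca[0].c == cb[0].c


def _small_state(features, capital=3, seed_infected=()):
    n = len(features)
    health = np.zeros(n, dtype=int)
    for i in seed_infected:
        health[i] = Health.INFECTED
    return SimState(
        features=np.asarray(features, dtype=float).reshape(n, 1),
        genomes=GenomeArrays.zero(n, 1),
        health=health,
        capital_limits=np.full(n, capital),
        graph=InteractionGraph(n=n),
        prev_risk_healthy=np.zeros(n),
    )


def _noiseless_config(**kw):
    return SimulationConfig(
        n_nodes=kw.pop("n_nodes", 4),
        utility=UtilityParams(interference_sd=0.0),
        **kw,
    )


def _oracle_eu(state, genome_rows, config):
    """Independent expected-utility oracle built from the scalar APIs:
    explicit pair loops, hand-rolled greedy admission, scalar risk and
    utility formulas.  Valid for deterministic settings (encounter rate 1,
    interference off)."""
    n = state.features.shape[0]
    up, ep = config.utility, config.epidemic
    nodes = [
        NodeState(id=i, features=state.features[i], genome=genome_rows[i],
                  health=Health(int(state.health[i])),
                  capital_limit=int(state.capital_limits[i]))
        for i in range(n)
    ]
    from dtcns import mutual_score, unilateral_score

    pairs = []
    for i, j in itertools.combinations(range(n), 2):
        m = mutual_score(
            unilateral_score(i, j, nodes, state.graph, True),
            unilateral_score(j, i, nodes, state.graph, True),
        )
        if (pair_reward(m, nodes[i].health, up) >= 0
                and pair_reward(m, nodes[j].health, up) >= 0):
            pairs.append((m, i, j))
    pairs.sort(key=lambda t: -t[0])
    spent = np.zeros(n, dtype=int)
    edges = []
    for m, i, j in pairs:
        if spent[i] < nodes[i].capital_limit and spent[j] < nodes[j].capital_limit:
            edges.append((i, j, m))
            spent[i] += 1
            spent[j] += 1
    graph = InteractionGraph.from_edges(n, [(i, j) for i, j, _ in edges])
    for i, j, m in edges:
        graph.intensity[(i, j)] = m
    eu = np.zeros(n)
    for i in range(n):
        score_sum = sum(m for a, b, m in edges if i in (a, b))
        deg = graph.degree(i)
        r_h = up.reward_scale * score_sum - deg * up.base_cost
        r_i = up.reward_scale * score_sum - deg * up.infection_penalty * up.base_cost
        n_inf = sum(1 for j in graph.neighbors(i) if state.health[j] == Health.INFECTED)
        n_hea = deg - n_inf
        risk_h = 1 - (1 - ep.transmissibility) ** n_inf
        risk_i = 1 - (1 - ep.transmissibility) ** n_hea
        u_h = interaction_utility(r_h, risk_h, 0.0, Health.HEALTHY, up.utility_discount)
        u_i = interaction_utility(r_i, 0.0, risk_i, Health.INFECTED, up.utility_discount)
        eu[i] = expected_utility(
            u_h, u_i, Health(int(state.health[i])),
            float(state.prev_risk_healthy[i]), ep.recovery,
        )
    return eu


def test_single_candidate_returns_status_quo():
    state = _small_state([0.2, 0.8, 0.5])
    cfg = _noiseless_config(n_nodes=3, style="inactive")
    cands = propose_candidates("inactive", state.genomes, 2, np.random.default_rng(0))
    chosen = evaluate_candidates(cands, state, cfg, np.random.default_rng(0))
    assert (chosen.P == state.genomes.P).all()
    assert (chosen.C == state.genomes.C).all()


def test_egocentric_prefers_rewarding_genome():
    """A genome that creates positive-reward interactions beats one that
    keeps the node isolated (no noise, exhaustive oracle)."""
    state = _small_state([0.95, 0.9, 0.85, 0.1])
    cfg = _noiseless_config(style="egocentric")
    good = PreferenceGenome(p=[1], w_p=[1.0], h=[-1], w_h=[1.0], c=1, w_c=1.0)
    bad = PreferenceGenome(p=[-1], w_p=[1.0], h=[1], w_h=[1.0], c=-1, w_c=1.0)
    cands = CandidateSet(
        style="egocentric",
        per_node=[[state.genomes.row(i)] for i in range(4)],
    )
    cands.per_node[0] = [state.genomes.row(0), good, bad]
    chosen = evaluate_candidates(cands, state, cfg, np.random.default_rng(0))

    # oracle: evaluate each of node 0's candidates exhaustively
    options = cands.per_node[0]
    scores = []
    for genome in options:
        rows = [genome] + [state.genomes.row(i) for i in range(1, 4)]
        scores.append(_oracle_eu(state, rows, cfg)[0])
    best = int(np.argmax(scores))
    assert scores[best] > scores[0]  # the run actually improves on the status quo
    assert chosen.P[0].tolist() == options[best].p.tolist()
    assert chosen.H[0].tolist() == options[best].h.tolist()


def test_cooperative_picks_higher_total_eu():
    state = _small_state([0.9, 0.8, 0.7, 0.6])
    cfg = _noiseless_config(style="cooperative")
    rng = np.random.default_rng(2)
    quo = state.genomes.copy()
    strong = state.genomes.copy()
    strong.P[:] = 1
    strong.H[:] = -1
    weak = state.genomes.copy()
    weak.P[:] = -1
    cands = CandidateSet(style="cooperative", joint=[quo, strong, weak])
    chosen = evaluate_candidates(cands, state, cfg, rng)
    totals = [
        _oracle_eu(state, [g.row(i) for i in range(4)], cfg).sum()
        for g in (quo, strong, weak)
    ]
    assert int(np.argmax(totals)) == 1
    assert (chosen.P == strong.P).all()


def test_cooperative_choice_attains_pool_maximum():
    """The adopted joint assignment realises the maximum total expected
    utility over the evaluated pool (noise off, deterministic rollouts)."""
    cfg = _noiseless_config(n_nodes=5, style="cooperative")
    for seed in range(5):
        rng = np.random.default_rng(seed)
        state = _small_state(rng.uniform(0, 1, 5).tolist(), capital=2)
        joint = propose_candidates("cooperative", state.genomes, 2, rng)
        totals = [
            _oracle_eu(state, [g.row(i) for i in range(5)], cfg).sum()
            for g in joint.joint
        ]
        chosen = evaluate_candidates(joint, state, cfg, rng)
        chosen_total = _oracle_eu(
            state, [chosen.row(i) for i in range(5)], cfg
        ).sum()
        assert chosen_total == pytest.approx(max(totals))


# ---------------------------------------------------------------------------
# the loop


def test_inactive_zero_genomes_form_no_interactions():
    """Neutral genomes score 1/3 < cost 0.4, so rewards are negative and no
    interaction clears the admission gate."""
    cfg = _noiseless_config(n_nodes=10, style="inactive", iterations=5, replicates=1)
    traj = run(cfg, rng_seed=0)
    assert all(rec.graph.n_edges() == 0 for rec in traj.records)


def test_health_constant_without_transmission_or_recovery():
    cfg = SimulationConfig(
        n_nodes=10, style="ignorant", iterations=10, replicates=1,
        epidemic=EpidemicParams(transmissibility=0.0, recovery=0.0),
    )
    traj = run(cfg, rng_seed=1)
    for rec in traj.records:
        assert np.array_equal(rec.health, traj[0].health)


def test_trajectory_bit_identical_under_seed():
    cfg = SimulationConfig(n_nodes=12, style="ignorant", iterations=15, replicates=1)
    a = run(cfg, rng_seed=5)
    b = run(cfg, rng_seed=5)
    for ra, rb in zip(a, b):
        assert ra.graph.intensity == rb.graph.intensity
        assert np.array_equal(ra.health, rb.health)
        assert np.array_equal(ra.utility, rb.utility)
        from dataclasses import asdict

        ma, mb = asdict(ra.metrics), asdict(rb.metrics)
        assert ma.keys() == mb.keys()
        for key in ma:
            assert ma[key] == mb[key] or (np.isnan(ma[key]) and np.isnan(mb[key]))


def test_trajectory_lengths_and_replicates():
    cfg = SimulationConfig(n_nodes=6, style="inactive", iterations=0, replicates=1)
    assert len(run(cfg)) == 1
    cfg = SimulationConfig(n_nodes=8, style="ignorant", iterations=4, replicates=8)
    trajs = run_replicates(cfg)
    assert len(trajs) == 8
    assert all(len(t) == 5 for t in trajs)
    # distinct derived streams: at least two replicates differ
    healths = [tuple(t[0].health.tolist()) for t in trajs]
    graphs = [frozenset(t[-1].graph.intensity) for t in trajs]
    assert len(set(healths)) > 1 or len(set(graphs)) > 1


def test_reference_run_has_101_records():
    cfg = _noiseless_config(n_nodes=30, style="inactive", iterations=100, replicates=1)
    assert len(run(cfg, rng_seed=0)) == 101


def test_capacity_respected_every_iteration():
    cfg = SimulationConfig(n_nodes=12, style="ignorant", capital_limit=3,
                           iterations=25, replicates=1)
    traj = run(cfg, rng_seed=2)
    for rec in traj.records[1:]:
        assert (rec.graph.degrees() <= 3).all()


def test_collaborative_pooled_capacity_every_iteration():
    cfg = SimulationConfig(n_nodes=10, style="collaborative", capital_limit=2,
                           iterations=10, replicates=1)
    traj = run(cfg, rng_seed=3)
    for rec in traj.records[1:]:
        assert 2 * rec.graph.n_edges() <= 10 * 2


def test_mean_interactions_monotone_in_capital(capital_sweep_means):
    """More social capital never lowers the mean interaction count."""
    means = capital_sweep_means
    assert means[5] <= means[10] <= means[15] <= means[20]
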