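# Methods

## Model

The simulator couples two processes on a fixed population of n nodes: the
formation of a fresh interaction graph every iteration, and a
susceptible–infected–susceptible contagion spreading over the realised
interactions. Nodes are heterogeneous only through a feature vector drawn
once, i.i.d. uniform on [0, 1]^l, and through their mutable preference
genomes; everything else (capital limit, cost parameters, epidemic rates)
is uniform across the population.

One iteration executes in a fixed order: (1) preference mutation,
(2) encounter sampling, (3) pairwise scoring, (4) capital-constrained
formation, (5) rewards/risks/utilities on the realised graph,
(6) synchronous transmission and recovery, (7) metric recording. The
order matters: mutation sees only the previous iteration's realised graph
and risks, and the epidemic update acts on the graph formed in the same
iteration using pre-update health states.

Key modelling assumptions:

- **Interactions are memoryless.** The graph is rebuilt from scratch each
  iteration; persistence enters only through the closure score, which
  reads shared neighbourhoods from the previous realised graph (the
  backbone at the first iteration).
- **Admission is reward-gated.** An encountered pair forms an interaction
  only if the reward ε·Π − ψ^β·c₀ is non-negative at both endpoints, and
  pairs are admitted greedily by descending mutual score until capital
  runs out. Admission uses each node's actual health; hypothetical
  utilities in mutation rollouts force the deciding node's own health but
  keep the structure fixed.
- **Contagion uses binary contacts.** Transmission depends on the number
  of infected partners, not on interaction intensity, and recovery
  returns nodes to the susceptible pool — there is no immune compartment.
- **Decisions are myopic.** Expected utility is a one-step expectation
  over the node's own health transition, weighting the two hypothetical
  utilities by the previous iteration's infection risk (healthy nodes) or
  the recovery rate (infected nodes).

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| n_nodes | population size | 30 | reference scenario size |
| n_features (l) | feature-vector length | 1 | single uniform feature |
| encounter_rate (η) | per-pair encounter probability | 1.0 | all pairs meet |
| n_candidates (γ) | proposals per mutation decision | 2 | action-space size |
| capital_limit | interactions per node per iteration | 10 | scenario grid uses 5/10/15/20 |
| base_cost (c₀) | per-interaction cost, reward units | 0.40 | healthy nodes |
| infection_penalty (ψ) | cost multiplier when infected | 1.5 | infected cost 0.60 |
| reward_scale (ε) | score-to-reward scale | 1.0 | |
| utility_discount (δ) | infected-utility depreciation | 0.01 | |
| interference_sd | SD of evaluation noise | 0.01 | 0 gives the expectation mode |
| transmissibility (ζ^s) | per-contact infection probability | 0.20 | |
| recovery (ζ^r) | per-iteration recovery probability | 0.20 | |
| n_seeds | initially infected nodes | 1 | highest-degree; random on an empty backbone |
| iterations | simulation length | 100 | plus the index-0 initial state |
| replicates | independent runs per scenario | 8 | seeds rng_seed + replicate index |

Backbones: `unconnected` (no edges), `random` (exactly n_edges uniform
edges; the reference random backbone uses 56), `scale_free`
(preferential-attachment growth with m_attach = 2 edges per arriving
node, giving m·(n − m) = 56 edges at n = 30) and `file` (user edge list).
Backbone intensities are set to 1, as the backbone predates any scoring.

## What the generator emulates — and what it does not

The synthetic populations reproduce the study conditions of the reference
scenarios: uniform single features, neutral initial genomes (all
preferences 0, weights 1), full encounter rate, uniform capital limits
and the parameter defaults above. They do not emulate real contact data:
features are abstract, one-dimensional and static; there are no
communities, households or degree heterogeneity beyond what the dynamics
create; and all nodes share one mutation style per run. Passing tests
therefore demonstrate internal correctness of the mechanism and its
qualitative orderings (e.g. interactions increase with capital), not
predictive fidelity for any empirical social network.

## Numerical and design choices

- **Health encoding** is fixed to 0 = healthy, 1 = infected everywhere;
  the cost multiplier ψ^β and the risk exponents use this encoding.
- **Clipping.** Unilateral scores are clipped to [0, 1] after adding the
  closure term and Gaussian interference, honouring the score's stated
  range; mutual scores inherit the range by averaging.
- **Closure with an isolated evaluator** (zero-degree denominator)
  returns 0: no neighbourhood, no closure signal.
- **Group decision objective** is maximisation of the summed expected
  utility for both cooperative and collaborative styles; the two differ
  only in whether formation uses per-node or pooled capital budgets.
- **Tie-breaking** is status-quo-first, then uniform at random, both in
  candidate selection and (via random sort keys) in formation order and
  seed selection; all randomness flows through one NumPy generator per
  replicate, so runs are bit-reproducible under a fixed seed.
- **What-if rollouts resample** their own encounters and interference
  rather than reusing the realised draws; decision quality therefore
  degrades as interference grows relative to utility gaps, which is the
  intended behavioural mechanism.
- **Egocentric updates are simultaneous**: every node evaluates its
  candidates against the status-quo genomes of all others and the chosen
  genomes are applied together, modelling unawareness of others' moves.
- **Ignorant re-randomisation** happens every iteration; the style has no
  persistence rule by construction.
- **Stratified metrics** return NaN for empty strata (e.g. mean infected
  degree with no infected nodes); shortest-path averages cover connected
  pairs only, with disconnected pairs counted separately. Replicate
  standard deviations use the population convention (divide by k).
  Clustering histograms use ten equal bins on [0, 1].

## Problem sizes

The test suite and the acceptance script run the reference scenarios at
full scale — 30 nodes, 100 iterations, 8 replicates — for the ignorant
and cooperative styles and the capital grid {5, 10, 15, 20}; exhaustive
cross-checks (greedy maximality, scalar-vs-vectorised scoring, expected
utility oracles) run on instances of 3–8 nodes where brute force is
exact. Monte-Carlo oracle comparisons use 10⁵ exposure draws and 10⁴
transmission steps with binomial confidence bounds.

## Known limitations

- Under the reward-gated admission rule, a neutral (all-zero) genome
  scores exactly 1/3 < c₀ = 0.40, so inactive populations form no
  interactions at all, and an infected node needs a mutual score of at
  least 0.60 to interact. Score distributions under the default
  parameters rarely clear that bar, so single-seed epidemics typically go
  extinct before spreading regardless of mutation style; sustained
  outbreaks require lowering base_cost, raising capital and seeds, or
  widening the score range. The base cost is configurable for exactly
  this reason.
- The cooperative advantage over egocentric decisions is a statistical,
  whole-run property; on a single step a coordinate-wise egocentric pick
  can beat the best of a small joint pool (γ = 2), and the package makes
  no per-step ordering guarantee.
- Heterogeneous per-node capital limits, mixed mutation styles within a
  population, directed interactions and intensity-weighted transmission
  are out of scope.
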