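"""Pairwise interaction scoring and rewards.

A node i evaluates a potential interaction with node j by averaging three
component scores derived from its preference genome:

* homophily      pi^h = |f_i - f_j| . (h o w_h) / (2 l) + 1/2
* attachment     pi^p = f_j . (p o w_p) / (2 l) + 1/2
* closure        pi^c = c w_c |N(i) n N(j)| / |N(i)|   (0 if i is isolated)

The unilateral score is (pi^h + pi^p + pi^c) / 3 plus Gaussian evaluation
interference, clipped to [0, 1]; non-encountered pairs score 0.  The
mutual score is the mean of the two unilateral scores, and the reward a
node draws from an interaction is epsilon * score minus the interaction
cost (base cost, multiplied by the infection penalty when the node itself
is infected).

Scalar functions below mirror the definitions one pair at a time; the
``score_matrices`` path computes all pairs at once and is what the
simulation loop uses.  Tests cross-check the two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import Health, InteractionGraph, NodeState, UtilityParams

__all__ = [
    "ScoreMatrix",
    "homophily_score",
    "preferential_score",
    "closure_score",
    "unilateral_score",
    "mutual_score",
    "interaction_cost",
    "pair_reward",
    "total_reward",
    "component_matrices",
    "score_matrices",
]


@dataclass
class ScoreMatrix:
    """All pairwise scores for one evaluation round."""

    mutual: np.ndarray       # symmetric, zero diagonal
    unilateral: np.ndarray   # [i, j] = score i assigns to interacting with j
    encounter: np.ndarray    # symmetric boolean

    def to_csv(self, path: str) -> None:
        np.savetxt(path, self.mutual, delimiter=",")


def _check_lengths(*vecs: np.ndarray) -> None:
    lengths = {np.asarray(v).shape[-1] for v in vecs}
    if len(lengths) != 1:
        raise ValueError("feature/preference vectors must share length")


def homophily_score(
    f_i: np.ndarray, f_j: np.ndarray, h: np.ndarray, w_h: np.ndarray
) -> float:
    """Score for feature (dis)similarity, in [0, 1]."""
    f_i, f_j, h, w_h = map(np.asarray, (f_i, f_j, h, w_h))
    _check_lengths(f_i, f_j, h, w_h)
    l = f_i.shape[-1]
    return float(np.abs(f_i - f_j) @ (h * w_h) / (2 * l) + 0.5)


def preferential_score(f_j: np.ndarray, p: np.ndarray, w_p: np.ndarray) -> float:
    """Score for the partner's feature values, in [0, 1]."""
    f_j, p, w_p = map(np.asarray, (f_j, p, w_p))
    _check_lengths(f_j, p, w_p)
    l = f_j.shape[-1]
    return float(f_j @ (p * w_p) / (2 * l) + 0.5)


def closure_score(
    i: int, j: int, graph: InteractionGraph, c: int, w_c: float
) -> float:
    """Shared-neighbour score from i's perspective, in [-1, 1].

    Returns 0 for an isolated evaluator (no neighbourhood, no signal).
    """
    if i == j:
        raise ValueError("closure score is undefined for a self-pair")
    ni = graph.neighbors(i)
    if not ni:
        return 0.0
    nj = graph.neighbors(j)
    return float(c * w_c * len(ni & nj) / len(ni))


def unilateral_score(
    i: int,
    j: int,
    nodes: list[NodeState],
    graph_prev: InteractionGraph,
    encountered: bool,
    interference: float = 0.0,
) -> float:
    """Score node i assigns to interacting with j, clipped to [0, 1].

    ``interference`` is a realisation of the Gaussian evaluation noise
    (pass 0 for the expectation mode).  Closure is computed on the
    previous iteration's realised graph.
    """
    if not encountered:
        return 0.0
    gi = nodes[i].genome
    pi_h = homophily_score(nodes[i].features, nodes[j].features, gi.h, gi.w_h)
    pi_p = preferential_score(nodes[j].features, gi.p, gi.w_p)
    pi_c = closure_score(i, j, graph_prev, gi.c, gi.w_c)
    return float(np.clip((pi_h + pi_p + pi_c) / 3.0 + interference, 0.0, 1.0))


def mutual_score(unilateral_ij: float, unilateral_ji: float) -> float:
    """Mean of the two unilateral evaluations."""
    return 0.5 * (unilateral_ij + unilateral_ji)


def interaction_cost(health: Health, params: UtilityParams) -> float:
    """Per-interaction cost: base cost, penalised when infected."""
    return params.infection_penalty ** int(health) * params.base_cost


def pair_reward(score: float, health_i: Health, params: UtilityParams) -> float:
    """Reward node i draws from one interaction with mutual score ``score``."""
    return params.reward_scale * score - interaction_cost(health_i, params)


def total_reward(
    i: int, graph: InteractionGraph, pair_rewards: dict[tuple[int, int], float]
) -> float:
    """Sum of i's pairwise rewards over its realised interactions."""
    total = 0.0
    for edge in graph.intensity:
        if i in edge:
            if edge not in pair_rewards:
                raise KeyError(f"missing pair reward for edge {edge}")
            total += pair_rewards[edge]
    return total


# ---------------------------------------------------------------------------
# Vectorised path used by the simulation loop


def component_matrices(
    features: np.ndarray,
    P: np.ndarray,
    WP: np.ndarray,
    H: np.ndarray,
    WH: np.ndarray,
    C: np.ndarray,
    WC: np.ndarray,
    adj_prev: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Homophily, attachment and closure matrices for all ordered pairs.

    Row i holds node i's evaluations.  ``adj_prev`` is the previous
    realised adjacency matrix (closure source).
    """
    n, l = features.shape
    pref = (P * WP) @ features.T / (2 * l) + 0.5
    absdiff = np.abs(features[:, None, :] - features[None, :, :])
    hom = np.einsum("ijk,ik->ij", absdiff, H * WH) / (2 * l) + 0.5
    deg = adj_prev.sum(axis=1)
    common = adj_prev @ adj_prev
    denom = np.where(deg > 0, deg, 1.0)
    clo = (C * WC)[:, None] * common / denom[:, None]
    clo[deg == 0, :] = 0.0
    return hom, pref, clo


def score_matrices(
    features: np.ndarray,
    P: np.ndarray,
    WP: np.ndarray,
    H: np.ndarray,
    WH: np.ndarray,
    C: np.ndarray,
    WC: np.ndarray,
    adj_prev: np.ndarray,
    encounter: np.ndarray,
    interference: np.ndarray | None = None,
) -> ScoreMatrix:
    """All pairwise unilateral and mutual scores.

    ``interference`` is an (n, n) matrix of per-ordered-pair noise draws,
    or None for the expectation mode.
    """
    hom, pref, clo = component_matrices(features, P, WP, H, WH, C, WC, adj_prev)
    uni = (hom + pref + clo) / 3.0
    if interference is not None:
        uni = uni + interference
    uni = np.clip(uni, 0.0, 1.0)
    uni = np.where(encounter, uni, 0.0)
    np.fill_diagonal(uni, 0.0)
    mutual = 0.5 * (uni + uni.T)
    mutual = np.where(encounter, mutual, 0.0)
    np.fill_diagonal(mutual, 0.0)
    return ScoreMatrix(mutual=mutual, unilateral=uni, encounter=encounter)
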