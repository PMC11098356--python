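"""Infection/spreading risks and the stochastic epidemic update.

The contagion is susceptible-infected-susceptible shaped: a healthy node
with k infected interaction partners stays healthy with probability
(1 - zeta_s)^k, and an infected node recovers (returning to the healthy
pool) with probability zeta_r, both evaluated synchronously on the
pre-step health vector.  Transmission uses the binary interaction
indicator, not the interaction intensity.
"""

from __future__ import annotations

import numpy as np

from .model_core import EpidemicParams, Health, InteractionGraph

__all__ = [
    "infection_risk_healthy",
    "spreading_risk_infected",
    "risk_vectors",
    "transmit_and_recover",
]


def infection_risk_healthy(
    i: int,
    graph: InteractionGraph,
    health: np.ndarray,
    transmissibility: float,
) -> float:
    """Probability that healthy node i gets infected this iteration:
    1 - (1 - zeta_s)^(number of infected interaction partners)."""
    if health[i] != Health.HEALTHY:
        raise ValueError(f"node {i} is not healthy")
    k = sum(1 for j in graph.neighbors(i) if health[j] == Health.INFECTED)
    return 1.0 - (1.0 - transmissibility) ** k


def spreading_risk_infected(
    i: int,
    graph: InteractionGraph,
    health: np.ndarray,
    transmissibility: float,
) -> float:
    """Probability that infected node i infects at least one partner:
    1 - (1 - zeta_s)^(number of healthy interaction partners)."""
    if health[i] != Health.INFECTED:
        raise ValueError(f"node {i} is not infected")
    k = sum(1 for j in graph.neighbors(i) if health[j] == Health.HEALTHY)
    return 1.0 - (1.0 - transmissibility) ** k


def risk_vectors(
    adj: np.ndarray, health: np.ndarray, transmissibility: float
) -> tuple[np.ndarray, np.ndarray]:
    """Both risk formulas for every node at once.

    Returns (risk_if_healthy, risk_if_infected); each entry is the risk the
    node would carry in that health state given its partners' actual states.
    """
    health = np.asarray(health)
    n_infected = adj @ (health == Health.INFECTED)
    n_healthy = adj @ (health == Health.HEALTHY)
    keep = 1.0 - transmissibility
    return 1.0 - keep ** n_infected, 1.0 - keep ** n_healthy


def transmit_and_recover(
    graph: InteractionGraph,
    health: np.ndarray,
    params: EpidemicParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """One synchronous transmission/recovery step on the input state."""
    health = np.asarray(health)
    adj = graph.adjacency() if isinstance(graph, InteractionGraph) else np.asarray(graph)
    risk_h, _ = risk_vectors(adj, health, params.transmissibility)
    draws = rng.random(health.shape[0])
    new = health.copy()
    healthy = health == Health.HEALTHY
    infected = ~healthy
    new[healthy & (draws < risk_h)] = Health.INFECTED
    new[infected & (draws < params.recovery)] = Health.HEALTHY
    return new
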