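"""Interaction utility and one-step expected utility.

A healthy node's utility discounts its aggregated interaction reward by
its infection risk, U = R (1 - R^H); an infected node's utility is
depreciated by the discount delta and its spreading risk,
U = delta R (1 - R^I).

The expected utility used in preference mutation is a one-step
expectation over the node's own health transition: a currently healthy
node weighs the two hypothetical utilities by its previous infection
risk, an infected node by the recovery probability.
"""

from __future__ import annotations

import numpy as np

from .model_core import Health

__all__ = ["interaction_utility", "expected_utility", "utility_vectors"]


def interaction_utility(
    reward: float,
    risk_healthy: float,
    risk_infected: float,
    health: Health,
    discount: float,
) -> float:
    """Utility of one node given its realised reward and risks."""
    if health == Health.HEALTHY:
        return reward * (1.0 - risk_healthy)
    return discount * reward * (1.0 - risk_infected)


def expected_utility(
    u_healthy: float,
    u_infected: float,
    prev_health: Health,
    prev_risk_healthy: float,
    recovery: float,
) -> float:
    """One-step expectation of utility over the node's own health change.

    ``u_healthy``/``u_infected`` are the node's hypothetical utilities
    with its own health forced to each state on the same interaction
    structure; ``prev_risk_healthy`` is its infection risk on the previous
    realised graph.
    """
    if prev_health == Health.HEALTHY:
        return u_healthy * (1.0 - prev_risk_healthy) + u_infected * prev_risk_healthy
    return u_infected * (1.0 - recovery) + u_healthy * recovery


def utility_vectors(
    reward_if_healthy: np.ndarray,
    reward_if_infected: np.ndarray,
    risk_healthy: np.ndarray,
    risk_infected: np.ndarray,
    discount: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Hypothetical utilities (U^H, U^I) for every node at once."""
    u_h = reward_if_healthy * (1.0 - risk_healthy)
    u_i = discount * reward_if_infected * (1.0 - risk_infected)
    return u_h, u_i
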