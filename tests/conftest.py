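"""Shared fixtures: expensive replicate sweeps are run once per session."""

import numpy as np
import pytest

from dtcns import SimulationConfig, run_replicates


@pytest.fixture(scope="session")
def capital_sweep_means():
    """Mean interaction count per capital limit (ignorant style, 8 replicates
    of 100 iterations each, reference parameters)."""
    means = {}
    for cap in (5, 10, 15, 20):
        cfg = SimulationConfig(style="ignorant", capital_limit=cap, rng_seed=7)
        trajs = run_replicates(cfg)
        means[cap] = float(
            np.mean(
                [
                    np.mean([r.metrics.n_interactions for r in tr.records[1:]])
                    for tr in trajs
                ]
            )
        )
    return means
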