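"""Shared fixtures, including session-scoped benchmark runs.

The Monte Carlo recovery checks and the qualitative-ordering checks
share the same simulated datasets and fitted models, so those runs are
computed once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from netrl import RunConfig
from netrl.simulate import ScenarioSpec, run_benchmark

#: replication used by the in-suite Monte Carlo checks; the acceptance
#: script runs the same settings at its own (larger) replication.
N_DATASETS_NETRL = 8
N_DATASETS_BASELINE = 20
NETRL_CFG = RunConfig(omega=50, pi_reps=50)


@pytest.fixture(scope="session")
def sit1_results():
    """Per-dataset metrics: netRL-PM, lasso and elastic net, Scenario 1 /
    Situation 1 / u=10 / sigma=1."""
    return run_benchmark(
        ["netrl-beta:pm", "lasso", "elastic-net"],
        [ScenarioSpec(scenario=1, situation=1, u=10, sigma=1.0)],
        n_datasets=N_DATASETS_NETRL,
        seed=1,
        netrl_config=NETRL_CFG,
        per_dataset=True,
    )


@pytest.fixture(scope="session")
def sit2_netrl_results():
    """netRL-PM per-dataset metrics, Scenario 1 / Situation 2 / u=10."""
    return run_benchmark(
        ["netrl-beta:pm"],
        [ScenarioSpec(scenario=1, situation=2, u=10, sigma=1.0)],
        n_datasets=N_DATASETS_NETRL,
        seed=1,
        netrl_config=NETRL_CFG,
        per_dataset=True,
    )


@pytest.fixture(scope="session")
def elastic_net_tables():
    """Elastic-net mean TPR in Situation 1 (u=10) and Situation 2 (u=20)."""
    t1 = run_benchmark(
        ["elastic-net"], [ScenarioSpec(scenario=1, situation=1, u=10)],
        n_datasets=N_DATASETS_BASELINE, seed=1,
    )
    t2 = run_benchmark(
        ["elastic-net"], [ScenarioSpec(scenario=1, situation=2, u=20)],
        n_datasets=N_DATASETS_BASELINE, seed=1,
    )
    return float(t1["tpr"].iloc[0]), float(t2["tpr"].iloc[0])


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
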