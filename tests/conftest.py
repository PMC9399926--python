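"""Shared fixtures: desk-scale configuration and cached simulation batches.

The simulation-heavy batches are session-scoped and shared between the
behavioral tests and the acceptance tests, so each condition is simulated
once per session.
"""
from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

import wtanet as w

DESK_SCALE = 0.5  # 1,000-neuron network with indegree-preserving sparsity


@pytest.fixture(scope="session")
def desk_config() -> w.NetworkConfig:
    return w.default_config().scaled(DESK_SCALE, preserve_indegree=True)


def short_protocol(c: float, reversal=None, t_stim: float = 1000.0) -> w.TrialProtocol:
    """Trial with a trimmed delay: enough to classify the decision."""
    return w.TrialProtocol(coherence=c, t_pre=500.0, t_stim=t_stim, t_post=500.0,
                           reversal=reversal)


@pytest.fixture(scope="session")
def wta_batch(desk_config):
    """40 full-protocol trials at c = -51.2% (population A preferred)."""
    spec = w.ExperimentSpec(
        name="wta", config=desk_config, coherences_pct=(-51.2,), n_trials=40, seed=104,
    )
    return w.run_batch(spec)


@pytest.fixture(scope="session")
def coin_toss_batch(desk_config):
    """200 zero-coherence trials with stimulus fluctuations removed."""
    return w.coin_toss(desk_config, n_trials=200, seed=105, sigma0=0.0, t_post=500.0)


@pytest.fixture(scope="session")
def neurometric_batch(desk_config, wta_batch):
    """40 trials per level for |c| in {3.2 .. 25.6}%, A preferred.

    The 51.2% level reuses the full-protocol winner-take-all batch.
    """
    spec = w.ExperimentSpec(
        name="neurometric", config=desk_config,
        coherences_pct=(-3.2, -6.4, -12.8, -25.6), n_trials=40, seed=106, t_post=500.0,
    )
    df = w.run_batch(spec)
    import pandas as pd

    return pd.concat([df, wta_batch], ignore_index=True)


@pytest.fixture(scope="session")
def rt_zero_batch(desk_config):
    """40 zero-coherence trials with the configured stimulus fluctuations."""
    spec = w.ExperimentSpec(
        name="rt0", config=desk_config, coherences_pct=(0.0,), n_trials=40,
        seed=108, t_post=500.0,
    )
    return w.run_batch(spec)
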