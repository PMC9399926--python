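"""Coherence-coded stimulus rates, background noise rates, and trial timing.

The motion stimulus is a pair of Poisson generators, one per direction,
emulating direction-selective MT input.  Their mean rates follow the
symmetric linear model

    mu_A = mu0 * (0.5 - 0.5 c),    mu_B = mu0 * (0.5 + 0.5 c),

with signed coherence ``c`` in [-1, 1]: positive c favors population B.
During the stimulus the instantaneous rate of each generator is re-drawn
every 25 ms from a Gaussian N(mu, sigma0^2), clipped at zero — the
fluctuating-evidence component of the task.  Setting sigma0 = 0 removes it,
leaving background noise as the only stochastic drive.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import ConfigError, NetworkConfig

__all__ = [
    "coherence_to_means",
    "sample_stimulus_trace",
    "sample_background_rates",
    "TrialProtocol",
    "build_protocol",
    "stimulus_rate_blocks",
]


def coherence_to_means(mu0: float, c: float) -> tuple[float, float]:
    """Mean generator rates (mu_A, mu_B) in Hz for signed coherence c.

    ``c`` is a fraction in [-1, 1] (c = 0.032 for 3.2% coherence); the two
    means always sum to mu0.
    """
    if not -1.0 <= c <= 1.0:
        raise ConfigError(f"coherence must lie in [-1, 1], got {c}")
    return mu0 * (0.5 - 0.5 * c), mu0 * (0.5 + 0.5 * c)


def sample_stimulus_trace(
    mean: float,
    sigma0: float,
    t_stim: float,
    update_interval: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Piecewise-constant rate trace: one clipped Gaussian draw per block.

    Returns ``ceil(t_stim / update_interval)`` rates in Hz.  With
    ``sigma0 = 0`` the trace is deterministic and equal to ``mean``.
    """
    if mean < 0 or sigma0 < 0:
        raise ConfigError("mean and sigma0 must be non-negative")
    n_blocks = math.ceil(t_stim / update_interval)
    if sigma0 == 0:
        return np.full(n_blocks, mean)
    return np.clip(rng.normal(mean, sigma0, size=n_blocks), 0.0, None)


def sample_background_rates(
    n_neurons: int, mu: float, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-neuron background Poisson rates, fixed for a whole trial."""
    if mu <= 0:
        raise ConfigError(f"background mean rate must be positive, got {mu}")
    if sigma == 0:
        return np.full(n_neurons, mu)
    return np.clip(rng.normal(mu, sigma, size=n_neurons), 0.0, None)


@dataclass(frozen=True)
class TrialProtocol:
    """Timing and coherence schedule of one trial.

    ``t_pre`` of spontaneous activity, ``t_stim`` of stimulus, ``t_post`` of
    delay (all ms).  ``reversal``, if set, is ``(t_reverse, c_after)``:
    stimulus blocks starting at or after ``t_reverse`` (measured from
    stimulus onset) use coherence ``c_after``.
    """

    coherence: float
    t_pre: float = 500.0
    t_stim: float = 1000.0
    t_post: float = 1500.0
    reversal: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if min(self.t_pre, self.t_stim, self.t_post) < 0:
            raise ConfigError("all protocol durations must be non-negative")
        if not -1.0 <= self.coherence <= 1.0:
            raise ConfigError(f"coherence must lie in [-1, 1], got {self.coherence}")
        if self.reversal is not None:
            t_rev, c_after = self.reversal
            if not 0.0 <= t_rev <= self.t_stim:
                raise ConfigError(
                    f"reversal time {t_rev} ms outside the stimulus window [0, {self.t_stim}]"
                )
            if not -1.0 <= c_after <= 1.0:
                raise ConfigError(f"post-reversal coherence must lie in [-1, 1], got {c_after}")

    @property
    def t_total(self) -> float:
        return self.t_pre + self.t_stim + self.t_post

    @property
    def stim_onset(self) -> float:
        return self.t_pre

    @property
    def stim_end(self) -> float:
        return self.t_pre + self.t_stim


def build_protocol(
    c: float,
    t_pre: float = 500.0,
    t_stim: float = 1000.0,
    t_post: float = 1500.0,
    reversal: tuple[float, float] | None = None,
) -> TrialProtocol:
    """Convenience constructor validating the schedule."""
    return TrialProtocol(coherence=c, t_pre=t_pre, t_stim=t_stim, t_post=t_post, reversal=reversal)


def stimulus_rate_blocks(
    protocol: TrialProtocol, config: NetworkConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sampled per-block generator rates for one trial.

    Returns ``(block_starts_ms, rates_A, rates_B)``; block starts are
    relative to stimulus onset.  A reversal switches the block means from
    the schedule's initial coherence to ``c_after`` for blocks starting at
    or after ``t_reverse``.  The A and B draws come from the same stream in
    a fixed order (A first), so negating the coherence with the same stream
    swaps the traces.
    """
    n_blocks = math.ceil(protocol.t_stim / config.update_interval)
    starts = np.arange(n_blocks) * config.update_interval
    mu_a, mu_b = coherence_to_means(config.mu0, protocol.coherence)
    means_a = np.full(n_blocks, mu_a)
    means_b = np.full(n_blocks, mu_b)
    if protocol.reversal is not None:
        t_rev, c_after = protocol.reversal
        mu_a2, mu_b2 = coherence_to_means(config.mu0, c_after)
        after = starts >= t_rev
        means_a[after] = mu_a2
        means_b[after] = mu_b2
    if config.sigma0 == 0:
        return starts, means_a, means_b
    draws = rng.normal(0.0, config.sigma0, size=(n_blocks, 2))
    # attach the draw columns by coherence sign so that negating c under the
    # same stream swaps the A and B traces exactly (label symmetry)
    c_key = protocol.coherence
    if c_key == 0 and protocol.reversal is not None:
        c_key = protocol.reversal[1]
    col_a, col_b = (1, 0) if c_key < 0 else (0, 1)
    rates_a = np.clip(means_a + draws[:, col_a], 0.0, None)
    rates_b = np.clip(means_b + draws[:, col_b], 0.0, None)
    return starts, rates_a, rates_b
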