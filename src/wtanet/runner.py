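"""Single-trial orchestration: seeds, input realization, kernel invocation.

A trial is a pure function of (network, protocol, seed).  The master seed
expands through ``numpy.random.SeedSequence`` into fixed-order substreams —
background rates, stimulus rate trace, background input events, stimulus
input events — so results are reproducible regardless of how many of the
streams a given protocol consumes.
"""
from __future__ import annotations

import math

import numpy as np

from .network import Network
from .simulator import SpikeRecord, simulate
from .stimulus import TrialProtocol, sample_background_rates, stimulus_rate_blocks

__all__ = ["trial_streams", "run_network"]

_CHUNK_STEPS = 4000  # Poisson count generation chunk (bounds temporary int64 arrays)


def trial_streams(seed) -> dict[str, np.random.Generator]:
    """Expand one master seed into the trial's named substreams."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(6)
    names = ("connectivity", "background", "stimulus", "noise_events", "stim_events", "init")
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _poisson_counts(
    rng: np.random.Generator, lam_per_step: np.ndarray, n_steps: int, n: int
) -> np.ndarray:
    """(n_steps, n) uint8 Poisson counts, generated in bounded chunks.

    ``lam_per_step`` has shape (n,) — constant in time — or (n_steps, 1) —
    shared across neurons — and is broadcast against (n_steps, n).
    """
    out = np.empty((n_steps, n), dtype=np.uint8)
    for lo in range(0, n_steps, _CHUNK_STEPS):
        hi = min(lo + _CHUNK_STEPS, n_steps)
        lam = lam_per_step if lam_per_step.ndim == 1 else lam_per_step[lo:hi]
        out[lo:hi] = rng.poisson(np.broadcast_to(lam, (hi - lo, n))).astype(np.uint8)
    return out


def run_network(
    network: Network,
    protocol: TrialProtocol,
    seed,
    record_v: np.ndarray | None = None,
) -> SpikeRecord:
    """Simulate one trial and return its complete spike record.

    Identical (network, protocol, seed) triples produce identical records.
    Optionally records the membrane potential of the neurons in ``record_v``
    (exposed as ``record.v_traces``, shape ``(n_steps + 1, n_recorded)``).
    """
    cfg = network.config
    dt = cfg.dt
    n = network.n
    n_steps = int(round(protocol.t_total / dt))
    streams = trial_streams(seed)

    # background: one fixed rate per neuron, active the whole trial
    bg = streams["background"]
    rates = np.empty(n)
    exc_mask = network.cls == 0
    rates[exc_mask] = sample_background_rates(
        int(exc_mask.sum()), cfg.mu_noise_exc, cfg.sigma_noise_exc, bg
    )
    rates[~exc_mask] = sample_background_rates(
        int((~exc_mask).sum()), cfg.mu_noise_inh, cfg.sigma_noise_inh, bg
    )
    noise_counts = _poisson_counts(streams["noise_events"], rates * dt * 1e-3, n_steps, n)

    # stimulus: per-block rates expanded to per-step intensities for A and B
    stim_counts = None
    stim_idx = None
    stim_amp = None
    if protocol.t_stim > 0:
        starts, rates_a, rates_b = stimulus_rate_blocks(protocol, cfg, streams["stimulus"])
        onset_step = int(round(protocol.stim_onset / dt))
        stim_steps = int(round(protocol.t_stim / dt))
        block_steps = int(round(cfg.update_interval / dt))
        block_of = np.minimum(np.arange(stim_steps) // block_steps, len(starts) - 1)
        idx_a = np.asarray(network.populations["A"], dtype=np.int64)
        idx_b = np.asarray(network.populations["B"], dtype=np.int64)
        stim_idx = np.concatenate([idx_a, idx_b])
        stim_counts = np.zeros((n_steps, len(stim_idx)), dtype=np.uint8)
        ev = streams["stim_events"]
        window = slice(onset_step, onset_step + stim_steps)
        stim_counts[window, : len(idx_a)] = _poisson_counts(
            ev, rates_a[block_of, None] * dt * 1e-3, stim_steps, len(idx_a)
        )
        stim_counts[window, len(idx_a) :] = _poisson_counts(
            ev, rates_b[block_of, None] * dt * 1e-3, stim_steps, len(idx_b)
        )
        stim_amp = np.full(len(stim_idx), network.stim_amp_exc)

    # desynchronized start: membrane potentials drawn uniformly between rest
    # and threshold, so the onset of background drive causes no artificial
    # population-wide volley
    v_rest_arr = np.where(exc_mask, cfg.exc.v_rest, cfg.inh.v_rest)
    v_th_arr = np.where(exc_mask, cfg.exc.v_th, cfg.inh.v_th)
    v_init = streams["init"].uniform(v_rest_arr, v_th_arr)

    spk_step, spk_id, v_rec = simulate(
        n_steps=n_steps,
        dt=dt,
        cls=network.cls,
        cell_params=[cfg.exc, cfg.inh],
        port_tau=np.array([p.tau_syn for p in cfg.ports]),
        port_delay=np.array([p.delay for p in cfg.ports]),
        indptr=network.indptr,
        conn_tgt=network.conn_tgt,
        conn_amp=network.conn_amp,
        conn_port=network.conn_port,
        noise_counts=noise_counts,
        noise_amp=network.noise_amp,
        stim_counts=stim_counts,
        stim_idx=stim_idx,
        stim_amp=stim_amp,
        record_v=record_v,
        v_init=v_init,
    )
    record = SpikeRecord(
        times=spk_step * dt,
        neuron_ids=spk_id,
        populations=dict(network.populations),
        t_total=protocol.t_total,
    )
    record.v_traces = v_rec  # type: ignore[attr-defined]
    return record
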