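"""Clock-driven simulator for leaky integrate-and-fire neurons with
multi-port exponential postsynaptic currents.

The subthreshold system is linear, so each step advances membrane potential
and per-port currents with the exact propagator (closed-form exponentials);
the only grid artifacts are threshold detection (checked once per step, the
spike is stamped at the end of the step) and spike delivery (arrivals land on
grid points, exactly ``delay`` after emission).  Poisson input is consumed as
per-step event counts drawn ahead of the run with a seeded generator, which
makes a run a pure function of (configuration, seed).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .config import ConfigError, NeuronParams

__all__ = [
    "psc_amplitude_for_unit_psp",
    "generate_poisson_spikes",
    "connect_pairwise_bernoulli",
    "SpikeRecord",
    "simulate",
]

_ALPHA_LIMIT_TOL = 1e-9  # ms; below this |tau_m - tau_syn| uses the alpha-function limit


def psc_amplitude_for_unit_psp(params: NeuronParams, tau_syn: float) -> float:
    """Peak current (pA) of an exponential PSC whose PSP peaks at 1 mV.

    For a current-based synapse the unitary PSP of a quiescent membrane is

        v(t) = (I0 / C_m) * tau_m * tau_s / (tau_s - tau_m)
               * (exp(-t/tau_s) - exp(-t/tau_m)),

    which peaks at ``t* = ln(tau_m/tau_s) * tau_m tau_s / (tau_m - tau_s)``.
    This returns ``I0`` such that the peak equals exactly 1 mV; callers scale
    by the unitary amplitude J (mV) and the dimensionless weight w.  The
    degenerate limit ``tau_syn == tau_m`` (an alpha function, peak
    ``I0 tau_m / (C_m e)``) is handled in closed form.
    """
    if tau_syn <= 0:
        raise ConfigError(f"tau_syn must be positive, got {tau_syn}")
    tm, cm, ts = params.tau_m, params.c_m, tau_syn
    if abs(tm - ts) < _ALPHA_LIMIT_TOL:
        return cm * math.e / tm
    t_peak = (tm * ts / (tm - ts)) * math.log(tm / ts)
    peak_per_pa = (tm * ts / (cm * (ts - tm))) * (
        math.exp(-t_peak / ts) - math.exp(-t_peak / tm)
    )
    return 1.0 / peak_per_pa


def generate_poisson_spikes(
    rate: float, t_start: float, t_stop: float, rng: np.random.Generator
) -> np.ndarray:
    """Homogeneous Poisson spike times (ms) on ``[t_start, t_stop)``.

    Each call is one independent realization; attach one realization per
    target neuron, never a shared train.
    """
    if rate < 0:
        raise ConfigError(f"rate must be non-negative, got {rate}")
    if t_stop < t_start:
        raise ConfigError("t_stop must be >= t_start")
    if rate == 0 or t_stop == t_start:
        return np.empty(0)
    # draw count then order statistics: exact and vectorized
    n = rng.poisson(rate * (t_stop - t_start) * 1e-3)
    times = rng.uniform(t_start, t_stop, size=n)
    times.sort()
    return times


def connect_pairwise_bernoulli(
    n_source: int,
    n_target: int,
    p: float,
    rng: np.random.Generator,
    same_population: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Random connectivity: each ordered pair connected with probability p.

    Returns (source_ids, target_ids).  When source and target are the same
    population (``same_population``) autapses are excluded.
    """
    if not 0.0 <= p <= 1.0:
        raise ConfigError(f"connection probability must lie in [0, 1], got {p}")
    if p == 0.0 or n_source == 0 or n_target == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    mask = rng.random((n_source, n_target)) < p
    if same_population:
        np.fill_diagonal(mask, False)
    src, tgt = np.nonzero(mask)
    return src.astype(np.int64), tgt.astype(np.int64)


@dataclass
class SpikeRecord:
    """All spikes of one simulation run.

    ``times`` are in ms (non-decreasing), ``neuron_ids`` are global indices,
    and ``populations`` maps a population label to its ``range`` of global
    ids.  ``t_total`` is the simulated horizon in ms.
    """

    times: np.ndarray
    neuron_ids: np.ndarray
    populations: dict[str, range]
    t_total: float

    def __len__(self) -> int:
        return len(self.times)

    def population_of(self, neuron_id: int) -> str:
        for label, rng_ in self.populations.items():
            if neuron_id in rng_:
                return label
        raise KeyError(f"neuron id {neuron_id} outside all populations")

    def select(self, population: str) -> np.ndarray:
        """Spike times (ms) of one population."""
        if population not in self.populations:
            raise KeyError(f"unknown population {population!r}")
        r = self.populations[population]
        mask = (self.neuron_ids >= r.start) & (self.neuron_ids < r.stop)
        return self.times[mask]

    def counts(self) -> dict[str, int]:
        return {label: int(len(self.select(label))) for label in self.populations}


@njit(cache=True)
def _run_kernel(
    n_steps,
    n,
    cls,  # (n,) uint8 cell-class index
    v_rest,
    v_th,
    v_reset,  # (n_cls,) mV
    ref_steps,  # (n_cls,) int64
    prop_v,  # (n_cls,) exp(-dt/tau_m)
    coupling,  # (n_cls, n_ports) mV per pA of port current over one step
    decay,  # (n_ports,) exp(-dt/tau_syn)
    delay_steps,  # (n_ports,) int64
    indptr,
    conn_tgt,
    conn_amp,
    conn_port,  # CSR outgoing connectivity, amp in pA (signed)
    noise_counts,  # (n_steps, n) uint8
    noise_amp,  # (n,) pA per background event
    stim_counts,  # (n_steps, n_stim) uint8
    stim_idx,  # (n_stim,) global neuron ids
    stim_amp,  # (n_stim,) pA per stimulus event
    stim_port,  # int
    ev_step,
    ev_idx,
    ev_port,
    ev_amp,  # extra injected events, sorted by step
    rec_idx,  # (n_rec,) neuron ids whose V is recorded each step
    max_spikes,
    v_init,  # (n,) initial membrane potentials
):
    n_ports = decay.shape[0]
    buf_len = int(delay_steps.max()) + 1
    buf = np.zeros((n_ports, buf_len, n))
    isyn = np.zeros((n_ports, n))
    v = v_init.copy()
    refr = np.zeros(n, dtype=np.int64)
    spk_step = np.empty(max_spikes, dtype=np.int64)
    spk_id = np.empty(max_spikes, dtype=np.int32)
    n_spk = 0
    n_rec = rec_idx.shape[0]
    v_rec = np.zeros((n_steps + 1, n_rec))
    for r in range(n_rec):
        v_rec[0, r] = v[rec_idx[r]]
    n_stim = stim_idx.shape[0]
    n_ev = ev_step.shape[0]
    ev_ptr = 0

    for t in range(n_steps):
        slot = t % buf_len
        # deliver: ring-buffer arrivals, background and stimulus events
        for p in range(n_ports):
            for i in range(n):
                a = buf[p, slot, i]
                if a != 0.0:
                    isyn[p, i] += a
                    buf[p, slot, i] = 0.0
        if noise_counts.shape[0] > 0:
            for i in range(n):
                c = noise_counts[t, i]
                if c > 0:
                    isyn[0, i] += c * noise_amp[i]
        for k in range(n_stim):
            c = stim_counts[t, k]
            if c > 0:
                isyn[stim_port, stim_idx[k]] += c * stim_amp[k]
        while ev_ptr < n_ev and ev_step[ev_ptr] == t:
            isyn[ev_port[ev_ptr], ev_idx[ev_ptr]] += ev_amp[ev_ptr]
            ev_ptr += 1
        # integrate: exact propagator over [t, t+dt] using currents at t
        for i in range(n):
            ci = cls[i]
            if refr[i] > 0:
                refr[i] -= 1
                v[i] = v_reset[ci]
            else:
                acc = 0.0
                for p in range(n_ports):
                    acc += coupling[ci, p] * isyn[p, i]
                vi = v_rest[ci] + (v[i] - v_rest[ci]) * prop_v[ci] + acc
                if vi >= v_th[ci]:
                    if n_spk >= max_spikes:
                        return spk_step[:n_spk], spk_id[:n_spk], v_rec, True
                    spk_step[n_spk] = t + 1
                    spk_id[n_spk] = i
                    n_spk += 1
                    v[i] = v_reset[ci]
                    refr[i] = ref_steps[ci]
                    for k in range(indptr[i], indptr[i + 1]):
                        p = conn_port[k]
                        buf[p, (t + 1 + delay_steps[p]) % buf_len, conn_tgt[k]] += conn_amp[k]
                else:
                    v[i] = vi
        # decay currents to their start-of-next-step values
        for p in range(n_ports):
            d = decay[p]
            for i in range(n):
                isyn[p, i] *= d
        for r in range(n_rec):
            v_rec[t + 1, r] = v[rec_idx[r]]

    return spk_step[:n_spk], spk_id[:n_spk], v_rec, False


def subthreshold_coupling(params: NeuronParams, tau_syn: float, dt: float) -> float:
    """Exact-propagator voltage increment (mV) per pA of port current.

    Closed-form solution of the membrane equation driven by one exponential
    current over one step; degenerates to the alpha-function limit when
    ``tau_syn == tau_m``.
    """
    tm, cm, ts = params.tau_m, params.c_m, tau_syn
    if abs(tm - ts) < _ALPHA_LIMIT_TOL:
        return (dt / cm) * math.exp(-dt / tm)
    a = tm * ts / (cm * (ts - tm))
    return a * (math.exp(-dt / ts) - math.exp(-dt / tm))


def simulate(
    n_steps: int,
    dt: float,
    cls: np.ndarray,
    cell_params: list[NeuronParams],
    port_tau: np.ndarray,
    port_delay: np.ndarray,
    indptr: np.ndarray,
    conn_tgt: np.ndarray,
    conn_amp: np.ndarray,
    conn_port: np.ndarray,
    noise_counts: np.ndarray | None = None,
    noise_amp: np.ndarray | None = None,
    stim_counts: np.ndarray | None = None,
    stim_idx: np.ndarray | None = None,
    stim_amp: np.ndarray | None = None,
    stim_port: int = 1,
    ext_events: np.ndarray | None = None,
    record_v: np.ndarray | None = None,
    v_init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Low-level entry point around the compiled kernel.

    Parameters are pre-assembled arrays (see :mod:`wtanet.network` for the
    builder that produces them).  ``ext_events`` is an ``(n_ev, 4)`` float
    array of rows ``(step, neuron, port, amplitude_pA)`` injected directly
    into the port current at the given step — the hook used to probe single
    PSPs.  Returns ``(spike_steps, spike_ids, v_traces)``.
    """
    n = len(cls)
    n_ports = len(port_tau)
    for d in port_delay:
        if d < dt:
            raise ConfigError(f"synaptic delay {d} ms smaller than dt {dt} ms")
    v_rest = np.array([p.v_rest for p in cell_params])
    v_th = np.array([p.v_th for p in cell_params])
    v_reset = np.array([p.v_reset for p in cell_params])
    ref_steps = np.array([int(round(p.t_ref / dt)) for p in cell_params], dtype=np.int64)
    prop_v = np.array([math.exp(-dt / p.tau_m) for p in cell_params])
    coupling = np.array(
        [[subthreshold_coupling(p, ts, dt) for ts in port_tau] for p in cell_params]
    )
    decay = np.exp(-dt / np.asarray(port_tau, dtype=np.float64))
    delay_steps = np.array([int(round(d / dt)) for d in port_delay], dtype=np.int64)

    if noise_counts is None:
        noise_counts = np.zeros((0, n), dtype=np.uint8)
        noise_amp = np.zeros(n)
    if stim_counts is None:
        stim_counts = np.zeros((n_steps, 0), dtype=np.uint8)
        stim_idx = np.zeros(0, dtype=np.int64)
        stim_amp = np.zeros(0)
    if ext_events is None or len(ext_events) == 0:
        ev_step = np.zeros(0, dtype=np.int64)
        ev_idx = np.zeros(0, dtype=np.int64)
        ev_port = np.zeros(0, dtype=np.int64)
        ev_amp = np.zeros(0)
    else:
        ev = np.asarray(ext_events, dtype=np.float64)
        order = np.argsort(ev[:, 0], kind="stable")
        ev = ev[order]
        ev_step = ev[:, 0].astype(np.int64)
        ev_idx = ev[:, 1].astype(np.int64)
        ev_port = ev[:, 2].astype(np.int64)
        ev_amp = ev[:, 3]
    if record_v is None:
        record_v = np.zeros(0, dtype=np.int64)
    if v_init is None:
        v_init = np.array([cell_params[c].v_rest for c in cls])
    # generous cap: 500 Hz sustained mean rate across the whole network
    max_spikes = int(n * n_steps * dt * 0.5) + 10_000

    spk_step, spk_id, v_rec, overflow = _run_kernel(
        n_steps,
        n,
        np.ascontiguousarray(cls, dtype=np.uint8),
        v_rest,
        v_th,
        v_reset,
        ref_steps,
        prop_v,
        coupling,
        decay,
        delay_steps,
        np.ascontiguousarray(indptr, dtype=np.int64),
        np.ascontiguousarray(conn_tgt, dtype=np.int64),
        np.ascontiguousarray(conn_amp, dtype=np.float64),
        np.ascontiguousarray(conn_port, dtype=np.int64),
        np.ascontiguousarray(noise_counts, dtype=np.uint8),
        np.ascontiguousarray(noise_amp, dtype=np.float64),
        np.ascontiguousarray(stim_counts, dtype=np.uint8),
        np.ascontiguousarray(stim_idx, dtype=np.int64),
        np.ascontiguousarray(stim_amp, dtype=np.float64),
        stim_port,
        ev_step,
        ev_idx,
        ev_port,
        ev_amp,
        np.ascontiguousarray(record_v, dtype=np.int64),
        max_spikes,
        np.ascontiguousarray(v_init, dtype=np.float64),
    )
    if overflow:
        raise RuntimeError(
            "spike buffer overflow: network mean rate exceeded 500 Hz "
            "(runaway excitation — check weights)"
        )
    return spk_step, spk_id, v_rec
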