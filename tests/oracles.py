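"""Independent dense-step reference integrators used as test oracles.

These integrate the same subthreshold system as the production kernel with
a generic second-order (Heun) scheme at a microsecond step — deliberately
independent of the exact-propagator code path they check (the synaptic
currents decay analytically, which is exact for any scheme).
"""
from __future__ import annotations

import numpy as np

from wtanet.config import NeuronParams


def dense_subthreshold(
    params: NeuronParams,
    events: list[tuple[float, float, float]],
    t_stop: float,
    dt: float = 1e-3,
    v0: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Heun integration of the current-based membrane without threshold.

    ``events`` are ``(time_ms, tau_syn_ms, amplitude_pA)`` instantaneous
    jumps of an exponential synaptic current; an event at time t is part of
    the current driving the interval [t, t + dt).  Returns (times, v).
    """
    n = int(round(t_stop / dt))
    taus = sorted({ev[1] for ev in events})
    idx = {tau: k for k, tau in enumerate(taus)}
    decay = np.exp(-dt / np.array(taus)) if taus else np.empty(0)
    i_syn = np.zeros(len(taus))
    ev = sorted(events)
    v = params.v_rest if v0 is None else v0
    out = np.empty(n + 1)
    out[0] = v
    times = np.arange(n + 1) * dt
    ptr = 0
    inv_tau = 1.0 / params.tau_m
    inv_c = 1.0 / params.c_m
    for step in range(n):
        t = step * dt
        while ptr < len(ev) and ev[ptr][0] <= t + 1e-12:
            i_syn[idx[ev[ptr][1]]] += ev[ptr][2]
            ptr += 1
        i0 = i_syn.sum()
        i_syn_next = i_syn * decay
        i1 = i_syn_next.sum()
        f0 = -(v - params.v_rest) * inv_tau + i0 * inv_c
        v_pred = v + dt * f0
        f1 = -(v_pred - params.v_rest) * inv_tau + i1 * inv_c
        v = v + 0.5 * dt * (f0 + f1)
        i_syn = i_syn_next
        out[step + 1] = v
    return times, out


def dense_psp_peak(
    params: NeuronParams, tau_syn: float, amplitude: float, dt: float = 1e-3
) -> float:
    """Peak deflection (mV) of a single PSP, located by dense integration."""
    # the PSP peaks before max(tau_m, tau_syn); integrate past it
    horizon = 2.0 * (params.tau_m + tau_syn)
    _, v = dense_subthreshold(params, [(0.0, tau_syn, amplitude)], horizon, dt=dt)
    return float(np.max(v - params.v_rest))
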