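"""Construction of the two-population decision circuit.

Populations A and B (excitatory, direction-selective) and I (inhibitory)
are wired by pairwise-Bernoulli random connectivity.  Every excitatory
projection carries both an AMPA and an NMDA component; inhibition is GABA;
external Poisson drive (background noise to everyone, the two stimulus
generators to A and B) enters through AMPA-like ports.  Synaptic current
amplitudes are normalized per (receptor, target cell class) so that one
presynaptic spike at weight w deflects the postsynaptic membrane by exactly
J * w millivolts at its peak.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ConfigError, NetworkConfig, Port
from .simulator import connect_pairwise_bernoulli, psc_amplitude_for_unit_psp

__all__ = ["SynapseGroup", "Network", "projection_table", "build"]

_GENERATORS = ("noise", "stim_A", "stim_B")


@dataclass(frozen=True)
class SynapseGroup:
    """One population-to-population projection (or generator attachment).

    ``epsilon`` is the Bernoulli connection probability for recurrent groups
    and ``None`` for generator groups, which attach one independent Poisson
    source per target neuron.
    """

    source: str
    target: str
    port: Port
    epsilon: float | None
    w: float
    j: float  # mV, unitary PSP amplitude target

    @property
    def is_generator(self) -> bool:
        return self.source in _GENERATORS


def projection_table(config: NetworkConfig) -> list[SynapseGroup]:
    """The full wiring diagram implied by the weight multipliers.

    Within-population recurrent excitation is potentiated (AMPA by w_plus if
    configured, NMDA by w_nmda); cross-population excitation is depressed by
    w_minus on both components; excitatory drive onto the interneurons is
    potentiated by w_plus; GABA feedback onto the excitatory pools carries
    the tuned w_ie, recurrent inhibition w_ii, background generators
    w_noise.
    """
    eps, j = config.epsilon, config.j
    w_within_ampa = config.w_plus if config.potentiate_within_ampa else 1.0
    groups: list[SynapseGroup] = []
    for pop in ("A", "B"):
        other = "B" if pop == "A" else "A"
        groups += [
            SynapseGroup(pop, pop, Port.AMPA, eps, w_within_ampa, j),
            SynapseGroup(pop, pop, Port.NMDA, eps, config.w_nmda, j),
            SynapseGroup(pop, other, Port.AMPA, eps, config.w_minus, j),
            SynapseGroup(pop, other, Port.NMDA, eps, config.w_minus, j),
            SynapseGroup(pop, "I", Port.AMPA, eps, config.w_plus, j),
            SynapseGroup(pop, "I", Port.NMDA, eps, config.w_plus, j),
        ]
    for tgt in ("A", "B"):
        groups.append(SynapseGroup("I", tgt, Port.GABA, eps, config.w_ie, j))
    groups.append(SynapseGroup("I", "I", Port.GABA, eps, config.w_ii, j))
    for tgt in ("A", "B", "I"):
        groups.append(SynapseGroup("noise", tgt, Port.NOISE, None, config.w_noise, j))
    groups.append(SynapseGroup("stim_A", "A", Port.AMPA, None, config.w_stim, j))
    groups.append(SynapseGroup("stim_B", "B", Port.AMPA, None, config.w_stim, j))
    for g in groups:
        if g.target not in ("A", "B", "I") or (
            not g.is_generator and g.source not in ("A", "B", "I")
        ):
            raise ConfigError(f"unknown population label in group {g}")
    return groups


@dataclass
class Network:
    """A fully instantiated network, ready for :func:`wtanet.runner.run_network`.

    Holds the per-neuron class index, population id ranges, the outgoing CSR
    connectivity (targets, signed current amplitudes in pA, port per
    connection) and the per-target generator amplitudes.
    """

    config: NetworkConfig
    cls: np.ndarray  # (n,) 0 = excitatory, 1 = inhibitory
    populations: dict[str, range]
    indptr: np.ndarray
    conn_tgt: np.ndarray
    conn_amp: np.ndarray
    conn_port: np.ndarray
    noise_amp: np.ndarray  # (n,) pA per background event (NOISE port)
    stim_amp_exc: float  # pA per stimulus event on an excitatory cell
    audit: dict[str, int] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.cls)

    def summary(self) -> dict:
        """JSON-serialisable audit of sizes, groups and realized counts."""
        return {
            "populations": {k: [r.start, r.stop] for k, r in self.populations.items()},
            "n_total": self.n,
            "n_connections": int(len(self.conn_tgt)),
            "groups": dict(self.audit),
        }


def _unit_amp(config: NetworkConfig, port: Port, target_class: str) -> float:
    """Signed current amplitude (pA) producing a J-mV PSP peak at weight 1."""
    params = config.exc if target_class == "excitatory" else config.inh
    port_spec = config.port(port)
    return port_spec.sign * config.j * psc_amplitude_for_unit_psp(params, port_spec.tau_syn)


def build(config: NetworkConfig, rng: np.random.Generator | int | None = None) -> Network:
    """Instantiate neurons and random connectivity for ``config``.

    ``rng`` seeds the connectivity draw only; trial-level randomness
    (background rates, stimulus traces, input spikes) is supplied at run
    time.
    """
    rng = np.random.default_rng(rng)
    sizes = {"A": config.n_a, "B": config.n_b, "I": config.n_i}
    offsets, start = {}, 0
    for label in ("A", "B", "I"):
        offsets[label] = start
        start += sizes[label]
    n = start
    populations = {label: range(offsets[label], offsets[label] + sizes[label]) for label in sizes}
    cls = np.zeros(n, dtype=np.uint8)
    cls[offsets["I"]:] = 1
    class_of = {"A": "excitatory", "B": "excitatory", "I": "inhibitory"}

    src_all: list[np.ndarray] = []
    tgt_all: list[np.ndarray] = []
    amp_all: list[np.ndarray] = []
    port_all: list[np.ndarray] = []
    audit: dict[str, int] = {}
    for g in projection_table(config):
        if g.is_generator:
            continue
        src, tgt = connect_pairwise_bernoulli(
            sizes[g.source], sizes[g.target], g.epsilon, rng,
            same_population=(g.source == g.target),
        )
        amp = g.w * _unit_amp(config, g.port, class_of[g.target])
        src_all.append(src + offsets[g.source])
        tgt_all.append(tgt + offsets[g.target])
        amp_all.append(np.full(len(src), amp))
        port_all.append(np.full(len(src), int(g.port), dtype=np.int64))
        audit[f"{g.source}->{g.target}:{g.port.name}"] = len(src)

    if src_all:
        src = np.concatenate(src_all)
        tgt = np.concatenate(tgt_all)
        amp = np.concatenate(amp_all)
        port = np.concatenate(port_all)
    else:
        src = tgt = port = np.empty(0, dtype=np.int64)
        amp = np.empty(0)
    order = np.argsort(src, kind="stable")
    src, tgt, amp, port = src[order], tgt[order], amp[order], port[order]
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(indptr, src + 1, 1)
    indptr = np.cumsum(indptr)

    noise_amp = config.w_noise * np.where(
        cls == 0,
        _unit_amp(config, Port.NOISE, "excitatory"),
        _unit_amp(config, Port.NOISE, "inhibitory"),
    )
    stim_amp_exc = config.w_stim * _unit_amp(config, Port.AMPA, "excitatory")
    return Network(
        config=config,
        cls=cls,
        populations=populations,
        indptr=indptr,
        conn_tgt=tgt,
        conn_amp=amp,
        conn_port=port,
        noise_amp=noise_amp,
        stim_amp_exc=stim_amp_exc,
        audit=audit,
    )
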