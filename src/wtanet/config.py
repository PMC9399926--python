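"""Network configuration: cell parameters, receptor ports, weights, input rates.

The defaults reproduce a cortical two-population decision circuit: two
excitatory pools (A, B) of 800 pyramidal cells each, selective for the two
motion directions, and one pool of 400 interneurons providing shared feedback
inhibition.  Synapses are static current-based exponential PSCs on four
receptor ports (background noise, AMPA, NMDA, GABA); the slow NMDA time
constant (100 ms) on recurrent excitation is what lets the circuit integrate
evidence over hundreds of milliseconds.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Any, Mapping

__all__ = [
    "Port",
    "NeuronParams",
    "ReceptorPort",
    "PopulationSpec",
    "NetworkConfig",
    "default_config",
    "ConfigError",
]


class ConfigError(ValueError):
    """Raised when a configuration value violates an invariant."""


class Port(IntEnum):
    """Receptor channel identifiers (one exponential PSC per port)."""

    NOISE = 0
    AMPA = 1
    NMDA = 2
    GABA = 3


@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire membrane constants for one cell class.

    Attributes
    ----------
    v_rest : float
        Resting (leak) potential, mV.
    v_th : float
        Spike threshold, mV.
    v_reset : float
        Post-spike reset potential, mV.
    tau_m : float
        Membrane time constant, ms.
    c_m : float
        Membrane capacitance, pF.
    t_ref : float
        Absolute refractory period, ms.
    """

    v_rest: float
    v_th: float
    v_reset: float
    tau_m: float
    c_m: float
    t_ref: float

    def __post_init__(self) -> None:
        if not self.v_reset < self.v_th:
            raise ConfigError(f"v_reset ({self.v_reset}) must be below v_th ({self.v_th})")
        if self.tau_m <= 0:
            raise ConfigError(f"tau_m must be positive, got {self.tau_m}")
        if self.c_m <= 0:
            raise ConfigError(f"c_m must be positive, got {self.c_m}")
        if self.t_ref < 0:
            raise ConfigError(f"t_ref must be non-negative, got {self.t_ref}")


@dataclass(frozen=True)
class ReceptorPort:
    """One synaptic channel: label, decay time constant, delay and sign."""

    label: Port
    tau_syn: float  # ms
    delay: float  # ms
    sign: int  # +1 depolarizing, -1 hyperpolarizing

    def __post_init__(self) -> None:
        if self.tau_syn <= 0:
            raise ConfigError(f"tau_syn must be positive, got {self.tau_syn}")
        if self.delay <= 0:
            raise ConfigError(f"delay must be positive, got {self.delay}")
        if (self.sign == -1) != (self.label == Port.GABA):
            raise ConfigError("sign must be -1 exactly for the GABA port")


@dataclass(frozen=True)
class PopulationSpec:
    label: str  # "A", "B" or "I"
    size: int
    cell_class: str  # "excitatory" | "inhibitory"


@dataclass(frozen=True)
class NetworkConfig:
    """Full parameterization of the decision network and its inputs.

    All times in ms, potentials in mV, capacitances in pF, rates in Hz.
    """

    # population sizes (2:2:1 ratio at full scale)
    n_a: int = 800
    n_b: int = 800
    n_i: int = 400

    exc: NeuronParams = NeuronParams(
        v_rest=-70.0, v_th=-50.0, v_reset=-55.0, tau_m=20.0, c_m=500.0, t_ref=2.0
    )
    inh: NeuronParams = NeuronParams(
        v_rest=-70.0, v_th=-50.0, v_reset=-55.0, tau_m=10.0, c_m=200.0, t_ref=1.0
    )

    ports: tuple[ReceptorPort, ...] = (
        ReceptorPort(Port.NOISE, tau_syn=5.0, delay=0.5, sign=+1),
        ReceptorPort(Port.AMPA, tau_syn=2.0, delay=0.5, sign=+1),
        ReceptorPort(Port.NMDA, tau_syn=100.0, delay=2.5, sign=+1),
        ReceptorPort(Port.GABA, tau_syn=5.0, delay=0.5, sign=-1),
    )

    # unitary PSP amplitude and dimensionless weight multipliers
    j: float = 0.04  # mV
    w_plus: float = 1.7  # within-population (recurrent) potentiation
    w_minus: float = 0.8  # cross-population depression
    w_nmda: float = 4.25  # within-population recurrent NMDA potentiation
    # tuned multipliers with no printed reference value: inhibitory feedback
    # onto the excitatory pools (w_ie) must roughly balance the slow NMDA
    # self-excitation for the spontaneous state to be viable; w_ii and
    # w_noise complete the calibration (see docs/methods.md)
    w_ie: float = 12.0
    w_ii: float = 1.0
    w_noise: float = 1.7
    w_stim: float = 1.0
    # whether w_plus also potentiates the AMPA component of within-population
    # recurrent excitation (NMDA always carries w_nmda)
    potentiate_within_ampa: bool = True

    # recurrent connection probability (pairwise Bernoulli)
    epsilon: float = 0.1

    # stimulus model
    mu0: float = 772.0  # Hz, summed mean rate of the two stimulus generators
    sigma0: float = 48.0  # Hz, SD of the 25 ms rate resampling
    update_interval: float = 25.0  # ms

    # background noise (independent Poisson input to every neuron)
    mu_noise_exc: float = 7719.0
    sigma_noise_exc: float = 38.0
    mu_noise_inh: float = 5789.0
    sigma_noise_inh: float = 28.0

    dt: float = 0.1  # ms, simulation step

    def __post_init__(self) -> None:
        if min(self.n_a, self.n_b, self.n_i) < 1:
            raise ConfigError("population sizes must be positive")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ConfigError(f"epsilon must lie in [0, 1], got {self.epsilon}")
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        if self.j < 0:
            raise ConfigError("j must be non-negative")
        for p in self.ports:
            if p.delay < self.dt:
                raise ConfigError(
                    f"port {p.label.name}: delay {p.delay} ms smaller than dt {self.dt} ms"
                )
        if self.mu_noise_exc <= 0 or self.mu_noise_inh <= 0:
            raise ConfigError("background noise means must be positive")

    # -- convenience ----------------------------------------------------

    @property
    def n_total(self) -> int:
        return self.n_a + self.n_b + self.n_i

    @property
    def populations(self) -> tuple[PopulationSpec, ...]:
        return (
            PopulationSpec("A", self.n_a, "excitatory"),
            PopulationSpec("B", self.n_b, "excitatory"),
            PopulationSpec("I", self.n_i, "inhibitory"),
        )

    def port(self, label: Port) -> ReceptorPort:
        return self.ports[int(label)]

    def scaled(self, scale: float, preserve_indegree: bool = False) -> "NetworkConfig":
        """Return a copy with population sizes multiplied by ``scale``.

        The 2:2:1 A:B:I ratio is preserved.  With ``preserve_indegree`` the
        connection probability is divided by ``scale`` so every neuron keeps
        its expected number of recurrent afferents (the recurrent drive per
        cell is then unchanged, at the cost of a denser graph).
        """
        if scale <= 0:
            raise ConfigError("scale must be positive")
        eps = self.epsilon / scale if preserve_indegree else self.epsilon
        if eps > 1.0:
            raise ConfigError(f"indegree-preserving scale {scale} needs epsilon {eps} > 1")
        return replace(
            self,
            n_a=round(self.n_a * scale),
            n_b=round(self.n_b * scale),
            n_i=round(self.n_i * scale),
            epsilon=eps,
        )

    # -- (de)serialisation ----------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        def conv(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, Port):
                return obj.name
            if isinstance(obj, tuple):
                return [conv(x) for x in obj]
            return obj

        out = {}
        for f in dataclasses.fields(self):
            if f.name == "ports":
                out["ports"] = {
                    p.label.name: {"tau_syn": p.tau_syn, "delay": p.delay, "sign": p.sign}
                    for p in self.ports
                }
            else:
                out[f.name] = conv(getattr(self, f.name))
        return out

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "NetworkConfig":
        """Build a config from a (possibly partial) mapping; unknown keys fail."""
        known = {f.name: f for f in dataclasses.fields(cls)}
        kwargs: dict[str, Any] = {}
        for key, value in data.items():
            if key not in known:
                raise ConfigError(f"unknown configuration key: {key!r}")
            if key in ("exc", "inh"):
                base = dataclasses.asdict(getattr(cls(), key))
                extra = set(value) - set(base)
                if extra:
                    raise ConfigError(f"unknown {key} neuron keys: {sorted(extra)}")
                base.update(value)
                kwargs[key] = NeuronParams(**base)
            elif key == "ports":
                default = {p.label.name: p for p in cls().ports}
                for name, pdata in value.items():
                    if name not in default:
                        raise ConfigError(f"unknown port: {name!r}")
                    old = default[name]
                    default[name] = ReceptorPort(
                        label=old.label,
                        tau_syn=pdata.get("tau_syn", old.tau_syn),
                        delay=pdata.get("delay", old.delay),
                        sign=pdata.get("sign", old.sign),
                    )
                kwargs[key] = tuple(default[p.name] for p in Port)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def default_config() -> NetworkConfig:
    """The reference parameterization of the 2,000-neuron network."""
    return NetworkConfig()
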