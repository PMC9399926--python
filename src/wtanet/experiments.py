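"""Scripted experiment battery: batch trials, coin toss, ablations,
stimulus-duration and decision-reversal sweeps.

Every trial is independent: connectivity, background rates, stimulus
fluctuations and input spikes are all redrawn from a per-trial seed derived
deterministically from the experiment's master seed, so a batch is exactly
reproducible and control/ablation pairs can share their randomness
trial-for-trial (differences are then attributable to the single overridden
parameter).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .analysis import (
    DECISION_THRESHOLD_HZ,
    RateTrace,
    TrialOutcome,
    classify_decision,
    population_rate,
)
from .config import ConfigError, NetworkConfig, Port, ReceptorPort, default_config
from .network import build
from .runner import run_network
from .simulator import SpikeRecord
from .stimulus import TrialProtocol

__all__ = [
    "ExperimentSpec",
    "run_trial",
    "run_batch",
    "coin_toss",
    "duration_sweep",
    "reversal_sweep",
    "ablation_run",
    "apply_ablation",
    "COHERENCE_LEVELS_PCT",
]

# the canonical coherence sweep (percent, population B's preferred direction
# positive)
COHERENCE_LEVELS_PCT = (3.2, 6.4, 12.8, 25.6, 51.2)


@dataclass(frozen=True)
class ExperimentSpec:
    """Declarative description of one batch experiment."""

    name: str
    config: NetworkConfig = field(default_factory=default_config)
    coherences_pct: tuple[float, ...] = COHERENCE_LEVELS_PCT
    n_trials: int = 100
    seed: int = 0
    t_pre: float = 500.0
    t_stim: float = 1000.0
    t_post: float = 1500.0
    reversal: tuple[float, float] | None = None

    def protocol(self, c_pct: float) -> TrialProtocol:
        return TrialProtocol(
            coherence=c_pct / 100.0,
            t_pre=self.t_pre,
            t_stim=self.t_stim,
            t_post=self.t_post,
            reversal=self.reversal,
        )


def _trial_seed(master: int, *indices: int) -> list[int]:
    """Deterministic per-trial entropy for numpy's SeedSequence."""
    return [int(master)] + [int(i) for i in indices]


def run_trial(
    config: NetworkConfig,
    protocol: TrialProtocol,
    seed,
    keep_traces: bool = False,
    keep_spikes: bool = False,
    rate_window: float = 50.0,
    rate_step: float = 5.0,
) -> tuple[TrialOutcome, dict[str, RateTrace] | None, SpikeRecord | None]:
    """Build a fresh network, simulate one trial and classify it."""
    ss = np.random.SeedSequence(seed)
    conn_ss, run_ss = ss.spawn(2)
    net = build(config, rng=np.random.default_rng(conn_ss))
    record = run_network(net, protocol, seed=run_ss)
    traces = {
        lbl: population_rate(record, lbl, window=rate_window, step=rate_step)
        for lbl in ("A", "B")
    }
    outcome = classify_decision(
        traces["A"],
        traces["B"],
        stim_onset=protocol.stim_onset,
        stim_end=protocol.stim_end,
        coherence=protocol.coherence,
    )
    return (
        outcome,
        traces if keep_traces else None,
        record if keep_spikes else None,
    )


def _row(outcome: TrialOutcome, trial_id: int, seed_repr: str) -> dict:
    return {
        "trial_id": trial_id,
        "coherence_pct": outcome.coherence * 100.0,
        "seed": seed_repr,
        "winner": outcome.winner,
        "correct": outcome.correct,
        "decision_time_ms": outcome.decision_time,
        "persisted": outcome.persisted,
        "peak_rate_winner": outcome.peak_rate_winner,
        "end_rate_winner": outcome.end_rate_winner,
        "final_choice": outcome.final_choice,
    }


def run_batch(spec: ExperimentSpec, keep_traces: bool = False):
    """One independent trial per (coherence level, trial index).

    Returns a trial-summary DataFrame (and the per-trial B traces when
    ``keep_traces``).  Failed trials (e.g. runaway under an extreme
    configuration) are recorded with winner ``"error"`` rather than raised.
    """
    rows = []
    traces_out: list[tuple[TrialOutcome, RateTrace]] = []
    trial_id = 0
    for li, c_pct in enumerate(spec.coherences_pct):
        proto = spec.protocol(c_pct)
        for k in range(spec.n_trials):
            seed = _trial_seed(spec.seed, li, k)
            try:
                outcome, traces, _ = run_trial(
                    spec.config, proto, seed, keep_traces=keep_traces
                )
            except RuntimeError as exc:
                rows.append(
                    {"trial_id": trial_id, "coherence_pct": c_pct, "seed": str(seed),
                     "winner": "error", "correct": None, "decision_time_ms": None,
                     "persisted": None, "peak_rate_winner": None,
                     "end_rate_winner": None, "final_choice": "none"}
                )
                trial_id += 1
                continue
            rows.append(_row(outcome, trial_id, str(seed)))
            if keep_traces:
                traces_out.append((outcome, traces["B"]))
            trial_id += 1
    columns = ["trial_id", "coherence_pct", "seed", "winner", "correct",
               "decision_time_ms", "persisted", "peak_rate_winner",
               "end_rate_winner", "final_choice"]
    df = pd.DataFrame(rows, columns=columns)
    return (df, traces_out) if keep_traces else df


def neurometric_table(df: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a batch into (coherence_pct, n_trials, n_decided, pct_correct)."""
    out = []
    for c_pct, grp in df.groupby("coherence_pct"):
        decided = grp[grp["winner"].isin(["A", "B"])]
        n_corr = int((decided["correct"] == True).sum())  # noqa: E712
        out.append(
            {
                "coherence_pct": float(c_pct),
                "n_trials": len(grp),
                "n_decided": len(decided),
                "pct_correct": n_corr / len(decided) if len(decided) else np.nan,
            }
        )
    return pd.DataFrame(out).sort_values("coherence_pct", ignore_index=True)


def coin_toss(
    config: NetworkConfig,
    n_trials: int,
    seed: int = 0,
    sigma0: float | None = 0.0,
    t_pre: float = 500.0,
    t_stim: float = 1000.0,
    t_post: float = 1500.0,
) -> dict:
    """Zero-coherence trials: which population does noise alone favor?

    ``sigma0 = 0`` (the default here) removes the stimulus fluctuations so
    background noise is the only stochastic drive; pass ``None`` to keep
    the configured sigma0.  Returns percentages of A- and B-wins among
    decided trials.
    """
    cfg = config if sigma0 is None else replace(config, sigma0=sigma0)
    spec = ExperimentSpec(
        name="coin_toss", config=cfg, coherences_pct=(0.0,), n_trials=n_trials,
        seed=seed, t_pre=t_pre, t_stim=t_stim, t_post=t_post,
    )
    df = run_batch(spec)
    n_a = int((df["winner"] == "A").sum())
    n_b = int((df["winner"] == "B").sum())
    decided = n_a + n_b
    return {
        "n_trials": n_trials,
        "n_decided": decided,
        "n_undecided": int(n_trials - decided),
        "pct_a": 100.0 * n_a / decided if decided else np.nan,
        "pct_b": 100.0 * n_b / decided if decided else np.nan,
        "trials": df,
    }


def duration_sweep(
    config: NetworkConfig,
    durations: tuple[float, ...] = (500.0, 700.0, 900.0, 1000.0),
    c_pct: float = -12.8,
    n_trials: int = 20,
    seed: int = 0,
    t_pre: float = 500.0,
    t_post: float = 1500.0,
) -> pd.DataFrame:
    """Decided/persistent fractions as a function of stimulus duration.

    Shorter stimuli give the attractor less time to capture the dynamics,
    reducing the decided fraction.  Trials share seeds across durations.
    """
    rows = []
    for duration in durations:
        if duration < 0:
            raise ConfigError("durations must be non-negative")
        spec = ExperimentSpec(
            name=f"duration_{duration:g}", config=config, coherences_pct=(c_pct,),
            n_trials=n_trials, seed=seed, t_pre=t_pre, t_stim=duration, t_post=t_post,
        )
        df = run_batch(spec)
        decided = df["winner"].isin(["A", "B"])
        rows.append(
            {
                "duration_ms": duration,
                "n_trials": n_trials,
                "frac_decided": float(decided.mean()),
                "frac_persistent": float((df["persisted"] == True).mean()),  # noqa: E712
                "frac_correct_of_decided": float(
                    (df.loc[decided, "correct"] == True).mean()  # noqa: E712
                ) if decided.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)


def reversal_sweep(
    config: NetworkConfig,
    conditions: list[dict],
    n_trials: int = 20,
    seed: int = 0,
    t_pre: float = 500.0,
    t_post: float = 1500.0,
) -> pd.DataFrame:
    """Choice percentages under mid-stimulus coherence reversal.

    Each condition is ``{"c_pct": ..., "t_reverse": ..., "c_after_pct": ...,
    "t_stim": ...}`` (``t_reverse`` measured from stimulus onset;
    ``t_reverse == t_stim`` degenerates to no reversal).  The two canonical
    batteries are the reversal-time sweep (-6.4% flipped to +6.4% at 300,
    500, 700, 900, 1000 ms) and the reversal-intensity sweep (+12.8% for
    1 s, then increasingly negative coherence).
    """
    rows = []
    for cond in conditions:
        t_stim = float(cond.get("t_stim", 1000.0))
        t_rev = float(cond["t_reverse"])
        reversal = None
        if t_rev < t_stim:
            reversal = (t_rev, cond["c_after_pct"] / 100.0)
        spec = ExperimentSpec(
            name="reversal", config=config, coherences_pct=(cond["c_pct"],),
            n_trials=n_trials, seed=seed, t_pre=t_pre, t_stim=t_stim,
            t_post=t_post, reversal=reversal,
        )
        df = run_batch(spec)
        # the behavioral choice is the population dominating at trial end
        # (a strong reversal can displace an earlier threshold crossing)
        n_a = int((df["final_choice"] == "A").sum())
        n_b = int((df["final_choice"] == "B").sum())
        decided = n_a + n_b
        rows.append(
            {
                "c_pct": cond["c_pct"],
                "t_reverse_ms": t_rev,
                "c_after_pct": cond.get("c_after_pct", cond["c_pct"]),
                "n_trials": n_trials,
                "n_decided": decided,
                "pct_a": 100.0 * n_a / decided if decided else np.nan,
                "pct_b": 100.0 * n_b / decided if decided else np.nan,
            }
        )
    return pd.DataFrame(rows)


def reversal_time_conditions(
    times=(300.0, 500.0, 700.0, 900.0, 1000.0), c_pct: float = -6.4
) -> list[dict]:
    """The reversal-time battery: c flipped in sign at each time."""
    return [
        {"c_pct": c_pct, "t_reverse": t, "c_after_pct": -c_pct, "t_stim": 1000.0}
        for t in times
    ]


def reversal_intensity_conditions(
    intensities=(-3.2, -6.4, -12.8, -25.6, -51.2, -70.0, -80.0),
    c_pct: float = 12.8,
    t_second: float = 1000.0,
) -> list[dict]:
    """The reversal-intensity battery: +12.8% for 1 s, then a stronger
    opposite stimulus for another second."""
    return [
        {"c_pct": c_pct, "t_reverse": 1000.0, "c_after_pct": i, "t_stim": 1000.0 + t_second}
        for i in intensities
    ]


def apply_ablation(config: NetworkConfig, kind: str) -> NetworkConfig:
    """The two mechanism ablations.

    ``reduced_w_plus`` lowers the potentiated recurrent weight from 1.7 to
    1.4 (weakens the attractor: no persistence, no low-coherence
    categorical decisions).  ``fast_nmda`` sets the NMDA decay equal to the
    AMPA decay (removes slow reverberation: no ramping integration).
    """
    if kind == "reduced_w_plus":
        return replace(config, w_plus=1.4)
    if kind == "fast_nmda":
        ampa_tau = config.port(Port.AMPA).tau_syn
        nmda = config.port(Port.NMDA)
        ports = tuple(
            ReceptorPort(p.label, ampa_tau, p.delay, p.sign) if p.label == Port.NMDA else p
            for p in config.ports
        )
        return replace(config, ports=ports)
    raise ConfigError(f"unknown ablation kind {kind!r}")


def ablation_run(
    config: NetworkConfig,
    kind: str,
    coherences_pct: tuple[float, ...] = (0.0, 51.2),
    n_trials: int = 10,
    seed: int = 0,
    keep_traces: bool = False,
    **protocol_kwargs,
):
    """Paired control vs ablated batches sharing per-trial seeds."""
    out = {}
    for label, cfg in (("control", config), (kind, apply_ablation(config, kind))):
        spec = ExperimentSpec(
            name=f"ablation_{label}", config=cfg, coherences_pct=coherences_pct,
            n_trials=n_trials, seed=seed, **protocol_kwargs,
        )
        out[label] = run_batch(spec, keep_traces=keep_traces)
    return out
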