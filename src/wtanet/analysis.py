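"""Readouts: population rates, decision classification, reaction times,
decision-space trajectories, and the Weibull neurometric function.

The decision rule follows the standard firing-rate threshold convention:
a population has decided when its smoothed rate first reaches 15 Hz after
stimulus onset (and stays there for at least two consecutive samples, a
guard against single-window noise); the reaction time is that crossing time
minus stimulus onset.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import medfilt

from .config import ConfigError
from .simulator import SpikeRecord

__all__ = [
    "RateTrace",
    "TrialOutcome",
    "NeurometricCurve",
    "population_rate",
    "classify_decision",
    "decision_space",
    "weibull_percent_correct",
    "fit_weibull",
    "condition_on_outcome",
    "DECISION_THRESHOLD_HZ",
]

DECISION_THRESHOLD_HZ = 15.0


@dataclass
class RateTrace:
    """Sliding-window population firing rate (spikes per neuron per second).

    ``times`` are the causal window end points: ``rate[i]`` counts spikes in
    ``(times[i] - window, times[i]]`` divided by ``n_neurons * window``.
    """

    times: np.ndarray  # ms
    rate: np.ndarray  # Hz
    population: str
    window: float  # ms
    step: float  # ms

    def at(self, t: float) -> float:
        i = int(np.searchsorted(self.times, t))
        return float(self.rate[min(i, len(self.rate) - 1)])


@dataclass
class TrialOutcome:
    """Classified result of one trial."""

    winner: str  # "A", "B" or "none"
    decision_time: float | None  # ms from stimulus onset
    coherence: float
    correct: bool | None  # None when winner == "none" or coherence == 0
    persisted: bool | None  # winner rate above loser throughout the delay
    tie: bool = False
    peak_rate_winner: float | None = None  # Hz, during stimulus
    end_rate_winner: float | None = None  # Hz, mean over the last 500 ms
    end_rate_a: float | None = None  # Hz, mean over the last 500 ms
    end_rate_b: float | None = None

    @property
    def decided(self) -> bool:
        return self.winner != "none"

    @property
    def final_choice(self) -> str:
        """The population dominating at trial end (reversal experiments
        report this rather than the first threshold crossing)."""
        if self.end_rate_a is None or max(self.end_rate_a, self.end_rate_b) < DECISION_THRESHOLD_HZ:
            return "none"
        return "A" if self.end_rate_a >= self.end_rate_b else "B"


def population_rate(
    spikes: SpikeRecord,
    population: str,
    window: float = 50.0,
    step: float = 5.0,
    median_filter: bool = False,
) -> RateTrace:
    """Causal sliding-window rate of one population.

    ``window`` must be an integer multiple of ``step``.  The optional
    3-point median filter suppresses single-sample outliers.
    """
    if window <= 0 or step <= 0:
        raise ConfigError("window and step must be positive")
    n_sub = int(round(window / step))
    if abs(n_sub * step - window) > 1e-9:
        raise ConfigError("window must be an integer multiple of step")
    r = spikes.populations[population]  # KeyError for unknown labels
    n_neurons = len(r)
    t = spikes.select(population)
    n_bins = int(np.ceil(spikes.t_total / step))
    edges = np.arange(n_bins + 1) * step
    counts, _ = np.histogram(t, edges)
    kernel = np.ones(n_sub)
    sliding = np.convolve(counts, kernel)[: n_bins]  # causal: ends at bin i
    rate = sliding / (n_neurons * window * 1e-3)
    times = edges[1:]
    if median_filter:
        rate = medfilt(rate, kernel_size=3)
    return RateTrace(times=times, rate=rate, population=population, window=window, step=step)


def _first_sustained_crossing(
    trace: RateTrace, onset: float, threshold: float, min_consecutive: int
) -> float | None:
    above = (trace.rate >= threshold) & (trace.times > onset)
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= min_consecutive:
            return float(trace.times[i - min_consecutive + 1])
    return None


def classify_decision(
    rate_a: RateTrace,
    rate_b: RateTrace,
    stim_onset: float,
    stim_end: float | None = None,
    coherence: float = 0.0,
    threshold: float = DECISION_THRESHOLD_HZ,
    min_consecutive: int = 2,
) -> TrialOutcome:
    """Apply the rate-threshold decision rule to a pair of traces.

    The winner is the population whose rate first sustains ``threshold``
    after ``stim_onset``; simultaneous crossings are broken by the larger
    rate at the crossing, then by label A (flagged via ``tie``).  When
    ``stim_end`` is given, persistence (winner rate >= loser rate at every
    sample of the post-stimulus delay) and the stimulus-period peak /
    trial-end rates of the winner are reported as well.
    """
    if len(rate_a.times) != len(rate_b.times) or not np.allclose(rate_a.times, rate_b.times):
        raise ConfigError("rate traces must share a time grid")
    t_cross = {
        "A": _first_sustained_crossing(rate_a, stim_onset, threshold, min_consecutive),
        "B": _first_sustained_crossing(rate_b, stim_onset, threshold, min_consecutive),
    }
    tie = False
    if t_cross["A"] is None and t_cross["B"] is None:
        winner, t_dec = "none", None
    elif t_cross["A"] is None or (
        t_cross["B"] is not None and t_cross["B"] < t_cross["A"]
    ):
        winner, t_dec = "B", t_cross["B"]
    elif t_cross["B"] is None or t_cross["A"] < t_cross["B"]:
        winner, t_dec = "A", t_cross["A"]
    else:  # same sample: larger rate at crossing wins, then label A
        tie = True
        i = int(np.searchsorted(rate_a.times, t_cross["A"]))
        winner = "A" if rate_a.rate[i] >= rate_b.rate[i] else "B"
        t_dec = t_cross[winner]

    correct: bool | None = None
    if winner != "none" and coherence != 0.0:
        preferred = "B" if coherence > 0 else "A"
        correct = winner == preferred

    tail = rate_a.times > (rate_a.times[-1] - 500.0)
    end_a = float(rate_a.rate[tail].mean()) if tail.any() else None
    end_b = float(rate_b.rate[tail].mean()) if tail.any() else None

    persisted = peak = end = None
    if winner != "none" and stim_end is not None:
        w_tr, l_tr = (rate_a, rate_b) if winner == "A" else (rate_b, rate_a)
        delay = w_tr.times > stim_end
        if delay.any():
            persisted = bool(np.all(w_tr.rate[delay] >= l_tr.rate[delay]))
        stim_mask = (w_tr.times > stim_onset) & (w_tr.times <= stim_end)
        if stim_mask.any():
            peak = float(w_tr.rate[stim_mask].max())
        tail = w_tr.times > (w_tr.times[-1] - 500.0)
        end = float(w_tr.rate[tail].mean())

    return TrialOutcome(
        winner=winner,
        decision_time=None if t_dec is None else t_dec - stim_onset,
        coherence=coherence,
        correct=correct,
        persisted=persisted,
        tie=tie,
        peak_rate_winner=peak,
        end_rate_winner=end,
        end_rate_a=end_a,
        end_rate_b=end_b,
    )


def decision_space(rate_a: RateTrace, rate_b: RateTrace) -> tuple[np.ndarray, np.ndarray]:
    """Trajectory in the (rate_A, rate_B) plane.

    Returns ``(points, diag_distance)`` where ``points`` is an ordered
    ``(n, 2)`` array and ``diag_distance = |rate_A - rate_B| / sqrt(2)`` is
    the distance from the decision-space diagonal — the order parameter of
    the competition (a random walk near zero until the attractor captures
    the trajectory).
    """
    if len(rate_a.times) != len(rate_b.times) or not np.allclose(rate_a.times, rate_b.times):
        raise ConfigError("rate traces must share a time grid")
    pts = np.column_stack([rate_a.rate, rate_b.rate])
    dist = np.abs(rate_a.rate - rate_b.rate) / np.sqrt(2.0)
    return pts, dist


def weibull_percent_correct(c: np.ndarray | float, alpha: float, beta: float):
    """Neurometric Weibull function: 1 - 0.5 exp(-(c/alpha)^beta).

    ``c`` is the unsigned coherence in percent; returns the expected
    fraction correct (0.5 at c = 0, saturating at 1).
    """
    c = np.asarray(c, dtype=float)
    out = 1.0 - 0.5 * np.exp(-((c / alpha) ** beta))
    return float(out) if out.ndim == 0 else out


@dataclass
class NeurometricCurve:
    """Weibull fit of percent-correct versus coherence."""

    coherences: np.ndarray  # percent, unsigned
    pct_correct: np.ndarray  # fractions in [0, 1]
    alpha: float | None
    beta: float | None
    residuals: np.ndarray | None
    ok: bool
    message: str = ""


def fit_weibull(
    coherences: np.ndarray, pct_correct: np.ndarray, p0: tuple[float, float] = (10.0, 1.5)
) -> NeurometricCurve:
    """Least-squares Weibull fit; degenerate data flags the fit instead of raising.

    ``coherences`` in percent (unsigned), ``pct_correct`` as fractions.
    Data that carry no slope information (all at chance, or saturated at
    1.0 everywhere) are reported with ``ok=False``.
    """
    c = np.asarray(coherences, dtype=float)
    p = np.asarray(pct_correct, dtype=float)
    if len(c) < 3:
        raise ConfigError("need at least 3 coherence levels to fit")
    if np.any((p < 0) | (p > 1)):
        raise ConfigError("pct_correct values must lie in [0, 1]")
    spread = p.max() - p.min()
    if spread < 1e-3 or np.all(p >= 1.0 - 1e-12):
        return NeurometricCurve(c, p, None, None, None, ok=False,
                                message="degenerate data: percent-correct carries no slope")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                weibull_percent_correct, c, p, p0=p0,
                bounds=([1e-9, 1e-9], [np.inf, np.inf]), maxfev=20_000,
            )
    except RuntimeError as exc:
        return NeurometricCurve(c, p, None, None, None, ok=False, message=str(exc))
    alpha, beta = float(popt[0]), float(popt[1])
    resid = p - weibull_percent_correct(c, alpha, beta)
    return NeurometricCurve(c, p, alpha, beta, resid, ok=True)


def condition_on_outcome(
    trials: list[tuple[TrialOutcome, RateTrace]],
) -> dict[tuple[bool, bool], RateTrace]:
    """Mean population-B rate traces split by outcome and stimulus identity.

    ``trials`` pairs each outcome with the B-population rate trace of that
    trial.  Keys are ``(b_won, stimulus_prefers_b)``; the four cells are the
    correct B-win, erroneous B-win, correct B-loss, and erroneous B-loss
    conditions.  Zero-coherence trials are rejected (correctness undefined)
    and undecided trials skipped; empty cells are omitted with a warning.
    """
    cells: dict[tuple[bool, bool], list[RateTrace]] = {}
    for outcome, trace in trials:
        if outcome.coherence == 0:
            raise ConfigError("conditioning requires nonzero coherence (correct undefined at c=0)")
        if not outcome.decided:
            continue
        key = (outcome.winner == "B", outcome.coherence > 0)
        cells.setdefault(key, []).append(trace)
    out: dict[tuple[bool, bool], RateTrace] = {}
    for key in [(True, True), (True, False), (False, False), (False, True)]:
        if key not in cells:
            warnings.warn(f"conditioned-average cell {key} is empty; omitted")
            continue
        traces = cells[key]
        ref = traces[0]
        mean_rate = np.mean([tr.rate for tr in traces], axis=0)
        out[key] = RateTrace(
            times=ref.times, rate=mean_rate, population="B",
            window=ref.window, step=ref.step,
        )
    return out
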