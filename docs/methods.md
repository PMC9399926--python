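# Methods

## Model

`wtanet` simulates a cortical circuit for two-alternative perceptual
decisions, patterned on the decision-correlated activity of area LIP during
random-dot motion discrimination. Two excitatory populations, A and B
(800 pyramidal cells each at the reference scale), are selective for the
two motion directions; a shared pool of 400 interneurons provides feedback
inhibition. Strong recurrent excitation within each selective population —
carried mostly by a slow NMDA-like synaptic current — and competition
through the shared inhibition give the circuit two attractor states in
which one population fires persistently while the other is suppressed.
A coherence-coded external stimulus biases which attractor captures the
dynamics; the identity of the active population after the stimulus is the
model's "choice", held as working memory through the delay.

### Neurons

Leaky integrate-and-fire with current-based exponential postsynaptic
currents and four receptor ports:

    C_m dV/dt = -(C_m/tau_m)(V - E_L) + sum_p I_p(t)
    tau_p dI_p/dt = -I_p  (+ jump on spike arrival)

| parameter | excitatory | inhibitory |
|---|---|---|
| E_L, V_th, V_reset | −70, −50, −55 mV | −70, −50, −55 mV |
| tau_m | 20 ms | 10 ms |
| C_m | 500 pF | 200 pF |
| tau_ref | 2 ms | 1 ms |

Port decay constants: noise 5 ms, AMPA 2 ms, NMDA 100 ms, GABA 5 ms;
delays 0.5 ms except NMDA at 2.5 ms (standing in for the NMDA rise time).
There is no spike-initiation exponential, adaptation current or external
bias current; the NMDA port has no voltage dependence (the current-based
model carries the NMDA phenotype solely in its 100 ms decay).

The subthreshold system is linear, so each 0.1 ms step uses the exact
propagator (closed-form exponentials); threshold is checked once per step
and a crossing emits the spike at the end of the step. During
refractoriness the membrane is clamped to V_reset while synaptic currents
continue to evolve. With this scheme the only discretization artifacts are
grid-aligned event times; the test suite verifies the dt = 0.1 ms
trajectory against a microsecond dense reference to 1e-6 mV.

### Synapses and weight normalization

Connectivity is pairwise-Bernoulli with probability ε between every
connected pair of populations (no autapses). Each connection's current
amplitude is normalized per (receptor, target cell class) so that a single
spike at weight 1 produces a PSP peak of exactly J = 0.04 mV, then scaled
by a dimensionless weight:

| projection | AMPA | NMDA | GABA |
|---|---|---|---|
| within A or B | w+ = 1.7 | w_NMDA = 4.25 | — |
| between A and B | w− = 0.8 | w− = 0.8 | — |
| A,B → I | w+ | w+ | — |
| I → A,B | — | — | w_ie = 12 |
| I → I | — | — | w_ii = 1 |
| noise generators | (noise port) w_noise = 1.7 | — | — |
| stimulus generators | w_stim = 1 | — | — |

All weights are static. w+, w−, w_NMDA and J are the published reference
values; ε (default 0.1), w_ie, w_ii, w_noise and w_stim have no published
values and were calibrated (below).

### Inputs

Every neuron receives an independent Poisson background train whose rate
is drawn once per trial from N(7719, 38²) Hz for excitatory and
N(5789, 28²) Hz for inhibitory cells. The motion stimulus is a pair of
Poisson generators with the symmetric linear coherence code

    mu_A = mu0 (0.5 − 0.5 c),   mu_B = mu0 (0.5 + 0.5 c),
    mu0 = 772 Hz,  c ∈ [−1, 1]  (positive c favors B),

re-drawn every 25 ms from N(mu, sigma0²), sigma0 = 48 Hz, clipped at zero.
Each target neuron receives its own independent realization of its
generator (shared trains would synchronize the population artificially).
Poisson input is consumed as per-step event counts on the 0.1 ms grid,
which is distribution-identical to a grid-constrained generator spike
train; `generate_poisson_spikes` also provides continuous-time
realizations for analysis and testing.

### Trials

A trial is 500 ms of spontaneous activity, 1,000 ms of stimulus, and
1,500 ms of delay (3 s total), all configurable; reversal protocols switch
the coherence of the blocks after a given time. Membrane potentials start
uniformly distributed between rest and threshold so that stimulus onset
meets a desynchronized population rather than an artificial volley.
A trial is a pure function of (configuration, seed): the master seed
expands through `numpy.random.SeedSequence` into fixed-order substreams
(connectivity, background rates, stimulus trace, background events,
stimulus events, initial potentials), and two runs with the same seed are
bit-identical.

## Readouts

Population rates use a causal 50 ms sliding window advanced in 5 ms steps
(optionally median-filtered). A population has decided when its rate first
reaches 15 Hz after stimulus onset and stays there for two consecutive
samples (a guard against single-window noise); the reaction time is that
crossing minus stimulus onset. Simultaneous crossings are broken by the
larger rate, then by label A, and flagged. Persistence means the winner's
rate stays at or above the loser's at every sample of the delay. Reversal
experiments report the final choice — the population dominating the last
500 ms — since a strong reversal can displace an earlier crossing. The
neurometric function is percent-correct versus unsigned coherence in
percent, fitted by least squares with 1 − 0.5 exp(−(c/α)^β).

## Calibration

The published parameter set is incomplete: the connection probability ε,
the inhibitory weights, and the generator weights are unstated ("chosen
after tuning"). With all published values fixed, the remaining knobs were
calibrated on qualitative regime criteria only — a stable (non-runaway)
network, a baseline that does not decide spontaneously, stimulus-triggered
winner-take-all with post-stimulus persistence, and noise-driven decisions
at zero coherence:

* **w_noise = 1.7.** At weight 1 the 7,719 Hz background depolarizes an
  excitatory cell by only ~10 of the 20 mV to threshold with ~0.5 mV of
  shot noise: the network is permanently silent. Potentiating the
  background connections by w+ (the same factor as the other feedforward
  projections) places the operating point ~17 mV above rest, the regime in
  which the stimulus can ignite activity.
* **w_ie = 12.** The within-population NMDA coupling is linear in this
  model (~2 mV of mean drive per Hz of population rate at the reference
  indegree) and must be balanced by inhibition; at I→E weights near 1 the
  network is runaway-unstable for any ε. w_ie ≈ 12 yields winning-population
  rates of ~20–40 Hz and interneuron rates under 100 Hz, matching the
  reported dynamic range.
* **ε = 0.1** for all recurrent projections, the conventional cortical
  sparseness. Desk-scale runs use the 1,000-neuron network with ε scaled
  to 0.2 so every neuron keeps its expected indegree — per-neuron
  recurrent drive then matches the 2,000-neuron reference, which behaves
  equivalently (verified at both scales).

## What the simulated conditions do and do not show

The calibrated network reproduces: categorical, self-sustained decisions
triggered by the stimulus at every coherence including zero; an unbiased
noise-driven coin toss when stimulus fluctuations are removed (sigma0 = 0);
percent-correct rising with coherence with a Weibull scale near the
reference α ≈ 9.2; faster and less dispersed reaction times at high
coherence; insensitivity to late stimulus reversals; and the loss of
ramping, competition and decision when the NMDA decay is collapsed onto
the AMPA decay.

Known deviations, all traceable to the linear (non-saturating)
current-based synapse model:

* **Quiescent baseline.** Before stimulus the network is silent rather
  than firing at a few Hz. An active symmetric state is unstable here for
  any accessible parameter setting: the difference mode (A − B) is
  amplified by within-population NMDA drive that shared inhibition cannot
  stabilize, and without NMDA saturation its gain exceeds one whenever the
  populations are active. Decisions are therefore ignition events, which
  also makes reaction times shorter than the reference figures (the
  orderings and dispersion relations are preserved).
* **Robust persistence.** The winner's delay state is stabilized by the
  same excitation–inhibition balance loop that stabilizes the baseline:
  when the winner's rate dips, inhibition dips proportionally and restores
  the drive. Consequently reducing w+ to 1.4 does not abolish persistence
  or low-coherence decisions in this implementation, and no achievable
  reverse stimulus re-ignites the suppressed population once the
  competition is resolved (a −80% late reversal does not flip the choice).
  Both behaviors rely, in the conductance-based original, on marginally
  persistent states held near their bifurcation by NMDA saturation.
  The corresponding acceptance tests are expected to fail and are left
  failing rather than weakened.

## Problem sizes

Behavioral batches run at the 1,000-neuron scale: 40 trials per coherence
level for the neurometric sweep and winner-take-all statistics, 200–300
trials for the coin toss, 25 per reversal condition, 8 per ablation cell.
Decision-only batches trim the delay to 500 ms; persistence measurements
keep the full 1.5 s delay.
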