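# wtanet

A spiking winner-take-all attractor network for binary perceptual decision
making.

## The problem

During random-dot motion discrimination, neurons in parietal area LIP ramp
up their firing as evidence for "their" direction accumulates, keep firing
through the memory delay, and predict the saccadic choice. `wtanet`
implements the classic two-population attractor account of that data as a
network of 2,000 leaky integrate-and-fire neurons: two excitatory pools A
and B (800 cells each) selective for the two directions, and 400
interneurons providing shared feedback inhibition. Slow NMDA-mediated
recurrent excitation (decay 100 ms) lets each pool integrate its input
over hundreds of milliseconds; the shared inhibition makes the pools
compete, so the network relaxes into one of two attractor states — a
categorical decision held as working memory after the stimulus ends.

The stimulus is a pair of Poisson generators whose mean rates encode the
signed motion coherence c through the symmetric linear model

    mu_A = mu0 (0.5 − 0.5 c),   mu_B = mu0 (0.5 + 0.5 c),   mu0 = 772 Hz,

with the instantaneous rates re-drawn every 25 ms (SD sigma0 = 48 Hz).
Every neuron additionally receives independent Poisson background noise —
the source of trial-to-trial choice variability.

The package contains the simulator (exact-propagator LIF with multi-port
exponential PSCs, compiled with numba), the network builder, the stimulus
protocols (coherence sweeps, duration sweeps, mid-stimulus reversals,
mechanism ablations), and the analysis layer (population rates, 15 Hz
decision rule, reaction times, decision-space trajectories, Weibull
neurometric fits). It is intended for computational neuroscientists who
want a self-contained, reproducible re-implementation of the model and its
experiment battery. See `docs/methods.md` for the model details,
calibration and known limitations.

## Worked example

Simulate one high-coherence trial of the 1,000-neuron desk-scale network
and classify the decision:

```python
import wtanet as w

cfg = w.default_config().scaled(0.5, preserve_indegree=True)
proto = w.build_protocol(c=0.512)          # 51.2% coherence toward B
outcome, traces, _ = w.run_trial(cfg, proto, seed=42, keep_traces=True)
print(outcome.winner, outcome.decision_time, outcome.persisted)
```

prints

```
B 250.0 True
```

population B (the stimulated direction) reaches the 15 Hz decision
threshold 250 ms after stimulus onset and keeps firing above its rival for
the entire 1.5 s delay — a correct, persistent decision. A zero-coherence
"coin toss" batch:

```python
res = w.coin_toss(cfg, n_trials=20, seed=7, t_post=500.0)
print(res["n_decided"], round(res["pct_a"], 1))
```

```
20 60.0
```

all 20 trials reach a decision even though the stimulus carries no net
evidence, and the winner split (60/40 here at n = 20) is statistically
even: with sigma0 = 0 the choice is driven entirely by the background
noise.

The same batteries are available from the shell:

```
wtanet simulate --coherence 51.2 --seed 7 --scale 0.5 --out runs/demo
wtanet batch --n-trials 40 --scale 0.5 --out runs/sweep
wtanet coin-toss --n-trials 200 --scale 0.5 --out runs/coin
wtanet ablation --kind fast_nmda --scale 0.5 --out runs/ablation
```

Every run writes its spike TSVs, summary CSVs and a manifest (config hash,
seed, outputs); identical (config, seed) pairs reproduce outputs
bit-for-bit.

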