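# sleepwake

Conductance-based simulation and perturbation analysis of the neural
circuits that switch the brain from NREM sleep to wakefulness.

Sleep-to-wake transitions are controlled by a small set of subcortical
neuromodulatory populations — hypocretin/orexin (Hcrt) neurons of the
lateral hypothalamus, noradrenergic locus-coeruleus neurons (NE/LC),
histaminergic (His), cholinergic (ACh) and dopaminergic (DA) nuclei —
whose interactions can now be dissected with optogenetic stimulation and
inhibition.  `sleepwake` is a toolkit for researchers designing or
interpreting such experiments.  It couples:

- a **spiking-network simulator**: single-compartment Hodgkin–Huxley-type
  neurons with spike-triggered adaptation, difference-of-exponentials
  synapses (including the 2 s-rise / 30 s-decay hypocretin-receptor
  conductance responsible for delayed, minute-scale NE/LC activation),
  square-pulse/constant optogenetic actuation, a neocortical rate unit
  with state and output feedback, and a threshold device that converts
  arousal activity into a binary sleep/wake timeline;
- a **statistical layer** for the three organizing concepts of the
  sleep-regulatory network: *hierarchical gating* — circuit B gates
  circuit A when, writing a, b, c for P[S-to-W] under (A stimulated),
  (A stimulated + B inhibited), (A and B stimulated), a > b and c > a;
  *feedback* — a rule-based closed-loop optogenetic controller; and
  *redundancy* — binary codebooks whose codewords pair unit-activity bits
  with the behavioral-state LSB, with probabilistic dominance, dominance
  closure ("structure"), redundancy degree, minimum Hamming distance and
  ε-based relevance of appended bits;
- an exactly solvable **logistic surrogate** transition model,
  P[wake | x] = σ(w·x + b), used as an independent oracle for every
  statistic in the layer above.

See `docs/methods.md` for the model equations, parameter meanings, the
calibration targets, and known limitations.

## Worked example

Run the reference experiment — 10 Hcrt and 10 NE/LC neurons, 10 s of
20-Hz Hcrt stimulation — and test the gating hierarchy on the full
60-neuron circuit:

```python
from sleepwake import build_circuit
from sleepwake.experiments import fig1_experiment
from sleepwake.hierarchy import SimulatorEngine, gating_test

r = fig1_experiment(seed=1)
print(f"NE/LC activation lag: {r.lag_ms:.0f} ms")
print(f"persistence after stimulus offset: {r.persistence_ms/1000:.1f} s")
print(f"sleep-to-wake transitions: {r.trial.timeline.transitions}")

res = gating_test("Hcrt", "NE/LC", SimulatorEngine(build_circuit("fig4")),
                  n_trials=24, seed=40)
print(f"a={res.a:.3f} b={res.b:.3f} c={res.c:.3f} -> NE/LC gates Hcrt: {res.verdict}")
```

prints (seed 1 / seed 40; the gating test takes a few minutes):

```
NE/LC activation lag: 1950 ms
persistence after stimulus offset: 65.2 s
sleep-to-wake transitions: [14200.0, 27850.0]
a=0.417 b=0.000 c=1.000 -> NE/LC gates Hcrt: True
```

The lag and persistence are the signature of the slow hypocretin-receptor
conductance: NE/LC firing rises only ~2 s after Hcrt firing and outlasts
the stimulus by more than a minute, producing the first wake transition at t ≈ 14.2 s
(a brief mid-trial sleep excursion yields the second crossing).  The gating triple shows NE/LC's veto/facilitation power over
hypocretin-induced awakenings: inhibiting NE/LC abolishes transitions
(b = 0), co-stimulating it makes them certain (c = 1).

The same machinery is scriptable from the shell:

```bash
sleepwake simulate --circuit fig1 --duration 120000 --stim Hcrt:10000:10000:20:10
sleepwake gating-test --circuit fig4 --a Hcrt --b "NE/LC" --trials 24
sleepwake codebook-scan --codebook codebook2 --weights 2.0,1.0 --bias -1.0
sleepwake patterns --pops "Hcrt,NE/LC,NC"
```

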