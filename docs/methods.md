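# Methods

## Scope and model overview

`sleepwake` models the NREM-to-wake transition as the output of a small
network of interacting neuromodulatory populations — hypocretin/orexin
(Hcrt), noradrenergic locus coeruleus (NE/LC), histamine (His), local GABA
pools, and a neocortical effector — probed by optogenetic-style
stimulation and inhibition.  Three formal ideas sit on top of the
simulator: a pairwise *hierarchical-gating* test on transition
probabilities, a *threshold-device / feedback* description of how arousal
activity becomes a behavioral state, and a binary *codebook* formalism for
redundancy among arousal circuits.  Vigilance is deliberately binary
(sleep vs wake); REM, EEG staging, thalamocortical spindles, glial and
circadian mechanisms are out of scope.

## Neuron model

All populations share one single-compartment template: classic squid-type
transient Na⁺ (m³h) and delayed-rectifier K⁺ (n⁴) currents with leak
(C = 1 µF/cm², g_Na = 120, g_K = 36, g_L = 0.3 mS/cm²; E_Na = +50,
E_K = −77, E_leak = −54.4 mV; rest ≈ −65 mV), plus:

- **Spike-triggered AHP adaptation**: a conductance g_AHP (reversal E_K)
  incremented by `adapt_increment` at each spike and decaying with
  `adapt_tau` = 400 ms.  This is the mechanism that produces the slow
  tonic regimes of the arousal nuclei: a bare template fires at 50–90 Hz
  under suprathreshold drive, while with the NE/LC increment
  (0.5 mS/cm²) the adapted rate at the default tonic stimulation
  amplitude (21 µA/cm²) falls in the 2–3 Hz wake band.  Hcrt uses a
  smaller increment (0.1) so pulse-train stimulation drives phasic firing
  near the pulse rate; His is intermediate (0.3).
- **White current noise** per neuron (0.5 µA/cm²·√ms), and multiplicative
  5 % conductance jitter per neuron, so that trials vary and transition
  probabilities are non-degenerate.  Trial-to-trial variability is
  dominated by the resampled connectivity and jitter, not by the noise.

Integration is fixed-step with dt = 0.05 ms.  Gating variables use
exponential Euler with tabulated rate functions (0.05-mV voltage grid);
the membrane equation, being linear in V given the conductances, is also
advanced by exponential Euler.  A fully explicit V-update is marginally
unstable at the spike peak for this dt (the effective membrane time
constant dips below 2·dt), so the exponential update was chosen; halving
dt changes deterministic trial-mean rates by well under 5 % (tested).
Voltages outside ±150 mV abort the trial with an error naming the neuron
and time.

## Synapses

Conductances are difference-of-exponentials waveforms normalized to peak
at `gmax`, implemented as two first-order filters incremented on each
delayed presynaptic spike.  Kinds and default kinetics:

| kind | rise (ms) | decay (ms) | E_rev (mV) | role |
|---|---|---|---|---|
| fast_excitatory | 0.5 | 5 | 0 | glutamatergic co-transmission |
| slow_hcrt | 2000 | 30000 | 0 | hypocretin receptor |
| fast_gabaa | 0.5 | 10 | −80 | local inhibition |
| slow_inhibitory_peptide | 200 | 20000 | −80 | peptidergic co-release (off by default) |
| slow_histamine | 50 | 2000 | 0 | histaminergic modulation |

The slow hypocretin conductance is the load-bearing element: a 10-s
presynaptic volley accumulates a depolarization that rises over seconds
(hence the > 0.5-s NE/LC activation lag) and decays over tens of seconds
(hence minute-scale persistence after stimulus offset).  A single spike
still carries ≈ 18 % of its peak conductance a minute later.

Connectivity between connected populations is Erdős–Rényi with p = 0.5,
resampled per trial seed.  Individual connection weights are
`gmax/(p·N_pre)` so that `gmax` is the aggregate conductance a
postsynaptic cell receives per presynaptic population volley, making the
calibration robust to population-size overrides.

## Circuits and calibration targets

Builders reproduce a complexity ladder: `fig1` (10 Hcrt + 10 NE/LC),
`fig2` (50 neurons: 20+20 plus a 10-neuron GABA pool and the neocortical
unit), `fig4` (60 neurons: 15+15 Hcrt/NE-LC, 10 His, 10 GABA-1, 10
GABA-2), `fig5`/`fig6` (adds ACh_BF, ACh_LDT, DA wired to the neocortex
only — placeholder wiring, since their efferent targets inside the
modeled circuit are not established; `fig6` carries the signed edge
annotations).

The synaptic gains are calibrated once, against the qualitative regime
targets the model is required to meet, and then frozen:

- **Quiescence**: no stimulation ⇒ Hcrt and NE/LC below 0.5 Hz (they are
  essentially silent; the noise amplitude keeps membrane fluctuations
  ≈ 0.4 mV, far from threshold).
- **Two-population circuit** (`fig1`, slow gmax 0.007): 10-s, 20-Hz Hcrt
  stimulation gives an NE/LC activation lag of 1.5–2.5 s and persistence
  (rate continuously above 0.2 Hz) of 64–70 s after offset across seeds.
  A higher gain (0.008) was rejected because the stronger drive pushes
  NE/LC into transient depolarization block at stimulus offset.
- **GABA coherence** (`fig2`, GABA→principal gmax 2.0): with tonic Hcrt
  drive, the shared inhibitory pool phase-locks the adaptation-paced
  rhythms of Hcrt and NE/LC; peak magnitude-squared coherence of their
  200-ms rate series in 0.5–10 Hz rises from ≈ 0.05–0.09 (GABA efferents
  zeroed) to ≈ 0.5–0.7.  The pool is silenced by zeroing its efferent
  conductances so topology, seeds, and noise streams are matched.
- **Full circuit** (`fig4`, Hcrt→NE/LC slow gmax 0.0014): GABA-balanced
  histamine keeps every population's 1-s peak rate below the 30-Hz
  ceiling, and NE/LC recruitment by Hcrt stimulation alone is deliberately
  *marginal* — across trials the transition probability sits near 0.5,
  which is precisely the regime in which the gating hierarchy is
  observable: inhibiting NE/LC (−5 µA/cm²) vetoes the transition (b ≈ 0),
  co-stimulating it makes the transition certain (c ≈ 1).

## Readout and statistics

Spikes are upward crossings of −20 mV with a 2-ms refractory rule.
Population rates are centered sliding-window counts (1-s window, 50-ms
step for classification; 200-ms window when a series feeds the spectral
estimator, since a 1-s boxcar suppresses the whole 0.5–10 Hz band).
Coherence is Welch magnitude-squared coherence, 4-s segments, 50 %
overlap, peak within 0.5–10 Hz.

The vigilance timeline applies a threshold device to the arousal signal —
the neocortical rate unit when present, otherwise the NE/LC rate — with
threshold 1.5 Hz, hysteresis 0.5 Hz (release at 1.0 Hz) and a 1-s minimum
dwell that discards shorter wake excursions.  The neocortical unit is a
first-order filter (τ = 1 s) of a weighted sum of its afferent rates
(NE/LC weight 1.0, His/ACh/DA 0.1), with two feedback paths: a state
feedback current onto Hcrt proportional to the NC rate (0.02 µA/cm² per
Hz — present but deliberately weak, so it does not distort the open-loop
calibrations) and an output feedback drive (0.5 Hz) to the NC while the
wake state holds.

P[S-to-W] for a protocol is the fraction of trials (seeds s, s+1, …)
whose timeline contains a sleep→wake crossing inside the observation
window, by default protocol onset to onset + 30 s.  The window form was
chosen over an instantaneous hazard because the underlying quantity of
interest is "did this perturbation produce an awakening", and it bounds
trial length.  Intervals are Wilson 95 % (valid at small n, unlike Wald);
at k = 0 or k = n the score interval excludes the raw proportion, so the
reported interval is minimally widened to contain it.

## Hierarchical gating

B gates A iff a > b and c > a, where a, b, c are P[S-to-W] under
(A stimulated), (A stimulated + B inhibited), (A and B stimulated), run
with matched onsets and durations and disjoint seed blocks.  Two decision
rules are provided: `point` (strict inequalities of the estimates) and
the default `ci` (the compared Wilson intervals must be disjoint) — the
defining inequalities concern true probabilities, and finite trials need
a statistical criterion.  Ties, including c = a, conservatively yield
"not gating" and are flagged.  No antisymmetry is assumed: with symmetric
facilitation both directions can gate.  The shipped defaults are
calibrated so that in the 60-neuron circuit NE/LC gates Hcrt under the
CI rule with 24 trials per condition (a ≈ 0.4–0.5, b = 0, c = 1).

## Codebooks

A codeword is (unit bits, state bit): unit bit = 1 iff that population's
rate strictly exceeds its per-unit threshold (thresholds are config
inputs — they are preparation-dependent and no canonical values exist);
LSB = 1 denotes wake.  The shipped layouts are the 7-bit book
(NE, ACh, DA, Hcrt, 5-HT, His, state — hierarchy order), the 3-bit
(NE, ACh, state) and 2-bit (NE, state) books, plus the 4-bit extension
with DA appended for the redundancy example.  Bit order is data, not
code.  Probability tables store the conditional P[LSB=1 | unit pattern];
a codeword's probability is that conditional for LSB = 1 and its
complement for LSB = 0.  Dominance (P[C1] > P[C2]) is defined only for
comparable codewords (same LSB or same unit bits); incomparable queries
raise an error rather than returning false.  Redundancy degree is the
codeword bit-length — an explicitly non-coding-theoretic definition: the
full binary codebook has minimum Hamming distance 1 and corrects
nothing.  ε-relevance of an appended bit compares the extended table with
its restriction; the default δ = 0.05 absolute probability operationalizes
"sufficiently small", which is otherwise unspecified.

## Logistic surrogate

The surrogate maps a perturbation vector (+1 stimulated, 0 untouched, −1
inhibited; codebook patterns use their raw {0,1} bits) through
P = σ(w·x + b).  It exists to make the statistical layer exactly
testable: closed-form tables are the oracle for Monte-Carlo estimation,
monotone weights prove the dominance partial order, and a zero-weight bit
gives exact restriction consistency.  No claim is made that the biology
is logistic, and the surrogate is never used where the simulator is the
object under test.

## What the simulator does and does not emulate

The synthetic circuits reproduce the qualitative regime structure that
the analysis layer needs — quiescent NREM baselines, delayed/persistent
hypocretin action, tonic 2–3 Hz NE/LC wake firing, GABA-mediated
synchrony, marginal-recruitment gating.  They do not emulate receptor
subtype pharmacology, opsin photocycles, EEG, REM phenomena,
multi-compartment morphology, or quantitative firing statistics of real
recordings; passing tests therefore validate the machinery and its
calibrated regimes, not fits to physiological data.

## Problem sizes and numerical choices

Default dt = 0.05 ms; 100-ms integration chunks with per-chunk derived
RNG seeds (reproducible regardless of chunk scheduling); voltage
recording at 1-ms stride.  The shipped reference runs use the trial
lengths above (120 s for the two-population trial, 60 s for coherence,
40 s for stability, 32 s per gating trial with 24 trials per condition);
these sizes make the full reproduction script a matter of minutes on one
CPU while leaving every decision margin (lag, persistence, coherence gap,
ceiling, interval disjointness) wide.  Monte-Carlo oracle checks use
10,000 trials per pattern.  Ties in every strict comparison resolve to
the conservative (negative) verdict; degenerate inputs (empty spike
trains, empty signals, zero-trial requests) raise typed errors rather
than returning defaults.

## Known limitations

- Edge scores (1–10) cannot be inferred from data here; the shipped
  values for the four annotated constants are documented placeholders
  encoding only the NE/LC-above-Hcrt ordering.
- ACh and DA populations are simulated but their intra-circuit targets
  are placeholder wiring to the neocortical unit.
- The gating calibration is intentionally knife-adjacent (a ≈ 0.5); very
  small trial counts under the CI rule will correctly withhold a verdict.
- The sleep-maintenance codebook is not represented: its bit composition
  is not recoverable from the source material this package models.
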