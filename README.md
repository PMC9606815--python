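# seqreplay

A computational model of how episodic *sequences* are encoded by a
fast-learning hippocampus and gradually consolidated into a slow-learning
cortex through time-compressed replays during slow-wave sleep (SWS).  It is
aimed at computational neuroscientists studying systems-level memory
consolidation: the simulator reproduces cued sequence recall, emergent
salience-biased replay, retrograde-amnesia-style lesions, replay
competition between memories, and consolidation with hippocampal plasticity
suppressed during sleep.

## The model

Both memory regions are recurrent competitive networks of item neurons with
shunting dynamics (one neuron per percept, joined across regions by fixed
one-to-one projections).  Activation *aₓ* ∈ [0, 1] of item *x* obeys

    σₐ daₓ/dt = −aₓ/τₐ + (1 − aₓ)·Eₓ − aₓ·Iₓ

where the excitation Eₓ sums feedforward drive (input register → cortex at
gain μ_c; cortex → hippocampus at gain μ_h), spreading excitation
γ·Σ_y w_yx·a_y through learned directed links, a sigmoidal self-excitation
α·aₓᵐ/(aₓᵐ + tₐᵐ), and (cortex only) hippocampal feedback ζ·[hₓ]⁺; the
inhibition Iₓ sums lateral inhibition β·Σ_{y≠x} a_y and a sigmoidal function
θ·gₓⁿ/(gₓⁿ + t_hⁿ) of a slow inactivation current gₓ that terminates
prolonged activations:

    σ_g dgₓ/dt = −gₓ/τ_g + (1 − gₓ)·κaₓ

Directed link weights w_xy ∈ [0, 1] follow a causal rate-based rule — a
presynaptic item active while the postsynaptic activation *rises*
potentiates the link; a falling postsynaptic activation depresses it by the
fraction Q:

    dw_xy/dt = −w_xy/τ_w,eff + η·aₓ(1 − w_xy)·([da_y/dt]⁺ − Q[−da_y/dt]⁺)

with η_h ≫ η_c (the hippocampus learns an order of magnitude faster) and a
much shorter effective decay time in the hippocampus (≈1.2 days) than the
cortex (≈288 days).  Each item also carries a salience trace, a leaky moving
average of its waking cortical activation (ds/dt = −s/τ_s + λa, λ = 0 in
sleep).  A night of SWS is a 50 s block of 1 Hz slow oscillations: each
0.5 s UP state samples one item (or a fixed-salience "null" outcome) with
probability proportional to salience, pulses it briefly into the cortical
input register, and lets activity sweep through the learned links at the
fast sleep timescale — a time-compressed replay that trains the cortex.
Recall accuracy is the percentage of a target sequence crossing the 0.01
cortical threshold in correct order; recall time is cue onset to the final
crossing (30 s ceiling for incomplete recalls).

## Worked example

Six experiment presets ship with the package (`seqreplay presets list`):
`baseline`, `lesion`, `salience_two_seq`, `competition`, `hc_sleep_off`,
`overlap`.  The baseline experiment trains the five-item sequence ABCDE ten
times on Day 1 and then lets four nights of sleep consolidate it, testing
recall each morning:

```bash
$ seqreplay run baseline --seed 42 --out runs/baseline
day 1: cue A accuracy 100% recall time 5.67 s
day 2: cue A accuracy 100% recall time 3.64 s
day 3: cue A accuracy 100% recall time 3.26 s
day 4: cue A accuracy 100% recall time 3.08 s
day 5: cue A accuracy 100% recall time 2.86 s
results written to runs/baseline
```

Recall is already perfect after Day-1 training (the hippocampal trace
carries it), and the recall time then *shrinks* night after night — the
signature of consolidation: sleep replays strengthen the cortical links, so
the recall cascade runs faster.  The output directory holds `recalls.csv`,
`replays.csv` (every UP state with its cue and threshold crossings),
`weights.csv` (link-weight trajectories), `salience.csv`, `summary.json`
and a reproducibility manifest; `seqreplay report runs/baseline` prints
summary tables.  For instance, the final cortical weight endpoints show
A→B as the weakest forward link (0.48 vs 0.59–0.82 for the later links):
replays cued by B, C, D or E never traverse the A→B fragment, so it is the
least rehearsed — an emergent prediction of salience-cued fragmentary
replay.

The same experiments are available as library calls
(`seqreplay.load_preset`, `seqreplay.run_experiment`), and custom schedules
can be written as small YAML files (see `src/seqreplay/presets/` for the
format).  Model behaviour is documented in `docs/methods.md`.

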