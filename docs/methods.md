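# Methods

## Model

Two regions — hippocampus (HC) and cortex (CTX) — are simulated as
recurrent competitive networks with one rate neuron per percept ("item").
The regions share an index space and are joined by fixed item-specific
projections: the input register drives cortical items (gain μ_c), cortical
activation drives the matching hippocampal item (gain μ_h), and rectified
hippocampal activation feeds back to the matching cortical item (gain ζ).
Within a region every neuron inhibits every other (gain β), excites itself
through a sigmoid (α, order m, threshold t_a), and excites other items
through learned directed weights (gain γ).  A slow inactivation current g
accumulates while an item is active and shuts it down through a second
sigmoid (θ, order n, threshold t_h); this is what terminates each item's
activation burst and hands the network to the next item in a sequence.

All state variables are clamped to [0, 1] after every forward-Euler step
(Δt = 1 ms; the shunting form keeps the continuous system in bounds, but
Euler can overshoot).  Within one step: (1) excitatory/inhibitory inputs
and the analytic derivatives are evaluated at the previous step's state,
synchronously for both regions (HC sees the previous step's cortical
activation); (2) weights update from the same pre-update snapshot; (3)
activations and inactivation currents update; (4) new links instantiate
from post-update co-activations (wake training only); (5) salience updates
from post-update cortical activations (wake only).  The derivative fed to
the learning rule is the analytic right-hand side of the activation ODE
divided by σ_a, not a finite difference, which removes Δt-order noise from
the learning signal.

## Parameters

Defaults (units of seconds; gains dimensionless): σ_a,wake = 2,
σ_a,sleep = 0.04, τ_a = 0.8, μ_h = 2, μ_c = 1, γ = 0.9, α = 1, m = 2,
t_a = 0.09, ζ = 0.5, β = 15, θ = 10, n = 2, t_h = 0.02, σ_g = 10 (wake),
τ_g = 1.2, κ = 1, Q = 0.5, η_h = 15, η_c = 1.5, τ_s = 86 400,
λ_wake = 1000, λ_sleep = 0, null salience 0.5.  Protocol constants:
training input 0.1 for 2 s per item with 5 ms inter-stimulus interval and
1 min between trials; recall cue 0.1 for 1.5 s, observation to 30 s; sleep
cue pulse 0.2 for 12.5 ms (12 steps on the 1 ms grid); 50 UP states of
0.5 s per night at 1 Hz; recall and link-instantiation thresholds 0.01.

Two published constants admit more than one reading and are exposed as
configuration:

- **Weight decay (`tau_w_unit`, `decay_scaled_by_eta`).**  The printed
  τ_w values (1.5552×10⁹, 3.73248×10¹⁰) are treated as milliseconds, and
  the passive-decay term is scaled by η as the learning rule is written.
  The effective e-fold decay is then ≈1.2 days for hippocampal weights and
  ≈288 days for cortical ones.  This is the only reading under which the
  reported phenomena exist at all: an untouched hippocampal trace must fade
  on the scale of a day or two for replay competition to erase a memory
  within a four-day schedule, while the cortical trace is effectively
  permanent over a week.  Dropping η from the decay (`decay_scaled_by_eta:
  false`) gives 18-day/432-day decay and a hippocampal store that never
  forgets within an experiment.
- **Inactivation speed in sleep (`sigma_g_sleep`).**  Sleep accelerates
  activation dynamics via σ_a (50× between the printed wake and sleep
  values).  The *fall* of each activation burst is driven by the
  inactivation current, so by default σ_g is scaled by the same
  sleep/wake ratio (10 → 0.2), making sleep dynamics an exact time-rescaled
  copy of wake dynamics.  With a wake-speed σ_g, replay bursts cannot
  terminate inside a 0.5 s UP state: replays stall as one long ignition
  with low-amplitude co-activation of successors, which both prevents
  full-sequence replays and lets every cued UP state potentiate cortical
  links far faster than the intended gradual, multi-night consolidation.
  Set `sigma_g_sleep` explicitly to pin any other value.

With these defaults, ten Day-1 training trials drive the mean hippocampal
forward weight to a peak of ≈86% of maximum while the cortical mean stays
≈15%, and nightly consolidation then raises the cortical mean roughly
0.16 → 0.32 → 0.43 → 0.53 → 0.61 across four nights.

## Experiments and the event-driven runner

An experiment is a list of days (training blocks, recall tests) plus
nightly SWS blocks, expanded onto a clock: day *d* occupies
[(d−1)·86400, d·86400) s, morning tests run at hour 8, training starts at
hour 9, a same-day test follows the last trial by 60 s, and sleep starts at
hour 23.  The published schedules give no wall-clock placement; these
defaults matter only through salience decay (τ_s = 1 day) and are
configurable.  Idle gaps are skipped analytically: activations and
inactivation currents are zeroed and weights/salience follow their exact
decay-only solutions.  Before each skip the runner integrates a settle
window (default 10 s) of zero-input dynamics so that the activity tail left
by the previous event decays — and depresses/accumulates into weights and
salience — the same way continuous integration would; a regression test
holds event-driven and fully-integrated one-hour timelines to within 10⁻⁴
relative on all weights.

Recall tests are probes with plasticity left on (recall strengthens
existing links) and integration continues after the 1.5 s cue until the
target completes or 30 s elapse.  New links can only be instantiated during
training presentations, at the first co-activation of two items above the
0.01 threshold, per region, bidirectionally at weight 0.

Sleep blocks draw one cue per UP state from the salience distribution
(items plus a null outcome of fixed salience 0.5), consume exactly one
uniform variate per draw from the experiment's single seeded generator —
the only stochastic element in a run, making runs bit-reproducible — and
pulse the cued item into the cortical input register.  DOWN states are
skipped in closed form (the state is zero; only weight decay applies).
Replay records attribute each cued UP state to the training sequence
containing its cue item; per-night replay shares use non-null cued UP
states as the denominator.  A replay counts as *full*, and gets a duration
(first-to-last crossing), only when every item of the attributed sequence
crosses the recall threshold within the UP state.

## Numerical choices and degenerate inputs

- Forward Euler at Δt = 1 ms everywhere; sleep dynamics have a 32 ms
  activation time constant, i.e. ≥30 steps per time constant.  Halving the
  sleep step changes per-night cortical weight growth by <1%.
- Threshold crossings are upward transitions of the cortical activation
  through 0.01; simultaneous same-step crossings are ordered by descending
  post-step activation (a deterministic tie-break; ties are grid artifacts).
- The 12.5 ms sleep pulse rounds to 12 steps on the 1 ms grid.
- Closed-form decay uses exp(−t/τ_eff); over a 12 h gap it agrees with the
  stepped Euler decay map to ≈2×10⁻⁹ relative, far inside the 10⁻⁵
  tolerance asserted in tests.
- Zero-size networks (no items yet), empty training sequences, unknown cue
  labels, negative gaps and malformed configurations raise typed errors;
  non-finite states raise a numerical-instability error naming the item.
- A compiled (numba) kernel integrates long segments; a pure-numpy
  reference stepper defines the semantics and a regression test holds the
  two paths to 10⁻⁹ relative agreement over hundreds of steps.

## What passing tests do and do not show

The simulator's "data" are self-generated: item sequences are abstract
labels, one neuron per item, with clean, noise-free drives.  Passing tests
therefore demonstrate the internal consistency of the dynamical model and
its published operating points — not that real hippocampal/cortical
populations behave this way.  Distributed item representations, overlapping
population codes, noisy afferents, neuromodulatory salience factors
(novelty, reward), sharp-wave-ripple structure, REM and multi-stage sleep
are all outside the model.

## Known limitations

- The replay-competition schedule reproduces graded recall degradation
  (recall times lengthen day by day once a rival sequence dominates sleep
  replay) but not a hard collapse of recall accuracy to the cue-only
  minimum within five days: under the published parameter set, partially
  consolidated cortical links (≳0.2) keep pushing successor items over the
  0.01 threshold, and probes-with-plasticity refresh the hippocampal trace.
  The corresponding acceptance check is retained and fails honestly.
- Skip links (e.g. A→C) form once training co-activations exceed threshold
  and strengthen during compressed replays; with long consolidation they
  can bring a successor's rival within milliseconds of an ordering error.
  Long-range/contextual recall is explicitly out of scope.
- Replay compression relative to waking recall spans roughly 20–120× at the
  default speed factors (which set a 50× ratio); the realized ratio of a
  given replay depends on the strength of the traversed weights.
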