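# Methods

## Model

The network is a single layer of n = 100 excitatory Izhikevich neurons
with all-to-all lateral connectivity (no self-connections) and
one-to-one feedforward wiring: input channel i drives neuron i only.
Membrane dynamics per neuron:

    dv/dt = 0.04 v² + 5 v + 140 − u + I + ε
    du/dt = a (b v − u)

with a = 0.02, b = 0.2. A spike is registered when v reaches
v_peak = 30 mV, after which v ← c and u ← u + d. The input current I
enters with a depolarizing sign: the network contains no inhibition, so
excitatory external and lateral drive must raise the membrane
potential. ε is uniform voltage noise in [−S_ε/2, +S_ε/2] with
S_ε = 0.6, redrawn independently for every neuron at every step.

The total current is I = I_ext + I_lat. External input contributes
S_ext when the neuron's channel carries a spike at the current step;
lateral input is the sum of incoming weights from neurons that spiked
on the **previous** step (one-step synaptic delay). The defaults
c = −65 mV, d = 8 are the standard regular-spiking parameterization for
a = 0.02, b = 0.2, and S_ext = 20 is chosen so that a single external
event reliably fires a resting neuron (one 1-ms pulse of 20 raises v
from −70 mV past the firing region); all three are configurable.

Integration is forward Euler at dt = 1 ms with a synchronous update:
spike flags of a step are determined from the post-update voltages, so
ordering among simultaneous spikes is irrelevant. If a voltage ever
becomes non-finite (possible under runaway weight growth with extreme
plasticity parameters) the simulation raises a numerical-blow-up error,
which the optimizer maps to fitness 0.

## Task and inputs

A stimulus is a 100-dimensional binary vector with a fixed number K of
active bits; sparseness Sp = |d₀−d₁|/(d₀+d₁) (K = 20, 10, 5 give
Sp = 0.6, 0.8, 0.9). A continual-familiarity stream of length N is
generated step by step: with probability p_new (default 0.5) the
stimulus is a fresh random pattern; otherwise it copies the stimulus
R steps earlier, provided that source exists, was itself novel, and has
not been repeated yet — so no pattern ever occurs more than twice and a
copy is labelled familiar (1). When the source is ineligible a fresh
pattern is emitted instead. Fresh patterns are re-drawn on collision
with any previously emitted pattern, which keeps labels exact even at
small K. At p_new = 0.5 the expected familiar fraction is 1/3.

Template-correlated pattern sets fix a binary template with K active
bits; each pattern inherits round(K·p_match) active bits (round half to
even) uniformly from the template's active positions and draws the rest
uniformly from its inactive positions, so sparseness is constant and
the expected template overlap is K·p_match.

Each presentation encodes the pattern as homogeneous Poisson spike
trains: every active channel receives a Poisson(rate·T/1000) event
count with times uniform over the T = 1000 ms window (rate 100 Hz);
inactive channels are silent. The encoder stores exact continuous event
times — so repeated draws have Poisson dispersion — and the
discretization to the 1-ms simulation grid (coincident events in one
bin collapse to a single step event) happens only when the train drives
the network. A familiar stimulus is re-encoded independently: only the
active-channel set is preserved, never the spike times.

## Plasticity

Per-neuron activity traces decay exactly exponentially each step
(A ← A·exp(−dt/τₐ)) and gain a_inc per spike. Within a simulation step
the weight update runs **before** the trace update, so a postsynaptic
spike is paired with the presynaptic trace as it stood at the end of
the previous step; this prevents a same-step spike pair from
reinforcing itself through its own fresh increments.

- Hebbian rule (η > 0): for every postsynaptic spiker i,
  w[i,j] += η·A[j] for all j ≠ i. Potentiation-only; inputs are
  rate-coded, so the rule emphasizes *which* neurons co-fire, not their
  order.
- Anti-Hebbian rule (η < 0): w[i,j] ← max(w_min, w[i,j] + η·A[j]·w[i,j]).
  The multiplicative form makes depression proportional to the current
  weight and the floor w_min > 0 prevents total connectivity collapse.
  w_min exists only for this rule (the Hebbian floor is 0).

Every norm_interval simulation steps, each neuron's incoming weights
are rescaled to sum to W_total (zero rows untouched). Normalization is
applied after clipping and may push weights below w_min; the floor is
re-applied at the next anti-Hebbian update. The interval counter runs
over simulation steps and persists across presentations. Weights are
initialized uniformly at random and row-normalized to W_total.

The network runs continuously: membrane state, traces and weights carry
over between presentations with no gap and no reset (a reset option
exists for ablation only).

## Decoding

Both readouts use only the stimulated population (neurons whose input
bit is 1); the network is purely input-driven, so other neurons are
silent. Spike count is the population-mean per-neuron count over the
window. Rsync convolves each binary spike train with exp(−t/τ),
τ = 5 ms, on the 1-ms grid over exactly T samples (no burn-in), then
divides the temporal variance of the population-mean trace by the mean
per-neuron temporal variance. Population-variance normalization is used
in both numerator and denominator — the ratio is insensitive to the
shared convention. An all-silent population scores 0.

Classification is a threshold: Hebbian networks call values **above**
threshold familiar (repetition enhancement), anti-Hebbian networks call
values **below** threshold familiar; exact ties are novel. The
threshold is fitted by scanning midpoints between consecutive sorted
unique metric values plus ±sentinels, maximizing balanced accuracy
Acc = (1−f_new)·P_TP + f_new·(1−P_FP), f_new = 1/(1+p_new); accuracy
ties break toward the smaller threshold, and the sentinel guarantees
the fitted threshold never scores below the constant classifier.

## Genetic optimization

Each generation holds 12 parameter sets: the 3 best of the previous
generation (elites, copied unmodified), 3 mutants (one uniformly chosen
parameter of an elite scaled by U(0.75, 1.25), clamped to its range,
integers re-rounded), 3 crossovers (the three elite pairs; each child
takes a random half of the parameter names from one parent — the extra
name from the first on odd counts), and 3 freshly sampled sets.
Fitness is the balanced accuracy of a fresh network on a freshly
generated N = 300 stimulus stream with a freshly fitted threshold; a
new dataset per generation prevents the threshold from overfitting one
sequence. Termination: 300 generations, any fitness reaching 1.0, or no
strict improvement of the generation best for 15 consecutive
generations. The best-ever individual's threshold is frozen for
subsequent evaluation.

Sampling ranges (package defaults, logged with every run): η magnitude
log-uniform in [1e−4, 1]; τₐ ∈ [1, 500] ms; a_inc ∈ [0.1, 5];
W_total ∈ [1, 200]; norm_interval log-uniform integer in [1, 10⁴]
steps; w_min ∈ [0, 1] (anti-Hebbian only — a static bound covering the
regime where the floor is a small fraction of the per-connection share
of W_total). The stagnation rule tracks strict improvement of the
generation-best fitness.

## Experiment protocol

A protocol cell is (rule, metric, sparseness, optimization R). Each
replicate runs an independent GA at the fixed R, then evaluates the
frozen parameters and threshold on fresh 500-stimulus streams for every
R in 1…30 with plasticity on; generalizability is the mean accuracy
over the swept R values. Seeding is hierarchical from one master seed
via `numpy` SeedSequence spawning (master → replicate → GA / sweep
streams), so every run is bit-reproducible and evaluation data are
disjoint from optimization data.

## Connectivity analysis

Learned matrices are first rescaled by dividing by the incoming-weight
total, putting runs with different W_total on a common scale. The Gini
index is computed over all off-diagonal entries, zeros included
(inequality "across the network"), via the pairwise-difference
definition Σᵢⱼ|xᵢ−xⱼ|/(2n²·mean). Transitivity and betweenness
centrality operate on a binarized, symmetrized graph: edge (i,j) iff
max(w[i,j], w[j,i]) strictly exceeds a threshold, by default the mean
positive off-diagonal weight (so an all-equal matrix yields an empty
graph). Betweenness is normalized by (n−1)(n−2)/2 and summarized by its
mean over nodes. Binary rather than weighted graph metrics were chosen
because they have standard, exhaustively testable definitions; the
threshold is configurable.

## Numerical and testing choices

- The reference Hebbian parameter set used in the end-to-end tests
  (η = 0.5, τₐ = 60 ms, a_inc = 1, W_total = 50, norm_interval = 1000
  steps, S_ext = 20) was hand-tuned at sparseness 0.9, R = 3; it is
  also the package default.
- Test problem sizes are scaled to keep the suite fast: the end-to-end
  check uses 100-stimulus streams over 10 seeds, and the optimizer
  smoke test runs 10 generations on 50-stimulus evaluation sets. The
  full protocol (500 stimuli, 300-stimulus GA evaluations, 20
  replicates) is available through the experiment module and CLI.
- The repetition-enhancement check warms the network up with three
  novel stimuli before the probe pair: a cold-started network fires
  extra spikes on its very first presentation because spike-frequency
  adaptation (u) has not yet built up, which would mask the
  enhancement; in continuous operation the network is always adapted.
- Graph-metric correctness is verified against independent brute-force
  enumeration (triangle/triple counting and exhaustive simple-path
  search) on every graph of up to 7 nodes, with `networkx` serving as
  the production implementation.

## What the synthetic task does and does not show

The generator reproduces the study conditions exactly: random binary
patterns of fixed sparseness, geometric repeat structure with
p_new = 0.5, optional template correlations, rate-only Poisson
encoding. It does not emulate natural-stimulus statistics, graded
activations, overlapping receptive fields, or inhibitory circuits, so
passing tests demonstrate the mechanism (familiarity stored in lateral
weights and read out from rate or synchrony) rather than performance on
real sensory data.

## Known limitations

- With long normalization intervals and large η, Hebbian weight growth
  can run away within a window and overflow the Euler integrator; this
  is detected and reported (fitness 0 during optimization) rather than
  prevented.
- The anti-Hebbian regime is fragile by construction (depression erodes
  the very structure the decoders need) and typically performs near
  baseline at high sparseness.
- Exact Izhikevich reset values (c, d) and the input scale S_ext are
  convention-based defaults, not fitted quantities.
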