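# Methods

## The decoding problem

An anesthetized-rat barrel column is driven by whisker deflections of three
amplitudes (large/medium/small ↔ 2.8/2.0/1.6 V piezo drive, 5 ms pulses,
61/63/61 trials) while a laminar probe records 27 in-cortex channels across
layers II–VI. Under urethane-like anesthesia the cortex alternates at
roughly 1 Hz between active UP and quiescent DOWN states, which condition
the evoked responses. The package asks: can the deflection amplitude be
decoded from the local field potential (LFP) or the multi-unit activity
(MUA), and how do hand-crafted evoked-response features, classical machine
learning and spiking neural networks compare?

Because the in-vivo recordings are not publicly downloadable, every
quantitative result in this repository is computed on data from the
synthetic generator below. The pipeline itself is agnostic to the source:
it consumes an HDF5 recording plus a stimulus table.

## Synthetic recordings

`synth.generate_recording` plants, into Gaussian broadband noise
(default sd 5 µV):

- **States.** Alternating UP/DOWN intervals with gamma-distributed
  durations (shape 2, mean 0.5 s per state, i.e. a ~1 Hz cycle). The gamma
  shape avoids degenerate near-zero intervals. Background MUA is Poisson
  per channel: 12 Hz during UP, 0.5 Hz during DOWN by default; spikes are
  rendered as ~1.2 ms biphasic waveforms (−70 µV peak) that live in the
  300–3000 Hz band.
- **Evoked LFP.** A difference of alpha functions per channel: the fast
  negative lobe starts 8 ms after stimulus onset and troughs at 25 ms
  (3 ms later for small stimuli — the planted latency effect), followed by
  a slower positive rebound within 100 ms (0.35 of the trough magnitude).
  Trough magnitude = intensity gain (300/220/150 µV) × layer gain (III and
  IV largest, 1.0; VI smallest, 0.35) × 1.4 when the stimulus falls in a
  DOWN state.
- **Evoked MUA.** A spike burst within 100 ms whose per-channel expected
  count scales with intensity (6/4.5/3) and layer gain, and whose first-
  spike latency is 7 ms + 4 ms in DOWN + 4 ms for small stimuli (sd
  1.5 ms); later spikes follow an exponential (6 ms) inter-spike cascade.
- **Truth sidecar.** `truth_state` and `truth_peak` columns are split off
  by `split_truth` and are consumed only by tests, never by the pipeline.
  `truth_state` is deliberately the *windowed* UP context — UP activity
  anywhere in the 50 ms pre-onset window — because that is exactly what the
  state labeler is defined to report; the evoked gains themselves use the
  instantaneous state at onset. The two differ on the few trials with a
  state transition inside the window.

The generator's defaults are the study conditions (185 trials, 27
channels, layer partition 4/5/5/4/4/5 summing to 27 along the 65 µm-pitch
probe). The inter-stimulus interval defaults to the desk-test value of
1.5 s; the in-vivo protocol's 10 s is a config switch — none of the
computed quantities (firing rates, features, accuracies) depend on the gap
length, which exists in vivo to avoid adaptation, a phenomenon the
generator does not model. Sampling rate defaults to 10 kHz (25 kHz
accepted) to keep session arrays small.

What the generator does **not** emulate: electrode drift and gliosis,
spike-waveform diversity and overlap, non-Gaussian or spatially correlated
noise, adaptation across trials, traveling slow waves, and any intrinsic
coupling between network state and response variability beyond the planted
gain/latency shifts. Passing tests therefore show that the pipeline's
machinery recovers planted structure at realistic scales — not that the
in-vivo effect sizes or accuracies are reproduced.

## Preprocessing

Band splitting uses zero-phase (forward–backward) elliptic filtering —
zero-phase so that band filtering cannot bias onset-latency estimates.
Defaults: order 4 per section, 0.01 dB passband ripple, 40 dB stopband.
The small ripple keeps double-filtering of in-band signals within 1 % RMS.
Two numerical realizations matter:

- The spike band (300–3000 Hz) is a high-pass/low-pass elliptic cascade;
  a single wide-band design of the same order is numerically poor.
- The LFP band's 0.1 Hz corner cannot be realized as a float64 IIR at
  these sampling rates (pole radii within 1e-4 of the unit circle produce
  several-percent passband error). The low cut is therefore implemented as
  baseline subtraction: the 300 Hz-low-passed trace is block-averaged to
  10 Hz, the same elliptic low-pass at 0.1 Hz is applied there (well
  conditioned), and the interpolated baseline is subtracted. Traces
  shorter than ~4 s fall back to mean subtraction.

Spike detection thresholds |x| at 3·σₙ with σₙ = median(|x|)/0.6745 — the
robust estimate that avoids threshold inflation by the spikes themselves;
plain SD and single-polarity detection are config options. A 1 ms dead
time makes one waveform yield one spike time. Note an intrinsic property
of a 3σ threshold: on Gaussian noise it admits a false-crossing floor
(≈0.27 % of samples) that is independent of the noise amplitude; state
detection therefore relies on the UP-rate contrast standing well above
that floor, as it does in vivo.

MUA events are maximal spike runs with gaps strictly below 20 ms; ties at
exactly 20 ms split events. Layer-scope grouping pools member channels'
spike times first.

## State detection

Per electrode, the instantaneous firing rate is the spike count in a 10 ms
window stepped by 1 ms (expressed in Hz; only the scale-invariant
comparison to the threshold matters). The cumulative trace sums all
electrodes and is thresholded strictly above its global session mean
(computed over the full session, evoked epochs included). Each window is
timestamped by its **end**: with start-timestamps a post-stimulus burst
would activate windows beginning up to 10 ms before the stimulus and leak
into the pre-stimulus investigation window — the causal alignment removes
that artifact. A stimulus is UP when a supra-threshold run intersects the
half-open window [onset − 50 ms, onset), so the onset sample itself never
contributes; zero-activity traces label everything DOWN.

## Evoked features

From the layer-averaged LFP, downsampled to 2500 Hz (1000 Hz on the
classifier path):

- **ROL** — first instant within 20 ms of onset where |d(trace)/dt|
  exceeds mean(bas′) + 3·sd(bas′), bas′ being the derivative over a
  pre-stimulus baseline (10 s nominally; shorter baselines are a parameter
  and the tests use 1 s with the 1.5 s inter-stimulus interval). No
  crossing → missing value.
- **RPA** — the onset-to-trough drop |trace(ROL) − RP|, RP the most
  negative value within 50 ms of ROL. The drop is the reading that is
  positive and monotone in response size; a literal signed sum of the two
  voltages can cancel.
- **PR** — maximum positive voltage within 100 ms after the main peak;
  absent when the window never goes positive.
- **tLFP** — AUC/RD, where RD runs from ROL to the first return to the
  ROL-instant voltage after the main peak (capped at 300 ms and flagged
  when capped) and AUC is the unsigned area between trace and that level.
- **MUA features** — first MUA event with onset < t1 ≤ onset + 100 ms:
  latency t1 − onset, duration t2 − t1, rate n/duration (missing, not
  infinite, for single-spike events). Duration is computed although, as on
  the real data, it carries little information.

## Statistics

Rank-sum, Kruskal–Wallis and Dunn tests are implemented from their
formulas with midrank tie corrections; scipy is used only as a
cross-check oracle in the tests. The rank-sum p-value is computed by exact
enumeration of rank assignments whenever C(n₁+n₂, n₁) ≤ 2·10⁵ and by the
tie-corrected normal approximation otherwise (full enumeration at two
samples of 20 would be ~10¹¹ assignments). Identical constant samples
yield p = 1. The significance grid mirrors the study's layout: per layer
and feature, diagonal cells are UP-vs-DOWN rank-sum tests per intensity;
triangles are intensity pairs within UP (upper) and DOWN (lower) via
Dunn's z gated on a Kruskal–Wallis rejection at α = 0.05. Dunn p-values
are unadjusted by default (Holm by flag); no grid-wide multiplicity
correction is applied. Star levels: * ≤ 0.05, ** ≤ 0.01, *** ≤ 0.001,
**** ≤ 1e-4. Directions come from median differences.

## Threshold-crossing encoding

N_thresh = 50 thresholds are spaced uniformly over the signal range at the
midpoints of N equal bins — strictly inside the range, so a full-range
monotone sweep crosses every threshold exactly once. A rising channel
fires at sample t+1 iff x_t ≤ ϑᵢ < x_{t+1} (strict on the new sample);
falling channels mirror this. The range is the pooled min/max of the
training split, fixed at test time to avoid leakage (per-trial ranges are
a config option). A staircase reconstruction (signed event count ×
threshold step) inverts the code to within one step and serves as a
property test.

## Liquid state machine

LIF neurons with exponential PSCs: V_rest = 0 mV, C_m = 30 pF, τ_m =
30 ms (so R = 1 GΩ and the 7 pA constant current rests the membrane at
7 mV, comfortably below the 15 mV threshold), τ_syn 3 ms (E) / 2 ms (I),
refractory 2 ms, reset 13.8 mV. Each neuron receives exactly 2 excitatory
and 1 inhibitory recurrent connection; weights are drawn per class
(EE N(100,70), EI N(500,350), IE/II N(−400,280) pA) and clipped to their
sign; delays N(10,20) ms clipped to [3,200] ms. Inputs fan out to 4
random excitatory targets with U(15,45) pA (MUA, 27 channels, 100 E +
25 I neurons) or U(250,750) pA (encoded LFP, 100 channels, 330 E + 80 I).
Each neuron also has an independent 100 Hz Poisson noise generator with
weight N(2,1) pA (the noise source is unspecified in the original
description; a per-neuron Poisson generator is this package's choice).

Recurrent synapses are dynamic: event-driven Tsodyks–Markram updates with
per-class (U, τ_rec, τ_fac) means EE (0.5, 1.1 s, 0.05 s), EI (0.05,
0.125 s, 1.2 s), IE (0.25, 0.7 s, 0.02 s), II (0.32, 0.144 s, 0.06 s),
jittered ±50 % per synapse — the classic cortical-microcircuit convention
these parameters were adapted from. Utilization and resources provably
stay in [0,1].

Integration is fixed-step at 0.1 ms with delays rounded to the grid;
initial membrane potentials are uniform over [0, θ) to desynchronize the
network (the −70 mV table value is available as an init option but is an
artifact of a different convention). Simulations abort on non-finite
state. With default weight scales the mean population rate on synthetic
MUA input is ~16 Hz, below the 50 Hz operating bound the liquid is
calibrated to. The excitatory spike trains are exponentially filtered
(τ = 5 ms) and read 45 ms after onset (the MUA variant mirrors the LFP
values, which are the only ones stated); each trial is simulated with 1 s
of pre-onset input so spontaneous activity shapes the liquid. The readout
is a one-vs-one linear SVM; its C and the input/E/I weight scales are the
grid-searched hyperparameters.

**Hardware profile (DYNAP-SE).** Synapses are grouped by sign and synaptic
time constant into at most four types; each type's unit magnitude is the
median |w| of the type and every synapse becomes round(|w|/unit) parallel
unit connections. Per-neuron fan-in (recurrent + input connections,
counting multiplicity) is truncated to 64 by trimming the largest
multiplicities first (deterministic). Delays are zeroed, dynamics become
static, and τ_m, θ, V_reset and C_m are jittered per neuron by N(1, 0.2)
clipped at ±2 sd. Without short-term depression the hardware liquid runs
hotter at unit scales; the weight-scale grid search is the intended
counterweight.

## BPTT-trained spiking network

Discrete time, δt = 1 ms, τ = 20 ms (α = exp(−δt/τ) ≈ 0.951), R_m = 1 GΩ,
threshold b = 0.01 interpreted in volts (10 mV — consistent with GΩ × pA
scales; a unitless reading is a config flag), refractory 2 ms (duration
unstated; mirrors the liquid). Membrane update V ← αV + (1−α)R_m·I with
reset by subtracting b at the spike step. The spike derivative w.r.t. the
normalized potential v = (V−b)/b is γ·max(0, 1−|v|) with γ = 0.3.
Readouts are three leaky integrators (τ = 20 ms) with a softmax on their
values at the end of the 50 ms post-onset window; loss is cross-entropy
plus an L1 penalty, optimized by plain SGD (momentum is not used) with the
learning rate halved after 10 stalled validation epochs and early stopping
at the best validation accuracy.

Connectivity matches the liquid's scheme (2E+1I in-degree, 4-target input
fan-out) and is kept there by a rewiring rule in the Deep-Rewiring family:
weights are sign × magnitude with magnitude ≥ 0; a magnitude driven
negative goes dormant and a fresh connection is resampled uniformly among
free scheme-respecting slots, so the live count is invariant. Optional
Gaussian parameter noise (the rewiring temperature) is scaled by √lr.

The backward pass is hand-derived and verified against finite differences
of a "soft" forward pass in which the hard spike is replaced by the exact
antiderivative of the pseudo-derivative — making the analytic BPTT
gradient the true gradient of that differentiable network.

## Baselines

- **FF**: one hidden layer of 80 ReLU units on the 50-sample 1 kHz
  post-onset LFP window, per-feature standardized with training-split
  statistics (zero-variance columns guarded); L-BFGS (50 iterations,
  step 0.001), L2 1e-3, init U(−k,k) with k = 1/√fan_in (1/fan_in by
  flag), early stopping by per-iteration validation accuracy.
- **LSTM**: 64 units fed the same window sequentially through one input;
  SGD lr 0.1, momentum 0.9, batch 32, 250 epochs, early stopping; forward
  and backward passes are hand-written NumPy.
- **HC+RF**: 100-tree random forest on {RPA, PR, ROL, tLFP, window mean,
  window sd}; grid over features-per-tree, min-samples-split and
  Gini/entropy.
- **RF (MUA)**: the same forest on per-channel exponentially filtered
  spike counts (τ = 16 ms) read 30 ms after onset.

## Evaluation protocol

Each evaluation is 20 independent runs (count configurable): fresh
stratified 80/20 train/test split, 20 % of train as validation, grid
search by validation accuracy, one test evaluation; the report is the
mean ± sd of per-run test accuracies (sd over runs, never within-run).
Stratification protects the ~185-trial scale from empty-class test sets;
a flag restores plain random splits. LSM runs resample the network wiring
along with the split. State-conditioned evaluation trains on all data and
scores UP-only and DOWN-only test subsets; layer-conditioned evaluation
reruns the full encoded-LFP LSM pipeline per cortical layer. PSTHs use
4 ms bins aligned to onset.

## Problem sizes and numerical choices in the shipped tests

The test suite and acceptance script choose sizes that exercise the full
pipeline at desk scale: unit tests run on 15-trial sessions; planted-effect
recovery and state-labeler agreement use 30 trials/class at a high-SNR
condition (UP 80 Hz vs DOWN 0.2 Hz per channel, noise sd 2 µV — a firing
contrast far above the 3σ detector's false-crossing floor); the end-to-end
classification check uses 45 trials over 5 protocol runs; the
no-planted-state-effect check averages the UP/DOWN accuracy gap over five
independently generated datasets, because within one ~60-trial dataset the
gap is dominated by which intrinsically hard trials happen to carry which
state label; the acceptance script simulates all 185 trials. Seeds fix
every stochastic component; identical configurations are bit-reproducible.

## Known limitations

- Synthetic accuracies are not comparable to in-vivo ones; effect sizes
  are planted, noise is white and Gaussian, and trial counts are small.
- The hardware-constrained liquid is a software emulation; analog-circuit
  temporal dynamics (slow/fast synapse time constants per type, mismatch
  correlations) are reduced to the documented four-type quantization and
  parameter jitter.
- The exact-enumeration rank-sum path is bounded by combination count, so
  moderately sized samples use the normal approximation.
- Pairwise class probabilities for the readout are softmax over SVM
  decision values rather than a pairwise-coupling estimate.
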