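# Methods

## Circuit models

Neurons are stochastic leaky integrators on a discrete grid of step `δt`
(1 ms for the synthetic benchmark, 2 ms for real-style protocols).  The
membrane voltage follows

    v_j^t = α_j v_j^{t−1} + (1 − α_j) u_j^t − v_thr,j z_j^{t−1} + ξ_j^t,

with `α_j = exp(−δt/τ_m,j)`, `τ_m` 30 ms for excitatory and 10 ms for
inhibitory cells, and input current `u` summing delayed recurrent spikes
(divided by `δt`), the binary 10 ms stimulus pulses through non-negative
input weights, and any injected perturbation current.  Voltages are
dimensionless; thresholds initialize at `v_thr = 1` and are trainable.
The noise `ξ_j^t` is Gaussian with sd `β_j v_thr,j √δt` (β initialized at
0.14) and is *counter-based*: the draw for (trial, neuron, step) is fixed by
the trial seed alone (`numpy` Philox streams keyed by `(seed, trial)`), so a
perturbation current changes a simulation only through its own effect, never
by shifting the noise stream.  This makes perturbed/unperturbed differences
exact per trial and gives the feedforward-closure property: if a structural
mask forbids all B→A synapses, any perturbation confined to B leaves A's
spikes bit-identical.

Spikes are Bernoulli with escape probability `min(1, exp((v − v_thr)/v_0))`
followed by a 4 ms absolute refractory period (subtractive reset `−v_thr z`).
The escape temperature `v_0` is not a measured quantity; the default is
`0.2 · v_thr,init` and it is saved with every model.  The sigmoidal ("no
spike") variant replaces the draw by the rate `σ((v − v_thr)/v_0)`, keeps the
same additive voltage noise, and by default applies no reset and no
refractoriness (both recorded in the model archive).

Delays: each synapse carries one delay drawn uniformly from {2, 3} ms with a
stored seed; delays round half-up to steps (3 ms → 2 steps at δt = 2 ms), so
a delay never becomes acausal.

Jaw readout: `ỹ_t` integrates delayed excitatory spiking with
`τ_jaw = 5 ms`; the movement is `y = exp(ỹ) + b`.  Inhibitory weights are
structurally zero.

## Losses and optimization

Both data terms z-score with statistics of the *recorded* data, frozen from
the full training set (not per minibatch).  The PSTH term filters
trial-averaged activity with a centered 8 ms boxcar (edge replication; the
filter is a dense matrix so its adjoint in the backward pass is exact) and
normalizes per neuron by the data trace's time mean/sd.  The trial-matching
term filters per-trial area-average traces with a 32 ms boxcar, normalizes
per (area, time) by the data's trial mean/sd, concatenates areas (and the
jaw as an extra area when present), and minimizes over one-to-one trial
assignments with the exact Hungarian solver; with several sessions the loss
is the average of per-session terms.  Zero-variance denominators are floored
at 0.1 × the mean positive sd and flagged.  Trial-count mismatches are
resolved by seeded subsampling of the larger side.

Gradients are computed by backpropagation through time written directly in
numpy.  The spike discontinuity uses the piecewise-linear surrogate
`max(0, 1 − |(v − v_thr)/v_0|) · (dampening/v_0)` evaluated on the linear
argument, zeroed during refractoriness; dampening defaults to 0.3.  On the
sigmoidal variant the pass is exact: every parameter gradient matches
central finite differences to < 1e−4 relative error (tested).  The PSTH and
trial-matching gradients are rescaled to unit global norm before summing
(a parameter-free way to give both objectives comparable influence; the
reweighting is pluggable).  The optimizer is Adam, default learning rate
1e−3, with a projection after every update: negative efficacies clipped to
zero (Dale's law), cross-area inhibitory and masked entries re-zeroed, jaw
weights of inhibitory neurons re-zeroed.

Two numerical guards exist because the escape-noise parameterization makes
the surrogate *sparse*: at baseline rates of a few Hz the voltage sits
several noise-sd below threshold, so the triangular surrogate is active in
only ~0.1–1% of neuron-steps, and the optimization (i) needs input weights
initialized strongly enough that the stimulus visibly drives the network
(default input scale 4.0 in threshold units; with weak input the response
window never produces near-threshold events and the stimulus pathway cannot
learn), and (ii) keeps a floor under the trainable noise scale β (default
0.05; 0.10 during reference-circuit construction).  Without the floor the
optimizer quenches β early — trial-to-trial variability is expensive for the
losses at baseline times — which kills both the hit/miss variability the
benchmark requires and the surrogate gradient flow itself.

Sparsity: a p = 1/2 penalty (sum of square roots) on efficacies above the
pruning threshold α = 1e−7, with weights λ1 (input), λ2 (all recurrent), λ3
(cross-area blocks); entries below α are pruned to exactly zero and stay
pruned (this also removes the |w|^{−1/2} singularity).  Pruning activates
when any λ is nonzero.  λ3 is chosen by the provided grid-search utility as
the largest value whose held-out trial-matching loss stays within 5% of the
λ3 = 0 loss; defaults are λ1 = λ2 = λ3 = 0.

Stopping: a fixed step count (the synthetic-dataset rule; the full-scale
default is 4000 steps), or checkpoint selection by trial-type accuracy
closest to the data plus highest trial-matched correlation (the real-data
rule).  Divergence restores the last finite checkpoint.

Fitting modes: reference-circuit construction trains recurrent and input
weights, thresholds and noise scales; network reconstruction trains the
recurrent weights only, inheriting everything else from the reference
circuit; real-data mode additionally trains the jaw readout.

## Synthetic benchmark

The generator emulates two cortical areas that respond together (hit) or
stay quiescent together (miss), each with probability 0.5.  Per-neuron
baselines are log-normal with mean/sd 2.9/1.25 Hz (excitatory) and
4.47/1.31 Hz (inhibitory); hit trials add a double-exponential transient
(rise 5 ms, fall 20 ms; the equal-τ limit degenerates to the alpha function)
delayed 4 ms in area A and 12 ms in area B.  The transient's
population-average peak is 20 Hz above baseline with mild log-normal
(σ = 0.4) heterogeneity across neurons.  Target "recordings" are
inhomogeneous-Bernoulli spike trains around these rate profiles, so the data
side of every loss carries realistic Poisson-like trial-to-trial
variability.

A trial is a hit when area A's population rate, averaged over the response
window, exceeds 8 Hz.  The window is stimulus onset to onset + 60 ms.  A
200 ms window was considered and rejected: with a 20 Hz peak and ~3.2 Hz
baseline the double-exponential transient adds only ~3.2 Hz to a 200 ms
average (total ~6.4 Hz), leaving the 8 Hz threshold unreachable on hit
trials, whereas the 60 ms window yields ~13.8 Hz (hits) vs ~3.2 Hz (misses)
— the threshold separates the modes with many standard errors on a
250-neuron area.  The window is configurable.

Reference circuits RefCirc1 (feedforward: the B→A block removed from the
structural mask, hence exactly zero at every step) and RefCirc2 (recurrent)
are trained against the same targets in reference mode with the
checkpoint-selection stopping rule (trial-type accuracy + trial-matched
correlation on held-out target trials).  Their initialization boosts the
cross-area blocks by a factor of 8 before balancing and spectral
normalization, so that inter-area projections are dynamically effective —
the benchmark's whole question is whether inter-area coupling carries
signal.  Full-scale defaults are 2 × 250 neurons, 2000 generated trials
(half train/half test), 4000 steps.

What the generator does *not* emulate: correlated (shared) noise across
neurons beyond what the recurrent dynamics produce, slow non-stationarity
across trials, behavioral covariates beyond the hit/miss dichotomy, and
multi-session unit non-overlap (the stitching machinery is exercised with
synthetic splits).  Tests passing on this benchmark therefore demonstrate
the machinery and the structural claims (sign constraints, closure,
gradient laws), not fidelity to any particular in-vivo dataset.

## Perturbations

Optogenetic inactivation injects a current into an area's inhibitory
population, activation into its excitatory population; synthetic defaults
are Δu = 1.0 and 0.08 respectively in a 40 ms square window from 20 ms
before to 20 ms after stimulus onset, scalable by a light-power factor.
Real-style windows (stimulus: whisker ± 100 ms; delay: whisker + 100 ms to
cue − 100 ms; choice: cue to trial end) target inhibitory cells; stimulus
and delay windows ramp linearly to zero over the final 50% of the window to
avoid rebound excitation (ramp fraction configurable).  Model quality on
perturbed trials is scored by the change of hit (or lick) probability
relative to the reference and by the trial-matching distance restricted to
non-targeted areas, normalized with the reference's unperturbed statistics.
Lick classification uses a multilayer perceptron with two 128-unit hidden
layers trained on labeled jaw traces.

## Gradient-targeted µ-perturbations

Sensitivity maps g = dY/du of the integrated movement come from the same
backward pass (exact for the sigmoidal variant, surrogate for spiking).  The
first-order prediction ΔY ≈ Σ_I g Δu is validated by matched-seed
perturbed/unperturbed pairs; its residual shrinks at least linearly with
amplitude on the differentiable model.  Target selection takes the k most
extreme summed gradients in a 100 ms window (k = 20; the zero-norm control
takes the 40 smallest |g|).  The closed-loop protocol records a preparation
to t* = cue − 100 ms, retrieves the nearest databank trial by squared
distance between 32 ms-filtered, per-area-normalized population traces
truncated at t* (scikit-learn nearest neighbors), and delivers the
µ-perturbation (default amplitude 0.1, 10% of an inactivation) at t*.

A caveat documented deliberately: on *untrained* spiking networks at low
rates the surrogate map underestimates the influence of neurons whose
voltages rarely approach threshold, so the zero-gradient-norm control is
only meaningful where gradients are accurate (the differentiable variant, or
well-fitted spiking models in an active regime).  The directional claims
(high-gradient targets increase movement, low decrease, shuffled in
between) hold on spiking models in an active operating regime (~30 Hz,
threshold 0.4) where near-threshold events are common.

## Scaled-down study sizes

Full-scale defaults (250 neurons/area, 2000 trials, 4000 steps) are kept as
package defaults.  The test suite and the acceptance script run the same
pipelines at reduced sizes chosen once: 50 neurons/area (40 excitatory/10
inhibitory), 200 ms trials, 256 target trials, 1200 reference-training steps
with batch 32 for the reference circuits; 400-trial datasets and 150-step
reconstruction fits for the model-comparison experiments (three seeds per
variant); 100 neurons/area and 120 steps for the acceptance script's
feedforward-closure circuit, whose reported quantity (Δ hit rate = 0) is
exact at any size by structural closure.

## Known limitations

- The benchmark's reduced-scale reference circuits reproduce the
  bimodal hit/miss statistics only approximately (the hit-rate band is
  enforced by checkpoint selection rather than full convergence); the
  response distribution straddles the 8 Hz threshold more narrowly than a
  fully converged large-scale circuit would.
- At reduced scale, reference training shrinks the recurrent circuit's
  learned feedback towards zero: the targets make area A's rates
  conditionally independent of B given the trial type, so feedback only
  earns its keep through the jointly-bimodal trial statistics, which the
  reduced-scale optimization reaches only approximately.  The
  hypothesis-separation property (perturbing B changes A's dynamics under
  recurrence but not under the feedforward mask) is therefore asserted on
  constructed circuits with live feedback; on trained micro instances the
  feedforward closure side remains exact while the recurrent side's
  response can be arbitrarily weak.
- Surrogate gradients are biased where the triangular kernel is inactive;
  gradient-based claims are exact only for the sigmoidal variant.
- Conductance-based dynamics, short-term plasticity, multi-compartment
  neurons and non-binary per-bin spike counts are out of scope, as are
  spike sorting, video processing and NWB ingestion.
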