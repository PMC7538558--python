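# Methods

This note documents the models, the synthetic retina, the numerical
choices and the known limitations of `rgcmodes`.

## Synthetic retina

The generator stands in for a mouse retina explanted onto a 64×64
CMOS-MEA (42 µm pitch) and stimulated through a projector at 30 Hz.  It
is deliberately the *simplest* encoder that produces the statistical
structure the analysis assumes: stimulus-locked population modes, and
receptive-field-like unit averages.

**Encoding model.**  Each neuron is a linear–nonlinear unit

    rate_n(t) = baseline_n + gain_n · max(⟨k_n, frame_{t−latency_n}⟩, 0)

with a difference-of-Gaussians kernel k_n = ±(G(σ_c) − G(σ_s)), both
components normalized to unit mass so the kernel integrates to zero and
uniform frames evoke exactly the baseline.  Defaults: σ_c ~ U(3.5, 4.5)
px with σ_s = 2σ_c (receptive fields a few hundred µm across at the
42 µm pitch), gain 150 Hz per unit drive and baseline 2 Hz, which give
mean rates ≈ 5 Hz and peak rates ≈ 25 Hz under a contrast-0.5 grating —
realistic RGC territory; latency 2 frames (≈ 67 ms).  ON/OFF polarity
is assigned at random (50/50).

**Visual angle.**  The paper-style spatial frequencies are in
cycles/degree, so a pixels↔degrees convention is required; the full
64-pixel frame width is fixed at 45° of visual field.  This puts the
three grating frequencies used in the impairment protocol (0.011,
0.023, 0.045 cpd) at 0.5, 1.0 and 2.0 cycles per frame.  Any fixed
convention preserves the frequency ordering, which is all the analysis
uses.

**Impairment.**  Progressive GABA-receptor blockade is emulated as a
graded loss of spatio-temporal precision, not as receptor biophysics.
Level ℓ ∈ {0, 1, 2} adds a blur width b_ℓ ∈ {0, 6, 12} px in quadrature
to both kernel sigmas — exactly equivalent to convolving the kernel
with a Gaussian, so the response to spatial frequency f is attenuated
by exp(−2π²f²b_ℓ²): monotone in level and strongest at high frequency.
Latency jitter sd {0, 3, 6} frames is applied as its *expected* effect,
a temporal Gaussian smoothing of the driven rate, which keeps
`simulate_rates` deterministic (stochasticity enters only through spike
generation).  These two mechanisms produce the qualitative physiology
the analysis is meant to detect: information loss that grows with
impairment and bites hardest at fine gratings, with counterphase
confusion in the latent states.

**Spike generation.**  Spikes are drawn from a log-Gaussian Cox
process: Poisson counts per frame bin with intensity
rate · exp(z − sd²/2), z a squared-exponential Gaussian-process draw
(sd 0.25, lengthscale 0.1 s by default).  The −sd²/2 correction keeps
the expected count equal to the time-integral of the supplied rate.
With sd = 0 the process is plain inhomogeneous Poisson.  The generator
therefore matches the model family the rate-inference stage assumes,
which is the point: inference is tested against its own assumptions.

**What the generator does not emulate:** retinal circuit dynamics
(adaptation, gain control, surround delays), correlated noise across
neurons beyond stimulus-driven correlations, spike-sorting errors, and
electrode-level artifacts.  Passing tests therefore demonstrate that
the analysis chain recovers structure *when its assumptions hold*, not
that it is robust to everything a real recording contains.

## Rate inference

Counts y_b in Δ = 1/30 s bins are modeled as y_b ~ Poisson(exp(g_b))
with g ~ GP(μ, K), K squared-exponential.  The MAP of g is found by
Newton iteration in the numerically stable B = I + W^{1/2} K W^{1/2}
form with a backtracking line search in the whitened parametrization;
non-convergence raises rather than returning partial output.  The rate
is exp(ĝ)/Δ, strictly positive by construction.

Hyperparameters: kernel variance 1.0; prior mean = each neuron's
empirical log mean rate; lengthscale 0.25 s by default.  The experiment
protocols use 0.1 s instead, chosen to resolve the 8 phase bins
(125 ms) of a 1 Hz grating.

On the sinusoidal benchmark (5 + 4 sin(2πt) Hz, 30 s, one train) the
MAP achieves ≈ 2.5–2.8 Hz RMSE.  This is the information-limited
regime: ~150 spikes must constrain a 1 Hz modulation, and a kernel
smoother with truth-tuned bandwidth does *worse* (≈ 3.2 Hz).  Only an
estimator told the rate is periodic (cycle averaging) does materially
better; the LGCP prior does not encode periodicity.

**Selection filter.**  A neuron is kept if max−min of the
finite-difference derivative of its inferred rate exceeds a threshold.
Two documented consequences: linear ramps score 0 (ramping cells count
as tonic), and the threshold must sit above the *noise floor* of the
inferred rates — a genuinely tonic neuron's LGCP fit still wiggles.
The protocol default (10 Hz/s) was calibrated once on synthetic data
to drop silent and truly constant traces while keeping every
stimulus-modulated neuron; stimulus-modulated neurons sit one to two
orders of magnitude above it.

## Energy models

All training is contrastive divergence (CD-k, default k = 1) with
momentum 0.9, weight decay 1e-4, batch 64 and learning rate 1e-3
(protocols use 2e-3); positive statistics use hidden probabilities
(Rao-Blackwellized), the negative phase starts at the data.  Gaussian
visibles are fixed at unit variance; standardization upstream enforces
it.

**mcRBM.**  The factored third-order energy with nonpositive pooling
P guarantees a positive-definite conditional precision
I − C diag(P h_c) Cᵀ for *every* binary precision configuration, so
block-Gibbs can sample the exact conditional Gaussian.  The negative
phase defaults to hybrid Monte Carlo on the marginal free energy
(latents summed out analytically; 20 leapfrog steps, step size adapted
toward 90% acceptance), with plain block-Gibbs as an alternative; both
target the same density.  A deliberate design choice: the visibles are
*not* length-normalized inside the covariance term.  Normalization
makes the conditional only approximately Gaussian and decouples the
sampler from the analytic conditional; keeping the plain quadratic
form makes the model exactly the energy written above, testable by
enumeration and exact conditional sampling.  P is initialized as a
block structure (each precision unit pools a contiguous factor group,
bias +2 so precision units start "on") and clipped to ≤ 0 after every
update.

**cRBM.**  History order 12 by default.  For periodic stimuli the
spacing s is derived from the counterphase rule
order·s ≈ half period / bin width, rounded to the nearest integer and
accepted within a 25% relative tolerance (at 30 Hz bins and a 1 Hz
grating: s = 1, span 0.4 s vs the 0.5 s half period); outside the
tolerance the spacing is refused with the nearest feasible value
reported.  Gradients for A_k and B_k are the standard dynamic-bias
extensions of CD.

**Oracles.**  For small models the exact log-likelihood (partition
function by enumeration over the smaller layer; Gaussian visibles
integrated analytically) and the exact log-likelihood gradient are
implemented independently of the training path and used as test
oracles: conditionals agree with Boltzmann ratios to 1e-10, Gibbs
chain occupancies match exp(−E)/Z, the expected CD-1 update is
positively aligned with the exact gradient, and exact likelihood rises
over training.

## Mode analysis and evaluation

Latent probabilities are binarized deterministically at 0.5
(probabilities of exactly 0.5 round up); sampling-based binarization is
available behind a seed for sensitivity checks.  The mcRBM state is the
concatenation of mean- and precision-unit bits, with a mean-only
option.  The stimulus–response lag used when averaging defaults to the
generator's known latency (2 frames) in the protocols and is
configurable elsewhere.

State/unit-triggered averages are plain pixelwise means of the
triggering frames; samples whose lag or history reaches before t = 0
are skipped and counted.  Temporal averages are ordered most-delayed
first.

Mutual information uses the plug-in estimator on empirical joint
counts, base 2, normalized by the stimulus entropy.  No bias correction
is applied; instead every comparison carries a shuffled-label
permutation null (seeded), which exposes the finite-sample bias
honestly — with many distinct states the null NMI is visibly above
zero, and conclusions are drawn only relative to it.  Grating analyses
label frames by phase bin (8/cycle); orientation+phase and
condition-tag labelings are available.

## Experiment protocols (desk scale)

The protocol sizes are scaled-down analogs of a 16×16-electrode patch
(the recorded patches held ~60–130 neurons):

- grating modes: 100 neurons, 8 orientations × 3 s, mcRBM 16 mean /
  64 factors / 16 precision units, 100 epochs;
- impairment sweep: 48 neurons, 3 frequencies × 3 levels × 30 s, one
  mcRBM (8/32/8) per condition;
- temporal modes: 48 neurons, 40 s drifting grating, cRBM with 12
  history layers;
- LGCP benchmark: 20 independent 30-s trains.

Each protocol runs in roughly one to two minutes on a single CPU; the
full suite plus the acceptance script stays within a few minutes.

## Limitations

- The plug-in NMI is biased upward at small sample counts; only
  comparisons against the permutation null or between conditions of
  equal size are meaningful.
- Binary-state spaces grow as 2^N; with noisy probabilities near 0.5
  the observed state count can approach the sample count, which
  inflates both the NMI and its null.  The protocols keep latent sizes
  moderate for this reason.
- The LGCP MAP is a point estimate; no posterior uncertainty over
  rates is propagated into the downstream analysis.
- HMC step-size adaptation is a simple multiplicative rule targeting
  90% acceptance, adequate for the moderate dimensionalities used here.
- The impairment model captures precision loss only; real GABA
  blockade also changes mean rates, adaptation and correlational
  structure in ways the generator does not represent.
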