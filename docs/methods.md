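# Methods

## Model

`sigdiff` implements a denoising-diffusion probabilistic model for
multichannel time-series signals. The forward process corrupts a signal
x₀ over T steps with the Gaussian kernel

    q(xₜ | xₜ₋₁) = N(xₜ; √(1−βₜ) xₜ₋₁, βₜ I),

whose closed-form marginal is xₜ = √ᾱₜ x₀ + √(1−ᾱₜ) ε with
αₜ = 1 − βₜ and ᾱₜ = ∏ₛ≤ₜ αₛ. The β schedule is chosen so that x_T is
approximately standard normal: the default is linear from 1e-4 to 0.02;
a squared-cosine schedule (offset s = 0.008, β clipped at 0.999 and the
ᾱ table recomputed from the clipped β so the product identity holds
exactly) is available. Timesteps are 1..T in the mathematics and 0..T−1
in array storage.

The learned reverse kernel p(xₜ₋₁ | xₜ) is Gaussian with mean

    μ_θ = (xₜ − βₜ/√(1−ᾱₜ) · ε_θ(xₜ, t, c)) / √αₜ

and a diagonal variance log-interpolated between the posterior variance
β̃ₜ = (1−ᾱₜ₋₁)/(1−ᾱₜ)·βₜ and βₜ by a second network output v ∈ [0,1]:
log Σ = v log βₜ + (1−v) log β̃ₜ. Since β̃₁ = 0 (ᾱ₀ := 1), the t = 1 entry
of the log-variance table is floored at the t = 2 value, and the final
reverse step is taken deterministically (mean only). Both parameterised
variance (learned v, the default) and fixed variance (v forced to an
endpoint) are expressible through the same interpolation.

**Loss.** Training minimises the hybrid objective
L = L_simple + λ·L_vlb with λ = 0.001. L_simple is the mean squared
error E‖ε − ε_θ‖² at a uniformly sampled step per example. L_vlb is the
per-step term of the evidence lower bound: the KL divergence between the
Gaussian posterior q(xₜ₋₁|xₜ,x₀) and the learned kernel for t > 1, and
the Gaussian negative log-likelihood of x₀ for t = 1, evaluated with the
predicted mean detached from the gradient so the bound trains only the
variance output. A learned variance requires this extra signal; the
detachment keeps the noise prediction governed solely by L_simple.

**Training.** Adam (lr 2e-3 by default, global gradient-norm clip 5), a
seeded 90/10 train/validation split, and early stopping on the
validation loss with configurable patience (default 10 epochs). The
validation loss is evaluated with a fixed RNG so the same (t, ε) draws
are used every epoch, making the curve comparable across epochs. An
optional exponential moving average of the weights (decay 0.999) can be
enabled; it is off by default so desk-scale runs stay exactly
reproducible step for step. Signals are normalised per channel to
[−1, 1] from the training data's min/max before training and mapped back
on output; a constant channel is centred at 0 rather than pinned to an
endpoint. If the loss turns non-finite, training aborts and returns the
last best checkpoint.

**Sampling.** Ancestral sampling: x_T ~ N(0, I), then the reverse kernel
from t = T down to 1, adding noise scaled by √Σ for t > 1 and none at
t = 1.

## Network

The noise predictor is a 1D U-Net over the time axis: an encoder of
residual blocks (GroupNorm → SiLU → conv3, with the timestep embedding
projected and added between the two convolutions), optional single-head
self-attention after residual blocks, downsampling by strided
convolution (max-pooling available by flag), a residual+attention
bottleneck, and a mirrored decoder whose levels first concatenate the
matching encoder feature map. Two conv heads emit ε and v (sigmoid).
Default desk-scale size: 3 levels, base 16 channels, multipliers
(1, 2, 4), attention at the deepest level, ~244k parameters.

Conditioning:

* **Timestep** — sinusoidal position embedding followed by a two-layer
  MLP, added inside every residual block.
* **Class label** — a learned embedding added to the timestep embedding,
  so every residual block sees both.
* **Signal** — the conditioning signal (a degraded copy at the model's
  native length) is concatenated channel-wise with the sampling state
  and fused back to the input channel count by a width-1 convolution at
  every reverse step.

All networks (U-Net, the LSTM discriminator, the CNN classifier) run on
a small reverse-mode automatic-differentiation engine over numpy arrays
written for this package (`sigdiff.nn`); every primitive's gradient is
verified against central finite differences in the test suite.

## Synthetic data

The simulator emulates a five-class benchmark built from the classical
cylinder/bell/funnel primitives: cylinder (plateau), bell (linear ramp
up, drop), funnel (jump, linear decay), bell-then-funnel, and two
separated cylinders. Events occupy a window from 25% to 70% of the
signal by default; per-signal variation comes from Gaussian jitter of
the event boundaries (variance `pattern_var`, default 25 samples² at
length 512, rescaled proportionally at other lengths in the
experiments), an event amplitude drawn from N(1.0, 0.04), and additive
white noise with sd 0.05. These defaults give clearly separable classes
with realistic within-class variability.

Degradations model common biosignal contamination: thermal noise (white
Gaussian, sd = magnitude); baseline wander from varying electrode
contact (a sum of three sinusoids with periods ≥ length/4 and Dirichlet-
weighted amplitudes summing to the magnitude); motion artifacts (a
Poisson number of 1–3-sample spikes with Gamma-distributed amplitude of
mean = magnitude and random sign); masked gaps (1–3 contiguous zeroed
runs totalling exactly `gap_fraction` of the signal, with the
observation mask returned); and downsampling (keep every k-th sample,
plus the final sample so the endpoints anchor the interpolation, then
linear re-interpolation to the original length so the conditional input
always matches model dimensions).

What the simulator does not emulate: physiological waveform morphology
(PQRST complexes, activity-specific accelerometry), 1/f noise spectra,
inter-subject variability, or non-stationary class boundaries. Passing
tests therefore demonstrate that the machinery works end to end on
controlled signals with known structure, not that it reaches any
particular fidelity on clinical recordings.

## Evaluation metrics

**Wavelet coherence.** Morlet (ω₀ = 6) continuous wavelet transform on a
dyadic scale grid (s₀ = 2 samples, 4 voices per octave). The coherence
is |S(W_x W̄_y)|² / (S(|W_x|²) S(|W_y|²)) with S a smoothing operator;
smoothing is mandatory because the unsmoothed single-realisation
coherence is identically 1. S applies a scale-dependent Gaussian in time
(σ = scale) and a 3-point boxcar across scales, after 1/s rectification.
Values are clipped to [0, 1]; a constant signal yields coherence 0 with
a warning. The set score draws seeded random (real, synthetic) pairs
(default cap 1000), averages each pair's coherence map over time and
scale (and channels), and reports 100 × the mean — a 0–100 scale where
identical sets with identity pairing score exactly 100. For random
pairing the two sets are first put in a canonical order by content
digest so the score is exactly symmetric in its arguments.

**Discriminative score.** A 2-layer LSTM (hidden 64) is trained to
label real vs synthetic sequences; the pooled set is split 80/20
stratified, a further 20% of the training part is held out for early
stopping, and the score is |test accuracy − 0.5| ∈ [0, 0.5]: 0 means
indistinguishable. Sequences longer than 128 steps are strided down to
bound the recurrent graph. Table-style reports elsewhere describe this
as a classification-error-like quantity; the |accuracy − 0.5| convention
is used because "lower is better" values near 0 for good generators are
only consistent with that reading.

**UMAP overlay.** Both sets are flattened to vectors and embedded
jointly (one shared UMAP fit), returning origin-tagged 2D coordinates
and optionally a two-colour scatter plot. The neighbour parameter is
shrunk automatically with a warning when the sets are smaller than it.

**Classification report.** Per-class one-vs-rest TP/FP/FN with
p = TP/(TP+FP), r = TP/(TP+FN), F1 = 2TP/(2TP+FP+FN), the 0/0 → 0
convention, and macro averages. Verified against a brute-force
confusion-matrix oracle and scikit-learn.

## Applied pipelines

Signal-conditional models are trained on pairs formed on the fly: each
epoch every clean signal is degraded afresh by a spec drawn from the
task's degradation family, so the model learns the family rather than a
fixed pairing, and conditioning is blind to the realised noise level.
Restoration (denoise / impute / upsample) reports the mean of a small
ensemble of conditional samples (default 4 draws) — a posterior-mean
estimate that removes most sampling variance from the restored signal.
Imputation additionally copies every observed sample back verbatim, so
only gaps are synthesised. The upsampling entry point checks the
requested factor against the factors the checkpoint was trained with.

The imbalance pipeline tops up each under-represented class to a target
count with label-conditional samples (exact post-condition counts),
then retrains a pinned small 1D-CNN (two conv-pool blocks and a dense
head, fixed seed) on the imbalanced and the rebalanced sets and
evaluates both on an untouched test set; exact duplicate signals across
train and test are rejected as leakage. Personalisation is supported
only as a warm start (`train --init-from`).

## Experiment scales and design choices

The packaged experiments are sized for a single CPU: length-64 signals,
T = 100 diffusion steps, a 3-level U-Net with base 16 channels, and a
few hundred training signals. Unconditional distribution recovery uses
one class, n = 256, at most 30 epochs; the conditional experiments use
three classes and up to 60 epochs (their conditional objectives converge
more slowly). The imbalance experiment deliberately uses a noisier,
more overlapping variant of the simulator (noise sd 0.35, amplitude
variance 0.09, boundary-jitter variance 64 at length 64) with one class
subsampled to 5%: under the clean defaults the classifier is already
perfect despite the imbalance, leaving nothing for augmentation to
demonstrate; the harder conditions instantiate the minority-class
failure that rebalancing is meant to repair.

Other numerical choices: β̃ log-floor at the t = 2 value (above);
improvement threshold 1e-6 for early stopping; Kaiming-uniform
initialisation seeded per build so identical configs give bit-identical
models; float64 arithmetic throughout the networks; degenerate
(constant) channels centred by the normaliser; coherence denominators
below 1e-300 defined as coherence 0.

## Known limitations

Pure-numpy training limits practical scale to roughly 10⁵-parameter
models and a few hundred signals; there is no GPU path, no DDIM-style
accelerated sampler, and no classifier-free guidance. The wavelet
set-score's pairing/aggregation is one reasonable reconstruction of a
set-level coherence statistic; absolute values depend on the smoothing
choices, so scores are best compared within a fixed configuration.
Synthetic-data results do not transfer claims to clinical signals.
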