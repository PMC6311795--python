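# Methods

This note documents the models, the synthetic data, and the numerical
and design choices behind `gliadbn`, in the spirit of a model reference
rather than a tutorial.

## 1. Signal model of the synthetic generator

Each trial is a 32 × (fs·duration) matrix built per channel as a sum of
unit-RMS band-limited Gaussian oscillations in θ (4–8), α (8–12),
β (12–30) and γ (30–45 Hz), scaled by per-trial/per-channel random
amplitudes, plus 1/f-shaped background noise; all channels of a subject
are then mixed by a fixed row-stochastic matrix
A = (1−m)·I + m·S (m = `mixing_strength`) to induce interchannel
correlation.  Baseline band amplitudes are 4/5/3/2 (θ/α/β/γ, arbitrary
microvolt-scale units) with trial-level jitter of 20% and channel-level
jitter of 10% of baseline.

Labels modulate the amplitudes:

* **arousal** adds ±½·d·(0.2·baseline) to β and γ amplitudes (sign by
  class), giving a standardized class separation ≈ d = `effect_size` on
  broadband high-frequency power;
* **valence** adds an antisymmetric ±¼·d·(0.2·baseline_α) shift to the
  α amplitudes of the right vs left members of the 14 homologous pairs,
  so the right-minus-left α power difference separates the classes.

Labels are balanced assignments per subject per dimension (counts differ
by at most one), not i.i.d. flips, so 10-fold CV folds at n = 40 remain
meaningful.  Everything is drawn from seed streams keyed by
(seed, subject, purpose), so output is bit-reproducible.

Defaults mirror the emulated recording protocol: 32 subjects × 40 trials
× 32 channels at 128 Hz, 60 s per trial.  Tests and the acceptance
script use 8-second trials — long enough for the 2-s Welch windows, EMD
and approximate entropy to be well defined, and the band-power and
asymmetry statistics the pipeline measures are duration-invariant.

**What the generator does not emulate:** ocular/muscle artifacts, volume
conduction physics, non-stationarity within a trial, realistic
cross-band coupling, or stimulus structure.  Passing end-to-end tests
therefore demonstrate that the pipeline recovers the *kind* of
statistical structure it is built to detect (band power and asymmetry
effects of a known size), not field performance on real recordings.

## 2. Feature extraction (664 dimensions)

Preprocessing: polyphase anti-aliased resampling to 128 Hz (when the
input rate is higher), then a 4th-order Butterworth band-pass 4–45 Hz
applied forward–backward (zero phase).  Inputs shorter than the filter
warm-up are rejected.

* **F1 — time statistics** (4 × 32): mean; *population* variance
  (divide by N); zero-crossing rate defined as sign changes of the
  mean-removed signal divided by N−1; approximate entropy ApEn(m, r)
  with the field-standard m = 2, r = 0.2·SD (self-matches included, so a
  constant signal has ApEn exactly 0).  Both conventions are exposed as
  arguments.
* **F2 — band PSD** (5 × 32): Welch with 2-s Hann windows, 50% overlap;
  a band value is the *mean PSD over in-band frequency bins*
  (half-open intervals, lo ≤ f < hi).  Averaging (vs integrating) is a
  genuine ambiguity; the mean was chosen and is applied consistently,
  so downstream standardization makes the two equivalent up to a
  per-column constant.
* **F3 — power differences** (4 × 14): right minus left band PSD for
  the 14 named pairs in θ, α, β, γ — slow-α is excluded, which is what
  makes the count 56.
* **F4/F5 — Hilbert–Huang features** (2 × 5 × 32): empirical mode
  decomposition by standard sifting (cubic-spline envelopes through
  local extrema with the two outermost extrema mirrored past each end;
  Cauchy-type sift stop criterion with threshold 0.2; at most 10 IMFs;
  extraction stops when the residual has fewer than two maxima or
  minima).  Each IMF's analytic signal gives amplitude a(t) and
  instantaneous frequency f(t) = (1/2π)·dφ/dt.  Per band: the mean of
  a(t)² over all (IMF, t) samples with f(t) in the band, and the
  a²-weighted mean of f(t) over the same samples; both are 0 when no
  sample falls in the band.  The outer 5% of samples per side are
  excluded (Hilbert edge effects), and IMFs carrying less than 1e−6 of
  the signal energy are discarded as sifting residue so they cannot
  dilute the in-band averages.  A constant channel produces no IMFs and
  contributes zeros.  δ-band (1–4 Hz) slots are retained even though
  the band-pass removes most δ energy, preserving the printed 664-wide
  layout; they are near zero in practice.

Per-subject standardization z-scores each column of the subject's
instance matrix; zero-spread columns map to 0.  Stored (mean, sd) can be
applied to held-out rows for leakage-free evaluation.

## 3. RBM core

Energy E(v, h) = −v′Wh − b′v − c′h.  The first layer uses Gaussian
visible units with unit variance (inputs are z-scored); upper layers are
binary-visible since they consume activation probabilities.  Hidden
*probabilities* (never Bernoulli samples) are used as hidden outputs;
CD-1 samples hidden states only inside its single Gibbs step, and the
reconstruction uses visible probabilities/means.  Training is
mean-gradient mini-batch CD (batch 8) with momentum 0.5, weight decay
1e−4, Gaussian(0, 0.01) weight init and zero biases, all seeded.  The CD
step count, visible-unit type and sampling of hidden states are
configurable.

Models with ≤ 20 total units expose exact log-likelihood, the exact
likelihood gradient and the exact visible distribution by enumeration;
these are the oracles used in testing (gradient vs central finite
differences; Gibbs chain vs enumerated distribution in total variation).

The **discriminative RBM** augments the visible layer with a one-hot
2-class label group (label-to-hidden weights U, label biases d).  The
class posterior is exact:
p(y|x) ∝ exp(d_y + Σⱼ softplus(cⱼ + U_{yj} + (xW)ⱼ)), and the model is
trained by gradient descent on the exact conditional NLL — a purely
discriminative objective; no sampling is involved anywhere in the
classifier.  With zero hidden units this degenerates to the label-prior
softmax (intercept-only logistic regression), a property the tests use.

## 4. Glia chain semantics

The printed update rule for the glia effect has two readings that had to
be fixed:

* **Threshold operand.**  The firing condition compares σ(h\*ⱼ) — the
  unit's activation probability — to θ, so that θ's natural [0, 1]
  sweep range is meaningful.  Comparing the unbounded preactivation to
  a θ ∈ [0, 1] would make the sweep range arbitrary.
* **Timing condition.**  Refractory semantics: a cell may fire only
  when (step − last_fire) ≥ T.  The alternative literal reading ("time
  since last activation must be *less* than T") would permanently
  silence any cell quiet for T steps, which is degenerate.

Chain state: g(0) = 0, last_fire = −∞ (all cells eligible at the first
step).  Propagation is strictly first-to-last with a one-step delay;
cell 1 has no predecessor.  The chain order defaults to hidden-unit
index order and is configurable as a permutation, since nothing maps
channels to hidden units canonically.

**Step granularity.**  The chain advances once per mini-batch update,
driven by the *batch-mean* preactivation.  Per-sample stepping would
make the glia trajectory depend on the sample order inside a batch;
per-epoch stepping would make the chain nearly static.  Batch-mean
stepping is deterministic, cheap, and lets the wavefront evolve on the
same time scale as the weights.

Defaults: α = 0.8, β = 0.4, θ = 0.75 (the well-performing region of the
parameter sweeps), T = 5 batch-steps (T is never printed anywhere; 5
keeps a cell silent for roughly one epoch of the default batch layout).
With α = 0 the coupled trajectory is *bitwise* identical to plain CD
training under the same seed — the package's strongest regression
anchor, asserted in the tests.  Glia act only in pretraining; fine-tuned
and inference-time forward passes are pure functions of the weights.

## 5. DBN-GC and the ensemble

Greedy pretraining trains each layer's RBM (glia-coupled when enabled)
on the activation probabilities of the layers below; training layer k
never modifies layers < k.  Fine-tuning adds a 2-neuron softmax head and
runs plain SGD with momentum 0.9 and learning rate 0.3 on mean
cross-entropy, with early stopping on a training-loss plateau (patience
20, min improvement 1e−5).  These optimizer values were chosen for
reliable convergence of the sigmoid stack: Gaussian-visible CD needs a
small learning rate (0.005 here; larger rates saturate the first hidden
layer), while fine-tuning needs a large one because the pretrained
weights are small and the gradient signal attenuates through three
sigmoid layers.  One model is trained per emotion dimension.

The ensemble splits the 664-vector into F1…F5, trains one DBN-GC per
subset (default last-hidden widths 90/120/45/45/50, fusion input 350),
discards the branch heads, and fits the discriminative RBM (50 hidden
units by default — unconstrained by the architecture and config-exposed)
on the concatenated abstractions.  Branch training and fusion training
are strictly stagewise: fusion never mutates branch weights.  Glia
hyperparameters are shared across branches, matching the
one-global-parameter sweep design.  The parameter sweep varies one of
α/β/θ over a 20-point grid (0.05…1.00, step 0.05) with the others held
at defaults and reports mean CV accuracy per dimension.

A stack may be built with *zero* layers, making the branch a
passthrough; with all branches degenerate the ensemble provably reduces
to a discriminative RBM on the raw features, which the tests exploit as
an exact cross-check of the fusion path.

## 6. Cross-validation protocol

Participant-specific k-fold CV (k = 10): folds are stratified on the
dimension's labels when each class has ≥ k members, else plain seeded
shuffling; test folds are disjoint and cover all instances.  The default
standardization z-scores the subject's *full* instance matrix before
splitting — faithful to the protocol being reproduced, but it leaks test
statistics into training.  The `strict_cv` switch standardizes with
training-fold statistics only.  F1 is positive-class by default
(macro-F1 via flag) and defined as 0 when precision + recall = 0.
Aggregation averages folds within subject, then reports
mean/median/SD across subjects, and is permutation-invariant over
subjects.

## 7. Problem sizes used in tests and acceptance runs

End-to-end checks use 1 subject × 40 trials of 8-second EEG,
reduced branch sizes (32/24/16 per branch, fusion hidden 16) and
10 pretraining epochs — small enough to run the whole stack many times
while keeping every pipeline stage (EMD, ApEn, glia-coupled CD,
fine-tuning, fusion, CV) fully exercised.  With effect size d = 3 the
ensemble reaches ≥ 0.85 mean CV accuracy on both dimensions across
seeds; with d = 0 it stays inside the binomial 95% band around chance.
Exact-oracle checks run on 4×3 and 3×2 unit RBMs where enumeration is
feasible.

## 8. Known limitations

* EMD has no unique definition; different envelope/boundary conventions
  change IMF details.  The implementation is validated on signals with
  known decompositions (pure and mixed tones), not against a specific
  external toolbox.
* The generator's class effects are stationary within trials, so it
  cannot probe time-varying emotion signatures.
* The discriminative objective is purely p(y|x); a generative/hybrid
  weighting is a natural extension and the objective is isolated enough
  to add one.
* Accuracies quoted anywhere in this repository are on synthetic data
  and are not comparable to results on real recordings.
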