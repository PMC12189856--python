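# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish.

## Problem setting

Resting-state EEG carries oscillatory signatures of Parkinson's disease
(PD), most prominently disrupted beta-band (13–30 Hz) activity in
cortico-basal-ganglia circuits. The package classifies multichannel EEG
recordings into PD vs. healthy control (HC) at the level of short frames:
each recording is cut into overlapping 2 s windows with 1 s overlap, every
window–channel pair is summarized by a fixed vector of spectral,
wavelet, entropy and morphology features, and the resulting channels ×
features matrix is one classification instance for a hybrid
CNN → attention → LSTM network.

## Synthetic cohorts

Real PD/HC EEG corpora cannot be redistributed with the package, so every
stage is exercised on synthetic cohorts with a known ground truth. Each
subject's signal is

* one sinusoid per canonical band (delta 0.5–4, theta 4–8, alpha 8–13,
  beta 13–30, gamma 30–45 Hz), with the component frequency drawn
  uniformly within the band per subject (inter-subject variability the
  classifier must tolerate), random phase per channel, and amplitudes
  jittered ±20% around `component_amplitude` (default 2, arbitrary
  microvolt-scale units);
* a 1/f-shaped background, synthesized by shaping white-noise FFT
  amplitudes by f^(−exponent/2) (default exponent 1), rescaled to
  `background_sd` (default 1);
* white Gaussian noise (`noise_sd`, default 1).

The class contrast is a per-class amplitude multiplier on selected bands;
the default puts ×2 on the PD beta component, a deliberately strong, clean
effect. Seeding splits one root seed per subject by counter
(`SeedSequence.spawn`), so cohorts are bit-reproducible and subjects
independent.

What the generator does **not** emulate: ocular/muscle artifacts, volume
conduction and channel correlation structure, non-stationarity,
medication effects, realistic effect sizes. Passing tests on these cohorts
therefore demonstrate that the pipeline's machinery is correct and that it
recovers a known spectral class difference — not that the reported
clinical-scale accuracies transfer to real recordings.

The amplitude scale and noise floor are conventional choices; nothing
downstream depends on absolute units (the feature set is scale-covariant
in a documented way, and model inputs are standardized).

## Windowing

Frames are laid left-to-right from sample 0 with step = frame length −
overlap (0-based, half-open). Trailing samples that do not fill a frame
are dropped rather than padded, keeping all spectral estimates on equal
footing. No filtering, re-referencing or artifact rejection is applied by
default; `window(..., preprocess=...)` accepts a user hook.

## Feature families

Per frame–channel vector (N = 1000 samples at 500 Hz by default):

* **Band power** — mean Welch PSD over the band's frequency bins
  (low ≤ f < high). The mean-over-bins convention (rather than integrated
  power) is deliberate and matched by the tests' periodogram oracle.
  Welch parameters: 1 s Hann segments, 50% overlap, no detrending — at
  least 2–3 averaged segments inside a 2 s frame, 1 Hz bin spacing.
* **Beta/alpha ratio** — the classical PD marker. Alpha power at or below
  an epsilon floor (1e−12) triggers the floor and a per-instance flag.
* **Median frequency** — smallest bin frequency at which the cumulative
  PSD reaches half the total.
* **Spectral entropy** — Shannon entropy in bits of the PSD normalized to
  a probability mass; zero-power bins contribute 0.
* **Wavelet level means** — mean absolute detail coefficient at DWT levels
  1..L plus the final approximation (Daubechies-4, L = 5). At 500 Hz the
  detail levels span ≈125–250, 62–125, 31–62, 16–31 and 8–16 Hz, so levels
  4–5 roughly track beta/alpha. Family and depth are configurable.
* **Approximate entropy** — standard template-matching ApEn(m, r·SD) with
  m = 2, r = 0.2 (field conventions), Chebyshev distance, self-matches
  included, natural log. A zero-variance input returns 0 (perfectly
  regular) with a flag. An alternative amplitude-histogram entropy
  (Shannon entropy of a 10-bin amplitude distribution, natural log) is
  available via `apen_method="amplitude"`; the template form is the
  default because it is what the statistic's name and provenance denote.
* **Skewness / kurtosis** — population moments (divide by N); kurtosis is
  *not* excess-adjusted, so a Gaussian gives ≈3.
* **Zero-crossing rate** — sign-change fraction over the N−1 adjacent
  pairs, in [0, 1].

The feature order is frozen and versioned (`ctesm-features-v1`, 18
columns with the defaults). Undefined features become a sentinel
(default 0) plus a recorded flag; channels are never dropped.

Scale behavior under x → c·x (c > 0): band powers ×c², wavelet means ×c,
everything else invariant (ApEn because r is proportional to the SD).
This is property-tested.

## Augmentation

Each instance X (channels × features) produces `n_variants` (default 50)
synthetic matrices: (1) add N(0, 0.05²) noise entry-wise, (2) multiply by
one scalar from U[0.9, 1.1], (3) "dynamic modulation" — add zero-mean
per-entry offsets bounded by `modulation_strength`·SD(X) (default
strength 0.1), then re-center the matrix to its post-noise mean. The
modulation step is under-specified in the literature this mimics; the
implementation here is the package's interpretation, chosen so that
feature centering is maintained exactly: a variant's mean differs from
its parent's only by the averaged noise, i.e. within 3·σ/√(C·F) at the
usual 3-sigma level. With the default 50 variants the set expands N → 51N
with label proportions preserved.

The noise SD acts on the raw feature scale, which is heterogeneous across
features; `standardize_noise=True` scales it per feature column instead.
By default augmentation is applied to the **training partition only**;
`augment_before_split=True` augments first and splits afterwards, which
leaks synthetic siblings of test frames into training — supported for
protocol comparability with studies that augment before splitting,
documented as measuring interpolation rather than generalization.

## Classifier

Input instances are standardized per feature column (statistics from the
training partition only), then:

1. **CNN block**: Conv1d(F→32, k=3, valid) + ReLU, Conv1d(32→64, k=3) +
   ReLU, MaxPool(2), BatchNorm — all along the electrode axis with the
   features as input channels. The pooled electrode axis becomes the
   sequence axis: T = (C − 2(k−1))//pool, D = 64 (C=40 → T=18).
2. **Transformer block**: 4-head scaled dot-product self-attention
   (d_k=16), residual + layer norm; two-layer FFN (ReLU affine 64→64,
   affine 64→64), residual + layer norm; dropout 0.3 after the block.
   Layer normalization is non-affine — plain (x−μ)/σ over the feature
   axis — so the normalization identities (row mean 0, SD 1; scale
   invariance) hold exactly. The printed transformer form this follows
   shows a single affine inside the feed-forward residual; the standard
   two-layer expand-project FFN is used here with ff_dim as the hidden
   width, a deliberate design choice.
3. **LSTM head**: single LSTM (64 units, forget bias 1) over the T steps;
   the final hidden state feeds a dense+softmax output.

All layer widths are package choices sized to train on one CPU in
seconds; every value is exposed in `ModelConfig`, which validates that
the model dimension is divisible by the head count.

Training: Adam (lr 1e−3), categorical cross-entropy, 50 epochs, batch 32,
80/20 train–test split with 10% of the training data as a validation
split, per-epoch train/validation accuracy and loss recorded. The default
split is by frame; `split_by="subject"` holds out whole subjects and is
what the package's own end-to-end checks use, because frames of one
subject are strongly dependent and frame-level splits overstate
generalization. One integer seed fans out by counter to cohort
generation, splitting, augmentation and weight init/shuffling.

The network and its gradients are implemented directly in numpy (explicit
backprop per layer, verified against central finite differences in the
test suite); the model is small enough (~10⁵ parameters) that an autodiff
framework would add nothing but a dependency.

Ablations: `use_lstm=False` replaces the LSTM with mean pooling over T
feeding the dense head; `use_dropout=False` removes dropout (batch
normalization stays — it is part of the CNN block definition, not an
optional regularizer).

## Evaluation and the channel screen

Metrics come from the confusion matrix; precision/recall/F1 are
macro-averaged by default (robust to frame-count imbalance between
classes), with micro/weighted available. The channel screen takes the
per-subject per-channel mean amplitude as the statistical unit — the
subject, not the frame, is the independent unit — and compares groups per
channel with a two-sample Student t-test and one-way ANOVA. With two
groups and pooled variance these are one test (t² = F), kept exact by
defaulting to equal-variance t; Welch's t and Benjamini–Hochberg q-values
are options. Raw p-values are reported without correction by default,
matching the presentation style of per-channel screening tables.

## Problem sizes

Desk-scale defaults used by the package's own verification runs: 12
subjects per class, 40 channels, 500 Hz, 16 s recordings (15 frames per
subject, 360 instances), beta multiplier 2, classifier trained without
augmentation for the held-out accuracy check and with it for the demo
pipeline. The demo configuration is smaller still (6 subjects/class, 16
channels, 8 s, 5 variants, 15 epochs). These sizes are the package's
choice of a minimal convincing demonstration; nothing prevents users from
scaling all of them up.

## Known limitations

* The synthetic class effect is far cleaner than clinical EEG; held-out
  accuracies near 1.0 on these cohorts say nothing about clinical
  performance.
* ApEn is O(n²) per channel-frame and dominates extraction time (~15 ms
  per 1000-sample vector); long recordings extract slowly.
* The EDF writer targets plain EDF with 1 s records and integer sampling
  rates; EDF+ annotations are out of scope.
* Batch normalization uses running statistics at inference; two models
  trained with different batch orders can differ slightly even with equal
  final weights elsewhere.
* The under-specified "dynamic modulation" augmentation step follows this
  package's interpretation (documented above); other readings are
  plausible.
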