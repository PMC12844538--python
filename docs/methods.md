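# Methods

`emofuse` predicts a listener's continuous emotional response to music —
valence (pleasantness) and arousal (activation), each on the 1–9 rating
scale used by the DEAP corpus — from two synchronized modalities: the music
audio itself and 32-channel EEG recorded while listening.  This note
documents the model, the signal-processing choices, the synthetic data the
package is validated on, and the limits of what those validations show.

## Feature extraction

### Audio timbre descriptors

Audio is mixed to mono, resampled to the analysis rate (default 22 050 Hz),
and cut into 1-second windows with 50 % overlap.  A window is kept iff its
end lies strictly before the end of the track, so a 60-second track yields
exactly 118 windows.  Each window is Hann-tapered and transformed; with
p_k = |S_k| / Σ|S_k| the L1-normalised magnitude distribution over
frequencies f_k, the five descriptors per window are

| descriptor | definition | units |
|---|---|---|
| spectral centroid | C = Σ f_k p_k | Hz |
| centroid spread | √(Σ (f_k − C)² p_k) | Hz |
| centroid skewness | Σ (f_k − C)³ p_k / spread³ | – |
| spectral entropy | −Σ p_k log p_k / log K | ∈ [0, 1] |
| spectral flux | ‖p − p_prev‖₂ (0 for the first window) | – |

Conventions: an all-zero (silent) spectrum maps every descriptor to 0
rather than NaN; entropy is normalised by the total bin count K so the
log base cancels.  These formula choices, the Hann taper, and the
strict-end window rule are fixed here because the source protocol names the
features without formulas; the strict-end rule is the unique simple rule
producing 118 windows per minute.

### EEG band-power features

EEG trials are 32 channels × 7 680 samples at 128 Hz (60 s).  The pipeline:

1. Zero-phase 4th-order Butterworth bandpass 0.5–45 Hz (`sosfiltfilt`),
   covering delta (0.5–4 Hz), theta (4–8), alpha (8–13), beta (13–30) and
   low gamma (30–45).
2. Per-channel power spectral density.  Default estimator: Welch with
   2-second (256-sample) Hann segments and 50 % overlap — the averaging
   stabilises band peaks; a full-length periodogram is available via
   `compute_psd(mode="periodogram")`.
3. Per channel × band, the features are the frequency of the maximum PSD
   value within the band and that PSD value itself (ties break toward the
   lower frequency).  32 channels × 5 bands × 2 = 320 numbers per trial.

Inputs are assumed artifact-cleaned (the DEAP preprocessed release already
is); no artifact rejection is re-implemented.

## The fusion regressor

Three branches are summed elementwise into the (valence, arousal) pair:

* **MLP** d → 1000 → 1000 → 2 on the tabular features: the 590 flattened
  timbre values plus, by default, the 320 EEG band-peak values (d = 910).
  Peak powers enter as log10 so band-power *ratios* — the physiologically
  meaningful quantity — are linear in the features.  The composed input
  width is computed from the data; an explicit `mlp_input_dim` override
  exists for non-default feature sets.
* **Audio CNN** on the raw mono waveform, resampled to
  `audio_branch_rate` (default 250 Hz).  The branch architecture is:
  conv(8 filters, k=9) → depthwise conv(depth multiplier 2 → 16 channels,
  k=32) → ELU → average pool(4) → dropout(0.5) → depthwise conv(16, k=26)
  → pointwise conv(16→16) → ELU → flatten → dense(200) → dense(2).
  All convolutions use "same" padding so short inputs survive the large
  kernels.  "16 depthwise filters after an 8-channel layer" is realised as
  depth multiplier 2 — the only consistent reading.
* **EEG CNN** — the same architecture on the (32 × n_freqs) log-PSD matrix,
  treated as 32 parallel sequences over the frequency axis.

ELU is used in the MLP as well, matching the CNN blocks.  Output clipping
to [1, 9] is off by default; metrics are computed on the raw sums.

The audio-only **ablation** variant drops the EEG CNN and the EEG block of
the MLP input entirely; its forward pass has no EEG-consuming parameters,
so EEG input perturbations cannot change its output even in principle.

The network is implemented directly on numpy arrays with hand-written
backpropagation (`emofuse.nn`): dense, standard/depthwise/pointwise 1-D
convolutions (FFT-based, exact to float accuracy), ELU, average pooling,
inverted dropout, and Adam.  Every layer's gradients are pinned against
central-difference numerical gradients in the test suite.

### Choice of the audio branch rate

The flatten → dense(200) layer grows linearly with the waveform length
(12 M weights at 250 Hz for a 60 s trial, 48 M at 1 kHz).  250 Hz keeps a
desk-scale single-CPU training run in minutes while preserving the
waveform envelope; discriminative spectral detail reaches the model through
the timbre features regardless.  The rate is an ordinary config field.

## Training protocol

* Split 8:1:1 into train/validation/test by seeded permutation
  (remainder to train; 1 280 trials give 1 024/128/128).
* Loss: mean absolute error over both outputs.  Optimizer: Adam,
  lr 1e-3, batch 32, decoupled weight decay 1e-3 on weight matrices
  (never biases).  Weight decay is the principal defence against the wide
  dense layers memorising small training sets.
* Early stopping on validation MAE with patience 20, max 150 epochs; the
  best-validation epoch's weights are restored.  150 epochs is a
  desk-scale choice; early stopping governs the actual stopping point.
* Each branch's final bias is initialised to mean(y)/n_branches so the
  fused prediction starts at the label mean, and the two CNN branches'
  output weight matrices are initialised at zero so the prediction starts
  from the feature branch and the convolutional branches fade in as their
  output weights grow — a standard stabilisation for summed fusion heads
  on small samples.
* All randomness (split, init, shuffling, dropout) flows from a single run
  seed; two runs with the same seed are bit-identical.
* Tabular features and log-PSD inputs are z-scored with statistics fitted
  on the training portion only.

## Metrics

MAE = (1/n) Σ|y−x|; MAPE = (100/n) Σ|(y−x)/y| in percent;
R² = 1 − Σ(y−x)²/Σ(y−ȳ)².  Pooled metrics concatenate the valence and
arousal series; per-target metrics are reported separately.  A truth value
of zero (impossible for 1–9 ratings) flags MAPE as undefined instead of
raising.  These are the standard definitions; the protocol this package
follows prints two of the formulas with typographical slips (a stray
"1 −" before MAPE and a missing "1 −" in R²) that are inconsistent with
its own reported values, so the standard forms are used.

## Channel attribution

`attribute_channels` scores each EEG electrode by mean |gradient × input|
of the summed outputs with respect to every EEG-derived model input: the
channel's row of the log-PSD matrix entering the EEG CNN plus (when
enabled) the channel's band-peak columns entering the MLP, aggregated per
channel over the evaluation set.  A channel-occlusion variant (zero the
channel's inputs, measure the mean absolute prediction shift) is available
as a cross-check.  The audio-only ablation model has no EEG path and
raises a structured error.

## Synthetic data

The generator emulates the DEAP preprocessed layout — 32 subjects × 40
one-minute trials, 32-channel EEG at 128 Hz, paired mono audio, labels in
[1, 9] — with a known generative link so recovery can be verified:

* Latent (v, a) are uniform on [1, 9] per trial (uniform rather than
  DEAP's empirical rating distribution: it maximises identifiability).
  Recorded labels add Gaussian rating noise (sd 0.25 rating units,
  a modest self-report jitter) and clip to [1, 9].
* **Audio** (frequency-domain synthesis, one inverse FFT per trial):
  twelve harmonics of a random fundamental in 190–260 Hz whose amplitude
  decay flattens as v rises (amplitudes L1-normalised so total harmonic
  mass is v-independent), a faint 1/f background, and a 2–8 kHz noise band
  whose level scales with v.  The measured spectral-centroid level rises
  monotonically with v (rank correlation ≈ 1 across trials).
* **EEG**: per channel, one sinusoid per band (random in-band frequency
  and phase) with a 1/f-like amplitude profile over pink background noise.
  On the designated signal channels (default Fp1, Fp2, P3, P4) the beta
  amplitude rises and the alpha amplitude falls log-linearly with a, so
  the beta/alpha power ratio increases monotonically with arousal.
  Off-signal channels carry no label information.
* Valence lives (almost) exclusively in audio and arousal exclusively in
  EEG, giving the EEG-off ablation a guaranteed direction.
* Datasets are lazy sequences; each trial is synthesised on demand from
  per-(subject, trial) seed streams, so items are bit-identical across
  instances regardless of access order and the default 1 280-trial corpus
  needs no bulk memory.
* `generate_deap_format_fixture` writes per-subject files in the DEAP
  preprocessed release layout (pickled dict, 'data' (40 × 40 × 8064):
  32 EEG rows with a 3 s baseline prefix plus 8 white-noise placeholder
  peripheral rows; 'labels' (40 × 4)) that round-trip exactly through the
  reader.

What the generator does **not** emulate: real music structure (beyond
spectral statistics), ERP morphology, eye-blink/muscle artifacts,
inter-subject variability in electrode coupling, or DEAP's empirical
rating distribution.  Passing tests therefore demonstrate that the
pipeline recovers planted, monotone spectral links at realistic SNR — not
that it attains any particular accuracy on real DEAP recordings.

## Problem sizes used in validation

The end-to-end learning checks train on a reduced study of 8 subjects ×
20 trials (160 examples; 8:1:1 split) with arousal planted only in
Fp1/Fp2, so one trained run serves both the ablation contrast and the
attribution-recovery check.  Unit tests use shorter trials (4–12 s) and
lower audio rates; the DEAP-shape invariants (7 680 samples, 1 280
trials, 8 064-sample release rows) are asserted at the default
configuration.

## Known limitations

* The printed MLP input width of 1 278 in the source protocol cannot be
  reconciled with any stated feature composition (590 + 320 = 910); the
  default is the composed width, with 1 278 available as an explicit
  override.
* Whether PSD should be computed per 1-s window (aligned with audio
  windows) or once per trial is unspecified upstream; the default is
  per-trial.
* MAPE is large whenever true ratings are near 1 even for good absolute
  fits; it is reported for completeness but R² and MAE are the primary
  measures.
* Training three summed overparameterised branches on ~10² examples is
  intrinsically split-sensitive; held-out R² on 32 pooled test values
  carries sampling noise of several hundredths.
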