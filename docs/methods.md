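# Methods

## Problem and pipeline

The package classifies single-lead ECG heartbeats into the five AAMI
categories (N, S, V, F, Q).  The processing chain is: read an annotated
record (WFDB, lead II preferred) → denoise → downsample 360 → 125 Hz →
segment a fixed 188-sample window per annotated R peak → z-score each window
→ stratified train/val/test split → SMOTE-balance the training split →
train the dual-branch network → evaluate on the untouched test split.

R-peak *detection* is out of scope: segmentation consumes the expert R-peak
annotations that ship with the data (or with the synthetic generator).

## Preprocessing choices

**Denoising.**  No specific filter is mandated by the task, so the denoiser
is a pluggable zero-phase Butterworth cascade chosen to satisfy explicit
band constraints: high-pass order 6 at 0.8 Hz (≥ 20 dB rejection of
everything at or below 0.5 Hz, where baseline wander lives) and low-pass
order 6 at 45 Hz (≤ 1 dB loss across 1–35 Hz, which carries the P-QRS-T
energy).  Forward–backward filtering (`sosfiltfilt`) gives zero phase, so R
peaks do not move (verified to ≤ 1 sample).  A plain 0.5–40 Hz band-pass was
rejected because with squared (zero-phase) magnitude response it loses
> 1 dB already at 35 Hz.

**Downsampling.**  Polyphase resampling (`resample_poly`, Kaiser window,
linear edge padding) with the exact rational ratio 125/360; annotation
indices are rescaled by the same rational factor and rounded.  Output length
is `round(n · 125/360)`.

**Segmentation.**  The window is `[r − 90, r + 98)` (0-based, half-open): 90
samples before the R sample and 98 from it onward, the only reading under
which 90 + 98 = 188 with the R sample included.  Beats with insufficient
context at the record edges are skipped and counted in provenance — never
zero-padded, because padding would fabricate morphology.

**Normalisation.**  Per-window z-score `(x − μ)/(σ + ε)` with the
*population* standard deviation and ε = 1e-6.  The formula carries no Bessel
correction, and the ε guard only makes sense if σ can be exactly 0 (constant
window), which the population form permits.

## Class balancing

SMOTE with k = 5 Euclidean neighbours (the technique's canonical default),
target policy "equalise every class to the majority count", λ ~ U[0, 1]
interpolation.  Original rows are preserved verbatim; classes with fewer
than k + 1 members use all available neighbours; a single-member class falls
back to replication with a provenance warning.  Balancing is *refused* for
datasets tagged as validation or test splits — the tag travels in the
dataset's provenance, so the contract is enforced structurally rather than
by convention.

## Architecture

Defaults (all exposed in `ModelConfig`): stem Conv1d(1→64, kernel 7, stride
1, padding 3) + BN + ReLU; residual blocks (64→64, s1), (64→128, s2),
(128→256, s1), each two kernel-3 convolutions with BN before ReLU and an
identity skip, or a 1×1 strided convolution where shape changes; global
average pooling to 256.  Transformer branch: scalar embedding to
d_model = 128, sinusoidal positional encoding, two post-norm encoder layers
(4 heads, d_k = 32, FFN 256, ReLU, dropout 0.1), average pooling to 128.
Gated fusion: bias-free projections W_c (256→256) and W_t (128→256) — the
fusion equations are bare matrix products — followed by a biased gate MLP
512→256→256 with ReLU between its layers and a sigmoid output; the fused
vector is the per-dimension convex combination.  Classifier: 256→128, ReLU,
dropout 0.3, 128→5, softmax; argmax ties break to the lowest class index.

Open points resolved as package choices: the FFN activation is ReLU, the
encoder layers are post-norm (residual then LayerNorm), batch-norm sits
after every convolution before its ReLU, and weight initialisation is the
uniform fan-in scheme with one master seed.

Ablation variants re-wire the same components — `cnn_only` (head on c),
`transformer_only` (head on t), `concat_no_gate` (head on [c̃; t̃]) — so a
variant comparison isolates the fusion mechanism rather than changing
capacity elsewhere.  Both branches are constructed for every variant, which
lets tests prove the unwired branch is ignored.

## Numerical engine

No deep-learning framework is used: layers and the training loop run on a
purpose-built reverse-mode autodiff engine over numpy arrays
(`hctgnet._autodiff`).  Design points that matter for correctness and for
CPU throughput:

* float32 working precision; every op is validated against central finite
  differences in float64 in the test suite;
* fused implementations (with hand-written backward passes) for the affine
  map, layer norm, batch norm and the attention core; the attention core
  processes the batch in cache-sized chunks and retains only the softmax
  weights and a boolean dropout mask for backward;
* the tape is freed progressively during backpropagation, and an explicit
  no-grad mode skips tape construction during inference;
* training uses gradient accumulation: the optimiser sees the configured
  batch (default 256) while the engine processes micro-batches (default 64)
  to bound peak memory (~0.8 GB).  This is mathematically identical to a
  single large batch except that batch-norm statistics are computed per
  micro-batch.

## Training protocol

Adam (lr₀ = 1e-3, weight decay 1e-4 added to gradients, β = (0.9, 0.999)),
cosine annealing `η(e) = η_min + ½(lr₀ − η_min)(1 + cos(πe/T_max))` with
T_max = 100 and η_min = 1e-6 (clamped beyond T_max), batch size 256,
gradient clipping at global L2 norm 1.0, cross-entropy loss (unweighted —
imbalance is handled by SMOTE), early stopping on validation loss with
patience 10 and restoration of the best-validation checkpoint.  One master
seed drives splitting, SMOTE, initialisation, dropout and batch shuffling;
runs are bit-reproducible given the seed.

**Splitting.**  Beat-level stratified split: the test fraction (default 0.2)
is held out first per class, then the remainder is split 80/20 into
train/val.  Per-class proportions hold to within one sample.  Beat-level
splitting follows the protocol being reproduced but is known to inflate
metrics relative to inter-patient splits, because beats from one recording
appear on both sides; treat absolute numbers accordingly.

## Synthetic data

The generator exists so every stage is testable without a download, and its
defaults are the package's study conditions.  Beats are sums of Gaussian
bumps for P, Q, R, S, T at 360 or 125 Hz.  Class signatures: S has 40 % of
the normal P amplitude and a shortened RR interval (0.55 s vs 0.80 s); V has
three-fold wider QRS deflections and no P wave; F is the elementwise mean of
the N and V templates; Q is a systematically distorted template (widened
low-amplitude QRS, inverted T, paced-beat-like) plus Student-t (df 2) noise
with its realised RMS pinned at 0.15 mV.  The Q design is deliberate: a
class defined as "clean template plus independent noise" can never be
nearest-neighbour-separable from the clean class itself, because the
distance from a noisy window to the clean template is always smaller than
between two independent noisy windows — the distortion must therefore live
in the template.  Per-beat template jitter (8 % amplitudes and widths, 4 ms
centres), neighbouring beats rendered at ±RR inside each window (making
timing cues visible), 0.02 mV white noise, and record-level contaminants
(sinusoidal baseline wander, default 0.1 mV at 0.25 Hz, plus white noise)
complete the model.

What this emulates: class-specific morphology, timing cues, annotation
bookkeeping, realistic contaminants for the denoiser.  What it does not:
physiological dynamics (no ODE model), inter-patient variability, electrode
artifacts, rhythm context beyond one RR interval, or the heavy class
imbalance of real archives (the generator emits balanced classes unless
told otherwise).  A model that passes the synthetic learnability test has
demonstrably learned the pipeline's feature contrasts; nothing here claims
clinical-grade performance on real ECGs.

## Problem sizes used in tests and the acceptance run

The learnability check trains the full variant on 200/50/50 beats per class
(train/val/test) with a 15-epoch budget — convergence on the separable
synthetic task occurs around epochs 5–8, so the cap is comfortable — and
requires test macro-F1 ≥ 0.95.  The ablation table in the acceptance script
uses 80 beats per class and 12 epochs per variant at batch size 64 — with
only ~320 training beats, the default batch of 256 would leave the optimiser
a handful of updates, so the scaled-down run trades batch size for update
count (identically for all four variants).  The table reports the variants'
metrics side by side without asserting an ordering, since the ordering
observed on real data need not transfer to synthetic beats.  Unit and
property tests use 10–50 beats per class.

## Known limitations

* Beat-level splits overstate generalisation to unseen patients.
* The denoiser is a fixed linear filter; pathological baseline excursions
  (electrode pops) are better served by median or wavelet methods, which can
  be swapped in via the preprocessing config.
* The engine is single-threaded numpy; training beyond ~10⁴ beats per run
  is possible but slow compared with GPU frameworks.
* Metrics assume single-label beats; multi-label or rhythm-level tasks are
  out of scope.
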