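# Methods

## Problem and scope

`maknet` classifies single-lead ECG beats into the five AAMI classes —
N (normal and bundle-branch-block beats), S (supraventricular ectopy),
V (ventricular ectopy), F (ventricular/normal fusion) and Q
(paced/unclassifiable) — from fixed-length windows cut around annotated
R peaks. It implements the MAK-Net architecture (multi-scale convolutions,
efficient channel attention, a bidirectional GRU and a Kolmogorov–Arnold
head) together with the preprocessing pipeline and the two class-imbalance
remedies it is normally paired with: focal loss and SMOTE oversampling.
Everything runs on plain numpy; the reverse-mode autodiff engine, the Adam
optimizer and every layer are part of the package, which keeps the whole
computation inspectable and dependency-light.

## Preprocessing

* **Segmentation.** One window per beat annotation, spanning
  `[r − half_width, r + half_width)` with `half_width = 150` samples at
  360 Hz, so each segment has 300 samples and the R sample sits at index
  150. Half-open windows and 0-based indices are used throughout. Beats
  whose window crosses a record edge are dropped and counted, never
  silently. (A 301-sample convention — R sample plus 150 on each side — is
  equally defensible; 300 was chosen for even pooling arithmetic.)
* **Denoising.** Per-segment discrete wavelet shrinkage: `db4`, 3 levels
  (comfortable maximum for 300 samples), soft thresholding at the universal
  threshold σ·√(2·ln N) with σ = MAD(level-1 detail)/0.6745. Only detail
  coefficients are thresholded; the approximation band is untouched, so a
  zero threshold reconstructs the input exactly. All settings are exposed in
  `WaveletSpec`.
* **Normalization.** Per-segment min–max to [0, 1]:
  `x_new = (x − x_min)/(x_max − x_min)`. Idempotent; constant segments raise
  a degenerate-segment error and are dropped (and logged) by the pipeline.
* **Splitting.** Beat-level (intra-patient) random split with
  val = ⌈0.2·n⌉, test = ⌈0.2·n⌉, train = remainder. At n = 109,447 beats
  this yields 65,667 / 21,890 / 21,890. Unstratified by default; a
  stratified option applies the same rule per class.
* **Label mapping.** The 15 MIT-BIH beat symbols collapse onto the five
  AAMI classes (N: N/L/R; S: A/a/J/S/e/j; V: V/E; F: F; Q: //f/Q). Unknown
  symbols raise; non-beat annotations are filtered at read time.

## Architecture

Input: a (batch, 1, 300) normalized segment. Stages:

1. **Stem** — four sequential ConvBlocks (Conv1d k=3 → BatchNorm → ReLU →
   MaxPool k=2, stride 1, padding 1). This pooling parameterization grows
   the length by one sample per block (300 → 304); it is kept as stated
   because it is harmless and the arithmetic is tested.
   Default widths 16/32/64/128.
2. **Multi-scale fusion** — four parallel Conv1d branches with kernels
   3/11/21/31 ("same" padding), combined by a learnable softmax-normalized
   weighted average initialized uniform (¼ each, so the block starts as a
   plain average and degenerates gracefully); then BN → ReLU →
   dropout (p = 0.3) → max-pool. A parallel ConvBlock branch and a
   1×1-convolution residual skip (also max-pooled, to match the grown
   length) are fused by element-wise addition.
3. **Attention** — MLPBlock → ECA → MLPBlock → ECA. Each MLPBlock runs a
   full Conv→BN→ReLU→Conv main path plus a partial convolution over the
   first ⌈C/4⌉ channels (identity on the rest; FasterNet-style ratio ¼),
   fused by addition. ECA pools each channel to a scalar, runs a single
   1-D convolution across the channel axis with adaptive kernel
   k = nearest odd integer to |log₂(C)/γ + b/γ| (γ = 2, b = 1; ties toward
   the smaller odd value), and multiplies channels by the resulting
   logistic weights.
4. **BiGRU** — two stacked bidirectional GRU layers, hidden 256 per
   direction; per-step outputs are the concatenation of forward and
   backward states (the standard bidirectional reading; the alternative
   weighted-sum merge its gate notation suggests is not used). A temporal
   mean-pool follows (mean preferred over last-step for noise robustness).
5. **KAN head** — widths 512 → 570 → 5. Every edge carries
   φ(u) = w_b·silu(u) + w_s·Σᵢ cᵢ·Bᵢ(u) with a cubic B-spline basis
   (order k = 3) on a fixed uniform grid of G = 5 intervals over [−1, 1]
   (G + k = 8 basis functions per edge); nodes only sum, plus a bias.
   A tanh squash precedes each KAN layer so inputs respect the spline
   range; values that still stray are clamped by the basis. The grid is
   fixed during training (no grid updates). Edge activations are
   exportable (knots, coefficients, curves sampled at 101 points) and a
   layer can be rebuilt from its export bit-exactly.

Softmax over the 5 classes closes the model. Published work fixes only the
kernel sizes, dropout and the 6.11-million-parameter total, not the widths;
the defaults above were chosen once, with the KAN hidden width (570) as the
single calibration knob that makes `count_parameters` come out at
6,108,125 ≈ 6.11M. Ablation variants replace exactly one component:
`single_scale_k` (one kernel), `no_attention`, `no_bigru` (pool straight
after attention), `no_kan` (plain linear head of matching widths).

## Losses and imbalance remedies

Both losses act on post-softmax probabilities of the true class p_t,
clamped at 1e−12: cross-entropy is −log p_t (batch mean); focal loss is
α_y·(1 − p_t)^γ·(−log p_t) with γ = 2 and α defaulting to all ones (no
class weighting unless configured) — at γ = 0 it reduces to α-weighted
cross-entropy exactly, which is asserted to 1e−10.

SMOTE synthesizes minority rows as x + u·(x_nn − x), u ~ U[0, 1], with
x_nn one of the k = 5 nearest same-class neighbours under exact Euclidean
search (brute force; the training sets involved make approximate search
unnecessary). Original rows are preserved verbatim; per-class counts hit
their targets exactly ("equalize to majority" by default). Oversampling is
only reachable through `apply_smote`, which takes a split-tagged dataset and
forwards the training rows exclusively — validation and test rows cannot
leak into the oversampler.

## Training and evaluation

Adam (lr 5e−4, batch 64, 60 epochs by default), fixed epoch count with
seeded per-epoch shuffling, and checkpoint selection by best validation
macro-F1 (published results do not state a selection rule; best-validation
is the conservative choice and "last" is available). Evaluation reduces a
split to a 5×5 confusion matrix (rows true, columns predicted, fixed
N/S/V/F/Q order; argmax ties break to the lower class index).

Metric conventions, one of which is nonstandard and deliberate: per class,
one-vs-rest precision, recall, F1 and specificity; the per-class
**accuracy column repeats the recall**, because that is how results tables
in this literature are laid out. The aggregate row uses unweighted macro
means for F1/recall/precision/specificity but **overall accuracy**
(trace/total) for the accuracy cell — the only convention that reproduces
the published aggregate rows from their per-class columns. All reported
cells are rounded half-up to 4 decimals. One published aggregate cell does
not follow from its own column: the SMOTE table's specificity column
averages to 0.99904 → 0.9990, while 0.9991 is printed; the tests assert the
recomputed value.

## Synthetic data

The generator emulates what the pipeline needs and no more: each beat is a
sum of five Gaussian deflections (P, Q, R, S, T) at 360 Hz with baseline
wander (0.3 Hz sinusoid), power-line interference (50/60 Hz) and white
noise, all with random phases/draws under a single seed. Class identities
are parameter offsets from the normal template — S: earlier flattened P and
shortened RR; V: widened lower R, absent P, inverted T; F: the N/V midpoint;
Q: flat P with a narrow pacing spike — scaled by a `separability` knob.
At separability 0 the classes coincide (nearest-centroid accuracy is
chance, tested at 0.2 ± 0.03); at 5 they are trivially separable (> 0.95).
Default class proportions follow the imbalanced training distribution the
package targets (54,171/1,807/4,348/483/4,858). Records are laid out with
truncated-normal RR jitter (clipped at ±3 s.d. to keep annotations sorted)
and annotated at the true R-deflection centres.

What this generator does **not** model: real QRS morphology variation
within a class, inter-patient variability, rhythm context (RR sequences
carry only one class's statistics at a time), motion artifacts, electrode
issues. Tests passing on this data demonstrate pipeline and architecture
correctness and directional behaviour of the imbalance remedies — not
clinical performance.

## Desk-scale study sizes and findings

The repository's own experiments are deliberately small so the full test
suite runs on one CPU in minutes: ~3,000 beats with the published class
ratios, separability 1.5, model widths stem (2, 3) / 4 fusion channels /
GRU hidden 3 / KAN hidden 6, Adam lr 2e−3, batch 32, 5 epochs, five
training seeds. Under these conditions:

* SMOTE lifts minority (S, F) recall far above the no-remedy baseline in
  every seed, and the ordering SMOTE ≥ focal ≥ none holds. Focal loss alone
  does not move minority recall off zero in 5 epochs — its gradient
  reweighting is too weak to overcome a 100:1 imbalance in ~300 optimizer
  steps, mirroring the full-scale finding that oversampling dominates
  reweighting.
* The full-architecture-versus-`no_bigru` comparison does **not** reproduce
  its full-scale direction at this budget: the recurrent path needs more
  optimization steps than 5 epochs provide, so the simpler variant matches
  or beats the full model (verified across learning rates 2e−3–1e−2,
  batches 16/32, GRU widths 3–8, and on SMOTE-balanced data; per-block
  gradients are finite-difference checked, ruling out an implementation
  cause). The corresponding acceptance test is left failing rather than
  weakened; reproducing that direction requires full-scale training.

## Numerical choices

* float64 throughout; gradient finite-difference checks at relative 1e−3.
* Probability clamp 1e−12 in losses; distributions validated to 1e−6.
* BatchNorm: batch statistics in training, running averages (momentum 0.1)
  in evaluation; the unbiased variance feeds the running average.
* Max-pool gradient credits the first maximum on ties; argmax prediction
  ties break to the lower class index.
* B-spline inputs clamped to the grid range; the rightmost interior
  interval is closed so u = hi has a well-defined basis.
* ECA kernel-size ties (|log₂C/γ + b/γ| exactly between two odd integers)
  resolve toward the smaller kernel.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical seeds give bit-identical datasets,
  builds and training histories on one platform.

## Known limitations

* WFDB support is a minimal reader/writer (header formats 16 and 212,
  MIT-format annotations) sufficient for the MIT-BIH layout and this
  package's fixtures; it is not a general WFDB implementation.
* No R-peak detection: annotated R positions are required.
* KAN grid adaptation, pruning and symbolic extraction are out of scope;
  spline exports are provided for downstream analysis.
* Training the 6.11M-parameter default configuration in this pure-numpy
  stack is possible but slow; the package's own studies use the tiny-width
  configurations above.
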