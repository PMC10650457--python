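# Methods

## Pipeline model

`pyrafex` treats radiograph classification as feature engineering over a
fixed multi-scale geometry rather than end-to-end learning. An image is
stretched to a square working resolution (default 224 px, plain bilinear,
aspect ratio not preserved), tiled into non-overlapping patch grids at
each configured scale (defaults 28/56/112 px; every scale must divide the
working side exactly), and each patch is bilinearly upscaled back to the
working resolution. Views are ordered smallest scale first, row-major
within a scale, full image last; this order is part of the contract, so
feature columns are stable across runs and machines. With the defaults an
image yields 85 views, and a 1000-dimensional backbone yields an
85,000-column exemplar vector.

### Bilinear convention

Resampling uses half-pixel sample centers with edge clamping
(align-corners disabled) and no antialiasing prefilter. The kernel is
implemented in-package so the convention is pinned; the test suite checks
it against both a per-pixel hand oracle and `skimage.transform.resize`
(order 1, no antialiasing), which follows the same convention. Because
bilinear output is a convex combination of inputs, intensities remain in
[0, 1] through every stage. Grayscale sources are channel-replicated to
three channels on load, and 8-bit files are scaled by 1/255.

## Backbones

A backbone is any pure mapping from a working-resolution RGB image to a
finite vector of fixed length. Two implementations ship:

* **Stub backbone** (default): grayscale, mean-pool to a fixed 14 × 14
  grid, flatten, seeded Gaussian random projection to `output_dim`
  (default 1000), tanh. It is deterministic given its seed, sensitive to
  image content, and fast — the properties the pipeline's tests need.
  It is a backbone in its own right (random-projection features), not an
  approximation of any particular network.
* **Pretrained adapter**: wraps a locally available torchvision model and
  exposes a chosen layer (default the 1000-unit classifier head) with the
  network's own preprocessing, in eval mode. If torch/torchvision or the
  weights are absent it raises a dedicated error naming the stub as the
  offline alternative. Which internal layer best serves a given retrained
  network is left as a parameter rather than fixed.

## NCA feature selection

The selector is the feature-weighting form of neighborhood component
analysis: weighted ℓ1 distances D_w(i,j) = Σ_l w_l²|x_il − x_jl|, an
exponential kernel with width σ, leave-one-out soft-neighbor assignment
probabilities p_ij, and the regularized objective
ξ(w) = (1/N) Σ_i Σ_{j≠i} y_ij p_ij − λ‖w‖², maximized by full-batch
gradient ascent with the analytic gradient. The classical
linear-transform NCA (learning a projection matrix) is deliberately out
of scope; the weighting form is what feature *selection* requires.

Defaults and why:

* **σ = 1** after z-scoring: distances are already scale-free, so a unit
  kernel width is neutral.
* **λ = 1/N**: shrinks with sample size so regularization never dominates
  a large dataset; with very wide tables (D ≫ N) the penalty term is
  large at the all-ones start, but it is uniform across columns and so
  does not disturb the *ranking* the selector needs.
* **w₀ = 1, learning rate 0.01** with halving on any objective decrease
  (the step is rejected) and 5% growth after accepted steps: fully
  deterministic given the config, no stochastic passes.
* **Stopping**: relative objective improvement below 1e-6, or `max_iter`
  (default 100). The best-objective iterate is returned, so the
  best-so-far trace is non-decreasing by construction.
* **Standardization** uses the population sd (ddof = 0); zero-variance
  columns are mapped to zero, excluded from distances, and reported.
* Ranking is by w² with ties broken by ascending column index, so
  selection is deterministic.

Wide tables are handled by blocking over columns (pure memory layout,
bit-identical to the naive formula) and, when the unique-pair difference
matrix fits a fixed element budget, by caching |x_i − x_j| for all
unordered pairs once per fit, which reduces each iteration to two
matrix–vector products.

## Classification and evaluation

The classifier preset mirrors the common toolbox "quadratic SVM":
polynomial kernel of degree 2, box constraint C = 1, kernel offset 1, and
kernel scale √D over the D selected columns (inputs divided by √D, i.e.
poly-kernel γ = 1/D), one-vs-one multiclass coding, inputs standardized
within each training fold. All values are explicit and overridable; none
is tuned to any dataset. Model fitting uses scikit-learn's `SVC`.

Stratified folds are dealt per class round-robin after a seeded shuffle,
so per-class fold sizes differ by at most one; a class smaller than the
fold count degrades to a warning instead of an error. Cross-validation
offers two protocols: `per_fold` (default) fits standardization, the NCA
weights and the top-k cut on each training split only — the leakage-free
protocol — while `global` computes the selection once on all rows first,
for reproducing workflows that select before splitting. On signal-free
data the global protocol is optimistically biased; the suite checks the
direction of that bias on averaged replicates.

Metrics follow the standard one-vs-rest definitions per class (recall,
specificity, precision, F1, binarized accuracy) plus overall accuracy,
reported as percentages; zero-denominator ratios are NaN with a warning.
Full precision is kept internally and rounding to two decimals happens
only at presentation. In binary tasks recall of one class equals
specificity of the other; this identity is property-tested.

## Synthetic data

The image generator renders, per class, a deterministic stripe pattern
whose period is drawn from the configured texture scales plus a
class-specific ellipse, with seeded Gaussian noise per image. Fine
periods make classes separable in small patches, coarse periods and the
ellipse in large ones, so removing pyramid levels measurably hurts —
which is what makes the pyramid's contribution testable. The table
generator plants a known set of informative columns shifted by a stated
effect size (in noise-sd units) between two balanced classes; the planted
indices are verified by a direct mean-gap statistic before being used to
judge the selector, so the oracle is the generating spec, not the method
under test. The defaults (2 classes, 20 images per class at 224 px,
stripe periods 8 and 64 px, noise sd 0.05; tables 200 × 50 with 5
informative columns at 2 sd) are the conditions the test suite and the
acceptance script run at. These fixtures emulate multi-scale class
structure only — not radiograph anatomy, acquisition noise, implants or
fracture morphology — so passing tests demonstrate the pipeline's
mechanics and protocol correctness, not clinical performance.

## Problem sizes and numerical choices

Unit tests run at a reduced geometry (56-px working side, 14/28-px
patches, 20-dim stub) where every stage is exercised in under a second.
The end-to-end checks run the full geometry (224 px, 85 views, 1000-dim
stub, 85,000 columns) on 2 × 20 images with k_select = 200 and the NCA
ascent capped at 15 iterations — the package's fixture-scale default,
chosen because on these separable fixtures the weight ranking stabilizes
within the first few iterations. Soft-neighbor probabilities are computed
with a per-row max shift before exponentiation, so huge distances cannot
underflow the normalization. Feature CSVs are written with 17 significant
digits and parsed in round-trip mode, making table serialization
byte-stable and lossless; determinism of every artifact from (config,
seeds) is asserted at the byte level.

## Known limitations

* The stub backbone is linear-projection-based; it demonstrates and tests
  the pipeline but does not approach the discriminative power of a
  pretrained CNN on real radiographs.
* Only non-overlapping, axis-aligned square patches at divisor scales are
  supported; no strided or letterboxed variants.
* NCA ascent is full-batch; for N beyond a few thousand samples the N²
  pair structure becomes the bottleneck and a sub-sampled extension (the
  config's seed is reserved for it) would be needed.
* The `global` selection protocol exists for reproduction of
  selection-before-CV workflows and is knowingly optimistic; results
  intended for reporting should use `per_fold`.
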