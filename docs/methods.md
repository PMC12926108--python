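# Methods

## Problem setting

High-dimensional classification tasks — microarray transcriptomics is the
motivating case — increasingly receive their *features* over time: probe
sets, sensor channels or derived measurements arrive one column at a time,
and a working feature subset must be maintained online without ever seeing
the full feature space. Arriving columns are additionally incomplete: each
cell is missing with some rate ρ (equipment failures, profiling limits).
This package maintains a selected feature subset over such a sparse feature
stream.

Per buffered block of H columns the pipeline runs three stages:

1. **Completion.** The M×H block with observation set Λ is completed by a
   rank-L latent-factor model: factors U (M×L) and V (H×L) are trained by
   stochastic gradient descent only on observed cells, minimising per cell
   ½(f_mj − u_m·v_j)² + λ/2(‖u_m‖² + ‖v_j‖²), and missing cells are filled
   with u_m·v_j. Observed cells always pass through unchanged.
2. **Wrapper selection.** A genetic algorithm evolves binary inclusion
   vectors over the candidate pool (previously selected features ∪ the
   block's features), minimising J(b) = α·ε(X_b, y) + β·‖b‖₀/n, where ε is a
   classifier's validation error. Roulette selection uses weights
   1/(f + ι); single-point crossover (probability p_c), independent bit
   flips (probability p_m) and elitism — the best-so-far chromosome replaces
   the worst offspring — complete one generation. Elitism makes the
   best-fitness trajectory non-increasing.
3. **Relevance and redundancy analysis.** Each winning feature is classified
   against the label by Fisher-z tests of (partial) correlation conditioned
   on subsets of the other winners (dependent under all tested subsets →
   strong; under some → weak; under none → irrelevant, and dropped). The
   survivors then pass a Markov-blanket redundancy prune: visiting features
   weakest-association-first, a feature is removed when some small
   conditioning set ζ of the remaining features renders it conditionally
   independent of the label.

Features rejected at any block are not recalled later; the candidate pool at
block t is at most |S_{t−1}| + H.

## Parameters that matter

| Parameter | Default | Meaning / why |
| --- | --- | --- |
| H (buffer width) | 20 | columns per processed block |
| L (latent rank) | 5 | rank of the completion model; L ≪ min(M, H) |
| η (learning rate) | 0.01 | SGD step; too large ⇒ explicit divergence error |
| λ (regularisation) | 0.05 | per-observed-cell ridge on both factor rows |
| max_epochs / rel_tol / min_epochs | 500 / 1e-5 / 50 | stopping rule (below) |
| init scale | 0.004 | factors start uniform on [0, 0.004) |
| N (population) | 30 | GA population size |
| T_max | 100 | GA generations |
| p_c, p_m, p0 | 0.8, 0.05, 0.5 | crossover, mutation, init-bit probabilities |
| α, β | 1.0, 0.01 | error weight and sparsity weight in J(b) |
| ι | 1e-6 | roulette weight floor, prevents division by zero |
| wrapper classifier | linear SVM | fitness core for the stream pipeline |
| fitness protocol k | 2 (pipeline), 0 (standalone default) | 0 = one stratified 70/30 hold-out, k≥2 = stratified k-fold |
| alpha (CI tests) | 0.05 | level of the Fisher-z / G² tests |
| d (max conditioning) | 3 | largest conditioning-set size searched |

Notes on the less obvious choices:

* **β = 0.01** keeps the objective error-first: the sparsity term only
  breaks ties between subsets of equal error. A `mutation_strength`
  parameter is accepted and recorded for interface completeness but has no
  role in the binary bit-flip operator.
* **Empty subsets** are scored with the majority-class error, so the empty
  set never looks like a perfect classifier.
* **min_epochs = 50**: the near-zero factor initialisation creates a flat
  cold-start plateau (gradients scale with the factor magnitudes), during
  which per-epoch loss changes are far below `rel_tol` even though training
  has barely begun. The relative-change stop therefore only activates after
  a 50-epoch burn-in; on desk-scale blocks the plateau ends within ~20
  epochs.
* **Pipeline wrapper = linear SVM with stratified 2-fold error.** A wrapper
  GA compares thousands of subsets; the comparison is only meaningful when
  genuine between-subset error differences exceed the split noise of the
  error estimate. A single 70/30 hold-out on M = 200 has ≈0.04 standard
  error — comparable to the effect of dropping a real feature — whereas
  stratified 2-fold validation uses every sample once and the linear SVM
  shows the largest margin between informative and redundant subsets of the
  four wrappers. k-NN (k=3), a 6-tree random forest and CART are available
  behind the same interface for subset evaluation and benchmarking.
* **Seeding.** One master seed is split into independent substreams (factor
  initialisation, GA, split seeds) via `numpy` seed sequences, so no
  component's draws can perturb another's; a run is exactly reproducible
  from its master seed, and fitness values depend only on the bit pattern
  (evaluation order is immaterial, enabling caching).

## Statistical tests

Conditional independence is tested with Fisher's z transform of the partial
correlation (binary labels are numerically encoded); z = atanh(r)·√(M−q−3)
with q conditioners, two-sided normal p-value. Labels with ≥3 classes fall
back to a G² likelihood-ratio test on quantile-discretised values,
stratified over the conditioning set. A residual with vanishing variance
(duplicate fully explained by its conditioning set) is treated as the
limiting case of conditional independence.

The benchmarking module reports repeated stratified-CV accuracy on the
percent scale, the Friedman chi-square test over a methods × datasets
accuracy table (rank 1 = best, average ranks on ties, statistic
12/(nk(k+1))·ΣR_j² − 3n(k+1) on k−1 degrees of freedom), and an exact
Wilcoxon signed-rank test: zero differences discarded, average ranks on
ties, and the exact null distribution of R⁺ computed by convolution over
the ranks — algebraically identical to enumerating all 2ⁿ sign
assignments — for n ≤ 25, with a tie-corrected normal approximation beyond.

## The synthetic stream generator

The generator emulates the data regime the pipeline assumes, with known
ground truth:

* A shared M×L standard-normal latent matrix A; every column is A·w plus
  i.i.d. measurement noise (`noise_sd`, default 0.1), so the matrix is
  approximately rank-L.
* **Informative features** get one orthonormal latent direction each
  (coefficient ±U(0.9, 1.1)); the label thresholds their equal-weight sum at
  its median (or XORs two thresholded columns). Equal shares make every
  planted feature individually recoverable: its partial correlation with
  the label given any ≤3 of the others stays ≈0.3–0.5 at M = 200. (With
  unequal shares or mutually correlated informative features, a
  conditional-independence prune *correctly* reduces the set to a smaller
  Markov blanket — recovery of "all planted features" is then not a
  well-posed target.)
* **Redundant features** are scalar multiples (±U(0.5, 2)) of one
  informative source, degraded by idiosyncratic per-sample jitter with sd
  0.75× the source's sd. The jitter makes the source the identifiably
  better channel of the pair — the gap in both label correlation (ratio
  ≈0.8) and wrapper error exceeds sampling noise at M = 200 — while the
  duplicate remains exactly conditionally independent of the label given
  its source. Because the jitter is idiosyncratic, no combination of other
  features can reconstruct it (a shared low-rank jitter would let a linear
  classifier use other columns as suppressors and cancel it, making the
  duplicate as good as its source). With `noise_sd = 0` all corruption is
  off: duplicates are exact multiples and the matrix has rank exactly L.
* **Noise features** are idiosyncratic Gaussian columns scaled to match the
  informative columns: individually and jointly independent of the label
  and of every other feature. (Noise columns built inside the informative
  latent space — even orthogonal to the label direction — are linear
  contrasts of the clean informative components; a multivariate classifier
  can combine such columns with one informative column to reconstruct the
  whole label score, which silently makes "noise" informative. Truly
  uninformative features must be idiosyncratic.) Like all stochastic
  corruption they vanish at `noise_sd = 0`.
* The MCAR mask hides each cell independently with probability ρ.

## What the synthetic tests do and do not show

Passing the planted-recovery suite shows the pipeline recovers additive,
individually-informative signals, discards label-independent features and
removes degraded duplicates under MCAR missingness at the stated sizes
(M = 200, 100 features, ρ = 0.1). It does not show robustness to
non-Gaussian marginals, correlated (MAR/MNAR) missingness, concept drift,
interaction-only signals (beyond the XOR label option), or feature spaces
whose informative set is itself mutually redundant — in the last case the
pipeline intentionally returns a minimal blanket rather than the full
planted set.

## Numerical choices and degenerate inputs

* SGD visits observed cells in a fresh seed-controlled shuffle each epoch;
  both factor rows of a cell update simultaneously from pre-update values.
  The epoch loop is JIT-compiled (numba) with a pure-NumPy reference path
  kept and tested for exact agreement.
* Non-finite training loss raises a divergence error naming the learning
  rate rather than silently producing NaN completions.
* Partial-correlation degeneracy is judged relative to each variable's own
  scale (residual norm < 1e-7× the centred norm); constant candidate
  columns are classified irrelevant at the pipeline level, while the raw
  test raises a degenerate-variance error.
* Worst-offspring ties in elitism break to the lowest index; roulette uses
  the first cumulative weight ≥ r; both for determinism.
* The last partial buffer is processed as a narrower block rather than
  discarded. A block's missing rate uses all M·H cells as denominator
  (the per-column definition is the H = 1 special case).

## Known limitations

* Rejected features cannot re-enter the selected set in later blocks; a
  genuinely informative feature lost to one unlucky wrapper comparison is
  gone. This is inherent to the no-recall streaming design.
* The conditional-independence search is restricted to conditioning sets of
  size ≤ d from the currently selected features; true higher-order
  redundancy beyond d is invisible.
* Wrapper fitness estimates share one split seed per block; the GA can
  slightly overfit the split when thousands of subsets are compared — the
  sparsity term and the subsequent CI prune absorb most of the resulting
  noise-feature churn.
* Per-block factors are trained independently (no cross-block sharing), so
  completion quality does not improve as the stream progresses.
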