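# Methods

## The model

`condviab` predicts cellular viability `y = f(x | n)` where `x` is a
standardized protein-coding expression vector and `n` is a compound feature
vector: a 512-bit Morgan fingerprint (radius 2, folded) with the assay
concentration appended as a 513th feature. The conditional architecture is
feature-wise linear modulation (FiLM): an expression encoder (linear /
ReLU / batch-norm / dropout blocks, then a linear projection to an embedding
of width *g*) is modulated by per-feature affine transforms
`h -> gamma * h + beta`, where each FiLM layer's `(gamma, beta)` of length
*g* are generated by a linear head from the compound embedding. Each FiLM
layer is followed by a linear/ReLU/batch-norm/dropout block; a final linear
layer compresses to a scalar viability. Training minimizes mean-squared
error with Adam (decoupled weight decay), early-stopping on a validation
split grouped by cell line.

Baselines and ablations share this skeleton:

* **scale** — the generators emit only `gamma` (`beta` fixed at 0);
* **shift** — only `beta` (`gamma` fixed at 1);
* **concatenation** — an unconditioned multilayer perceptron over
  `[x, n]`, its hidden widths chosen automatically so its trainable
  parameter count matches the FiLM model within 10%;
* **straw** — the FiLM architecture with each compound's fingerprint
  replaced by a fixed random binary code (concentration kept real),
  ablating structural information while preserving compound identity.

The FiLM generators' final layers are initialized so `gamma ~ 1, beta ~ 0`:
the untrained network starts as an unconditioned predictor, which
stabilizes early optimization. The generator is separate per FiLM layer.

An optional multiplicative **gene gate** (an elementwise diagonal layer on
the expression input, initialized at 1, shrunk by a proximal L1 step during
optimization) performs input feature selection. High-dimensional expression
with few truly informative genes is exactly the regime where dense
first-layer weights spread credit over the span of the training
transcriptomes; the gate's multiplicative parameterization biases learning
toward genuinely sparse gene usage, which concentrates input gradients — and
hence integrated-gradients attributions — on the genes the model actually
exploits. The gate is off by default and enabled for the attribution
benchmark model.

Everything is implemented on numpy (float32 forward/backward), with analytic
backpropagation to parameters and to both input blocks; the input-gradient
path is what integrated gradients consumes. Gradient correctness is tested
against central finite differences.

## Featurization

* Fingerprints: RDKit Morgan generator, radius 2, folded to 512 bits.
  Compound pairs (two SMILES joined by `;;`) are combined bitwise-OR.
* Concentration: micromolar, appended un-logged by default. All benchmark
  models instead consume `log10` micromolar (a provided option): the
  0.001–300 uM range spans 5.5 decades, and feeding it raw starves the
  expression pathway during optimization (the dose axis dominates every
  gradient), makes training unstable from seed to seed, and renders the
  integrated-gradients path pathologically nonlinear (the whole
  dose-response is crossed in the first ~0.1% of the straight-line path
  from the zero baseline). On the log scale the dose feature is
  commensurate with z-scored expression.
* Expression: per-gene z-score with population standard deviation
  (divisor N), training-cohort statistics frozen for reuse. Zero-spread
  genes are set to 0 rather than dropped, keeping the gene axis fixed
  across cohorts. New cohorts are harmonized onto the training gene axis
  with mean imputation of missing genes, erroring below a 50% match.
* Cross-validation folds are grouped by cell line (all examples of a cell
  line share a fold; fold sizes differ by at most one cell line), so no
  transcriptome appears on both sides of a split.

## Dose-response modeling

Predicted curves over the default grid (32 points, log10-uniform,
0.001–300 uM) pass a QC cascade before fitting: while any of the four
largest concentrations' viabilities is ≥20% above the fifth largest's
(relative reading `v >= 1.2 * v_ref`; an absolute reading is available), the
largest point is dropped and the rule re-checked. Surviving curves need at
least 16 points and a minimum viability ≤ 0.4. Fits use the log-logistic
family `v(x) = c + (d - c) / (1 + exp(b (ln x - ln e)))` with bounded
least squares, multi-start over `e`, and a 4 → 3 (`c = 0`) → 2
(`c = 0, d = 1`) parameter fallback on optimizer failure (non-convergence,
non-finite values, or a parameter pinned at a bound). Fits with
`e` outside [0.001, 300] uM are flagged out of range.

IC50 is the absolute 50%-viability crossing, solved in closed form from the
fitted parameters (undefined when the curve never crosses 0.5). AUC is the
trapezoidal integral of viability over log10 concentration normalized by
the log-range (flat `v = 1` gives exactly 1), min-max scaled per compound
across a cohort when requested; responders are calls at `auc_scaled <=
threshold` (inclusive). ED50 of this family equals `e`; relative potency is
tested by the delta method on log-ED50s with a two-sided t test on the
combined residual degrees of freedom.

## Attribution

Integrated gradients from zero baselines, both input blocks attributed.
The path integral is discretized with a trapezoidal rule (endpoints
included, end weights halved). On a piecewise-linear (ReLU) network the
trapezoid rule is exact within linear segments, giving completeness gaps
well under 1% at the default 50 steps; a left-endpoint Riemann sum has
O(1/steps) error and cannot reach that tolerance. Attributions are taken
in inference mode (batch-norm statistics frozen) at each pair's predicted
IC50; ensemble attribution is the mean of member attributions.

Adjusted attributions z-score each gene within each cell line across that
cell line's pair rows (population sd; zero spread -> 0), removing
cell-line-specific magnitude effects. Adjustment is idempotent and
invariant to per-cell location/scale changes in the raw rows.

Soundness controls re-run the attribution pipeline through (i) an
architecturally identical but untrained, randomly initialized model and
(ii) a model trained on label-permuted data, reporting per-row Pearson
correlations with the true model's raw and adjusted attributions.

Raw integrated gradients scale with the input, so for a dense-input model
their magnitudes correlate strongly with the transcriptome — the classic
confound that per-cell-line adjustment removes. The benchmark demonstrates
this coupling (and its removal by adjustment) on the standard dense
architecture. Notably, the sparse gene gate largely removes the confound
at the source: a gated model's raw attributions are already concentrated
on the genes it uses, so their correlation with transcript magnitudes
drops from ~0.6 to ~0.1. Both numbers are reported.

In the synthetic benchmark the downstream analyses (clustering, per-target
tests) operate on the **magnitude** of adjusted attributions. The
generator's transcriptomes are symmetric around each gene's mean, so a
target gene's attribution sign genuinely flips from cell line to cell line
(it follows `z_g(cell) * w_g`); the class-specific information is carried
by which genes have large adjusted magnitudes, not by their signs. An
analytic oracle model makes this concrete: K-means on signed adjusted
vectors recovers MOA classes at AMI ~0.22, on magnitudes at ~1.0.

## Interpretation

* Control compound set (CCS): MOA classes with at least two compounds
  attributed in every cell line.
* K-means/AMI: scikit-learn K-means (k = number of classes by default),
  adjusted mutual information over several seeded trials; source
  comparisons use two-sided Wilcoxon rank-sum tests.
* Wilcoxon rank-sum: exact small-sample distribution when tie-free and
  small, tie-corrected normal approximation otherwise (scipy's policy);
  verified against full enumeration for group sizes ≤ 6.
* Multiple testing: Benjamini-Hochberg step-up throughout.
* Leiden clustering on a cosine-similarity kNN graph (k = 15 default),
  RBConfiguration partition, seeded.
* Differential attribution: per-gene rank-sum of a cluster (or merged
  clusters) against all remaining rows, BH across genes, ranked by q then
  |mean difference|, top-10 markers reported.
* Network statistics: connectivity of a node set is its induced-subgraph
  edge density (absent nodes count with degree zero), comparable across
  set sizes; the raw edge count is available. Monte-Carlo nulls draw
  same-size sets from a caller-supplied pool with a +1-smoothed empirical
  p. Because the induced edge count of a small set is integer-valued, the
  smoothed p is discrete; calibration is therefore assessed with
  randomized tie-broken p-values, which are exactly uniform under the
  null. Interaction enrichment is an upper-tail hypergeometric test on
  induced edges against the background pair universe (STRING's
  degree-corrected model is deliberately not reproduced); gene-set
  enrichment over GMT files uses the one-sided hypergeometric overlap
  tail.

## Synthetic cohorts

The generator emulates the structure of a large cell-line viability screen:

* transcriptomes: per-gene Gaussian baselines with unit-scaled cell-line
  offsets `z`;
* compounds: drawn from a bundled list of ~50 public drug-like SMILES, so
  fingerprinting is exercised on real structures; grouped into MOA classes
  with disjoint planted target-gene sets shared within a class;
* potency: `log10 IC50(cell, compound) = alpha_compound +
  sum_{g in targets} w_g z_g(cell)`, clipped to the grid interior. The
  per-compound offset `alpha` is a sparse linear readout of fingerprint
  bits (standardized across the cohort, mapped into [-2, 1.5] log10 uM):
  potency runs in chemotypes, so chemical structure carries real signal
  and ablating it has measurable consequences. MOA class assignment is
  *independent* of structure, so structural similarity alone says nothing
  about mechanism. Cell-effect weights have sd 0.4 decades per class
  (about a 2.5-fold IC50 spread across cells, a realistic pharmacogenomic
  effect size);
* viability: `1 / (1 + (conc / IC50)^h) + N(0, noise_sd)`, clipped at 0,
  with Hill slope `h = 2` and noise sd 0.05 — so noiseless viability at
  the true IC50 is exactly 0.5 and the clean curve is the log-logistic
  with `b = h, c = 0, d = 1, e = IC50`;
* interactions: a sparse random background graph plus a clique planted on
  each class's target set, scores in (0.7, 1].

What it does **not** emulate: count-based RNA-seq noise, correlated gene
modules, assay plate effects, heteroscedastic viability noise, compound
pairs with interaction effects, or the empirical CTRP viability
distribution. Passing benchmarks here demonstrates that the machinery
recovers planted mechanisms under a clean generative model, not that it
will do so on real screens.

## Benchmark designs and problem sizes

Two seeded cohorts, sized for their questions:

* **Variant benchmark** — 36 cell lines x 400 genes x 48 compounds
  (6 classes). Six cell lines and two compounds per class are held out;
  models train on the train-cell x train-compound block and are scored on
  all pairs involving a held-out cell or compound, so held-out R^2 probes
  generalization across biology *and* chemistry — the regime where a
  structural ablation fails visibly (the straw model cannot predict the
  potency of a compound it has no structural handle on). Training: 40
  epochs max, patience 8. At this scale the conditioning variants and the
  parameter-matched concatenation baseline perform within a few
  hundredths of R^2 of each other (conditioning's larger advantage
  appears at data scales this benchmark does not reach); the ablation
  gap, by contrast, is large.
* **Attribution benchmark** — 72 cell lines x 300 genes x 36 compounds,
  log10-concentration features, FiLM model with the sparse gene gate,
  trained with generous patience (150 epochs max, patience 30, weight
  decay 1e-3). Gene-level attribution interrogates the learned
  gene-dependence, which requires (i) enough distinct transcriptomes for
  the planted expression link to be statistically identifiable and
  (ii) training past the point where dose-shape and potency saturate the
  validation loss, since the per-cell-line expression dependence is the
  last thing the optimizer fits.

Sizes were chosen so the full benchmark run (five variants, a long-trained
model, a label-permuted control, dose-response fits for every pair, and
all interpretation analyses) completes in CPU minutes.

## Numerical choices

* float32 network arithmetic; float64 everywhere else.
* Multi-start log-logistic fitting: five `e` starts log-spaced over the
  observed concentration range; tolerances 1e-14; bounds
  `b in (0, 50], c in [-1, 1.5], d in [-0.5, 2.5], e in [1e-5, 1e4]` uM.
* Seeds: every stage derives a 31-bit seed from the global seed and a
  stage name (BLAKE2 digest), so stages are independently reproducible.
* Degenerate inputs: zero-spread genes -> 0 (warned); cell lines with a
  single attributed pair cannot be adjusted (library errors; the CLI
  drops them with a warning); curves never crossing 0.5 -> no IC50.

## Known limitations

* The per-pair "planted targets in the top 5% of a single pair's adjusted
  attribution vector" recovery rate is information-limited at desk scale:
  with n transcriptomes against p genes, even the ideal minimum-norm
  linear learner localizes targets in the top 5% for well under 70% of
  pairs at n/p ~ 0.2 (the gene gate's sparsity bias recovers much of the
  gap). Group-level statistics (per-class rank-sum tests, clustering) are
  far better powered and are the recommended interpretation route.
* The concatenation baseline's width search matches parameter counts, not
  FLOPs or depth.
* Training determinism holds for a fixed BLAS thread configuration;
  different thread counts can reorder floating-point reductions.
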