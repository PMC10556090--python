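# Methods

This note documents the models, procedures and design choices behind
`proglimit`, in the spirit of the methods documentation of mature
statistical packages: what is computed, under which assumptions, which knobs
matter, and what the synthetic benchmarks do and do not establish.

## Harrell's concordance index

For risk scores `s`, times `t` and event indicators `δ`, a pair `(i, j)` is
comparable iff `t_i < t_j` and `δ_i = 1`; it is concordant iff `s_i > s_j`
and counts 0.5 when `s_i = s_j`.  Pairs with tied times are not comparable.
C is the concordant fraction over comparable pairs.  These are Harrell's
original conventions; the implementation is a vectorized O(n²) pair count
and is checked exactly against a naive double-loop oracle and, on tie-free
data, against scikit-survival's estimator.  When no comparable pair exists
(all samples censored, or all times tied) the result is undefined and a
dedicated exception is raised rather than a sentinel value returned.

Orientation is fixed package-wide: **higher score = higher risk**.  Every
model adapter conforms to this, which is what makes C-values comparable
across the nine models (and prevents silent `1 − C` bugs).

## Prognostic models

Nine censoring-aware learners sit behind one `fit`/`predict_risk` contract
(`ModelSpec` → `FittedModel`).  Implementations delegate to scikit-survival
where it provides the algorithm; the maximally-selected-rank forest is
implemented here because no installed library offers one.

| id | model | notable defaults |
|----|-------|------------------|
| `coxph` | unpenalized Cox partial likelihood | ridge jitter 0.01 applied automatically when the Hessian is singular or p ≥ n, escalated (1.0, 100.0) until the Newton solve is finite |
| `lasso` / `elastic_net` | Coxnet penalized Cox path (L1 / mixing 0.5) | penalty chosen by internal 3-fold CV on the training fold only, scored by held-out C |
| `ridge` | L2-penalized Cox | strength from {0.01, 0.1, 1, 10, 100} by internal 3-fold CV |
| `gb_linear` | boosted Cox likelihood, componentwise-linear base learners | 100 steps, learning rate 0.1 |
| `gb_tree` | boosted Cox likelihood, depth-≤3 trees | 100 steps, learning rate 0.1 |
| `rsf` | random survival forest, log-rank splits | 500 trees, mtry = ⌈√p⌉, min leaf 15 |
| `rank_rf` | forest with maximally selected rank statistics | 100 trees; split variable drawn uniformly among mtry candidates, cutpoint maximizing the standardized log-rank statistic over in-node deciles |
| `stree` | single survival tree, log-rank splits | min leaf 15 |

All hyperparameters are exposed through `ModelSpec.hyperparams`; the
defaults follow the cited algorithms' canonical settings.  Linear models
expose the linear predictor as the risk score; trees and ensembles expose
an expected-cumulative-hazard (mortality) score.  For `rank_rf`, decoupling
the variable choice from the cutpoint choice counteracts the bias of
log-rank splitting toward high-cardinality variables; restricting candidate
cutpoints to in-node deciles bounds the computation while preserving the
"maximally selected" idea.  A model that fails to converge returns a
flagged result with a diagnostic instead of raising, so grid runs record
the cell as missing rather than aborting.

## Gene-set construction

* **Random** — `n_sets` uniform draws of `set_size` distinct genes.  The
  default size of 20 is the size at which random signatures are known to
  perform near-optimally; it also makes ML-selected sets comparable.
* **Reported** — plain-text files, one symbol per line, `#` comments;
  case-insensitive matching against the dataset; sets matching under 50% of
  their listed genes are dropped with a warning.  A handful of public
  breast-cancer panels ship with the package as editable fixtures; the
  loader, not the curated content, is the contract.
* **UM** — per-gene univariable Cox fits (own Newton solver, Breslow ties);
  the gene with the largest |Wald z| wins, ties broken lexicographically.
* **SRC** — random-survival-forest permutation importance.  Importance is
  the drop in held-out C after permuting one gene, averaged over 2
  permutations × 3 independent event-stratified 70/30 splits.  A single
  split makes the ranking hostage to one unlucky partition; averaging over
  a few splits stabilized recovery markedly on synthetic ground truth.
* **SRC-VH** — variable hunting: subsets sampled with probability ∝ SRC
  importance, a forest fitted per subset, genes ordered by minimal depth
  and added while held-out C improves; the final set keeps genes whose
  selection frequency reaches the mean frequency.  Returns small,
  high-precision sets by construction.
* **MRMR** — greedy `argmax(relevance − redundancy)` with relevance =
  |univariable Cox Wald z| and redundancy = mean |Pearson r| with the
  already-selected genes.
* **CF** — conditional permutation importance: a gene is permuted within
  strata formed by quartile bins of its most-correlated partners
  (|r| > 0.2, up to 2 partners), removing importance owed purely to
  correlated neighbours.  Because a shared latent factor makes signal genes
  mutually correlated, CF *by design* recovers fewer of them than SRC on
  the synthetic benchmark — that is the estimator working as intended, not
  a defect.

Forest-based selectors prefilter to the 500 highest-variance genes by
default (flag to disable) for tractability.  Permutation importances are
measured on held-out splits rather than out-of-bag samples: the installed
forest implementation does not expose per-tree OOB membership cleanly, and
a held-out C drop estimates the same quantity.

## Evaluation and aggregation

One event-stratified `StratifiedKFold(5)` permutation per signature, seeded
from the grid seed and the (dataset, set, model) indices, makes every grid
bit-reproducible.  Expression is standardized per gene on the training fold
only (no leakage).  Event stratification avoids folds with no comparable
pairs in small cohorts.  Fold failures (non-convergence, undefined C)
become missing values; the signature median is taken over available folds.

MOM/MAD/MAX summarize each (dataset, model) group.  "Fraction above"
curves use strict inequality, so boundary behaviour is exact: the ceiling
estimate is the smallest grid threshold where the fraction of signatures
with median C above it falls below 1%.  Cohort correlations report both
Pearson and Spearman with two-sided p-values and require at least three
datasets.  Random-signature-superiority prevalence is the fraction of
random signatures strictly above a reference signature's median C, per
(dataset, model), plus the across-group mean.

## The synthetic cohort generator

Per sample, a latent factor `z ~ N(0,1)`; a fraction of genes reads
`w·z + ε`, the rest pure `ε ~ N(0, σ)`.  Event times follow a Weibull
(default shape 1 = exponential) proportional-hazards model with hazard
∝ `exp(β·z)`, scaled so the median event time at `z = 0` equals
`baseline_median_time` (default 10 years).  Censoring is independent
exponential, its rate solved numerically so the expected censoring fraction
matches the target — realized event rates land within a few points of
`1 − censor_rate_target` for n ≥ 400.  Everything is deterministic given
the seed, and the generator returns the true `z` and the loaded-gene list
for oracle evaluations.

What this emulates: the empirically central feature of expression cohorts —
risk flowing through a shared proliferation-like program that many genes
tag redundantly, which is what produces random-signature superiority and an
information ceiling.  What it does not emulate: platform effects, batch
structure, non-linear gene interactions, competing risks, or informative
censoring.  Passing tests on this generator therefore validate the
machinery and its statistical behaviour under the stated model, not the
clinical performance of any signature.

## Missing-information simulation

Images (28×28, 256 grey levels) stand in for patients.  Per repetition,
2000 images are drawn from the pool; their two leading principal components
(refit per stack, mean-centered, scores standardized to unit variance)
define deterministic survival times `T = MST · exp(S · (PC1 + PC2))`, with
MST = 10 years and S = 0.6 (a right-skew typical of survival
distributions).  Noise at level `p` replaces each pixel independently by a
uniform draw from [0, 255] with probability `p` — chosen precisely so that
`p = 1` is exactly information-free (C must fall to 0.5) and `p` is
interpretable as the destroyed-information fraction; initial information is
`100% − noise%` by definition.  The PCA is refit on each noised stack
(reduction sits downstream of the corruption), a two-covariate Cox model is
fit against the true times with a small ridge (1e-3) to keep the separable
zero-noise case finite, and Harrell's C is computed in-sample — with 2
covariates and 2000 all-uncensored samples, optimism is negligible.  The
per-level aggregate is the median over 100 repetitions, with the standard
error of the median via the normal approximation `1.2533·σ/√R`.  Mean
normalized pixel entropy `H = −Σ p_k ln p_k / ln 256` (computed on a
256-image subsample per repetition, which is ample for a mean) provides the
alternative x-axis; the normalizer `ln 256` is the entropy of a uniform
histogram over all grey levels.

Numerical notes: the internal Cox-Newton solver uses Breslow ties,
step-halving, and clips the shifted linear predictor at −700 so that the
diverging coefficients of the separable zero-noise fit never underflow the
risk-set sums.  At 2000 images the zero-noise fit orders the deterministic
times perfectly up to at most a few inverted pairs in ~2 million (median C
≥ 0.9999); at a few hundred images the finite-sample Cox direction can
leave a single inverted pair, which is why small-stack tests assert
near-perfection rather than exactness.

The built-in digit generator renders crude stroke-skeleton digits (0–9)
with random pose, pen width and ink intensity on a dark background —
matching the ink statistics (sparse bright strokes, low-dimensional latent
pose) of the classic handwritten-digit corpora so that no download is
needed.  An IDX-format reader accepts the standard container of those
corpora for users who want the real images.  On the synthetic digits the
calibration lands close to what real handwritten digits give: the median C
reaches 0.75 at roughly 75–80% noise, and more than half the information is
already gone at C = 0.8.

## Problem sizes and defaults in the test-suite

The packaged tests exercise the full pipeline at desk scale: cohorts of
60–400 samples and 50–500 genes, forests of 20–100 trees, grids of up to
800 evaluated signatures (with the stub scorer for cardinality checks), and
image simulations of 400–2000 images with 5–100 repetitions.  These sizes
are the package's choice of a thorough-but-quick default; all of them are
parameters, and the defaults embedded in the API (500-tree forests, 100
repetitions, 2000 images) are the study-scale settings.

## Known limitations

* Reported-signature fixtures are illustrative public panels, not a curated
  census of the literature; the RSS comparison takes an arbitrary reference
  gene set as a parameter.
* Penalized-model regularization paths use small internal CV grids; for
  serious per-dataset tuning, widen `hyperparams`.
* The conditional-importance (CF) conditioning scheme — quartile strata of
  up to two most-correlated partners — is a declared simplification of
  conditional inference forests.
* In-sample C in the image simulation slightly exceeds 0.5 at full noise
  (≈ 0.508 with 2 fitted covariates on 2000 samples): the expected optimism
  of any fitted score, well inside the calibration tolerance.
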