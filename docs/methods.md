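# Methods

## The pair-indicator statistic

For DEirlncRNAs A and B (A < B lexicographically, fixing the orientation
once and for all), each sample contributes S(A,B) = 1 iff expr(A) >
expr(B), with exact ties scored 0. Because S is a within-sample rank
statistic of two genes, it is invariant to any strictly increasing
per-sample transform of the expression matrix — the package's defining
robustness property, asserted bit-for-bit in the test suite. Orientation
only flips S and the sign of the downstream Cox coefficient; fixing it
lexicographically makes runs reproducible. Tie handling (S = 0) matters
only on discretized data; ties are logged when they occur.

The skew filter retains a pair only if its one-frequency lies strictly
between q_min and 1 − q_min (default q_min = 0.2, i.e. both indicator
values occur in more than 20% of samples). The boundary is exclusive; the
filter is idempotent. Pairs are built on tumor samples only, since the
survival model is fit on tumors; screens that contrast cohorts use both.

## Screens

A lncRNA is *immune-related* when it correlates with at least one curated
immune gene at r > 0.4 and p < 0.001 (strict, as the workflow prints
them). Correlation is Pearson on log2(x+1) values across tumor + normal
samples; Spearman is available by argument. p-values use the classical
t transform on n − 2 df. Constant profiles are skipped with a warning.

Differential expression over the immune-related lncRNAs: logFC =
log2((mean_tumor + ε)/(mean_normal + ε)) with ε = 0.001 guarding
unexpressed genes; a two-sided Wilcoxon rank-sum p; Benjamini–Hochberg
FDR across tested genes; a gene is up/down when |logFC| > 1.5 and
FDR < 0.5 (both strict). The unusually permissive FDR threshold is kept
deliberately as the workflow's stated default and is configurable.

## Signature selection

1. **Univariate Cox screen.** One single-covariate Cox fit per pair,
   Newton maximization of the Efron partial likelihood, vectorized across
   pairs (hundreds of fits in well under a second). Pairs with Wald
   p < 0.05 survive. Constant covariates and fits drifting to separation
   (|β| > 15) are dropped loudly, never silently.
2. **Lasso-Cox with cross-validation.** The L1 path comes from the
   coordinate-descent elastic-net solver in scikit-survival (a glmnet
   port, Breslow ties). Ten event-stratified folds, deterministic given
   the seed; each fold is scored by the deviance
   −2·[loglik_all(β) − loglik_train(β)] with a matching Breslow partial
   likelihood (the scheme glmnet uses for Cox models); the λ minimizing
   the mean CV deviance is chosen (λ_min; λ_1se available). If the active
   set at λ_min is empty the model falls back to the strongest penalty
   with a nonempty active set — the sparsest establishable model — so a
   null data set yields one or two pairs for the stepwise stage to reject
   rather than dozens.
3. **Stepwise AIC.** Bidirectional stepwise selection over the lasso set,
   starting from the full candidate model, minimizing the partial-likelihood
   AIC of the multivariate Cox fit (lifelines, Efron ties). Exactly
   duplicated and complementary binary columns are collinear in a Cox
   linear predictor and are pre-dropped (later-listed loses). An empty
   final model raises: the signature cannot be established.

The risk score is the final model's linear predictor Σ βᵢSᵢ. All three
stages' survivors are recorded in `provenance_` because the stages are
nested and audits need all of them.

## Evaluation

*Time-dependent ROC* at horizon t uses the cumulative-case/dynamic-control
definition: cases have an observed event by t, controls are still under
observation past t, samples censored at or before t are excluded. No IPCW
weighting — the simple estimator is transparent and exactly checkable
against a pairwise-comparison oracle; inverse-probability weighting is a
noted extension. The AUC is the Mann–Whitney probability with ties
counted 1/2. The risk-group cutoff maximizes the Youden index TPR − FPR
on the 5-year curve, ties resolved toward the lower threshold, and that
single cutoff feeds every downstream grouping (KM, clinical tests, immune
association) so group sizes have one source of truth.

KM curves, two-group log-rank tests (overall and within each molecular
subtype) and the clinical Cox reports delegate to lifelines. Clinical
covariates are ordinal-coded (stage-like labels by their natural order,
other categories by sorted level); age is dichotomized at 65 years for
the rank tests but enters Cox models continuously. Exactly collinear
covariates are dropped from the joint model by rank inspection. The
clinical association tests are *unpaired* rank tests (rank-sum for two
levels, Kruskal–Wallis beyond) — the groups being compared are
independent patients, whatever a workflow description may call the test.

Immune association is rank-based throughout (Wilcoxon between risk
groups, Spearman against the continuous score, BH within stratum), hence
invariant to monotone rescaling of the score. Deconvolved cell fractions
are consumed, never computed. Enrichment is an upper-tail hypergeometric
overrepresentation test, p = P(X ≥ k), BH across sets; the universe is
the measured coding genes, not the genome, conditioning on measurability.

## The synthetic cohort generator

The generator is the pipeline's generative inverse and its defaults are
the study conditions used everywhere: 600 tumor and 60 normal samples,
200 candidate lncRNAs, 100 immune mRNAs on 4 latent modules, 60
module-loading (immune) lncRNAs of which 30 carry a ±2.5 log2 tumor
shift, 10 true pairs with |β| = 0.8, Weibull baseline (shape 1.5, scale
8 years), ~30% independent censoring, modest age/stage effects (0.02 per
year, 0.3 per stage), and a LumA-dominant subtype mix.

Mechanics and the reasons behind them:

- Expression is Gaussian on log2 with unit variance and gene means
  uniform on [2, 6], exponentiated to a log-normal FPKM-like scale.
  Loadings of 0.9 put the population lncRNA–immune-mRNA correlation at
  0.81, comfortably above the 0.4 screen; a configuration whose loading
  product cannot clear the screen threshold is rejected at construction.
- The two genes of a true pair share a latent module and a mean, so their
  difference — and hence the pair indicator — is driven by gene-level
  noise: indicators sit near one-frequency 0.5 (surviving the skew
  filter) and are independent across the 10 pairs, which keeps the true
  risk-score variance at its nominal Σβ²/4 and the problem's difficulty
  stable across seeds.
- Survival: hazard h(t) = h₀(t)·exp(Σ βᵢSᵢ + γᵀz) with Weibull h₀ and
  S computed by the package's own pair code, so "truth" and "estimate"
  mean the same statistic. Event times by inverse-transform sampling;
  shape 1 reduces to the exponential special case used as a closed-form
  oracle. The exponential censoring rate is solved by root-finding
  against the realized event times; a >10-point miss warns.
- The fraction table couples Macrophage_M2 positively and CD8_T
  negatively to the true risk on the logit scale before a softmax, giving
  the immune-association module a known signed target; under a null
  cohort the coupling vanishes. Gene sets comprise one set per latent
  module (enriched in the mRNAs the signature genes correlate with) plus
  random background sets.
- One global seed fans out to per-component child streams
  (expression / survival / fractions / sets), so each stage is
  reproducible in isolation.

What the generator does *not* emulate: negative-binomial count noise,
library-size and batch effects, subtype-dependent expression or survival
differences, and informative censoring. Passing the recovery studies
therefore demonstrates the statistical machinery is correct and calibrated
under the model's own assumptions — not that the signature generalizes to
any real cohort.

## Validation studies and their scale

`recovery_study` (defaults, 10 seeds, one third of tumors held out of
every fitting step) measures true-pair recovery in the final signature,
held-out Harrell C, held-out 5-year AUC and the low-vs-high log-rank p;
`null_study` repeats the pipeline on all-β-zero cohorts. A null cohort
can legitimately fail to establish a signature (every selection stage may
come up empty); the study then scores a constant, uninformative score,
whose concordance is exactly 0.5. Ten seeds keep the studies to a few
minutes on one CPU while leaving the medians stable; the same studies are
what `scripts/acceptance.py` re-runs.

## Known limitations

- The time-dependent ROC is unweighted; with heavy censoring before the
  horizon it estimates a conditional quantity.
- Stepwise-AIC selection inherits the usual instability of stepwise
  procedures; provenance of all three stages is recorded for this reason.
- p-values in the uni-Cox screen are not corrected for the number of
  pairs screened — by design, matching the workflow it mirrors; the
  lasso and stepwise stages are the overfitting control.
- ID normalization strips Ensembl version suffixes; non-Ensembl
  identifiers pass through untouched.
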