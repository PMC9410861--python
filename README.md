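# irlpair

Immune-related lncRNA **pair** (IRLP) prognostic signatures for tumor
transcriptomes, with a ground-truth synthetic-cohort generator so the whole
workflow can be developed and validated offline.

## The problem and the statistic

Single-gene lncRNA signatures depend on absolute expression values, and so
on normalization, platform and batch. The IRLP approach sidesteps this: for
a pair of genes (A, B) — A before B in lexicographic gene-id order — each
sample is summarized by a binary indicator

    S(A, B; sample) = 1  if  expr(A) > expr(B)  in that sample, else 0.

S depends only on the *within-sample ordering* of two genes, so it is
invariant to any strictly increasing per-sample transform of the data
(log, scaling, quantile shifts). The pipeline, modeled on the published
breast-cancer IRLP workflow, is:

1. **irlncRNA screen** — lncRNAs correlated with a curated immune gene
   list (Pearson on log2(x+1), r > 0.4, p < 0.001);
2. **DEirlncRNA screen** — tumor-vs-normal differential expression among
   those (Wilcoxon rank-sum, |log2 FC| > 1.5, BH FDR < 0.5);
3. **pair matrix** — all C(D, 2) indicators, then a *skew filter* keeping
   pairs whose one-frequency lies strictly in (0.2, 0.8);
4. **signature** — univariate Cox screen (Efron ties, Wald p < 0.05) →
   lasso-penalized Cox with 10-fold cross-validation (deviance-minimizing
   λ) → bidirectional stepwise AIC multivariate Cox. The risk score is
   the linear predictor RS = Σᵢ βᵢ·Sᵢ;
5. **evaluation** — time-dependent ROC at 1/3/5 years, Youden-optimal
   cutoff on the 5-year curve, Kaplan–Meier + log-rank overall and per
   molecular subtype, clinical uni-/multivariate Cox, immune-cell-fraction
   and checkpoint-gene association (rank-based), and hypergeometric
   gene-set enrichment of coding genes correlated with signature lncRNAs.

The model-fitting core is exposed as scikit-learn style estimators
(`PairIndicator` transformer, `IRLPSignature` estimator with
`fit`/`predict`/`score`), and every stage is also available as a plain
function on the package's containers.

## Worked example

```python
from irlpair import (SimulationConfig, simulate_cohort, run_pipeline,
                     true_pair_recovery)

cohort = simulate_cohort(SimulationConfig(seed=1))     # 600 tumors, 60 normals
res = run_pipeline(cohort.lnc_expr, cohort.mrna_expr, cohort.clinical,
                   cohort.immune_genes, test_fraction=1/3, seed=1)

print(len(res.coexpression.immune_lncrnas))   # 60   irlncRNAs flagged
print(len(res.de.de_genes))                   # 30   DEirlncRNAs
print(res.n_candidate_pairs)                  # 435  = C(30, 2)
print(len(res.pair_matrix.indicator))         # 126  pairs pass the skew filter
print(len(res.signature.selected_pairs_))     # 20   pairs in the signature
print(round(res.cindex_test, 3))              # 0.741  held-out C-index
print(round(res.roc_test[5.0].auc, 3))        # 0.796  held-out 5-year AUC
print(true_pair_recovery(res, cohort.truth))  # 1.0  all 10 true pairs found
```

The generator plants 10 prognostic pairs with |β| = 0.8 among 200 candidate
lncRNAs; the run above recovers all of them, and the held-out C-index of
0.74 means the score correctly orders ~3 of every 4 comparable patient
pairs by survival.

The same analysis runs from the shell on a cohort directory:

```bash
irlpair simulate cohort_dir --seed 1
irlpair run-all cohort_dir results_dir --seed 1 --test-fraction 0.33
```

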