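"""Screening of immune-related lncRNAs (irlncRNAs) and DEirlncRNAs.

Two stages mirror the front of the IRLP workflow: (1) a coexpression
screen flags a lncRNA as immune-related when it correlates with at least
one curated immune gene above ``r_min`` with ``p < p_max``; (2) a
tumor-vs-normal differential-expression screen over the flagged lncRNAs
keeps those with ``|log2 FC| > lfc_min`` at ``FDR < fdr_max``.

Correlations are Pearson on log2(x+1) values by default (Spearman
available); the DE test is a two-sided Wilcoxon rank-sum with
Benjamini-Hochberg correction across tested lncRNAs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import NORMAL, TUMOR, ExpressionMatrix, ImmuneGeneSet

log = logging.getLogger(__name__)


def _corr_with_p(X: np.ndarray, Y: np.ndarray, method: str = "pearson"):
    """All-pairs correlation between rows of X and rows of Y with two-sided p.

    Rows with zero variance yield NaN r and p (callers skip them).
    p-values use the t approximation t = r * sqrt((n-2)/(1-r^2)) on n-2 df,
    identical to the classical Pearson test; for Spearman the same statistic
    is applied to midrank-transformed data.
    """
    n = X.shape[1]
    if n < 3:
        raise ValueError("need at least 3 shared samples for a correlation test")
    if method == "spearman":
        X = stats.rankdata(X, axis=1)
        Y = stats.rankdata(Y, axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    xs = np.sqrt((Xc ** 2).sum(axis=1))
    ys = np.sqrt((Yc ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ Yc.T) / np.outer(xs, ys)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    r[xs == 0, :] = np.nan
    r[:, ys == 0] = np.nan
    p[np.isnan(r)] = np.nan
    return r, p


@dataclass
class CoexpressionResult:
    """Edges (lncRNA, immune gene, r, p) and the per-lncRNA immune flag."""

    edges: pd.DataFrame
    is_immune_related: pd.Series
    n_skipped_constant: int = 0

    @property
    def immune_lncrnas(self) -> list[str]:
        return list(self.is_immune_related.index[self.is_immune_related])

    def write_edges(self, path, passing_only: bool = True) -> None:
        e = self.edges
        if passing_only:
            e = e[e["passes"]]
        e.to_csv(path, sep="\t", index=False)


def coexpression_screen(lnc_expr: ExpressionMatrix, mrna_expr: ExpressionMatrix,
                        immune: ImmuneGeneSet, r_min: float = 0.4,
                        p_max: float = 0.001, method: str = "pearson") -> CoexpressionResult:
    """Flag lncRNAs correlated (r > r_min, p < p_max) with >= 1 immune gene.

    Correlations are computed across all shared samples (tumor + normal)
    on log2(x+1) values.  Both thresholds are strict inequalities.
    """
    immune_in_matrix = [g for g in mrna_expr.gene_ids if g in immune.genes]
    if not immune_in_matrix:
        raise ValueError("no immune genes found in the mRNA expression matrix")
    shared = [s for s in lnc_expr.sample_ids if s in set(mrna_expr.sample_ids)]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples; need >= 3")
    L = lnc_expr.log2p1()[shared]
    M = mrna_expr.log2p1().loc[immune_in_matrix, shared]

    r, p = _corr_with_p(L.to_numpy(), M.to_numpy(), method=method)
    n_skipped = int(np.isnan(r).sum())
    if n_skipped:
        log.warning("skipped %d lncRNA-immune pairs with a constant profile", n_skipped)

    passes = (r > r_min) & (p < p_max)
    passes &= ~np.isnan(r)
    lncs = np.repeat(L.index.to_numpy(), len(immune_in_matrix))
    edges = pd.DataFrame({
        "lncRNA": lncs,
        "immune_gene": np.tile(np.asarray(immune_in_matrix), len(L.index)),
        "r": r.ravel(),
        "p": p.ravel(),
        "passes": passes.ravel(),
    })
    flag = pd.Series(passes.any(axis=1), index=L.index, name="is_immune_related")
    return CoexpressionResult(edges, flag, n_skipped)


@dataclass
class DEResult:
    """Per-lncRNA tumor-vs-normal differential expression summary."""

    table: pd.DataFrame  # columns: logFC, p, fdr, direction

    @property
    def de_genes(self) -> list[str]:
        t = self.table
        return list(t.index[t["direction"] != "ns"])

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene")


def differential_expression(lnc_expr: ExpressionMatrix, genes=None,
                            lfc_min: float = 1.5, fdr_max: float = 0.5,
                            eps: float = 0.001) -> DEResult:
    """Tumor-vs-normal DE over the given lncRNAs (default: all in matrix).

    log2 FC is ``log2((mean_tumor + eps) / (mean_normal + eps))`` on the
    raw abundance scale; the p-value is a two-sided Wilcoxon rank-sum; FDR
    is Benjamini-Hochberg over the tested genes.  A gene is called up/down
    when ``|logFC| > lfc_min`` and ``FDR < fdr_max`` (strict, as in the
    screening convention this mirrors).
    """
    tum = lnc_expr.cohort_samples(TUMOR)
    nor = lnc_expr.cohort_samples(NORMAL)
    if len(tum) < 2 or len(nor) < 2:
        raise ValueError(
            f"need >= 2 samples per cohort (tumor={len(tum)}, normal={len(nor)})")
    genes = list(genes) if genes is not None else lnc_expr.gene_ids
    missing = [g for g in genes if g not in set(lnc_expr.gene_ids)]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing[:5]}")
    T = lnc_expr.values.loc[genes, tum].to_numpy()
    N = lnc_expr.values.loc[genes, nor].to_numpy()

    logfc = np.log2((T.mean(axis=1) + eps) / (N.mean(axis=1) + eps))
    pvals = np.empty(len(genes))
    for i in range(len(genes)):
        if np.ptp(T[i]) == 0 and np.ptp(N[i]) == 0 and T[i, 0] == N[i, 0]:
            pvals[i] = 1.0
            continue
        pvals[i] = stats.mannwhitneyu(T[i], N[i], alternative="two-sided").pvalue
    fdr = multipletests(pvals, method="fdr_bh")[1]

    direction = np.where((logfc > lfc_min) & (fdr < fdr_max), "up",
                         np.where((logfc < -lfc_min) & (fdr < fdr_max), "down", "ns"))
    table = pd.DataFrame({"logFC": logfc, "p": pvals, "fdr": fdr,
                          "direction": direction}, index=pd.Index(genes, name="gene"))
    return DEResult(table)
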