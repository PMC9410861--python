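"""Coding genes correlated with signature lncRNAs, and gene-set enrichment.

The correlated-gene screen keeps protein-coding genes with |Pearson R| above
``r_min`` (default 0.6) at p < 0.05 against any signature lncRNA, on
log2(x+1) expression.  Enrichment of the pooled correlated set against a
GMT collection is an upper-tail hypergeometric overrepresentation test
with Benjamini-Hochberg correction across sets; the universe is the set of
measured coding genes, not the genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix
from .screen import _corr_with_p

log = logging.getLogger(__name__)


@dataclass
class CorrelatedGeneSet:
    """Coding genes passing the |R|/p screen, per lncRNA and pooled."""

    per_lnc: dict[str, pd.DataFrame]
    missing_lncs: list = field(default_factory=list)

    @property
    def pooled(self) -> list[str]:
        genes: set[str] = set()
        for tbl in self.per_lnc.values():
            genes.update(tbl.index)
        return sorted(genes)


def correlated_coding_genes(lnc_expr: ExpressionMatrix, mrna_expr: ExpressionMatrix,
                            signature_lncs, r_min: float = 0.6,
                            p_max: float = 0.05) -> CorrelatedGeneSet:
    """Coding genes with |R| > r_min and p < p_max against signature lncRNAs.

    Signature lncRNAs absent from the matrix are recorded as missing and
    the rest proceed.  Both thresholds are strict.
    """
    signature_lncs = list(signature_lncs)
    present = [g for g in signature_lncs if g in set(lnc_expr.gene_ids)]
    missing = [g for g in signature_lncs if g not in set(lnc_expr.gene_ids)]
    if missing:
        log.warning("signature lncRNAs missing from matrix: %s", missing[:5])
    if not present:
        raise ValueError("no signature lncRNA present in the expression matrix")
    shared = [s for s in lnc_expr.sample_ids if s in set(mrna_expr.sample_ids)]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples")
    L = lnc_expr.log2p1().loc[present, shared]
    M = mrna_expr.log2p1()[shared]
    r, p = _corr_with_p(L.to_numpy(), M.to_numpy())
    per_lnc = {}
    for i, lnc in enumerate(present):
        mask = (np.abs(r[i]) > r_min) & (p[i] < p_max) & ~np.isnan(r[i])
        per_lnc[lnc] = pd.DataFrame(
            {"R": r[i, mask], "p": p[i, mask]},
            index=pd.Index(M.index[mask], name="gene"))
    return CorrelatedGeneSet(per_lnc, missing)


def hypergeometric_enrichment(query, sets: dict[str, set], universe) -> pd.DataFrame:
    """Overrepresentation of `query` in each gene set by hypergeometric test.

    p = P(X >= k) with X ~ Hypergeometric(N = |universe|, K = |set|,
    n = |query|), all memberships intersected with the universe first.
    Returns a frame sorted by BH-adjusted q.
    """
    universe = set(universe)
    query = set(query) & universe
    if not query:
        raise ValueError("query is empty after intersecting with the universe")
    rows = []
    for name, members in sets.items():
        members = members & universe
        if not members:
            continue
        k = len(query & members)
        K, n, N = len(members), len(query), len(universe)
        # upper tail: P(X >= k) = sf(k - 1)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": name, "overlap": k, "set_size": K,
                     "query_size": n, "universe_size": N, "p": p})
    if not rows:
        raise ValueError("no gene set overlaps the universe")
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values("q", kind="mergesort").reset_index(drop=True)
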