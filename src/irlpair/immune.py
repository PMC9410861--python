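"""Immune-landscape association of the risk groups.

Consumes a deconvolved sample x cell-type fraction table (CIBERSORT-style;
deconvolution itself is out of scope) and an immune-checkpoint gene panel,
and reports rank-based associations with the risk score: within each
molecular subtype, cell-type fractions are compared between risk groups
(two-sided Wilcoxon rank-sum) and correlated with the continuous score
(Spearman), with Benjamini-Hochberg correction across cell types within a
subtype.  All outputs are invariant to monotone rescaling of the score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix
from .signature import RiskProfile

log = logging.getLogger(__name__)

#: Immunosuppression biomarkers reported alongside IRLP risk groups.
DEFAULT_CHECKPOINT_PANEL = ("LAG3", "CTLA4", "PDCD1", "PDCD1LG2")


def _spearman(x: np.ndarray, y: np.ndarray):
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _ranksum(a: np.ndarray, b: np.ndarray) -> float:
    if np.array_equal(np.sort(a), np.sort(b)):
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def tiic_group_comparison(fractions: pd.DataFrame, risk: RiskProfile,
                          strata: pd.Series | None = None,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Per-(subtype, cell type) association of infiltration with risk.

    Returns a long frame with the Wilcoxon p (high vs low group), the
    Spearman rho/p against the continuous score, and BH-adjusted q-values
    per stratum.  Strata with an empty risk group are skipped with a
    warning, never silently dropped from the log.
    """
    groups = risk.groups
    shared = [s for s in fractions.index if s in groups.index]
    fr = fractions.loc[shared]
    groups = groups.loc[shared]
    scores = risk.scores.loc[shared]

    layers: dict[str, pd.Index] = {"all": fr.index}
    if strata is not None:
        for label in pd.unique(strata.loc[shared].dropna()):
            layers[str(label)] = fr.index[strata.loc[shared] == label]

    rows = []
    for name, idx in layers.items():
        g = groups.loc[idx]
        lo, hi = idx[g == "low"], idx[g == "high"]
        if len(lo) < 2 or len(hi) < 2:
            log.warning("stratum %r lacks >= 2 samples per risk group; skipped", name)
            continue
        stratum_rows = []
        for cell in fr.columns:
            p_rs = _ranksum(fr.loc[lo, cell].to_numpy(), fr.loc[hi, cell].to_numpy())
            rho, p_rho = _spearman(scores.loc[idx].to_numpy(),
                                   fr.loc[idx, cell].to_numpy())
            direction = "higher_in_high" if fr.loc[hi, cell].median() > fr.loc[lo, cell].median() \
                else "higher_in_low"
            stratum_rows.append({"stratum": name, "cell_type": cell,
                                 "wilcoxon_p": p_rs, "spearman_rho": rho,
                                 "spearman_p": p_rho, "direction": direction})
        q = multipletests([r["wilcoxon_p"] for r in stratum_rows], method="fdr_bh")[1]
        for r, qv in zip(stratum_rows, q):
            r["q"] = float(qv)
            r["significant"] = qv < alpha
        rows.extend(stratum_rows)
    return pd.DataFrame(rows)


@dataclass
class CheckpointReport:
    table: pd.DataFrame
    missing: list

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def checkpoint_correlation(mrna_expr: ExpressionMatrix, risk: RiskProfile,
                           panel=DEFAULT_CHECKPOINT_PANEL) -> CheckpointReport:
    """Spearman correlation of checkpoint-gene expression with the risk score.

    Expression enters as log2(x+1).  Also reports the high-vs-low rank-sum
    p per gene.  Panel genes absent from the matrix are listed as missing;
    the rest proceed.
    """
    panel = list(panel)
    if not panel:
        raise ValueError("empty checkpoint panel")
    shared = [s for s in risk.scores.index if s in set(mrna_expr.sample_ids)]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples")
    expr = mrna_expr.log2p1()[shared]
    scores = risk.scores.loc[shared]
    have_groups = risk.cutoff is not None
    groups = risk.groups.loc[shared] if have_groups else None

    missing = [g for g in panel if g not in expr.index]
    if missing:
        log.warning("checkpoint genes missing from matrix: %s", missing)
    rows = []
    for gene in panel:
        if gene not in expr.index:
            continue
        x = expr.loc[gene].to_numpy()
        rho, p = _spearman(scores.to_numpy(), x)
        row = {"gene": gene, "spearman_rho": rho, "spearman_p": p}
        if have_groups:
            lo = x[(groups == "low").to_numpy()]
            hi = x[(groups == "high").to_numpy()]
            row["wilcoxon_p"] = _ranksum(lo, hi) if len(lo) and len(hi) else np.nan
        rows.append(row)
    return CheckpointReport(pd.DataFrame(rows), missing)
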