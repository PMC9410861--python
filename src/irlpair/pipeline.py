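"""End-to-end IRLP analysis: screens -> pairs -> signature -> evaluation.

`run_pipeline` wires the stages together on in-memory containers and is
what the CLI, the acceptance script and the recovery tests all call.  An
optional held-out fraction of tumor samples is excluded from every
model-fitting step (screens included among tumors used for pairing) and
used only to validate the risk score (C-index, held-out ROC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import TUMOR, ClinicalTable, ExpressionMatrix, ImmuneGeneSet
from .enrichment import correlated_coding_genes, hypergeometric_enrichment
from .immune import DEFAULT_CHECKPOINT_PANEL, checkpoint_correlation, tiic_group_comparison
from .pairs import build_pair_matrix, skew_filter, split_pair_label, PairIndicatorMatrix
from .screen import coexpression_screen, differential_expression
from .signature import IRLPSignature, RiskProfile
from .survival import (
    clinical_cox,
    concordance,
    group_vs_clinical_tests,
    km_logrank,
    time_dependent_roc,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything one pipeline run produces; numbers, not figures."""

    coexpression: object = None
    de: object = None
    pair_matrix: PairIndicatorMatrix | None = None
    n_candidate_pairs: int = 0
    signature: IRLPSignature | None = None
    risk: RiskProfile | None = None            # all tumors, cutoff set
    cutoff: float = float("nan")
    roc: dict = field(default_factory=dict)    # horizon -> TimeROC (training)
    cindex_train: float = float("nan")
    test_samples: list = field(default_factory=list)
    cindex_test: float = float("nan")
    roc_test: dict = field(default_factory=dict)
    km: object = None
    clinical_tests: pd.DataFrame | None = None
    clinical_cox: object = None
    tiic: pd.DataFrame | None = None
    checkpoints: object = None
    enrichment: pd.DataFrame | None = None

    @property
    def signature_genes(self) -> list[str]:
        genes: set[str] = set()
        for label in self.signature.selected_pairs_:
            genes.update(split_pair_label(label))
        return sorted(genes)


def _split_tumors(clin: ClinicalTable, tumor_samples, test_fraction, seed):
    """Event-stratified held-out split of the eligible tumor samples."""
    elig = clin.eligible()
    usable = [s for s in tumor_samples if s in elig.index]
    if test_fraction <= 0:
        return usable, []
    rng = np.random.default_rng(seed)
    test = []
    for ev in (0, 1):
        grp = [s for s in usable if elig.loc[s, "event"] == ev]
        grp = list(np.array(grp)[rng.permutation(len(grp))])
        test.extend(grp[: int(round(test_fraction * len(grp)))])
    test = set(test)
    return [s for s in usable if s not in test], sorted(test)


def run_pipeline(lnc_expr: ExpressionMatrix, mrna_expr: ExpressionMatrix,
                 clinical: ClinicalTable, immune_genes: ImmuneGeneSet, *,
                 fractions: pd.DataFrame | None = None,
                 gene_sets: dict | None = None,
                 checkpoint_panel=DEFAULT_CHECKPOINT_PANEL,
                 r_min: float = 0.4, coexpr_p_max: float = 0.001,
                 lfc_min: float = 1.5, fdr_max: float = 0.5,
                 q_min: float = 0.2, unicox_p_max: float = 0.05,
                 n_folds: int = 10, lambda_rule: str = "min",
                 roc_horizons=(1.0, 3.0, 5.0), cutoff_horizon: float = 5.0,
                 test_fraction: float = 0.0, seed: int | None = None) -> PipelineResult:
    """Run the whole IRLP analysis; returns a populated PipelineResult.

    With ``test_fraction > 0`` the pair matrix, the signature and the
    cutoff are learned on the training tumors only; the held-out tumors
    contribute the ``cindex_test`` / ``roc_test`` entries.
    """
    res = PipelineResult()

    res.coexpression = coexpression_screen(lnc_expr, mrna_expr, immune_genes,
                                           r_min=r_min, p_max=coexpr_p_max)
    immune_lncs = res.coexpression.immune_lncrnas
    if not immune_lncs:
        raise ValueError("coexpression screen flagged no immune-related lncRNA")
    res.de = differential_expression(lnc_expr, genes=immune_lncs,
                                     lfc_min=lfc_min, fdr_max=fdr_max)
    de_genes = res.de.de_genes
    if len(de_genes) < 2:
        raise ValueError(f"only {len(de_genes)} DEirlncRNAs; need >= 2 to pair")

    tumors = lnc_expr.cohort_samples(TUMOR)
    train, test = _split_tumors(clinical, tumors, test_fraction, seed)
    res.test_samples = test

    expr_train = lnc_expr.subset_samples(train)
    pm_all = build_pair_matrix(expr_train, de_genes)
    res.n_candidate_pairs = len(pm_all.indicator)
    pm = skew_filter(pm_all, q_min=q_min)
    if len(pm.indicator) == 0:
        raise ValueError("skew filter removed every candidate pair")
    res.pair_matrix = pm

    X_train = pm.to_feature_frame()
    elig = clinical.eligible()
    y_train = elig.loc[X_train.index, ["time", "event"]]
    est = IRLPSignature(p_max=unicox_p_max, n_folds=n_folds,
                        lambda_rule=lambda_rule, random_state=seed)
    est.fit(X_train, y_train)
    res.signature = est

    # score every tumor (train + held-out) on the retained pairs
    tumor_expr = lnc_expr.subset_samples([s for s in tumors])
    pm_tumor = build_pair_matrix(tumor_expr, de_genes)
    X_all = pm_tumor.to_feature_frame()
    scores = pd.Series(est.predict(X_all), index=X_all.index, name="risk_score")

    risk_train = RiskProfile(scores.loc[train])
    for h in roc_horizons:
        res.roc[h] = time_dependent_roc(risk_train, clinical, h)
    res.cutoff = res.roc[cutoff_horizon].cutoff if cutoff_horizon in res.roc \
        else time_dependent_roc(risk_train, clinical, cutoff_horizon).cutoff
    res.risk = RiskProfile(scores, res.cutoff)
    res.cindex_train = concordance(risk_train, clinical)

    if test:
        risk_test = RiskProfile(scores.loc[test])
        res.cindex_test = concordance(risk_test, clinical)
        for h in roc_horizons:
            try:
                res.roc_test[h] = time_dependent_roc(risk_test, clinical, h)
            except ValueError as exc:
                log.warning("held-out ROC at %g years unavailable: %s", h, exc)

    strata = clinical.frame["subtype"] if "subtype" in clinical.frame.columns else None
    res.km = km_logrank(res.risk, clinical, strata=strata)
    res.clinical_tests = group_vs_clinical_tests(res.risk, clinical)
    res.clinical_cox = clinical_cox(res.risk, clinical)

    if fractions is not None:
        res.tiic = tiic_group_comparison(fractions, res.risk, strata=strata)
    panel_present = [g for g in (checkpoint_panel or ())
                     if g in set(mrna_expr.gene_ids)]
    if panel_present:
        res.checkpoints = checkpoint_correlation(mrna_expr, res.risk,
                                                 panel=panel_present)
    elif checkpoint_panel:
        log.info("no checkpoint-panel gene in the matrix; step skipped")

    if gene_sets is not None:
        corr = correlated_coding_genes(lnc_expr, mrna_expr, res.signature_genes)
        if corr.pooled:
            res.enrichment = hypergeometric_enrichment(
                corr.pooled, gene_sets, universe=mrna_expr.gene_ids)
        else:
            log.warning("no coding gene passed the correlation screen; "
                        "enrichment skipped")
    return res


def true_pair_recovery(result: PipelineResult, truth) -> float:
    """Fraction of ground-truth pairs present in the final signature."""
    if not truth.true_pairs:
        return float("nan")
    selected = set(result.signature.selected_pairs_)
    return sum(l in selected for l in truth.true_pair_labels) / len(truth.true_pairs)
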