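"""Survival evaluation of the risk score.

Time-dependent ROC at a horizon t uses the cumulative-case / dynamic-control
definition: cases are samples with an observed event by t, controls are
samples still under observation past t, and samples censored at or before t
are excluded.  The AUC is the Mann-Whitney probability
P(score_case > score_control) with ties counted 1/2, and the risk-group
cutoff is the threshold maximizing the Youden index TPR - FPR (ties broken
toward the lower threshold), conventionally on the 5-year curve.

Kaplan-Meier curves and two-group log-rank tests (overall and per molecular
subtype) and the clinical uni-/multivariate Cox reports are delegated to
lifelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from sksurv.metrics import concordance_index_censored

from .containers import ClinicalTable
from .signature import RiskProfile

log = logging.getLogger(__name__)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class TimeROC:
    """ROC at one horizon: curve points, AUC and the Youden-optimal cutoff."""

    horizon: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    cutoff: float
    n_cases: int
    n_controls: int

    def points(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "fpr": self.fpr, "tpr": self.tpr})


def _roc_case_control(clin: ClinicalTable, horizon: float, scores: pd.Series):
    tyears = clin.times_in_years()
    f = clin.eligible()
    shared = [s for s in scores.index if s in f.index]
    t = tyears.loc[shared].to_numpy()
    e = f.loc[shared, "event"].to_numpy(int)
    s = scores.loc[shared].to_numpy(float)
    case = (e == 1) & (t <= horizon)
    ctrl = t > horizon
    return s[case], s[ctrl]


def time_dependent_roc(risk: RiskProfile, clin: ClinicalTable,
                       horizon: float) -> TimeROC:
    """ROC of the risk score for events by `horizon` (in years).

    Raises if either the case or the control set is empty at the horizon.
    """
    cases, ctrls = _roc_case_control(clin, horizon, risk.scores)
    n1, n0 = len(cases), len(ctrls)
    if n1 == 0 or n0 == 0:
        raise ValueError(
            f"no {'cases' if n1 == 0 else 'controls'} at horizon {horizon} years")
    # Mann-Whitney AUC with midranks (ties 1/2)
    ranks = stats.rankdata(np.concatenate([cases, ctrls]))
    auc = (ranks[:n1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    # curve over thresholds: classify case iff score > c; -inf captures (1,1)
    thr = np.concatenate([[-np.inf], np.unique(np.concatenate([cases, ctrls]))])
    tpr = np.array([(cases > c).mean() for c in thr])
    fpr = np.array([(ctrls > c).mean() for c in thr])
    youden = tpr - fpr
    best = np.max(youden)
    cutoff = thr[np.nonzero(youden >= best - 1e-12)[0][0]]  # lowest maximizer
    order = np.argsort(fpr, kind="mergesort")
    return TimeROC(horizon, fpr[order], tpr[order], thr[order], float(auc),
                   float(cutoff), n1, n0)


def youden_cutoff(risk: RiskProfile, clin: ClinicalTable,
                  horizon: float = 5.0) -> float:
    """The risk-group cutoff: Youden-optimal threshold of the horizon-year ROC."""
    return time_dependent_roc(risk, clin, horizon).cutoff


@dataclass
class KMComparison:
    """Two-group KM curves and log-rank tests, overall or per stratum."""

    strata: dict = field(default_factory=dict)
    # strata[name] = {"chisq", "p", "n": {group: int}, "curves": {group: DataFrame}}

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, res in self.strata.items():
            row = {"stratum": name, "chisq": res["chisq"], "p": res["p"]}
            row.update({f"n_{g}": n for g, n in res["n"].items()})
            rows.append(row)
        return pd.DataFrame(rows)


def _km_curve(time, event) -> pd.DataFrame:
    km = KaplanMeierFitter()
    km.fit(time, event)
    tbl = km.event_table
    return pd.DataFrame({
        "time": km.survival_function_.index.to_numpy(),
        "survival": km.survival_function_.iloc[:, 0].to_numpy(),
        "at_risk": tbl["at_risk"].reindex(km.survival_function_.index).to_numpy(),
    })


def km_logrank(risk: RiskProfile, clin: ClinicalTable, cutoff: float | None = None,
               strata: pd.Series | None = None) -> KMComparison:
    """Kaplan-Meier + log-rank between risk groups, overall and per stratum.

    `strata` is an optional per-sample label series (e.g. molecular
    subtype); each stratum is analyzed independently and strata where one
    group is empty are skipped with a warning.
    """
    prof = risk if cutoff is None else risk.with_cutoff(cutoff)
    groups = prof.groups
    f = clin.eligible()
    shared = [s for s in groups.index if s in f.index]
    f = f.loc[shared]
    groups = groups.loc[shared]

    layers: dict[str, pd.Index] = {"all": f.index}
    if strata is not None:
        for label in pd.unique(strata.loc[shared].dropna()):
            layers[str(label)] = f.index[strata.loc[shared] == label]

    out = KMComparison()
    for name, idx in layers.items():
        g = groups.loc[idx]
        lo, hi = idx[g == "low"], idx[g == "high"]
        if len(lo) == 0 or len(hi) == 0:
            log.warning("stratum %r has an empty risk group; skipped", name)
            continue
        res = logrank_test(f.loc[lo, "time"], f.loc[hi, "time"],
                           f.loc[lo, "event"], f.loc[hi, "event"])
        out.strata[name] = {
            "chisq": float(res.test_statistic),
            "p": float(res.p_value),
            "n": {"low": len(lo), "high": len(hi)},
            "curves": {
                "low": _km_curve(f.loc[lo, "time"], f.loc[lo, "event"]),
                "high": _km_curve(f.loc[hi, "time"], f.loc[hi, "event"]),
            },
        }
    return out


DEFAULT_CLINICAL_VARIABLES = ("event", "age", "sex", "t_stage", "n_stage",
                              "m_stage", "stage", "subtype")


def group_vs_clinical_tests(risk: RiskProfile, clin: ClinicalTable,
                            variables=None, age_cut: float = 65.0) -> pd.DataFrame:
    """Rank tests of the risk score across clinical-variable levels.

    Two levels -> two-sided Wilcoxon rank-sum; more than two levels ->
    Kruskal-Wallis.  Age is dichotomized at `age_cut` years.  Degenerate
    variables (fewer than two levels with >= 2 samples) are skipped with a
    warning.  Stars follow the <0.001/<0.01/<0.05 convention.
    """
    f = clin.eligible()
    shared = [s for s in risk.scores.index if s in f.index]
    f = f.loc[shared]
    scores = risk.scores.loc[shared]
    if variables is None:
        variables = [v for v in DEFAULT_CLINICAL_VARIABLES if v in f.columns]
    rows = []
    for var in variables:
        vals = f[var]
        if var == "age":
            vals = pd.Series(np.where(vals >= age_cut, f">={age_cut:g}",
                                      f"<{age_cut:g}"), index=vals.index)
        vals = vals.dropna()
        counts = vals.value_counts()
        levels = counts.index[counts >= 2]
        if len(levels) < 2:
            log.warning("clinical variable %r degenerate; skipped", var)
            continue
        grouped = [scores.loc[vals.index[vals == l]].to_numpy() for l in levels]
        if len(levels) == 2:
            if np.array_equal(np.sort(grouped[0]), np.sort(grouped[1])):
                p = 1.0  # identical score distributions
            else:
                p = float(stats.mannwhitneyu(grouped[0], grouped[1],
                                             alternative="two-sided").pvalue)
            test = "wilcoxon_rank_sum"
        else:
            p = float(stats.kruskal(*grouped).pvalue)
            test = "kruskal_wallis"
        rows.append({"variable": var, "test": test, "n_levels": len(levels),
                     "p": p, "stars": significance_stars(p)})
    return pd.DataFrame(rows)


@dataclass
class ClinicalCoxReport:
    """Uni- and multivariate Cox tables over risk score + clinical covariates."""

    univariate: pd.DataFrame
    multivariate: pd.DataFrame
    dropped: list = field(default_factory=list)


_STAGE_ORDER = {"I": 1, "II": 2, "III": 3, "IV": 4,
                "T1": 1, "T2": 2, "T3": 3, "T4": 4,
                "N0": 0, "N1": 1, "N2": 2, "N3": 3,
                "M0": 0, "M1": 1}


def _code_covariate(vals: pd.Series) -> pd.Series:
    """Ordinal-code a clinical covariate: numerics pass through, stage-like
    labels map to their order, other categories factorize by sorted level."""
    if np.issubdtype(vals.dtype, np.number):
        return vals.astype(float)
    s = vals.astype(str)
    if set(s.dropna()) <= set(_STAGE_ORDER):
        return s.map(_STAGE_ORDER).astype(float)
    cats = sorted(s.dropna().unique())
    return s.map({c: i for i, c in enumerate(cats)}).astype(float)


def clinical_cox(risk: RiskProfile, clin: ClinicalTable,
                 covariates=("age", "n_stage", "t_stage", "stage")) -> ClinicalCoxReport:
    """Cox reports testing the risk score against clinical covariates.

    One univariate fit per covariate (risk score first) and one joint
    multivariate fit.  Covariates exactly collinear with earlier-listed
    ones are dropped from the joint model with a warning.
    """
    f = clin.eligible()
    shared = [s for s in risk.scores.index if s in f.index]
    f = f.loc[shared]
    design = pd.DataFrame({"risk_score": risk.scores.loc[shared]})
    for c in covariates:
        if c not in f.columns:
            log.warning("covariate %r absent from clinical table; skipped", c)
            continue
        design[c] = _code_covariate(f[c])
    design = design.dropna()
    f = f.loc[design.index]
    n_events = int(f["event"].sum())
    if n_events < 10 * design.shape[1]:
        log.warning("only %d events for %d covariates (< 10 per covariate)",
                    n_events, design.shape[1])

    def _fit(cols):
        df = design[cols].copy()
        df["_time"], df["_event"] = f["time"], f["event"]
        cph = CoxPHFitter()
        cph.fit(df, duration_col="_time", event_col="_event")
        s = cph.summary
        return pd.DataFrame({"hr": s["exp(coef)"],
                             "hr_lower": s["exp(coef) lower 95%"],
                             "hr_upper": s["exp(coef) upper 95%"],
                             "p": s["p"]})

    uni = pd.concat([_fit([c]) for c in design.columns])

    kept, dropped = [], []
    M = np.empty((len(design), 0))
    for c in design.columns:
        v = design[c].to_numpy(float)[:, None]
        cand = np.hstack([M, v])
        if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(M):
            M, kept = cand, kept + [c]
        else:
            dropped.append(c)
    if dropped:
        log.warning("dropped collinear covariates from joint model: %s", dropped)
    multi = _fit(kept)
    return ClinicalCoxReport(uni, multi, dropped)


def concordance(risk: RiskProfile, clin: ClinicalTable) -> float:
    """Harrell's C-index of the risk score on the eligible samples.

    A constant score has no discrimination and returns 0.5.
    """
    f = clin.eligible()
    shared = [s for s in risk.scores.index if s in f.index]
    s = risk.scores.loc[shared].to_numpy(float)
    if np.ptp(s) == 0:
        return 0.5
    c = concordance_index_censored(f.loc[shared, "event"].astype(bool),
                                   f.loc[shared, "time"].astype(float), s)
    return float(c[0])
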