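"""Prognostic pair selection and the IRLP risk score.

Three nested stages turn the candidate pair-indicator matrix into a
signature:

1. univariate Cox screen — one Efron partial-likelihood fit per pair,
   keep Wald p < 0.05;
2. L1-penalized (lasso) Cox over the survivors with 10-fold
   cross-validation choosing the penalty that minimizes the held-out
   partial-likelihood deviance (glmnet's lambda.min rule);
3. bidirectional stepwise selection minimizing AIC over the multivariate
   Cox model, starting from the lasso-selected set; final coefficients
   come from the refitted multivariate model.

The risk score of a sample is the linear predictor sum_i beta_i * S_i over
the selected pair indicators.  `IRLPSignature` packages the three stages
as a scikit-learn estimator (fit / predict / score); the module-level
functions expose each stage on the pipeline's own containers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.metrics import concordance_index_censored
from sksurv.util import Surv

from . import cox
from .containers import ClinicalTable, survival_arrays
from .pairs import PairIndicatorMatrix

log = logging.getLogger(__name__)


class EmptySignatureError(RuntimeError):
    """Raised when no pair survives selection: the signature cannot be built."""


def as_survival(y):
    """Coerce y to (time: float array, event: bool array).

    Accepts a sksurv structured array, a (time, event) tuple, or a
    DataFrame with ``time``/``event`` columns.
    """
    if isinstance(y, np.ndarray) and y.dtype.names:
        names = {n.lower(): n for n in y.dtype.names}
        tname = next(n for k, n in names.items() if "time" in k or k in ("t", "futime"))
        ename = next(n for k, n in names.items()
                     if "event" in k or "status" in k or "cens" in k or k == "e")
        return y[tname].astype(float), y[ename].astype(bool)
    if isinstance(y, pd.DataFrame):
        return y["time"].to_numpy(float), y["event"].to_numpy(bool)
    time, event = y
    return np.asarray(time, float), np.asarray(event, bool)


def _drop_collinear(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop later-listed columns identical (or complementary) to earlier ones.

    For binary indicators, S and 1-S carry the same information in a Cox
    linear predictor, so complements count as collinear too.
    """
    seen: dict[bytes, str] = {}
    keep, dropped = [], []
    for c in X.columns:
        v = X[c].to_numpy()
        key, ckey = v.tobytes(), (1 - v).tobytes() if v.max() <= 1 else None
        if key in seen or (ckey is not None and ckey in seen):
            dropped.append(c)
        else:
            seen[key] = c
            keep.append(c)
    if dropped:
        log.warning("dropped %d collinear covariates: %s", len(dropped), dropped[:5])
    return X[keep], dropped


def _fit_multicox(X: pd.DataFrame, time, event):
    """lifelines multivariate fit; returns (fitter, AIC) or (None, inf)."""
    df = X.copy()
    df["_time"], df["_event"] = time, event.astype(int)
    try:
        cph = CoxPHFitter()
        cph.fit(df, duration_col="_time", event_col="_event")
        return cph, float(cph.AIC_partial_)
    except (ConvergenceError, np.linalg.LinAlgError, ValueError):
        return None, np.inf


def _null_partial_aic(time, event) -> float:
    """AIC of the covariate-free Cox model (log-likelihood at beta = 0)."""
    t_sorted, e_sorted, _ = cox._sorted_survival(time, event)
    groups = cox._event_groups(t_sorted, e_sorted)
    ll, _, _ = cox.efron_loglik_grad_hess(
        np.zeros(1), np.zeros((len(t_sorted), 1)), groups)
    return float(-2.0 * ll[0])


def lasso_path_cv(X: pd.DataFrame, time, event, n_folds: int = 10,
                  seed=None, lambda_rule: str = "min"):
    """Cross-validated lasso-Cox path; returns (alpha, nonzero columns, cv table).

    The path is fit with the coordinate-descent elastic-net solver
    (scikit-survival's glmnet port, pure L1 here); each fold's deviance is
    scored as -2 * (loglik_all(beta) - loglik_train(beta)) with Breslow
    ties, the cross-validation scheme glmnet uses for Cox models.  Folds
    are stratified by event status and deterministic given ``seed``.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    if event.sum() < n_folds:
        raise ValueError(f"need >= {n_folds} events for {n_folds}-fold CV")
    if X.shape[1] < 2:
        raise ValueError("need >= 2 candidate pairs for the lasso stage")
    y = Surv.from_arrays(event=event, time=time)
    base = CoxnetSurvivalAnalysis(l1_ratio=1.0, alpha_min_ratio=0.01, n_alphas=60)
    base.fit(X.to_numpy(), y)
    alphas = base.alphas_

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    dev = np.full((n_folds, len(alphas)), np.nan)
    Xa = X.to_numpy()
    for k, (tr, _) in enumerate(skf.split(Xa, event.astype(int))):
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas)
        m.fit(Xa[tr], y[tr])
        n_fit = m.coef_.shape[1]  # the solver may truncate the path
        for a, alpha in enumerate(alphas):
            beta = m.coef_[:, min(a, n_fit - 1)]
            ll_all = cox.breslow_loglik(beta, Xa, time, event)
            ll_tr = cox.breslow_loglik(beta, Xa[tr], time[tr], event[tr])
            dev[k, a] = -2.0 * (ll_all - ll_tr)
    mean_dev = dev.mean(axis=0)
    se_dev = dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
    i_min = int(np.argmin(mean_dev))
    if lambda_rule == "min":
        i_sel = i_min
    elif lambda_rule == "1se":
        within = mean_dev <= mean_dev[i_min] + se_dev[i_min]
        i_sel = int(np.nonzero(within)[0][0])  # alphas descend: first = largest
    else:
        raise ValueError(f"unknown lambda rule {lambda_rule!r}")
    nnz_per_alpha = (base.coef_ != 0).sum(axis=0)
    selected = list(X.columns[base.coef_[:, i_sel] != 0])
    if not selected:
        with_nz = np.nonzero(nnz_per_alpha > 0)[0]
        if len(with_nz) == 0:
            raise EmptySignatureError("lasso path has no nonzero coefficients")
        i_sel = int(with_nz[0])  # strongest penalty with a nonempty active set
        selected = list(X.columns[base.coef_[:, i_sel] != 0])
        log.warning("empty active set at lambda_min; fell back to alpha=%g",
                    alphas[i_sel])
    cv_table = pd.DataFrame({"alpha": alphas, "mean_deviance": mean_dev,
                             "se_deviance": se_dev,
                             "n_nonzero": nnz_per_alpha})
    return float(alphas[i_sel]), selected, cv_table


def stepwise_aic(X: pd.DataFrame, time, event, tol: float = 1e-6):
    """Bidirectional stepwise AIC minimization starting from the full set.

    Returns the final fitted lifelines model and the retained columns.
    An empty final model raises EmptySignatureError.
    """
    X, _ = _drop_collinear(X)
    current = list(X.columns)
    cph, aic = _fit_multicox(X[current], time, event)
    if cph is None:
        # full model unfittable: try dropping covariates greedily from scratch
        aic = np.inf
    null_aic = _null_partial_aic(time, event)
    all_cols = list(X.columns)
    while True:
        moves = []
        for c in current:
            reduced = [x for x in current if x != c]
            if reduced:
                m, a = _fit_multicox(X[reduced], time, event)
            else:
                m, a = None, null_aic
            moves.append((a, "drop", c, m, reduced))
        for c in all_cols:
            if c not in current:
                m, a = _fit_multicox(X[current + [c]], time, event)
                moves.append((a, "add", c, m, current + [c]))
        if not moves:
            break
        best = min(moves, key=lambda t: t[0])
        if best[0] < aic - tol:
            aic, _, _, cph, current = best
            if not current:
                raise EmptySignatureError(
                    "stepwise selection emptied the model; signature cannot be established")
        else:
            break
    if not current or cph is None:
        raise EmptySignatureError(
            "no multivariate Cox model could be fit; signature cannot be established")
    return cph, current


class IRLPSignature(BaseEstimator):
    """Immune-related lncRNA-pair prognostic signature (uni-Cox -> lasso -> stepwise).

    A scikit-learn style survival estimator over a binary pair-indicator
    feature matrix.  ``fit`` expects samples x pairs (0/1) and a survival
    outcome (sksurv structured array, ``(time, event)`` tuple, or a
    DataFrame with ``time``/``event``); ``predict`` returns the risk score
    sum_i beta_i * S_i.

    Parameters
    ----------
    p_max : float, default=0.05
        Wald-p threshold of the univariate screen.
    n_folds : int, default=10
        Cross-validation folds of the lasso stage, stratified by event.
    lambda_rule : {"min", "1se"}, default="min"
        Penalty choice on the CV deviance curve.
    stepwise : bool, default=True
        Run the bidirectional AIC stage; otherwise the lasso set is refit
        directly.
    random_state : int or None
        Seeds the CV fold assignment.

    Attributes
    ----------
    unicox_ : DataFrame of per-pair univariate fits (beta, HR, CI, Wald p).
    alpha_ : chosen lasso penalty (None when the lasso stage was skipped).
    cv_deviance_ : per-alpha cross-validated deviance table.
    selected_pairs_ : final pair labels, in signature order.
    coef_ : Series of final multivariate Cox coefficients.
    summary_ : final-model table (beta, HR, 95% CI, p).
    provenance_ : dict with the surviving pairs of every stage.
    """

    def __init__(self, p_max: float = 0.05, n_folds: int = 10,
                 lambda_rule: str = "min", stepwise: bool = True,
                 random_state=None, min_events: int = 10):
        self.p_max = p_max
        self.n_folds = n_folds
        self.lambda_rule = lambda_rule
        self.stepwise = stepwise
        self.random_state = random_state
        self.min_events = min_events

    def fit(self, X: pd.DataFrame, y) -> "IRLPSignature":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(X)
        time, event = as_survival(y)
        if len(time) != len(X):
            raise ValueError("X and y disagree on sample count")
        if event.sum() < self.min_events:
            raise ValueError(
                f"only {int(event.sum())} events; need >= {self.min_events}")

        uni = cox.fit_univariate_many(X, time, event)
        self.unicox_ = uni
        survivors = list(uni.index[(uni["p"] < self.p_max) & uni["converged"]])
        if not survivors:
            raise EmptySignatureError("no pair passed the univariate Cox screen")

        if len(survivors) >= 2:
            self.alpha_, lasso_sel, self.cv_deviance_ = lasso_path_cv(
                X[survivors], time, event, n_folds=self.n_folds,
                seed=self.random_state, lambda_rule=self.lambda_rule)
        else:
            self.alpha_, lasso_sel, self.cv_deviance_ = None, list(survivors), None
            log.info("single uni-Cox survivor; lasso stage skipped")

        if self.stepwise:
            cph, final = stepwise_aic(X[lasso_sel], time, event)
        else:
            Xd, _ = _drop_collinear(X[lasso_sel])
            cph, aic = _fit_multicox(Xd, time, event)
            if cph is None:
                raise EmptySignatureError("multivariate refit failed to converge")
            final = list(Xd.columns)

        self.model_ = cph
        self.selected_pairs_ = final
        self.coef_ = cph.params_.loc[final].rename("beta")
        s = cph.summary
        self.summary_ = pd.DataFrame({
            "beta": s["coef"], "hr": s["exp(coef)"],
            "hr_lower": s["exp(coef) lower 95%"],
            "hr_upper": s["exp(coef) upper 95%"], "p": s["p"],
        }).loc[final]
        self.provenance_ = {"unicox": survivors, "lasso": lasso_sel,
                            "stepwise": final}
        return self

    def predict(self, X) -> np.ndarray:
        """Risk score per sample: sum of beta_i * S_i over signature pairs."""
        check_is_fitted(self, "coef_")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(X)
        missing = [p for p in self.selected_pairs_ if p not in X.columns]
        if missing:
            raise ValueError(f"pair features missing from X: {missing[:5]}")
        return X[self.selected_pairs_].to_numpy(float) @ self.coef_.to_numpy()

    def score(self, X, y) -> float:
        """Harrell's concordance index of the risk score (higher is better)."""
        time, event = as_survival(y)
        return float(concordance_index_censored(event, time, self.predict(X))[0])

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "coef_")
        return {
            "format": "irlpair-signature",
            "version": 1,
            "pairs": list(self.selected_pairs_),
            "beta": {k: float(v) for k, v in self.coef_.items()},
            "lasso_alpha": self.alpha_,
            "random_state": self.random_state,
            "thresholds": {"unicox_p_max": self.p_max,
                           "lambda_rule": self.lambda_rule},
            "provenance": self.provenance_,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


@dataclass
class RiskProfile:
    """Per-sample risk scores, optionally dichotomized at a cutoff."""

    scores: pd.Series
    cutoff: float | None = None

    @property
    def groups(self) -> pd.Series:
        """'high' iff score > cutoff (strict), else 'low'."""
        if self.cutoff is None:
            raise ValueError("no cutoff set on this risk profile")
        return pd.Series(np.where(self.scores > self.cutoff, "high", "low"),
                         index=self.scores.index, name="risk_group")

    def with_cutoff(self, cutoff: float) -> "RiskProfile":
        return RiskProfile(self.scores, float(cutoff))

    def write(self, path) -> None:
        out = self.scores.to_frame("risk_score")
        if self.cutoff is not None:
            out["risk_group"] = self.groups
        out.to_csv(path, sep="\t", index_label="sample")


# -- thin functional wrappers on the pipeline containers ---------------------

def _aligned(pm: PairIndicatorMatrix, clin: ClinicalTable):
    X = pm.to_feature_frame()
    time, event, samples = survival_arrays(clin, X.index)
    return X.loc[samples], time, event


def unicox_screen(pm: PairIndicatorMatrix, clin: ClinicalTable,
                  p_max: float = 0.05) -> pd.DataFrame:
    """Univariate Cox over every pair; returns the full table with a
    ``selected`` column marking Wald p < p_max."""
    X, time, event = _aligned(pm, clin)
    if event.sum() < 10:
        raise ValueError(f"only {int(event.sum())} events; need >= 10")
    res = cox.fit_univariate_many(X, time, event)
    res["selected"] = (res["p"] < p_max) & res["converged"]
    return res


def lasso_cox_select(pm: PairIndicatorMatrix, clin: ClinicalTable,
                     candidates, n_folds: int = 10, seed=None,
                     lambda_rule: str = "min"):
    """Lasso-Cox with CV over the uni-Cox survivors; returns (pairs, alpha)."""
    X, time, event = _aligned(pm, clin)
    alpha, selected, _ = lasso_path_cv(X[list(candidates)], time, event,
                                       n_folds=n_folds, seed=seed,
                                       lambda_rule=lambda_rule)
    return selected, alpha


def stepwise_multicox(pm: PairIndicatorMatrix, clin: ClinicalTable,
                      candidates) -> IRLPSignature:
    """AIC-stepwise multivariate refit of the lasso-selected pairs.

    Returns a fitted IRLPSignature carrying the final pairs/coefficients
    (the earlier stages' provenance lists just the given candidates).
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate pairs given")
    X, time, event = _aligned(pm, clin)
    cph, final = stepwise_aic(X[candidates], time, event)
    est = IRLPSignature()
    est.model_ = cph
    est.alpha_ = None
    est.cv_deviance_ = None
    est.unicox_ = None
    est.selected_pairs_ = final
    est.coef_ = cph.params_.loc[final].rename("beta")
    s = cph.summary
    est.summary_ = pd.DataFrame({
        "beta": s["coef"], "hr": s["exp(coef)"],
        "hr_lower": s["exp(coef) lower 95%"],
        "hr_upper": s["exp(coef) upper 95%"], "p": s["p"],
    }).loc[final]
    est.provenance_ = {"unicox": candidates, "lasso": candidates,
                       "stepwise": final}
    return est


def risk_score(model: IRLPSignature, pm: PairIndicatorMatrix) -> RiskProfile:
    """Score every sample of the pair matrix with a fitted signature."""
    X = pm.to_feature_frame()
    return RiskProfile(pd.Series(model.predict(X), index=X.index,
                                 name="risk_score"))
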