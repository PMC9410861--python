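import itertools

import numpy as np
import pandas as pd
import pytest

from irlpair import IRLPSignature
from irlpair.signature import (
    EmptySignatureError,
    RiskProfile,
    _fit_multicox,
    _null_partial_aic,
    as_survival,
    lasso_path_cv,
    stepwise_aic,
)


def _simulate(rng, betas, n, censor=0.2):
    """Binary covariates + exponential PH survival with the given betas."""
    X = pd.DataFrame(rng.integers(0, 2, size=(n, len(betas))).astype(float),
                     columns=[f"P{i}|Q{i}" for i in range(len(betas))])
    eta = X.to_numpy() @ np.asarray(betas)
    t = rng.exponential(1.0 / np.exp(eta))
    c = rng.exponential(np.quantile(t, 1 - censor) * 3, size=n) if censor else np.full(n, np.inf)
    return X, np.minimum(t, c), (t <= c)


class TestLassoStage:
    def test_strong_pair_selected_among_noise(self, rng):
        betas = [1.0] + [0.0] * 9
        X, t, e = _simulate(rng, betas, 500)
        alpha, selected, cv = lasso_path_cv(X, t, e, n_folds=5, seed=0)
        assert "P0|Q0" in selected
        assert cv["mean_deviance"].notna().all()

    def test_null_pairs_rarely_selected(self):
        """Pure-noise pairs: L1 sparsity keeps the average selected
        fraction low across seeds."""
        fractions = []
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            X, t, e = _simulate(rng, [0.0] * 50, 500, censor=0.0)
            try:
                _, selected, _ = lasso_path_cv(X, t, e, n_folds=5, seed=seed)
            except EmptySignatureError:
                selected = []
            fractions.append(len(selected) / 50)
        assert np.mean(fractions) <= 0.10

    def test_too_few_candidates_is_error(self, rng):
        X, t, e = _simulate(rng, [0.5], 100)
        with pytest.raises(ValueError, match="candidate"):
            lasso_path_cv(X, t, e)

    def test_fold_assignment_deterministic_given_seed(self, rng):
        X, t, e = _simulate(rng, [0.8, 0.0, 0.3], 300)
        out1 = lasso_path_cv(X, t, e, n_folds=5, seed=7)
        out2 = lasso_path_cv(X, t, e, n_folds=5, seed=7)
        assert out1[0] == out2[0] and out1[1] == out2[1]


class TestStepwiseStage:
    def test_duplicated_covariate_collapses_to_one(self, rng):
        X, t, e = _simulate(rng, [0.9], 400)
        X["dup"] = X["P0|Q0"]
        cph, final = stepwise_aic(X, t, e)
        assert final == ["P0|Q0"]

    def test_complementary_indicator_is_collinear(self, rng):
        X, t, e = _simulate(rng, [0.9], 400)
        X["comp"] = 1.0 - X["P0|Q0"]
        _, final = stepwise_aic(X, t, e)
        assert final == ["P0|Q0"]

    def test_informative_covariates_all_retained_and_aic_optimal(self, rng):
        """Independent prognostic covariates: stepwise keeps all, and the
        full model beats every sub-model in an exhaustive AIC scan."""
        X, t, e = _simulate(rng, [0.8, 0.8, 0.8], 800, censor=0.0)
        cph, final = stepwise_aic(X, t, e)
        assert sorted(final) == sorted(X.columns)
        full_aic = float(cph.AIC_partial_)
        for k in range(3):
            for sub in itertools.combinations(X.columns, k):
                aic = (_null_partial_aic(t, e) if k == 0
                       else _fit_multicox(X[list(sub)], t, e)[1])
                assert full_aic < aic

    def test_noise_covariates_dropped(self, rng):
        X, t, e = _simulate(rng, [1.0, 0.0, 0.0], 500, censor=0.0)
        _, final = stepwise_aic(X, t, e)
        assert "P0|Q0" in final


class TestIRLPSignatureEstimator:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(5)
        X, t, e = _simulate(rng, [0.9, -0.9, 0.0, 0.0, 0.0, 0.0], 500)
        est = IRLPSignature(n_folds=5, random_state=0).fit(X, (t, e))
        return est, X, t, e

    def test_provenance_is_nested(self, fitted):
        est, *_ = fitted
        assert set(est.provenance_["stepwise"]) <= set(est.provenance_["lasso"])
        assert set(est.provenance_["lasso"]) <= set(est.provenance_["unicox"])
        assert est.selected_pairs_ == est.provenance_["stepwise"]

    def test_true_pairs_recovered_with_correct_signs(self, fitted):
        est, *_ = fitted
        assert "P0|Q0" in est.selected_pairs_ and "P1|Q1" in est.selected_pairs_
        assert est.coef_["P0|Q0"] > 0 > est.coef_["P1|Q1"]

    def test_predict_is_linear_score(self, fitted):
        est, X, _, _ = fitted
        scores = est.predict(X)
        manual = X[est.selected_pairs_].to_numpy() @ est.coef_.to_numpy()
        assert np.allclose(scores, manual)

    def test_score_is_concordance_above_half(self, fitted):
        est, X, t, e = fitted
        assert est.score(X, (t, e)) > 0.6

    def test_serialization_round_trip(self, fitted, tmp_path):
        import json
        est, *_ = fitted
        est.save(tmp_path / "sig.json")
        doc = json.loads((tmp_path / "sig.json").read_text())
        assert doc["pairs"] == est.selected_pairs_
        assert doc["beta"] == {k: pytest.approx(v) for k, v in est.coef_.items()}
        assert doc["version"] == 1

    def test_too_few_events_is_error(self, rng):
        X, t, _ = _simulate(rng, [0.5, 0.5], 30)
        with pytest.raises(ValueError, match="events"):
            IRLPSignature().fit(X, (t, np.zeros(30, dtype=bool)))

    def test_missing_pair_feature_on_predict(self, fitted):
        est, X, _, _ = fitted
        with pytest.raises(ValueError, match="missing"):
            est.predict(X.drop(columns=[est.selected_pairs_[0]]))


class TestRiskProfile:
    def test_score_arithmetic(self):
        beta = pd.Series({"a|b": 0.5, "c|d": -1.0})
        S = np.array([[1.0, 1.0], [0.0, 0.0]])
        scores = S @ beta.to_numpy()
        assert scores[0] == pytest.approx(-0.5)
        assert scores[1] == 0.0

    def test_additivity_over_disjoint_pair_sets(self, rng):
        S = pd.DataFrame(rng.integers(0, 2, size=(10, 4)).astype(float),
                         columns=list("abcd"))
        b1 = pd.Series({"a": 0.3, "b": -0.2})
        b2 = pd.Series({"c": 1.0, "d": 0.4})
        both = pd.concat([b1, b2])
        assert np.allclose(S[both.index] @ both,
                           S[b1.index] @ b1 + S[b2.index] @ b2)

    def test_grouping_strict_above_cutoff(self):
        prof = RiskProfile(pd.Series([0.1, 0.5, 0.9], index=list("xyz")), cutoff=0.5)
        assert list(prof.groups) == ["low", "low", "high"]
        with pytest.raises(ValueError):
            RiskProfile(pd.Series([1.0], index=["x"])).groups


def test_as_survival_accepts_common_shapes():
    from sksurv.util import Surv
    t = np.array([1.0, 2.0]); e = np.array([True, False])
    for y in (Surv.from_arrays(event=e, time=t), (t, e),
              pd.DataFrame({"time": t, "event": e})):
        tt, ee = as_survival(y)
        assert np.allclose(tt, t) and np.array_equal(ee, e)
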