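import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from irlpair import km_logrank, time_dependent_roc
from irlpair.signature import RiskProfile
from irlpair.survival import (
    clinical_cox,
    concordance,
    group_vs_clinical_tests,
    significance_stars,
)

from conftest import make_clinical


def roc_oracle(case_scores, ctrl_scores):
    """Brute-force AUC (pairwise comparisons, ties 1/2) and Youden cutoff
    by exhaustive scan over all n+1 thresholds."""
    auc = np.mean([(c > d) + 0.5 * (c == d)
                   for c in case_scores for d in ctrl_scores])
    thresholds = [-np.inf] + sorted(set(np.concatenate([case_scores, ctrl_scores])))
    best, best_thr = -np.inf, None
    for thr in thresholds:
        j = np.mean(case_scores > thr) - np.mean(ctrl_scores > thr)
        if j > best + 1e-12:
            best, best_thr = j, thr
    return auc, best_thr


def _profile(scores):
    return RiskProfile(pd.Series(scores, index=[f"s{i}" for i in range(len(scores))]))


class TestTimeDependentROC:
    def test_perfect_separation_gives_auc_one(self):
        clin = make_clinical([1, 2, 9, 9, 8], [1, 1, 0, 0, 0])
        roc = time_dependent_roc(_profile([5.0, 4.0, 1.0, 0.5, 0.2]), clin, 5.0)
        assert roc.auc == 1.0
        assert roc.n_cases == 2 and roc.n_controls == 3

    def test_censored_before_horizon_excluded(self):
        clin = make_clinical([1, 3, 9], [1, 0, 0])  # s1 censored at 3 < 5
        roc = time_dependent_roc(_profile([2.0, 1.0, 0.0]), clin, 5.0)
        assert roc.n_cases == 1 and roc.n_controls == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_and_cutoff_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        times = rng.exponential(5, size=n)
        events = rng.random(n) < 0.7
        scores = np.round(rng.normal(size=n), 1)  # ties likely
        clin = make_clinical(times, events.astype(int))
        roc = time_dependent_roc(_profile(scores), clin, 4.0)
        case = scores[(events == 1) & (times <= 4.0)]
        ctrl = scores[times > 4.0]
        auc, cut = roc_oracle(case, ctrl)
        assert roc.auc == pytest.approx(auc, abs=1e-12)
        assert roc.cutoff == pytest.approx(cut)

    def test_auc_equals_mannwhitney_u(self, rng):
        n = 80
        times = rng.exponential(5, size=n)
        events = rng.random(n) < 0.6
        scores = rng.normal(size=n)
        clin = make_clinical(times, events.astype(int))
        roc = time_dependent_roc(_profile(scores), clin, 4.0)
        case = scores[(events == 1) & (times <= 4.0)]
        ctrl = scores[times > 4.0]
        u = stats.mannwhitneyu(case, ctrl, alternative="two-sided").statistic
        assert roc.auc == pytest.approx(u / (len(case) * len(ctrl)), abs=1e-12)

    def test_label_permutation_null_auc_half(self):
        rng = np.random.default_rng(1)
        n = 200
        times = rng.exponential(5, size=n)
        events = (rng.random(n) < 0.7).astype(int)
        clin = make_clinical(times, events)
        aucs = [time_dependent_roc(_profile(rng.permutation(np.arange(n) / n)),
                                   clin, 4.0).auc for _ in range(100)]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    def test_no_cases_is_error(self):
        clin = make_clinical([9, 9], [0, 0])
        with pytest.raises(ValueError, match="cases"):
            time_dependent_roc(_profile([1.0, 2.0]), clin, 5.0)


def logrank_oracle(t1, e1, t2, e2):
    """Hand computation of the two-group log-rank chi-square: at each event
    time, observed vs hypergeometric-expected deaths in group 1."""
    times = np.concatenate([t1, t2])
    events = np.concatenate([e1, e2])
    grp = np.concatenate([np.zeros(len(t1)), np.ones(len(t2))])
    O = E = V = 0.0
    for tau in sorted(set(times[events == 1])):
        at_risk = times >= tau
        n = at_risk.sum()
        n1 = (at_risk & (grp == 0)).sum()
        d = ((times == tau) & (events == 1)).sum()
        d1 = ((times == tau) & (events == 1) & (grp == 0)).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestKMLogrank:
    def _risk(self, scores, cutoff):
        return RiskProfile(pd.Series(scores, index=[f"s{i}" for i in range(len(scores))]),
                           cutoff=cutoff)

    def test_identical_groups_give_null_statistic(self):
        times = [1, 2, 3, 4, 1, 2, 3, 4]
        events = [1, 1, 0, 1, 1, 1, 0, 1]
        clin = make_clinical(times, events)
        risk = self._risk([0, 0, 0, 0, 1, 1, 1, 1], 0.5)
        res = km_logrank(risk, clin)
        assert res.strata["all"]["chisq"] == pytest.approx(0.0, abs=1e-10)
        assert res.strata["all"]["p"] == pytest.approx(1.0)

    def test_ten_subject_dataset_matches_hand_worked_table(self):
        times = [6, 7, 10, 15, 19, 25, 3, 5, 8, 12]
        events = [1, 0, 1, 1, 0, 1, 1, 1, 1, 1]
        groups = [0] * 6 + [1] * 4
        clin = make_clinical(times, events)
        risk = self._risk(groups, 0.5)
        res = km_logrank(risk, clin)
        t = np.array(times, float); e = np.array(events); g = np.array(groups)
        expected = logrank_oracle(t[g == 0], e[g == 0], t[g == 1], e[g == 1])
        assert res.strata["all"]["chisq"] == pytest.approx(expected, abs=1e-3)

    def test_km_without_censoring_is_empirical_survival(self):
        times = [1.0, 2.0, 3.0, 4.0]
        clin = make_clinical(times + [1.0, 2.0, 3.0, 4.0], [1] * 8)
        risk = self._risk([0, 0, 0, 0, 1, 1, 1, 1], 0.5)
        curve = km_logrank(risk, clin).strata["all"]["curves"]["low"]
        surv = curve.set_index("time")["survival"]
        for i, tau in enumerate(times):
            assert surv[tau] == pytest.approx(1 - (i + 1) / 4)

    def test_stratified_analysis_skips_empty_group(self, caplog):
        times = [1, 2, 3, 4, 5, 6]
        clin = make_clinical(times, [1] * 6)
        risk = self._risk([0, 0, 1, 1, 0, 0], 0.5)
        strata = pd.Series(["A", "A", "A", "A", "B", "B"],
                           index=risk.scores.index)
        res = km_logrank(risk, clin, strata=strata)
        assert "A" in res.strata and "B" not in res.strata


class TestClinicalTests:
    def test_identical_scores_across_levels_p_one(self):
        clin = make_clinical([5] * 6, [1] * 6, stage=[1, 1, 1, 2, 2, 2])
        risk = RiskProfile(pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                                     index=clin.sample_ids))
        out = group_vs_clinical_tests(risk, clin, variables=["stage"])
        assert out.loc[0, "p"] == 1.0

    def test_total_shift_attains_exact_minimal_p(self):
        """Non-overlapping score shift between two small levels: the exact
        rank-sum p equals the enumeration minimum 2 / C(16, 8)."""
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 1, 8)
        b = a + 10.0
        clin = make_clinical([5] * 16, [1] * 16, grp=["A"] * 8 + ["B"] * 8)
        risk = RiskProfile(pd.Series(np.concatenate([a, b]), index=clin.sample_ids))
        out = group_vs_clinical_tests(risk, clin, variables=["grp"])
        exact_min = 2.0 / math.comb(16, 8)
        assert out.loc[0, "p"] == pytest.approx(exact_min, rel=1e-9)
        assert out.loc[0, "stars"] == "***"

    def test_single_level_variable_skipped(self):
        clin = make_clinical([5] * 4, [1] * 4, sex=["F"] * 4)
        risk = RiskProfile(pd.Series([1.0, 2, 3, 4], index=clin.sample_ids))
        out = group_vs_clinical_tests(risk, clin, variables=["sex"])
        assert out.empty

    def test_three_levels_use_kruskal(self, rng):
        clin = make_clinical([5] * 9, [1] * 9, stage=[1, 1, 1, 2, 2, 2, 3, 3, 3])
        risk = RiskProfile(pd.Series(rng.normal(size=9), index=clin.sample_ids))
        out = group_vs_clinical_tests(risk, clin, variables=["stage"])
        assert out.loc[0, "test"] == "kruskal_wallis"

    def test_stars_convention(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.2) == ""


class TestClinicalCox:
    def _cohort(self, rng, n, beta_age=0.0):
        age = rng.normal(60, 10, size=n)
        t = rng.exponential(1.0 / np.exp(beta_age * (age - 60)))
        clin = make_clinical(t, [1] * n, age=age,
                             stage=rng.choice([1, 2, 3], size=n))
        risk = RiskProfile(pd.Series(rng.normal(size=n), index=clin.sample_ids))
        return risk, clin

    def test_null_covariate_ci_covers_one(self):
        """Covariate independent of survival: 95% CI covers HR = 1 in most
        replicates."""
        cover = 0
        for rep in range(20):
            rng = np.random.default_rng(rep)
            risk, clin = self._cohort(rng, 300)
            rep_out = clinical_cox(risk, clin, covariates=["age"]).univariate
            lo, hi = rep_out.loc["age", ["hr_lower", "hr_upper"]]
            cover += lo <= 1.0 <= hi
        assert cover >= 17  # ~95% coverage, small-sample slack

    def test_duplicate_covariate_dropped_from_joint_model(self, rng):
        risk, clin = self._cohort(rng, 100)
        clin.frame["age2"] = clin.frame["age"]
        rep = clinical_cox(risk, clin, covariates=["age", "age2"])
        assert rep.dropped == ["age2"]
        assert "age2" not in rep.multivariate.index
        assert "age2" in rep.univariate.index

    def test_uni_and_multi_agree_for_independent_covariates(self):
        rng = np.random.default_rng(9)
        n = 2000
        age = rng.normal(60, 10, size=n)
        score = rng.normal(size=n)
        t = rng.exponential(1.0 / np.exp(0.5 * score))
        clin = make_clinical(t, [1] * n, age=age)
        risk = RiskProfile(pd.Series(score, index=clin.sample_ids))
        rep = clinical_cox(risk, clin, covariates=["age"])
        uni = np.log(rep.univariate.loc["risk_score", "hr"])
        multi = np.log(rep.multivariate.loc["risk_score", "hr"])
        assert uni == pytest.approx(multi, abs=0.1)
        assert uni == pytest.approx(0.5, abs=0.1)


def test_concordance_constant_score_is_half(rng):
    clin = make_clinical(rng.exponential(size=20), [1] * 20)
    assert concordance(RiskProfile(pd.Series(np.ones(20), index=clin.sample_ids)),
                       clin) == 0.5
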