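import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test
from scipy import stats

from irlpair import coexpression_screen, parse_gtf_biotypes
from irlpair.simulate import (
    SimulationConfig,
    SyntheticTruth,
    emit_cohort,
    null_config,
    simulate_cohort,
    simulate_expression,
    simulate_survival,
    true_pair_matrix,
)

from conftest import SMALL


class TestConfigValidation:
    def test_infeasible_coexpression_calibration_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            SimulationConfig(loading_lnc=0.5, loading_mrna=0.5)  # product 0.25 < 0.4

    def test_true_pairs_cannot_exceed_de_genes(self):
        with pytest.raises(ValueError, match="true pairs"):
            SimulationConfig(n_de=4, n_true_pairs=3)

    def test_subtype_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="proportions"):
            SimulationConfig(subtype_props={"LumA": 0.5, "LumB": 0.4})


class TestExpressionGenerator:
    def test_same_seed_reproduces_identically(self):
        cfg = SimulationConfig(**SMALL)
        l1, m1, _ = simulate_expression(cfg)
        l2, m2, _ = simulate_expression(cfg)
        pd.testing.assert_frame_equal(l1.values, l2.values)
        pd.testing.assert_frame_equal(m1.values, m2.values)

    def test_zero_noise_gives_perfect_module_correlation(self):
        cfg = SimulationConfig(**{**SMALL, "loading_lnc": 1.0, "loading_mrna": 1.0,
                                  "n_de": 0, "n_true_pairs": 0})
        lnc, mrna, truth = simulate_expression(cfg)
        g = truth.immune_lncs[0]
        m = truth.module_of_gene[g]
        partner = next(k for k, v in truth.module_of_gene.items()
                       if v == m and k.startswith("IMMSIM"))
        # on the generator's own (log2) scale both genes are mu + z exactly
        r = stats.pearsonr(np.log2(lnc.values.loc[g]),
                           np.log2(mrna.values.loc[partner])).statistic
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_coexpression_screen_recovers_truth_flagged_lncs(self):
        """Calibration: across seeds, nearly all truth-flagged immune
        lncRNAs clear the r > 0.4, p < 0.001 screen."""
        rates = []
        for seed in range(12):
            cfg = SimulationConfig(**{**SMALL, "seed": seed})
            lnc, mrna, truth = simulate_expression(cfg)
            from irlpair.containers import ImmuneGeneSet
            imm = ImmuneGeneSet({g for g in mrna.gene_ids if g.startswith("IMMSIM")})
            res = coexpression_screen(lnc, mrna, imm)
            flagged = set(res.immune_lncrnas)
            rates.append(np.mean([g in flagged for g in truth.immune_lncs]))
        assert np.median(rates) >= 0.9

    def test_de_genes_have_large_true_logfc(self):
        cfg = SimulationConfig(**SMALL)
        _, _, truth = simulate_expression(cfg)
        assert len(truth.de_genes) == SMALL["n_de"]
        assert all(abs(s) > 1.5 for s in truth.de_genes.values())


class TestSurvivalGenerator:
    def test_exponential_special_case_mean(self):
        """kappa = 1, no covariate effects, no censoring: event times are
        exponential with mean equal to the Weibull scale."""
        cfg = null_config(n_tumor=10000, n_normal=10, n_lnc=12, n_immune_mrna=8,
                          n_other_mrna=8, n_immune_lnc=6, n_de=2,
                          weibull_shape=1.0, weibull_scale=8.0,
                          censoring_rate=0.0, seed=3)
        lnc, _, truth = simulate_expression(cfg)
        clin = simulate_survival(cfg, truth, lnc_expr=lnc)
        f = clin.eligible()
        assert f["event"].all()
        assert f["time"].mean() == pytest.approx(8.0, rel=0.05)

    def test_null_logrank_p_uniform_over_random_splits(self):
        cfg = null_config(n_tumor=300, n_normal=10, n_lnc=12, n_immune_mrna=8,
                          n_other_mrna=8, n_immune_lnc=6, n_de=2, seed=5)
        lnc, _, truth = simulate_expression(cfg)
        clin = simulate_survival(cfg, truth, lnc_expr=lnc)
        f = clin.eligible()
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(40):
            mask = rng.random(len(f)) < 0.5
            res = logrank_test(f["time"][mask], f["time"][~mask],
                               f["event"][mask], f["event"][~mask])
            ps.append(res.p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_strong_single_pair_separates_km_curves(self):
        cfg = SimulationConfig(**{**SMALL, "n_tumor": 600, "n_true_pairs": 1,
                                  "beta_magnitude": 2.0, "seed": 9})
        lnc, _, truth = simulate_expression(cfg)
        clin = simulate_survival(cfg, truth, lnc_expr=lnc)
        pm = true_pair_matrix(lnc, truth)
        S = pm.indicator.iloc[0]
        f = clin.eligible()
        g1, g0 = S[S == 1].index, S[S == 0].index
        res = logrank_test(f.loc[g1, "time"], f.loc[g0, "time"],
                           f.loc[g1, "event"], f.loc[g0, "event"])
        assert res.p_value < 0.001

    def test_censoring_rate_calibrated(self):
        cfg = SimulationConfig(**SMALL)
        lnc, _, truth = simulate_expression(cfg)
        clin = simulate_survival(cfg, truth, lnc_expr=lnc)
        achieved = 1.0 - clin.eligible()["event"].mean()
        assert achieved == pytest.approx(cfg.censoring_rate, abs=0.10)

    def test_true_risk_scored_on_pipeline_identical_indicators(self):
        cfg = SimulationConfig(**SMALL)
        lnc, _, truth = simulate_expression(cfg)
        simulate_survival(cfg, truth, lnc_expr=lnc)
        pm = true_pair_matrix(lnc, truth)
        betas = pd.Series({f"{a}|{b}" if a < b else f"{b}|{a}": bt
                           for a, b, bt in truth.true_pairs})
        manual = pm.indicator.T[betas.index] @ betas
        assert np.allclose(truth.true_risk[manual.index], manual)


class TestEmitCohort:
    @pytest.fixture(scope="class")
    def outdir(self, tmp_path_factory):
        cfg = SimulationConfig(**{**SMALL, "n_tumor": 60, "n_normal": 15})
        return emit_cohort(cfg, tmp_path_factory.mktemp("cohort") / "sim")

    def test_gtf_round_trips_through_parser(self, outdir):
        ann = parse_gtf_biotypes(outdir / "annotation.gtf")
        assert set(ann.biotype.values()) == {"lncRNA", "protein_coding"}

    def test_truth_json_reloads_and_rescores(self, outdir):
        truth = SyntheticTruth.load(outdir / "truth.json")
        again = SyntheticTruth.load(outdir / "truth.json")
        assert truth.true_pairs == again.true_pairs
        pd.testing.assert_series_equal(truth.true_risk, again.true_risk)

    def test_refuses_nonempty_directory(self, outdir):
        with pytest.raises(FileExistsError):
            emit_cohort(SimulationConfig(**SMALL), outdir)

    def test_cli_run_all_smoke(self, outdir, tmp_path):
        from click.testing import CliRunner
        from irlpair.cli import main
        out = tmp_path / "results"
        r = CliRunner().invoke(main, ["run-all", str(outdir), str(out),
                                      "--seed", "1"])
        assert r.exit_code == 0, r.output
        assert (out / "signature.json").exists()
        assert (out / "risk_scores.tsv").exists()
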