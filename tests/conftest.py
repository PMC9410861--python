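import numpy as np
import pandas as pd
import pytest

from irlpair import run_pipeline, simulate_cohort
from irlpair.containers import ClinicalTable, ExpressionMatrix
from irlpair.simulate import SimulationConfig


SMALL = dict(n_tumor=150, n_normal=30, n_lnc=60, n_immune_mrna=40,
             n_other_mrna=60, n_immune_lnc=24, n_de=12, n_true_pairs=4,
             seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """A scaled-down synthetic cohort shared by integration tests."""
    return simulate_cohort(SimulationConfig(**SMALL))


@pytest.fixture(scope="session")
def small_result(small_cohort):
    """Full pipeline run on the small cohort (fit once, reused read-only)."""
    c = small_cohort
    return run_pipeline(c.lnc_expr, c.mrna_expr, c.clinical, c.immune_genes,
                        fractions=c.fractions, gene_sets=c.gene_sets,
                        test_fraction=1 / 3, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_expr(values, genes, samples, cohorts):
    """Tiny ExpressionMatrix from plain lists."""
    df = pd.DataFrame(values, index=genes, columns=samples, dtype=float)
    return ExpressionMatrix(df, pd.Series(cohorts, index=samples))


def make_clinical(times, events, **cols):
    idx = [f"s{i}" for i in range(len(times))]
    frame = pd.DataFrame({"time": times, "event": events, **cols}, index=idx)
    return ClinicalTable(frame)
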