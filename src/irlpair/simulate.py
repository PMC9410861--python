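"""Ground-truth synthetic cohorts for the IRLP pipeline.

The generator is the pipeline's generative inverse.  Expression is built
from latent per-sample immune-module scores: immune mRNAs load on a module,
immune lncRNAs load on the same modules (calibrated so their population
correlation with at least one immune gene clears the coexpression
threshold), a subset of immune lncRNAs receives a tumor-cohort mean shift
(the DE genes), and everything is exponentiated to a nonnegative FPKM-like
scale.  Survival then follows a Weibull proportional-hazards model whose
linear predictor is the true pair risk score sum_i beta_i * S_i (with the
pair indicators computed exactly as the pipeline computes them) plus
clinical covariate effects; censoring is independent exponential,
calibrated to a target rate.  The realized truth (immune lncRNAs, DE
genes, true pairs and coefficients, per-sample true risk) is serialized
alongside the data so any pipeline stage can be scored for recovery.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import optimize

from .containers import (
    NORMAL,
    TUMOR,
    ClinicalTable,
    ExpressionMatrix,
    GeneAnnotation,
    ImmuneGeneSet,
)
from .pairs import PairIndicatorMatrix, build_pair_matrix, pair_label

log = logging.getLogger(__name__)

#: Subtype mix of a large breast-tumor cohort (LumA-dominant).
DEFAULT_SUBTYPE_PROPS = {"LumA": 0.478, "LumB": 0.216, "Basal": 0.187,
                         "Her2": 0.100, "Normal": 0.019}

CELL_TYPES = ("CD8_T", "CD4_T", "B_cells", "NK", "Monocytes",
              "Macrophage_M0", "Macrophage_M1", "Macrophage_M2",
              "Dendritic", "Mast", "Neutrophils", "Treg")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions."""

    n_tumor: int = 600
    n_normal: int = 60
    n_lnc: int = 200               # candidate lncRNAs
    n_immune_mrna: int = 100
    n_other_mrna: int = 200
    n_modules: int = 4             # latent immune modules
    n_immune_lnc: int = 60         # lncRNAs loading on a module
    n_de: int = 30                 # immune lncRNAs with a tumor shift
    n_true_pairs: int = 10
    beta_magnitude: float = 0.8    # |beta| of every true pair
    loading_lnc: float = 0.9       # module loading of immune lncRNAs
    loading_mrna: float = 0.9      # module loading of immune mRNAs
    target_r: float = 0.4          # coexpression threshold to calibrate against
    de_shift: float = 2.5          # log2 tumor mean shift of DE genes
    weibull_shape: float = 1.5     # kappa; 1 = exponential
    weibull_scale: float = 8.0     # lambda_w, years
    censoring_rate: float = 0.3
    gamma_age: float = 0.02        # log-hazard per year of age (centered)
    gamma_stage: float = 0.3       # log-hazard per overall-stage step
    subtype_props: dict = field(default_factory=lambda: dict(DEFAULT_SUBTYPE_PROPS))
    fraction_coupling: float = 1.0  # logit tilt of the coupled cell types
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de > self.n_immune_lnc or self.n_immune_lnc > self.n_lnc:
            raise ValueError("need n_de <= n_immune_lnc <= n_lnc")
        if 2 * self.n_true_pairs > self.n_de:
            raise ValueError("true pairs reference more genes than n_de provides")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring rate must be in [0, 1)")
        if abs(sum(self.subtype_props.values()) - 1.0) > 1e-6:
            raise ValueError("subtype proportions must sum to 1")
        if self.loading_lnc * self.loading_mrna <= self.target_r:
            raise ValueError(
                f"infeasible calibration: loading product "
                f"{self.loading_lnc * self.loading_mrna:.3f} <= target r {self.target_r}"
                " (population coexpression cannot clear the screen)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def null_config(**overrides) -> SimulationConfig:
    """Global-null cohort: no prognostic pairs, no covariate effects."""
    base = dict(n_true_pairs=0, gamma_age=0.0, gamma_stage=0.0)
    base.update(overrides)
    return SimulationConfig(**base)


@dataclass
class SyntheticTruth:
    """Realized ground truth, sufficient to score any stage's recovery."""

    config: SimulationConfig
    immune_lncs: list
    de_genes: dict            # gene -> true log2 shift
    true_pairs: list          # (lnc_a, lnc_b, beta), canonical orientation
    true_risk: pd.Series      # per tumor sample
    module_of_gene: dict

    @property
    def true_pair_labels(self) -> list[str]:
        return [pair_label(a, b) for a, b, _ in self.true_pairs]

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "immune_lncs": list(self.immune_lncs),
            "de_genes": {g: float(v) for g, v in self.de_genes.items()},
            "true_pairs": [[a, b, float(bt)] for a, b, bt in self.true_pairs],
            "true_risk": {k: float(v) for k, v in self.true_risk.items()},
            "module_of_gene": dict(self.module_of_gene),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(SimulationConfig(**d["config"]), d["immune_lncs"],
                   d["de_genes"],
                   [tuple(t) for t in d["true_pairs"]],
                   pd.Series(d["true_risk"]), d["module_of_gene"])


def _child_rngs(seed: int, n: int):
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(c) for c in ss.spawn(n)]


def simulate_expression(cfg: SimulationConfig):
    """Generate (lnc_expr, mrna_expr, truth-without-survival).

    Deterministic given ``cfg.seed``.  Gene values are 2**x with x Gaussian
    on the log2 scale (log-normal FPKM-like abundances).
    """
    rng, _, _ = _child_rngs(cfg.seed, 3)
    n = cfg.n_tumor + cfg.n_normal
    samples = [f"T{i:04d}" for i in range(cfg.n_tumor)] + \
              [f"N{i:04d}" for i in range(cfg.n_normal)]
    cohort = pd.Series([TUMOR] * cfg.n_tumor + [NORMAL] * cfg.n_normal,
                       index=samples)
    tumor_mask = np.arange(n) < cfg.n_tumor

    Z = rng.standard_normal((cfg.n_modules, n))  # latent module scores

    lnc_ids = [f"LNCSIM{i:04d}" for i in range(cfg.n_lnc)]
    imm_ids = [f"IMMSIM{i:04d}" for i in range(cfg.n_immune_mrna)]
    oth_ids = [f"MRNASIM{i:04d}" for i in range(cfg.n_other_mrna)]

    module_of: dict[str, int] = {}

    def _module_gene(m: int, loading: float, mu: float) -> np.ndarray:
        eps = rng.standard_normal(n)
        return mu + loading * Z[m] + np.sqrt(1 - loading ** 2) * eps

    # immune mRNAs
    mrna_rows = []
    for i, g in enumerate(imm_ids):
        m = i % cfg.n_modules
        mu = rng.uniform(2.0, 6.0)
        module_of[g] = m
        mrna_rows.append(_module_gene(m, cfg.loading_mrna, mu))
    for g in oth_ids:
        mu = rng.uniform(2.0, 6.0)
        mrna_rows.append(mu + rng.standard_normal(n))

    # lncRNAs: immune-module-correlated block first, then independent noise
    de_genes: dict[str, float] = {}
    lnc_rows = []
    pair_gene_mu = rng.uniform(3.0, 5.0, size=cfg.n_true_pairs)
    pair_gene_shift = cfg.de_shift * rng.choice([-1.0, 1.0], size=cfg.n_true_pairs)
    for i, g in enumerate(lnc_ids):
        if i < cfg.n_immune_lnc:
            # pair members share a module, so their indicator is driven by
            # gene-level noise and the 10 true indicators are independent
            m = (i // 2) % cfg.n_modules
            k_pair = i // 2 if i < 2 * cfg.n_true_pairs else None
            if k_pair is not None:
                mu = pair_gene_mu[k_pair]        # pair members share a mean
            else:
                mu = rng.uniform(2.0, 6.0)
            x = _module_gene(m, cfg.loading_lnc, mu)
            module_of[g] = m
            if i < cfg.n_de:
                shift = (pair_gene_shift[k_pair] if k_pair is not None
                         else cfg.de_shift * rng.choice([-1.0, 1.0]))
                x = x + shift * tumor_mask
                de_genes[g] = float(shift)
        else:
            x = rng.uniform(2.0, 6.0) + rng.standard_normal(n)
        lnc_rows.append(x)

    lnc_expr = ExpressionMatrix(
        pd.DataFrame(np.exp2(np.asarray(lnc_rows)), index=lnc_ids, columns=samples),
        cohort)
    mrna_expr = ExpressionMatrix(
        pd.DataFrame(np.exp2(np.asarray(mrna_rows)), index=imm_ids + oth_ids,
                     columns=samples), cohort)

    # true pairs: consecutive DE genes, canonical orientation, fixed |beta|
    true_pairs = []
    signs = rng.choice([-1.0, 1.0], size=cfg.n_true_pairs)
    for k in range(cfg.n_true_pairs):
        a, b = sorted((lnc_ids[2 * k], lnc_ids[2 * k + 1]))
        true_pairs.append((a, b, float(cfg.beta_magnitude * signs[k])))

    truth = SyntheticTruth(cfg, lnc_ids[:cfg.n_immune_lnc], de_genes,
                           true_pairs, pd.Series(dtype=float), module_of)
    return lnc_expr, mrna_expr, truth


def true_pair_matrix(lnc_expr: ExpressionMatrix,
                     truth: SyntheticTruth) -> PairIndicatorMatrix:
    """Indicators of the true pairs on the tumor samples, pipeline-identical."""
    genes = sorted({g for a, b, _ in truth.true_pairs for g in (a, b)})
    tumor = lnc_expr.subset_samples(lnc_expr.cohort_samples(TUMOR))
    pm = build_pair_matrix(tumor, genes)
    return PairIndicatorMatrix(pm.indicator.loc[truth.true_pair_labels])


def simulate_survival(cfg: SimulationConfig, truth: SyntheticTruth,
                      pm_truth: PairIndicatorMatrix | None = None,
                      lnc_expr: ExpressionMatrix | None = None) -> ClinicalTable:
    """Weibull PH survival driven by the true pair risk score.

    hazard(t | s) = h0(t) * exp(sum_i beta_i S_i(s) + gamma' z_s) with
    Weibull h0; event times by inverse-transform sampling; independent
    exponential censoring with its rate solved to hit the target censoring
    fraction on the realized event times.  Updates ``truth.true_risk``.
    """
    if pm_truth is None:
        if cfg.n_true_pairs > 0:
            if lnc_expr is None:
                raise ValueError("need pm_truth or lnc_expr to score true pairs")
            pm_truth = true_pair_matrix(lnc_expr, truth)
    _, rng, _ = _child_rngs(cfg.seed, 3)

    if pm_truth is not None and cfg.n_true_pairs > 0:
        samples = pm_truth.sample_ids
        betas = np.array([b for _, _, b in truth.true_pairs])
        S = pm_truth.indicator.loc[truth.true_pair_labels].to_numpy().T
        risk = S @ betas
    else:
        if lnc_expr is None:
            raise ValueError("need lnc_expr to enumerate tumor samples")
        samples = lnc_expr.cohort_samples(TUMOR)
        risk = np.zeros(len(samples))
    n = len(samples)
    truth.true_risk = pd.Series(risk, index=samples, name="true_risk")

    age = np.clip(rng.normal(58.0, 12.0, size=n), 25.0, 90.0).round(1)
    stage = rng.choice([1, 2, 3, 4], size=n, p=[0.18, 0.55, 0.22, 0.05])
    sex = rng.choice(["F", "M"], size=n, p=[0.99, 0.01])
    labels = list(cfg.subtype_props)
    subtype = rng.choice(labels, size=n,
                         p=[cfg.subtype_props[l] for l in labels])

    eta = risk - risk.mean() + cfg.gamma_age * (age - age.mean()) \
        + cfg.gamma_stage * (stage - 2.0)
    # Weibull PH: S(t) = exp(-(t/lam)^kappa * e^eta)
    u = rng.uniform(size=n)
    T = cfg.weibull_scale * (-np.log(u) / np.exp(eta)) ** (1.0 / cfg.weibull_shape)

    if cfg.censoring_rate > 0:
        def _mean_cens(theta):
            return np.mean(1.0 - np.exp(-theta * T)) - cfg.censoring_rate
        theta = optimize.brentq(_mean_cens, 1e-9, 1e6)
        C = rng.exponential(1.0 / theta, size=n)
    else:
        C = np.full(n, np.inf)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    achieved = 1.0 - event.mean()
    if abs(achieved - cfg.censoring_rate) > 0.10:
        log.warning("achieved censoring rate %.2f vs target %.2f",
                    achieved, cfg.censoring_rate)

    t_stage = "T" + pd.Series(np.clip(stage + rng.integers(-1, 2, size=n), 1, 4)).astype(str)
    n_stage = "N" + pd.Series(np.clip(stage - 1 + rng.integers(0, 2, size=n), 0, 3)).astype(str)
    m_stage = np.where(stage == 4, "M1", "M0")
    frame = pd.DataFrame({
        "time": np.round(time, 4), "event": event, "age": age, "sex": sex,
        "t_stage": t_stage.to_numpy(), "n_stage": n_stage.to_numpy(),
        "m_stage": m_stage, "stage": stage, "subtype": subtype,
    }, index=pd.Index(samples, name="sample"))
    return ClinicalTable(frame, time_unit="years")


def simulate_fractions(cfg: SimulationConfig, truth: SyntheticTruth) -> pd.DataFrame:
    """CIBERSORT-style fraction table, two cell types coupled to true risk.

    Macrophage_M2 is tilted up and CD8_T down with the true risk score on
    the logit scale (softmax keeps rows on the simplex), mirroring the
    signed structure the association module is meant to detect.  Under a
    null cohort (constant true risk) fractions are independent of risk.
    """
    _, _, rng = _child_rngs(cfg.seed, 3)
    samples = list(truth.true_risk.index)
    n, k = len(samples), len(CELL_TYPES)
    base = rng.normal(0.0, 0.3, size=k)
    logits = base + rng.normal(0.0, 0.5, size=(n, k))
    r = truth.true_risk.to_numpy()
    z = (r - r.mean()) / r.std() if r.std() > 0 else np.zeros(n)
    i_m2 = CELL_TYPES.index("Macrophage_M2")
    i_cd8 = CELL_TYPES.index("CD8_T")
    logits[:, i_m2] += cfg.fraction_coupling * z
    logits[:, i_cd8] -= cfg.fraction_coupling * z
    w = np.exp(logits - logits.max(axis=1, keepdims=True))
    fr = w / w.sum(axis=1, keepdims=True)
    return pd.DataFrame(fr, index=pd.Index(samples, name="sample"),
                        columns=list(CELL_TYPES))


def simulate_gene_sets(cfg: SimulationConfig, truth: SyntheticTruth,
                       mrna_ids, n_random_sets: int = 8) -> dict[str, set]:
    """GMT-style sets: one per immune module (enriched in module mRNAs
    correlated with the signature genes) plus random background sets."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(4)[3])
    mrna_ids = list(mrna_ids)
    sets: dict[str, set] = {}
    for m in range(cfg.n_modules):
        members = {g for g, mm in truth.module_of_gene.items()
                   if mm == m and g in set(mrna_ids)}
        extra = rng.choice(mrna_ids, size=10, replace=False)
        sets[f"MODULE_{m}_SET"] = members | set(extra)
    for k in range(n_random_sets):
        size = int(rng.integers(15, 40))
        sets[f"RANDOM_SET_{k}"] = set(rng.choice(mrna_ids, size=size, replace=False))
    return sets


@dataclass
class SimulatedCohort:
    """Everything one run of the generator produces, in memory."""

    lnc_expr: ExpressionMatrix
    mrna_expr: ExpressionMatrix
    clinical: ClinicalTable
    immune_genes: ImmuneGeneSet
    annotation: GeneAnnotation
    fractions: pd.DataFrame
    gene_sets: dict
    truth: SyntheticTruth


def simulate_cohort(cfg: SimulationConfig | None = None, **overrides) -> SimulatedCohort:
    """One call, full cohort: expression, survival, fractions, sets, truth."""
    if cfg is None:
        cfg = SimulationConfig(**overrides)
    lnc_expr, mrna_expr, truth = simulate_expression(cfg)
    clinical = simulate_survival(cfg, truth, lnc_expr=lnc_expr)
    fractions = simulate_fractions(cfg, truth)
    imm_ids = [g for g in mrna_expr.gene_ids if g.startswith("IMMSIM")]
    sets = simulate_gene_sets(cfg, truth, mrna_expr.gene_ids)
    ann = GeneAnnotation(
        {g: "lncRNA" for g in lnc_expr.gene_ids}
        | {g: "protein_coding" for g in mrna_expr.gene_ids},
        {})
    return SimulatedCohort(lnc_expr, mrna_expr, clinical,
                           ImmuneGeneSet(set(imm_ids)), ann, fractions, sets, truth)


def _write_gtf(path, annotation: GeneAnnotation) -> None:
    with open(path, "w") as fh:
        pos = 1000
        for g, b in annotation.biotype.items():
            gtype = {"lncRNA": "lncRNA", "protein_coding": "protein_coding"}.get(b, "misc_RNA")
            attrs = f'gene_id "{g}"; gene_type "{gtype}"; gene_name "{g}";'
            fh.write(f"chrS\tsim\tgene\t{pos}\t{pos + 500}\t.\t+\t.\t{attrs}\n")
            pos += 1000


def _write_gmt(path, sets: dict) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "synthetic"] + sorted(members)) + "\n")


def emit_cohort(cfg: SimulationConfig, outdir, overwrite: bool = False) -> Path:
    """Write a full synthetic cohort as plain-text files.

    Refuses a non-empty existing directory unless ``overwrite`` is set.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(f"{outdir} exists and is not empty")
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(cfg)

    expr = pd.concat([cohort.lnc_expr.values, cohort.mrna_expr.values])
    expr.round(4).to_csv(outdir / "expression.tsv", sep="\t", index_label="gene")
    cohort.lnc_expr.cohort.to_frame("cohort").to_csv(
        outdir / "samples.tsv", sep="\t", index_label="sample")
    cohort.clinical.frame.drop(columns=["eligible"]).to_csv(
        outdir / "clinical.tsv", sep="\t", index_label="sample")
    (outdir / "immune_genes.txt").write_text(
        "\n".join(sorted(cohort.immune_genes.genes)) + "\n")
    _write_gtf(outdir / "annotation.gtf", cohort.annotation)
    cohort.fractions.round(5).to_csv(outdir / "fractions.tsv", sep="\t",
                                     index_label="sample")
    _write_gmt(outdir / "sets.gmt", cohort.gene_sets)
    cohort.truth.save(outdir / "truth.json")
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh)
    return outdir
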