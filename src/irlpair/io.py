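"""Readers and writers for the external formats the pipeline consumes.

Expression and clinical tables are plain TSV; gene annotation is GTF
(gene-feature rows only); the immune gene list is one identifier per line;
gene sets are GMT; immune-cell fractions are a CIBERSORT-style TSV with
samples in rows.  All identifier joins strip Ensembl version suffixes.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pyranges

from .containers import (
    BIOTYPE_CODING,
    BIOTYPE_LNC,
    BIOTYPE_OTHER,
    ClinicalTable,
    ExpressionMatrix,
    GeneAnnotation,
    ImmuneGeneSet,
    strip_gene_version,
)

log = logging.getLogger(__name__)

#: GENCODE biotypes conventionally folded into the lncRNA class.
DEFAULT_LNC_BIOTYPES = frozenset({
    "lncRNA", "lincRNA", "antisense", "antisense_RNA", "sense_intronic",
    "sense_overlapping", "processed_transcript", "3prime_overlapping_ncRNA",
    "bidirectional_promoter_lncRNA", "macro_lncRNA", "non_coding",
})


def read_expression(path, cohort_map: dict, duplicate_policy: str = "max") -> ExpressionMatrix:
    """Read a genes-in-rows TSV expression matrix with declared cohorts.

    Parameters
    ----------
    path : path-like
        TSV with a header row of sample ids; first column holds gene ids.
    cohort_map : dict
        sample id -> ``"tumor"`` / ``"normal"``; must cover every sample.
    duplicate_policy : {"max", "mean", "first"}
        How duplicate gene rows (same id after version stripping) are
        collapsed; the default keeps the per-sample maximum.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise ValueError(
                f"non-numeric expression value in column {col!r}, row {bad!r}")
    df.index = [strip_gene_version(str(g)) for g in df.index]
    if df.index.duplicated().any():
        n = int(df.index.duplicated().sum())
        log.info("collapsing %d duplicate gene rows by %r", n, duplicate_policy)
        grouped = df.groupby(level=0, sort=False)
        if duplicate_policy == "max":
            df = grouped.max()
        elif duplicate_policy == "mean":
            df = grouped.mean()
        elif duplicate_policy == "first":
            df = grouped.first()
        else:
            raise ValueError(f"unknown duplicate policy {duplicate_policy!r}")
    unknown = [s for s in df.columns if s not in cohort_map]
    if unknown:
        raise ValueError(f"samples missing from cohort map: {unknown[:5]}")
    cohort = pd.Series({s: cohort_map[s] for s in df.columns})
    return ExpressionMatrix(df, cohort)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t")


def parse_gtf_biotypes(path, lnc_biotype_names=DEFAULT_LNC_BIOTYPES) -> GeneAnnotation:
    """Partition genes into lncRNA / protein_coding / other from a GTF.

    Only ``gene``-feature rows are used.  The biotype attribute may be
    called ``gene_type`` (GENCODE) or ``gene_biotype`` (Ensembl).  Records
    without a gene_id are skipped with a counted warning; zero usable gene
    records is a hard error.
    """
    gr = pyranges.read_gtf(str(path))
    df = gr.df if hasattr(gr, "df") else gr
    genes = df[df["Feature"] == "gene"]
    if "gene_type" in genes.columns:
        bio_col = "gene_type"
    elif "gene_biotype" in genes.columns:
        bio_col = "gene_biotype"
    else:
        raise ValueError("GTF gene records carry no gene_type/gene_biotype attribute")
    skipped = 0
    biotype: dict[str, str] = {}
    symbol: dict[str, str] = {}
    for _, row in genes.iterrows():
        gid = row.get("gene_id")
        if gid is None or (isinstance(gid, float) and np.isnan(gid)) or gid == "":
            skipped += 1
            continue
        gid = strip_gene_version(str(gid))
        raw = row.get(bio_col)
        if raw in lnc_biotype_names:
            biotype[gid] = BIOTYPE_LNC
        elif raw == "protein_coding":
            biotype[gid] = BIOTYPE_CODING
        else:
            biotype[gid] = BIOTYPE_OTHER
        name = row.get("gene_name")
        if isinstance(name, str) and name:
            symbol[gid] = name
    if skipped:
        log.warning("skipped %d GTF gene records without gene_id", skipped)
    if not biotype:
        raise ValueError(f"no gene records parsed from {path}")
    return GeneAnnotation(biotype, symbol)


def split_by_biotype(expr: ExpressionMatrix, ann: GeneAnnotation):
    """Split an expression matrix into (lncRNA, protein-coding) sub-matrices.

    Genes absent from the annotation are dropped (counted in the log);
    either class coming out empty is a hard error.
    """
    lnc, coding, dropped = [], [], 0
    for g in expr.gene_ids:
        b = ann.biotype.get(g)
        if b == BIOTYPE_LNC:
            lnc.append(g)
        elif b == BIOTYPE_CODING:
            coding.append(g)
        else:
            dropped += 1
    if dropped:
        log.info("dropped %d genes not annotated as lncRNA/protein_coding", dropped)
    if not lnc or not coding:
        raise ValueError(
            f"empty biotype partition (lncRNA={len(lnc)}, coding={len(coding)})")
    return expr.subset_genes(lnc), expr.subset_genes(coding)


def read_immune_genes(path) -> ImmuneGeneSet:
    """One gene identifier per line; blank lines and '#' comments ignored."""
    genes = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.add(strip_gene_version(line))
    return ImmuneGeneSet(genes)


def read_clinical(path, column_map: dict | None = None,
                  time_unit: str = "years") -> ClinicalTable:
    """Read a per-sample clinical TSV (first column sample id).

    ``column_map`` renames source columns onto the canonical names
    (``time``, ``event``, ``age``, ``sex``, ``t_stage``, ``n_stage``,
    ``m_stage``, ``stage``, ``subtype``).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if column_map:
        df = df.rename(columns=column_map)
    return ClinicalTable(df, time_unit=time_unit)


def write_clinical(clin: ClinicalTable, path) -> None:
    clin.frame.drop(columns=["eligible"]).to_csv(path, sep="\t")


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene-set collection: set name, description, then member ids."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (needs name, description, members): {line[:60]!r}")
        sets[parts[0]] = {strip_gene_version(g) for g in parts[2:] if g}
    if not sets:
        raise ValueError(f"no gene sets parsed from {path}")
    return sets


#: Columns CIBERSORT appends after the fractions; tolerated and dropped.
_CIBERSORT_EXTRA = ("P-value", "Correlation", "RMSE", "Absolute score", "P.value")


def read_cell_fractions(path, tolerance: float = 0.01) -> pd.DataFrame:
    """CIBERSORT-style sample x cell-type fraction table.

    Fractions must be nonnegative and sum to 1 per sample within
    ``tolerance`` (deviations are logged, not fatal, to accommodate
    absolute-mode outputs).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.drop(columns=[c for c in _CIBERSORT_EXTRA if c in df.columns])
    if (df.to_numpy() < 0).any():
        raise ValueError("negative cell fraction")
    sums = df.sum(axis=1)
    off = sums[(sums - 1.0).abs() > tolerance]
    if len(off):
        log.warning("%d samples with fraction sums off 1 by > %g (max dev %g)",
                    len(off), tolerance, float((off - 1).abs().max()))
    return df
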