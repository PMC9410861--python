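"""Core in-memory containers for the IRLP pipeline.

Everything is a thin, validated wrapper around a :class:`pandas.DataFrame`
so the containers compose with the scientific Python stack; the wrappers
exist to enforce the invariants the pipeline relies on (nonnegative
abundances, unique identifiers, declared tumor/normal cohorts, eligible
survival records).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TUMOR = "tumor"
NORMAL = "normal"

#: Closed biotype vocabulary used throughout the package.
BIOTYPE_LNC = "lncRNA"
BIOTYPE_CODING = "protein_coding"
BIOTYPE_OTHER = "other"

SUBTYPE_LEVELS = ("LumA", "LumB", "Her2", "Basal", "Normal", "unknown")


def strip_gene_version(gene_id: str) -> str:
    """Drop a trailing Ensembl version suffix (``ENSG000123.4`` -> ``ENSG000123``).

    TCGA-style matrices, GTFs and curated gene lists routinely disagree on
    version suffixes; every identifier join in the package goes through this
    normalization first.
    """
    if "." in gene_id and gene_id.split(".")[0].startswith("ENS"):
        return gene_id.rsplit(".", 1)[0]
    return gene_id


@dataclass
class ExpressionMatrix:
    """Gene x sample abundance matrix (FPKM-like) with per-sample cohort labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes in rows, samples in columns, nonnegative reals.
    cohort : pandas.Series
        Per-sample label, ``"tumor"`` or ``"normal"``, indexed by sample id.
    """

    values: pd.DataFrame
    cohort: pd.Series

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise ValueError(f"duplicate gene id in expression matrix: {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id in expression matrix: {dup!r}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if np.isnan(arr).any():
            gene = v.index[np.isnan(arr).any(axis=1)][0]
            raise ValueError(f"missing value in expression matrix at gene {gene!r}")
        if (arr < 0).any():
            gene = v.index[(arr < 0).any(axis=1)][0]
            raise ValueError(f"negative expression value at gene {gene!r}")
        missing = set(v.columns) - set(self.cohort.index)
        if missing:
            raise ValueError(f"samples without a cohort label: {sorted(missing)[:5]}")
        bad = set(self.cohort.loc[list(v.columns)]) - {TUMOR, NORMAL}
        if bad:
            raise ValueError(f"unknown cohort labels: {sorted(bad)}")
        self.cohort = self.cohort.loc[list(v.columns)]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def cohort_samples(self, label: str) -> list[str]:
        return list(self.cohort.index[self.cohort == label])

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.cohort)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        samples = list(samples)
        return ExpressionMatrix(self.values[samples], self.cohort.loc[samples])

    def log2p1(self) -> pd.DataFrame:
        """log2(x + 1) transform used by every correlation in the pipeline."""
        return np.log2(self.values + 1.0)


@dataclass
class GeneAnnotation:
    """gene_id -> biotype (closed vocabulary) and gene_id -> symbol maps."""

    biotype: dict[str, str]
    symbol: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        allowed = {BIOTYPE_LNC, BIOTYPE_CODING, BIOTYPE_OTHER}
        bad = set(self.biotype.values()) - allowed
        if bad:
            raise ValueError(f"biotype vocabulary is closed; unknown: {sorted(bad)}")

    def genes_of(self, biotype: str) -> set[str]:
        return {g for g, b in self.biotype.items() if b == biotype}


@dataclass
class ImmuneGeneSet:
    """Curated set of immune-related gene identifiers (ImmPort-style)."""

    genes: set[str]

    def __post_init__(self) -> None:
        self.genes = {strip_gene_version(g) for g in self.genes}
        if not self.genes:
            raise ValueError("immune gene set is empty")


class ClinicalTable:
    """Per-sample survival record and clinical covariates.

    The underlying frame is indexed by sample id with columns ``time``
    (nonnegative, in the declared unit), ``event`` (0/1) and any of
    ``age``, ``sex``, ``t_stage``, ``n_stage``, ``m_stage``, ``stage``,
    ``subtype``.  Samples with missing time or event are retained but
    flagged ineligible; survival analyses only ever see eligible rows.
    """

    def __init__(self, frame: pd.DataFrame, time_unit: str = "years"):
        if "time" not in frame.columns or "event" not in frame.columns:
            raise ValueError("clinical table needs 'time' and 'event' columns")
        if frame.index.duplicated().any():
            raise ValueError("duplicate sample ids in clinical table")
        if time_unit not in ("years", "months", "days"):
            raise ValueError(f"unknown time unit {time_unit!r}")
        frame = frame.copy()
        eligible = frame["time"].notna() & frame["event"].notna()
        ok = frame.loc[eligible]
        if (ok["time"] < 0).any():
            raise ValueError("negative survival time")
        if not set(ok["event"].unique()) <= {0, 1}:
            raise ValueError("event indicator must be 0/1")
        frame["eligible"] = eligible
        if "subtype" in frame.columns:
            bad = set(frame["subtype"].dropna()) - set(SUBTYPE_LEVELS)
            if bad:
                raise ValueError(f"unknown subtype labels: {sorted(bad)}")
        self.frame = frame
        self.time_unit = time_unit

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def eligible(self) -> pd.DataFrame:
        """Rows with observed time and event, time/event coerced to float/int."""
        f = self.frame.loc[self.frame["eligible"]].copy()
        f["time"] = f["time"].astype(float)
        f["event"] = f["event"].astype(int)
        return f

    def times_in_years(self) -> pd.Series:
        """Eligible survival times converted to years for ROC horizons."""
        scale = {"years": 1.0, "months": 1.0 / 12.0, "days": 1.0 / 365.25}[self.time_unit]
        return self.eligible()["time"] * scale

    def subset(self, samples) -> "ClinicalTable":
        return ClinicalTable(self.frame.loc[list(samples)].drop(columns=["eligible"]),
                             self.time_unit)


def survival_arrays(clin: ClinicalTable, samples=None):
    """(time, event) float/bool arrays for the given samples (eligible only)."""
    f = clin.eligible()
    if samples is not None:
        samples = [s for s in samples if s in f.index]
        f = f.loc[samples]
    return f["time"].to_numpy(float), f["event"].to_numpy(bool), list(f.index)
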