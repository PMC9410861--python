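"""Binary lncRNA-pair indicators — the signature's normalization-free statistic.

For every unordered pair {A, B} of DEirlncRNAs (oriented so A precedes B
in lexicographic gene-id order) and every sample, the indicator is

    S(A, B; sample) = 1  if expr(A, sample) > expr(B, sample) else 0

(ties score 0).  S depends only on the within-sample ordering of the two
genes, so it is invariant to any strictly increasing per-sample transform
of the expression values — the property that makes the pair statistic
robust to normalization and unit choices.

A skew filter then drops near-constant pairs: a pair is retained only if
its one-frequency lies strictly between ``q_min`` and ``1 - q_min``
(default 0.2, i.e. both indicator values occur in more than 20% of
samples).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .containers import ExpressionMatrix

log = logging.getLogger(__name__)

PAIR_SEP = "|"


def pair_label(a: str, b: str) -> str:
    return f"{a}{PAIR_SEP}{b}"


def split_pair_label(label: str) -> tuple[str, str]:
    a, b = label.split(PAIR_SEP)
    return a, b


def _indicator_block(values: np.ndarray, genes: list[str]):
    """All C(D,2) canonical pair indicators from a gene x sample array."""
    order = np.argsort(np.asarray(genes, dtype=object))
    genes_sorted = [genes[i] for i in order]
    V = values[order]
    ai, bi = np.triu_indices(len(genes_sorted), k=1)
    S = (V[ai] > V[bi]).astype(np.int8)
    labels = [pair_label(genes_sorted[i], genes_sorted[j]) for i, j in zip(ai, bi)]
    return S, labels


@dataclass
class PairIndicatorMatrix:
    """Pair x sample binary indicator matrix with per-pair one-frequencies."""

    indicator: pd.DataFrame  # index "A|B", columns samples, values 0/1

    def __post_init__(self) -> None:
        arr = self.indicator.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("pair indicators must be 0/1")
        if self.indicator.index.duplicated().any():
            raise ValueError("duplicate pair labels")

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return [split_pair_label(l) for l in self.indicator.index]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.indicator.columns)

    @property
    def one_frequency(self) -> pd.Series:
        return self.indicator.mean(axis=1).rename("one_frequency")

    def to_feature_frame(self) -> pd.DataFrame:
        """Samples x pairs orientation for model fitting."""
        return self.indicator.T

    def write(self, path, summary_path=None) -> None:
        self.indicator.to_csv(path, sep="\t", index_label="pair")
        if summary_path is not None:
            self.one_frequency.to_frame().to_csv(summary_path, sep="\t",
                                                 index_label="pair")


def build_pair_matrix(expr: ExpressionMatrix, genes) -> PairIndicatorMatrix:
    """Emit all C(D,2) candidate pair indicators for the given genes.

    Genes are oriented canonically (lexicographic id order picks the
    "former" member); ties in expression score 0.  Missing genes are a
    hard error.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError(f"need >= 2 genes to form pairs, got {len(genes)}")
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene ids in pair gene list")
    missing = [g for g in genes if g not in set(expr.gene_ids)]
    if missing:
        raise ValueError(f"genes absent from expression matrix: {missing[:5]}")
    V = expr.values.loc[genes].to_numpy()
    n_ties = 0
    S, labels = _indicator_block(V, genes)
    # count exact ties for the log: positions where neither strictly greater
    order = np.argsort(np.asarray(genes, dtype=object))
    Vs = V[order]
    ai, bi = np.triu_indices(len(genes), k=1)
    n_ties = int((Vs[ai] == Vs[bi]).sum())
    if n_ties:
        log.info("%d exact expression ties scored as 0", n_ties)
    ind = pd.DataFrame(S, index=pd.Index(labels, name="pair"),
                       columns=expr.sample_ids)
    return PairIndicatorMatrix(ind)


def skew_filter(pm: PairIndicatorMatrix, q_min: float = 0.2) -> PairIndicatorMatrix:
    """Retain pairs with q_min < one_frequency < 1 - q_min (strict).

    Idempotent; preserves pair order.  An empty result is allowed and
    logged, not an error.
    """
    if not 0.0 < q_min < 0.5:
        raise ValueError(f"q_min must be in (0, 0.5), got {q_min}")
    f = pm.one_frequency
    keep = (f > q_min) & (f < 1.0 - q_min)
    if not keep.any():
        log.warning("skew filter removed every pair (q_min=%g)", q_min)
    return PairIndicatorMatrix(pm.indicator.loc[keep[keep].index])


class PairIndicator(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer from expression features to pair indicators.

    Works on the sklearn orientation (samples x genes).  ``fit`` decides
    which pairs survive the skew filter on the training samples; ``transform``
    emits the binary indicator for exactly those pairs, so train-time pair
    selection is honored on new cohorts.

    Parameters
    ----------
    q_min : float, default=0.2
        Skew-filter bound; pairs kept iff q_min < one-frequency < 1 - q_min
        on the training data.  Set ``filter_skewed=False`` to keep all pairs.
    filter_skewed : bool, default=True
    """

    def __init__(self, q_min: float = 0.2, filter_skewed: bool = True):
        self.q_min = q_min
        self.filter_skewed = filter_skewed

    def fit(self, X: pd.DataFrame, y=None) -> "PairIndicator":
        if not isinstance(X, pd.DataFrame):
            raise TypeError("PairIndicator expects a samples x genes DataFrame")
        genes = list(X.columns)
        if len(genes) < 2:
            raise ValueError("need >= 2 gene columns")
        S, labels = _indicator_block(X.to_numpy().T, genes)
        freq = S.mean(axis=1)
        if self.filter_skewed:
            if not 0.0 < self.q_min < 0.5:
                raise ValueError(f"q_min must be in (0, 0.5), got {self.q_min}")
            keep = (freq > self.q_min) & (freq < 1.0 - self.q_min)
        else:
            keep = np.ones(len(labels), dtype=bool)
        self.feature_names_in_ = np.asarray(genes, dtype=object)
        self.pair_labels_ = [l for l, k in zip(labels, keep) if k]
        self.one_frequency_ = pd.Series(freq[keep], index=self.pair_labels_,
                                        name="one_frequency")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "pair_labels_")
        out = np.empty((len(X), len(self.pair_labels_)), dtype=np.int8)
        for j, label in enumerate(self.pair_labels_):
            a, b = split_pair_label(label)
            out[:, j] = (X[a].to_numpy() > X[b].to_numpy()).astype(np.int8)
        return pd.DataFrame(out, index=X.index, columns=self.pair_labels_)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "pair_labels_")
        return np.asarray(self.pair_labels_, dtype=object)
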