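"""Reference-gene-based normalization and fold-change DE calling.

Validated reference (housekeeping) genes are turned into per-sample
normalization factors — the geometric mean of the reference genes'
expression in each sample — and every gene's expression is divided by its
sample's factor.  Differential expression between two condition groups is
then the ratio of normalized group means, called up/down at a strict
fold-change threshold (default 2).  A concordance summary compares such
calls against an external DE table (e.g. a count-based pipeline's output).

Exposed as functions over the io containers and as the
:class:`ReferenceNormalizer` scikit-learn transformer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from stableref.io import ExpressionMatrix, SampleDesign

logger = logging.getLogger("stableref")

__all__ = [
    "NormalizationFactors",
    "DECallSet",
    "ConcordanceSummary",
    "normalization_factors",
    "normalize_matrix",
    "relative_de",
    "de_calls_from_table",
    "concordance",
    "ReferenceNormalizer",
]


@dataclass
class NormalizationFactors:
    """Per-sample geometric-mean expression of the chosen reference genes."""

    factors: pd.Series
    hk_ids: list[str]

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("normalization factors must be positive")


@dataclass
class DECallSet:
    """Per-gene fold change and up/down/ns call under one normalization."""

    table: pd.DataFrame  # columns: fc, log2fc, call
    method_label: str = "hk_norm"
    fc_threshold: float = 2.0

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.table.index]

    def calls(self) -> pd.Series:
        return self.table["call"]


@dataclass
class ConcordanceSummary:
    n_same_call: int
    n_same_direction_diff_magnitude: int
    n_discordant: int
    per_gene: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_total(self) -> int:
        return (
            self.n_same_call
            + self.n_same_direction_diff_magnitude
            + self.n_discordant
        )


def normalization_factors(
    matrix: ExpressionMatrix, hk_ids: list[str]
) -> NormalizationFactors:
    """Geometric mean of the reference genes' expression, per sample."""
    missing = [g for g in hk_ids if g not in set(matrix.transcript_ids)]
    if missing:
        raise ValueError(f"reference genes absent from the matrix: {missing}")
    if not hk_ids:
        raise ValueError("at least one reference gene is required")
    sub = matrix.values.loc[hk_ids]
    zero = sub <= 0
    if zero.any().any():
        g, s = np.argwhere(zero.to_numpy())[0]
        raise ValueError(
            f"reference gene {hk_ids[g]!r} is not expressed in sample "
            f"{sub.columns[s]!r}; normalization factor undefined"
        )
    if len(hk_ids) == 1:  # exact identity for a single reference
        factors = sub.iloc[0].rename("factor")
    else:
        factors = pd.Series(
            sps.gmean(sub.to_numpy(dtype=float), axis=0),
            index=sub.columns,
            name="factor",
        )
    return NormalizationFactors(factors, list(hk_ids))


def normalize_matrix(
    matrix: ExpressionMatrix, factors: NormalizationFactors
) -> pd.DataFrame:
    """Divide every sample column by its normalization factor."""
    return matrix.values.div(factors.factors, axis=1)


def relative_de(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    hk_ids: list[str],
    treat: str,
    control: str,
    fc_threshold: float = 2.0,
    group_mean: str = "arithmetic",
    method_label: str | None = None,
) -> DECallSet:
    """Fold-change DE between two groups after reference-gene normalization.

    ``fc = mean(normalized treat) / mean(normalized control)`` per gene;
    calls are ``up`` iff fc strictly exceeds ``fc_threshold``, ``down`` iff
    fc is strictly below ``1/fc_threshold``, else ``ns``.  Genes with a zero
    control mean get an undefined fc (NaN) and an ``ns`` call, logged —
    trace expression cannot support a ratio.
    """
    treat_samples = [s for s in design.samples_in(treat) if s in matrix.sample_ids]
    ctrl_samples = [s for s in design.samples_in(control) if s in matrix.sample_ids]
    if not treat_samples or not ctrl_samples:
        raise ValueError("both groups must contain samples present in the matrix")
    factors = normalization_factors(matrix, hk_ids)
    norm = normalize_matrix(matrix, factors)

    def agg(frame: pd.DataFrame) -> pd.Series:
        if group_mean == "arithmetic":
            return frame.mean(axis=1)
        if group_mean == "geometric":
            return pd.Series(
                sps.gmean(frame.to_numpy(dtype=float), axis=1), index=frame.index
            )
        raise ValueError(f"unknown group_mean {group_mean!r}")

    t_mean = agg(norm[treat_samples])
    c_mean = agg(norm[ctrl_samples])
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = t_mean / c_mean
    undefined = c_mean == 0
    if undefined.any():
        for g in norm.index[undefined]:
            logger.warning(
                "gene %s: control group mean is zero; fold change undefined", g
            )
    fc = fc.where(~undefined, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(fc)
    call = pd.Series("ns", index=norm.index)
    call[fc > fc_threshold] = "up"
    call[fc < 1.0 / fc_threshold] = "down"
    table = pd.DataFrame({"fc": fc, "log2fc": log2fc, "call": call})
    return DECallSet(
        table,
        method_label=method_label or f"hk_norm({','.join(hk_ids)})",
        fc_threshold=fc_threshold,
    )


def de_calls_from_table(
    table: pd.DataFrame,
    fc_threshold: float = 2.0,
    method_label: str = "external",
    significant_col: str | None = None,
) -> DECallSet:
    """Build a DECallSet from an external DE table.

    ``table`` must be indexed by gene and carry ``log2fc`` or ``fc``.  When
    ``significant_col`` is given, genes flagged non-significant are forced
    to ``ns`` regardless of their fold change.
    """
    if "fc" in table.columns:
        fc = table["fc"].astype(float)
    elif "log2fc" in table.columns:
        fc = np.exp2(table["log2fc"].astype(float))
    else:
        raise ValueError("external DE table needs an 'fc' or 'log2fc' column")
    call = pd.Series("ns", index=table.index)
    call[fc > fc_threshold] = "up"
    call[fc < 1.0 / fc_threshold] = "down"
    if significant_col is not None:
        flag = table[significant_col].astype(bool)
        call[~flag] = "ns"
    out = pd.DataFrame({"fc": fc, "log2fc": np.log2(fc), "call": call})
    return DECallSet(out, method_label=method_label, fc_threshold=fc_threshold)


def concordance(a: DECallSet, b: DECallSet) -> ConcordanceSummary:
    """Per-gene agreement of two DE call sets.

    Categories: identical call; differing call but not opposite direction
    (e.g. one ``up``, the other ``ns``) — same direction, different
    magnitude; opposite calls (``up`` vs ``down``) — discordant.  The three
    counts partition the shared gene universe.
    """
    if set(a.gene_ids) != set(b.gene_ids):
        raise ValueError("DE call sets cover different gene universes")
    genes = a.gene_ids
    ca = a.table["call"]
    cb = b.table["call"].reindex(genes)
    rows = []
    for g in genes:
        x, y = ca[g], cb[g]
        if x == y:
            cat = "same_call"
        elif {x, y} == {"up", "down"}:
            cat = "discordant"
        else:
            cat = "same_direction_diff_magnitude"
        rows.append(
            {
                "gene": g,
                "call_a": x,
                "call_b": y,
                "log2fc_a": a.table.at[g, "log2fc"],
                "log2fc_b": b.table.at[g, "log2fc"],
                "category": cat,
            }
        )
    per_gene = pd.DataFrame(rows).set_index("gene")
    counts = per_gene["category"].value_counts()
    return ConcordanceSummary(
        n_same_call=int(counts.get("same_call", 0)),
        n_same_direction_diff_magnitude=int(
            counts.get("same_direction_diff_magnitude", 0)
        ),
        n_discordant=int(counts.get("discordant", 0)),
        per_gene=per_gene,
    )


class ReferenceNormalizer(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer dividing samples by reference-gene factors.

    ``X`` is a samples × genes frame.  ``fit`` computes each sample's factor
    (geometric mean of the ``reference_genes`` columns); ``transform``
    divides every gene's value by its sample's factor.  Because the factor
    is recomputed per sample, the transform is invariant to rescaling any
    sample row — the defining property of between-sample normalization by
    internal controls.
    """

    def __init__(self, reference_genes: list[str] | None = None):
        self.reference_genes = reference_genes

    def fit(self, X, y=None):
        frame = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        if not self.reference_genes:
            raise ValueError("reference_genes must be a non-empty list")
        self.feature_names_in_ = np.asarray(frame.columns, dtype=object)
        self.n_features_in_ = frame.shape[1]
        self.factors_ = self._factors(frame)
        return self

    def _factors(self, frame: pd.DataFrame) -> pd.Series:
        missing = [g for g in self.reference_genes if g not in frame.columns]
        if missing:
            raise ValueError(f"reference genes absent from X: {missing}")
        sub = frame[self.reference_genes]
        if (sub <= 0).any().any():
            raise ValueError("reference genes must be positive in every sample")
        return pd.Series(
            sps.gmean(sub.to_numpy(dtype=float), axis=1),
            index=frame.index,
            name="factor",
        )

    def transform(self, X):
        check_is_fitted(self, "factors_")
        frame = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        factors = self._factors(frame)  # stateless across batches by design
        return frame.div(factors, axis=0)
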