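"""Genome-wide expression-stability screening.

Candidate reference (housekeeping) genes are mined from an RNA-seq
expression matrix with a filter cascade:

1. **constitutive** — detected (above a threshold, default 0) in every sample;
2. **MFC** (maximum fold change) = max/min over samples < 2;
3. **CV** of expression < 20 % *or* |CV| of log2 expression < 5 %;
4. for final recommendations: mean expression inside a 50–1,000 window and a
   unique isoform (one transcript per gene in the annotation).

The screen is exposed both as module functions over the io containers and as
the :class:`StabilityScreen` estimator (a scikit-learn feature selector over
a samples × transcripts frame).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from stableref.io import ExpressionMatrix, IsoformIndex

logger = logging.getLogger("stableref")

__all__ = [
    "ScreenConfig",
    "ScreenSummary",
    "transcript_stats",
    "select_stable",
    "recommend_references",
    "top_overlap",
    "partition_by_expression",
    "StabilityScreen",
]

STATS_COLUMNS = [
    "mean", "sd", "cv_pct", "log_mean", "log_cv_abs_pct", "mfc",
    "constitutive", "n_samples_expressed",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the stability filter cascade.

    ``cv_max``/``logcv_max`` are percentages; ``mfc_max`` a fold change;
    ``expr_min``/``expr_max`` bound the mean expression window used by
    :func:`recommend_references` (FPKM-scale units).
    """

    cv_max: float = 20.0
    mfc_max: float = 2.0
    logcv_max: float = 5.0
    expr_min: float = 50.0
    expr_max: float = 1000.0
    require_unique_isoform: bool = True
    detect_threshold: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.expr_min < self.expr_max):
            raise ValueError("need 0 < expr_min < expr_max")
        if self.cv_max <= 0:
            raise ValueError("cv_max must be positive")

    def relaxed(self) -> "ScreenConfig":
        """The relaxed preset: CV < 30 % instead of 20 %."""
        return replace(self, cv_max=30.0)

    def narrow_window(self) -> "ScreenConfig":
        """Expression window 100–1,000 instead of 50–1,000."""
        return replace(self, expr_min=100.0)


@dataclass(frozen=True)
class ScreenSummary:
    """Counts and percentage fields of a screening run."""

    n_total: int
    n_constitutive: int
    n_stable: int

    @property
    def pct_constitutive(self) -> float:
        return round(100.0 * self.n_constitutive / self.n_total, 2)

    @property
    def pct_stable(self) -> float:
        return round(100.0 * self.n_stable / self.n_total, 2)


def transcript_stats(
    matrix: ExpressionMatrix,
    detect_threshold: float = 0.0,
    ddof: int = 1,
    log_base: float = 2.0,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Per-transcript stability descriptives.

    Returns a frame indexed by transcript id with columns ``mean``, ``sd``
    (sample SD, ``ddof`` defaulting to n−1), ``cv_pct`` (100·sd/mean),
    ``log_mean``/``log_cv_abs_pct`` (on log2 values; only for constitutive
    transcripts), ``mfc`` (max/min over samples; NaN when any sample is at or
    below the detection threshold), ``constitutive`` and
    ``n_samples_expressed``.
    """
    v = matrix.values
    if v.shape[1] < 2:
        raise ValueError("stability statistics need at least two samples")
    arr = v.to_numpy(dtype=float) + pseudocount
    mean = arr.mean(axis=1)
    sd = arr.std(axis=1, ddof=ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, 100.0 * sd / mean, np.nan)
    expressed = arr > detect_threshold
    n_expr = expressed.sum(axis=1)
    constitutive = n_expr == arr.shape[1]
    mfc = np.full(arr.shape[0], np.nan)
    log_mean = np.full(arr.shape[0], np.nan)
    log_cv = np.full(arr.shape[0], np.nan)
    if constitutive.any():
        sub = arr[constitutive]
        mfc[constitutive] = sub.max(axis=1) / sub.min(axis=1)
        logs = np.log(sub) / math.log(log_base)
        lm = logs.mean(axis=1)
        ls = logs.std(axis=1, ddof=ddof)
        log_mean[constitutive] = lm
        with np.errstate(divide="ignore", invalid="ignore"):
            log_cv[constitutive] = np.abs(
                np.where(lm != 0, 100.0 * ls / lm, np.inf)
            )
    out = pd.DataFrame(
        {
            "mean": mean,
            "sd": sd,
            "cv_pct": cv,
            "log_mean": log_mean,
            "log_cv_abs_pct": log_cv,
            "mfc": mfc,
            "constitutive": constitutive,
            "n_samples_expressed": n_expr,
        },
        index=v.index,
    )
    return out


def select_stable(
    stats: pd.DataFrame, config: ScreenConfig | None = None
) -> tuple[list[str], pd.DataFrame]:
    """Apply the constitutive + MFC + (CV or log-CV) filter.

    A transcript is kept iff it is constitutive, its MFC is below
    ``mfc_max``, and either its CV is below ``cv_max`` or the absolute CV of
    its log expression is below ``logcv_max``.  Returns the kept ids (input
    order) and a per-transcript ledger with ``passed`` and ``pass_clause``
    (``"cv"``, ``"logcv"`` — whichever clause admitted it, CV first — or
    ``""``).
    """
    config = config or ScreenConfig()
    cv_ok = stats["cv_pct"] < config.cv_max
    logcv_ok = stats["log_cv_abs_pct"] < config.logcv_max
    base = stats["constitutive"] & (stats["mfc"] < config.mfc_max)
    passed = base & (cv_ok | logcv_ok)
    clause = np.where(
        passed & cv_ok, "cv", np.where(passed & logcv_ok, "logcv", "")
    )
    ledger = pd.DataFrame(
        {"passed": passed.fillna(False), "pass_clause": clause}, index=stats.index
    )
    kept = [str(t) for t in stats.index[ledger["passed"]]]
    return kept, ledger


def recommend_references(
    stats: pd.DataFrame,
    config: ScreenConfig | None = None,
    index: IsoformIndex | None = None,
) -> pd.DataFrame:
    """Ranked reference-gene recommendations.

    Applies :func:`select_stable`, then the mean-expression window
    (``expr_min`` ≤ mean ≤ ``expr_max``) and, when
    ``require_unique_isoform``, the one-transcript-per-gene filter.  Sorted
    ascending by CV, ties broken by transcript id.
    """
    config = config or ScreenConfig()
    kept, _ = select_stable(stats, config)
    sub = stats.loc[kept]
    in_window = (sub["mean"] >= config.expr_min) & (sub["mean"] <= config.expr_max)
    sub = sub[in_window]
    if config.require_unique_isoform:
        if index is None:
            raise ValueError(
                "an IsoformIndex is required when require_unique_isoform is set"
            )
        counts = {}
        keep_rows = []
        for t in sub.index:
            c = index.count_for_transcript(str(t))
            if c is None:
                logger.warning(
                    "transcript %s has no isoform annotation; excluded from "
                    "recommendations", t,
                )
                continue
            if c == 1:
                keep_rows.append(t)
            counts[t] = c
        sub = sub.loc[keep_rows]
        sub = sub.assign(isoform_count=[counts[t] for t in sub.index])
    order = sorted(sub.index, key=lambda t: (sub.at[t, "cv_pct"], str(t)))
    return sub.loc[order]


def top_overlap(stats_a: pd.Series, stats_b: pd.Series, n: int) -> float:
    """Fraction of transcripts shared by the top-*n* of two stability metrics.

    Top-*n* means the *n* smallest metric values; ties are broken by
    transcript id so the sets are deterministic.
    """
    if set(stats_a.index) != set(stats_b.index):
        raise ValueError("metrics must cover the same transcript universe")
    if not 0 < n <= len(stats_a):
        raise ValueError(f"n={n} outside the universe size {len(stats_a)}")

    def top(s: pd.Series) -> set[str]:
        order = sorted(s.index, key=lambda t: (s[t], str(t)))
        return {str(t) for t in order[:n]}

    return len(top(stats_a) & top(stats_b)) / n


def partition_by_expression(
    stats: pd.DataFrame, cutoff: float = 1.0
) -> tuple[list[str], list[str]]:
    """Split transcripts into low (mean < cutoff) and high expression sets."""
    low = stats.index[stats["mean"] < cutoff]
    high = stats.index[stats["mean"] >= cutoff]
    return [str(t) for t in low], [str(t) for t in high]


class StabilityScreen(SelectorMixin, BaseEstimator):
    """Scikit-learn feature selector keeping stably expressed transcripts.

    ``X`` is a samples × transcripts frame (or array).  ``fit`` computes
    per-transcript stability descriptives; ``get_support``/``transform``
    select the transcripts passing the constitutive + MFC + (CV | log-CV)
    filter.  Recommendations (expression window + isoform uniqueness) are
    available through :meth:`recommend`.

    Parameters mirror :class:`ScreenConfig`; ``sd_ddof`` chooses the SD
    denominator (1 → n−1 sample SD) and ``log_base`` the logarithm of the
    log-CV clause.

    Attributes
    ----------
    stats_ : pandas.DataFrame
        Per-transcript descriptives (see :func:`transcript_stats`).
    ledger_ : pandas.DataFrame
        Per-transcript ``passed`` / ``pass_clause``.
    summary_ : ScreenSummary
        Total / constitutive / stable counts with percentage fields.
    """

    def __init__(
        self,
        cv_max: float = 20.0,
        mfc_max: float = 2.0,
        logcv_max: float = 5.0,
        expr_min: float = 50.0,
        expr_max: float = 1000.0,
        require_unique_isoform: bool = True,
        detect_threshold: float = 0.0,
        sd_ddof: int = 1,
        log_base: float = 2.0,
        pseudocount: float = 0.0,
    ):
        self.cv_max = cv_max
        self.mfc_max = mfc_max
        self.logcv_max = logcv_max
        self.expr_min = expr_min
        self.expr_max = expr_max
        self.require_unique_isoform = require_unique_isoform
        self.detect_threshold = detect_threshold
        self.sd_ddof = sd_ddof
        self.log_base = log_base
        self.pseudocount = pseudocount

    def _config(self) -> ScreenConfig:
        return ScreenConfig(
            cv_max=self.cv_max,
            mfc_max=self.mfc_max,
            logcv_max=self.logcv_max,
            expr_min=self.expr_min,
            expr_max=self.expr_max,
            require_unique_isoform=self.require_unique_isoform,
            detect_threshold=self.detect_threshold,
        )

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            frame = X
        else:
            X = np.asarray(X, dtype=float)
            frame = pd.DataFrame(
                X, columns=[f"t{i}" for i in range(X.shape[1])]
            )
        self.feature_names_in_ = np.asarray(frame.columns, dtype=object)
        self.n_features_in_ = frame.shape[1]
        matrix = ExpressionMatrix(frame.T)
        self.stats_ = transcript_stats(
            matrix,
            detect_threshold=self.detect_threshold,
            ddof=self.sd_ddof,
            log_base=self.log_base,
            pseudocount=self.pseudocount,
        )
        kept, self.ledger_ = select_stable(self.stats_, self._config())
        self.selected_ids_ = kept
        self.summary_ = ScreenSummary(
            n_total=int(self.stats_.shape[0]),
            n_constitutive=int(self.stats_["constitutive"].sum()),
            n_stable=len(kept),
        )
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "ledger_")
        return self.ledger_["passed"].to_numpy(dtype=bool)

    def recommend(self, index: IsoformIndex | None = None) -> pd.DataFrame:
        check_is_fitted(self, "stats_")
        return recommend_references(self.stats_, self._config(), index)
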