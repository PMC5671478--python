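"""RT-qPCR reference-gene stability analysis.

Implements the four standard stability algorithms on a panel of candidate
genes assayed by RT-qPCR, plus their geometric-mean consensus and the
pairwise-variation analysis of the optimal number of reference genes:

* **geNorm** — average pairwise variation *M* of a gene's log2 expression
  ratios against every other candidate, with stepwise exclusion of the least
  stable gene, and the pairwise-variation curve V(n/n+1) that decides how
  many reference genes are worth using (cutoff 0.15).
* **comparative ΔCt** — mean, over all partner genes, of the SD of pairwise
  Cq differences across samples.
* **BestKeeper** — per-gene Cq dispersion (mean absolute deviation from the
  arithmetic mean, as in the classic spreadsheet tool; sample SD optional)
  plus the BestKeeper index (per-sample geometric mean Cq) and each gene's
  Pearson correlation with it.
* **NormFinder** — model-based decomposition of a gene's variation into
  intra-group variance and shrunken inter-group bias.

Every method yields a stability value per gene (lower = more stable) and a
strict ordinal ranking (ties broken by gene id); the consensus is the
geometric mean of the four ranks, as popularised by the RefFinder tool.

Two surfaces are provided: plain functions over :class:`~stableref.io.CqMatrix`
(:func:`genorm`, :func:`delta_ct`, :func:`bestkeeper`, :func:`normfinder`,
:func:`consensus_rank`) and scikit-learn estimators over samples × genes
frames (:class:`GeNorm`, :class:`DeltaCt`, :class:`BestKeeper`,
:class:`NormFinder`, :class:`ConsensusRanker`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from stableref.io import CqMatrix, SampleDesign

logger = logging.getLogger("stableref")

__all__ = [
    "QcRule",
    "RelativeQuantityMatrix",
    "MethodStability",
    "GeNormResult",
    "BestKeeperResult",
    "ConsensusRanking",
    "qc_candidates",
    "cq_descriptives",
    "relative_quantities",
    "genorm",
    "delta_ct",
    "bestkeeper",
    "normfinder",
    "consensus_rank",
    "rank_geomean",
    "evaluate_panel",
    "GeNorm",
    "DeltaCt",
    "BestKeeper",
    "NormFinder",
    "ConsensusRanker",
]

V_CUTOFF_DEFAULT = 0.15


# ---------------------------------------------------------------------------
# QC and descriptives
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QcRule:
    """Assay acceptance rule: efficiency > 1.8, R² > 0.99, every Cq < 40."""

    min_efficiency: float = 1.8
    min_r2: float = 0.99
    max_cq: float = 40.0

    def __post_init__(self) -> None:
        if not 1.0 < self.min_efficiency <= 2.2:
            raise ValueError("min_efficiency must be in (1, 2.2]")
        if not 0.0 < self.min_r2 <= 1.0:
            raise ValueError("min_r2 must be in (0, 1]")


def qc_candidates(
    cq: CqMatrix, rule: QcRule | None = None
) -> tuple[list[str], pd.DataFrame]:
    """Filter candidate assays by efficiency, calibration R² and Cq ceiling.

    A gene passes iff its amplification efficiency exceeds
    ``rule.min_efficiency``, its calibration-curve R² exceeds
    ``rule.min_r2`` and every observed (non-missing) Cq is below
    ``rule.max_cq``.  A missing efficiency or R² fails QC with reason
    ``"missing"``.  Returns the passing gene ids (input order) and a ledger
    frame with ``passed`` plus a semicolon-joined ``reasons`` column.
    """
    rule = rule or QcRule()
    rows = []
    passing = []
    for g in cq.gene_ids:
        reasons = []
        eff = cq.efficiency_of.get(g)
        r2 = None if cq.r2_of is None else cq.r2_of.get(g)
        if eff is None:
            reasons.append("missing efficiency")
        elif eff <= rule.min_efficiency:
            reasons.append(f"efficiency {eff} <= {rule.min_efficiency}")
        if r2 is None:
            reasons.append("missing r2")
        elif r2 <= rule.min_r2:
            reasons.append(f"r2 {r2} <= {rule.min_r2}")
        row = cq.cq.loc[g]
        observed = row.dropna()
        if (observed >= rule.max_cq).any():
            reasons.append(f"Cq >= {rule.max_cq}")
        ok = not reasons
        if ok:
            passing.append(g)
        rows.append({"gene": g, "passed": ok, "reasons": ";".join(reasons)})
    ledger = pd.DataFrame(rows).set_index("gene")
    return passing, ledger


def cq_descriptives(cq: CqMatrix) -> pd.DataFrame:
    """Per-gene Cq descriptives: mean, SD (n−1), min, max, P25, P75, IQR.

    Percentiles use linear interpolation.  Genes with missing cells are
    skipped with a warning.
    """
    rows = {}
    for g in cq.gene_ids:
        row = cq.cq.loc[g]
        if row.isna().any():
            logger.warning("gene %s skipped in descriptives: missing Cq", g)
            continue
        x = row.to_numpy(dtype=float)
        p25, p75 = np.percentile(x, [25, 75])
        rows[g] = {
            "mean": x.mean(),
            "sd": x.std(ddof=1),
            "min": x.min(),
            "max": x.max(),
            "p25": p25,
            "p75": p75,
            "iqr": p75 - p25,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# relative quantities
# ---------------------------------------------------------------------------


@dataclass
class RelativeQuantityMatrix:
    """Genes × samples relative quantities in (0, 1].

    ``q[g, s] = E_g ** (min_s' Cq[g, s'] − Cq[g, s])`` — the sample with a
    gene's minimum Cq (highest expression) gets q = 1.
    """

    q: pd.DataFrame
    efficiency_used: dict[str, float] = field(default_factory=dict)

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.q.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.q.columns]


def relative_quantities(cq: CqMatrix) -> RelativeQuantityMatrix:
    """Transform a complete Cq grid to efficiency-corrected quantities."""
    complete = cq.drop_incomplete()
    if complete.cq.empty:
        raise ValueError("no complete Cq rows to transform")
    eff_used = {g: complete.efficiency(g) for g in complete.gene_ids}
    for g, e in eff_used.items():
        if e <= 1.0:
            raise ValueError(f"efficiency of {g!r} must exceed 1, got {e}")
    arr = complete.cq.to_numpy(dtype=float)
    e = np.array([eff_used[g] for g in complete.gene_ids])[:, None]
    q = e ** (arr.min(axis=1, keepdims=True) - arr)
    return RelativeQuantityMatrix(
        pd.DataFrame(q, index=complete.cq.index, columns=complete.cq.columns),
        efficiency_used=eff_used,
    )


# ---------------------------------------------------------------------------
# stability containers
# ---------------------------------------------------------------------------


def _ordinal_ranks(value_of: dict[str, float]) -> dict[str, int]:
    """Strict ordinal ranks ascending by (value, gene id)."""
    order = sorted(value_of, key=lambda g: (value_of[g], str(g)))
    return {g: i + 1 for i, g in enumerate(order)}


@dataclass
class MethodStability:
    """Per-gene stability values and strict ordinal ranks of one method."""

    method: str
    value_of: dict[str, float]
    rank_of: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rank_of:
            self.rank_of = _ordinal_ranks(self.value_of)
        k = len(self.value_of)
        if sorted(self.rank_of.values()) != list(range(1, k + 1)):
            raise ValueError(f"{self.method}: ranks are not a permutation of 1..{k}")

    def as_series(self) -> pd.Series:
        return pd.Series(self.value_of, name=self.method)


@dataclass
class GeNormResult:
    """Outcome of the stepwise geNorm analysis."""

    m_at_exclusion: dict[str, float]
    exclusion_order: list[str]
    ranking: list[str]
    v_curve: dict[int, float]
    optimal_n: int
    v_flag: str = ""
    full_panel_m: dict[str, float] = field(default_factory=dict)

    def as_method_stability(self) -> MethodStability:
        rank_of = {g: i + 1 for i, g in enumerate(self.ranking)}
        return MethodStability("genorm", dict(self.m_at_exclusion), rank_of)


@dataclass
class BestKeeperResult:
    stability: MethodStability
    index: pd.Series | None
    corr_of: dict[str, float]
    inconsistent: list[str]


@dataclass
class ConsensusRanking:
    """Geometric-mean aggregation of per-method ordinal ranks."""

    geomean_of: dict[str, float]
    final_rank_of: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.final_rank_of:
            self.final_rank_of = _ordinal_ranks(self.geomean_of)


# ---------------------------------------------------------------------------
# geNorm
# ---------------------------------------------------------------------------


def _pairwise_v(logq: pd.DataFrame) -> pd.DataFrame:
    """V[j, k] = sample SD over columns of (logq_j − logq_k)."""
    genes = list(logq.index)
    arr = logq.to_numpy(dtype=float)
    k = len(genes)
    V = np.zeros((k, k))
    for j in range(k):
        diff = arr[j][None, :] - arr
        V[j] = diff.std(axis=1, ddof=1)
    return pd.DataFrame(V, index=genes, columns=genes)


def genorm(
    q: RelativeQuantityMatrix, v_cutoff: float = V_CUTOFF_DEFAULT
) -> GeNormResult:
    """Stepwise geNorm stability analysis.

    ``M_j`` is the mean, over the other genes in the current set, of the
    sample SD of log2 expression ratios.  The gene with the highest *M* is
    removed (ties: lexicographically last id first, so a fully degenerate
    zero-variance panel ranks by id), its *M* at removal recorded, until two
    genes remain; the final pair shares the final *M*.  The V-curve compares
    normalization factors built from the *n* vs *n+1* best genes; the optimal
    number of reference genes is the smallest *n* with V(n/n+1) below
    ``v_cutoff``.
    """
    genes = q.gene_ids
    if len(genes) < 3:
        raise ValueError("geNorm needs at least 3 genes")
    if q.q.shape[1] < 2:
        raise ValueError("geNorm needs at least 2 samples")
    logq = pd.DataFrame(
        np.log2(q.q.to_numpy(dtype=float)), index=q.q.index, columns=q.q.columns
    )
    V = _pairwise_v(logq)

    current = list(genes)
    m_at: dict[str, float] = {}
    exclusion: list[str] = []
    full_panel_m = {
        g: float(V.loc[g, [h for h in genes if h != g]].mean()) for g in genes
    }
    while len(current) > 2:
        m = {
            g: float(V.loc[g, [h for h in current if h != g]].mean())
            for g in current
        }
        worst = max(current, key=lambda g: (m[g], str(g)))
        m_at[worst] = m[worst]
        exclusion.append(worst)
        current.remove(worst)
    a, b = sorted(current)
    final_m = float(V.loc[a, b])
    m_at[a] = final_m
    m_at[b] = final_m
    ranking = [a, b] + list(reversed(exclusion))

    # V-curve: normalization factors from the n best-ranked genes
    v_curve: dict[int, float] = {}
    k = len(genes)
    for n in range(2, k):
        nf_n = logq.loc[ranking[:n]].mean(axis=0)
        nf_n1 = logq.loc[ranking[: n + 1]].mean(axis=0)
        v_curve[n] = float((nf_n - nf_n1).std(ddof=1))
    below = [n for n, v in v_curve.items() if v < v_cutoff]
    if len(below) == len(v_curve):
        optimal_n, flag = 2, "all-below"
    elif not below:
        optimal_n, flag = 2, "none-below"
    else:
        optimal_n, flag = min(below), ""
    return GeNormResult(
        m_at_exclusion=m_at,
        exclusion_order=exclusion,
        ranking=ranking,
        v_curve=v_curve,
        optimal_n=optimal_n,
        v_flag=flag,
        full_panel_m=full_panel_m,
    )


# ---------------------------------------------------------------------------
# comparative delta-Ct
# ---------------------------------------------------------------------------


def delta_ct(cq: CqMatrix) -> MethodStability:
    """Mean over partner genes of the SD of pairwise Cq differences."""
    complete = cq.drop_incomplete()
    genes = complete.gene_ids
    if len(genes) < 2:
        raise ValueError("delta-Ct needs at least 2 complete genes")
    arr = complete.cq.to_numpy(dtype=float)
    k = len(genes)
    sds = np.zeros((k, k))
    for j in range(k):
        sds[j] = (arr[j][None, :] - arr).std(axis=1, ddof=1)
    values = {
        genes[j]: float(np.delete(sds[j], j).mean()) for j in range(k)
    }
    return MethodStability("delta_ct", values)


# ---------------------------------------------------------------------------
# BestKeeper
# ---------------------------------------------------------------------------


def bestkeeper(cq: CqMatrix, use_sd: bool = False) -> BestKeeperResult:
    """BestKeeper dispersion, index and index correlations.

    Dispersion is the mean absolute deviation of a gene's Cq from its
    arithmetic mean (the classic tool's "SD [±CP]"); pass ``use_sd=True``
    for the n−1 sample SD instead.  The BestKeeper index is the per-sample
    geometric mean of Cq across genes; each gene's Pearson correlation with
    it is reported but not used for ranking.  Genes with dispersion > 1
    cycle are flagged inconsistent.
    """
    complete = cq.drop_incomplete()
    genes = complete.gene_ids
    if not genes:
        raise ValueError("no complete genes for BestKeeper")
    arr = complete.cq.to_numpy(dtype=float)
    centred = arr - arr.mean(axis=1, keepdims=True)
    if use_sd:
        disp = arr.std(axis=1, ddof=1)
    else:
        disp = np.abs(centred).mean(axis=1)
    values = {g: float(d) for g, d in zip(genes, disp)}
    stability = MethodStability("bestkeeper", values)
    index = None
    corr: dict[str, float] = {}
    if len(genes) >= 2:
        index = pd.Series(
            sps.gmean(arr, axis=0), index=complete.cq.columns, name="bestkeeper_index"
        )
        for j, g in enumerate(genes):
            if np.allclose(arr[j], arr[j][0]) or np.allclose(index, index.iloc[0]):
                corr[g] = np.nan
            else:
                corr[g] = float(sps.pearsonr(arr[j], index.to_numpy())[0])
    inconsistent = [g for g, d in values.items() if d > 1.0]
    return BestKeeperResult(stability, index, corr, inconsistent)


# ---------------------------------------------------------------------------
# NormFinder
# ---------------------------------------------------------------------------


def _normfinder_decomposition(
    x: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-group variance decomposition on a k × n expression block.

    Returns (sigma2, d): the floored intra-group variance estimate per gene
    and the per-gene mean of sample-centred expression.
    """
    k, n = x.shape
    if k < 3:
        raise ValueError("NormFinder needs at least 3 genes")
    if n < 2:
        raise ValueError("NormFinder needs at least 2 samples per group")
    z = x - x.mean(axis=0, keepdims=True)
    v = z.var(axis=1, ddof=1)
    sigma2 = np.maximum(0.0, (v - v.sum() / (k * (k - 1))) * k / (k - 2))
    d = z.mean(axis=1)
    return sigma2, d


def normfinder(
    cq: CqMatrix,
    design: SampleDesign | None = None,
    use_groups: bool = True,
) -> MethodStability:
    """Model-based stability from intra-group variance and inter-group bias.

    Works on ``x = −Cq`` (one cycle = one doubling on the log2 scale).  With
    groups, each gene's stability is the mean over groups of
    ``|shrunken bias| + sqrt(intra-group variance / n_g)``; without groups it
    is the square root of the single-group variance estimate.
    """
    complete = cq.drop_incomplete()
    genes = complete.gene_ids
    if len(genes) < 3:
        raise ValueError("NormFinder needs at least 3 genes")
    x = -complete.cq.to_numpy(dtype=float)
    samples = complete.sample_ids

    if not use_groups or design is None:
        sigma2, _ = _normfinder_decomposition(x)
        values = {g: float(np.sqrt(s2)) for g, s2 in zip(genes, sigma2)}
        return MethodStability("normfinder", values)

    groups = [g for g in design.groups if set(design.samples_in(g)) & set(samples)]
    if len(groups) < 2:
        raise ValueError("NormFinder with groups needs at least 2 groups")
    cols = {s: i for i, s in enumerate(samples)}
    sigma2 = np.zeros((len(genes), len(groups)))
    d = np.zeros((len(genes), len(groups)))
    n_per = np.zeros(len(groups))
    for gi, grp in enumerate(groups):
        idx = [cols[s] for s in design.samples_in(grp) if s in cols]
        if len(idx) < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 samples")
        n_per[gi] = len(idx)
        sigma2[:, gi], d[:, gi] = _normfinder_decomposition(x[:, idx])

    G = len(groups)
    d_bar = d.mean(axis=1, keepdims=True)
    dev = d - d_bar
    gamma2 = max(
        0.0,
        float((dev**2).mean() * G / (G - 1) - (sigma2 / n_per[None, :]).mean()),
    )
    noise = sigma2 / n_per[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        shrink = np.where(gamma2 + noise > 0, gamma2 / (gamma2 + noise), 0.0)
    b = dev * shrink
    rho = (np.abs(b) + np.sqrt(noise)).mean(axis=1)
    values = {g: float(r) for g, r in zip(genes, rho)}
    return MethodStability("normfinder", values)


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------


def rank_geomean(ranks) -> float:
    """Geometric mean of a sequence of (positive) ordinal ranks."""
    r = np.asarray(list(ranks), dtype=float)
    if (r <= 0).any():
        raise ValueError("ranks must be positive")
    return float(np.exp(np.log(r).mean()))


def consensus_rank(results) -> ConsensusRanking:
    """Aggregate per-method rankings by the geometric mean of ranks.

    ``results`` is an iterable of :class:`MethodStability` objects or plain
    ``{gene: rank}`` mappings (e.g. ranks transcribed from a published
    report, where ties may share a rank).  All methods must cover the same
    gene set.  Final ranks are ordinal on the geomean, ties broken by id.
    """
    rank_maps = []
    for r in results:
        rank_maps.append(r.rank_of if isinstance(r, MethodStability) else dict(r))
    if not rank_maps:
        raise ValueError("no method results supplied")
    universe = set(rank_maps[0])
    for rm in rank_maps[1:]:
        if set(rm) != universe:
            missing = universe.symmetric_difference(rm)
            raise ValueError(f"methods disagree on gene universe: {sorted(missing)}")
    geomean = {
        g: rank_geomean([rm[g] for rm in rank_maps]) for g in rank_maps[0]
    }
    return ConsensusRanking(geomean)


def evaluate_panel(
    cq: CqMatrix,
    design: SampleDesign | None = None,
    use_groups: bool = True,
    bestkeeper_sd: bool = False,
    v_cutoff: float = V_CUTOFF_DEFAULT,
) -> tuple[pd.DataFrame, GeNormResult]:
    """Run all four stability methods plus consensus on one Cq panel.

    Returns a report frame with one row per gene — per-method stability
    values and ranks, consensus geomean and final rank — and the full
    :class:`GeNormResult` (V-curve, optimal reference-gene number).
    """
    complete = cq.drop_incomplete()
    bk = bestkeeper(complete, use_sd=bestkeeper_sd)
    dct = delta_ct(complete)
    gn = genorm(relative_quantities(complete), v_cutoff=v_cutoff)
    gn_ms = gn.as_method_stability()
    nf = normfinder(complete, design=design, use_groups=use_groups and design is not None)
    consensus = consensus_rank([bk.stability, dct, gn_ms, nf])
    genes = complete.gene_ids
    report = pd.DataFrame(
        {
            "bestkeeper_value": [bk.stability.value_of[g] for g in genes],
            "bestkeeper_rank": [bk.stability.rank_of[g] for g in genes],
            "deltact_value": [dct.value_of[g] for g in genes],
            "deltact_rank": [dct.rank_of[g] for g in genes],
            "genorm_value": [gn_ms.value_of[g] for g in genes],
            "genorm_rank": [gn_ms.rank_of[g] for g in genes],
            "normfinder_value": [nf.value_of[g] for g in genes],
            "normfinder_rank": [nf.rank_of[g] for g in genes],
            "geomean": [consensus.geomean_of[g] for g in genes],
            "final_rank": [consensus.final_rank_of[g] for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    return report.sort_values("final_rank"), gn


# ---------------------------------------------------------------------------
# scikit-learn estimators
# ---------------------------------------------------------------------------


def _frame_from_X(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"g{i}" for i in range(X.shape[1])])


class _CqStabilityEstimator(BaseEstimator):
    """Shared fit plumbing: X is a samples × genes frame of Cq values.

    Fitted attributes: ``stability_`` (Series of per-gene values, lower =
    better) and ``ranking_`` (Series of strict ordinal ranks).
    """

    def __init__(self, efficiencies: dict[str, float] | None = None):
        self.efficiencies = efficiencies

    def _to_cq(self, X) -> CqMatrix:
        frame = _frame_from_X(X)
        self.feature_names_in_ = np.asarray(frame.columns, dtype=object)
        self.n_features_in_ = frame.shape[1]
        return CqMatrix(frame.T, efficiency_of=dict(self.efficiencies or {}))

    def _finalize(self, ms: MethodStability):
        self.stability_ = pd.Series(ms.value_of, name=ms.method)
        self.ranking_ = pd.Series(ms.rank_of, name=f"{ms.method}_rank")
        self.method_stability_ = ms
        return self

    def fit(self, X, y=None):  # pragma: no cover - overridden
        raise NotImplementedError


class GeNorm(_CqStabilityEstimator):
    """geNorm stepwise stability estimator.

    Additional fitted attributes: ``result_`` (the full
    :class:`GeNormResult`), ``v_curve_`` and ``optimal_n_``.
    """

    def __init__(self, efficiencies=None, v_cutoff: float = V_CUTOFF_DEFAULT):
        super().__init__(efficiencies)
        self.v_cutoff = v_cutoff

    def fit(self, X, y=None):
        cq = self._to_cq(X)
        self.result_ = genorm(relative_quantities(cq), v_cutoff=self.v_cutoff)
        self.v_curve_ = dict(self.result_.v_curve)
        self.optimal_n_ = self.result_.optimal_n
        return self._finalize(self.result_.as_method_stability())


class DeltaCt(_CqStabilityEstimator):
    """Comparative ΔCt stability estimator."""

    def fit(self, X, y=None):
        return self._finalize(delta_ct(self._to_cq(X)))


class BestKeeper(_CqStabilityEstimator):
    """BestKeeper dispersion estimator.

    Additional fitted attributes: ``index_`` (per-sample geometric-mean Cq)
    and ``index_corr_`` (per-gene Pearson r against the index).
    """

    def __init__(self, efficiencies=None, use_sd: bool = False):
        super().__init__(efficiencies)
        self.use_sd = use_sd

    def fit(self, X, y=None):
        res = bestkeeper(self._to_cq(X), use_sd=self.use_sd)
        self.index_ = res.index
        self.index_corr_ = pd.Series(res.corr_of, name="index_corr")
        self.inconsistent_ = list(res.inconsistent)
        return self._finalize(res.stability)


class NormFinder(_CqStabilityEstimator):
    """NormFinder model-based stability estimator.

    ``y`` (group labels per sample) enables the grouped decomposition; with
    ``y=None`` the single-group variance estimate is used.
    """

    def fit(self, X, y=None):
        cq = self._to_cq(X)
        design = None
        if y is not None:
            labels = list(np.asarray(y, dtype=object))
            if len(labels) != len(cq.sample_ids):
                raise ValueError("y must give one group label per sample")
            design = SampleDesign(dict(zip(cq.sample_ids, map(str, labels))))
        return self._finalize(
            normfinder(cq, design=design, use_groups=design is not None)
        )


class ConsensusRanker(BaseEstimator):
    """Fit all four stability methods and aggregate their ranks.

    Fitted attributes: ``report_`` (per-gene values/ranks of each method,
    geomean and final rank, best first), ``geomean_``, ``final_rank_``,
    ``genorm_result_``.
    """

    def __init__(
        self,
        efficiencies: dict[str, float] | None = None,
        use_groups: bool = True,
        bestkeeper_sd: bool = False,
        v_cutoff: float = V_CUTOFF_DEFAULT,
    ):
        self.efficiencies = efficiencies
        self.use_groups = use_groups
        self.bestkeeper_sd = bestkeeper_sd
        self.v_cutoff = v_cutoff

    def fit(self, X, y=None):
        frame = _frame_from_X(X)
        self.feature_names_in_ = np.asarray(frame.columns, dtype=object)
        self.n_features_in_ = frame.shape[1]
        cq = CqMatrix(frame.T, efficiency_of=dict(self.efficiencies or {}))
        design = None
        if y is not None and self.use_groups:
            design = SampleDesign(
                dict(zip(cq.sample_ids, map(str, np.asarray(y, dtype=object))))
            )
        self.report_, self.genorm_result_ = evaluate_panel(
            cq,
            design=design,
            use_groups=design is not None,
            bestkeeper_sd=self.bestkeeper_sd,
            v_cutoff=self.v_cutoff,
        )
        self.geomean_ = self.report_["geomean"]
        self.final_rank_ = self.report_["final_rank"]
        self.optimal_n_ = self.genorm_result_.optimal_n
        return self

    def top_genes(self, n: int = 2) -> list[str]:
        check_is_fitted(self, "report_")
        return [str(g) for g in self.report_.index[:n]]
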