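"""Unit and oracle tests for the RT-qPCR stability methods.

The geNorm and NormFinder oracles below are deliberately independent,
loop-level evaluations of each method's defining formulas (no shared code
with the implementation) so that agreement is meaningful.
"""

import math

import numpy as np
import pandas as pd
import pytest

from stableref import (
    BestKeeper,
    ConsensusRanker,
    CqMatrix,
    DeltaCt,
    GeNorm,
    NormFinder,
    QcRule,
    SampleDesign,
    bestkeeper,
    consensus_rank,
    cq_descriptives,
    delta_ct,
    evaluate_panel,
    genorm,
    normfinder,
    qc_candidates,
    rank_geomean,
    relative_quantities,
)
from tests.conftest import random_cq_frame

# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def _sd(xs):
    m = sum(xs) / len(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))


def genorm_oracle(cq_frame: pd.DataFrame, eff: float = 2.0):
    """Stepwise geNorm by direct recomputation of every pairwise SD."""
    genes = list(cq_frame.index)
    samples = list(cq_frame.columns)
    logq = {
        g: [
            math.log2(eff ** (min(cq_frame.loc[g]) - cq_frame.loc[g, s]))
            for s in samples
        ]
        for g in genes
    }

    def V(a, b):
        return _sd([logq[a][i] - logq[b][i] for i in range(len(samples))])

    current = list(genes)
    m_at, order = {}, []
    while len(current) > 2:
        m = {
            g: sum(V(g, h) for h in current if h != g) / (len(current) - 1)
            for g in current
        }
        worst = max(current, key=lambda g: (m[g], g))
        m_at[worst] = m[worst]
        order.append(worst)
        current.remove(worst)
    a, b = sorted(current)
    m_at[a] = m_at[b] = V(a, b)
    return m_at, order, [a, b] + order[::-1]


def normfinder_oracle(cq_frame: pd.DataFrame, groups: dict[str, list[str]]):
    """Grouped NormFinder stability by literal evaluation of the model."""
    genes = list(cq_frame.index)
    k, G = len(genes), len(groups)
    sigma2, d = {}, {}
    for grp, samples in groups.items():
        n = len(samples)
        x = {g: [-cq_frame.loc[g, s] for s in samples] for g in genes}
        z = {}
        for j in range(n):
            col_mean = sum(x[g][j] for g in genes) / k
            for g in genes:
                z.setdefault(g, []).append(x[g][j] - col_mean)
        v = {g: _sd(z[g]) ** 2 for g in genes}
        sum_v = sum(v.values())
        for g in genes:
            sigma2[(g, grp)] = max(
                0.0, (v[g] - sum_v / (k * (k - 1))) * k / (k - 2)
            )
            d[(g, grp)] = sum(z[g]) / n
    d_bar = {g: sum(d[(g, grp)] for grp in groups) / G for g in genes}
    mean_dev2 = sum(
        (d[(g, grp)] - d_bar[g]) ** 2 for g in genes for grp in groups
    ) / (k * G)
    mean_noise = sum(
        sigma2[(g, grp)] / len(groups[grp]) for g in genes for grp in groups
    ) / (k * G)
    gamma2 = max(0.0, mean_dev2 * G / (G - 1) - mean_noise)
    rho = {}
    for g in genes:
        parts = []
        for grp, samples in groups.items():
            noise = sigma2[(g, grp)] / len(samples)
            denom = gamma2 + noise
            b = (d[(g, grp)] - d_bar[g]) * (gamma2 / denom) if denom > 0 else 0.0
            parts.append(abs(b) + math.sqrt(noise))
        rho[g] = sum(parts) / G
    return rho


# ---------------------------------------------------------------------------
# QC and descriptives
# ---------------------------------------------------------------------------


class TestQc:
    def make(self, eff, r2, cq_vals=(25.0, 26.0)):
        return CqMatrix(
            pd.DataFrame({"s1": [cq_vals[0]], "s2": [cq_vals[1]]}, index=["g"]),
            efficiency_of={"g": eff},
            r2_of={"g": r2},
        )

    def test_low_efficiency_rejected(self):
        passing, ledger = qc_candidates(self.make(1.615, 0.993))
        assert passing == []
        assert "efficiency" in ledger.loc["g", "reasons"]

    def test_good_assay_passes(self):
        passing, _ = qc_candidates(self.make(1.931, 0.999))
        assert passing == ["g"]

    def test_cq_ceiling(self):
        passing, ledger = qc_candidates(self.make(1.9, 0.999, (25.0, 40.0)))
        assert passing == []
        assert "Cq" in ledger.loc["g", "reasons"]

    def test_missing_metadata_fails_with_reason(self):
        cq = CqMatrix(pd.DataFrame({"s1": [25.0]}, index=["g"]))
        passing, ledger = qc_candidates(cq, QcRule())
        assert passing == []
        assert "missing" in ledger.loc["g", "reasons"]


class TestDescriptives:
    def test_hand_computed(self):
        cq = CqMatrix(
            pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["g"],
                         columns=list("abcd"))
        )
        row = cq_descriptives(cq).loc["g"]
        assert row["sd"] == pytest.approx(1.29099, abs=1e-4)
        assert row["iqr"] == pytest.approx(1.5)
        assert (row["p25"], row["p75"]) == (1.75, 3.25)

    def test_constant_row(self):
        cq = CqMatrix(pd.DataFrame([[20.0] * 3], index=["g"],
                                   columns=list("abc")))
        row = cq_descriptives(cq).loc["g"]
        assert row["sd"] == 0.0 and row["iqr"] == 0.0

    def test_shift_invariance(self):
        cq1 = CqMatrix(pd.DataFrame([[20.0, 22.0, 21.0]], index=["g"],
                                    columns=list("abc")))
        cq2 = CqMatrix(cq1.cq + 5.0)
        r1, r2 = cq_descriptives(cq1).loc["g"], cq_descriptives(cq2).loc["g"]
        assert r1["sd"] == r2["sd"] and r1["iqr"] == r2["iqr"]


class TestRelativeQuantities:
    def test_minimum_cq_maps_to_one_and_formula(self):
        cq = CqMatrix(
            pd.DataFrame({"s1": [20.0], "s2": [21.0], "s3": [22.0]}, index=["g"]),
            efficiency_of={"g": 1.9},
        )
        q = relative_quantities(cq).q.loc["g"]
        assert q["s1"] == 1.0
        assert q["s2"] == pytest.approx(1.9 ** -1)
        assert q["s3"] == pytest.approx(0.27700831, abs=1e-6)

    def test_default_efficiency_halves_per_cycle(self):
        cq = CqMatrix(pd.DataFrame({"s1": [20.0], "s2": [21.0]}, index=["g"]))
        assert relative_quantities(cq).q.loc["g", "s2"] == 0.5


# ---------------------------------------------------------------------------
# the four methods
# ---------------------------------------------------------------------------


class TestGeNorm:
    def test_worked_three_gene_panel(self, abc_cq):
        res = genorm(relative_quantities(abc_cq))
        assert res.exclusion_order == ["C"]
        assert res.m_at_exclusion["C"] == pytest.approx(1.8257, abs=1e-4)
        assert res.m_at_exclusion["A"] == 0.0 and res.m_at_exclusion["B"] == 0.0
        assert res.ranking[:2] == ["A", "B"]

    def test_constant_factor_pair_has_zero_v(self, abc_cq):
        # A and B differ by exactly 2 cycles everywhere -> V_AB = 0
        res = genorm(relative_quantities(abc_cq))
        assert res.full_panel_m["A"] == res.full_panel_m["B"]

    def test_degenerate_panel_ranks_by_id(self):
        cq = CqMatrix(pd.DataFrame(np.full((4, 5), 25.0),
                                   index=["d", "b", "a", "c"],
                                   columns=[f"s{i}" for i in range(5)]))
        res = genorm(relative_quantities(cq))
        assert all(v == 0.0 for v in res.m_at_exclusion.values())
        assert res.ranking == ["a", "b", "c", "d"]

    def test_v_curve_all_below_cutoff_means_two_genes(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(18, 32, size=(5, 1))
        tight = pd.DataFrame(
            base + rng.normal(0, 0.01, size=(5, 8)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(8)],
        )
        res = genorm(relative_quantities(CqMatrix(tight)))
        assert res.optimal_n == 2
        assert res.v_flag == "all-below"

    def test_needs_three_genes(self):
        cq = CqMatrix(pd.DataFrame([[20.0, 21.0], [22.0, 23.0]],
                                   index=["A", "B"], columns=["s1", "s2"]))
        with pytest.raises(ValueError, match="3 genes"):
            genorm(relative_quantities(cq))

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_stepwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 7))
        frame = random_cq_frame(rng, k, 6)
        res = genorm(relative_quantities(CqMatrix(frame)))
        m_at, order, ranking = genorm_oracle(frame)
        assert res.exclusion_order == order
        assert res.ranking == ranking
        for g in frame.index:
            assert res.m_at_exclusion[g] == pytest.approx(m_at[g], abs=1e-9)


class TestDeltaCt:
    def test_parallel_profiles_give_zero(self):
        cq = CqMatrix(pd.DataFrame([[20.0, 21.0, 22.0], [25.0, 26.0, 27.0]],
                                   index=["A", "B"], columns=list("xyz")))
        res = delta_ct(cq)
        assert res.value_of["A"] == 0.0 and res.value_of["B"] == 0.0

    def test_worked_three_gene_panel(self, abc_cq):
        res = delta_ct(abc_cq)
        assert res.value_of["A"] == pytest.approx(0.91287, abs=1e-4)

    def test_shift_invariance(self, abc_cq):
        shifted = CqMatrix(
            abc_cq.cq.add(pd.Series({"A": 3.0, "B": 0.0, "C": -1.0}), axis=0)
        )
        r1, r2 = delta_ct(abc_cq), delta_ct(shifted)
        for g in "ABC":
            assert r1.value_of[g] == pytest.approx(r2.value_of[g], abs=1e-12)


class TestBestKeeper:
    def test_mad_hand_values(self):
        cq = CqMatrix(pd.DataFrame([[20.0, 22.0], [20.0, 22.0]],
                                   index=["X", "Y"], columns=["s1", "s2"]))
        assert bestkeeper(cq).stability.value_of["X"] == 1.0
        cq3 = CqMatrix(pd.DataFrame([[20.0, 22.0, 21.0], [20.0, 21.0, 22.0]],
                                    index=["X", "Y"], columns=list("abc")))
        assert bestkeeper(cq3).stability.value_of["X"] == pytest.approx(2 / 3)

    def test_sd_mode(self):
        cq = pd.DataFrame([[20.0, 22.0, 21.0], [25.0, 25.0, 25.0]],
                          index=["X", "Y"], columns=list("abc"))
        res = bestkeeper(CqMatrix(cq), use_sd=True)
        assert res.stability.value_of["X"] == pytest.approx(1.0)

    def test_gene_tracking_index_has_corr_one(self):
        rng = np.random.default_rng(1)
        base = rng.normal(25, 1, 8)
        cq = CqMatrix(pd.DataFrame([base, base],
                                   index=["X", "Y"],
                                   columns=[f"s{i}" for i in range(8)]))
        res = bestkeeper(cq)
        assert res.corr_of["X"] == pytest.approx(1.0, abs=1e-9)

    def test_dispersion_above_one_flagged(self):
        cq = CqMatrix(pd.DataFrame([[20.0, 24.0, 20.0, 24.0],
                                    [25.0, 25.1, 25.0, 25.1]],
                                   index=["bad", "good"], columns=list("abcd")))
        res = bestkeeper(cq)
        assert res.inconsistent == ["bad"]


class TestNormFinder:
    def grouped(self, frame):
        s = list(frame.columns)
        half = len(s) // 2
        design = SampleDesign({x: ("G1" if i < half else "G2")
                               for i, x in enumerate(s)})
        return design, {"G1": s[:half], "G2": s[half:]}

    def test_constant_panel_is_perfectly_stable(self):
        frame = pd.DataFrame(np.full((4, 6), 25.0),
                             index=list("abcd"),
                             columns=[f"s{i}" for i in range(6)])
        design, _ = self.grouped(frame)
        res = normfinder(CqMatrix(frame), design)
        assert all(v == 0.0 for v in res.value_of.values())

    def test_per_gene_shift_invariance(self):
        rng = np.random.default_rng(5)
        frame = random_cq_frame(rng, 4, 6)
        design, _ = self.grouped(frame)
        shifted = frame + rng.normal(0, 3, size=(4, 1))
        r1 = normfinder(CqMatrix(frame), design)
        r2 = normfinder(CqMatrix(shifted), design)
        for g in frame.index:
            assert r1.value_of[g] == pytest.approx(r2.value_of[g], abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 7))
        frame = random_cq_frame(rng, k, 6)
        design, groups = self.grouped(frame)
        res = normfinder(CqMatrix(frame), design)
        rho = normfinder_oracle(frame, groups)
        for g in frame.index:
            assert res.value_of[g] == pytest.approx(rho[g], abs=1e-9)

    def test_needs_three_genes(self):
        frame = pd.DataFrame([[20.0, 21.0], [22.0, 23.0]],
                             index=["A", "B"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="3 genes"):
            normfinder(CqMatrix(frame), None, use_groups=False)


class TestConsensus:
    @pytest.mark.parametrize(
        "ranks,expected",
        [((2, 1, 7, 1), 1.9343), ((1, 1, 1, 1), 1.0), ((3, 4, 5, 4), 3.9360)],
    )
    def test_rank_geomean(self, ranks, expected):
        assert rank_geomean(ranks) == pytest.approx(expected, abs=1e-4)

    def test_consensus_bounds_and_unanimity(self):
        ranks_a = {"x": 1, "y": 2, "z": 3}
        cr = consensus_rank([ranks_a, ranks_a, ranks_a])
        assert cr.geomean_of["x"] == 1.0
        assert cr.final_rank_of == {"x": 1, "y": 2, "z": 3}
        assert all(1.0 <= v <= 3.0 + 1e-12 for v in cr.geomean_of.values())

    def test_universe_mismatch_errors(self):
        with pytest.raises(ValueError, match="universe"):
            consensus_rank([{"x": 1, "y": 2}, {"x": 1, "z": 2}])


# ---------------------------------------------------------------------------
# cross-method invariants and estimator surface
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("seed", range(5))
def test_per_gene_shift_leaves_all_methods_unchanged(seed):
    """Assay-specific Cq offsets (primer chemistry) must not affect stability."""
    rng = np.random.default_rng(seed)
    frame = random_cq_frame(rng, 5, 8)
    shifts = rng.normal(0, 4, size=(5, 1))
    design = SampleDesign({s: ("G1" if i < 4 else "G2")
                           for i, s in enumerate(frame.columns)})
    for f in (
        lambda x: delta_ct(CqMatrix(x)).value_of,
        lambda x: bestkeeper(CqMatrix(x)).stability.value_of,
        lambda x: genorm(relative_quantities(CqMatrix(x))).m_at_exclusion,
        lambda x: normfinder(CqMatrix(x), design).value_of,
    ):
        before, after = f(frame), f(frame + shifts)
        for g in frame.index:
            assert before[g] == pytest.approx(after[g], abs=1e-9)


@pytest.mark.parametrize("seed", range(5))
def test_full_panel_genorm_m_equals_delta_ct(seed):
    """With perfect doubling both reduce to mean pairwise SD of Cq differences."""
    rng = np.random.default_rng(seed)
    frame = random_cq_frame(rng, int(rng.integers(3, 9)), 8)
    gn = genorm(relative_quantities(CqMatrix(frame)))
    dc = delta_ct(CqMatrix(frame))
    for g in frame.index:
        assert gn.full_panel_m[g] == pytest.approx(dc.value_of[g], abs=1e-9)


def test_sample_permutation_invariance():
    rng = np.random.default_rng(11)
    frame = random_cq_frame(rng, 5, 8)
    perm = list(rng.permutation(frame.columns))
    for f in (
        lambda x: delta_ct(CqMatrix(x)).value_of,
        lambda x: bestkeeper(CqMatrix(x)).stability.value_of,
        lambda x: genorm(relative_quantities(CqMatrix(x))).m_at_exclusion,
    ):
        before, after = f(frame), f(frame[perm])
        for g in frame.index:
            assert before[g] == pytest.approx(after[g], abs=1e-12)


def test_estimators_fit_on_samples_by_genes_frame(abc_cq):
    X = abc_cq.cq.T  # samples × genes, sklearn orientation
    for est in (GeNorm(), DeltaCt(), BestKeeper()):
        est.fit(X)
        assert set(est.stability_.index) == {"A", "B", "C"}
        assert sorted(est.ranking_) == [1, 2, 3]
    nf = NormFinder().fit(X, y=["G1", "G1", "G2", "G2"])
    assert set(nf.stability_.index) == {"A", "B", "C"}
    gn = GeNorm().fit(X)
    assert gn.optimal_n_ >= 2 and set(gn.v_curve_) == {2}


def test_consensus_ranker_matches_evaluate_panel(abc_cq):
    X = abc_cq.cq.T
    cr = ConsensusRanker(use_groups=False).fit(X)
    report, gn = evaluate_panel(abc_cq)
    pd.testing.assert_frame_equal(cr.report_, report)
    assert cr.top_genes(2) == list(report.index[:2])
    assert cr.get_params()["use_groups"] is False
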