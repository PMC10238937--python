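"""Per-taxon contribution decomposition, driver selection, Fisher independence."""

import numpy as np
import pandas as pd
import pytest

import phycosplit as ps
from phycosplit.attribution import ContributionSet, bonferroni_cutoff
from phycosplit.compositional import ClrMatrix
from phycosplit.ordination import PcaModel


def toy_model():
    """Two replicates of a three-taxon community at rounds 2 and 10."""
    taxa = ["t1", "t2", "t3"]
    # per sample columns sum to zero (valid CLR)
    values = pd.DataFrame(
        {
            "r1_s": [1.0, 0.0, -1.0],   # rep 1, round 2
            "r1_e": [0.0, 0.0, 0.0],    # rep 1, round 10
            "r2_s": [1.0, 0.0, -1.0],
            "r2_e": [0.0, 0.0, 0.0],
        },
        index=taxa,
    )
    samples = pd.DataFrame(
        {
            "soil": "B",
            "treatment": "hybrid",
            "growth_period_days": 12,
            "round": [2, 10, 2, 10],
            "replicate": [1, 1, 2, 2],
        },
        index=values.columns,
    )
    clr = ClrMatrix(values, pseudocount=1.0, samples=samples)
    loadings = pd.DataFrame([[0.0, 0.6, 0.8]], index=["PC1"], columns=taxa)
    pca = PcaModel(
        loadings=loadings,
        scores=pd.DataFrame(np.zeros((4, 1)), index=values.columns, columns=["PC1"]),
        eigenvalues=np.array([1.0]),
        variance_fractions=np.array([1.0]),
        feature_means=pd.Series(0.0, index=taxa),
    )
    return pca, clr


class TestTaxonContributions:
    def test_zero_loading_and_zero_change_give_zero(self):
        pca, clr = toy_model()
        c = ps.taxon_contributions(pca, clr, axis=1, soil="B", treatment="hybrid")
        # t1 changes but has zero loading; t2 has loading but no change
        assert c.medians["t1"] == 0.0
        assert c.medians["t2"] == 0.0
        assert c.medians["t3"] == pytest.approx(0.8)
        assert c.displacements.tolist() == pytest.approx([0.8, 0.8])

    def test_axis_sign_flip_invariance(self, pca, clr):
        c1 = ps.taxon_contributions(
            pca, clr, axis=2, soil="B", treatment="hybrid", growth_period_days=12
        )
        flipped = PcaModel(
            loadings=-pca.loadings,
            scores=-pca.scores,
            eigenvalues=pca.eigenvalues,
            variance_fractions=pca.variance_fractions,
            feature_means=pca.feature_means,
        )
        c2 = ps.taxon_contributions(
            flipped, clr, axis=2, soil="B", treatment="hybrid", growth_period_days=12
        )
        pd.testing.assert_series_equal(c1.medians, c2.medians)

    def test_abs_contributions_bound_displacement(self, pca, clr):
        """Triangle inequality: the sign-free contributions of a replicate sum
        to at least its projection displacement."""
        c = ps.taxon_contributions(
            pca, clr, axis=2, soil="B", treatment="hybrid", growth_period_days=12
        )
        sums = c.contributions.abs().sum(axis=0)
        for rep in c.displacements.index:
            assert sums[rep] >= c.displacements[rep] - 1e-9

    def test_missing_round_reported(self, pca, clr):
        with pytest.raises(ValueError, match="missing round"):
            ps.taxon_contributions(
                pca, clr, axis=2, round_start=2, round_end=99,
                soil="B", treatment="hybrid", growth_period_days=12,
            )


def fake_contrib(medians: pd.Series) -> ContributionSet:
    reps = pd.DataFrame({"rep1": medians})
    return ContributionSet(
        axis=2, group={}, contributions=reps, medians=medians,
        abs_medians=medians.abs(), displacements=pd.Series([0.0], index=["rep1"]),
        orientation=1, round_start=2, round_end=10,
    )


class TestSelectDrivers:
    def test_percentile_arithmetic(self):
        m = pd.Series(np.arange(1000.0), index=[f"t{i}" for i in range(1000)])
        sel = ps.select_drivers(fake_contrib(m), percentile=97.5)
        assert len(sel.selected) == 25

    def test_all_equal_selects_nothing(self):
        m = pd.Series(1.0, index=[f"t{i}" for i in range(100)])
        sel = ps.select_drivers(fake_contrib(m))
        assert sel.selected == set()

    def test_few_taxa_warns(self):
        m = pd.Series(np.arange(10.0), index=[f"t{i}" for i in range(10)])
        with pytest.warns(UserWarning):
            ps.select_drivers(fake_contrib(m))

    def test_planted_suppressed_taxa_recovered(self, pca, clr, truth):
        """>= 80% of planted algae-suppressed taxa become PC2 drivers for
        tau12 soil-B hybrids."""
        c = ps.taxon_contributions(
            pca, clr, axis=2, soil="B", treatment="hybrid", growth_period_days=12
        )
        sel = ps.select_drivers(c, percentile=97.5)
        planted = set(truth.suppressed_set)
        assert len(sel.selected & planted) / len(planted) >= 0.8


class TestSelectionOverlap:
    def test_identical_and_disjoint(self):
        assert ps.selection_overlap({"a", "b"}, {"a", "b"})["percent_in_common"] == 100.0
        assert ps.selection_overlap({"a"}, {"b"})["percent_in_common"] == 0.0

    def test_both_empty_undefined(self):
        rep = ps.selection_overlap(set(), set())
        assert rep["percent_in_common"] is None


class TestIndependenceTest:
    def test_three_vs_three_split_p(self):
        """Community table [[3,0],[0,3]] has two-sided Fisher p = 0.1."""
        hyb = [{"x"}, {"x"}, {"x"}]
        ctl = [set(), set(), set()]
        res, cutoff, sig = ps.selection_independence_test({"x"}, hyb, ctl)
        assert res.loc["x", "p_value"] == pytest.approx(0.1)
        assert cutoff == pytest.approx(0.05)
        assert sig == set()

    def test_degenerate_margin_flagged(self):
        hyb = [{"y"}, {"y"}]
        ctl = [{"y"}, {"y"}]
        res, _, _ = ps.selection_independence_test({"y"}, hyb, ctl)
        assert res.loc["y", "degenerate"]
        assert res.loc["y", "p_value"] == 1.0

    def test_bonferroni_cutoffs(self):
        assert bonferroni_cutoff(0.05, 77) == pytest.approx(0.000649, abs=5e-7)
        assert bonferroni_cutoff(0.05, 721) == pytest.approx(6.94e-5, rel=1e-3)

    def test_requires_both_treatments(self):
        with pytest.raises(ValueError):
            ps.selection_independence_test({"x"}, [], [{"x"}])
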