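"""Compositional preprocessing: closure, rare-taxon filter, CLR, Shannon."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import phycosplit as ps
from conftest import make_table, meta


class TestRelativeAbundance:
    def test_closure(self, tiny_table):
        rel = ps.relative_abundance(tiny_table)
        assert np.allclose(rel.sum(axis=0), 1.0)
        assert np.allclose(rel["s1"], [0.5, 0.5, 0.0])
        assert np.allclose(rel["s2"], [0.75, 0.25, 0.0])

    def test_zero_total_sample_named(self):
        t = make_table(np.array([[0, 1], [0, 1]]), [meta("empty"), meta("ok", rep=2)])
        with pytest.raises(ValueError, match="empty"):
            ps.relative_abundance(t)


class TestRareTaxa:
    def test_cutoff_matches_printed_value(self):
        assert round(float(np.exp(-8.2)), 5) == 0.00027

    def test_retained_and_dropped(self):
        # t3 max rel abundance 1e-4 < exp(-8.2); t2 at 1e-3 retained
        n = 10_000
        counts = np.array([[n - 11, n], [10, 0], [1, 0]])
        t = make_table(counts, [meta("a"), meta("b", rep=2)])
        filt, dropped = ps.remove_rare_taxa(t)
        assert dropped == ["t3"]
        assert list(filt.taxon_ids) == ["t1", "t2"]

    def test_boundary_exactly_at_cutoff_retained(self):
        frac = float(np.exp(-8.2))
        n = 1_000_000
        k = int(round(frac * n))
        counts = np.array([[n - k], [k]])
        t = make_table(counts, [meta("a")])
        rel = ps.relative_abundance(t).iloc[1, 0]
        assert rel >= frac  # taxon sits at/above the threshold
        filt, dropped = ps.remove_rare_taxa(t)
        assert dropped == []

    def test_idempotent(self, table):
        once, dropped1 = ps.remove_rare_taxa(table)
        twice, dropped2 = ps.remove_rare_taxa(once)
        assert dropped2 == []
        pd.testing.assert_frame_equal(once.counts, twice.counts)

    def test_all_dropped_errors(self):
        t = make_table(np.array([[1], [1]]), [meta("a")])
        with pytest.raises(ValueError):
            ps.remove_rare_taxa(t, log_threshold=10.0)


class TestClr:
    def test_uniform_counts_map_to_zero(self):
        t = make_table(np.ones((4, 1), dtype=int), [meta("a")])
        clr = ps.clr_transform(t)
        assert np.allclose(clr.values.to_numpy(), 0.0)

    def test_two_taxon_example(self):
        # counts (9, 0), pseudocount 1: ln(10/sqrt(10)) = 1.1513
        t = make_table(np.array([[9], [0]]), [meta("a")])
        clr = ps.clr_transform(t)
        assert np.allclose(clr.values["a"], [1.15129, -1.15129], atol=1e-5)

    def test_columns_sum_to_zero(self, clr):
        assert np.allclose(clr.values.sum(axis=0), 0.0, atol=1e-9)

    @settings(deadline=None, max_examples=25)
    @given(
        counts=st.lists(st.integers(0, 500), min_size=3, max_size=8),
        scale=st.integers(2, 50),
    )
    def test_scale_invariance_with_matched_pseudocount(self, counts, scale):
        """Scaling counts and pseudocount together leaves the CLR unchanged."""
        arr = np.array(counts)[:, None]
        t1 = make_table(arr, [meta("a")])
        t2 = make_table(arr * scale, [meta("a")])
        c1 = ps.clr_transform(t1, pseudocount=1.0)
        c2 = ps.clr_transform(t2, pseudocount=float(scale))
        assert np.allclose(c1.values.to_numpy(), c2.values.to_numpy(), atol=1e-10)

    def test_nonpositive_pseudocount_rejected(self, tiny_table):
        with pytest.raises(ValueError):
            ps.clr_transform(tiny_table, pseudocount=0.0)


class TestShannon:
    def test_single_taxon_zero(self):
        t = make_table(np.array([[5], [0]]), [meta("a")])
        assert ps.shannon_diversity(t)["a"] == 0.0

    def test_uniform_is_ln_n(self):
        for n in (2, 5, 17):
            t = make_table(np.full((n, 1), 7), [meta("a")])
            assert np.isclose(ps.shannon_diversity(t)["a"], np.log(n))

    def test_direct_summation_example(self):
        # p = (0.5, 0.25, 0.25) -> 1.0397
        t = make_table(np.array([[2], [1], [1]]), [meta("a")])
        assert np.isclose(ps.shannon_diversity(t)["a"], 1.0397, atol=1e-4)

    def test_matches_scipy_entropy(self, tiny_table):
        rel = ps.relative_abundance(tiny_table)
        ours = ps.shannon_diversity(tiny_table)
        for sid in tiny_table.sample_ids:
            assert np.isclose(ours[sid], stats.entropy(rel[sid].to_numpy()))

    @settings(deadline=None, max_examples=25)
    @given(counts=st.lists(st.integers(1, 100), min_size=2, max_size=10))
    def test_permutation_invariant_and_uniform_maximal(self, counts):
        arr = np.array(counts)[:, None]
        t = make_table(arr, [meta("a")])
        t_perm = make_table(arr[::-1], [meta("a")])
        h = ps.shannon_diversity(t)["a"]
        assert np.isclose(h, ps.shannon_diversity(t_perm)["a"])
        assert h <= np.log(len(counts)) + 1e-12


class TestCountTable:
    def test_duplicate_sample_ids_rejected(self):
        counts = pd.DataFrame(
            [[1, 2], [3, 4]], index=["t1", "t2"], columns=["s", "s"]
        )
        samples = pd.DataFrame([meta("s")]).set_index("sample_id")
        with pytest.raises(ValueError, match="duplicate"):
            ps.CountTable(counts, samples)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            make_table(np.array([[-1], [2]]), [meta("a")])

    def test_roundtrip_io(self, tiny_table, tmp_path):
        tiny_table.write(tmp_path / "c.tsv", tmp_path / "s.csv")
        back = ps.read_count_table(tmp_path / "c.tsv", tmp_path / "s.csv")
        pd.testing.assert_frame_equal(back.counts, tiny_table.counts, check_names=False)
        assert list(back.samples["soil"]) == list(tiny_table.samples["soil"])
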