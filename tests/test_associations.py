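import math

import numpy as np
import pandas as pd
import pytest

from somalex.associations import (
    attach_segment_means,
    cgc_enrichment,
    compare_absolute_segment_means,
    kruskal_wallis,
    log2_fold_change,
    rank_genes_by_mean_vrd,
    select_extremes,
    spearman,
    status_percentages,
)
from somalex.types import SomalexError, UndefinedValueError


class TestLog2FoldChange:
    @pytest.mark.parametrize(
        "t,n,expected", [(4, 1, 2.0), (1, 4, -2.0), (8, 8, 0.0)]
    )
    def test_values_at_vanishing_floor(self, t, n, expected):
        assert log2_fold_change(t, n, floor=1e-12) == pytest.approx(expected)

    def test_both_zero_is_missing(self):
        assert math.isnan(log2_fold_change(0.0, 0.0))

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            log2_fold_change(-1.0, 2.0)


class TestSpearman:
    def test_monotone_relationships(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman(x, [v**2 for v in x])[0] == pytest.approx(1.0)
        assert spearman(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_hand_computed_rank_example(self):
        # d = (1,-1,1,-1), sum d^2 = 4, rho = 1 - 6*4/(4*15) = 0.6
        rho, _ = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6)

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedValueError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestKruskalWallis:
    def test_identical_groups_have_zero_h(self):
        h, p = kruskal_wallis([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert h == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_two_group_example(self):
        # ranks 1..6, R1=6, R2=15 -> H = 12/42*(12+75) - 21 = 27/7
        h, _ = kruskal_wallis([[1, 2, 3], [10, 11, 12]])
        assert h == pytest.approx(27 / 7, abs=1e-9)

    def test_exchangeable_groups_are_insignificant(self):
        vals = [3.0, 1.0, 4.0, 1.5, 9.0]
        _, p = kruskal_wallis([vals, list(reversed(vals)), vals])
        assert p > 0.9

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(SomalexError):
            kruskal_wallis([[1, 2, 3]])


class TestExtremes:
    def _calls(self):
        return pd.DataFrame(
            {
                "gene": list("abcde"),
                "v_rd": [2.5, 2.5, 1.5, 3.0, 2.2],
                "log2fc": [1.5, -1.2, 3.0, 0.5, np.nan],
            }
        )

    def test_threshold_definitions(self):
        up, down = select_extremes(self._calls())
        assert list(up["gene"]) == ["a"]
        assert list(down["gene"]) == ["b"]

    def test_sets_disjoint_and_within_high_vrd(self):
        up, down = select_extremes(self._calls())
        assert set(up.index).isdisjoint(down.index)
        assert (up["v_rd"] > 2).all() and (down["v_rd"] > 2).all()


class TestGeneRanking:
    def test_min_mutation_threshold_and_ordering(self):
        calls = pd.DataFrame(
            {
                "gene": ["a"] * 3 + ["b"] * 2 + ["c"] * 3,
                "v_rd": [1.0, 2.0, 3.0, 9.0, 9.0, 4.0, 4.0, 4.0],
            }
        )
        ranked = rank_genes_by_mean_vrd(calls, min_mutations=3)
        assert list(ranked["gene"]) == ["c", "a"]  # b has only 2 mutations
        assert ranked.iloc[1]["mean_v_rd"] == pytest.approx(2.0)

    def test_ties_break_alphabetically(self):
        calls = pd.DataFrame(
            {"gene": ["z"] * 3 + ["a"] * 3, "v_rd": [1.0] * 6}
        )
        ranked = rank_genes_by_mean_vrd(calls, min_mutations=3)
        assert list(ranked["gene"]) == ["a", "z"]


class TestCgcEnrichment:
    def test_concentrated_selection_is_significant(self):
        cgc = {f"g{i}" for i in range(20)}
        background = {f"g{i}" for i in range(40)}  # half CGC
        chi2, p, table = cgc_enrichment(set(list(cgc)[:10]), background, cgc)
        assert p < 0.01
        assert table[0].tolist() == [10, 0]

    def test_proportional_selection_is_null(self):
        cgc = {f"g{i}" for i in range(20)}
        background = {f"g{i}" for i in range(40)}
        selected = {"g0", "g1", "g20", "g21"}  # same CGC share as background
        _, p, _ = cgc_enrichment(selected, background, cgc)
        assert p > 0.9

    def test_empty_selection_rejected(self):
        with pytest.raises(SomalexError):
            cgc_enrichment(set(), {"a"}, {"a"})

    def test_zero_margin_rejected(self):
        with pytest.raises(SomalexError):
            cgc_enrichment({"a"}, {"a", "b"}, set())


class TestSegmentComparison:
    def _data(self):
        calls = pd.DataFrame(
            {
                "sample_id": ["s1", "s1", "s2", "s2"],
                "chrom": ["chr1"] * 4,
                "pos": [100, 200, 100, 90_000],
                "group": ["A", "A", "B", "B"],
            }
        )
        segments = pd.DataFrame(
            {
                "sample_id": ["s1", "s2"],
                "chrom": ["chr1", "chr1"],
                "start": [1, 1],
                "end": [1000, 1000],
                "segment_mean": [0.1, -1.5],
            }
        )
        return calls, segments

    def test_join_and_unmatched_tally(self):
        calls, segments = self._data()
        joined, n_unmatched = attach_segment_means(calls, segments)
        assert n_unmatched == 1  # pos 90_000 overlaps no segment
        assert len(joined) == 3

    def test_absolute_means_compared_between_groups(self):
        calls, segments = self._data()
        joined, _ = attach_segment_means(calls, segments)
        out = compare_absolute_segment_means(joined, "group")
        by_group = out.set_index("group")
        assert by_group.loc["B", "median_abs_segment_mean"] == pytest.approx(1.5)
        assert by_group.loc["A", "median_abs_segment_mean"] == pytest.approx(0.1)


class TestStatusPercentages:
    def test_rounded_shares(self):
        pct = status_percentages(3, 5, 40)
        assert pct["SOM_E"] == 7.5
        assert pct["SOM_L"] == 12.5

    def test_counts_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            status_percentages(30, 30, 40)
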