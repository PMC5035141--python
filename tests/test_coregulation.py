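import math
from itertools import product
from math import comb

import pandas as pd
import pytest

from ppescreen.coregulation import (REGIONS, VennPartition,
                                    class_counts, classify_coregulation,
                                    coregulated_count, coregulation_summary,
                                    partition_de_sets, partition_from_counts,
                                    sets_from_partition,
                                    top_fraction_overlap_test)
from ppescreen.datasets import load_published_venn_counts

# published per-region counts of the screen's DE genes, per direction
PUBLISHED = {
    "up": {"S_only": 190, "E_only": 373, "C_only": 633, "SE_only": 25,
           "SC_only": 93, "EC_only": 53, "SEC": 57},
    "down": {"S_only": 233, "E_only": 187, "C_only": 440, "SE_only": 18,
             "SC_only": 37, "EC_only": 9, "SEC": 4},
}
PUBLISHED_MARGINALS = {"up": {"S": 365, "E": 508, "C": 836},
                       "down": {"S": 292, "E": 218, "C": 490}}


def published_partition(direction: str) -> VennPartition:
    return partition_from_counts(PUBLISHED[direction], direction)


class TestPartitionDeSets:
    def test_five_element_enumeration(self):
        part = partition_de_sets({"a", "b", "c"}, {"b", "c", "d"},
                                 {"c", "d", "e"})
        assert part.regions == {
            "S_only": {"a"}, "E_only": set(), "C_only": {"e"},
            "SE_only": {"b"}, "SC_only": set(), "EC_only": {"d"},
            "SEC": {"c"},
        }

    def test_empty_sets(self):
        part = partition_de_sets(set(), set(), set())
        assert all(not members for members in part.regions.values())

    def test_regions_disjoint_and_cover_union(self):
        s, e, c = {"a", "b", "x"}, {"b", "y", "x"}, {"c", "x", "y"}
        part = partition_de_sets(s, e, c)
        all_members = [g for members in part.regions.values() for g in members]
        assert len(all_members) == len(set(all_members))
        assert set(all_members) == s | e | c

    @pytest.mark.parametrize("direction", ["up", "down"])
    def test_published_regions_reproduce_marginals(self, direction):
        """Re-partitioning sets realising the published per-region counts
        yields the published per-group DE totals."""
        part = published_partition(direction)
        s, e, c = sets_from_partition(part)
        repartitioned = partition_de_sets(s, e, c, direction)
        assert repartitioned.counts == PUBLISHED[direction]
        for which, expected in PUBLISHED_MARGINALS[direction].items():
            assert repartitioned.marginal(which) == expected

    def test_packaged_counts_match_frozen_values(self):
        table = load_published_venn_counts()
        for direction in ("up", "down"):
            sub = table[table["direction"] == direction]
            assert dict(zip(sub["region"], sub["count"])) == PUBLISHED[direction]


class TestClassifyCoregulation:
    def test_singleton_gene_classes(self):
        part = partition_de_sets({"s"}, {"e"}, {"c"})
        calls = classify_coregulation(part)
        assert calls.loc["s", "reg_class"] == "six1_independent"
        assert calls.loc["e", "reg_class"] == "eya1_independent"
        assert calls.loc["c", "reg_class"] == "coregulated_combined_only"

    def test_each_gene_classified_once(self):
        part = partition_de_sets({"a", "b", "c"}, {"b", "c", "d"},
                                 {"c", "d", "e"})
        calls = classify_coregulation(part)
        assert len(calls) == 5
        assert not calls.index.has_duplicates

    def test_class_counts_sum_to_union(self):
        part = published_partition("up")
        calls = classify_coregulation(part)
        union = set().union(*part.regions.values())
        assert sum(class_counts(calls).values()) == len(union)

    def test_published_up_aggregates(self):
        """The up-direction classifier reproduces the screen's printed
        class arithmetic: 690 co-regulated, 283 Six1-independent, 426
        Eya1-independent."""
        calls = classify_coregulation(published_partition("up"))
        counts = class_counts(calls)
        assert coregulated_count(calls) == 690          # 633 + 57
        assert counts["six1_independent"] == 283        # 190 + 93
        assert counts["eya1_independent"] == 426        # 373 + 53
        assert counts["ambiguous_pair_only"] == 25

    def test_published_down_aggregates(self):
        calls = classify_coregulation(published_partition("down"))
        counts = class_counts(calls)
        assert coregulated_count(calls) == 444          # 440 + 4
        assert counts["six1_independent"] == 270        # 233 + 37
        assert counts["eya1_independent"] == 196        # 187 + 9


class TestCoregulationSummary:
    def test_published_fractions(self):
        up = classify_coregulation(published_partition("up"))
        down = classify_coregulation(published_partition("down"))
        summary = coregulation_summary(up, down)
        assert summary["pct_coregulated_up"] == 60.8    # 690 / 1134
        assert summary["pct_all_three_up"] == 93.4      # 57 / 61
        assert summary["coregulated_up"] == 690
        assert summary["coregulated_down"] == 444

    def test_zero_denominator_marked_undefined(self):
        empty = classify_coregulation(partition_de_sets(set(), set(), set()))
        summary = coregulation_summary(empty, empty)
        assert summary["pct_coregulated_up"] is None
        assert summary["pct_coregulated_up_status"] == "undefined"


def hypergeom_pmf(k: int, n: int, ka: int, kb: int) -> float:
    """P(overlap = k) of two fixed-size subsets of an n-universe."""
    if k < max(0, ka + kb - n) or k > min(ka, kb):
        return 0.0
    return comb(kb, k) * comb(n - kb, ka - k) / comb(n, ka)


def two_sided_overlap_p(k: int, n: int, ka: int, kb: int) -> float:
    """Two-sided Fisher p by enumerating all tables with fixed margins."""
    observed = hypergeom_pmf(k, n, ka, kb)
    return sum(p for j in range(min(ka, kb) + 1)
               if (p := hypergeom_pmf(j, n, ka, kb)) <= observed * (1 + 1e-9))


class TestTopFractionOverlapTest:
    def _ranking(self, n, prefix="g"):
        return [f"{prefix}{i:03d}" for i in range(n)]

    def test_identical_rankings_maximal_overlap(self):
        genes = self._ranking(100)
        odds, p = top_fraction_overlap_test(genes, genes, 0.1)
        assert odds == math.inf
        assert p == pytest.approx(two_sided_overlap_p(10, 100, 10, 10))

    def test_zero_overlap_small_universe(self):
        genes = self._ranking(20)
        reversed_ranking = genes[::-1]
        odds, p = top_fraction_overlap_test(genes, reversed_ranking, 0.1)
        assert p == pytest.approx(two_sided_overlap_p(0, 20, 2, 2))
        assert p == pytest.approx(1.0)

    def test_full_overlap_small_universe(self):
        """Overlap 2 of top-2 sets in a 20-gene universe: the observed
        table's point mass is 1/C(20,2) = 1/190."""
        genes = self._ranking(20)
        assert hypergeom_pmf(2, 20, 2, 2) == pytest.approx(1 / 190)
        _, p = top_fraction_overlap_test(genes, genes, 0.1)
        assert p == pytest.approx(two_sided_overlap_p(2, 20, 2, 2))

    def test_differing_universes_rejected(self):
        with pytest.raises(ValueError):
            top_fraction_overlap_test(self._ranking(10), self._ranking(12), 0.2)

    def test_series_input_ties_broken_by_gene_id(self):
        scores = pd.Series({"gB": 1.0, "gA": 1.0, "gC": 0.5, "gD": 0.1})
        other = ["gA", "gD", "gB", "gC"]
        # fraction 0.25 -> top set size 1; the tie at 1.0 resolves to gA
        _, p_match = top_fraction_overlap_test(scores, other, 0.25)
        _, p_expected = top_fraction_overlap_test(["gA", "gB", "gC", "gD"],
                                                  other, 0.25)
        assert p_match == p_expected

    @pytest.mark.parametrize("n, fraction, shift", [
        (20, 0.1, 0), (30, 0.2, 3), (50, 0.1, 2), (40, 0.25, 10),
    ])
    def test_matches_enumeration_oracle(self, n, fraction, shift):
        """p equals brute-force enumeration over all hypergeometric
        outcomes for small universes."""
        genes = self._ranking(n)
        shifted = genes[shift:] + genes[:shift]
        k_top = math.ceil(fraction * n)
        overlap = len(set(genes[:k_top]) & set(shifted[:k_top]))
        _, p = top_fraction_overlap_test(genes, shifted, fraction)
        assert p == pytest.approx(two_sided_overlap_p(overlap, n, k_top, k_top),
                                  rel=1e-9)
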