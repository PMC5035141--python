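import math
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppescreen.enrichment import (EnrichmentError, GeneSetCollection,
                                  category_composition,
                                  cluster_enrichment_score, ease_score,
                                  enrich_terms, fisher_enrichment, read_gmt,
                                  read_cluster_table, score_clusters)


def upper_tail_oracle(k: int, n_background: int, n_term: int,
                      n_query: int) -> float:
    """P(overlap >= k) by explicit summation of hypergeometric masses."""
    total = 0.0
    for j in range(k, min(n_term, n_query) + 1):
        if n_query - j > n_background - n_term:
            continue
        total += (comb(n_term, j) * comb(n_background - n_term, n_query - j)
                  / comb(n_background, n_query))
    return min(total, 1.0)


def genes(n: int, prefix: str = "g") -> list[str]:
    return [f"{prefix}{i:03d}" for i in range(n)]


class TestFisherEnrichment:
    def test_zero_overlap_is_one(self):
        background = genes(30)
        assert fisher_enrichment(background[:5], background[10:15],
                                 background) == 1.0

    def test_query_equals_background_is_one(self):
        background = genes(30)
        assert fisher_enrichment(background, background[:7],
                                 background) == pytest.approx(1.0)

    def test_worked_example_vs_summation(self):
        """Background 100, query 10, term 20, overlap 8."""
        background = genes(100)
        term = background[:20]
        query = background[:8] + background[50:52]
        p = fisher_enrichment(query, term, background)
        assert p == pytest.approx(upper_tail_oracle(8, 100, 20, 10), rel=1e-9)

    def test_empty_background_rejected(self):
        with pytest.raises(EnrichmentError):
            fisher_enrichment(set(), set(), set())

    def test_query_outside_background_rejected(self):
        with pytest.raises(EnrichmentError):
            fisher_enrichment({"stray"}, set(), set(genes(5)))

    @pytest.mark.parametrize("n_bg, n_term, n_query, overlap", [
        (20, 5, 8, 3), (40, 12, 10, 6), (60, 30, 15, 10), (15, 3, 3, 0),
        (60, 10, 10, 10),
    ])
    def test_matches_enumeration_for_small_backgrounds(self, n_bg, n_term,
                                                       n_query, overlap):
        background = genes(n_bg)
        term = background[:n_term]
        query = background[:overlap] + background[n_term:n_term + n_query - overlap]
        p = fisher_enrichment(query, term, background)
        assert p == pytest.approx(upper_tail_oracle(overlap, n_bg, n_term,
                                                    n_query), rel=1e-9)
        e = ease_score(query, term, background)
        assert e == pytest.approx(
            upper_tail_oracle(max(overlap - 1, 0), n_bg, n_term, n_query),
            rel=1e-9)


class TestEaseScore:
    def test_single_overlap_reduces_to_one(self):
        background = genes(30)
        term = background[:10]
        query = [background[0]] + background[20:24]
        assert ease_score(query, term, background) == 1.0

    def test_worked_example_equals_shifted_fisher(self):
        background = genes(100)
        term = background[:20]
        query = background[:8] + background[50:52]
        assert ease_score(query, term, background) == pytest.approx(
            upper_tail_oracle(7, 100, 20, 10), rel=1e-9)

    @given(st.data())
    @settings(max_examples=1000, deadline=None, derandomize=True)
    def test_ease_never_more_significant_than_fisher(self, data):
        """Removing one overlap success can only raise the tail p-value."""
        n_bg = data.draw(st.integers(5, 45))
        background = genes(n_bg)
        n_term = data.draw(st.integers(1, n_bg))
        n_query = data.draw(st.integers(1, n_bg))
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        term = set(rng.choice(background, n_term, replace=False))
        query = set(rng.choice(background, n_query, replace=False))
        assert (ease_score(query, term, background)
                >= fisher_enrichment(query, term, background) - 1e-12)


class TestClusterEnrichmentScore:
    def test_single_p(self):
        assert cluster_enrichment_score([0.1]) == pytest.approx(1.0)

    def test_geometric_mean_of_extreme_ps(self):
        """EASE p-values 1e-40 and 1e-46 give the enrichment score E = 43,
        the magnitude class of a very strongly enriched cluster."""
        assert cluster_enrichment_score([1e-40, 1e-46]) == pytest.approx(43.0)

    def test_all_ones_give_zero(self):
        assert cluster_enrichment_score([1.0, 1.0, 1.0]) == 0.0

    def test_empty_and_zero_rejected(self):
        with pytest.raises(EnrichmentError):
            cluster_enrichment_score([])
        with pytest.raises(EnrichmentError):
            cluster_enrichment_score([0.0, 0.5])

    def test_permutation_invariant_and_monotone(self):
        ps = [0.2, 1e-5, 0.7, 1e-12]
        e = cluster_enrichment_score(ps)
        assert cluster_enrichment_score(ps[::-1]) == pytest.approx(e)
        smaller = [0.1, 1e-5, 0.7, 1e-12]  # lowered one member p
        assert cluster_enrichment_score(smaller) > e


class TestCategoryComposition:
    def test_single_category(self):
        comp = category_composition(["a", "b"], {"a": "binding", "b": "binding"})
        assert comp.loc["binding", "percent"] == 100.0

    def test_binding_fraction_structure(self):
        """53 of 100 assignments in binding-type categories gives 53%."""
        mapping = {f"g{i}": ("binding" if i < 53 else "enzyme")
                   for i in range(100)}
        comp = category_composition(mapping.keys(), mapping)
        assert comp.loc["binding", "percent"] == pytest.approx(53.0)
        assert comp["percent"].sum() == pytest.approx(100.0)

    def test_unmapped_genes_counted_unclassified(self):
        comp = category_composition(["a", "b", "c"], {"a": "binding"})
        assert comp.loc["unclassified", "count"] == 2

    def test_empty_gene_set(self):
        comp = category_composition([], {"a": "binding"})
        assert comp.empty


class TestGmtAndClusters:
    def test_gmt_round_trip_and_background(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("term1\tdesc\tg1\tg2\n"
                        "term2\tanother desc\tg2\tg3\tg4\n")
        collection = read_gmt(path)
        assert collection.terms == {"term1": {"g1", "g2"},
                                    "term2": {"g2", "g3", "g4"}}
        assert collection.background == {"g1", "g2", "g3", "g4"}
        restricted = read_gmt(path, background={"g1", "g2", "g3"})
        assert restricted.terms["term2"] == {"g2", "g3"}

    def test_gmt_short_row_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("term1\tdesc-without-genes\n")
        with pytest.raises(EnrichmentError, match="line 1"):
            read_gmt(path)

    def test_collection_rejects_stray_genes(self):
        with pytest.raises(EnrichmentError):
            GeneSetCollection(terms={"t": {"x"}}, background={"y"})

    def test_enrich_terms_and_cluster_scores(self, tmp_path):
        background = genes(50)
        collection = GeneSetCollection(
            terms={"termA": set(background[:10]), "termB": set(background[30:45])},
            background=set(background))
        query = set(background[:8])
        results = enrich_terms(query, collection)
        assert set(results.index) == {"termA", "termB"}
        assert results.loc["termA", "fisher_p"] < results.loc["termB", "fisher_p"]
        assert (results["ease_p"] >= results["fisher_p"] - 1e-12).all()

        cluster_path = tmp_path / "clusters.tsv"
        cluster_path.write_text("cluster_id\tterm_id\nc1\ttermA\nc1\ttermB\n")
        clusters = read_cluster_table(cluster_path)
        scores = score_clusters(results, clusters)
        expected = -np.log10(results["ease_p"]).mean()
        assert scores.loc["c1", "enrichment_score"] == pytest.approx(expected)

    def test_cluster_with_unknown_term_rejected(self):
        results = pd.DataFrame({"ease_p": [0.5]}, index=["termA"])
        with pytest.raises(EnrichmentError, match="missing"):
            score_clusters(results, {"c1": ["termA", "ghost"]})
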