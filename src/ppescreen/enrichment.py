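"""Gene-set enrichment: Fisher/EASE per-term p-values and cluster scores.

Per-term enrichment of a query gene list against a background universe is
the upper-tail hypergeometric probability (one-sided Fisher exact test).
The EASE score is its conservative variant: one gene is removed from the
query-term overlap before the same tail probability is computed, which
penalises terms supported by very few genes. Related terms grouped into a
cluster (the grouping is user input) are summarised by the enrichment
score E = -log10 of the geometric mean of the member terms' EASE p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

P_FLOOR = 1e-300


class EnrichmentError(ValueError):
    """Invalid enrichment inputs."""


@dataclass
class GeneSetCollection:
    """Named gene sets (terms) over an explicit background universe."""

    terms: dict[str, set[str]] = field(default_factory=dict)
    background: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            stray = genes - self.background
            if stray:
                raise EnrichmentError(
                    f"term {term!r} contains genes outside the background: "
                    f"{sorted(stray)[:5]}")


def _check_universe(query: set[str], term: set[str], background: set[str]) -> None:
    if not background:
        raise EnrichmentError("background set is empty")
    if not query <= background:
        raise EnrichmentError("query genes must be a subset of the background")
    if not term <= background:
        raise EnrichmentError("term genes must be a subset of the background")


def _hypergeom_upper_tail(k: int, n_background: int, n_term: int,
                          n_query: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N=background, K=term, n=query)."""
    return float(min(1.0, stats.hypergeom.sf(k - 1, n_background, n_term,
                                             n_query)))


def fisher_enrichment(query: Iterable[str], term: Iterable[str],
                      background: Iterable[str]) -> float:
    """One-sided Fisher (hypergeometric upper-tail) enrichment p-value."""
    query, term, background = set(query), set(term), set(background)
    _check_universe(query, term, background)
    k = len(query & term)
    return _hypergeom_upper_tail(k, len(background), len(term), len(query))


def ease_score(query: Iterable[str], term: Iterable[str],
               background: Iterable[str]) -> float:
    """EASE p-value: the Fisher tail with one overlap success removed.

    The overlap k is replaced by max(k - 1, 0) with all margins unchanged,
    so ease_score >= fisher_enrichment always.
    """
    query, term, background = set(query), set(term), set(background)
    _check_universe(query, term, background)
    k = max(len(query & term) - 1, 0)
    return _hypergeom_upper_tail(k, len(background), len(term), len(query))


def enrich_terms(query: Iterable[str], collection: GeneSetCollection,
                 ) -> pd.DataFrame:
    """Fisher and EASE p-values for every term in the collection."""
    query = set(query)
    rows = []
    for term_id in sorted(collection.terms):
        genes = collection.terms[term_id]
        rows.append({
            "term_id": term_id,
            "k": len(query & genes),
            "n_query": len(query),
            "n_term": len(genes),
            "n_background": len(collection.background),
            "fisher_p": fisher_enrichment(query, genes, collection.background),
            "ease_p": ease_score(query, genes, collection.background),
        })
    return pd.DataFrame(
        rows, columns=["term_id", "k", "n_query", "n_term", "n_background",
                       "fisher_p", "ease_p"]).set_index("term_id")


def cluster_enrichment_score(member_ease_p: Sequence[float]) -> float:
    """E = -log10 of the geometric mean of member EASE p-values.

    Computed in log space; p-values are floored at 1e-300 first, so inputs
    of exactly zero are rejected rather than silently mapped.
    """
    ps = list(member_ease_p)
    if not ps:
        raise EnrichmentError("cluster has no member EASE p-values")
    for p in ps:
        if not 0.0 < p <= 1.0:
            raise EnrichmentError(f"EASE p-value {p} outside (0, 1]")
    logs = np.log10(np.maximum(np.asarray(ps, dtype=float), P_FLOOR))
    return float(-logs.mean())


def score_clusters(results: pd.DataFrame,
                   clusters: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Enrichment score E per user-supplied term cluster.

    ``clusters`` maps cluster id to its member term ids; members must be
    present in the per-term ``results`` table (index term_id, column
    ``ease_p``).
    """
    rows = []
    for cluster_id in sorted(clusters):
        members = list(clusters[cluster_id])
        missing = [t for t in members if t not in results.index]
        if missing:
            raise EnrichmentError(
                f"cluster {cluster_id!r}: terms missing from results: {missing}")
        e = cluster_enrichment_score(results.loc[members, "ease_p"].tolist())
        rows.append({"cluster_id": cluster_id, "n_terms": len(members),
                     "enrichment_score": e})
    return pd.DataFrame(
        rows, columns=["cluster_id", "n_terms", "enrichment_score"]
    ).set_index("cluster_id")


def category_composition(genes: Iterable[str],
                         category_map: Mapping[str, str]) -> pd.DataFrame:
    """Percentage of genes per functional category.

    Genes absent from the map are counted under ``unclassified``.
    Percentages sum to 100 within rounding; an empty gene set yields an
    empty table.
    """
    genes = sorted(set(genes))
    if not genes:
        return pd.DataFrame(columns=["count", "percent"])
    assigned = pd.Series(
        {g: category_map.get(g, "unclassified") for g in genes})
    counts = assigned.value_counts().sort_index()
    out = pd.DataFrame({"count": counts})
    out["percent"] = 100.0 * out["count"] / out["count"].sum()
    out.index.name = "category"
    return out


def read_gmt(path: str | Path, background: Iterable[str] | None = None,
             ) -> GeneSetCollection:
    """Read a GMT file (term, description, then tab-separated gene ids).

    If ``background`` is omitted it defaults to the union of all term
    genes; terms are intersected with an explicit background when given.
    """
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise EnrichmentError(
                    f"{path}: line {lineno}: GMT rows need term, description "
                    "and at least one gene")
            terms[parts[0]] = {g for g in parts[2:] if g}
    if background is None:
        bg = set().union(*terms.values()) if terms else set()
    else:
        bg = set(background)
        terms = {t: genes & bg for t, genes in terms.items()}
    return GeneSetCollection(terms=terms, background=bg)


def read_cluster_table(path: str | Path) -> dict[str, list[str]]:
    """Two-column TSV (cluster_id, term_id) -> cluster to member terms."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["cluster_id", "term_id"]:
        raise EnrichmentError(
            f"{path}: expected columns cluster_id, term_id")
    return {cid: sub["term_id"].tolist()
            for cid, sub in df.groupby("cluster_id", sort=True)}
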