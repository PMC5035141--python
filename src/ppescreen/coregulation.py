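"""Venn partitioning of per-group DE sets and co-regulation classification.

Genes called differentially expressed (per direction) in the Six1-alone,
Eya1-alone and combined-injection groups are partitioned into the seven
disjoint Venn regions over the three sets. From the regions each gene gets
a regulatory class:

``coregulated_all_three``
    DE in all three groups: joint regulation supported by three
    independent comparisons.
``coregulated_combined_only``
    DE only when both factors are co-overexpressed: candidate genes with a
    high requirement for the joint complex.
``six1_independent`` / ``eya1_independent``
    DE under one factor but never under the other alone: regulation by
    that factor that does not require its partner.
``ambiguous_pair_only``
    DE in both single-factor groups but, inconsistently, not in the
    combined group. Kept as its own class and excluded from the
    co-regulated aggregate.

The co-regulated aggregate is ``coregulated_all_three`` plus
``coregulated_combined_only``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

REGIONS = ("S_only", "E_only", "C_only", "SE_only", "SC_only", "EC_only", "SEC")

REG_CLASSES = (
    "coregulated_all_three",
    "coregulated_combined_only",
    "six1_independent",
    "eya1_independent",
    "ambiguous_pair_only",
)

#: Venn regions aggregated into each regulatory class.
CLASS_REGIONS: Mapping[str, tuple[str, ...]] = {
    "coregulated_all_three": ("SEC",),
    "coregulated_combined_only": ("C_only",),
    "six1_independent": ("S_only", "SC_only"),
    "eya1_independent": ("E_only", "EC_only"),
    "ambiguous_pair_only": ("SE_only",),
}

COREGULATED_CLASSES = ("coregulated_all_three", "coregulated_combined_only")


@dataclass
class VennPartition:
    """The 7 disjoint regions over DE sets S (Six1), E (Eya1), C (combined)."""

    direction: str
    regions: dict[str, set[str]] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {r: len(self.regions[r]) for r in REGIONS}

    def marginal(self, which: str) -> int:
        """|S|, |E| or |C| reconstructed from the regions."""
        members = {
            "S": ("S_only", "SE_only", "SC_only", "SEC"),
            "E": ("E_only", "SE_only", "EC_only", "SEC"),
            "C": ("C_only", "SC_only", "EC_only", "SEC"),
        }[which]
        return sum(len(self.regions[r]) for r in members)


def partition_de_sets(s: Iterable[str], e: Iterable[str], c: Iterable[str],
                      direction: str = "up") -> VennPartition:
    """Partition three DE gene sets into the 7 disjoint Venn regions."""
    s, e, c = set(s), set(e), set(c)
    regions = {
        "S_only": s - e - c,
        "E_only": e - s - c,
        "C_only": c - s - e,
        "SE_only": (s & e) - c,
        "SC_only": (s & c) - e,
        "EC_only": (e & c) - s,
        "SEC": s & e & c,
    }
    return VennPartition(direction=direction, regions=regions)


def classify_coregulation(partition: VennPartition) -> pd.DataFrame:
    """One regulatory class per gene in the partition's union.

    Returns a DataFrame indexed by gene_id with columns ``direction`` and
    ``reg_class``.
    """
    rows = []
    for reg_class, region_names in CLASS_REGIONS.items():
        for region in region_names:
            for gene in sorted(partition.regions[region]):
                rows.append((gene, partition.direction, reg_class))
    df = pd.DataFrame(rows, columns=["gene_id", "direction", "reg_class"])
    return df.set_index("gene_id").sort_index()


def class_counts(calls: pd.DataFrame) -> dict[str, int]:
    counts = calls["reg_class"].value_counts().to_dict()
    return {c: int(counts.get(c, 0)) for c in REG_CLASSES}


def coregulated_count(calls: pd.DataFrame) -> int:
    """Size of the co-regulated aggregate (all-three plus combined-only)."""
    return int(calls["reg_class"].isin(COREGULATED_CLASSES).sum())


def coregulation_summary(up_calls: pd.DataFrame,
                         down_calls: pd.DataFrame) -> dict:
    """Directional balance of co-regulated genes.

    Reports the percentage of the co-regulated aggregate that is
    up-regulated, overall and restricted to genes supported by all three
    treatment groups. Percentages are rounded to one decimal; a zero
    denominator yields ``None`` with an ``'undefined'`` marker.
    """
    up_counts, down_counts = class_counts(up_calls), class_counts(down_calls)

    def _pct(up: int, down: int):
        if up + down == 0:
            return None, "undefined"
        return round(100.0 * up / (up + down), 1), "ok"

    up_coreg = coregulated_count(up_calls)
    down_coreg = coregulated_count(down_calls)
    pct_all, status_all = _pct(up_coreg, down_coreg)
    up_sec = up_counts["coregulated_all_three"]
    down_sec = down_counts["coregulated_all_three"]
    pct_sec, status_sec = _pct(up_sec, down_sec)
    return {
        "up_class_counts": up_counts,
        "down_class_counts": down_counts,
        "coregulated_up": up_coreg,
        "coregulated_down": down_coreg,
        "pct_coregulated_up": pct_all,
        "pct_coregulated_up_status": status_all,
        "coregulated_all_three_up": up_sec,
        "coregulated_all_three_down": down_sec,
        "pct_all_three_up": pct_sec,
        "pct_all_three_up_status": status_sec,
    }


def _top_set(ranking, fraction: float) -> tuple[set[str], list[str]]:
    """Top-``fraction`` genes of a ranking.

    ``ranking`` is either an ordered gene-id sequence (best first) or a
    pandas Series of scores indexed by gene id, sorted here by descending
    score with ties broken lexicographically by gene id.
    """
    if isinstance(ranking, pd.Series):
        ordered = sorted(ranking.index, key=lambda g: (-ranking[g], g))
    else:
        ordered = list(ranking)
    k = math.ceil(fraction * len(ordered))
    return set(ordered[:k]), ordered


def top_fraction_overlap_test(ranked_a, ranked_b, fraction: float = 0.1,
                              alternative: str = "two-sided",
                              ) -> tuple[float, float]:
    """Fisher's exact test for overlap of the top fractions of two rankings.

    Both rankings must cover the same gene universe. The 2x2 table crosses
    membership in the top ``ceil(fraction * n)`` of each ranking. Returns
    ``(odds_ratio, p_value)``; a table with an empty off-diagonal cell
    reports ``math.inf`` as the odds-ratio sentinel.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    top_a, universe_a = _top_set(ranked_a, fraction)
    top_b, universe_b = _top_set(ranked_b, fraction)
    if set(universe_a) != set(universe_b):
        raise ValueError("rankings cover different gene universes")
    n = len(universe_a)
    k = len(top_a & top_b)
    table = [
        [k, len(top_a) - k],
        [len(top_b) - k, n - len(top_a) - len(top_b) + k],
    ]
    odds_ratio, p = stats.fisher_exact(table, alternative=alternative)
    if table[0][1] == 0 and table[1][0] == 0 and k > 0:
        odds_ratio = math.inf
    return float(odds_ratio), float(p)


def partition_from_counts(counts: Mapping[str, int], direction: str,
                          prefix: str = "g") -> VennPartition:
    """Build a synthetic membership partition realising given region counts.

    Gene ids are generated deterministically per region; useful for
    exercising the classifier on published per-region counts.
    """
    regions: dict[str, set[str]] = {}
    for region in REGIONS:
        n = int(counts.get(region, 0))
        regions[region] = {f"{prefix}_{direction}_{region}_{i:04d}"
                           for i in range(n)}
    return VennPartition(direction=direction, regions=regions)


def sets_from_partition(partition: VennPartition,
                        ) -> tuple[set[str], set[str], set[str]]:
    """Recover the three DE sets S, E, C from a partition."""
    r = partition.regions
    s = r["S_only"] | r["SE_only"] | r["SC_only"] | r["SEC"]
    e = r["E_only"] | r["SE_only"] | r["EC_only"] | r["SEC"]
    c = r["C_only"] | r["SC_only"] | r["EC_only"] | r["SEC"]
    return s, e, c
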