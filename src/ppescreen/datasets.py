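"""Loaders for the small published-value tables shipped with the package."""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _data_path(name: str):
    return resources.files("ppescreen") / "data" / name


def load_candidate_tf_table() -> pd.DataFrame:
    """Published log2 fold changes for the 32 candidate transcriptional
    regulators selected in the Six1/Eya1 placodal explant screen.

    Columns ``fc_six1``, ``fc_eya1`` and ``fc_six1_eya1`` hold the
    per-treatment-group induction log2 fold changes; absent entries
    (printed as "-" in the published summary) are NaN.
    """
    with resources.as_file(_data_path("candidate_tf_log2fc.tsv")) as path:
        return pd.read_csv(path, sep="\t", index_col="gene_id")


def load_published_venn_counts() -> pd.DataFrame:
    """Published per-region Venn counts of DE genes over the three
    treatment groups (S = Six1 alone, E = Eya1 alone, C = combined), per
    direction."""
    with resources.as_file(_data_path("venn_regions_published.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def load_known_six1_targets() -> list[tuple[str, str]]:
    """Previously established Six1 targets used as recovery controls."""
    with resources.as_file(_data_path("known_six1_targets.tsv")) as path:
        df = pd.read_csv(path, sep="\t")
    return list(df.itertuples(index=False, name=None))
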