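"""Candidate prioritisation: well-supported targets, TF selection, recovery.

The well-supported list demands an induction of at least ``fc_min_log2``
(two-fold by default) in at least two of the three individual treatment
groups; entries absent from a group's table (printed as "-" in published
summaries) count as failures. Optionally a two-fold separation from the
un-injected control response is also required. Transcription-factor status
is always an explicit curated input set, never inferred, and named rescue
genes can be carried into the candidate list despite failing the
threshold.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GROUP_FC_COLUMNS = ("fc_six1", "fc_eya1", "fc_six1_eya1")


class PrioritizationError(ValueError):
    """Invalid prioritisation inputs."""


def well_supported_list(fc_table: pd.DataFrame, fc_min_log2: float = 1.0,
                        require_control: bool = False) -> pd.DataFrame:
    """Candidate records from a per-gene per-group log2 fold-change table.

    ``fc_table`` is indexed by gene_id with columns ``fc_six1``,
    ``fc_eya1``, ``fc_six1_eya1`` and optionally ``fc_control``; NaN marks
    an absent entry and fails the threshold. A gene is well supported when
    it clears ``fc_min_log2`` (inclusive) in at least two groups and, when
    ``require_control`` is set, every passing group's fold change exceeds
    the control fold change by at least 1 log2 unit.
    """
    missing = [c for c in GROUP_FC_COLUMNS if c not in fc_table.columns]
    if missing:
        raise PrioritizationError(f"fc_table missing columns: {missing}")
    if require_control and "fc_control" not in fc_table.columns:
        raise PrioritizationError(
            "require_control=True needs an fc_control column")

    out = fc_table.copy()
    group_fc = out[list(GROUP_FC_COLUMNS)]
    passing = group_fc >= fc_min_log2  # NaN compares False
    out["n_groups_passing"] = passing.sum(axis=1).astype(int)
    supported = out["n_groups_passing"] >= 2
    if require_control:
        sep = group_fc.sub(out["fc_control"], axis=0).where(passing)
        # every passing group must sit >= 1 log2 unit above the control
        supported &= sep.min(axis=1) >= 1.0
    out["well_supported"] = supported
    return out


def select_candidates(records: pd.DataFrame, tf_annotation: Iterable[str],
                      rescue: Iterable[str] = ()) -> pd.DataFrame:
    """Well-supported genes that are annotated TFs, plus rescued genes.

    Rescue genes are included regardless of threshold status and flagged
    ``rescue=True`` unless they qualify on their own.
    """
    tf_set, rescue_set = set(tf_annotation), set(rescue)
    missing = rescue_set - set(records.index)
    if missing:
        raise PrioritizationError(
            f"rescue genes absent from fc_table: {sorted(missing)}")
    selected = records[records["well_supported"]
                       & records.index.isin(tf_set)].copy()
    selected["is_tf"] = True
    selected["rescue"] = False
    rescued_only = sorted(rescue_set - set(selected.index))
    if rescued_only:
        extra = records.loc[rescued_only].copy()
        extra["is_tf"] = extra.index.isin(tf_set)
        extra["rescue"] = True
        selected = pd.concat([selected, extra])
    return selected.sort_index()


def known_target_recovery(
    contrast_fc: Mapping[str, Mapping[str, float]],
    known_targets: Sequence[tuple[str, str]],
    de_sets: Mapping[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Report recovery of externally established targets in the screen.

    ``contrast_fc`` maps injection group to {gene: log2FC} over the
    screen's transcriptome; ``known_targets`` is a list of (gene, source)
    pairs; ``de_sets`` optionally maps group to its DE gene set so the
    report can name the group(s) in which each target was called DE.
    A target absent from every group's table is reported as not present in
    the transcriptome.
    """
    groups = sorted(contrast_fc)
    rows = []
    for gene, source in known_targets:
        present = any(gene in contrast_fc[g] for g in groups)
        row: dict = {"gene_id": gene, "source": source,
                     "in_transcriptome": present}
        de_in = []
        for g in groups:
            fc = contrast_fc[g].get(gene, np.nan)
            row[f"fc_{g}"] = fc
            if de_sets is not None and gene in de_sets.get(g, set()):
                de_in.append(g)
        row["de_in_groups"] = ",".join(de_in)
        rows.append(row)
    columns = (["gene_id", "source", "in_transcriptome"]
               + [f"fc_{g}" for g in groups] + ["de_in_groups"])
    return pd.DataFrame(rows, columns=columns).set_index("gene_id")
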