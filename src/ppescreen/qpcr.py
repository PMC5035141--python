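"""Relative quantification of qPCR inductions by the delta-delta-Ct method.

Per biological replicate and condition, the target gene's Ct is normalised
against a reference gene (Smn2 in the original screen) to give
``dCt = ct_target - ct_reference``; the induction is
``ddCt = dCt(chx_dex) - dCt(chx)``, so ``RQ = eff**(-ddCt)`` and
``log2FC = -ddCt * log2(eff)`` with the amplification efficiency ``eff``
defaulting to the ideal doubling of 2. RQ and log2FC are each averaged
arithmetically across biological replicates, with standard deviation.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

QPCR_COLUMNS = ("gene_id", "condition", "biological_replicate",
                "ct_target", "ct_reference")


class QpcrError(ValueError):
    """Malformed or incomplete qPCR measurements."""


def read_qpcr_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in QPCR_COLUMNS if c not in df.columns]
    if missing:
        raise QpcrError(f"{path}: missing columns {missing}")
    return df


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in QPCR_COLUMNS if c not in df.columns]
    if missing:
        raise QpcrError(f"measurements missing columns {missing}")
    bad = set(df["condition"]) - {"chx", "chx_dex"}
    if bad:
        raise QpcrError(f"unknown condition tokens: {sorted(bad)}")
    cts = df[["ct_target", "ct_reference"]].to_numpy(dtype=float)
    if not np.isfinite(cts).all() or (cts <= 0).any():
        raise QpcrError("Ct values must be positive and finite")
    # technical replicates (duplicate rows per gene/condition/replicate)
    # are mean-collapsed on Ct before dCt
    return (df.groupby(["gene_id", "condition", "biological_replicate"],
                       as_index=False)[["ct_target", "ct_reference"]].mean())


def relative_quantification(measurements: pd.DataFrame,
                            efficiency: float = 2.0,
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-replicate and per-gene RQ / log2 fold change.

    Returns ``(per_replicate, per_gene)``: the first has one row per gene
    and biological replicate with ``ddct``, ``rq`` and ``log2fc``; the
    second averages RQ and log2FC independently across replicates and
    reports their standard deviations (ddof=1, NaN for a single
    replicate).
    """
    if efficiency <= 1.0:
        raise QpcrError("amplification efficiency must exceed 1")
    df = _validate(measurements)
    df["dct"] = df["ct_target"] - df["ct_reference"]
    wide = df.pivot(index=["gene_id", "biological_replicate"],
                    columns="condition", values="dct")
    wide = wide.reindex(columns=["chx", "chx_dex"])
    incomplete = wide[wide.isna().any(axis=1)]
    if len(incomplete):
        gene, rep = incomplete.index[0]
        raise QpcrError(
            f"gene {gene!r} biological replicate {rep}: missing one condition")
    per_rep = wide.reset_index()
    per_rep["ddct"] = per_rep["chx_dex"] - per_rep["chx"]
    per_rep["rq"] = efficiency ** (-per_rep["ddct"])
    per_rep["log2fc"] = -per_rep["ddct"] * math.log2(efficiency)
    per_rep = per_rep[["gene_id", "biological_replicate", "ddct", "rq",
                       "log2fc"]]

    per_gene = per_rep.groupby("gene_id").agg(
        n_replicates=("rq", "size"),
        mean_rq=("rq", "mean"), sd_rq=("rq", "std"),
        mean_log2fc=("log2fc", "mean"), sd_log2fc=("log2fc", "std"),
    )
    return per_rep, per_gene
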