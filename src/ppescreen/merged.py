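"""Merged-replicate re-analysis: pooled schemes, per-gene test, FDR control.

Individual treatment groups carry only two replicates per arm, too few for
a per-gene significance test, so the screen's second pass pools injection
groups that share an overexpressed factor and treats their replicates as
equivalent:

=============  ==============================  =====================
scheme         pooled injection groups         replicates per arm
=============  ==============================  =====================
``six1_m``     six1, six1_eya1                 4
``eya1_m``     eya1, six1_eya1                 4
``six1_eya1_m`` six1, eya1, six1_eya1          6
=============  ==============================  =====================

Each gene is then tested for a DEX vs CHX difference with an
unequal-variance (Welch) two-sample test on log2(FPKM + 1) replicate
values, and false discovery is controlled with the Benjamini-Hochberg
step-up procedure. A gene is called significant only if it both clears
q < alpha and passes the fold-change/expression/control filter cascade on
the pooled contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .contrasts import DEFilterCriteria, compute_contrast, de_pass_mask
from .io import ExpressionMatrix

MERGED_SCHEMES: dict[str, tuple[str, ...]] = {
    "six1_m": ("six1", "six1_eya1"),
    "eya1_m": ("eya1", "six1_eya1"),
    "six1_eya1_m": ("six1", "eya1", "six1_eya1"),
}


class MergedAnalysisError(ValueError):
    """Invalid merged scheme or insufficient replication."""


def merge_replicates(matrix: ExpressionMatrix, scheme: str) -> ExpressionMatrix:
    """Pool the scheme's injection groups into one two-condition design.

    Samples of member groups are relabelled to a single ``six1_eya1``-style
    pooled injection token (the scheme name) with replicate indices
    renumbered consecutively within each treatment arm.
    """
    if scheme not in MERGED_SCHEMES:
        raise MergedAnalysisError(
            f"unknown scheme {scheme!r}; expected one of {sorted(MERGED_SCHEMES)}")
    members = MERGED_SCHEMES[scheme]
    for group in members:
        if not matrix.sample_ids(injection=group):
            raise MergedAnalysisError(
                f"scheme {scheme!r}: injection group {group!r} absent from matrix")

    columns: dict[str, np.ndarray] = {}
    rows = []
    for treatment in ("chx", "chx_dex"):
        rep = 0
        for group in members:
            for sid in matrix.sample_ids(injection=group, treatment=treatment):
                rep += 1
                new_id = f"{scheme}_{treatment}_r{rep}"
                columns[new_id] = matrix.values[sid].to_numpy()
                # pooled samples all carry the six1_eya1 token: every member
                # group overexpresses at least one of the two factors
                rows.append({"sample_id": new_id, "injection": "six1_eya1",
                             "treatment": treatment, "replicate": rep})
    values = pd.DataFrame(columns, index=matrix.gene_ids.copy())
    samples = pd.DataFrame(rows).set_index("sample_id")
    return ExpressionMatrix(values=values, samples=samples)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over the sorted p-values,
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise MergedAnalysisError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def welch_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float, bool]:
    """Two-sided Welch test of mean(b) != mean(a).

    Returns ``(statistic, p, degenerate)``. Degenerate zero-variance cases
    follow fixed conventions: equal means with no variance anywhere give
    p = 1; unequal means with no variance give the minimum representable
    positive p and are flagged.
    """
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = b.mean() - a.mean()
    se2 = va / na + vb / nb
    if se2 == 0.0:
        if diff == 0.0:
            return 0.0, 1.0, False
        return np.sign(diff) * np.inf, float(np.finfo(float).tiny), True
    t = diff / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0)), False


def test_merged(matrix: ExpressionMatrix, alpha: float = 0.05,
                criteria: DEFilterCriteria | None = None,
                control: pd.DataFrame | None = None,
                pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-gene Welch test (DEX vs CHX) on a pooled matrix with BH FDR.

    ``control`` is the un-injected contrast table used by the filter
    cascade's control criterion (omit to skip it). The ``significant``
    column requires both q < ``alpha`` and a pass of the filter cascade in
    either direction on the pooled contrast.

    Returns a DataFrame indexed by gene_id with columns ``log2fc``,
    ``statistic``, ``p_value``, ``q_value``, ``degenerate``,
    ``significant``.
    """
    if criteria is None:
        criteria = DEFilterCriteria()
    injection = str(matrix.samples["injection"].iloc[0])
    chx_ids = matrix.sample_ids(treatment="chx")
    dex_ids = matrix.sample_ids(treatment="chx_dex")
    if len(chx_ids) < 2 or len(dex_ids) < 2:
        raise MergedAnalysisError(
            "need at least 2 replicates per pooled condition "
            f"(got {len(chx_ids)} CHX, {len(dex_ids)} CHX+DEX)")

    log_chx = np.log2(matrix.values[chx_ids].to_numpy() + 1.0)
    log_dex = np.log2(matrix.values[dex_ids].to_numpy() + 1.0)
    stats_out = np.empty(matrix.n_genes)
    p_out = np.empty(matrix.n_genes)
    degen = np.zeros(matrix.n_genes, dtype=bool)
    for i in range(matrix.n_genes):
        stats_out[i], p_out[i], degen[i] = welch_test(log_chx[i], log_dex[i])
    q_out = benjamini_hochberg(p_out)

    contrast = compute_contrast(matrix, injection, pseudocount=pseudocount)
    pass_up = de_pass_mask(contrast, control, criteria, "up")
    pass_down = de_pass_mask(contrast, control, criteria, "down")

    out = pd.DataFrame({
        "log2fc": contrast["log2fc"],
        "statistic": stats_out,
        "p_value": p_out,
        "q_value": q_out,
        "degenerate": degen,
        "pass_filters": (pass_up | pass_down),
    }, index=matrix.gene_ids)
    out["significant"] = (out["q_value"] < alpha) & out["pass_filters"]
    return out
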