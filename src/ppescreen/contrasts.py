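"""Per-injection-group induction contrasts and the three-criterion DE filter.

For each injection group the induction contrast compares the CHX+DEX arm
(factor in the nucleus) against the CHX arm (factor cytoplasmic) of the same
group. A gene is called differentially expressed when it clears three
criteria: an expression floor in the induced state, a minimum induction fold
change, and a control criterion against the un-injected group that removes
genes responding to dexamethasone itself rather than to the translocated
factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import INJECTIONS, ExpressionMatrix

CONTRAST_COLUMNS = ("mean_fpkm_chx", "mean_fpkm_dex", "log2fc")


class ContrastError(ValueError):
    """Missing design cells or inconsistent contrast inputs."""


@dataclass
class DEFilterCriteria:
    """Thresholds of the differential-expression filter cascade.

    fc_min_log2
        Minimum |log2 fold change| of the induction contrast (default 1,
        i.e. two-fold).
    fpkm_min
        Expression floor on the mean FPKM of the higher condition (the
        CHX+DEX arm for up-regulation, the CHX arm for down-regulation).
    control_rule
        ``'delta'``: require the experimental fold change to differ from
        the un-injected control fold change by at least
        ``control_delta_min_log2`` (two-fold by default), in the direction
        tested. ``'absolute'``: require the control fold change itself to
        stay below ``control_abs_max_log2`` (above its negative for the
        down direction).
    """

    fc_min_log2: float = 1.0
    fpkm_min: float = 1.0
    control_rule: str = "delta"
    control_delta_min_log2: float = 1.0
    control_abs_max_log2: float = 0.5

    def __post_init__(self) -> None:
        if self.control_rule not in ("delta", "absolute"):
            raise ContrastError(f"unknown control_rule {self.control_rule!r}")
        for name in ("fc_min_log2", "fpkm_min", "control_delta_min_log2",
                     "control_abs_max_log2"):
            if getattr(self, name) < 0:
                raise ContrastError(f"{name} must be non-negative")


def compute_contrast(matrix: ExpressionMatrix, injection: str,
                     pseudocount: float = 1.0) -> pd.DataFrame:
    """Induction contrast (CHX+DEX vs CHX) for one injection group.

    Replicate FPKM values are averaged per treatment arm before the fold
    change; the log2 fold change uses a pseudocount on both means:
    ``log2((mean_dex + pc) / (mean_chx + pc))``.

    Returns a DataFrame indexed by gene_id with columns ``mean_fpkm_chx``,
    ``mean_fpkm_dex`` and ``log2fc``.
    """
    if injection not in INJECTIONS:
        raise ContrastError(f"unknown injection group {injection!r}")
    chx = matrix.sample_ids(injection=injection, treatment="chx")
    dex = matrix.sample_ids(injection=injection, treatment="chx_dex")
    if not chx:
        raise ContrastError(f"no CHX samples for injection group {injection!r}")
    if not dex:
        raise ContrastError(f"no CHX+DEX samples for injection group {injection!r}")
    mean_chx = matrix.values[chx].mean(axis=1)
    mean_dex = matrix.values[dex].mean(axis=1)
    log2fc = np.log2((mean_dex + pseudocount) / (mean_chx + pseudocount))
    return pd.DataFrame({
        "mean_fpkm_chx": mean_chx,
        "mean_fpkm_dex": mean_dex,
        "log2fc": log2fc,
    })


def de_pass_mask(experimental: pd.DataFrame, control: pd.DataFrame | None,
                 criteria: DEFilterCriteria, direction: str) -> pd.Series:
    """Boolean per-gene mask of the filter cascade for one direction.

    ``control`` is the un-injected group's contrast table over the same
    genes; pass ``None`` to skip the control criterion (used when a design
    carries no un-injected arm).
    """
    if direction not in ("up", "down"):
        raise ContrastError(f"direction must be 'up' or 'down', got {direction!r}")
    if control is not None:
        if set(experimental.index) != set(control.index):
            raise ContrastError(
                "experimental and control contrasts cover different genes")
        control = control.loc[experimental.index]

    fc = experimental["log2fc"]
    if direction == "up":
        floor_ok = experimental["mean_fpkm_dex"] >= criteria.fpkm_min
        fc_ok = fc >= criteria.fc_min_log2
    else:
        floor_ok = experimental["mean_fpkm_chx"] >= criteria.fpkm_min
        fc_ok = fc <= -criteria.fc_min_log2

    if control is None:
        ctrl_ok = pd.Series(True, index=experimental.index)
    else:
        cfc = control["log2fc"]
        if criteria.control_rule == "delta":
            delta = fc - cfc if direction == "up" else cfc - fc
            ctrl_ok = delta >= criteria.control_delta_min_log2
        else:
            if direction == "up":
                ctrl_ok = cfc < criteria.control_abs_max_log2
            else:
                ctrl_ok = cfc > -criteria.control_abs_max_log2
    return floor_ok & fc_ok & ctrl_ok


def apply_de_filters(experimental: pd.DataFrame, control: pd.DataFrame | None,
                     criteria: DEFilterCriteria, direction: str) -> set[str]:
    """Gene ids passing the three-criterion filter in ``direction``."""
    mask = de_pass_mask(experimental, control, criteria, direction)
    return set(experimental.index[mask])


def contrast_report(experimental: pd.DataFrame, control: pd.DataFrame | None,
                    criteria: DEFilterCriteria) -> pd.DataFrame:
    """Per-group output table: contrast values, control fold change, and
    pass flags for both directions."""
    out = experimental.copy()
    if control is not None:
        out["control_log2fc"] = control.loc[out.index, "log2fc"]
    out["pass_up"] = de_pass_mask(experimental, control, criteria, "up")
    out["pass_down"] = de_pass_mask(experimental, control, criteria, "down")
    return out
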