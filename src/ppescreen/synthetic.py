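"""Synthetic FPKM matrices with planted direct-target structure.

Emulates the explant screen design: four injection groups (Six1-GR alone,
Eya1-GR alone, both together, and un-injected controls), each split into a
CHX arm (translation blocked, factor kept cytoplasmic) and a CHX+DEX arm
(factor translocated to the nucleus), with a small number of biological
replicates per arm.

Planted gene classes encode the response-threshold model of the screen:

``coreg_high_threshold``
    Responds to either factor alone (and to both): induced in the DEX arm
    of all three injected groups.
``coreg_low_threshold``
    Requires both factors above endogenous levels: induced only in the
    combined-injection group.
``six1_only`` / ``eya1_only``
    Responds whenever the named factor is overexpressed (alone or in the
    combination), independently of the other factor.
``dex_artifact``
    Responds to dexamethasone itself: induced in every group including the
    un-injected control. The control filter of the screen must remove these.
``null``
    No planted effect anywhere.

Expression is generated in log2(FPKM + 1) space: a gene's baseline level is
drawn once, planted effects are added only in DEX samples of the affected
groups, i.i.d. Gaussian replicate noise is added per sample, and FPKM is
recovered as ``2**x - 1`` (clipped at zero). Working in the shifted space
means a planted effect of ``e`` log2 units is exactly the pseudocount-1
induction fold change the contrast stage computes, so truth tables and
measured contrasts share a scale. By default baselines are floored at
FPKM = 1, mirroring a transcriptome from which low-expressed genes have
already been removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import INJECTIONS, TREATMENTS, ExpressionMatrix

GENE_CLASSES = (
    "null",
    "coreg_low_threshold",
    "coreg_high_threshold",
    "six1_only",
    "eya1_only",
    "dex_artifact",
)

#: Injection groups whose DEX arm carries the planted effect, per class.
AFFECTED_GROUPS: Mapping[str, tuple[str, ...]] = {
    "null": (),
    "coreg_low_threshold": ("six1_eya1",),
    "coreg_high_threshold": ("six1", "eya1", "six1_eya1"),
    "six1_only": ("six1", "six1_eya1"),
    "eya1_only": ("eya1", "six1_eya1"),
    "dex_artifact": ("six1", "eya1", "six1_eya1", "uninjected"),
}

DEFAULT_CLASS_PROPORTIONS: Mapping[str, float] = {
    "null": 0.87,
    "coreg_low_threshold": 0.04,
    "coreg_high_threshold": 0.01,
    "six1_only": 0.03,
    "eya1_only": 0.03,
    "dex_artifact": 0.02,
}


class SimulationConfigError(ValueError):
    """Invalid simulation parameters."""


@dataclass
class SimulationConfig:
    """Parameters of one simulated screen.

    Effect magnitudes are log2 units; ``effect_log2_mean``/``effect_log2_sd``
    may be scalars (applied to every non-null class) or per-class mappings.
    ``down_fraction`` is the fraction of each effect-carrying class planted
    with a negative (down-regulated) effect.
    """

    n_genes: int = 2000
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS))
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 2.0
    baseline_log2_min: float | None = 1.0
    effect_log2_mean: float | Mapping[str, float] = 3.0
    effect_log2_sd: float | Mapping[str, float] = 0.5
    down_fraction: float = 0.37
    replicate_noise_sd: float = 0.3
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise SimulationConfigError("n_genes must be >= 1")
        if self.n_replicates < 1:
            raise SimulationConfigError("n_replicates must be >= 1")
        unknown = set(self.class_proportions) - set(GENE_CLASSES)
        if unknown:
            raise SimulationConfigError(f"unknown gene classes: {sorted(unknown)}")
        if any(p < 0 for p in self.class_proportions.values()):
            raise SimulationConfigError("class proportions must be non-negative")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationConfigError(
                f"class proportions sum to {total}, expected 1")
        if self.baseline_log2_sd < 0 or self.replicate_noise_sd < 0:
            raise SimulationConfigError("sd parameters must be non-negative")
        for sd in self._per_class(self.effect_log2_sd).values():
            if sd < 0:
                raise SimulationConfigError("effect sd must be non-negative")
        if not 0.0 <= self.down_fraction <= 1.0:
            raise SimulationConfigError("down_fraction must be in [0, 1]")

    def _per_class(self, value: float | Mapping[str, float]) -> dict[str, float]:
        if isinstance(value, Mapping):
            unknown = set(value) - set(GENE_CLASSES)
            if unknown:
                raise SimulationConfigError(
                    f"effect parameters name unknown classes: {sorted(unknown)}")
            return dict(value)
        return {c: float(value) for c in GENE_CLASSES if c != "null"}

    def effect_mean(self, gene_class: str) -> float:
        return self._per_class(self.effect_log2_mean).get(gene_class, 0.0)

    def effect_sd(self, gene_class: str) -> float:
        return self._per_class(self.effect_log2_sd).get(gene_class, 0.0)


def _allocate_counts(n: int, proportions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of ``n`` genes to classes."""
    keys = [c for c in GENE_CLASSES if c in proportions]
    exact = {c: n * proportions[c] for c in keys}
    counts = {c: math.floor(exact[c]) for c in keys}
    short = n - sum(counts.values())
    by_remainder = sorted(keys, key=lambda c: (-(exact[c] - counts[c]), c))
    for c in by_remainder[:short]:
        counts[c] += 1
    return counts


EFFECT_COLUMNS = [f"effect_{g}" for g in INJECTIONS]


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate one simulated screen and its truth table.

    Returns the FPKM matrix (4 injection groups x 2 treatments x
    ``n_replicates`` samples) and a truth table with one row per gene:
    ``gene_class``, ``direction`` (``up``/``down``, empty for nulls),
    ``baseline_log2`` and the planted log2 effect per injection group.
    Identical configs (including seed) yield identical outputs.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    rng_effect = np.random.default_rng(seeds[0])
    rng_baseline = np.random.default_rng(seeds[1])
    rng_noise = np.random.default_rng(seeds[2])

    n = config.n_genes
    counts = _allocate_counts(n, config.class_proportions)
    classes: list[str] = []
    for c in GENE_CLASSES:
        classes.extend([c] * counts.get(c, 0))
    gene_ids = [f"gene{i:06d}" for i in range(n)]

    directions: list[str] = []
    signed_effects = np.zeros(n)
    start = 0
    for c in GENE_CLASSES:
        k = counts.get(c, 0)
        if k == 0:
            continue
        block = slice(start, start + k)
        start += k
        if c == "null":
            directions.extend([""] * k)
            continue
        n_down = int(round(k * config.down_fraction))
        directions.extend(["down"] * n_down + ["up"] * (k - n_down))
        mag = rng_effect.normal(config.effect_mean(c), config.effect_sd(c), size=k)
        mag = np.clip(mag, 0.0, None)
        sign = np.where(np.arange(k) < n_down, -1.0, 1.0)
        signed_effects[block] = sign * mag

    baseline = rng_baseline.normal(
        config.baseline_log2_mean, config.baseline_log2_sd, size=n)
    if config.baseline_log2_min is not None:
        # emulate a transcriptome already floored at low expression
        baseline = np.clip(baseline, config.baseline_log2_min, None)

    effects = pd.DataFrame(0.0, index=pd.Index(gene_ids, name="gene_id"),
                           columns=EFFECT_COLUMNS)
    class_arr = np.asarray(classes)
    for c in GENE_CLASSES:
        mask = class_arr == c
        if not mask.any():
            continue
        for group in AFFECTED_GROUPS[c]:
            effects.loc[mask, f"effect_{group}"] = signed_effects[mask]

    sample_rows = []
    columns = {}
    for injection in INJECTIONS:
        for treatment in TREATMENTS:
            for rep in range(1, config.n_replicates + 1):
                sid = f"{injection}_{treatment}_r{rep}"
                sample_rows.append(
                    {"sample_id": sid, "injection": injection,
                     "treatment": treatment, "replicate": rep})
                x = baseline.copy()
                if treatment == "chx_dex":
                    x = x + effects[f"effect_{injection}"].to_numpy()
                if config.replicate_noise_sd > 0:
                    x = x + rng_noise.normal(0.0, config.replicate_noise_sd, size=n)
                columns[sid] = np.clip(np.exp2(x) - 1.0, 0.0, None)

    values = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    matrix = ExpressionMatrix(values=values, samples=samples)

    truth = pd.DataFrame(
        {"gene_class": classes, "direction": directions,
         "baseline_log2": baseline},
        index=pd.Index(gene_ids, name="gene_id"),
    ).join(effects)
    return matrix, truth


def expected_log2fc(truth: pd.DataFrame) -> pd.DataFrame:
    """Noise-free expected induction contrast per gene and injection group.

    Null genes map to zero in every group. Raises on a truth table whose
    ``gene_class`` column contains unknown classes.
    """
    unknown = set(truth["gene_class"]) - set(GENE_CLASSES)
    if unknown:
        raise SimulationConfigError(f"unknown gene classes: {sorted(unknown)}")
    out = truth[EFFECT_COLUMNS].copy()
    out.columns = list(INJECTIONS)
    return out


def write_truth_table(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index_label="gene_id")


def read_truth_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
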