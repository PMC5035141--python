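"""Reading, writing and pre-filtering of expression tables and annotation hits.

The screen's universal substrate is a gene x sample matrix of FPKM values
together with a sample sheet describing the factorial design: injection
group (``six1``, ``eya1``, ``six1_eya1`` or ``uninjected``) crossed with
treatment (``chx``: translation blocked, hormone withheld; ``chx_dex``:
translation blocked, nuclear translocation of the GR-fusion factor induced
by dexamethasone) and a replicate index.

Annotation of assembled transcript models against an mRNA database arrives
as BLAST tabular (outfmt 6) best hits; :func:`condense_annotations` reduces
the transcript-level matrix to one row per distinct annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

INJECTIONS = ("six1", "eya1", "six1_eya1", "uninjected")
TREATMENTS = ("chx", "chx_dex")

SAMPLE_SHEET_COLUMNS = ("sample_id", "injection", "treatment", "replicate")

#: Column order of NCBI BLAST tabular output (-outfmt 6).
BLAST_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


class ExpressionIOError(ValueError):
    """Malformed expression table, sample sheet or annotation file."""


@dataclass(frozen=True)
class SampleDescriptor:
    """Design metadata for one RNA-seq sample."""

    sample_id: str
    injection: str
    treatment: str
    replicate: int

    def __post_init__(self) -> None:
        if self.injection not in INJECTIONS:
            raise ExpressionIOError(
                f"sample {self.sample_id!r}: unknown injection token "
                f"{self.injection!r} (expected one of {INJECTIONS})"
            )
        if self.treatment not in TREATMENTS:
            raise ExpressionIOError(
                f"sample {self.sample_id!r}: unknown treatment token "
                f"{self.treatment!r} (expected one of {TREATMENTS})"
            )
        if int(self.replicate) < 1:
            raise ExpressionIOError(
                f"sample {self.sample_id!r}: replicate must be a positive integer"
            )


@dataclass
class ExpressionMatrix:
    """Gene x sample FPKM matrix with a design-aware sample sheet.

    Parameters
    ----------
    values
        DataFrame indexed by ``gene_id`` with one column per ``sample_id``;
        entries are non-negative FPKM.
    samples
        DataFrame indexed by ``sample_id`` with columns ``injection``,
        ``treatment`` and ``replicate``; row order matches the column order
        of ``values``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ExpressionIOError(f"duplicate gene ids: {dups[:5]}")
        if (self.values.to_numpy() < 0).any():
            raise ExpressionIOError("negative FPKM values in expression matrix")
        missing = [s for s in self.values.columns if s not in self.samples.index]
        if missing:
            raise ExpressionIOError(
                f"samples present in matrix but absent from sample sheet: {missing}"
            )
        # validate tokens and uniqueness of design triples
        triples = set()
        for sid in self.samples.index:
            row = self.samples.loc[sid]
            desc = SampleDescriptor(
                sample_id=str(sid),
                injection=str(row["injection"]),
                treatment=str(row["treatment"]),
                replicate=int(row["replicate"]),
            )
            key = (desc.injection, desc.treatment, desc.replicate)
            if key in triples:
                raise ExpressionIOError(
                    f"duplicate (injection, treatment, replicate) triple {key}"
                )
            triples.add(key)
        # align sample sheet to matrix column order
        self.samples = self.samples.loc[list(self.values.columns)]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def sample_ids(self, injection: str | None = None,
                   treatment: str | None = None) -> list[str]:
        """Sample ids matching the given design cell (None = any)."""
        mask = pd.Series(True, index=self.samples.index)
        if injection is not None:
            mask &= self.samples["injection"] == injection
        if treatment is not None:
            mask &= self.samples["treatment"] == treatment
        return list(self.samples.index[mask])

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values[list(sample_ids)].copy(),
            samples=self.samples.loc[list(sample_ids)].copy(),
        )

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.loc[list(gene_ids)].copy(),
            samples=self.samples.copy(),
        )


@dataclass(frozen=True)
class AnnotationHit:
    """Best BLAST hit linking a transcript model to an annotation."""

    transcript_id: str
    annotation_id: str
    e_value: float
    bitscore: float
    gene_symbol: str = ""

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ExpressionIOError(
                f"hit {self.transcript_id!r}->{self.annotation_id!r}: "
                "negative e-value"
            )


def read_expression_table(matrix_path: str | Path,
                          sample_sheet_path: str | Path) -> ExpressionMatrix:
    """Read an FPKM TSV (first column ``gene_id``) and its sample sheet."""
    matrix_path, sample_sheet_path = Path(matrix_path), Path(sample_sheet_path)
    values = pd.read_csv(matrix_path, sep="\t", index_col="gene_id")
    sheet = pd.read_csv(sample_sheet_path, sep="\t", dtype={"sample_id": str})
    missing_cols = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing_cols:
        raise ExpressionIOError(
            f"sample sheet {sample_sheet_path} missing columns {missing_cols}"
        )
    if sheet["sample_id"].duplicated().any():
        raise ExpressionIOError("duplicate sample_id in sample sheet")
    sheet = sheet.set_index("sample_id")
    return ExpressionMatrix(values=values, samples=sheet)


def write_expression_table(matrix: ExpressionMatrix, matrix_path: str | Path,
                           sample_sheet_path: str | Path) -> None:
    matrix.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
    matrix.samples.to_csv(sample_sheet_path, sep="\t", index_label="sample_id")


def read_blast_tabular(path: str | Path,
                       e_value_cutoff: float = 1e-5) -> list[AnnotationHit]:
    """Parse 12-column BLAST tabular output into per-transcript best hits.

    Hits with e-value above ``e_value_cutoff`` are dropped. Of the remaining
    hits per query transcript, only the one with the highest bitscore is
    retained; ties go to the lowest e-value, then the lexicographically
    smallest subject id, so the result is deterministic.
    """
    hits: dict[str, tuple[float, float, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(BLAST_COLUMNS):
                raise ExpressionIOError(
                    f"{path}: line {lineno}: expected {len(BLAST_COLUMNS)} "
                    f"tab-separated fields, got {len(parts)}"
                )
            try:
                evalue = float(parts[10])
                bitscore = float(parts[11])
            except ValueError as exc:
                raise ExpressionIOError(
                    f"{path}: line {lineno}: non-numeric evalue/bitscore"
                ) from exc
            if evalue < 0:
                raise ExpressionIOError(
                    f"{path}: line {lineno}: negative e-value"
                )
            if evalue > e_value_cutoff:
                continue
            query, subject = parts[0], parts[1]
            # sort key: best = max bitscore, then min evalue, then min subject
            cand = (-bitscore, evalue, subject)
            if query not in hits or cand < hits[query]:
                hits[query] = cand
    return [
        AnnotationHit(transcript_id=q, annotation_id=subj,
                      e_value=ev, bitscore=-negbs)
        for q, (negbs, ev, subj) in sorted(hits.items())
    ]


def condense_annotations(
    matrix: ExpressionMatrix,
    hits: Sequence[AnnotationHit],
    rule: str = "max",
) -> tuple[ExpressionMatrix, int]:
    """Collapse the transcript-level matrix to one row per annotation.

    ``rule='max'`` (default) keeps, for each annotation hit by several
    transcript models, the model with the highest mean FPKM across all
    samples (ties to the lexicographically smallest transcript id); FPKM is
    length-normalised, so summing across models would double-count.
    ``rule='sum'`` sums FPKM across models instead. Unannotated transcripts
    are dropped; their count is returned alongside the condensed matrix.
    """
    if rule not in ("max", "sum"):
        raise ExpressionIOError(f"unknown condense rule {rule!r}")
    by_transcript: dict[str, str] = {}
    for hit in hits:
        if hit.transcript_id in by_transcript:
            raise ExpressionIOError(
                f"transcript {hit.transcript_id!r} has multiple hits; "
                "apply read_blast_tabular best-hit selection first"
            )
        by_transcript[hit.transcript_id] = hit.annotation_id

    annotated = [t for t in matrix.gene_ids if t in by_transcript]
    n_dropped = matrix.n_genes - len(annotated)
    sub = matrix.values.loc[annotated]
    ann = pd.Series({t: by_transcript[t] for t in annotated}, name="annotation_id")

    if rule == "sum":
        out = sub.groupby(ann, sort=True).sum()
    else:
        mean_fpkm = sub.mean(axis=1)
        keep = []
        # highest mean FPKM wins; ties to lexicographic transcript id
        order = sorted(annotated, key=lambda t: (-mean_fpkm[t], t))
        seen: set[str] = set()
        for t in order:
            a = ann[t]
            if a not in seen:
                seen.add(a)
                keep.append(t)
        out = sub.loc[keep]
        out.index = pd.Index([ann[t] for t in keep], name="gene_id")
        out = out.sort_index()
    out.index.name = "gene_id"
    condensed = ExpressionMatrix(values=out, samples=matrix.samples.copy())
    return condensed, n_dropped


def filter_low_expression(matrix: ExpressionMatrix,
                          fpkm_min: float = 1.0) -> ExpressionMatrix:
    """Drop genes whose mean FPKM across all samples is below ``fpkm_min``.

    The boundary is inclusive: a gene at exactly ``fpkm_min`` is retained.
    Row order is preserved.
    """
    if fpkm_min < 0:
        raise ExpressionIOError("fpkm_min must be non-negative")
    keep = matrix.values.mean(axis=1) >= fpkm_min
    return ExpressionMatrix(
        values=matrix.values.loc[keep].copy(),
        samples=matrix.samples.copy(),
    )
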