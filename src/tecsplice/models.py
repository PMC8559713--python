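"""Core domain types for the splice-isoform census.

Coordinate convention
---------------------
All genomic intervals are stored 0-based, half-open ``(start, end)``.
Conversion from the 1-based inclusive GTF convention happens exclusively in
:mod:`tecsplice.io` so there is a single conversion site in the package.

Exon lists are always kept sorted by genomic start, regardless of strand;
5'/3' orientation is resolved through the ``strand`` field wherever it
matters (UTR arithmetic, flanking-intron extraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "TranscriptModel",
    "Annotation",
    "SampleMeta",
    "ExpressionMatrix",
    "JunctionCounts",
    "TranscriptParts",
    "ValidationError",
    "transcript_parts",
]


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript on a genome.

    Parameters
    ----------
    transcript_id, gene_id, chrom : str
        Identifiers; ``chrom`` is the single chromosome the transcript lies on.
    strand : str
        ``"+"`` or ``"-"``. Unstranded features (``"."``) are accepted at
        construction but rejected by strand-dependent operations such as
        UTR decomposition.
    exons : list of (int, int)
        0-based half-open genomic intervals, sorted ascending and pairwise
        non-overlapping.
    cds : (int, int), optional
        Genomic span of the coding region. Both boundaries must fall inside
        the exon union.
    biotype : str
        Gene biotype the transcript belongs to (e.g. ``"protein_coding"``).
    novel : bool
        True for transcripts absent from the reference annotation.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: tuple[int, int] | None = None
    biotype: str = "protein_coding"
    novel: bool = False

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(
                f"{self.transcript_id}: strand must be '+', '-' or '.', got {self.strand!r}"
            )
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript has no exons")
        self.exons = [(int(s), int(e)) for s, e in self.exons]
        for s, e in self.exons:
            if e <= s:
                raise ValidationError(
                    f"{self.transcript_id}: exon ({s}, {e}) has end <= start"
                )
        if self.exons != sorted(self.exons):
            raise ValidationError(f"{self.transcript_id}: exons not sorted by start")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValidationError(
                    f"{self.transcript_id}: exons ({s1},{e1}) and ({s2},{e2}) overlap"
                )
        if self.cds is not None:
            cs, ce = int(self.cds[0]), int(self.cds[1])
            self.cds = (cs, ce)
            if ce <= cs:
                raise ValidationError(f"{self.transcript_id}: CDS end <= start")
            if not (self._exonic_overlap(cs, cs + 1) and self._exonic_overlap(ce - 1, ce)):
                raise ValidationError(
                    f"{self.transcript_id}: CDS boundaries outside exon union"
                )

    def _exonic_overlap(self, start: int, end: int) -> int:
        return sum(max(0, min(e, end) - max(s, start)) for s, e in self.exons)

    @property
    def length(self) -> int:
        """Mature transcript length: sum of exon lengths (nt)."""
        return sum(e - s for s, e in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def junctions(self) -> list[tuple[int, int]]:
        """Splice junctions as (donor_end, acceptor_start) genomic pairs.

        Coordinates are genomic (left exon end, right exon start) independent
        of strand; combined with ``strand`` they identify a junction uniquely.
        """
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    def introns(self) -> list[tuple[int, int]]:
        """Intron intervals (0-based half-open) between consecutive exons."""
        return [(d, a) for d, a in self.junctions()]


class TranscriptParts(NamedTuple):
    """Strand-aware UTR/CDS decomposition of a transcript (lengths in nt)."""

    utr5_len: int
    cds_len: int
    utr3_len: int
    coding: bool


def transcript_parts(t: TranscriptModel) -> TranscriptParts:
    """Split a transcript's mature length into 5'UTR, CDS and 3'UTR.

    For a coding transcript the three parts sum to the transcript length.
    The 5' end is the leftmost exon base on the plus strand and the
    rightmost on the minus strand. Non-coding transcripts return
    ``(0, 0, 0, coding=False)``.

    Raises
    ------
    ValidationError
        If the transcript is unstranded (UTR sides undefined) or the CDS is
        not fully exonic.
    """
    if t.cds is None:
        return TranscriptParts(0, 0, 0, False)
    if t.strand not in {"+", "-"}:
        raise ValidationError(
            f"{t.transcript_id}: unstranded transcript rejected for UTR analysis"
        )
    cs, ce = t.cds
    cds_len = t._exonic_overlap(cs, ce)
    left = sum(max(0, min(e, cs) - s) for s, e in t.exons if s < cs)
    right = sum(max(0, e - max(s, ce)) for s, e in t.exons if e > ce)
    if left + cds_len + right != t.length:
        raise ValidationError(f"{t.transcript_id}: CDS outside exon union")
    if t.strand == "+":
        return TranscriptParts(left, cds_len, right, True)
    return TranscriptParts(right, cds_len, left, True)


@dataclass
class Annotation:
    """A set of transcript models grouped by gene."""

    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)
    genes: dict[str, list[str]] = field(default_factory=dict)
    gene_biotype: dict[str, str] = field(default_factory=dict)

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self.transcripts:
            raise ValidationError(f"duplicate transcript_id {t.transcript_id}")
        self.transcripts[t.transcript_id] = t
        self.genes.setdefault(t.gene_id, []).append(t.transcript_id)
        self.gene_biotype.setdefault(t.gene_id, t.biotype)

    def gene_transcripts(self, gene_id: str) -> list[TranscriptModel]:
        return [self.transcripts[tid] for tid in self.genes[gene_id]]

    def n_isoforms(self) -> pd.Series:
        """Number of annotated isoforms per gene."""
        return pd.Series(
            {g: len(tids) for g, tids in self.genes.items()}, name="n_isoforms"
        )

    def transcript_gene(self) -> pd.Series:
        """transcript_id -> gene_id mapping as a Series."""
        return pd.Series(
            {tid: t.gene_id for tid, t in self.transcripts.items()}, name="gene_id"
        )

    def validate(self) -> None:
        for tid, t in self.transcripts.items():
            if t.gene_id not in self.genes:
                raise ValidationError(f"{tid}: gene {t.gene_id} missing from gene index")
        for g, tids in self.genes.items():
            if len(set(tids)) != len(tids):
                raise ValidationError(f"{g}: duplicate transcript ids")


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one RNA-seq sample."""

    sample_id: str
    tissue: str
    condition: str = "control"
    replicate: int = 1


@dataclass
class ExpressionMatrix:
    """Feature x sample abundance table with sample metadata.

    ``values`` is a pandas DataFrame (rows = features, columns = sample ids);
    ``feature_level`` is ``"gene"`` or ``"transcript"``; ``unit`` records
    whether values are TPM or counts.
    """

    values: pd.DataFrame
    feature_level: str
    samples: list[SampleMeta]
    unit: str = "TPM"

    def __post_init__(self) -> None:
        if self.feature_level not in {"gene", "transcript"}:
            raise ValidationError(f"bad feature_level {self.feature_level!r}")
        if self.values.shape[1] < 1:
            raise ValidationError("expression matrix needs at least one sample")
        if not self.values.index.is_unique:
            raise ValidationError("feature ids are not unique")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("negative expression values")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample_id in metadata")
        if list(self.values.columns) != ids:
            raise ValidationError("sample metadata does not match matrix columns")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def meta(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def samples_where(self, **conditions: str) -> list[str]:
        """Sample ids whose metadata match all given field=value pairs."""
        out = []
        for s in self.samples:
            if all(getattr(s, k) == v for k, v in conditions.items()):
                out.append(s.sample_id)
        return out

    def by_tissue(self, tissues: Iterable[str] | None = None) -> pd.DataFrame:
        """Collapse to one column per tissue (mean across that tissue's samples).

        Raises
        ------
        ValidationError
            If the resulting tissue columns would be duplicated.
        """
        wanted = None if tissues is None else list(tissues)
        groups: dict[str, list[str]] = {}
        for s in self.samples:
            if wanted is None or s.tissue in wanted:
                groups.setdefault(s.tissue, []).append(s.sample_id)
        if wanted is not None:
            missing = [t for t in wanted if t not in groups]
            if missing:
                raise ValidationError(f"tissues absent from matrix: {missing}")
            if len(wanted) != len(set(wanted)):
                raise ValidationError("duplicate tissue columns requested")
        cols = {t: self.values[ids].mean(axis=1) for t, ids in sorted(groups.items())}
        return pd.DataFrame(cols)

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        metas = [self.meta(s) for s in sample_ids]
        return ExpressionMatrix(
            self.values[sample_ids].copy(), self.feature_level, metas, self.unit
        )


@dataclass
class JunctionCounts:
    """Per-sample read support for splice junctions.

    ``counts`` has a MultiIndex (gene_id, donor, acceptor, strand) and one
    integer column per sample. ``donor``/``acceptor`` are the genomic
    (exon-end, next-exon-start) coordinates of the junction.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.counts.index
        if list(idx.names) != ["gene_id", "donor", "acceptor", "strand"]:
            raise ValidationError(
                "junction index must be (gene_id, donor, acceptor, strand)"
            )
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValidationError("negative junction counts")
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("junction counts must be integral")
        don = idx.get_level_values("donor")
        acc = idx.get_level_values("acceptor")
        if (don == acc).any():
            raise ValidationError("junction with donor == acceptor")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def junctions_per_gene(self, min_reads: int = 1) -> pd.DataFrame:
        """Distinct supported junctions per gene per sample.

        A junction is counted in a sample when its read support is at least
        ``min_reads``.
        """
        supported = (self.counts >= min_reads).astype(int)
        return supported.groupby(level="gene_id").sum()
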