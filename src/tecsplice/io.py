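"""Readers and writers for GTF, FASTA and the pipeline's TSV tables.

GTF handling follows the Ensembl dialect (attributes ``gene_id``,
``transcript_id``, ``gene_biotype``). Files are 1-based inclusive on disk;
the conversion to the package's internal 0-based half-open convention
happens here and only here. Parsing is delegated to :mod:`gffutils` after a
light line-validation pass so that malformed input can be reported with a
line number.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    Annotation,
    ExpressionMatrix,
    JunctionCounts,
    SampleMeta,
    TranscriptModel,
    ValidationError,
)

logger = logging.getLogger("tecsplice")

__all__ = [
    "GtfParseError",
    "read_gtf",
    "write_gtf",
    "read_fasta",
    "write_fasta",
    "read_expression",
    "write_expression",
    "read_junctions",
    "write_junctions",
    "read_id_list",
    "write_id_list",
]

_STRANDS = {"+", "-", "."}


class GtfParseError(ValueError):
    """Raised for malformed GTF input; message names the offending line."""


def _validate_gtf_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GtfParseError(
                    f"{path}:{lineno}: non-integer coordinates {fields[3]!r}/{fields[4]!r}"
                ) from exc
            if start < 1 or end < start:
                raise GtfParseError(
                    f"{path}:{lineno}: invalid coordinate range {start}-{end}"
                )
            if fields[6] not in _STRANDS:
                raise GtfParseError(f"{path}:{lineno}: invalid strand {fields[6]!r}")


def read_gtf(path: str | Path) -> Annotation:
    """Read an Ensembl-dialect GTF into an :class:`Annotation`.

    1-based inclusive coordinates are converted to 0-based half-open; exons
    are stored ascending by genomic start regardless of strand. Transcripts
    without any exon line are dropped with a warning. A transcript whose
    features span more than one chromosome (or strand) raises
    :class:`~tecsplice.models.ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"GTF file not found: {path}")
    _validate_gtf_lines(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    info: dict[str, dict] = {}
    seen: set[str] = set()
    for feat in db.all_features():
        if feat.featuretype not in {"exon", "CDS", "transcript"}:
            continue
        tid = feat.attributes.get("transcript_id", [None])[0]
        gid = feat.attributes.get("gene_id", [None])[0]
        if tid is None or gid is None:
            raise GtfParseError(
                f"{path}: feature at {feat.seqid}:{feat.start} lacks "
                "gene_id/transcript_id attributes"
            )
        seen.add(tid)
        rec = info.setdefault(
            tid,
            {
                "gene_id": gid,
                "chrom": feat.seqid,
                "strand": feat.strand,
                "biotype": feat.attributes.get("gene_biotype", ["protein_coding"])[0],
                "novel": feat.attributes.get("novel", ["false"])[0].lower() == "true",
            },
        )
        if rec["chrom"] != feat.seqid:
            raise ValidationError(f"{tid}: transcript spans multiple chromosomes")
        if rec["strand"] != feat.strand:
            raise ValidationError(f"{tid}: inconsistent strand between features")
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append((feat.start - 1, feat.end))
        elif feat.featuretype == "CDS":
            cds.setdefault(tid, []).append((feat.start - 1, feat.end))

    ann = Annotation()
    for tid in sorted(seen):
        if tid not in exons:
            logger.warning("stage=read_gtf transcript=%s rejected=no_exon_line", tid)
            continue
        rec = info[tid]
        spans = cds.get(tid)
        cds_span = (min(s for s, _ in spans), max(e for _, e in spans)) if spans else None
        ann.add(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=sorted(exons[tid]),
                cds=cds_span,
                biotype=rec["biotype"],
                novel=rec["novel"],
            )
        )
    ann.validate()
    logger.info(
        "stage=read_gtf input=%s transcripts=%d genes=%d",
        path, len(ann.transcripts), len(ann.genes),
    )
    return ann


def _attr(gene_id: str, tid: str, biotype: str, novel: bool) -> str:
    return (
        f'gene_id "{gene_id}"; transcript_id "{tid}"; '
        f'gene_biotype "{biotype}"; novel "{str(novel).lower()}";'
    )


def write_gtf(annotation: Annotation, path: str | Path) -> None:
    """Write an annotation as Ensembl-dialect GTF (1-based inclusive).

    Output is deterministic: features are ordered by (gene_id,
    transcript_id, exon start), so identical annotations produce
    byte-identical files.
    """
    path = Path(path)
    lines = ["#!tecsplice transcript models; coordinates 1-based inclusive"]
    for gid in sorted(annotation.genes):
        for tid in sorted(annotation.genes[gid]):
            t = annotation.transcripts[tid]
            attrs = _attr(gid, tid, t.biotype, t.novel)
            lines.append(
                "\t".join(
                    [t.chrom, "tecsplice", "transcript", str(t.start + 1),
                     str(t.end), ".", t.strand, ".", attrs]
                )
            )
            for s, e in t.exons:
                lines.append(
                    "\t".join(
                        [t.chrom, "tecsplice", "exon", str(s + 1), str(e),
                         ".", t.strand, ".", attrs]
                    )
                )
            if t.cds is not None:
                cs, ce = t.cds
                lines.append(
                    "\t".join(
                        [t.chrom, "tecsplice", "CDS", str(cs + 1), str(ce),
                         ".", t.strand, "0", attrs]
                    )
                )
    path.write_text("\n".join(lines) + "\n")
    logger.info("stage=write_gtf output=%s lines=%d", path, len(lines))


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a chrom -> sequence mapping (upper-case)."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sorted(genome.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def write_expression(
    matrix: ExpressionMatrix, values_path: str | Path, samples_path: str | Path
) -> None:
    """Write an expression matrix plus its sample-metadata sheet as TSV."""
    out = matrix.values.copy()
    out.index.name = "feature_id"
    out.to_csv(values_path, sep="\t", na_rep=".", float_format="%.6g")
    meta = pd.DataFrame(
        [
            {"sample_id": s.sample_id, "tissue": s.tissue,
             "condition": s.condition, "replicate": s.replicate}
            for s in matrix.samples
        ]
    )
    meta.to_csv(samples_path, sep="\t", index=False)


def read_expression(
    values_path: str | Path,
    samples_path: str | Path,
    feature_level: str,
    unit: str = "TPM",
) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0, na_values=".")
    meta = pd.read_csv(samples_path, sep="\t")
    samples = [
        SampleMeta(str(r.sample_id), str(r.tissue), str(r.condition), int(r.replicate))
        for r in meta.itertuples()
    ]
    return ExpressionMatrix(values, feature_level, samples, unit)


def write_junctions(junctions: JunctionCounts, path: str | Path) -> None:
    junctions.counts.reset_index().to_csv(path, sep="\t", index=False)


def read_junctions(path: str | Path) -> JunctionCounts:
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(["gene_id", "donor", "acceptor", "strand"])
    return JunctionCounts(df)


def write_id_list(ids, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(map(str, ids))) + ("\n" if len(ids) else ""))


def read_id_list(path: str | Path) -> set[str]:
    text = Path(path).read_text()
    return {line.strip() for line in text.splitlines() if line.strip()}
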