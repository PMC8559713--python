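"""Differential transcript usage and transcript-structure analysis.

Aire, the facilitator of promiscuous gene expression in medullary TEC, is
assessed here through three lenses: which transcripts drop when Aire is
knocked out (NB exact test per transcript, fold change >= 2 at BH p <
0.05), whether a transcript is "classical" (a coding transcript with both
a 5' and a 3' UTR), and whether Aire-dependent transcripts differ in
length and in per-part (5'UTR / CDS / 3'UTR) composition from their
non-Aire-dependent counterparts (Kolmogorov-Smirnov and rank-sum tests).
Transcript length throughout is the mature length (sum of exon lengths).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import Annotation, TranscriptModel, transcript_parts
from .stats import bh_adjust, nb_exact_test, normalize_libsize

__all__ = [
    "StructureClass",
    "transcript_usage_test",
    "classify_structure",
    "structure_table",
    "length_shift_tests",
    "aire_length_analysis",
]


@dataclass(frozen=True)
class StructureClass:
    """Structural class of one transcript: classical / nonclassical / unannotated."""

    transcript_id: str
    structure: str
    utr5_len: int
    cds_len: int
    utr3_len: int


def classify_structure(t: TranscriptModel) -> StructureClass:
    """Classify a transcript's structure.

    classical = CDS present with both UTRs non-empty; nonclassical = CDS
    present but a missing UTR; unannotated = no CDS.
    """
    parts = transcript_parts(t)
    if not parts.coding:
        cls = "unannotated"
    elif parts.utr5_len > 0 and parts.utr3_len > 0:
        cls = "classical"
    else:
        cls = "nonclassical"
    return StructureClass(t.transcript_id, cls, parts.utr5_len, parts.cds_len,
                          parts.utr3_len)


def structure_table(annotation: Annotation) -> pd.DataFrame:
    """Structure class and part lengths for every transcript."""
    rows = []
    for tid in sorted(annotation.transcripts):
        t = annotation.transcripts[tid]
        sc = classify_structure(t)
        rows.append(
            {"transcript_id": tid, "gene_id": t.gene_id, "structure": sc.structure,
             "length": t.length, "utr5_len": sc.utr5_len, "cds_len": sc.cds_len,
             "utr3_len": sc.utr3_len}
        )
    return pd.DataFrame(rows).set_index("transcript_id")


def transcript_usage_test(
    transcript_counts: pd.DataFrame,
    ko_samples: list[str],
    pos_samples: list[str],
    dispersion: float = 0.1,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Differential transcript usage, Aire-knockout versus Aire-positive TEC.

    Per transcript NB exact test on replicate counts; a transcript is
    Aire-regulated (positively) when it is higher in the Aire-positive
    condition with fold change >= ``fc_threshold`` and BH p < ``alpha``.
    Returns the MA-plot table (mean expression, fold change, significance).
    """
    if len(ko_samples) < 2 or len(pos_samples) < 2:
        raise ValueError("need >= 2 replicates per condition")
    counts = transcript_counts[ko_samples + pos_samples]
    factors, _ = normalize_libsize(counts)
    f_ko = factors[ko_samples].to_numpy()
    f_pos = factors[pos_samples].to_numpy()
    recs = []
    for tid, row in counts.iterrows():
        r = nb_exact_test(
            row[ko_samples].to_numpy(float), row[pos_samples].to_numpy(float),
            dispersion, f_ko, f_pos,
        )
        recs.append((tid, (r.mean_a + r.mean_b) / 2.0, 2.0 ** r.log2_fold_change,
                     r.direction, r.p))
    out = pd.DataFrame(
        recs, columns=["transcript_id", "mean_expression", "fold_change",
                       "direction", "p"]
    ).set_index("transcript_id")
    out["padj"] = bh_adjust(out["p"].to_numpy())
    out["aire_regulated"] = (
        (out["direction"] == "b>a")  # higher in Aire-positive
        & (out["fold_change"] >= fc_threshold)
        & (out["padj"] < alpha)
    )
    return out


def length_shift_tests(lengths_a, lengths_b) -> dict:
    """Compare two transcript-length distributions.

    Returns the exact two-sample KS statistic with its p-value, the
    two-sided rank-sum (Mann-Whitney, midranks with tie correction)
    p-value, and the mean difference (B - A).
    """
    a = np.asarray(lengths_a, dtype=float)
    b = np.asarray(lengths_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 observations per group")
    ks = sps.ks_2samp(a, b)
    if np.array_equal(np.sort(a), np.sort(b)):
        mwu_p = 1.0
    else:
        mwu_p = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    mean_diff = float(b.mean() - a.mean())
    return {
        "ks_statistic": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "ranksum_p": mwu_p,
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "mean_diff": mean_diff,
        "percent_diff": float(100.0 * mean_diff / a.mean()) if a.mean() else float("nan"),
        "n_a": int(a.size),
        "n_b": int(b.size),
    }


def aire_length_analysis(
    annotation: Annotation,
    usage: pd.DataFrame,
) -> dict:
    """Length/structure comparison of Aire-regulated vs other transcripts.

    Restricted, as in pipeline mode, to genes containing at least one
    significantly Aire-regulated transcript. Returns total-length tests,
    per-part (5'UTR/CDS/3'UTR) tests over coding transcripts, and the
    structure-class composition of both groups.
    """
    struct = structure_table(annotation)
    struct = struct.join(usage[["aire_regulated"]], how="inner")
    gene_has = struct.groupby("gene_id")["aire_regulated"].any()
    struct = struct[struct["gene_id"].map(gene_has)]
    reg = struct[struct["aire_regulated"]]
    other = struct[~struct["aire_regulated"]]
    if len(reg) < 2 or len(other) < 2:
        raise ValueError("too few transcripts in a comparison group")
    result = {
        "length": length_shift_tests(other["length"], reg["length"]),
        "structure_fraction_classical": {
            "aire_regulated": float((reg["structure"] == "classical").mean()),
            "other": float((other["structure"] == "classical").mean()),
        },
        "n_genes": int(gene_has.sum()),
    }
    coding_reg = reg[reg["structure"] != "unannotated"]
    coding_other = other[other["structure"] != "unannotated"]
    for part in ("utr5_len", "cds_len", "utr3_len"):
        if len(coding_reg) >= 2 and len(coding_other) >= 2:
            result[part] = length_shift_tests(coding_other[part], coding_reg[part])
    return result
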