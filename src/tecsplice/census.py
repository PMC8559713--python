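"""Detection-based transcriptome census.

Operations here quantify how completely a sample represents an annotated
transcriptome: per-sample detection fractions across TPM thresholds, the
fraction of a gene's annotated isoforms detected (the core comparison
between TEC-like and peripheral samples for tissue-restricted genes), the
gene-versus-transcript ANCOVA, Shannon entropy of isoform usage, the
alternatively-spliced fraction of multi-isoform genes by expression
quartile, and the representation of peripheral tissue-restricted
transcript sets in a target sample.

Detection is strict: a feature is detected when TPM > threshold (default
threshold 0).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .models import Annotation, ExpressionMatrix

logger = logging.getLogger("tecsplice")

__all__ = [
    "detect",
    "detection_fraction_curve",
    "census_summary",
    "isoform_fraction",
    "gene_transcript_ancova",
    "splice_entropy",
    "entropy_by_gene",
    "multi_isoform_as_fraction",
    "peripheral_representation",
    "uniquely_detected",
]


def detect(expr: ExpressionMatrix, threshold: float = 0.0) -> pd.DataFrame:
    """Boolean detection matrix: value > threshold (strict)."""
    if threshold < 0:
        raise ValueError("detection threshold must be non-negative")
    return expr.values > threshold


def detection_fraction_curve(
    expr: ExpressionMatrix,
    universe,
    thresholds=(0.0, 0.1, 0.5, 1.0, 2.0, 5.0),
) -> pd.DataFrame:
    """Fraction of a feature universe detected per sample per TPM threshold.

    Rows are thresholds, columns samples. The universe (e.g. all annotated
    protein-coding transcripts) must be non-empty; universe features absent
    from the matrix count as undetected.
    """
    universe = list(universe)
    if not universe:
        raise ValueError("empty feature universe")
    sub = expr.values.reindex(universe).fillna(0.0)
    rows = {}
    for thr in thresholds:
        if thr < 0:
            raise ValueError("detection threshold must be non-negative")
        rows[thr] = (sub > thr).sum(axis=0) / len(universe)
    out = pd.DataFrame(rows).T
    out.index.name = "threshold"
    return out


def census_summary(
    transcript_det: pd.DataFrame,
    annotation: Annotation,
) -> pd.DataFrame:
    """Per-sample detected gene/transcript counts, split known vs novel."""
    t2g = annotation.transcript_gene()
    novel = pd.Series(
        {tid: t.novel for tid, t in annotation.transcripts.items()}, name="novel"
    )
    det = transcript_det.reindex(t2g.index).fillna(False)
    rows = []
    for sample in det.columns:
        hits = det[sample]
        rows.append(
            {
                "sample_id": sample,
                "transcripts_detected": int(hits.sum()),
                "genes_detected": int(t2g[hits].nunique()),
                "known_detected": int((hits & ~novel).sum()),
                "novel_detected": int((hits & novel).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def isoform_fraction(
    transcript_det: pd.DataFrame,
    annotation: Annotation,
    categories: pd.Series | None = None,
) -> pd.DataFrame:
    """Fraction of annotated isoforms detected per multi-isoform gene per sample.

    Single-isoform genes are excluded (and counted in the log). Returns a
    long table (gene_id, sample_id, n_isoforms, n_detected, fraction,
    category) where ``category`` comes from the optional gene-category
    Series.
    """
    n_iso = annotation.n_isoforms()
    multi = n_iso[n_iso >= 2]
    logger.info(
        "stage=isoform_fraction multi_isoform_genes=%d single_excluded=%d",
        len(multi), int((n_iso < 2).sum()),
    )
    t2g = annotation.transcript_gene()
    det = transcript_det.reindex(t2g.index).fillna(False)
    detected = det.groupby(t2g).sum().reindex(multi.index).fillna(0)
    frac = detected.div(multi, axis=0)
    long = frac.stack().rename("fraction").reset_index()
    long.columns = ["gene_id", "sample_id", "fraction"]
    long["n_isoforms"] = long["gene_id"].map(multi)
    long["n_detected"] = detected.stack().reindex(
        pd.MultiIndex.from_frame(long[["gene_id", "sample_id"]])
    ).to_numpy().astype(int)
    if categories is not None:
        long["category"] = long["gene_id"].map(categories)
    return long


def gene_transcript_ancova(
    summary: pd.DataFrame,
    group_col: str = "group",
    exclude: list[str] | None = None,
) -> dict:
    """ANCOVA of detected transcripts against detected genes between groups.

    ``summary`` is indexed by sample with numeric columns ``genes`` and
    ``transcripts`` plus a two-level group label (e.g. peripheral vs TEC).
    Fits OLS ``transcripts ~ genes * group`` and reports the per-group
    slopes and the interaction-term p-value. Samples listed in ``exclude``
    (e.g. testis, mirroring a baseline fitted without outlier tissues) are
    dropped first.
    """
    df = summary.drop(index=exclude or [], errors="raise").copy()
    groups = sorted(df[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    sizes = df[group_col].value_counts()
    if (sizes < 3).any():
        raise ValueError(f"need >= 3 samples per group, got {sizes.to_dict()}")
    model = smf.ols(f"transcripts ~ genes * C({group_col})", data=df).fit()
    if model.params.isna().any():
        raise ValueError("singular design in ANCOVA fit")
    inter = [name for name in model.params.index if "genes:" in name]
    base_slope = float(model.params["genes"])
    inter_coef = float(model.params[inter[0]])
    return {
        "groups": groups,
        "slope": {groups[0]: base_slope, groups[1]: base_slope + inter_coef},
        "interaction_p": float(model.pvalues[inter[0]]),
        "n": {g: int(sizes[g]) for g in groups},
    }


def splice_entropy(isoform_tpm) -> float:
    """Shannon entropy (bits) of one gene's isoform TPM vector in one sample.

    p_i = TPM_i / sum(TPM); H = -sum p_i log2 p_i with 0*log0 = 0. Returns
    NaN when the total is 0.
    """
    x = np.asarray(isoform_tpm, dtype=float)
    if (x < 0).any():
        raise ValueError("negative TPM")
    total = x.sum()
    if total == 0:
        return float("nan")
    p = x[x > 0] / total
    return float(-(p * np.log2(p)).sum())


def entropy_by_gene(
    transcript_tpm: pd.DataFrame,
    annotation: Annotation,
    genes=None,
) -> pd.DataFrame:
    """Per-gene x sample isoform-usage entropy (bits), multi-isoform genes only."""
    n_iso = annotation.n_isoforms()
    wanted = n_iso[n_iso >= 2].index if genes is None else pd.Index(genes)
    t2g = annotation.transcript_gene().reindex(transcript_tpm.index)
    totals = transcript_tpm.groupby(t2g).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (transcript_tpm / totals).to_numpy()
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    ent = -pd.DataFrame(plogp, index=transcript_tpm.index,
                        columns=transcript_tpm.columns).groupby(t2g).sum()
    gene_total = transcript_tpm.groupby(t2g).sum()
    out = ent.where(gene_total > 0).reindex(wanted)
    out.index.name = "gene_id"
    return out


def _quartile(values: np.ndarray) -> np.ndarray:
    """Per-sample quartile assignment (0..3); ties fall to the lower quartile."""
    edges = np.quantile(values, [0.25, 0.5, 0.75])
    return np.searchsorted(edges, values, side="left")


def multi_isoform_as_fraction(
    transcript_det: pd.DataFrame,
    gene_tpm: pd.DataFrame,
    annotation: Annotation,
    gene_sets: dict[str, set],
    sample_of: dict[str, str],
    low_n: int = 5,
) -> pd.DataFrame:
    """Fraction of multi-isoform genes alternatively spliced, by expression quartile.

    For each labelled gene set (e.g. a tissue's iTRA genes) evaluated in its
    corresponding sample (``sample_of``), genes are stratified into
    within-sample expression quartiles (on gene TPM; ties to the lower
    quartile) and the fraction with more than one isoform detected is
    reported. Quartiles holding fewer than ``low_n`` genes are flagged.
    """
    n_iso = annotation.n_isoforms()
    t2g = annotation.transcript_gene()
    det_per_gene = transcript_det.groupby(t2g).sum()
    rows = []
    for label in sorted(gene_sets):
        sample = sample_of[label]
        genes = sorted(set(gene_sets[label]) & set(n_iso[n_iso >= 2].index))
        if not genes:
            continue
        tpm = gene_tpm.loc[genes, sample].to_numpy(dtype=float)
        quart = _quartile(tpm)
        n_det = det_per_gene.loc[genes, sample].to_numpy()
        for q in range(4):
            mask = quart == q
            n = int(mask.sum())
            frac = float((n_det[mask] > 1).mean()) if n else float("nan")
            rows.append(
                {"set": label, "sample_id": sample, "quartile": q + 1,
                 "n_genes": n, "fraction_spliced": frac, "low_n": n < low_n}
            )
    return pd.DataFrame(rows)


def peripheral_representation(
    restricted_sets: dict[str, set],
    target_detection: pd.Series,
) -> pd.DataFrame:
    """Fraction of each tissue's restricted transcripts detected in a target sample.

    ``target_detection`` is the boolean detection column of the target
    sample (e.g. mature TEC). Tissues with empty restricted sets report a
    missing fraction.
    """
    rows = []
    for tissue in sorted(restricted_sets):
        ids = sorted(restricted_sets[tissue])
        if not ids:
            rows.append({"tissue": tissue, "n_restricted": 0,
                         "n_detected": 0, "fraction": float("nan")})
            continue
        hits = target_detection.reindex(ids).fillna(False)
        rows.append(
            {"tissue": tissue, "n_restricted": len(ids),
             "n_detected": int(hits.sum()), "fraction": float(hits.mean())}
        )
    return pd.DataFrame(rows)


def uniquely_detected(
    transcript_det: pd.DataFrame,
    panel: list[str],
    novel_only: pd.Series | None = None,
) -> pd.Series:
    """Transcripts detected in exactly one sample of a representative panel.

    Returns the per-sample count of uniquely detected transcripts,
    optionally restricted to novel ones (boolean Series over transcripts).
    """
    det = transcript_det[panel]
    if novel_only is not None:
        det = det.loc[novel_only.reindex(det.index).fillna(False)]
    unique = det.sum(axis=1) == 1
    return det.loc[unique].sum(axis=0).astype(int)
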