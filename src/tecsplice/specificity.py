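"""Tissue-specificity scoring and gene classification.

The tau index of a per-tissue expression profile x is

    tau = sum_i (1 - x_i / x_max) / (N - 1)

computed here, per common practice, on log2(TPM + 1)-transformed values
(the raw-scale variant is available via ``log_transform=False``). tau is 0
for uniform expression and 1 for single-tissue expression. Genes with
tau >= 0.9 across the peripheral panel are tissue-restricted antigen (TRA)
genes; each TRA gene is assigned to its maximal-expression tissue (its
"iTRA" tissue). Genes more than two-fold down-regulated in Aire-knockout
TEC at BH p < 0.05 are Aire-regulated, yielding the three-way partition
Aire-TRA / non-Aire-TRA / non-TRA.

TEC-like samples must be excluded from the tissue panel used for tau:
tissue restriction is scored against peripheral tissues only.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .stats import bh_adjust, nb_exact_test, normalize_libsize

logger = logging.getLogger("tecsplice")

__all__ = [
    "compute_tau",
    "classify_restricted",
    "aire_differential",
    "classify_aire",
    "categorize_genes",
]


def compute_tau(expr_by_tissue, log_transform: bool = True) -> float:
    """tau tissue-specificity index of one per-tissue expression vector.

    Returns NaN (with a warning) for an all-zero vector, for which the
    index is undefined.
    """
    x = np.asarray(expr_by_tissue, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-d vector over >= 2 tissues")
    if (x < 0).any():
        raise ValueError("expression must be non-negative")
    if not x.any():
        logger.warning("stage=compute_tau all-zero expression vector; tau undefined")
        return float("nan")
    if log_transform:
        x = np.log2(x + 1.0)
    return float((1.0 - x / x.max()).sum() / (x.size - 1))


def _tau_matrix(tissue_expr: pd.DataFrame, log_transform: bool) -> pd.Series:
    x = tissue_expr.to_numpy(dtype=float)
    if log_transform:
        x = np.log2(x + 1.0)
    xmax = x.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = (1.0 - x / xmax[:, None]).sum(axis=1) / (x.shape[1] - 1)
    tau[xmax == 0] = np.nan
    return pd.Series(tau, index=tissue_expr.index, name="tau")


def classify_restricted(
    tissue_expr: pd.DataFrame,
    tau_threshold: float = 0.9,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Score tau for every feature and flag tissue-restricted ones.

    ``tissue_expr`` has one column per (peripheral) tissue; works at gene or
    transcript level. A feature is restricted iff tau >= ``tau_threshold``
    (strict >= comparison). The home tissue is the argmax of raw tissue
    expression; ties are broken by the lexicographically smallest tissue
    name and logged.
    """
    if tissue_expr.columns.duplicated().any():
        raise ValueError("duplicate tissue columns")
    if not 0.0 <= tau_threshold <= 1.0:
        raise ValueError("tau threshold must lie in [0, 1]")
    cols = sorted(tissue_expr.columns)
    expr = tissue_expr[cols]
    tau = _tau_matrix(expr, log_transform)
    arr = expr.to_numpy(dtype=float)
    home_idx = arr.argmax(axis=1)  # first (lexicographically smallest) on ties
    ties = (arr == arr.max(axis=1)[:, None]).sum(axis=1) > 1
    n_ties = int((ties & (arr.max(axis=1) > 0)).sum())
    if n_ties:
        logger.info("stage=classify_restricted argmax_ties=%d (lexicographic break)", n_ties)
    out = pd.DataFrame(index=expr.index)
    out["tau"] = tau
    out["restricted"] = tau >= tau_threshold
    out["home_tissue"] = [cols[i] for i in home_idx]
    out["max_tissue_expression"] = arr.max(axis=1)
    out.loc[~out["restricted"].fillna(False), "home_tissue"] = pd.NA
    return out


def aire_differential(
    gene_counts: pd.DataFrame,
    ko_samples: list[str],
    pos_samples: list[str],
    dispersion: float = 0.1,
) -> pd.DataFrame:
    """Per-gene differential test of Aire-knockout versus Aire-positive TEC.

    Uses the conditional NB exact test on the replicate counts of each
    gene. Fold change is reported as a positive magnitude with an explicit
    ``direction`` field (``down_in_ko`` / ``up_in_ko`` / ``equal``).
    """
    counts = gene_counts[ko_samples + pos_samples]
    factors, _ = normalize_libsize(counts)
    f_ko = factors[ko_samples].to_numpy()
    f_pos = factors[pos_samples].to_numpy()
    recs = []
    for gene, row in counts.iterrows():
        r = nb_exact_test(
            row[ko_samples].to_numpy(float), row[pos_samples].to_numpy(float),
            dispersion, f_ko, f_pos,
        )
        direction = {"a>b": "up_in_ko", "b>a": "down_in_ko", "equal": "equal"}[r.direction]
        recs.append((gene, r.mean_a, r.mean_b, 2.0 ** r.log2_fold_change,
                     r.log2_fold_change, direction, r.p))
    out = pd.DataFrame(
        recs, columns=["gene_id", "mean_ko", "mean_pos", "fold_change",
                       "abs_log2fc", "direction", "p"]
    ).set_index("gene_id")
    out["padj"] = bh_adjust(out["p"].to_numpy())
    return out


def classify_aire(
    stats: pd.DataFrame,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
) -> pd.Series:
    """Aire-regulated flag: fold change > threshold DOWN in knockout, BH p < threshold."""
    required = {"fold_change", "direction", "padj"}
    missing = required - set(stats.columns)
    if missing:
        raise KeyError(f"differential table missing columns: {sorted(missing)}")
    flag = (
        (stats["direction"] == "down_in_ko")
        & (stats["fold_change"] > fc_threshold)
        & (stats["padj"] < p_threshold)
    )
    return flag.rename("is_aire_regulated")


def categorize_genes(
    restricted: pd.DataFrame,
    aire_flags: pd.Series,
) -> pd.DataFrame:
    """Combine tau and Aire flags into the three-way gene classification.

    Categories partition all genes: ``Aire-TRA`` (restricted and
    Aire-regulated), ``non-Aire-TRA`` (restricted only) and ``non-TRA``.
    Every TRA gene carries exactly one iTRA tissue (its home tissue);
    non-TRA genes have a missing ``itra_tissue``.
    """
    out = pd.DataFrame(index=restricted.index)
    out["tau"] = restricted["tau"]
    out["is_tra"] = restricted["restricted"].fillna(False).astype(bool)
    out["is_aire_regulated"] = (
        aire_flags.reindex(restricted.index).fillna(False).astype(bool)
    )
    out["category"] = np.where(
        out["is_tra"] & out["is_aire_regulated"], "Aire-TRA",
        np.where(out["is_tra"], "non-Aire-TRA", "non-TRA"),
    )
    out["itra_tissue"] = restricted["home_tissue"].where(out["is_tra"], pd.NA)
    out["max_tissue_expression"] = restricted["max_tissue_expression"]
    counts = out["category"].value_counts()
    logger.info(
        "stage=categorize_genes aire_tra=%d non_aire_tra=%d non_tra=%d",
        counts.get("Aire-TRA", 0), counts.get("non-Aire-TRA", 0),
        counts.get("non-TRA", 0),
    )
    return out
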