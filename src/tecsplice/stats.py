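"""Count-based statistics shared across the census.

This module provides the simplified stand-ins used in place of the heavy
RNA-seq machinery (edgeR-style moderation is deliberately out of scope):

* library-size normalization by total count relative to the geometric mean;
* a conditional negative-binomial exact test on group sums that reduces to
  the exact binomial test when the dispersion is zero;
* Benjamini-Hochberg adjustment;
* Fisher's exact test with an explicit odds-ratio infinity convention;
* the per-gene splice-junction differential census with the per-tissue
  iTRA enrichment test;
* batched set-overlap (GO-style) enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .models import JunctionCounts

__all__ = [
    "NBTestResult",
    "EnrichmentResult",
    "normalize_libsize",
    "nb_exact_test",
    "bh_adjust",
    "fisher_exact",
    "set_enrichment",
    "differential_junction_census",
    "junction_census_all",
]


@dataclass(frozen=True)
class NBTestResult:
    """Outcome of one two-group count comparison."""

    mean_a: float
    mean_b: float
    log2_fold_change: float  # absolute magnitude; see ``direction``
    direction: str           # "a>b", "b>a" or "equal"
    p: float


@dataclass(frozen=True)
class EnrichmentResult:
    """One 2x2 set-overlap test. OR = ad/bc; inf when bc = 0 and ad > 0."""

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float
    alternative: str


def normalize_libsize(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Size factors (column total / geometric mean of totals) and normalized counts."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero-count columns: {bad}")
    factors = totals / sps.gmean(totals.to_numpy())
    return factors, counts / factors


def _group_sum(x, factors) -> tuple[float, float, int]:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if (arr < 0).any():
        raise ValueError("negative counts")
    f = np.ones_like(arr) if factors is None else np.atleast_1d(np.asarray(factors, float))
    if f.shape != arr.shape:
        raise ValueError("size factors do not match counts")
    return float(arr.sum()), float(f.sum()), arr.size


def nb_exact_test(
    counts_a,
    counts_b,
    dispersion: float = 0.0,
    factors_a=None,
    factors_b=None,
) -> NBTestResult:
    """Conditional exact test for a two-group count comparison.

    The test conditions on the total ``s = sum(a) + sum(b)``. Under the null
    the group-A sum follows, at dispersion 0, a Binomial(s, pi) with pi
    proportional to the summed size factors (the exact binomial test); at
    dispersion phi > 0 it follows the conditional law of two negative
    binomials with group-sum dispersions phi/n_reps. The two-sided p-value
    doubles the smaller tail (capped at 1). Fold change is computed from
    size-factor-normalized group means with a pseudo-count of 0.5.

    ``counts_a``/``counts_b`` may be scalars (no-replicate mode; a positive
    ``dispersion`` should then be supplied) or per-replicate vectors.
    """
    a, fa, na = _group_sum(counts_a, factors_a)
    b, fb, nb_ = _group_sum(counts_b, factors_b)
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    s = int(round(a + b))
    pi = fa / (fa + fb)
    a_int = int(round(a))

    if s == 0:
        p = 1.0
    elif dispersion == 0.0:
        lower = sps.binom.cdf(a_int, s, pi)
        upper = sps.binom.sf(a_int - 1, s, pi)
        p = float(min(1.0, 2.0 * min(lower, upper)))
    else:
        # For very large totals the (smooth) conditional law is evaluated on
        # a uniform ~20k-point grid; the stride cancels in normalization.
        stride = max(1, (s + 1) // 20000)
        k = np.arange(0, s + 1, stride, dtype=float)
        r_a = na / dispersion
        r_b = nb_ / dispersion
        mu_a = max(s * pi, 1e-12)
        mu_b = max(s * (1.0 - pi), 1e-12)
        # NB log-pmf written out with gammaln (much faster than the frozen
        # scipy distribution for long support vectors)
        la = np.log(mu_a / (r_a + mu_a))
        lb = np.log(mu_b / (r_b + mu_b))
        lp = gammaln(k + r_a) - gammaln(k + 1.0) + k * la
        lq = gammaln(s - k + r_b) - gammaln(s - k + 1.0) + (s - k) * lb
        logpmf = lp + lq
        pmf = np.exp(logpmf - logpmf.max())
        pmf /= pmf.sum()
        lower = pmf[k <= a_int].sum()
        upper = pmf[k >= a_int].sum()
        p = float(min(1.0, 2.0 * min(lower, upper)))

    mean_a = a / fa
    mean_b = b / fb
    ratio = (mean_a + 0.5) / (mean_b + 0.5)
    if np.isclose(ratio, 1.0):
        direction = "equal"
    else:
        direction = "a>b" if ratio > 1 else "b>a"
    return NBTestResult(
        mean_a=mean_a,
        mean_b=mean_b,
        log2_fold_change=abs(float(np.log2(ratio))),
        direction=direction,
        p=p,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (order-preserving, clipped at 1)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def fisher_exact(table, alternative: str = "two-sided") -> EnrichmentResult:
    """Fisher's exact test on a 2x2 table [[a, b], [c, d]].

    Two-sided p-values sum the probabilities of all tables (with fixed
    margins) no more likely than the observed one. The odds ratio is the
    sample estimate ad/bc, reported as ``inf`` when bc = 0 with ad > 0 and
    as ``nan`` (missing) for the degenerate 0/0 case.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValueError("table cells must be non-negative integers")
    a, b, c, d = (int(x) for x in arr.ravel())
    scipy_alt = {"two-sided": "two-sided", "greater": "greater", "less": "less"}
    if alternative not in scipy_alt:
        raise ValueError(f"unknown alternative {alternative!r}")
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative=scipy_alt[alternative])
    if b * c == 0:
        odds = float("nan") if a * d == 0 else float("inf")
    else:
        odds = (a * d) / (b * c)
    return EnrichmentResult(a, b, c, d, odds, float(p), alternative)


def set_enrichment(
    target: set,
    annotation_sets: dict[str, set],
    universe: set,
    alternative: str = "one-sided",
) -> pd.DataFrame:
    """Batched Fisher set-overlap tests with BH adjustment across sets.

    ``alternative`` is ``"one-sided"`` (overrepresentation, i.e. Fisher
    'greater') or ``"two-sided"``. The target must be a subset of the
    universe; annotation sets are intersected with the universe.
    """
    target = set(target)
    universe = set(universe)
    stray = target - universe
    if stray:
        raise ValueError(f"target ids outside universe: {sorted(stray)[:10]}")
    alt = "greater" if alternative == "one-sided" else "two-sided"
    rows = []
    for set_id in sorted(annotation_sets):
        members = set(annotation_sets[set_id]) & universe
        a = len(target & members)
        b = len(target - members)
        c = len(members - target)
        d = len(universe) - a - b - c
        res = fisher_exact([[a, b], [c, d]], alternative=alt)
        rows.append(
            {"set_id": set_id, "overlap": a, "target_only": b, "set_only": c,
             "neither": d, "odds_ratio": res.odds_ratio, "p": res.p}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["padj"] = bh_adjust(out["p"].to_numpy())
    else:
        out["padj"] = []
    return out


def differential_junction_census(
    junctions: JunctionCounts,
    sample_a: str,
    sample_b: str,
    classification: pd.DataFrame,
    tissue: str,
    min_reads: int = 1,
    dispersion: float = 0.1,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, EnrichmentResult]:
    """Per-gene splice-junction differential census between two samples.

    The unit compared is the number of distinct junctions per gene with at
    least ``min_reads`` support in a sample. Each gene is tested with the
    conditional NB exact test (no-replicate mode: fixed ``dispersion``);
    genes with BH-adjusted p < ``alpha`` and fold change > ``fc_threshold``
    are significant. The returned enrichment result asks (one-sided,
    'greater') whether genes with significantly *more* junctions in
    ``sample_b`` are enriched for the iTRA genes of ``tissue``.

    ``classification`` must be a gene-classification table (indexed by
    gene_id, with an ``itra_tissue`` column); an unknown tissue raises.
    """
    itra = classification["itra_tissue"].dropna()
    if tissue not in set(itra):
        raise ValueError(f"tissue {tissue!r} absent from classification")
    per_gene = junctions.junctions_per_gene(min_reads=min_reads)[[sample_a, sample_b]]
    per_gene = per_gene[per_gene.sum(axis=1) > 0]
    factors, _ = normalize_libsize(per_gene)
    fa, fb = float(factors[sample_a]), float(factors[sample_b])

    recs = []
    for gene, (ca, cb) in per_gene.iterrows():
        r = nb_exact_test(float(ca), float(cb), dispersion, [fa], [fb])
        recs.append((gene, int(ca), int(cb), r.log2_fold_change, r.direction, r.p))
    res = pd.DataFrame(
        recs, columns=["gene_id", "n_junctions_a", "n_junctions_b",
                       "abs_log2fc", "direction", "p"]
    ).set_index("gene_id")
    res["padj"] = bh_adjust(res["p"].to_numpy())
    res["significant"] = (res["padj"] < alpha) & (
        res["abs_log2fc"] > np.log2(fc_threshold)
    )
    res["higher_in_b"] = res["significant"] & (res["direction"] == "b>a")

    is_itra = res.index.isin(itra.index[itra == tissue])
    hi = res["higher_in_b"].to_numpy()
    a = int((hi & is_itra).sum())
    b = int((hi & ~is_itra).sum())
    c = int((~hi & is_itra).sum())
    d = int((~hi & ~is_itra).sum())
    enr = fisher_exact([[a, b], [c, d]], alternative="greater")
    return res, enr


def junction_census_all(
    junctions: JunctionCounts,
    tec_sample: str,
    tissue_samples: dict[str, str],
    classification: pd.DataFrame,
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the junction census of one TEC-like sample against every tissue.

    Returns the concatenated per-gene tables (with a ``tissue`` column) and
    a per-tissue enrichment table with BH adjustment across tissues.
    """
    gene_tabs, enr_rows = [], []
    for tissue in sorted(tissue_samples):
        tab, enr = differential_junction_census(
            junctions, tec_sample, tissue_samples[tissue], classification,
            tissue, **kwargs,
        )
        tab = tab.reset_index()
        tab.insert(0, "tissue", tissue)
        gene_tabs.append(tab)
        enr_rows.append(
            {"tissue": tissue, "itra_higher": enr.a, "other_higher": enr.b,
             "itra_not_higher": enr.c, "other_not_higher": enr.d,
             "odds_ratio": enr.odds_ratio, "p": enr.p}
        )
    enr_df = pd.DataFrame(enr_rows)
    enr_df["padj"] = bh_adjust(enr_df["p"].to_numpy())
    return pd.concat(gene_tabs, ignore_index=True), enr_df
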