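"""Nonparametric IDR (npIDR) reproducibility filter.

Transcript assemblies built from replicate sequencing pools contain
low-expression artifacts that appear in only one replicate. The npIDR of
an expression bin is the fraction of transcripts detected in exactly one
of two replicates among those detected in at least one:

    npIDR(bin) = |detected in exactly one| / |detected in at least one|

Bins are equal-occupancy on log10(TPM + eps) (20 by default, left-closed),
and the raw curve is smoothed by isotonic regression constrained to be
non-increasing with expression, reflecting the expectation that higher
expression cannot make detection less reproducible. Transcripts whose
smoothed npIDR is at or below a threshold (default 0.1) are accepted.

This is the standard expression-binned npIDR; no attempt is made to
reproduce any particular refinement of it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

__all__ = ["ReproducibilityCurve", "compute_npidr", "filter_reproducible"]

_EPS = 1e-3


@dataclass
class ReproducibilityCurve:
    """Expression-binned irreproducibility curve.

    ``bin_edges`` (length n_bins + 1) are on the log10(TPM + eps) scale;
    ``raw`` holds the per-bin npIDR (NaN for empty bins), ``counts`` the
    per-bin occupancy, and ``smoothed`` the monotone (non-increasing)
    fit with empty bins inherited from their neighbors.
    """

    bin_edges: np.ndarray
    raw: np.ndarray
    counts: np.ndarray
    smoothed: np.ndarray

    def bin_of(self, tpm) -> np.ndarray:
        x = np.log10(np.asarray(tpm, dtype=float) + _EPS)
        idx = np.searchsorted(self.bin_edges[1:-1], x, side="right")
        return idx

    def npidr_at(self, tpm) -> np.ndarray:
        """Smoothed npIDR at the given TPM value(s)."""
        return self.smoothed[self.bin_of(tpm)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low_log10tpm": self.bin_edges[:-1],
                "bin_high_log10tpm": self.bin_edges[1:],
                "n_elements": self.counts,
                "npidr_raw": self.raw,
                "npidr_smoothed": self.smoothed,
            }
        )


def compute_npidr(
    rep1: set[str],
    rep2: set[str],
    expression,
    n_bins: int = 20,
) -> ReproducibilityCurve:
    """Compute the binned npIDR curve from two replicate detection sets.

    ``expression`` maps transcript id -> TPM and must cover every
    transcript detected in either replicate.
    """
    rep1, rep2 = set(rep1), set(rep2)
    union = sorted(rep1 | rep2)
    if not union:
        raise ValueError("empty union of detections")
    expr = pd.Series(expression, dtype=float)
    missing = [t for t in union if t not in expr.index]
    if missing:
        raise ValueError(f"expression missing for detected transcripts: {missing[:10]}")
    x = np.log10(expr[union].to_numpy() + _EPS)
    qs = np.quantile(x, np.linspace(0.0, 1.0, n_bins + 1))
    qs[0] -= 1e-9
    qs[-1] += 1e-9
    edges = qs.copy()
    # guard against ties collapsing edges: enforce strictly increasing
    for i in range(1, len(edges)):
        if edges[i] <= edges[i - 1]:
            edges[i] = edges[i - 1] + 1e-12

    bin_idx = np.searchsorted(edges[1:-1], x, side="right")
    once = np.array([(t in rep1) != (t in rep2) for t in union])
    counts = np.bincount(bin_idx, minlength=n_bins).astype(int)
    n_once = np.bincount(bin_idx, weights=once.astype(float), minlength=n_bins)
    with np.errstate(invalid="ignore"):
        raw = np.where(counts > 0, n_once / np.maximum(counts, 1), np.nan)
    raw[counts == 0] = np.nan

    centers = 0.5 * (edges[:-1] + edges[1:])
    occupied = counts > 0
    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    iso.fit(centers[occupied], raw[occupied], sample_weight=counts[occupied])
    smoothed = iso.predict(centers)  # empty bins inherit via interpolation/clip
    smoothed = np.clip(smoothed, 0.0, 1.0)
    return ReproducibilityCurve(edges, raw, counts, smoothed)


def filter_reproducible(
    curve: ReproducibilityCurve,
    union_detections,
    expression,
    threshold: float = 0.1,
) -> set[str]:
    """Accept transcripts whose smoothed npIDR at their expression is <= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    expr = pd.Series(expression, dtype=float)
    ids = sorted(union_detections)
    vals = curve.npidr_at(expr[ids].to_numpy())
    return {t for t, v in zip(ids, vals) if v <= threshold}
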