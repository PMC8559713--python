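"""Local alternative-splicing events: enumeration, PSI and differential tests.

Events are enumerated from transcript models by pairwise structure
comparison, using the standard local-event vocabulary: skipped exon (SE),
retained intron (RI), mutually exclusive exons (MX), alternative 5'/3'
splice site (A5/A3, named strand-aware: the genomic-left alternative site
on the minus strand is an A3), and alternative first/last exon (AF/AL).
Event ids are coordinate-derived strings so results join stably across
runs.

PSI (percent spliced in) is available on two routes: the transcript-ratio
definition (sum of inclusion-isoform TPM over total event TPM) and the
count-based, length-normalized definition psi = (I/li) / (I/li + S/ls).

Differential splicing between two conditions is called per event with a
binomial likelihood-ratio test of the inclusion proportion (closed-form
MLE, chi-square with 1 df), BH-adjusted across events, applying the
caller's FDR and |dPSI| gates. This deliberately replaces the hierarchical
model of dedicated read-level tools while keeping their decision rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import xlogy

from .models import Annotation
from .stats import bh_adjust

__all__ = [
    "SpliceEvent",
    "EventCountTable",
    "enumerate_events",
    "psi_from_tpm",
    "psi_matrix_from_tpm",
    "psi_from_counts",
    "differential_events",
    "event_type_breakdown",
    "exon_inclusion_patterns",
    "microexon_summary",
]

EVENT_TYPES = ("SE", "RI", "MX", "A3", "A5", "AF", "AL")


@dataclass(frozen=True)
class SpliceEvent:
    """One local alternative-splicing event within a gene."""

    event_id: str
    gene_id: str
    event_type: str
    chrom: str
    strand: str
    coords: tuple
    inclusion: frozenset
    exclusion: frozenset
    cassette_length: int | None = None

    def __post_init__(self):
        if self.inclusion & self.exclusion:
            raise ValueError(f"{self.event_id}: inclusion/exclusion sets overlap")
        if not self.inclusion or not self.exclusion:
            raise ValueError(f"{self.event_id}: empty transcript set")


def _junc_sets(transcripts) -> dict[str, set]:
    return {t.transcript_id: set(t.junctions()) for t in transcripts}


def _members(juncs, required) -> frozenset:
    return frozenset(tid for tid, js in juncs.items() if required <= js)


def enumerate_events(annotation: Annotation) -> list[SpliceEvent]:
    """Enumerate SE/RI/MX/A5/A3/AF/AL events for every multi-transcript gene."""
    out: dict[str, SpliceEvent] = {}
    for gene_id in sorted(annotation.genes):
        ts = annotation.gene_transcripts(gene_id)
        if len(ts) < 2:
            continue
        chrom, strand = ts[0].chrom, ts[0].strand
        juncs = _junc_sets(ts)
        all_juncs = set().union(*juncs.values())
        exon_sets = {t.transcript_id: set(t.exons) for t in ts}

        def register(ev: SpliceEvent):
            out.setdefault(ev.event_id, ev)

        # --- SE and the flank map reused by MX -----------------------------
        flank_mids: dict[tuple, dict] = {}
        for t in ts:
            ex = t.exons
            for i in range(1, len(ex) - 1):
                a, e, b = ex[i - 1], ex[i], ex[i + 1]
                flank = (a[1], b[0])
                flank_mids.setdefault(flank, {})[e] = None
                skip = (a[1], b[0])
                if skip in all_juncs:
                    inc = _members(juncs, {(a[1], e[0]), (e[1], b[0])})
                    exc = _members(juncs, {skip}) - inc
                    if inc and exc:
                        register(SpliceEvent(
                            f"SE:{gene_id}:{chrom}:{a[1]}-{e[0]}:{e[1]}-{b[0]}:{strand}",
                            gene_id, "SE", chrom, strand,
                            (a[1], e[0], e[1], b[0]), inc, exc,
                            cassette_length=e[1] - e[0],
                        ))

        # --- MX: two middles sharing a flank, disjoint, never co-occurring --
        for (a_end, b_start), mids in flank_mids.items():
            mids = sorted(mids)
            for i in range(len(mids)):
                for j in range(i + 1, len(mids)):
                    x, y = mids[i], mids[j]
                    if x[1] > y[0]:  # overlapping -> not mutually exclusive slot
                        continue
                    if any(x in es and y in es for es in exon_sets.values()):
                        continue
                    inc = _members(juncs, {(a_end, x[0]), (x[1], b_start)})
                    exc = _members(juncs, {(a_end, y[0]), (y[1], b_start)}) - inc
                    if inc and exc:
                        register(SpliceEvent(
                            f"MX:{gene_id}:{chrom}:{a_end}-{x[0]}-{x[1]}:"
                            f"{y[0]}-{y[1]}-{b_start}:{strand}",
                            gene_id, "MX", chrom, strand,
                            (a_end, x[0], x[1], y[0], y[1], b_start), inc, exc,
                        ))

        # --- RI ------------------------------------------------------------
        for t in ts:
            ex = t.exons
            for i in range(len(ex) - 1):
                a, b = ex[i], ex[i + 1]
                span = (a[0], b[1])
                holders = frozenset(
                    tid for tid, es in exon_sets.items() if span in es
                )
                if holders:
                    exc = _members(juncs, {(a[1], b[0])}) - holders
                    if exc:
                        register(SpliceEvent(
                            f"RI:{gene_id}:{chrom}:{a[0]}:{a[1]}-{b[0]}:{b[1]}:{strand}",
                            gene_id, "RI", chrom, strand,
                            (a[0], a[1], b[0], b[1]), holders, exc,
                        ))

        # --- A5/A3: shared one splice site, alternative other ---------------
        donors_of_acc: dict[int, set] = {}
        accs_of_donor: dict[int, set] = {}
        for d, a in all_juncs:
            donors_of_acc.setdefault(a, set()).add(d)
            accs_of_donor.setdefault(d, set()).add(a)
        donor_exons = {
            end: [ex for es in exon_sets.values() for ex in es if ex[1] == end]
            for a, ds in donors_of_acc.items() for end in ds
        }
        acceptor_exons = {
            start: [ex for es in exon_sets.values() for ex in es if ex[0] == start]
            for d, accs in accs_of_donor.items() for start in accs
        }

        def overlapping(exlist1, exlist2) -> bool:
            return any(
                e1[0] < e2[1] and e2[0] < e1[1] for e1 in exlist1 for e2 in exlist2
            )

        for acc, donors in donors_of_acc.items():
            ds = sorted(donors)
            for i in range(len(ds)):
                for j in range(i + 1, len(ds)):
                    d1, d2 = ds[i], ds[j]
                    if not overlapping(donor_exons[d1], donor_exons[d2]):
                        continue
                    etype = "A5" if strand == "+" else "A3"
                    inc = _members(juncs, {(d2, acc)})  # longer exonic form
                    exc = _members(juncs, {(d1, acc)}) - inc
                    if inc and exc:
                        register(SpliceEvent(
                            f"{etype}:{gene_id}:{chrom}:{d1}|{d2}-{acc}:{strand}",
                            gene_id, etype, chrom, strand, (d1, d2, acc), inc, exc,
                        ))
        for don, accs in accs_of_donor.items():
            as_ = sorted(accs)
            for i in range(len(as_)):
                for j in range(i + 1, len(as_)):
                    a1, a2 = as_[i], as_[j]
                    if not overlapping(acceptor_exons[a1], acceptor_exons[a2]):
                        continue
                    etype = "A3" if strand == "+" else "A5"
                    inc = _members(juncs, {(don, a1)})  # longer exonic form
                    exc = _members(juncs, {(don, a2)}) - inc
                    if inc and exc:
                        register(SpliceEvent(
                            f"{etype}:{gene_id}:{chrom}:{don}-{a1}|{a2}:{strand}",
                            gene_id, etype, chrom, strand, (don, a1, a2), inc, exc,
                        ))

        # --- AF/AL: alternative terminal exons sharing the inner site -------
        left_term: dict[int, dict] = {}
        right_term: dict[int, dict] = {}
        for t in ts:
            if len(t.exons) < 2:
                continue
            first, last = t.exons[0], t.exons[-1]
            left_term.setdefault(t.junctions()[0][1], {})[first] = None
            right_term.setdefault(t.junctions()[-1][0], {})[last] = None

        def terminal_events(groups, left_side: bool):
            for inner, exons in groups.items():
                exl = sorted(exons)
                for i in range(len(exl)):
                    for j in range(i + 1, len(exl)):
                        e1, e2 = exl[i], exl[j]
                        if e1[1] > e2[0]:  # overlap -> alternative splice site
                            continue
                        etype = ("AF" if strand == "+" else "AL") if left_side else \
                                ("AL" if strand == "+" else "AF")
                        if left_side:
                            j1, j2 = (e1[1], inner), (e2[1], inner)
                        else:
                            j1, j2 = (inner, e1[0]), (inner, e2[0])
                        # distal terminal exon (e1 on the left side, e2 on the right)
                        distal, proximal = (j1, j2) if left_side else (j2, j1)
                        inc = frozenset(
                            tid for tid, js in juncs.items()
                            if distal in js and (e1 if left_side else e2) in exon_sets[tid]
                        )
                        exc = frozenset(
                            tid for tid, js in juncs.items()
                            if proximal in js and (e2 if left_side else e1) in exon_sets[tid]
                        ) - inc
                        if inc and exc:
                            register(SpliceEvent(
                                f"{etype}:{gene_id}:{chrom}:{e1[0]}-{e1[1]}|"
                                f"{e2[0]}-{e2[1]}@{inner}:{strand}",
                                gene_id, etype, chrom, strand,
                                (e1[0], e1[1], e2[0], e2[1], inner), inc, exc,
                            ))

        terminal_events(left_term, left_side=True)
        terminal_events(right_term, left_side=False)

    return [out[k] for k in sorted(out)]


def psi_from_tpm(event: SpliceEvent, transcript_tpm, min_total: float = 1.0):
    """Transcript-ratio PSI of one event in one sample.

    psi = sum TPM(inclusion) / sum TPM(inclusion + exclusion); returns
    (psi, support) with psi NaN when the denominator is below ``min_total``.
    """
    tpm = pd.Series(transcript_tpm, dtype=float)
    missing = (event.inclusion | event.exclusion) - set(tpm.index)
    if missing:
        raise KeyError(f"{event.event_id}: TPM missing for {sorted(missing)}")
    inc = float(tpm[list(event.inclusion)].sum())
    exc = float(tpm[list(event.exclusion)].sum())
    total = inc + exc
    if total < min_total:
        return float("nan"), total
    return inc / total, total


def psi_matrix_from_tpm(
    events: list[SpliceEvent],
    transcript_tpm: pd.DataFrame,
    min_total: float = 1.0,
) -> pd.DataFrame:
    """Event x sample PSI matrix from transcript TPMs (vectorized)."""
    tpm = transcript_tpm.to_numpy(dtype=float)
    pos = {tid: i for i, tid in enumerate(transcript_tpm.index)}
    inc = np.zeros((len(events), tpm.shape[1]))
    tot = np.zeros_like(inc)
    for i, ev in enumerate(events):
        inc[i] = tpm[[pos[t] for t in ev.inclusion]].sum(axis=0)
        tot[i] = inc[i] + tpm[[pos[t] for t in ev.exclusion]].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(tot >= min_total, inc / np.maximum(tot, 1e-300), np.nan)
    return pd.DataFrame(psi, index=[e.event_id for e in events],
                        columns=transcript_tpm.columns)


def psi_from_counts(
    inclusion: float,
    skipping: float,
    inc_len: float,
    skip_len: float,
    min_reads: int = 10,
) -> float:
    """Length-normalized count PSI: (I/li) / (I/li + S/ls); NaN below min_reads."""
    if inclusion < 0 or skipping < 0:
        raise ValueError("negative counts")
    if inc_len <= 0 or skip_len <= 0:
        raise ValueError("form lengths must be positive")
    if inclusion + skipping < min_reads:
        return float("nan")
    num = inclusion / inc_len
    den = num + skipping / skip_len
    return 0.0 if den == 0 else num / den


@dataclass
class EventCountTable:
    """Inclusion/skipping read counts per event per sample.

    ``inc``/``skip`` are event x sample DataFrames with identical shape;
    ``inc_len``/``skip_len`` give the effective form lengths used for PSI
    normalization; ``conditions`` maps sample id -> condition label.
    """

    inc: pd.DataFrame
    skip: pd.DataFrame
    inc_len: pd.Series
    skip_len: pd.Series
    conditions: dict[str, str]

    def samples_of(self, condition: str) -> list[str]:
        return [s for s, c in self.conditions.items() if c == condition]


def differential_events(
    table: EventCountTable,
    cond_a: str,
    cond_b: str,
    delta_threshold: float = 0.2,
    fdr_threshold: float = 0.05,
    min_reads: int = 10,
) -> pd.DataFrame:
    """Differential splicing between two conditions (binomial GLM LRT).

    Each condition needs at least two replicate samples. Events whose total
    read support in either condition falls below ``min_reads`` are reported
    with missing PSI and excluded from testing. Significance requires
    BH-adjusted p < ``fdr_threshold`` and |dPSI| > ``delta_threshold``.
    """
    sa, sb = table.samples_of(cond_a), table.samples_of(cond_b)
    if cond_a == cond_b or not sa or not sb:
        raise ValueError("need two distinct conditions present in the table")
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("need >= 2 replicates per condition")

    ia = table.inc[sa].sum(axis=1).to_numpy(float)
    ka = table.skip[sa].sum(axis=1).to_numpy(float)
    ib = table.inc[sb].sum(axis=1).to_numpy(float)
    kb = table.skip[sb].sum(axis=1).to_numpy(float)
    li = table.inc_len.to_numpy(float)
    ls = table.skip_len.to_numpy(float)

    ok = (ia + ka >= min_reads) & (ib + kb >= min_reads)

    def ll(i, k):
        n = i + k
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, i / np.maximum(n, 1), 0.5)
        return xlogy(i, p) + xlogy(k, 1 - p)

    ll_full = ll(ia, ka) + ll(ib, kb)
    ll_null = ll(ia + ib, ka + kb)
    lrt = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    p = sps.chi2.sf(lrt, df=1)

    def psi(i, k):
        with np.errstate(invalid="ignore", divide="ignore"):
            num = i / li
            den = num + k / ls
            return np.where(den > 0, num / den, np.nan)

    psi_a = np.where(ok, psi(ia, ka), np.nan)
    psi_b = np.where(ok, psi(ib, kb), np.nan)
    delta = psi_a - psi_b

    out = pd.DataFrame(
        {
            "psi_a": psi_a, "psi_b": psi_b, "delta_psi": delta,
            "p": np.where(ok, p, np.nan),
        },
        index=table.inc.index,
    )
    padj = np.full(len(out), np.nan)
    if ok.any():
        padj[ok] = bh_adjust(out.loc[ok, "p"].to_numpy())
    out["padj"] = padj
    out["significant"] = (
        (out["padj"] < fdr_threshold)
        & (out["delta_psi"].abs() > delta_threshold)
    ).fillna(False)
    return out


def event_type_breakdown(
    results: pd.DataFrame,
    event_info: pd.DataFrame,
    categories: pd.Series,
) -> pd.DataFrame:
    """Tally significant events by type and gene category.

    ``event_info`` is indexed by event_id with ``event_type`` and
    ``gene_id`` columns; ``categories`` maps gene_id to its three-way
    class.
    """
    sig = results.index[results["significant"]]
    info = event_info.loc[sig].copy()
    info["category"] = info["gene_id"].map(categories).fillna("non-TRA")
    tally = (
        info.groupby(["event_type", "category"]).size().rename("n_events").reset_index()
    )
    genes = info.groupby("category")["gene_id"].nunique().rename("n_genes")
    return tally.merge(genes, on="category", how="left")


def exon_inclusion_patterns(
    psi: pd.DataFrame,
    mtec_samples: list[str],
    tissue_samples: list[str],
    exon_lengths: pd.Series,
    min_exon_length: int = 50,
    mtec_mean_below: float = 0.1,
    mtec_max_below: float = 0.2,
    tissue_above: float = 0.5,
) -> pd.DataFrame:
    """Exons excluded from TEC transcripts but included in the periphery.

    Retains cassette exons longer than ``min_exon_length`` whose TEC-like
    mean PSI < ``mtec_mean_below`` AND TEC max PSI < ``mtec_max_below``
    AND which reach PSI > ``tissue_above`` in at least one peripheral
    tissue; returns their tissue PSI pattern matrix.
    """
    long_enough = exon_lengths.reindex(psi.index) > min_exon_length
    mtec = psi[mtec_samples]
    keep = (
        long_enough
        & (mtec.mean(axis=1) < mtec_mean_below)
        & (mtec.max(axis=1) < mtec_max_below)
        & (psi[tissue_samples].max(axis=1) > tissue_above)
    )
    return psi.loc[keep.fillna(False), tissue_samples + mtec_samples]


def microexon_summary(
    events: list[SpliceEvent],
    psi: pd.DataFrame,
    max_length: int = 30,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample PSI distribution of microexons (cassette length <= max_length).

    Returns (quantile summary per sample, full microexon PSI table). The
    length cutoff is inclusive: a 30-nt cassette is a microexon.
    """
    micro_ids = [
        e.event_id for e in events
        if e.event_type == "SE" and e.cassette_length is not None
        and e.cassette_length <= max_length
    ]
    sub = psi.loc[[i for i in micro_ids if i in psi.index]]
    summary = sub.quantile([0.25, 0.5, 0.75]).T
    summary.columns = ["q25", "median", "q75"]
    summary.index.name = "sample_id"
    summary["n_microexons"] = sub.notna().sum(axis=0).to_numpy()
    return summary, sub
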