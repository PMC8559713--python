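"""Synthetic multi-tissue splicing data with planted ground truth.

The generator emulates the study design the analysis modules target:

* a panel of peripheral tissues (21 by default) with one high-depth sample
  each, plus TEC-like samples (immature / mature Aire-positive /
  Aire-knockout, two replicates each);
* housekeeping genes expressed broadly versus tissue-restricted antigen
  (TRA) genes expressed in a single home tissue, a configurable fraction
  of which are Aire-dependent (down-regulated several-fold in the
  knockout);
* promiscuous gene expression in the TEC-like samples: every TRA gene is
  expressed there, but at a few percent of its home-tissue level and
  through only a configurable fraction of its isoforms -- the planted
  isoform and splice-junction deficit the census is designed to detect;
* multi-isoform gene architectures generating all seven local event types
  (SE genes carry cassette exons, a fraction of which are microexons
  whose inclusion is biased to the cerebellum sample);
* event inclusion/skipping counts for a control-versus-knockout contrast
  with planted dPSI on cassettes labelled "enhanced" or "repressed";
* a random genome in which the RBFOX recognition element WGCAUGM is
  planted at an elevated rate downstream of enhanced cassettes and
  upstream of repressed ones (motifs are written in the sense orientation
  of each gene, reverse-complemented on minus-strand genes);
* replicate detection pools with logistic, expression-dependent dropout
  for the npIDR reproducibility filter.

Every dataset is fully determined by the configuration (including its
seed); each operation draws from an independent, seed-derived stream so
stages can be re-run in any order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .events import EventCountTable, SpliceEvent
from .models import (
    Annotation,
    ExpressionMatrix,
    JunctionCounts,
    SampleMeta,
    TranscriptModel,
)

__all__ = [
    "TruthTable",
    "SimulatedExpression",
    "make_annotation",
    "make_expression",
    "make_event_counts",
    "make_replicate_pools",
]

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

TEC_SAMPLES = {
    "mTEC_mature_1": ("mTEC", "mature", 1),
    "mTEC_mature_2": ("mTEC", "mature", 2),
    "mTEC_immature_1": ("mTEC", "immature", 1),
    "mTEC_immature_2": ("mTEC", "immature", 2),
    "mTEC_aireko_1": ("mTEC", "aire_ko", 1),
    "mTEC_aireko_2": ("mTEC", "aire_ko", 2),
}

MICROEXON_TISSUE = "cerebellum"


@dataclass
class TruthTable:
    """Planted truth: per-gene categories, per-transcript flags, per-exon labels."""

    genes: pd.DataFrame
    transcripts: pd.DataFrame
    exons: pd.DataFrame
    events: pd.DataFrame | None = None


@dataclass
class SimulatedExpression:
    """Expression-level outputs of the generator."""

    transcript_tpm: ExpressionMatrix
    gene_tpm: ExpressionMatrix
    junctions: JunctionCounts
    transcript_counts: pd.DataFrame  # TEC samples only
    gene_counts: pd.DataFrame        # TEC samples only


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed) % (2**31), stream])


def _revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _motif_instance(motif: str, rng) -> str:
    from .motifs import IUPAC

    out = []
    for c in motif:
        opts = IUPAC[c.upper()]
        out.append(opts[int(rng.integers(len(opts)))] if len(opts) > 1 else opts)
    return "".join(out)


def _tx_to_genomic(exons, pos: int) -> int:
    """Map a transcript coordinate (5'-to-3' in the local sense frame) to genomic."""
    for s, e in exons:
        if pos < e - s:
            return s + pos
        pos -= e - s
    raise ValueError("transcript coordinate beyond transcript length")


# --------------------------------------------------------------------------
# gene architecture
# --------------------------------------------------------------------------

def _build_se_gene(cfg, rng, n_exons_range, n_iso_range):
    K = int(rng.integers(n_exons_range[0], n_exons_range[1] + 1))
    m = int(rng.integers(n_iso_range[0], n_iso_range[1] + 1))
    m = min(m, K - 1)
    cass_idx = sorted(rng.choice(np.arange(1, K - 1), size=m - 1, replace=False))
    micro = {i: bool(rng.random() < cfg.microexon_fraction) for i in cass_idx}
    lengths, starts, x = [], [], 300
    for i in range(K):
        if i in micro and micro[i]:
            ln = int(rng.integers(cfg.microexon_length[0], cfg.microexon_length[1] + 1))
        else:
            ln = int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
        starts.append(x)
        lengths.append(ln)
        x += ln + int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1))
    exons = [(s, s + ln) for s, ln in zip(starts, lengths)]
    txs = {"t01": {"exons": list(exons), "role": "full", "cassette": None}}
    cassettes = []
    for j, ci in enumerate(cass_idx):
        tid = f"t{j + 2:02d}"
        txs[tid] = {
            "exons": [e for k, e in enumerate(exons) if k != ci],
            "role": "skip",
            "cassette": exons[ci],
        }
        label = rng.choice(["enhanced", "repressed", "unregulated"], p=[0.25, 0.25, 0.5])
        cassettes.append(
            {"start": exons[ci][0], "end": exons[ci][1], "label": str(label),
             "micro": micro[ci], "skip_tid": tid}
        )
    return txs, cassettes


def _build_pair_gene(cfg, rng, archetype):
    K = int(rng.integers(cfg.n_exons[0], cfg.n_exons[1] + 1))
    lengths = rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1, size=K)
    introns = rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1, size=K)
    starts, x = [], 300
    for ln, intr in zip(lengths, introns):
        starts.append(x)
        x += int(ln) + int(intr)
    exons = [(s, s + int(ln)) for s, ln in zip(starts, lengths)]
    t0 = list(exons)
    if archetype == "a5":
        i = int(rng.integers(1, K - 1))
        d = int(rng.integers(30, 91))
        t1 = [(s, e + d) if k == i else (s, e) for k, (s, e) in enumerate(exons)]
    elif archetype == "a3":
        i = int(rng.integers(1, K - 1))
        d = int(rng.integers(30, 91))
        t1 = [(s - d, e) if k == i else (s, e) for k, (s, e) in enumerate(exons)]
    elif archetype == "ri":
        i = int(rng.integers(0, K - 1))
        t1 = exons[:i] + [(exons[i][0], exons[i + 1][1])] + exons[i + 2:]
    elif archetype == "mx":
        i = int(rng.integers(1, K - 1))
        ln = int(rng.integers(80, 121))
        ys = exons[i][1] + 280
        t1 = sorted(exons[:i] + [(ys, ys + ln)] + exons[i + 1:])
    elif archetype == "af":
        ln = int(rng.integers(80, 151))
        ns = exons[0][1] + 100
        t1 = sorted([(ns, ns + ln)] + exons[1:])
    elif archetype == "al":
        ln = int(rng.integers(80, 151))
        ns = exons[-1][1] + 150
        t1 = sorted(exons[:-1] + [(ns, ns + ln)])
    else:
        raise ValueError(archetype)
    return {"t01": {"exons": t0, "role": "full", "cassette": None},
            "t02": {"exons": t1, "role": "alt", "cassette": None}}, []


def make_annotation(
    cfg: SimulationConfig,
) -> tuple[Annotation, dict[str, str], TruthTable]:
    """Generate transcript models, a genome with planted motifs, and truth.

    Returns (annotation, genome, truth) where the truth table carries the
    gene categories/home tissues, per-transcript Aire flags, and per-exon
    cassette labels with planted-motif counts.
    """
    rng = _rng(cfg, 1)
    tissues = cfg.tissue_names
    n_tra = int(round(cfg.frac_tra * cfg.n_genes))
    tra_ids = set(rng.choice(cfg.n_genes, size=n_tra, replace=False).tolist())
    aire_ids = set(
        rng.choice(sorted(tra_ids), size=int(round(cfg.frac_aire * n_tra)),
                   replace=False).tolist()
    )
    archetypes = ["se", "a5", "a3", "ri", "mx", "af", "al"]
    arch_p = [0.5, 0.08, 0.08, 0.10, 0.08, 0.08, 0.08]

    ann = Annotation()
    genome: dict[str, str] = {}
    gene_rows, tx_rows, exon_rows = [], [], []
    tra_counter = 0
    for g in range(cfg.n_genes):
        gene_id = f"G{g + 1:04d}"
        chrom = f"chr_{gene_id}"
        strand = "+" if rng.random() < 0.5 else "-"
        is_tra = g in tra_ids
        is_aire = g in aire_ids
        if is_tra:
            home = tissues[tra_counter % len(tissues)]
            tra_counter += 1
            archetype = "se"
            txs, cassettes = _build_se_gene(
                cfg, rng, cfg.n_exons_tra, cfg.isoforms_per_tra_gene
            )
        else:
            home = None
            archetype = str(rng.choice(archetypes, p=arch_p))
            if archetype == "se":
                txs, cassettes = _build_se_gene(
                    cfg, rng, cfg.n_exons, cfg.isoforms_per_gene
                )
            else:
                txs, cassettes = _build_pair_gene(cfg, rng, archetype)

        # Aire flags and structure plan (per transcript, in the sense frame)
        tids = sorted(txs)
        aire_flags = {}
        if is_aire:
            flags = rng.random(len(tids)) < 0.5
            if not flags.any():
                flags[0] = True
            aire_flags = dict(zip(tids, flags))
        for tid in tids:
            info = txs[tid]
            aire_reg = bool(aire_flags.get(tid, False))
            if aire_reg:
                # planted length shift: extend the sense-terminal exon ~1 kb
                s, e = info["exons"][-1]
                info["exons"][-1] = (s, e + int(rng.integers(800, 1201)))
                structure = "classical"
            elif is_aire:
                structure = str(rng.choice(
                    ["classical", "nonclassical", "unannotated"], p=[0.3, 0.4, 0.3]
                ))
            else:
                structure = str(rng.choice(
                    ["classical", "nonclassical", "unannotated"], p=[0.6, 0.25, 0.15]
                ))
            info["aire"] = aire_reg
            info["structure"] = structure
            info["novel"] = bool(info["role"] != "full" and rng.random() < 0.3)

        span = max(e for info in txs.values() for _, e in info["exons"]) + 300

        def flip(iv):
            return (span - iv[1], span - iv[0])

        # usage bias: microexon cassettes -> cerebellum; otherwise a random
        # tissue for a fraction of non-TRA cassette genes
        bias_tissue, bias_skip = None, None
        if cassettes and not is_tra:
            micro_cas = [c for c in cassettes if c["micro"]]
            if micro_cas:
                bias_tissue, bias_skip = MICROEXON_TISSUE, micro_cas[0]["skip_tid"]
            elif rng.random() < cfg.biased_cassette_fraction:
                bias_tissue = str(rng.choice(tissues))
                bias_skip = str(rng.choice([c["skip_tid"] for c in cassettes]))

        for tid in tids:
            info = txs[tid]
            exons = info["exons"]
            L = sum(e - s for s, e in exons)
            cds = None
            if info["structure"] != "unannotated":
                utr5 = 0 if info["structure"] == "nonclassical" else int(
                    rng.integers(30, 71)
                )
                utr3 = int(rng.integers(int(0.15 * L), int(0.30 * L) + 1))
                utr3 = min(utr3, L - utr5 - 60)
                if utr3 < 1:
                    utr3 = 0
                cs = _tx_to_genomic(exons, utr5)
                ce = _tx_to_genomic(exons, L - utr3 - 1) + 1
                cds = (cs, ce)
            if strand == "-":
                exons_g = sorted(flip(iv) for iv in exons)
                cds_g = None if cds is None else flip(cds)
            else:
                exons_g, cds_g = exons, cds
            full_tid = f"{gene_id}.{tid}"
            ann.add(TranscriptModel(
                transcript_id=full_tid, gene_id=gene_id, chrom=chrom,
                strand=strand, exons=exons_g, cds=cds_g,
                biotype="protein_coding", novel=info["novel"],
            ))
            tx_rows.append({
                "transcript_id": full_tid, "gene_id": gene_id,
                "role": info["role"], "aire_regulated": info["aire"],
                "structure": info["structure"],
            })

        # genome + motif planting (final genomic coordinates)
        seq = _BASES[rng.integers(0, 4, size=span)]
        n_bg = rng.poisson(span / 1000.0 * cfg.motif_background_per_kb)
        for pos in rng.integers(0, span - 8, size=n_bg):
            inst = _motif_instance(cfg.motif, rng)
            if strand == "-":
                inst = _revcomp(inst)
            seq[pos: pos + len(inst)] = list(inst)
        win = 250
        extra_rate = (win / 1000.0) * cfg.motif_background_per_kb * max(
            cfg.motif_enrichment_rate - 1.0, 0.0
        )
        for cas in cassettes:
            s, e = (cas["start"], cas["end"]) if strand == "+" else flip(
                (cas["start"], cas["end"])
            )
            if cas["label"] == "enhanced":
                lo, hi = (e, e + win) if strand == "+" else (s - win, s)
            elif cas["label"] == "repressed":
                lo, hi = (s - win, s) if strand == "+" else (e, e + win)
            else:
                lo = hi = None
            planted = 0
            if lo is not None:
                for pos in rng.integers(lo + 2, hi - 9,
                                        size=rng.poisson(extra_rate)):
                    inst = _motif_instance(cfg.motif, rng)
                    if strand == "-":
                        inst = _revcomp(inst)
                    seq[pos: pos + len(inst)] = list(inst)
                    planted += 1
            exon_rows.append({
                "gene_id": gene_id, "chrom": chrom, "strand": strand,
                "start": s, "end": e, "label": cas["label"],
                "microexon": cas["micro"], "planted_motifs": planted,
                "skip_transcript": f"{gene_id}.{cas['skip_tid']}",
            })
        genome[chrom] = "".join(seq)

        category = ("Aire-TRA" if is_aire else "non-Aire-TRA") if is_tra else "non-TRA"
        gene_rows.append({
            "gene_id": gene_id, "category": category, "home_tissue": home,
            "archetype": archetype, "n_isoforms": len(tids),
            "bias_tissue": bias_tissue,
            "bias_skip_transcript": None if bias_skip is None else f"{gene_id}.{bias_skip}",
        })

    truth = TruthTable(
        genes=pd.DataFrame(gene_rows).set_index("gene_id"),
        transcripts=pd.DataFrame(tx_rows).set_index("transcript_id"),
        exons=pd.DataFrame(exon_rows),
    )
    ann.validate()
    return ann, genome, truth


# --------------------------------------------------------------------------
# expression
# --------------------------------------------------------------------------

def _sample_metas(cfg) -> list[SampleMeta]:
    metas = [SampleMeta(t, t, "peripheral", 1) for t in cfg.tissue_names]
    metas += [
        SampleMeta(sid, tissue, cond, rep)
        for sid, (tissue, cond, rep) in TEC_SAMPLES.items()
    ]
    return metas


def make_expression(
    cfg: SimulationConfig,
    annotation: Annotation,
    truth: TruthTable,
) -> SimulatedExpression:
    """Generate TPM matrices, junction counts and TEC count matrices.

    Adds the chosen TEC isoform subset of each TRA gene to the gene truth
    (column ``tec_isoforms``).
    """
    rng = _rng(cfg, 2)
    metas = _sample_metas(cfg)
    sample_ids = [m.sample_id for m in metas]
    tissues = cfg.tissue_names
    genes = list(truth.genes.index)
    gtab = truth.genes

    # per-gene baseline abundance and isoform usage. In Aire-dependent TRA
    # genes the Aire-regulated isoforms carry most of the usage mass (so the
    # knockout effect is visible at gene level) and are preferentially the
    # isoforms the TEC-like sample expresses.
    base = np.exp(rng.normal(cfg.mean_log_tpm, cfg.sd_log_tpm, size=len(genes)))
    aire_tx = truth.transcripts["aire_regulated"]
    usage, tec_iso, presence = {}, {}, {}
    for gi, gene in enumerate(genes):
        tids = sorted(annotation.genes[gene])
        u = rng.dirichlet(np.full(len(tids), 2.0))
        flagged = aire_tx[tids].to_numpy(dtype=bool)
        if flagged.any() and not flagged.all():
            u = np.where(flagged, 0.9 * u / u[flagged].sum(),
                         0.1 * u / u[~flagged].sum())
        usage[gene] = pd.Series(u, index=tids)
        if gtab.at[gene, "category"] != "non-TRA":
            n_keep = max(1, int(round(cfg.tec_isoform_fraction * len(tids))))
            order = sorted(tids, key=lambda t: (not aire_tx[t], rng.random()))
            tec_iso[gene] = sorted(order[:n_keep])
            presence[gene] = None
        else:
            presence[gene] = rng.random(len(tissues)) < cfg.non_tra_tissue_presence

    truth.genes = gtab.assign(
        tec_isoforms=[";".join(tec_iso.get(g, [])) for g in genes]
    )

    tids_all = sorted(annotation.transcripts)
    tid_pos = {tid: i for i, tid in enumerate(tids_all)}
    col_pos = {sid: j for j, sid in enumerate(sample_ids)}
    abund_np = np.zeros((len(tids_all), len(sample_ids)))
    for gi, gene in enumerate(genes):
        u = usage[gene]
        tids = list(u.index)
        rows = np.array([tid_pos[t] for t in tids])
        u_np = u.to_numpy()
        cat = gtab.at[gene, "category"]
        home = gtab.at[gene, "home_tissue"]
        bias_t = gtab.at[gene, "bias_tissue"]
        bias_skip = gtab.at[gene, "bias_skip_transcript"]
        if bias_t is not None and not pd.isna(bias_t):
            skip_mask = np.array([t == bias_skip for t in tids])
            u_bias = np.where(skip_mask, 0.05, 0.95 * u_np / u_np[~skip_mask].sum())
            u_nobias = np.where(skip_mask, 0.95, 0.05 * u_np / u_np[~skip_mask].sum())
        else:
            u_bias = u_nobias = None

        def usage_for(tissue_like):
            if u_bias is None:
                return u_np
            return u_bias if tissue_like == bias_t else u_nobias

        for ti, tissue in enumerate(tissues):
            if cat == "non-TRA":
                level = base[gi] * (1.0 if presence[gene][ti] else 0.0)
                vec = usage_for(tissue)
            else:
                level = base[gi] if tissue == home else 0.0
                vec = u_np
            if level > 0:
                abund_np[rows, col_pos[tissue]] = level * vec
        # TEC-like samples; the knockout reduces the Aire-regulated
        # transcripts themselves, leaving sibling isoforms untouched
        if cat != "non-TRA":
            keep = tec_iso[gene]
            keep_mask = np.array([t in keep for t in tids])
            u_tec = np.where(keep_mask, u_np / u_np[keep_mask].sum(), 0.0)
            flagged_np = aire_tx[tids].to_numpy(dtype=bool)
        for sid, (_, cond, _) in TEC_SAMPLES.items():
            if cat == "non-TRA":
                level = base[gi]
                vec = usage_for("mTEC")
            else:
                level = base[gi] * cfg.tec_expression_fraction
                if cond == "immature":
                    level *= cfg.immature_tra_fraction
                vec = u_tec
                if cond == "aire_ko":
                    vec = u_tec * np.where(flagged_np, 1.0 / cfg.aire_ko_fold, 1.0)
            abund_np[rows, col_pos[sid]] = level * vec

    noise = np.exp(rng.normal(0.0, cfg.tpm_lognorm_sigma, size=abund_np.shape))
    abund = pd.DataFrame(abund_np * noise, index=tids_all, columns=sample_ids)
    tpm = abund / abund.sum(axis=0) * 1e6

    transcript_tpm = ExpressionMatrix(tpm, "transcript", metas, "TPM")
    t2g = annotation.transcript_gene()
    gene_tpm = ExpressionMatrix(
        tpm.groupby(t2g).sum(), "gene", metas, "TPM"
    )

    # junction counts from transcript abundances
    junc_members: dict[tuple, list[str]] = {}
    for tid in tids_all:
        t = annotation.transcripts[tid]
        for d, a in t.junctions():
            junc_members.setdefault((t.gene_id, d, a, t.strand), []).append(tid)
    keys = sorted(junc_members)
    mean = np.zeros((len(keys), len(sample_ids)))
    tpm_np = tpm.to_numpy()
    tid_pos = {tid: i for i, tid in enumerate(tids_all)}
    for ki, key in enumerate(keys):
        rows = [tid_pos[tid] for tid in junc_members[key]]
        mean[ki] = tpm_np[rows].sum(axis=0) * cfg.junction_coverage / 100.0
    counts = _nb_draw(rng, mean, cfg.noise)
    jdf = pd.DataFrame(counts, columns=sample_ids,
                       index=pd.MultiIndex.from_tuples(
                           keys, names=["gene_id", "donor", "acceptor", "strand"]))
    junctions = JunctionCounts(jdf)

    # count matrices for the TEC conditions (differential tests)
    tec_ids = list(TEC_SAMPLES)
    tec_mean = tpm[tec_ids].to_numpy() * cfg.count_depth
    tcounts = pd.DataFrame(_nb_draw(rng, tec_mean, cfg.noise),
                           index=tids_all, columns=tec_ids)
    gcounts = tcounts.groupby(t2g).sum()
    return SimulatedExpression(transcript_tpm, gene_tpm, junctions, tcounts, gcounts)


def _nb_draw(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = m + dispersion * m^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(r, r / (r + mean[pos]))
    return out


# --------------------------------------------------------------------------
# event counts
# --------------------------------------------------------------------------

def make_event_counts(
    cfg: SimulationConfig,
    events: list[SpliceEvent],
    truth: TruthTable,
) -> EventCountTable:
    """Inclusion/skipping counts for a control-vs-knockout contrast.

    SE events whose cassette is labelled "enhanced" get PSI higher by
    ``planted_delta_psi`` in the control condition (the regulator present);
    "repressed" cassettes get the opposite shift; all other events are
    null. Counts are Binomial(coverage, p_inc) per replicate with the
    junction-count length normalization (inclusion form length 2,
    skipping form 1). Fills ``truth.events``.
    """
    rng = _rng(cfg, 3)
    label_of = {
        (r.gene_id, r.start, r.end): r.label for r in truth.exons.itertuples()
    }
    samples = {"ctrl_1": "control", "ctrl_2": "control",
               "ko_1": "ko", "ko_2": "ko"}
    rows_inc, rows_skip, meta = [], [], []
    for ev in events:
        if ev.event_type == "SE":
            li, ls = 2.0, 1.0
            cass = (ev.gene_id, ev.coords[1], ev.coords[2])
            label = label_of.get(cass, "unregulated")
        else:
            li, ls = 1.0, 1.0
            label = "unregulated"
        base = rng.uniform(0.3, 0.7)
        if label == "enhanced":
            psi_ctrl = base + cfg.planted_delta_psi / 2
            psi_ko = base - cfg.planted_delta_psi / 2
        elif label == "repressed":
            psi_ctrl = base - cfg.planted_delta_psi / 2
            psi_ko = base + cfg.planted_delta_psi / 2
        else:
            psi_ctrl = psi_ko = base
        inc_row, skip_row = {}, {}
        for sid, cond in samples.items():
            psi = psi_ctrl if cond == "control" else psi_ko
            p_inc = psi * li / (psi * li + (1 - psi) * ls)
            n = rng.poisson(cfg.event_coverage)
            i = rng.binomial(n, p_inc) if n > 0 else 0
            inc_row[sid] = i
            skip_row[sid] = n - i
        rows_inc.append(inc_row)
        rows_skip.append(skip_row)
        meta.append({
            "event_id": ev.event_id, "gene_id": ev.gene_id,
            "event_type": ev.event_type, "label": label,
            "true_psi_control": psi_ctrl, "true_psi_ko": psi_ko,
            "true_delta_psi": psi_ctrl - psi_ko,
            "regulated": label in ("enhanced", "repressed"),
        })
    idx = pd.Index([m["event_id"] for m in meta], name="event_id")
    truth.events = pd.DataFrame(meta).set_index("event_id")
    return EventCountTable(
        inc=pd.DataFrame(rows_inc, index=idx),
        skip=pd.DataFrame(rows_skip, index=idx),
        inc_len=pd.Series([2.0 if e.event_type == "SE" else 1.0 for e in events], index=idx),
        skip_len=pd.Series(1.0, index=idx),
        conditions=samples,
    )


# --------------------------------------------------------------------------
# replicate detection pools
# --------------------------------------------------------------------------

def make_replicate_pools(
    cfg: SimulationConfig,
    transcript_tpm: ExpressionMatrix,
) -> dict[str, tuple[set, set]]:
    """Two detection replicates per sample with expression-dependent dropout.

    Detection probability is logistic in log10(TPM): p = 1 / (1 +
    exp(-slope * (log10 TPM - midpoint))); transcripts below
    ``detect_floor_tpm`` (or at zero TPM) are never detected. With
    ``detect_dropout`` disabled both replicates equal the expressed set.
    """
    rng = _rng(cfg, 4)
    pools: dict[str, tuple[set, set]] = {}
    tpm = transcript_tpm.values
    for sid in tpm.columns:
        x = tpm[sid].to_numpy(dtype=float)
        expressed = x > max(cfg.detect_floor_tpm, 0.0)
        if not cfg.detect_dropout:
            ids = set(tpm.index[expressed])
            pools[sid] = (set(ids), set(ids))
            continue
        with np.errstate(divide="ignore"):
            logx = np.where(x > 0, np.log10(np.maximum(x, 1e-300)), -np.inf)
        p = 1.0 / (1.0 + np.exp(-cfg.detect_slope * (logx - cfg.detect_midpoint_log10tpm)))
        p = np.where(expressed, p, 0.0)
        r1 = rng.random(len(p)) < p
        r2 = rng.random(len(p)) < p
        pools[sid] = (set(tpm.index[r1]), set(tpm.index[r2]))
    return pools
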