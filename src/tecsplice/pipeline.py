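"""End-to-end orchestration of the synthetic splice-isoform census.

Runs the full chain on generated data: simulation -> reproducibility
filter -> gene classification -> detection census -> junction census ->
differential splicing -> Aire transcript-structure analysis -> motif
enrichment. Each stage writes deterministic TSV outputs; the run manifest
records the seed, the configuration echo and library versions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, aire, census, events, motifs, reproducibility, specificity, stats
from .config import AnalysisConfig, SimulationConfig, dump_config
from .simulate import (
    TEC_SAMPLES,
    SimulatedExpression,
    TruthTable,
    make_annotation,
    make_event_counts,
    make_expression,
    make_replicate_pools,
)

logger = logging.getLogger("tecsplice")

TEC_CENSUS_SAMPLE = "mTEC_mature_1"
KO_SAMPLES = ["mTEC_aireko_1", "mTEC_aireko_2"]
POS_SAMPLES = ["mTEC_mature_1", "mTEC_mature_2"]

STAGES = ("simulate", "filter", "classify", "census", "junctions",
          "events", "aire", "motifs")


@dataclass
class PipelineResult:
    """In-memory results of a pipeline run (stage name -> tables/objects)."""

    annotation: object
    genome: dict
    truth: TruthTable
    expression: SimulatedExpression
    tables: dict


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", na_rep=".", float_format="%.6g", index=index)


def run_pipeline(
    sim_cfg: SimulationConfig,
    ana_cfg: AnalysisConfig,
    outdir: str | Path | None = None,
    stages: tuple[str, ...] = STAGES,
) -> PipelineResult:
    """Run the requested stages (always starting from simulation).

    When ``outdir`` is given, each stage writes its TSV outputs there and a
    ``manifest.yaml`` records the seed, configuration and versions.
    """
    out = None
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)

    tables: dict = {}

    # ---- simulate --------------------------------------------------------
    annotation, genome, truth = make_annotation(sim_cfg)
    expr = make_expression(sim_cfg, annotation, truth)
    event_list = events.enumerate_events(annotation)
    event_counts = make_event_counts(sim_cfg, event_list, truth)
    pools = make_replicate_pools(sim_cfg, expr.transcript_tpm)
    logger.info(
        "stage=simulate genes=%d transcripts=%d events=%d junctions=%d",
        len(annotation.genes), len(annotation.transcripts),
        len(event_list), len(expr.junctions.counts),
    )
    if out is not None and "simulate" in stages:
        from .io import write_expression, write_fasta, write_gtf, write_junctions

        write_gtf(annotation, out / "annotation.gtf")
        write_fasta(genome, out / "genome.fa")
        write_expression(expr.transcript_tpm, out / "transcript_tpm.tsv",
                         out / "samples.tsv")
        write_expression(expr.gene_tpm, out / "gene_tpm.tsv", out / "samples.tsv")
        write_junctions(expr.junctions, out / "junction_counts.tsv")
        _write(truth.genes, out / "truth_genes.tsv")
        _write(truth.transcripts, out / "truth_transcripts.tsv")
        _write(truth.exons, out / "truth_exons.tsv", index=False)

    tpm = expr.transcript_tpm.values
    peripheral = sim_cfg.tissue_names

    # ---- reproducibility filter -----------------------------------------
    if "filter" in stages:
        rep1, rep2 = pools[TEC_CENSUS_SAMPLE]
        expression = tpm[TEC_CENSUS_SAMPLE]
        curve = reproducibility.compute_npidr(
            rep1, rep2, expression, n_bins=ana_cfg.npidr_bins
        )
        accepted = reproducibility.filter_reproducible(
            curve, rep1 | rep2, expression, threshold=ana_cfg.npidr_threshold
        )
        tables["npidr_curve"] = curve.to_frame()
        tables["npidr_accepted"] = sorted(accepted)
        logger.info("stage=filter union=%d accepted=%d",
                    len(rep1 | rep2), len(accepted))
        if out is not None:
            _write(curve.to_frame(), out / "npidr_curve.tsv", index=False)
            from .io import write_id_list

            write_id_list(sorted(accepted), out / "npidr_accepted.tsv")

    # ---- classification --------------------------------------------------
    gene_by_tissue = expr.gene_tpm.by_tissue(peripheral)
    restricted = specificity.classify_restricted(
        gene_by_tissue, ana_cfg.tau_threshold, ana_cfg.tau_log_transform
    )
    diff = specificity.aire_differential(
        expr.gene_counts, KO_SAMPLES, POS_SAMPLES,
        dispersion=sim_cfg.noise,
    )
    aire_flags = specificity.classify_aire(
        diff, ana_cfg.aire_fc_threshold, ana_cfg.aire_alpha
    )
    classification = specificity.categorize_genes(restricted, aire_flags)
    tables["classification"] = classification
    tables["aire_differential"] = diff

    tx_by_tissue = expr.transcript_tpm.by_tissue(peripheral)
    tx_restricted = specificity.classify_restricted(
        tx_by_tissue, ana_cfg.tau_threshold, ana_cfg.tau_log_transform
    )
    tables["transcript_restricted"] = tx_restricted
    if out is not None and "classify" in stages:
        _write(classification, out / "gene_classification.tsv")
        _write(diff, out / "aire_differential.tsv")
        _write(tx_restricted, out / "transcript_restricted.tsv")

    # ---- detection census ------------------------------------------------
    if "census" in stages:
        det = census.detect(expr.transcript_tpm, ana_cfg.detection_threshold)
        curve = census.detection_fraction_curve(
            expr.transcript_tpm, list(annotation.transcripts),
            ana_cfg.detection_grid,
        )
        summary = census.census_summary(det, annotation)
        iso_frac = census.isoform_fraction(det, annotation, classification["category"])
        entropy = census.entropy_by_gene(tpm, annotation)
        itra_sets = {
            t: set(classification.index[classification["itra_tissue"] == t])
            for t in peripheral
        }
        sample_of = {t: t for t in peripheral}
        as_frac = census.multi_isoform_as_fraction(
            det, expr.gene_tpm.values, annotation, itra_sets, sample_of
        )
        # the full TRA set evaluated in the TEC-like sample
        tra_all = {"mTEC_full_TRA": set(classification.index[classification["is_tra"]])}
        as_frac_tec = census.multi_isoform_as_fraction(
            det, expr.gene_tpm.values, annotation, tra_all,
            {"mTEC_full_TRA": TEC_CENSUS_SAMPLE},
        )
        restricted_tx_sets = {
            t: set(tx_restricted.index[tx_restricted["home_tissue"] == t])
            for t in peripheral
        }
        representation = census.peripheral_representation(
            restricted_tx_sets, det[TEC_CENSUS_SAMPLE]
        )
        # gene/transcript ANCOVA at a small positive detection threshold so
        # per-sample detection varies in every group
        det_01 = census.detect(expr.transcript_tpm, ana_cfg.detection_grid[1])
        summary_01 = census.census_summary(det_01, annotation)
        ancova_in = pd.DataFrame(
            {
                "genes": summary_01["genes_detected"],
                "transcripts": summary_01["transcripts_detected"],
            }
        )
        ancova_in["group"] = [
            "TEC" if s in TEC_SAMPLES else "peripheral" for s in ancova_in.index
        ]
        ancova = census.gene_transcript_ancova(
            ancova_in, exclude=["testis"] if "testis" in ancova_in.index else []
        )
        tables.update(
            detection_curve=curve, census_summary=summary,
            isoform_fraction=iso_frac, entropy=entropy,
            as_fraction=pd.concat([as_frac, as_frac_tec], ignore_index=True),
            representation=representation, ancova=ancova,
        )
        if out is not None:
            _write(curve, out / "detection_fractions.tsv")
            _write(summary, out / "census_summary.tsv")
            _write(iso_frac, out / "isoform_fraction.tsv", index=False)
            _write(entropy, out / "entropy.tsv")
            _write(tables["as_fraction"], out / "as_fraction_by_quartile.tsv",
                   index=False)
            _write(representation, out / "peripheral_representation.tsv",
                   index=False)
            (out / "ancova.yaml").write_text(yaml.safe_dump(ancova, sort_keys=True))

    # ---- junction census -------------------------------------------------
    if "junctions" in stages:
        gene_tab, enr = stats.junction_census_all(
            expr.junctions, TEC_CENSUS_SAMPLE, {t: t for t in peripheral},
            classification,
            min_reads=ana_cfg.junction_min_reads,
            dispersion=ana_cfg.no_replicate_dispersion,
            fc_threshold=ana_cfg.junction_fc_threshold,
            alpha=ana_cfg.junction_alpha,
        )
        tables["junction_genes"] = gene_tab
        tables["junction_enrichment"] = enr
        if out is not None:
            _write(gene_tab, out / "junction_census.tsv", index=False)
            _write(enr, out / "junction_itra_enrichment.tsv", index=False)

    # ---- differential splicing ------------------------------------------
    event_info = pd.DataFrame(
        {
            "event_id": [e.event_id for e in event_list],
            "gene_id": [e.gene_id for e in event_list],
            "event_type": [e.event_type for e in event_list],
            "cassette_length": [e.cassette_length for e in event_list],
        }
    ).set_index("event_id")
    diff_ev = events.differential_events(
        event_counts, "control", "ko",
        delta_threshold=ana_cfg.event_delta_psi,
        fdr_threshold=ana_cfg.event_fdr,
        min_reads=ana_cfg.psi_min_reads,
    )
    tables["differential_events"] = diff_ev
    tables["event_info"] = event_info
    if "events" in stages:
        breakdown = events.event_type_breakdown(
            diff_ev, event_info, classification["category"]
        )
        psi = events.psi_matrix_from_tpm(
            [e for e in event_list if e.event_type == "SE"],
            tpm, min_total=ana_cfg.psi_min_tpm,
        )
        cass_len = event_info.loc[psi.index, "cassette_length"]
        patterns = events.exon_inclusion_patterns(
            psi, list(TEC_SAMPLES), peripheral, cass_len,
            min_exon_length=ana_cfg.exon_min_length,
        )
        micro_summary, micro_psi = events.microexon_summary(
            event_list, psi, max_length=ana_cfg.microexon_max_length
        )
        tables.update(event_breakdown=breakdown, psi=psi,
                      exon_patterns=patterns, microexon_summary=micro_summary)
        if out is not None:
            _write(diff_ev, out / "differential_events.tsv")
            _write(breakdown, out / "event_breakdown.tsv", index=False)
            _write(psi, out / "psi_se_events.tsv")
            _write(patterns, out / "exon_inclusion_patterns.tsv")
            _write(micro_summary, out / "microexon_summary.tsv")

    # ---- Aire transcript structure --------------------------------------
    if "aire" in stages:
        usage = aire.transcript_usage_test(
            expr.transcript_counts, KO_SAMPLES, POS_SAMPLES,
            dispersion=sim_cfg.noise,
            fc_threshold=ana_cfg.usage_fc_threshold,
            alpha=ana_cfg.usage_alpha,
        )
        length_res = aire.aire_length_analysis(annotation, usage)
        tables["transcript_usage"] = usage
        tables["aire_length"] = length_res
        if out is not None:
            _write(usage, out / "transcript_usage.tsv")
            (out / "aire_length.yaml").write_text(
                yaml.safe_dump(length_res, sort_keys=True, default_flow_style=False)
            )

    # ---- motif enrichment ------------------------------------------------
    if "motifs" in stages:
        se_sig = diff_ev.join(event_info).query("event_type == 'SE'")
        enhanced_ids = se_sig.index[(se_sig["significant"]) & (se_sig["delta_psi"] > 0)]
        repressed_ids = se_sig.index[(se_sig["significant"]) & (se_sig["delta_psi"] < 0)]
        unreg_ids = se_sig.index[~se_sig["significant"]]
        ev_by_id = {e.event_id: e for e in event_list}

        def contexts(ids):
            ctxs = []
            for eid in ids:
                e = ev_by_id[eid]
                s, en = e.coords[1], e.coords[2]
                ctxs.append(motifs.extract_context(
                    genome, e.chrom, s, en, e.strand, eid,
                    ana_cfg.intron_window, ana_cfg.exon_window,
                ))
            return ctxs

        bg = contexts(unreg_ids)
        mseed = int(sim_cfg.seed) % (2**31 - 10) + 5
        for name, ids in (("enhanced", enhanced_ids), ("repressed", repressed_ids)):
            if len(ids) == 0 or len(bg) < len(ids):
                continue
            prof = motifs.permutation_enrichment(
                contexts(ids), bg, motif=ana_cfg.motif,
                n_perm=ana_cfg.n_permutations, fdr=ana_cfg.motif_fdr,
                seed=mseed, intron_window=ana_cfg.intron_window,
                exon_window=ana_cfg.exon_window,
                smooth_width=ana_cfg.smooth_width,
            )
            tables[f"motif_{name}"] = prof
            if out is not None:
                _write(prof.table, out / f"motif_profile_{name}.tsv", index=False)

    if out is not None:
        manifest = {
            "package": "tecsplice",
            "version": __version__,
            "seed": int(sim_cfg.seed),
            "stages": list(stages),
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "config": yaml.safe_load(dump_config(sim_cfg, ana_cfg)),
        }
        (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))

    return PipelineResult(annotation, genome, truth, expr, tables)
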