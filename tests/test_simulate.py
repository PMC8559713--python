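"""Synthetic-data generator: determinism and planted-truth contracts."""

import numpy as np
import pandas as pd
import pytest

from tecsplice.config import SimulationConfig
from tecsplice.events import enumerate_events
from tecsplice.simulate import (
    make_annotation,
    make_event_counts,
    make_expression,
    make_replicate_pools,
)
from tecsplice.specificity import compute_tau


@pytest.fixture(scope="module")
def small_run():
    cfg = SimulationConfig(n_genes=80, n_tissues=6, seed=17)
    ann, genome, truth = make_annotation(cfg)
    expr = make_expression(cfg, ann, truth)
    return cfg, ann, genome, truth, expr


class TestMakeAnnotation:
    def test_same_seed_identical_output(self):
        cfg = SimulationConfig(n_genes=25, n_tissues=4, seed=5)
        a1, g1, t1 = make_annotation(cfg)
        a2, g2, t2 = make_annotation(cfg)
        assert g1 == g2
        assert sorted(a1.transcripts) == sorted(a2.transcripts)
        for tid in a1.transcripts:
            assert a1.transcripts[tid].exons == a2.transcripts[tid].exons
        pd.testing.assert_frame_equal(t1.exons, t2.exons)

    def test_microexon_fraction_of_cassettes(self):
        cfg = SimulationConfig(n_genes=250, n_tissues=4, seed=6,
                               microexon_fraction=0.2)
        _, _, truth = make_annotation(cfg)
        ex = truth.exons
        lengths = ex.end - ex.start
        assert len(ex) > 100
        frac = (lengths <= 30).mean()
        # binomial tolerance around the configured rate
        se = np.sqrt(0.2 * 0.8 / len(ex))
        assert abs(frac - 0.2) < 5 * se
        assert ((lengths <= 30) == ex.microexon).all()

    def test_planted_motif_rate_follows_enrichment(self, small_run):
        _, _, _, truth, _ = small_run
        ex = truth.exons
        enhanced = ex[ex.label == "enhanced"]["planted_motifs"]
        unreg = ex[ex.label == "unregulated"]["planted_motifs"]
        assert enhanced.mean() > 0.5
        assert unreg.sum() == 0  # no targeted planting for unregulated exons

    def test_null_enrichment_plants_nothing_extra(self):
        cfg = SimulationConfig(n_genes=40, n_tissues=4, seed=7,
                               motif_enrichment_rate=1.0)
        _, _, truth = make_annotation(cfg)
        assert truth.exons["planted_motifs"].sum() == 0

    def test_genes_have_valid_models_and_events(self, small_run):
        _, ann, genome, truth, _ = small_run
        ann.validate()
        for t in ann.transcripts.values():
            assert t.end <= len(genome[t.chrom])
        events = enumerate_events(ann)
        by_type = {e.event_type for e in events}
        assert {"SE", "A5", "A3"} <= by_type | {"A5", "A3"}
        # every archetype present at this size produces its event
        archetypes = set(truth.genes["archetype"])
        expected = {"se": "SE", "ri": "RI", "mx": "MX", "af": "AF", "al": "AL"}
        for arch, etype in expected.items():
            if arch in archetypes:
                assert etype in {e.event_type for e in events}


class TestMakeExpression:
    def test_tra_gene_single_tissue_tau_one(self, small_run):
        cfg, ann, _, truth, expr = small_run
        by_tissue = expr.gene_tpm.by_tissue(cfg.tissue_names)
        tra = truth.genes[truth.genes.category != "non-TRA"].index
        taus = [compute_tau(by_tissue.loc[g].to_numpy()) for g in tra]
        assert np.nanmin(taus) > 0.95

    def test_housekeeping_tau_low(self, small_run):
        cfg, _, _, truth, expr = small_run
        by_tissue = expr.gene_tpm.by_tissue(cfg.tissue_names)
        hk = truth.genes[truth.genes.category == "non-TRA"].index
        taus = [compute_tau(by_tissue.loc[g].to_numpy()) for g in hk]
        assert np.nanmedian(taus) < 0.5

    def test_tec_isoform_subset_contract(self, small_run):
        cfg, ann, _, truth, expr = small_run
        tpm = expr.transcript_tpm.values["mTEC_mature_1"]
        for gene, row in truth.genes[truth.genes.category != "non-TRA"].iterrows():
            tids = ann.genes[gene]
            expected = max(1, round(cfg.tec_isoform_fraction * len(tids)))
            nonzero = int((tpm[tids] > 0).sum())
            assert nonzero == expected
            assert set(row.tec_isoforms.split(";")) == set(
                t for t in tids if tpm[t] > 0
            )

    def test_aire_ko_reduces_regulated_transcripts(self, small_run):
        cfg, ann, _, truth, expr = small_run
        tpm = expr.transcript_tpm.values
        aire_genes = truth.genes[truth.genes.category == "Aire-TRA"].index
        reg = truth.transcripts[
            truth.transcripts.gene_id.isin(aire_genes)
            & truth.transcripts.aire_regulated
        ].index
        expressed = [t for t in reg if tpm.loc[t, "mTEC_mature_1"] > 0]
        ratio = (
            tpm.loc[expressed, "mTEC_mature_1"].sum()
            / tpm.loc[expressed, "mTEC_aireko_1"].sum()
        )
        assert ratio > 2.0  # planted fold is >= 2 after TPM renormalization

    def test_junction_counts_are_valid(self, small_run):
        _, ann, _, _, expr = small_run
        jc = expr.junctions
        assert (jc.counts.to_numpy() >= 0).all()
        genes = set(jc.counts.index.get_level_values("gene_id"))
        assert genes <= set(ann.genes)


class TestMakeEventCounts:
    def test_null_events_centered_at_zero(self):
        cfg = SimulationConfig(n_genes=60, n_tissues=4, seed=8,
                               planted_delta_psi=0.0)
        ann, _, truth = make_annotation(cfg)
        table = make_event_counts(cfg, enumerate_events(ann), truth)
        inc = table.inc
        tot = table.inc + table.skip
        psi_ctrl = inc[["ctrl_1", "ctrl_2"]].sum(1) / tot[["ctrl_1", "ctrl_2"]].sum(1)
        psi_ko = inc[["ko_1", "ko_2"]].sum(1) / tot[["ko_1", "ko_2"]].sum(1)
        assert abs((psi_ctrl - psi_ko).mean()) < 0.02

    def test_counts_near_binomial_expectation(self):
        cfg = SimulationConfig(n_genes=40, n_tissues=4, seed=9)
        ann, _, truth = make_annotation(cfg)
        table = make_event_counts(cfg, enumerate_events(ann), truth)
        tot = (table.inc + table.skip)["ctrl_1"]
        assert abs(tot.mean() - cfg.event_coverage) < 5
        # recompute PSI from the planted probabilities for null SE events
        null = truth.events[~truth.events.regulated].index
        inc_frac = (table.inc.loc[null].sum(1) / (table.inc + table.skip).loc[null].sum(1))
        assert inc_frac.between(0.0, 1.0).all()

    def test_same_seed_identical_tables(self):
        cfg = SimulationConfig(n_genes=30, n_tissues=4, seed=10)
        ann, _, truth = make_annotation(cfg)
        evs = enumerate_events(ann)
        t1 = make_event_counts(cfg, evs, truth)
        t2 = make_event_counts(cfg, evs, truth)
        pd.testing.assert_frame_equal(t1.inc, t2.inc)
        pd.testing.assert_frame_equal(t1.skip, t2.skip)


class TestMakeReplicatePools:
    def test_dropout_disabled_replicates_identical(self, small_run):
        cfg, _, _, _, expr = small_run
        from dataclasses import replace

        nodrop = replace(cfg, detect_dropout=False)
        pools = make_replicate_pools(nodrop, expr.transcript_tpm)
        for r1, r2 in pools.values():
            assert r1 == r2

    def test_hard_floor_removes_low_tpm(self, small_run):
        cfg, _, _, _, expr = small_run
        from dataclasses import replace

        floored = replace(cfg, detect_floor_tpm=5.0)
        pools = make_replicate_pools(floored, expr.transcript_tpm)
        tpm = expr.transcript_tpm.values
        for sample, (r1, r2) in pools.items():
            low = set(tpm.index[tpm[sample] < 5.0])
            assert not (low & (r1 | r2))

    def test_high_tpm_detected_in_both(self, small_run):
        cfg, _, _, _, expr = small_run
        pools = make_replicate_pools(cfg, expr.transcript_tpm)
        tpm = expr.transcript_tpm.values
        hits, n = 0, 0
        for sample, (r1, r2) in pools.items():
            high = tpm.index[tpm[sample] >= 100.0]
            n += len(high)
            hits += sum(1 for t in high if t in r1 and t in r2)
        assert n > 50 and hits / n > 0.97
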