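"""Event enumeration, PSI computation and differential splicing."""

import math

import numpy as np
import pandas as pd
import pytest

from tecsplice.events import (
    EventCountTable,
    differential_events,
    enumerate_events,
    exon_inclusion_patterns,
    microexon_summary,
    psi_from_counts,
    psi_from_tpm,
    psi_matrix_from_tpm,
)

from conftest import annotation_of, make_tx


def events_of_type(events, etype):
    return [e for e in events if e.event_type == etype]


class TestEnumerateEvents:
    def test_single_transcript_gene_no_events(self):
        ann = annotation_of(make_tx("t1", [(0, 100), (200, 300)]))
        assert enumerate_events(ann) == []

    def test_cassette_exon_yields_one_se(self, toy_se_annotation):
        events = enumerate_events(toy_se_annotation)
        assert len(events) == 1
        ev = events[0]
        assert ev.event_type == "SE"
        assert ev.coords == (100, 200, 300, 400)
        assert ev.cassette_length == 100
        assert ev.inclusion == frozenset({"t1"})
        assert ev.exclusion == frozenset({"t2"})

    def test_alternative_donor_is_a5_on_plus_strand(self):
        t1 = make_tx("t1", [(0, 200), (500, 600)])
        t2 = make_tx("t2", [(0, 250), (500, 600)])
        events = enumerate_events(annotation_of(t1, t2))
        assert [e.event_type for e in events] == ["A5"]
        assert events[0].inclusion == frozenset({"t2"})  # longer exonic form

    def test_alternative_donor_is_a3_on_minus_strand(self):
        t1 = make_tx("t1", [(0, 200), (500, 600)], strand="-")
        t2 = make_tx("t2", [(0, 250), (500, 600)], strand="-")
        events = enumerate_events(annotation_of(t1, t2))
        assert [e.event_type for e in events] == ["A3"]

    def test_retained_intron(self):
        t1 = make_tx("t1", [(0, 100), (200, 300)])
        t2 = make_tx("t2", [(0, 300)])
        events = enumerate_events(annotation_of(t1, t2))
        assert [e.event_type for e in events] == ["RI"]
        assert events[0].inclusion == frozenset({"t2"})  # retaining form

    def test_mutually_exclusive_exons(self):
        t1 = make_tx("t1", [(0, 100), (200, 250), (400, 500)])
        t2 = make_tx("t2", [(0, 100), (300, 350), (400, 500)])
        events = enumerate_events(annotation_of(t1, t2))
        assert [e.event_type for e in events] == ["MX"]

    def test_alternative_first_and_last_exons(self):
        af1 = make_tx("t1", [(0, 100), (900, 1000), (1500, 1600)])
        af2 = make_tx("t2", [(300, 400), (900, 1000), (1500, 1600)])
        events = enumerate_events(annotation_of(af1, af2))
        assert [e.event_type for e in events] == ["AF"]
        al1 = make_tx("t1", [(0, 100), (500, 600)])
        al2 = make_tx("t2", [(0, 100), (800, 900)])
        events = enumerate_events(annotation_of(al1, al2))
        assert [e.event_type for e in events] == ["AL"]
        # sense flips terminal-event naming on the minus strand
        al1m = make_tx("t1", [(0, 100), (500, 600)], strand="-")
        al2m = make_tx("t2", [(0, 100), (800, 900)], strand="-")
        events = enumerate_events(annotation_of(al1m, al2m))
        assert [e.event_type for e in events] == ["AF"]

    def test_matches_hand_enumeration_on_three_isoform_gene(self):
        # full isoform plus two skip variants -> exactly 2 SE events
        full = make_tx("t1", [(0, 100), (200, 300), (400, 500), (600, 700)])
        s1 = make_tx("t2", [(0, 100), (400, 500), (600, 700)])
        s2 = make_tx("t3", [(0, 100), (200, 300), (600, 700)])
        events = enumerate_events(annotation_of(full, s1, s2))
        se = events_of_type(events, "SE")
        assert len(se) == 2
        coords = {e.coords for e in se}
        assert coords == {(100, 200, 300, 400), (300, 400, 500, 600)}
        for e in se:
            assert not (e.inclusion & e.exclusion)

    def test_event_ids_deterministic(self, toy_se_annotation):
        a = [e.event_id for e in enumerate_events(toy_se_annotation)]
        b = [e.event_id for e in enumerate_events(toy_se_annotation)]
        assert a == b


class TestPsi:
    def test_transcript_ratio_psi(self, toy_se_annotation):
        ev = enumerate_events(toy_se_annotation)[0]
        psi, total = psi_from_tpm(ev, {"t1": 6.0, "t2": 2.0})
        assert psi == pytest.approx(0.75) and total == 8.0

    def test_low_support_gated_to_missing(self, toy_se_annotation):
        ev = enumerate_events(toy_se_annotation)[0]
        psi, _ = psi_from_tpm(ev, {"t1": 0.4, "t2": 0.1}, min_total=1.0)
        assert math.isnan(psi)

    def test_all_mass_on_exclusion(self, toy_se_annotation):
        ev = enumerate_events(toy_se_annotation)[0]
        psi, _ = psi_from_tpm(ev, {"t1": 0.0, "t2": 5.0})
        assert psi == 0.0

    def test_count_psi_closed_forms(self):
        assert psi_from_counts(30, 10, 1.0, 1.0) == pytest.approx(0.75)
        assert psi_from_counts(10, 10, 2.0, 1.0) == pytest.approx(1 / 3)
        assert psi_from_counts(0, 40, 2.0, 1.0) == 0.0
        assert math.isnan(psi_from_counts(3, 2, 1.0, 1.0, min_reads=10))
        with pytest.raises(ValueError):
            psi_from_counts(-1, 5, 1.0, 1.0)

    def test_matrix_matches_scalar_route(self, toy_se_annotation):
        ev = enumerate_events(toy_se_annotation)[0]
        tpm = pd.DataFrame({"s1": [6.0, 2.0], "s2": [1.0, 3.0]}, index=["t1", "t2"])
        mat = psi_matrix_from_tpm([ev], tpm)
        assert mat.loc[ev.event_id, "s1"] == pytest.approx(0.75)
        assert mat.loc[ev.event_id, "s2"] == pytest.approx(0.25)


def _event_table(inc, skip, conditions, inc_len=2.0, skip_len=1.0):
    n_rows = len(next(iter(inc.values())))
    idx = pd.Index([f"e{i}" for i in range(n_rows)], name="event_id")
    return EventCountTable(
        inc=pd.DataFrame(inc, index=idx),
        skip=pd.DataFrame(skip, index=idx),
        inc_len=pd.Series(inc_len, index=idx),
        skip_len=pd.Series(skip_len, index=idx),
        conditions=conditions,
    )


class TestDifferentialEvents:
    conditions = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}

    def test_identical_conditions_null(self):
        inc = {s: [50] * 5 for s in self.conditions}
        skip = {s: [50] * 5 for s in self.conditions}
        res = differential_events(_event_table(inc, skip, self.conditions), "A", "B")
        assert np.allclose(res["delta_psi"], 0.0)
        assert not res["significant"].any()

    def test_planted_shift_detected_with_length_normalization(self):
        rng = np.random.default_rng(0)
        n = 120
        psi_a, psi_b = 0.7, 0.3
        inc, skip = {}, {}
        for s, cond in self.conditions.items():
            psi = psi_a if cond == "A" else psi_b
            p_inc = psi * 2 / (psi * 2 + (1 - psi))
            draws = rng.binomial(100, p_inc, size=n)
            inc[s] = draws
            skip[s] = 100 - draws
        res = differential_events(_event_table(inc, skip, self.conditions), "A", "B")
        assert res["significant"].mean() > 0.95
        assert res["delta_psi"].mean() == pytest.approx(0.4, abs=0.05)

    def test_single_condition_rejected(self):
        inc = {s: [10] for s in self.conditions}
        with pytest.raises(ValueError):
            differential_events(
                _event_table(inc, inc, self.conditions), "A", "A"
            )

    def test_one_replicate_rejected(self):
        conditions = {"a1": "A", "b1": "B", "b2": "B"}
        inc = {s: [10] for s in conditions}
        with pytest.raises(ValueError, match="replicates"):
            differential_events(_event_table(inc, inc, conditions), "A", "B")

    def test_low_support_events_not_tested(self):
        inc = {s: [1] for s in self.conditions}
        skip = {s: [1] for s in self.conditions}
        res = differential_events(
            _event_table(inc, skip, self.conditions), "A", "B", min_reads=10
        )
        assert res["p"].isna().all()
        assert not res["significant"].any()


class TestExonPatternsAndMicroexons:
    def test_inclusion_pattern_gates(self):
        psi = pd.DataFrame(
            {
                "mtec1": [0.05, 0.05, 0.05],
                "mtec2": [0.08, 0.25, 0.05],
                "brain": [0.90, 0.90, 0.30],
            },
            index=["keep", "max_gate", "never_high"],
        )
        lengths = pd.Series([120, 120, 120], index=psi.index)
        kept = exon_inclusion_patterns(
            psi, ["mtec1", "mtec2"], ["brain"], lengths
        )
        assert list(kept.index) == ["keep"]

    def test_short_exons_excluded_by_length_floor(self):
        psi = pd.DataFrame({"mtec1": [0.0], "mtec2": [0.0], "brain": [0.9]},
                           index=["short"])
        lengths = pd.Series([40], index=psi.index)
        kept = exon_inclusion_patterns(psi, ["mtec1", "mtec2"], ["brain"], lengths)
        assert kept.empty

    def test_microexon_boundary_inclusive(self, toy_se_annotation):
        from dataclasses import replace

        ev = enumerate_events(toy_se_annotation)[0]
        e30 = replace(ev, cassette_length=30)
        e31 = replace(ev, event_id="SE:other", cassette_length=31)
        psi = pd.DataFrame(
            {"s": [0.5, 0.5]}, index=[e30.event_id, e31.event_id]
        )
        summary, sub = microexon_summary([e30, e31], psi)
        assert list(sub.index) == [e30.event_id]
        assert summary.loc["s", "n_microexons"] == 1
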