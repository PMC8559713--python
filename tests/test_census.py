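"""Detection census: fractions, entropy, isoform fractions, ANCOVA."""

import math

import numpy as np
import pandas as pd
import pytest

from tecsplice.census import (
    detect,
    detection_fraction_curve,
    gene_transcript_ancova,
    isoform_fraction,
    multi_isoform_as_fraction,
    peripheral_representation,
    splice_entropy,
    uniquely_detected,
)

from conftest import annotation_of, expr_matrix, make_tx


class TestDetect:
    def test_strict_inequality_at_zero(self):
        em = expr_matrix({"s": [0.0, 0.01]})
        det = detect(em, 0.0)
        assert det["s"].tolist() == [False, True]

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            detect(expr_matrix({"s": [1.0]}), -0.1)


class TestDetectionFractionCurve:
    def test_fraction_arithmetic(self):
        vals = {"s": [1.0] * 601 + [0.0] * 399}
        em = expr_matrix(vals)
        em.values.index = [f"t{i}" for i in range(1000)]
        curve = detection_fraction_curve(em, list(em.values.index), (0.0,))
        assert curve.loc[0.0, "s"] == pytest.approx(0.601)

    def test_all_detected_fraction_one(self):
        em = expr_matrix({"s": [2.0, 3.0]})
        curve = detection_fraction_curve(em, list(em.values.index), (0.0,))
        assert curve.loc[0.0, "s"] == 1.0

    def test_curve_non_increasing_in_threshold(self):
        rng = np.random.default_rng(0)
        em = expr_matrix({"a": rng.exponential(1, 200), "b": rng.exponential(2, 200)})
        curve = detection_fraction_curve(
            em, list(em.values.index), (0.0, 0.1, 0.5, 1.0, 2.0, 5.0)
        )
        assert (curve.diff().dropna() <= 1e-12).all().all()

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            detection_fraction_curve(expr_matrix({"s": [1.0]}), [])


class TestSpliceEntropy:
    def test_single_isoform_zero(self):
        assert splice_entropy([5.0]) == 0.0
        assert splice_entropy([5.0, 0.0, 0.0]) == 0.0

    def test_equal_isoforms_log2k(self):
        assert splice_entropy([3.0] * 4) == pytest.approx(2.0)

    def test_worked_example(self):
        assert splice_entropy([0.5, 0.25, 0.25]) == pytest.approx(1.5)

    def test_zero_total_missing(self):
        assert math.isnan(splice_entropy([0.0, 0.0]))

    def test_bounded_by_log2_k(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            k = rng.integers(2, 9)
            x = rng.exponential(1.0, size=k)
            h = splice_entropy(x)
            assert -1e-12 <= h <= math.log2(k) + 1e-12


class TestIsoformFraction:
    def test_fraction_and_single_isoform_exclusion(self):
        ts = [
            make_tx("a1", [(0, 100)], gene="gA"),
            make_tx("a2", [(0, 100), (200, 300)], gene="gA"),
            make_tx("a3", [(0, 300)], gene="gA"),
            make_tx("a4", [(0, 50)], gene="gA"),
            make_tx("b1", [(0, 100)], gene="gB"),
        ]
        ann = annotation_of(*ts)
        em = expr_matrix({"s": [2.0, 1.0, 0.0, 0.0, 5.0]})
        em.values.index = ["a1", "a2", "a3", "a4", "b1"]
        long = isoform_fraction(em.values > 0, ann)
        assert set(long["gene_id"]) == {"gA"}  # single-isoform gB excluded
        assert long.loc[long.gene_id == "gA", "fraction"].iloc[0] == pytest.approx(0.5)

    def test_undetected_gene_fraction_zero(self):
        ann = annotation_of(
            make_tx("a1", [(0, 100)], gene="gA"),
            make_tx("a2", [(0, 200)], gene="gA"),
        )
        em = expr_matrix({"s": [0.0, 0.0]})
        em.values.index = ["a1", "a2"]
        long = isoform_fraction(em.values > 0, ann)
        assert long["fraction"].iloc[0] == 0.0


class TestGeneTranscriptAncova:
    @staticmethod
    def _summary(slope_a, slope_b, n=10, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        genes = rng.uniform(100, 200, size=2 * n)
        slopes = np.r_[np.full(n, slope_a), np.full(n, slope_b)]
        tx = slopes * genes + rng.normal(0, noise, size=2 * n)
        return pd.DataFrame(
            {
                "genes": genes,
                "transcripts": tx,
                "group": ["A"] * n + ["B"] * n,
            },
            index=[f"s{i}" for i in range(2 * n)],
        )

    def test_null_recovers_common_slope(self):
        res = gene_transcript_ancova(self._summary(3.0, 3.0, noise=1.0))
        assert res["slope"]["A"] == pytest.approx(3.0, abs=0.1)
        assert res["slope"]["B"] == pytest.approx(3.0, abs=0.1)
        assert res["interaction_p"] > 0.01

    def test_planted_slope_difference_detected(self):
        res = gene_transcript_ancova(self._summary(3.0, 2.0, noise=7.5))
        assert res["interaction_p"] < 0.01
        assert res["slope"]["A"] == pytest.approx(3.0, abs=0.1)
        assert res["slope"]["B"] == pytest.approx(2.0, abs=0.1)

    def test_too_few_samples_per_group_rejected(self):
        df = self._summary(3.0, 2.0, n=1)
        with pytest.raises(ValueError):
            gene_transcript_ancova(df)

    def test_exclusions_dropped_from_fit(self):
        df = self._summary(3.0, 3.0, noise=1.0)
        df.loc["s0", "transcripts"] = 1e6  # gross outlier
        res = gene_transcript_ancova(df, exclude=["s0"])
        assert res["slope"]["A"] == pytest.approx(3.0, abs=0.15)


class TestAsFractionAndRepresentation:
    def test_all_single_isoform_detected_fraction_zero(self):
        ts = [make_tx(f"t{i}{j}", [(0, 100 * (j + 1))], gene=f"g{i}")
              for i in range(8) for j in range(2)]
        ann = annotation_of(*ts)
        ids = [t.transcript_id for t in ts]
        det = pd.DataFrame({"s": [j == 0 for i in range(8) for j in range(2)]}, index=ids)
        gene_tpm = pd.DataFrame({"s": np.arange(1.0, 9.0)}, index=[f"g{i}" for i in range(8)])
        res = multi_isoform_as_fraction(
            det, gene_tpm, ann, {"set": {f"g{i}" for i in range(8)}}, {"set": "s"}
        )
        assert (res["fraction_spliced"].dropna() == 0.0).all()

    def test_three_of_four_spliced(self):
        ts = [make_tx(f"t{i}{j}", [(0, 100 * (j + 1))], gene=f"g{i}")
              for i in range(4) for j in range(2)]
        ann = annotation_of(*ts)
        ids = [t.transcript_id for t in ts]
        both = [True, True] * 3 + [True, False]
        det = pd.DataFrame({"s": both}, index=ids)
        gene_tpm = pd.DataFrame({"s": [5.0] * 4}, index=[f"g{i}" for i in range(4)])
        res = multi_isoform_as_fraction(
            det, gene_tpm, ann, {"set": {f"g{i}" for i in range(4)}}, {"set": "s"}
        )
        # ties all land in the lowest quartile
        q1 = res[res.quartile == 1].iloc[0]
        assert q1.n_genes == 4 and q1.fraction_spliced == pytest.approx(0.75)
        assert bool(q1.low_n)

    def test_peripheral_representation_fractions(self):
        det = pd.Series(
            [True] * 6 + [False] * 4, index=[f"t{i}" for i in range(10)]
        )
        res = peripheral_representation({"brain": {f"t{i}" for i in range(10)},
                                         "empty": set()}, det)
        brain = res[res.tissue == "brain"].iloc[0]
        assert brain.fraction == pytest.approx(0.6)
        assert math.isnan(res[res.tissue == "empty"].iloc[0].fraction)

    def test_uniquely_detected_counts(self):
        det = pd.DataFrame(
            {"tec": [True, True, False], "brain": [False, True, True]},
            index=["a", "b", "c"],
        )
        res = uniquely_detected(det, ["tec", "brain"])
        assert res["tec"] == 1 and res["brain"] == 1
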