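"""Count statistics: normalization, NB exact test, BH, Fisher, enrichments."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tecsplice.models import JunctionCounts
from tecsplice.stats import (
    bh_adjust,
    differential_junction_census,
    fisher_exact,
    nb_exact_test,
    normalize_libsize,
    set_enrichment,
)


def fisher_oracle_two_sided(a, b, c, d):
    """Exhaustive hypergeometric enumeration over tables with fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def pmf(k):
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = pmf(a)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-9))


class TestNormalizeLibsize:
    def test_equal_totals_unit_factors(self):
        counts = pd.DataFrame({"a": [5, 5], "b": [3, 7]})
        factors, norm = normalize_libsize(counts)
        assert np.allclose(factors, 1.0)
        assert np.allclose(norm.to_numpy(), counts.to_numpy())

    def test_geometric_mean_scaling(self):
        counts = pd.DataFrame({"a": [100], "b": [400]})
        factors, _ = normalize_libsize(counts)
        assert np.allclose(factors, [0.5, 2.0])

    def test_ordering_preserved_and_zero_column_rejected(self):
        counts = pd.DataFrame({"a": [10, 2, 7], "b": [1, 1, 1]})
        _, norm = normalize_libsize(counts)
        assert list(norm["a"].rank()) == list(counts["a"].rank())
        with pytest.raises(ValueError):
            normalize_libsize(pd.DataFrame({"a": [0, 0], "b": [1, 2]}))


class TestNBExactTest:
    def test_symmetric_null_p_one(self):
        r = nb_exact_test(7.0, 7.0, 0.0)
        assert r.p == 1.0 and r.direction == "equal"

    def test_binomial_limit_example(self):
        # dispersion 0, equal factors, a=10 b=0 -> 2 * (1/2)^10
        r = nb_exact_test(10.0, 0.0, 0.0)
        assert r.p == pytest.approx(2 * 0.5**10)

    def test_pseudocount_fold_change(self):
        r = nb_exact_test(20.0, 5.0, 0.0)
        assert 2.0**r.log2_fold_change == pytest.approx(20.5 / 5.5)
        assert r.direction == "a>b"

    @pytest.mark.parametrize("a,b", [(3, 9), (0, 5), (14, 14), (30, 2)])
    def test_dispersion_zero_matches_doubled_binomial_tails(self, a, b):
        from scipy import stats as sps

        r = nb_exact_test(float(a), float(b), 0.0)
        s = a + b
        expected = min(1.0, 2 * min(sps.binom.cdf(a, s, 0.5), sps.binom.sf(a - 1, s, 0.5)))
        assert r.p == pytest.approx(expected)

    def test_size_factors_shift_null(self):
        # b sequenced 3x deeper: a=10 vs b=30 is null-like
        r = nb_exact_test(10.0, 30.0, 0.0, [1.0], [3.0])
        assert r.p > 0.5
        assert r.mean_a == pytest.approx(r.mean_b)

    def test_dispersion_widens_the_null(self):
        p0 = nb_exact_test(40.0, 15.0, 0.0).p
        p1 = nb_exact_test(40.0, 15.0, 0.2).p
        assert p1 > p0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test(-1.0, 3.0, 0.0)


class TestBHAdjust:
    def test_worked_examples(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        assert np.allclose(bh_adjust([0.005, 0.1]), [0.01, 0.1])
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_bounded_and_order_invariant(self, ps):
        adj = bh_adjust(ps)
        assert (adj >= np.asarray(ps) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        # adjusted values preserve the ordering of the raw p-values
        order = np.argsort(ps, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()
        perm = np.random.RandomState(0).permutation(len(ps))
        assert np.allclose(bh_adjust(np.asarray(ps)[perm]), adj[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestFisherExact:
    def test_balanced_table(self):
        r = fisher_exact([[5, 5], [5, 5]])
        assert r.odds_ratio == pytest.approx(1.0)
        assert r.p == pytest.approx(1.0)

    def test_hand_enumerated_examples(self):
        assert fisher_exact([[2, 0], [0, 2]]).p == pytest.approx(1 / 3)
        assert fisher_exact([[3, 0], [0, 3]], "greater").p == pytest.approx(0.05)

    def test_or_conventions(self):
        assert fisher_exact([[4, 0], [2, 3]]).odds_ratio == float("inf")
        assert math.isnan(fisher_exact([[0, 0], [2, 3]]).odds_ratio)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1.5, 2], [3, 4]])

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 9, size=4)
            r = fisher_exact([[a, b], [c, d]])
            assert r.p == pytest.approx(
                fisher_oracle_two_sided(int(a), int(b), int(c), int(d)), abs=1e-9
            )


class TestSetEnrichment:
    def test_worked_overlap(self):
        universe = {f"g{i}" for i in range(100)}
        term = {f"g{i}" for i in range(20)}
        target = {f"g{i}" for i in range(8)} | {f"g{i}" for i in range(90, 92)}
        res = set_enrichment(target, {"term": term}, universe)
        row = res.iloc[0]
        # table [[8,2],[12,78]] -> OR = 624/24 = 26
        assert (row.overlap, row.target_only, row.set_only, row.neither) == (8, 2, 12, 78)
        assert row.odds_ratio == pytest.approx(26.0)

    def test_target_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside universe"):
            set_enrichment({"x"}, {"t": {"a"}}, {"a", "b"})

    def test_type_i_control_under_random_target(self):
        rng = np.random.default_rng(2)
        universe = {f"g{i}" for i in range(400)}
        sets = {
            f"s{j}": set(rng.choice(sorted(universe), size=40, replace=False))
            for j in range(40)
        }
        target = set(rng.choice(sorted(universe), size=50, replace=False))
        res = set_enrichment(target, sets, universe)
        assert (res["p"] < 0.05).mean() <= 0.1


class TestJunctionCensus:
    @staticmethod
    def _junctions(n_genes, rng, deficit_genes=(), deficit=0.2):
        rows, data_a, data_b = [], [], []
        for g in range(n_genes):
            gid = f"g{g:03d}"
            n_j = 100
            for j in range(n_j):
                rows.append((gid, 100 * j + 10, 100 * j + 60, "+"))
                lam_b = 8.0
                lam_a = lam_b * (deficit if gid in deficit_genes else 1.0)
                data_a.append(rng.poisson(lam_a))
                data_b.append(rng.poisson(lam_b))
        idx = pd.MultiIndex.from_tuples(
            rows, names=["gene_id", "donor", "acceptor", "strand"]
        )
        return JunctionCounts(pd.DataFrame({"tec": data_a, "liver": data_b}, index=idx))

    def test_equal_junction_counts_not_significant(self):
        rng = np.random.default_rng(3)
        classification = pd.DataFrame(
            {"itra_tissue": ["liver"] * 5 + [None] * 45},
            index=[f"g{g:03d}" for g in range(50)],
        )
        jc = self._junctions(50, rng)
        tab, enr = differential_junction_census(
            jc, "tec", "liver", classification, "liver"
        )
        assert tab["significant"].sum() == 0
        assert enr.p > 0.5

    def test_planted_deficit_enriches_itra(self):
        rng = np.random.default_rng(4)
        deficit = {f"g{g:03d}" for g in range(10)}
        classification = pd.DataFrame(
            {"itra_tissue": ["liver"] * 10 + [None] * 70},
            index=[f"g{g:03d}" for g in range(80)],
        )
        jc = self._junctions(80, rng, deficit_genes=deficit, deficit=0.02)
        tab, enr = differential_junction_census(
            jc, "tec", "liver", classification, "liver"
        )
        assert enr.odds_ratio > 1
        assert enr.p < 0.05

    def test_unknown_tissue_rejected(self):
        rng = np.random.default_rng(5)
        classification = pd.DataFrame(
            {"itra_tissue": [None] * 10}, index=[f"g{g:03d}" for g in range(10)]
        )
        jc = self._junctions(10, rng)
        with pytest.raises(ValueError, match="absent"):
            differential_junction_census(jc, "tec", "liver", classification, "liver")
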