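"""EASE-modified Fisher exact testing, BH correction and MSEA."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nmrfingerprint.data_model import PathwayLibrary
from nmrfingerprint.enrichment import (
    bh_adjust,
    ease_fisher,
    fisher_tail,
    msea,
    rank_pathway_table,
)
from nmrfingerprint.synthetic import generate_pathway_library


def hypergeom_tail_exact(k: int, n: int, K: int, N: int) -> Fraction:
    """Exhaustive rational-arithmetic hypergeometric upper tail P(X >= k)."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for x in range(max(k, 0), min(n, K) + 1):
        acc += Fraction(math.comb(K, x) * math.comb(N - K, n - x), total)
    return acc


class TestEaseFisher:
    def test_exact_value_against_rational_oracle(self):
        # N=20, K=5, n=5, k=4: Fisher tail 76/15504, EASE tail 1126/15504
        assert hypergeom_tail_exact(4, 5, 5, 20) == Fraction(76, 15504)
        assert hypergeom_tail_exact(3, 5, 5, 20) == Fraction(1126, 15504)
        assert fisher_tail(4, 5, 5, 20) == pytest.approx(76 / 15504, rel=1e-12)
        assert ease_fisher(4, 5, 5, 20) == pytest.approx(1126 / 15504, rel=1e-12)

    def test_small_overlap_saturates_at_one(self):
        assert ease_fisher(0, 5, 8, 30) == 1.0
        assert ease_fisher(1, 5, 8, 30) == 1.0

    def test_full_overlap_case(self):
        k = n = K = N = 6
        expected = float(hypergeom_tail_exact(k - 1, n, K, N))
        assert ease_fisher(k, n, K, N) == pytest.approx(expected, rel=1e-12)

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            ease_fisher(6, 5, 5, 20)
        with pytest.raises(ValueError):
            ease_fisher(2, 5, 25, 20)

    def test_never_below_fisher(self):
        # EASE is conservative relative to the unmodified Fisher tail
        count = 0
        for N in (10, 15, 20, 30):
            for K in range(1, N + 1, 3):
                for n in range(1, N + 1, 3):
                    for k in range(0, min(n, K) + 1):
                        assert ease_fisher(k, n, K, N) >= fisher_tail(k, n, K, N) - 1e-12
                        count += 1
        assert count >= 1000

    def test_nonincreasing_in_overlap(self):
        N, K, n = 40, 12, 10
        values = [ease_fisher(k, n, K, N) for k in range(0, min(n, K) + 1)]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))

    @given(st.integers(5, 40), st.data())
    @settings(max_examples=50, deadline=None)
    def test_matches_rational_oracle_everywhere(self, N, data):
        K = data.draw(st.integers(1, N))
        n = data.draw(st.integers(1, N))
        k = data.draw(st.integers(0, min(n, K)))
        expected = 1.0 if k <= 1 else float(hypergeom_tail_exact(k - 1, n, K, N))
        assert ease_fisher(k, n, K, N) == pytest.approx(expected, rel=1e-10)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_matches_suffix_min_definition(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(size=100)
        # oracle: literal min-over-suffix of the step-up definition
        order = np.argsort(p)
        m = len(p)
        scaled = p[order] * m / np.arange(1, m + 1)
        expected_sorted = [min(scaled[i:]) for i in range(m)]
        expected = np.empty(m)
        expected[order] = np.minimum(expected_sorted, 1.0)
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-14)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.uniform(size=50)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), q_sm, atol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=30)
        perm = rng.permutation(30)
        np.testing.assert_allclose(bh_adjust(p[perm]), bh_adjust(p)[perm], atol=1e-14)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


def _library(defs, universe=None, types=None):
    return PathwayLibrary(
        {pid: (pid, frozenset(members)) for pid, members in defs.items()},
        universe=universe,
        types=types,
    )


class TestMSEA:
    def test_full_membership_ranks_first(self):
        lib = _library(
            {"A": {"x1", "x2", "x3"}, "B": {"y1", "y2", "y3"}, "C": {"z1", "z2"}},
        )
        records = msea(["x1", "x2", "x3"], lib)
        assert records[0].pathway_id == "A"
        assert records[0].overlap == 3

    def test_planted_enriched_pathway_has_smallest_q(self):
        lib = generate_pathway_library(n_pathways=250, n_compounds=5432, seed=4)
        target = sorted(lib.members("path0001"))[:10]
        rng = np.random.default_rng(9)
        background = [f"C{int(i) + 1:05d}" for i in rng.integers(0, 5432, size=18)]
        query = list(dict.fromkeys(target[:8] + background))[:26]
        records = msea(query, lib)
        assert records[0].pathway_id == "path0001"
        assert records[0].q_bh == min(r.q_bh for r in records)

    def test_unknown_ids_dropped_with_count(self, caplog):
        lib = _library({"A": {"x", "y"}})
        records = msea(["x", "nope"], lib)
        assert records[0].list_n == 1

    def test_empty_effective_list(self):
        lib = _library({"A": {"x", "y"}})
        with pytest.raises(ValueError, match="universe"):
            msea(["zzz"], lib)

    def test_independent_of_pathway_iteration_order(self):
        defs = {"B": {"y", "x"}, "A": {"x", "z"}, "C": {"z", "y", "x"}}
        lib1 = _library(dict(defs))
        lib2 = _library(dict(reversed(list(defs.items()))))
        r1 = msea(["x", "y"], lib1)
        r2 = msea(["x", "y"], lib2)
        assert [r.pathway_id for r in r1] == [r.pathway_id for r in r2]
        assert [r.q_bh for r in r1] == [r.q_bh for r in r2]

    def test_min_overlap_filters(self):
        lib = _library({"A": {"x", "y"}, "B": {"z", "w"}})
        records = msea(["x", "y", "z"], lib, min_overlap=2)
        assert [r.pathway_id for r in records] == ["A"]

    def test_null_lists_are_conservative(self):
        # EASE under random queries: average p<=0.05 fraction stays below 0.05
        lib = generate_pathway_library(n_pathways=120, n_compounds=2000, seed=2)
        compounds = sorted(lib.universe)
        rng = np.random.default_rng(17)
        fracs = []
        for _ in range(30):
            query = [compounds[i] for i in rng.choice(len(compounds), 26, replace=False)]
            records = msea(query, lib)
            n_sig = sum(1 for r in records if r.p_ease <= 0.05)
            fracs.append(n_sig / lib.n_pathways)
        assert np.mean(fracs) <= 0.05


class TestRankPathwayTable:
    def test_grouped_by_type_then_overlap(self):
        lib = _library(
            {"A": {"x", "y", "z"}, "B": {"x"}, "C": {"x", "y"}},
            types={"A": "t1", "B": "t1", "C": "t2"},
        )
        records = msea(["x", "y", "z"], lib)
        df = rank_pathway_table(records, lib)
        assert df["pathway_id"].tolist() == ["A", "B", "C"]

    def test_global_fallback_without_types(self):
        lib = _library({"A": {"x", "y", "z"}, "B": {"x"}, "C": {"x", "y"}})
        records = msea(["x", "y", "z"], lib)
        df = rank_pathway_table(records, lib)
        assert df["pathway_id"].tolist() == ["A", "C", "B"]

    def test_deterministic_across_runs(self):
        lib = generate_pathway_library(n_pathways=40, n_compounds=400, n_types=3, seed=6)
        compounds = sorted(lib.universe)[:26]
        r1 = rank_pathway_table(msea(compounds, lib), lib)
        r2 = rank_pathway_table(msea(compounds, lib), lib)
        assert r1.equals(r2)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            rank_pathway_table([], None)
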