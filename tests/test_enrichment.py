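"""Hypergeometric machinery, 2x2 association, GO and mHG enrichment."""

import numpy as np
import pytest
from scipy import stats

from regulonscan.enrichment import (bonferroni, chi_square_2x2, go_enrichment,
                                    hypergeom_tail, overlap_matrix,
                                    ranked_enrichment_mhg)
from regulonscan.io_formats import GeneSet, ValidationError
from regulonscan.synthetic_data import simulate_geneset_overlap

from conftest import oracle_chi2, oracle_hypergeom_tail, oracle_mhg


class TestHypergeomTail:
    def test_all_five_of_five(self):
        assert hypergeom_tail(5, 5, 5, 10) == pytest.approx(1 / 252, rel=1e-12)

    def test_k_zero_is_one(self):
        assert hypergeom_tail(0, 40, 10, 100) == 1.0

    def test_matches_enumeration_small_universes(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            N = int(rng.integers(2, 13))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(max(0, n + K - N), min(K, n) + 1))
            assert hypergeom_tail(k, K, n, N) == pytest.approx(
                oracle_hypergeom_tail(k, K, n, N), abs=1e-12)

    def test_matches_scipy_and_complements_cdf(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            N = int(rng.integers(5, 500))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            k = int(rng.integers(max(0, n + K - N), min(K, n) + 1))
            p = hypergeom_tail(k, K, n, N)
            assert p == pytest.approx(stats.hypergeom.sf(k - 1, N, K, n), rel=1e-9, abs=1e-300)
            assert p + stats.hypergeom.cdf(k - 1, N, K, n) == pytest.approx(1.0, abs=1e-12)

    def test_extreme_tail_not_floored_to_zero(self):
        p = hypergeom_tail(259, 995, 259, 6000)
        assert 0.0 < p < 1e-100

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValidationError):
            hypergeom_tail(6, 5, 5, 10)


class TestChiSquare:
    def test_published_up_regulated_protein_table(self):
        # 11 of 28 up-regulated proteins are targets vs 265 of 1,203 measured
        res = chi_square_2x2([[11, 17], [254, 921]])
        assert 0.025 <= res.p_value <= 0.026

    def test_identical_proportions_stat_zero(self):
        res = chi_square_2x2([[10, 20], [30, 60]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_textbook_formula_on_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            t = rng.integers(1, 200, size=(2, 2))
            res = chi_square_2x2(t)
            assert res.statistic == pytest.approx(oracle_chi2(t), rel=1e-10)

    def test_fisher_agrees_in_ordering_for_large_cells(self):
        rng = np.random.default_rng(3)
        agree = 0
        total = 0
        for _ in range(200):
            t = rng.integers(10, 300, size=(2, 2))
            e = np.outer(t.sum(1), t.sum(0)) / t.sum()
            if e.min() < 10:
                continue
            res = chi_square_2x2(t)
            total += 1
            agree += (res.p_value < 0.05) == (res.fisher_p < 0.05)
        assert agree / total >= 0.95

    def test_zero_margin_recommends_fisher(self):
        with pytest.raises(ValidationError, match="Fisher"):
            chi_square_2x2([[0, 0], [5, 9]])


class TestBonferroni:
    def test_basic_and_edge_cases(self):
        assert bonferroni([0.01, 0.5], m=2) == [0.02, 1.0]
        assert bonferroni([0.0]) == [0.0]
        assert bonferroni([0.2]) == [0.2]  # single test unchanged


class TestGoEnrichment:
    def test_full_term_query_ranks_first(self, gene_universe):
        ids, universe = gene_universe
        terms = [GeneSet(f"GO:{i}", "", frozenset(ids[i * 20:(i + 1) * 20]))
                 for i in range(5)]
        results = go_enrichment(GeneSet("q", "", frozenset(ids[40:60])), terms, universe)
        assert results[0].query_name == "GO:2"
        assert results[0].p_raw < 1e-20
        assert all(r.p_raw > 0.5 for r in results[1:])

    def test_planted_enriched_term_recovered(self, gene_universe):
        ids, universe = gene_universe
        rng = np.random.default_rng(4)
        planted = set(rng.choice(ids, size=30, replace=False).tolist())
        terms = [GeneSet("planted", "", frozenset(planted))]
        terms += [GeneSet(f"rand{i}", "",
                          frozenset(rng.choice(ids, size=30, replace=False).tolist()))
                  for i in range(9)]
        query_members = set(rng.choice(sorted(planted), size=20, replace=False).tolist())
        query_members |= set(rng.choice(ids, size=10, replace=False).tolist())
        results = go_enrichment(GeneSet("q", "", frozenset(query_members)), terms, universe)
        assert results[0].query_name == "planted"

    def test_null_type_one_error_near_nominal(self, gene_universe):
        ids, universe = gene_universe
        rng = np.random.default_rng(5)
        term = GeneSet("t", "", frozenset(ids[:40]))
        rejections = 0
        n_seeds = 400
        for _ in range(n_seeds):
            q = GeneSet("q", "", frozenset(rng.choice(ids, size=30, replace=False).tolist()))
            r = go_enrichment(q, [term], universe)[0]
            rejections += r.p_raw < 0.05
        # hypergeometric p is discrete, hence conservative at the 5% level
        assert rejections / n_seeds <= 0.07

    def test_query_outside_universe_rejected(self, gene_universe):
        _, universe = gene_universe
        with pytest.raises(ValidationError):
            go_enrichment(GeneSet("q", "", frozenset(["zz"])), [], universe)


class TestRankedMhg:
    def test_three_top_genes_exact(self):
        ranked = [f"g{i}" for i in range(10)]
        term = GeneSet("T", "", frozenset(ranked[:3]))
        res = ranked_enrichment_mhg(ranked, term)
        assert res.mhg_stat == pytest.approx(1 / 120, rel=1e-9)
        assert res.p_exact == pytest.approx(1 / 120, rel=1e-9)
        assert (res.n_star, res.b_star) == (3, 3)
        assert res.enrichment_ratio == pytest.approx((3 / 3) / (3 / 10))

    def test_maximally_dispersed_term_not_enriched(self):
        ranked = [f"g{i}" for i in range(12)]
        term = GeneSet("T", "", frozenset(ranked[3::4]))  # spread through the list
        res = ranked_enrichment_mhg(ranked, term)
        assert res.p_exact > 0.5

    def test_exact_p_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(6)
        for N, B in [(8, 3), (10, 4), (9, 2)]:
            ranked = [f"g{i}" for i in range(N)]
            members = rng.choice(ranked, size=B, replace=False).tolist()
            term = GeneSet("T", "", frozenset(members))
            res = ranked_enrichment_mhg(ranked, term)

            def stat(indicator, N=N, B=B):
                b = np.cumsum(indicator)
                return min(stats.hypergeom.sf(b[n - 1] - 1, N, B, n)
                           for n in range(1, N))

            observed, p_enum, _ = oracle_mhg(
                np.array([g in term.members for g in ranked], dtype=np.int64), stat)
            assert res.mhg_stat == pytest.approx(observed, rel=1e-9)
            assert res.p_exact == pytest.approx(p_enum, rel=1e-9)

    def test_bounds_hold(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            N = int(rng.integers(5, 40))
            B = int(rng.integers(1, N))
            ranked = [f"g{i}" for i in range(N)]
            term = GeneSet("T", "", frozenset(
                rng.choice(ranked, size=B, replace=False).tolist()))
            res = ranked_enrichment_mhg(ranked, term)
            assert res.mhg_stat <= res.p_exact + 1e-12
            assert res.p_exact <= min(1.0, N * res.mhg_stat) + 1e-12

    def test_term_absent_from_list_rejected(self):
        with pytest.raises(ValidationError):
            ranked_enrichment_mhg(["a", "b"], GeneSet("T", "", frozenset(["z"])))


class TestOverlapMatrix:
    def test_generator_ground_truth_fraction(self):
        ref, queries, universe, truth = simulate_geneset_overlap(
            6000, 995, [1049], [384 / 1049], seed=0)
        assert truth.extras["overlap_counts"] == [384]
        res = overlap_matrix(ref, queries, universe)[0]
        assert res.overlap_count == 384
        assert res.fraction == pytest.approx(384 / 1049)
        assert res.p_bonferroni < 1e-10

    def test_disjoint_query_near_one(self):
        ref, queries, universe, _ = simulate_geneset_overlap(500, 100, [50], [0.0], seed=1)
        res = overlap_matrix(ref, queries, universe)[0]
        assert res.overlap_count == 0 and res.p_raw > 0.9

    def test_small_query_dropped(self):
        ref, queries, universe, _ = simulate_geneset_overlap(500, 100, [7, 50],
                                                             [0.5, 0.2], seed=2)
        res = overlap_matrix(ref, queries, universe, min_query_size=8)
        assert [r.query_name for r in res] == ["query2"]


class TestSimulateOverlapErrors:
    def test_infeasible_overlap_rejected(self):
        with pytest.raises(ValidationError):
            simulate_geneset_overlap(100, 90, [50], [0.0], seed=0)

    def test_query_equals_reference_min_p(self):
        ref, queries, universe, _ = simulate_geneset_overlap(200, 50, [50], [1.0], seed=3)
        res = overlap_matrix(ref, queries, universe)[0]
        assert res.overlap_count == 50
        assert res.p_raw == pytest.approx(
            hypergeom_tail(50, 50, 50, 200), rel=1e-12)
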