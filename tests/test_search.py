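import numpy as np
import pytest
from scipy import stats

from coexsearch import (ExpressionMatrix, QuerySignature, SeedGroup,
                        correlation_pvalue, ensemble_search,
                        pearson_correlation, search_by_signature)
from coexsearch.search import DegenerateProfileError
from .conftest import random_matrix


def _signature(values, seeds=("g0000",)):
    return QuerySignature(np.asarray(values, float), "mean",
                          SeedGroup("s", tuple(seeds)))


class TestPearsonCorrelation:
    def test_perfect_correlation_and_anticorrelation(self):
        r, n = pearson_correlation(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert (r, n) == (1.0, 3)
        r, _ = pearson_correlation(np.array([1.0, 2, 3]), np.array([3.0, 2, 1]))
        assert r == -1.0

    def test_matches_textbook_formula_and_scipy(self):
        """Cross-check against the covariance/(sd*sd) formula evaluated
        by hand and against scipy's independent implementation."""
        rng = np.random.default_rng(10)
        for _ in range(25):
            x, y = rng.normal(size=10), rng.normal(size=10)
            r, n = pearson_correlation(x, y)
            cov = np.mean((x - x.mean()) * (y - y.mean()))
            oracle = cov / (np.std(x) * np.std(y))
            assert r == pytest.approx(oracle, abs=1e-12)
            assert r == pytest.approx(stats.pearsonr(x, y).statistic, abs=1e-12)
            assert n == 10

    def test_pairwise_complete_positions_only(self):
        x = np.array([1.0, np.nan, 2, 3, 4])
        y = np.array([2.0, 5, np.nan, 4, 6])
        r, n = pearson_correlation(x, y)
        r_ref, _ = pearson_correlation(np.array([1.0, 3, 4]), np.array([2.0, 4, 6]))
        assert n == 3 and r == pytest.approx(r_ref)

    def test_degenerate_inputs_are_signaled(self):
        with pytest.raises(DegenerateProfileError):  # < 3 complete pairs
            pearson_correlation(np.array([1.0, np.nan, 2, np.nan]),
                                np.array([1.0, 2, np.nan, 3]))
        with pytest.raises(DegenerateProfileError):  # constant subvector
            pearson_correlation(np.array([5.0, 5, 5]), np.array([1.0, 2, 3]))


class TestCorrelationPvalue:
    def test_null_center_and_degenerate_bounds(self):
        assert correlation_pvalue(0.0, 10) == 1.0
        assert correlation_pvalue(1.0, 5) == 0.0
        assert correlation_pvalue(-1.0, 5) == 0.0

    def test_matches_t_distribution_tail(self):
        r, n = 0.8, 10
        t = r * np.sqrt((n - 2) / (1 - r * r))
        expected = 2 * stats.t.sf(t, n - 2)
        assert correlation_pvalue(r, n) == pytest.approx(expected, rel=1e-12)

    def test_calibrated_against_simulation_null(self):
        """Fraction of independent Gaussian pairs with |r| >= 0.8 at
        n = 10 must match the t-tail within 3 Monte-Carlo SEs: the
        t-test is exact under this null."""
        rng = np.random.default_rng(123)
        draws = 100_000
        x = rng.normal(size=(draws, 10))
        y = rng.normal(size=(draws, 10))
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        r = np.sum(xc * yc, axis=1) / np.sqrt(
            np.sum(xc**2, axis=1) * np.sum(yc**2, axis=1))
        p_expected = correlation_pvalue(0.8, 10)
        frac = np.mean(np.abs(r) >= 0.8)
        se = np.sqrt(p_expected * (1 - p_expected) / draws)
        assert abs(frac - p_expected) <= 3 * se

    def test_strictly_decreasing_in_abs_r(self):
        rs = np.linspace(0, 0.999, 50)
        ps = [correlation_pvalue(r, 12) for r in rs]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert correlation_pvalue(-0.5, 12) == correlation_pvalue(0.5, 12)


class TestSearchBySignature:
    def test_exact_copy_ranks_first(self):
        rng = np.random.default_rng(1)
        m = random_matrix(rng, 30, 10)
        sig = _signature(m.row("g0007").copy(), seeds=("g0007",))
        hits = search_by_signature(m, sig, 0.5)
        assert hits[0].gene_id == "g0007"
        assert hits[0].correlation == 1.0 and hits[0].p_value == 0.0
        assert hits[0].seed_flag

    def test_vacuous_threshold_returns_every_gene(self):
        rng = np.random.default_rng(2)
        m = random_matrix(rng, 25, 8)
        sig = _signature(rng.normal(size=8))
        hits = search_by_signature(m, sig, 1.0, keep_anticorrelated=True)
        assert {h.gene_id for h in hits} == set(m.gene_ids)

    def test_default_drops_anticorrelated_genes(self):
        m = ExpressionMatrix(["up", "down"], ["a", "b", "c", "d"],
                             np.array([[1.0, 2, 3, 4], [4.0, 3, 2, 1]]))
        sig = _signature([1.0, 2, 3, 4], seeds=("up",))
        assert [h.gene_id for h in search_by_signature(m, sig, 1.0)] == ["up"]
        both = search_by_signature(m, sig, 1.0, keep_anticorrelated=True)
        assert {h.gene_id for h in both} == {"up", "down"}

    def test_sorted_by_p_then_abs_r_then_input_order(self):
        rng = np.random.default_rng(3)
        m = random_matrix(rng, 40, 12)
        sig = _signature(rng.normal(size=12))
        hits = search_by_signature(m, sig, 1.0, keep_anticorrelated=True)
        keys = [(h.p_value, -abs(h.correlation)) for h in hits]
        assert keys == sorted(keys)

    def test_threshold_is_strict_and_monotone(self):
        rng = np.random.default_rng(4)
        m = random_matrix(rng, 60, 10)
        sig = _signature(rng.normal(size=10))
        all_hits = search_by_signature(m, sig, 1.0, keep_anticorrelated=True)
        cut = all_hits[len(all_hits) // 2].p_value
        at_cut = search_by_signature(m, sig, cut, keep_anticorrelated=True)
        assert all(h.p_value < cut for h in at_cut)  # strict <
        for lo, hi in [(0.01, 0.1), (0.1, 0.5), (0.5, 1.0)]:
            small = {h.gene_id for h in
                     search_by_signature(m, sig, lo, keep_anticorrelated=True)}
            large = {h.gene_id for h in
                     search_by_signature(m, sig, hi, keep_anticorrelated=True)}
            assert small <= large

    def test_scale_independence(self):
        """Replacing a row by a*y + c (a > 0) must leave its
        correlation, p-value, and rank unchanged."""
        rng = np.random.default_rng(5)
        m = random_matrix(rng, 50, 12)
        sig = _signature(rng.normal(size=12))
        before = search_by_signature(m, sig, 1.0, keep_anticorrelated=True)
        values = m.values.copy()
        idx = m.gene_ids.index("g0021")
        values[idx] = 2.7 * values[idx] - 13.0
        m2 = ExpressionMatrix(list(m.gene_ids), list(m.sample_labels), values)
        after = search_by_signature(m2, sig, 1.0, keep_anticorrelated=True)
        b = next(h for h in before if h.gene_id == "g0021")
        a = next(h for h in after if h.gene_id == "g0021")
        assert a.correlation == pytest.approx(b.correlation, abs=1e-12)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)
        assert [h.gene_id for h in after] == [h.gene_id for h in before]

    def test_false_positive_count_bounded_under_null(self):
        """10 planted copies of the signature always pass p < 0.01; the
        40 null genes yield about 40*alpha false positives, at most 3
        in any of 20 seeded replicates (binomial tail)."""
        worst = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            sig_vec = rng.normal(size=12)
            planted = sig_vec + rng.normal(0, 0.25, size=(10, 12))
            noise = rng.normal(size=(40, 12))
            ids = [f"p{i}" for i in range(10)] + [f"n{i}" for i in range(40)]
            m = ExpressionMatrix(ids, [f"s{j}" for j in range(12)],
                                 np.vstack([planted, noise]))
            hits = search_by_signature(m, _signature(sig_vec, seeds=("p0",)), 0.01)
            got = {h.gene_id for h in hits}
            assert all(f"p{i}" in got for i in range(10))
            worst = max(worst, sum(1 for g in got if g.startswith("n")))
        assert worst <= 3

    def test_bh_option_only_removes_hits(self):
        rng = np.random.default_rng(6)
        m = random_matrix(rng, 80, 10)
        sig = _signature(rng.normal(size=10))
        raw = {h.gene_id for h in search_by_signature(m, sig, 0.2)}
        bh = {h.gene_id for h in search_by_signature(m, sig, 0.2, bh_fdr=0.05)}
        assert bh <= raw

    def test_degenerate_genes_skipped_not_fatal(self):
        m = ExpressionMatrix(
            ["ok", "flat", "sparse"], ["a", "b", "c", "d"],
            np.array([[1.0, 2, 3, 4], [5.0, 5, 5, 5], [1.0, np.nan, np.nan, 2]]))
        hits = search_by_signature(m, _signature([1.0, 2, 3, 4], seeds=("ok",)), 1.0)
        assert [h.gene_id for h in hits] == ["ok"]


class TestEnsembleSearch:
    def test_union_semantics_on_a_handcrafted_case(self):
        # two seed rows, each dragging along its own correlated partner
        base = np.array([0.0, 1, 2, 3, 4, 5])
        rows = np.vstack([
            base,                      # seedA
            base[::-1],                # seedB (anticorrelated with A)
            base * 2 + 1,              # follows A
            base[::-1] * 0.5 - 2,      # follows B
            np.array([3.0, -1, 4, -2, 5, -3]),  # unrelated zig-zag
        ])
        m = ExpressionMatrix(["seedA", "seedB", "followA", "followB", "zig"],
                             [f"s{j}" for j in range(6)], rows)
        res = ensemble_search(m, SeedGroup("s", ("seedA", "seedB")), 0.01)
        assert {r.gene_id for r in res.results} == {"seedA", "seedB",
                                                    "followA", "followB"}
        assert set(res.per_seed_hits["seedA"]) == {"seedA", "followA"}
        assert set(res.per_seed_hits["seedB"]) == {"seedB", "followB"}

    def test_single_seed_ensemble_equals_plain_search(self):
        rng = np.random.default_rng(8)
        m = random_matrix(rng, 40, 10)
        seeds = SeedGroup("s", ("g0003",))
        ens = ensemble_search(m, seeds, 0.3)
        sig = QuerySignature(m.row("g0003").copy(), "delegate", seeds)
        plain = search_by_signature(m, sig, 0.3)
        assert [r.gene_id for r in ens.results] == [r.gene_id for r in plain]
        assert [r.p_value for r in ens.results] == [r.p_value for r in plain]

    def test_constituents_are_subsets_of_the_union(self):
        for seed in range(20):
            rng = np.random.default_rng(2000 + seed)
            m = random_matrix(rng, 30, 8, missing_frac=0.05)
            seeds = SeedGroup("s", tuple(m.gene_ids[:3]))
            res = ensemble_search(m, seeds, 0.3)
            union = {r.gene_id for r in res.results}
            per_seed = [set(h) for h in res.per_seed_hits.values()]
            assert union == set().union(*per_seed)
            for hits in per_seed:
                assert hits <= union

    def test_duplicates_keep_best_p_value(self):
        rng = np.random.default_rng(9)
        m = random_matrix(rng, 30, 10)
        seeds = SeedGroup("s", tuple(m.gene_ids[:4]))
        res = ensemble_search(m, seeds, 0.5)
        ids = [r.gene_id for r in res.results]
        assert len(ids) == len(set(ids))  # redundancy removed
        for r in res.results:
            best = min(
                (pearson_and_p(m, s, r.gene_id) for s in seeds.gene_ids
                 if r.gene_id in res.per_seed_hits[s]),
            )
            assert r.p_value == pytest.approx(best, abs=1e-15)


def pearson_and_p(m, seed_gene, gene):
    r, n = pearson_correlation(m.row(gene), m.row(seed_gene))
    return correlation_pvalue(r, n)
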