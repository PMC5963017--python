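import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from revsig import GeneSet, GeneSetCollection, Signature
from revsig.enrich import enrichment_score, overrep_test, preranked_test, rank_signature


def es_oracle(scores: np.ndarray, member: np.ndarray, p: float) -> float:
    """Brute-force O(N) walk of the running sum.

    Each step's value is recomputed from the hit/miss counts so far (no
    floating-point accumulation); exact |max| = |min| ties resolve positive.
    """
    w = np.abs(scores) ** p
    total = w[member].sum()
    if total <= 0:
        w = np.ones_like(w)
        total = member.sum()
    pen = 1.0 / (len(scores) - member.sum())
    hit_w, n_miss, best = 0.0, 0, 0.0
    for i in range(len(scores)):
        if member[i]:
            hit_w += w[i]
        else:
            n_miss += 1
        run = hit_w / total - n_miss * pen
        if abs(run) > abs(best) + 1e-12:
            best = run
        elif abs(abs(run) - abs(best)) <= 1e-12 and run > best:
            best = run
    return best


def ranked_series(scores, genes=None):
    genes = genes or [f"g{i:03d}" for i in range(len(scores))]
    return rank_signature(Signature("x", pd.Series(scores, index=genes)))


class TestEnrichmentScore:
    def test_single_member_first_rank_unweighted_is_one(self):
        ranked = ranked_series(np.arange(10, 0, -1, dtype=float))
        es, le = enrichment_score(ranked, {ranked.index[0]}, weight_p=0.0)
        assert es == 1.0 and le == [ranked.index[0]]

    def test_single_member_last_rank_unweighted_is_minus_one(self):
        ranked = ranked_series(np.arange(10, 0, -1, dtype=float))
        es, le = enrichment_score(ranked, {ranked.index[-1]}, weight_p=0.0)
        assert np.isclose(es, -1.0) and le == [ranked.index[-1]]

    def test_five_gene_hand_walk(self):
        ranked = ranked_series([5.0, 4.0, 3.0, 2.0, 1.0], list("abcde"))
        es, _ = enrichment_score(ranked, {"a", "c"}, weight_p=1.0)
        # walk: +5/8, -1/3, +3/8, -1/3, -1/3 -> peak after 'c' = 5/8 - 1/3 + 3/8
        assert np.isclose(es, 5 / 8 - 1 / 3 + 3 / 8)

    def test_set_covering_all_or_none_rejected(self):
        ranked = ranked_series([3.0, 2.0, 1.0], list("abc"))
        with pytest.raises(ValueError, match="undefined"):
            enrichment_score(ranked, {"a", "b", "c"})
        with pytest.raises(ValueError, match="undefined"):
            enrichment_score(ranked, {"zzz"})

    @given(st.data())
    def test_matches_brute_force_oracle(self, data):
        n = data.draw(st.integers(5, 40))
        k = data.draw(st.integers(1, n - 1))
        seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=n), 3)
        ranked = ranked_series(scores)
        member_genes = set(rng.choice(ranked.index, size=k, replace=False))
        p = data.draw(st.sampled_from([0.0, 1.0]))
        es, _ = enrichment_score(ranked, member_genes, weight_p=p)
        member = np.array([g in member_genes for g in ranked.index])
        assert np.isclose(es, es_oracle(ranked.to_numpy(), member, p), atol=1e-12)

    def test_unweighted_es_invariant_to_monotone_rescaling(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=30)
        genes = [f"g{i:03d}" for i in range(30)]
        sel = set(rng.choice(genes, 8, replace=False))
        e1, _ = enrichment_score(ranked_series(scores, genes), sel, weight_p=0.0)
        e2, _ = enrichment_score(ranked_series(3 * scores + 7, genes), sel, weight_p=0.0)
        assert np.isclose(e1, e2)

    def test_reversing_ranking_negates_unweighted_es(self):
        # holds whenever the extremum is unique (exact |max|=|min| ties
        # resolve positive in both orientations); seed chosen tie-free
        rng = np.random.default_rng(5)
        scores = rng.normal(size=25)
        genes = [f"g{i:03d}" for i in range(25)]
        sel = set(rng.choice(genes, 6, replace=False))
        e1, _ = enrichment_score(ranked_series(scores, genes), sel, weight_p=0.0)
        e2, _ = enrichment_score(ranked_series(-scores, genes), sel, weight_p=0.0)
        assert np.isclose(e1, -e2)

    def test_es_bounded_by_one(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            scores = rng.normal(size=30)
            genes = [f"g{i:03d}" for i in range(30)]
            sel = set(rng.choice(genes, rng.integers(1, 29), replace=False))
            es, _ = enrichment_score(ranked_series(scores, genes), sel)
            assert -1.0 <= es <= 1.0


class TestPrerankedTest:
    def _ranked(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        return ranked_series(rng.normal(size=n)), rng

    def test_top_k_set_hits_p_floor(self):
        ranked, _ = self._ranked()
        top = GeneSetCollection([GeneSet("top", frozenset(ranked.index[:10]))])
        res = preranked_test(ranked, top, n_perm=200, seed=1).table
        assert res.loc["top", "es"] > 0
        assert res.loc["top", "perm_p"] <= 2.0 / 200

    def test_fixed_seed_reproducible(self):
        ranked, rng = self._ranked(seed=2)
        sets = GeneSetCollection([
            GeneSet("s1", frozenset(rng.choice(ranked.index, 15, replace=False))),
            GeneSet("s2", frozenset(rng.choice(ranked.index, 8, replace=False))),
        ])
        r1 = preranked_test(ranked, sets, n_perm=150, seed=9).table
        r2 = preranked_test(ranked, sets, n_perm=150, seed=9).table
        pd.testing.assert_frame_equal(r1, r2)

    def test_nes_sign_matches_es_sign(self):
        ranked, rng = self._ranked(seed=3)
        sets = GeneSetCollection([
            GeneSet(f"s{i}", frozenset(rng.choice(ranked.index, 10, replace=False)))
            for i in range(5)
        ])
        tab = preranked_test(ranked, sets, n_perm=150, seed=4).table
        assert (np.sign(tab["nes"]) == np.sign(tab["es"])).all()

    def test_low_n_perm_warns(self):
        ranked, _ = self._ranked(seed=5)
        sets = GeneSetCollection([GeneSet("s", frozenset(ranked.index[:5]))])
        with pytest.warns(UserWarning, match="coarse"):
            preranked_test(ranked, sets, n_perm=50, seed=6)

    def test_zero_overlap_set_reported_untestable(self):
        ranked, _ = self._ranked(seed=7)
        sets = GeneSetCollection([GeneSet("absent", frozenset({"nope"}))])
        tab = preranked_test(ranked, sets, n_perm=150, seed=8).table
        assert np.isnan(tab.loc["absent", "perm_p"])


class TestOverrepTest:
    def test_set_identical_to_degs_is_minimal_p(self):
        universe = {f"g{i}" for i in range(100)}
        deg = {f"g{i}" for i in range(10)}
        sets = GeneSetCollection([GeneSet("self", frozenset(deg))])
        tab = overrep_test(deg, universe, sets)
        import scipy.stats

        minimal = scipy.stats.hypergeom.sf(9, 100, 10, 10)
        assert np.isclose(tab.loc["self", "p"], minimal)

    def test_empty_overlap_gives_p_one(self):
        universe = {f"g{i}" for i in range(50)}
        deg = {f"g{i}" for i in range(5)}
        sets = GeneSetCollection([GeneSet("other", frozenset({f"g{i}" for i in range(40, 50)}))])
        tab = overrep_test(deg, universe, sets)
        assert tab.loc["other", "p"] == 1.0

    def test_deg_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            overrep_test({"x"}, {"a", "b"}, GeneSetCollection([GeneSet("s", frozenset({"a"}))]))

    def test_random_draw_not_significant(self):
        rng = np.random.default_rng(11)
        universe = {f"g{i}" for i in range(500)}
        deg = set(rng.choice(sorted(universe), 50, replace=False))
        sets = GeneSetCollection([
            GeneSet(f"s{i}", frozenset(rng.choice(sorted(universe), 40, replace=False)))
            for i in range(10)
        ])
        tab = overrep_test(deg, universe, sets)
        assert (tab["adj_p"] > 0.05).all()
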