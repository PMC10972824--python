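import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from depresist import genesets


def brute_force_hypergeom_tail(n_uni, n_set, n_query, k):
    """P(overlap >= k) by enumeration of all C(N, n) draws."""
    universe = range(n_uni)
    members = set(range(n_set))
    hits = sum(1 for draw in itertools.combinations(universe, n_query)
               if len(members & set(draw)) >= k)
    return hits / comb(n_uni, n_query)


class TestHypergeometric:
    def test_known_exact_value(self):
        # N=10, K=4, n=3, k=3: 4 favourable draws of 120
        universe = [f"g{i}" for i in range(10)]
        gene_set = universe[:4]
        query = universe[:3]
        p, k = genesets.hypergeometric_enrichment(query, gene_set, universe)
        assert k == 3
        assert p == pytest.approx(4 / 120, abs=1e-12)

    def test_zero_overlap_tail_is_one(self):
        universe = [f"g{i}" for i in range(10)]
        p, k = genesets.hypergeometric_enrichment(universe[5:8], universe[:3], universe)
        assert k == 0 and p == pytest.approx(1.0)

    def test_combinatorial_identity_n20(self):
        universe = [f"g{i}" for i in range(20)]
        gene_set = universe[:5]
        query = universe[3:8]  # overlap = 2
        p, k = genesets.hypergeometric_enrichment(query, gene_set, universe)
        assert k == 2
        expected = 1 - (comb(5, 0) * comb(15, 5) + comb(5, 1) * comb(15, 4)) / comb(20, 5)
        assert p == pytest.approx(expected, abs=1e-12)

    def test_matches_enumeration_oracle_small_universe(self):
        n_uni = 8
        universe = [f"g{i}" for i in range(n_uni)]
        for n_set in range(1, n_uni + 1):
            for n_query in range(1, n_uni + 1):
                gene_set = universe[:n_set]
                query = universe[-n_query:]
                k = len(set(gene_set) & set(query))
                p, _ = genesets.hypergeometric_enrichment(query, gene_set, universe)
                assert p == pytest.approx(
                    brute_force_hypergeom_tail(n_uni, n_set, n_query, k), abs=1e-12)

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            genesets.hypergeometric_enrichment(["a"], ["a"], [])

    def test_query_outside_universe_errors(self):
        with pytest.raises(ValueError):
            genesets.hypergeometric_enrichment(["x"], ["a"], ["a", "b"])


class TestRunningSumEs:
    def test_top_two_set_reaches_one(self):
        es, leading = genesets.running_sum_es(
            np.array([5.0, 4, 3, 2, 1]), np.array([True, True, False, False, False]))
        assert es == pytest.approx(1.0)
        assert leading == [0, 1]

    def test_all_genes_no_misses(self):
        es, _ = genesets.running_sum_es(np.arange(5, 0, -1.0), np.ones(5, dtype=bool))
        assert es == pytest.approx(1.0)

    def test_es_bounded_by_one(self, rng):
        for _ in range(20):
            s = np.sort(rng.standard_normal(30))[::-1]
            flags = rng.random(30) < 0.3
            if not flags.any() or np.abs(s[flags]).sum() == 0:
                continue
            es, _ = genesets.running_sum_es(s, flags)
            assert abs(es) <= 1.0 + 1e-12

    def test_reversing_ranking_negates_es(self, rng):
        for _ in range(20):
            s = np.sort(rng.standard_normal(25))[::-1]
            flags = rng.random(25) < 0.3
            if flags.sum() in (0, 25):
                continue
            es_fwd, _ = genesets.running_sum_es(s, flags)
            es_rev, _ = genesets.running_sum_es(s[::-1], flags[::-1])
            assert es_rev == pytest.approx(-es_fwd, abs=1e-12)

    def test_all_zero_member_stats_error(self):
        s = np.array([1.0, 0.0, 0.0])
        flags = np.array([False, True, True])
        with pytest.raises(ValueError, match="zero"):
            genesets.running_sum_es(s, flags)


class TestGsea:
    @staticmethod
    def _ranking(rng, n=200):
        stats = pd.Series(np.sort(rng.standard_normal(n))[::-1],
                          index=[f"g{i}" for i in range(n)])
        return stats

    def test_undersized_set_excluded(self, rng):
        ranking = self._ranking(rng)
        coll = {"TINY": list(ranking.index[:9]), "OK": list(ranking.index[:15])}
        res = genesets.gsea(ranking, coll, nperm=200, min_size=10, seed=0)
        assert res.loc["TINY", "flag"] == "size"
        assert np.isnan(res.loc["TINY", "p"])
        assert res.loc["OK", "flag"] == ""

    def test_planted_top_loaded_set_recovered(self, rng):
        ranking = self._ranking(rng)
        coll = {"TOP": list(ranking.index[:20])}
        coll.update({f"RAND{i}": list(rng.choice(ranking.index, 20, replace=False))
                     for i in range(5)})
        res = genesets.gsea(ranking, coll, nperm=2000, seed=1)
        assert res.loc["TOP", "NES"] > 0
        assert res.loc["TOP", "FDR"] < 0.05

    def test_same_seed_identical_p(self, rng):
        ranking = self._ranking(rng)
        coll = {"A": list(ranking.index[10:30]), "B": list(ranking.index[50:75])}
        r1 = genesets.gsea(ranking, coll, nperm=500, seed=7)
        r2 = genesets.gsea(ranking, coll, nperm=500, seed=7)
        pd.testing.assert_series_equal(r1["p"], r2["p"])
        pd.testing.assert_series_equal(r1["NES"], r2["NES"])

    def test_nes_shares_es_sign(self, rng):
        ranking = self._ranking(rng)
        coll = {f"S{i}": list(rng.choice(ranking.index, 15, replace=False))
                for i in range(8)}
        res = genesets.gsea(ranking, coll, nperm=300, seed=2)
        ok = res["flag"] == ""
        assert (np.sign(res.loc[ok, "NES"]) == np.sign(res.loc[ok, "ES"])).all()


class TestSsgsea:
    def test_top_ranked_members_maximal_among_same_size_sets(self):
        """Exhaustive oracle on 8 genes: members holding the top ranks score highest."""
        genes = [f"g{i}" for i in range(8)]
        profile = pd.Series([8.0, 7, 6, 5, 4, 3, 2, 1], index=genes)
        m = 3
        scores = {}
        for subset in itertools.combinations(genes, m):
            scores[subset] = genesets.ssgsea_scores(
                profile, {"S": list(subset)})["S"]
        top = tuple(genes[:m])
        assert max(scores, key=scores.get) == top

    def test_input_order_permutation_invariant(self, rng):
        genes = [f"g{i}" for i in range(50)]
        profile = pd.Series(rng.permutation(np.arange(50, dtype=float)), index=genes)
        coll = {"A": genes[5:20], "B": genes[30:45]}
        base = genesets.ssgsea_scores(profile, coll)
        perm = rng.permutation(50)
        shuffled = profile.iloc[perm]
        out = genesets.ssgsea_scores(shuffled, coll)
        assert out["A"] == pytest.approx(base["A"], abs=1e-12)
        assert out["B"] == pytest.approx(base["B"], abs=1e-12)

    def test_upward_swap_past_nonmember_increases_score(self, rng):
        genes = [f"g{i}" for i in range(30)]
        for _ in range(10):
            values = rng.permutation(np.arange(30, dtype=float))
            profile = pd.Series(values, index=genes)
            members = set(rng.choice(genes, 8, replace=False))
            order = profile.sort_values(ascending=False).index
            # find an adjacent (non-member, member) pair in rank order
            pair = next(((order[i], order[i + 1]) for i in range(29)
                         if order[i] not in members and order[i + 1] in members), None)
            if pair is None:
                continue
            before = genesets.ssgsea_scores(profile, {"S": sorted(members)})["S"]
            swapped = profile.copy()
            swapped[pair[0]], swapped[pair[1]] = profile[pair[1]], profile[pair[0]]
            after = genesets.ssgsea_scores(swapped, {"S": sorted(members)})["S"]
            assert after > before

    def test_absent_set_skipped(self, rng):
        profile = pd.Series(rng.standard_normal(10), index=[f"g{i}" for i in range(10)])
        out = genesets.ssgsea_scores(profile, {"MISSING": ["x", "y"]})
        assert "MISSING" not in out.index

    def test_planted_signature_tracks_sensitivity(self, panel):
        """ssGSEA on the planted set anticorrelates with AUC across the panel."""
        from scipy.stats import spearmanr

        scores = genesets.ssgsea_matrix(
            panel.bundle.expression, {"SIG": panel.truth["signature_genes"]})
        auc = panel.bundle.responses.mean(axis=1)
        rho = spearmanr(scores.loc["SIG"], auc.loc[scores.columns]).statistic
        assert rho < -0.5


class TestPathwayScore:
    @pytest.mark.parametrize("nes,fdr,expected",
                             [(2.0, 0.01, 2.0), (-1.5, 0.1, -1.0), (0.5, 1.0, 0.0),
                              (-2.0, 1.0, 0.0)])
    def test_arithmetic(self, nes, fdr, expected):
        assert genesets.pathway_score(nes, fdr) == pytest.approx(expected, abs=1e-12)

    def test_fdr_floored_by_permutation_resolution(self):
        assert genesets.pathway_score(1.0, 0.0, nperm=999) == pytest.approx(3.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            genesets.pathway_score(np.nan, 0.5)
        with pytest.raises(ValueError):
            genesets.pathway_score(1.0, 1.5)
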