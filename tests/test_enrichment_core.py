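import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dpgsea import (
    DETable,
    ProtoMatrix,
    build_ranked_list,
    directional_hits,
    enrichment_scores,
    running_sum,
)

from _oracles import naive_scores, random_instance
from conftest import make_hits, make_ranked_list


class TestBuildRankedList:
    def test_neglog10_ranking_and_weights(self, tiny_de):
        rl = build_ranked_list(tiny_de, omega=1.0)
        assert rl.genes.tolist() == ["g1", "g2", "g3"]
        np.testing.assert_allclose(
            rl.weights, [-np.log10(0.001), -np.log10(0.1), -np.log10(0.9)]
        )
        assert rl.disease_dirs.tolist() == [1, -1, 1]
        # T carries the effect sign
        assert rl.rank_stat[1] < 0

    def test_omega_zero_gives_unit_weights(self, tiny_de):
        rl = build_ranked_list(tiny_de, omega=0.0)
        np.testing.assert_array_equal(rl.weights, np.ones(3))

    def test_equal_significance_breaks_ties_lexicographically(self):
        de = DETable(
            pd.DataFrame(
                {"gene": ["zzz", "aaa", "mmm"], "effect": [1.0, 1.0, 1.0],
                 "significance": [0.05, 0.05, 0.05]}
            )
        )
        rl = build_ranked_list(de)
        assert rl.genes.tolist() == ["aaa", "mmm", "zzz"]

    def test_signed_stat_ranking(self):
        de = DETable(
            pd.DataFrame(
                {"gene": ["a", "b", "c"], "effect": [-5.0, 2.0, 0.5],
                 "significance": [0.9, 0.1, 0.2]}
            )
        )
        rl = build_ranked_list(de, rank_stat_kind="signed_stat")
        assert rl.genes.tolist() == ["a", "b", "c"]
        assert rl.rank_stat[0] == -5.0

    def test_negative_omega_rejected(self, tiny_de):
        with pytest.raises(ValueError):
            build_ranked_list(tiny_de, omega=-1.0)


class TestDirectionalHits:
    def _setup(self, directions, effects, genes=("g1", "g2", "gx")):
        de = DETable(
            pd.DataFrame(
                {"gene": ["g1", "g2"], "effect": list(effects),
                 "significance": [0.01, 0.02]}
            )
        )
        proto = ProtoMatrix(
            pd.DataFrame(
                {"drug": ["d"] * len(genes), "gene": list(genes),
                 "direction": list(directions), "rank": range(1, len(genes) + 1)}
            )
        )
        return build_ranked_list(de), proto

    def test_antagonist_requires_opposite_signs(self):
        rl, proto = self._setup([1, 1, 1], [2.0, 1.0])
        assert directional_hits(rl, proto, "d", mode="antagonist").gamma == 0
        assert directional_hits(rl, proto, "d", mode="agonist").gamma == 2

    def test_absent_signature_genes_are_ignored(self):
        # signature {g1: up, g2: down, gx: up}; disease effects g1<0, g2>0
        rl, proto = self._setup([1, -1, 1], [-2.0, 1.0])
        hv = directional_hits(rl, proto, "d", mode="antagonist")
        assert hv.gamma == 2
        assert hv.hit_flags.tolist() == [True, True]

    def test_zero_disease_direction_never_matches(self):
        de = DETable(
            pd.DataFrame(
                {"gene": ["g1", "g2"], "effect": [0.0, -1.0],
                 "significance": [0.01, 0.02]}
            )
        )
        proto = ProtoMatrix(
            pd.DataFrame({"drug": ["d", "d"], "gene": ["g1", "g2"],
                          "direction": [1, 1], "rank": [1, 2]})
        )
        rl = build_ranked_list(de)
        assert directional_hits(rl, proto, "d").gamma == 1  # only g2


class TestRunningSum:
    def test_single_hit_at_top_unweighted(self):
        rl = make_ranked_list([5, 4, 3, 2, 1], omega=0.0)
        v = running_sum(rl, make_hits(5, [1]))
        np.testing.assert_allclose(v, [1.0, 0.75, 0.5, 0.25, 0.0], atol=1e-12)

    def test_weighted_two_hit_example(self):
        abs_t = [5, 4, 3, 2.5, 2, 1.5, 1, 0.5, 0.2, 0.1]
        rl = make_ranked_list(abs_t, omega=1.0)
        v = running_sum(rl, make_hits(10, [1, 4]))
        assert v[0] == pytest.approx(5 / 7.5, abs=1e-4)
        assert v[3] == pytest.approx(0.75, abs=1e-12)
        assert v[9] == pytest.approx(0.0, abs=1e-12)

    def test_terminal_value_is_zero(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            abs_t, signs, hits, omega = random_instance(rng)
            if hits.all():
                continue
            rl = make_ranked_list(abs_t, signs, omega)
            hv = make_hits(len(abs_t), np.flatnonzero(hits) + 1)
            assert running_sum(rl, hv)[-1] == pytest.approx(0.0, abs=1e-12)

    def test_gamma_zero_rejected(self):
        rl = make_ranked_list([3, 2, 1])
        with pytest.raises(ValueError):
            running_sum(rl, make_hits(3, []))

    def test_all_hits_returns_hit_fraction(self):
        rl = make_ranked_list([3, 2, 1], omega=0.0)
        v = running_sum(rl, make_hits(3, [1, 2, 3]))
        np.testing.assert_allclose(v, [1 / 3, 2 / 3, 1.0])


class TestEnrichmentScores:
    def test_weighted_two_hit_example(self):
        abs_t = [5, 4, 3, 2.5, 2, 1.5, 1, 0.5, 0.2, 0.1]
        rl = make_ranked_list(abs_t, omega=1.0)
        scores = enrichment_scores(rl, make_hits(10, [1, 4]))
        assert scores.es == pytest.approx(0.75, abs=1e-12)
        assert scores.l_max == 4 and scores.l_min == 10
        assert scores.tcs_raw == 6
        assert scores.tcs == pytest.approx(6 / 9, abs=1e-12)
        assert scores.leading_edge == ["g000", "g003"]

    def test_single_top_hit_is_maximal(self):
        rl = make_ranked_list([5, 4, 3, 2, 1], omega=0.0)
        scores = enrichment_scores(rl, make_hits(5, [1]))
        assert scores.es == pytest.approx(1.0) and scores.tcs == pytest.approx(1.0)

    def test_matches_naive_oracle_on_random_instances(self):
        rng = np.random.default_rng(20240917)
        for _ in range(300):
            abs_t, signs, hits, omega = random_instance(rng)
            rl = make_ranked_list(abs_t, signs, omega)
            hv = make_hits(len(abs_t), np.flatnonzero(hits) + 1)
            got = enrichment_scores(rl, hv)
            es, l_max, l_min, tcs_raw, tcs = naive_scores(abs_t, hits.tolist(), omega)
            assert got.es == pytest.approx(es, abs=1e-12)
            assert (got.l_max, got.l_min, got.tcs_raw) == (l_max, l_min, tcs_raw)
            assert got.tcs == pytest.approx(tcs, abs=1e-12)
            assert 0.0 <= got.es <= 1.0 and 0.0 <= got.tcs <= 1.0
            assert got.leading_edge  # non-empty whenever gamma >= 1

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        weights=st.lists(st.floats(0.01, 10.0), min_size=3, max_size=30),
        hit_seed=st.integers(0, 2**31 - 1),
        omega=st.sampled_from([0.0, 0.5, 1.0, 2.0]),
    )
    def test_score_bounds_and_closure_hold_generally(self, weights, hit_seed, omega):
        abs_t = np.sort(np.asarray(weights))[::-1].copy()
        p = len(abs_t)
        rng = np.random.default_rng(hit_seed)
        gamma = int(rng.integers(1, p))
        rl = make_ranked_list(abs_t, rng.choice([-1, 1], p), omega)
        hv = make_hits(p, rng.choice(p, gamma, replace=False) + 1)
        v = running_sum(rl, hv)
        assert abs(v[-1]) < 1e-12
        scores = enrichment_scores(rl, hv)
        assert 0.0 <= scores.es <= 1.0 + 1e-12
        assert 0.0 <= scores.tcs <= 1.0
        assert scores.leading_edge

    def test_permuting_non_hit_labels_leaves_scores_unchanged(self):
        # swap gene labels among non-signature genes (stats stay in place)
        sig = [0.001, 0.01, 0.05, 0.2, 0.5, 0.9]
        eff = [1.0, -2.0, 1.5, -0.5, 0.7, -1.1]
        genes_a = ["s1", "n1", "s2", "n2", "n3", "n4"]
        genes_b = ["s1", "n4", "s2", "n3", "n2", "n1"]  # non-hits permuted
        proto = ProtoMatrix(
            pd.DataFrame({"drug": ["d", "d"], "gene": ["s1", "s2"],
                          "direction": [-1, -1], "rank": [1, 2]})
        )
        results = []
        for genes in (genes_a, genes_b):
            de = DETable(pd.DataFrame({"gene": genes, "effect": eff, "significance": sig}))
            rl = build_ranked_list(de)
            hv = directional_hits(rl, proto, "d", mode="antagonist")
            results.append(enrichment_scores(rl, hv))
        assert results[0].es == results[1].es
        assert results[0].tcs == results[1].tcs
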