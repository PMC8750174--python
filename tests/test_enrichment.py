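"""Hypergeometric ORA, BH adjustment, kappa scores, and term clustering."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oxscreen import synthetic_data
from oxscreen.enrichment import (
    GeneSet,
    bh_adjust,
    cluster_terms,
    hypergeometric_p,
    kappa_score,
    run_ora,
)
from oxscreen.exceptions import InvalidParameterError, UndefinedKappaError


def _enumerate_tail(k, K, n, N):
    """Oracle: exhaustive enumeration of all C(N, n) draws."""
    hits = total = 0
    successes = set(range(K))
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(successes.intersection(draw)) >= k:
            hits += 1
    return hits / total


class TestHypergeometric:
    def test_zero_overlap_has_probability_one(self):
        assert hypergeometric_p(0, 5, 5, 20) == 1.0

    def test_all_five_in_five_draws_from_ten(self):
        # exactly 1 of C(10,5)=252 draws contains all 5 successes
        assert hypergeometric_p(5, 5, 5, 10) == pytest.approx(1 / 252)

    @pytest.mark.parametrize("N", [4, 8, 12])
    def test_matches_enumeration_oracle(self, N):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(min(K, n) + 1):
                    assert hypergeometric_p(k, K, n, N) == pytest.approx(
                        _enumerate_tail(k, K, n, N), abs=1e-12
                    )

    def test_decreasing_in_k(self):
        ps = [hypergeometric_p(k, 6, 6, 20) for k in range(7)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_impossible_configuration_rejected(self):
        with pytest.raises(InvalidParameterError):
            hypergeometric_p(6, 5, 5, 10)
        with pytest.raises(InvalidParameterError):
            hypergeometric_p(1, 11, 5, 10)


def _bh_hand(p):
    """Oracle: step-up by hand — p*m/rank then cumulative minimum from the top."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_worked_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_equal_p_stay_equal(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    def test_matches_hand_step_up_and_never_below_raw(self, p):
        adj = bh_adjust(p)
        assert adj == pytest.approx(_bh_hand(p))
        assert (np.asarray(adj) >= np.asarray(p) - 1e-12).all()

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=25),
        st.sampled_from([0.01, 0.05, 0.1, 0.25]),
    )
    def test_rejection_set_matches_classic_step_up(self, p, alpha):
        adj = bh_adjust(p)
        # classic step-up: largest rank r with p_(r) <= r*alpha/m rejects p_(1..r)
        m = len(p)
        s = sorted(p)
        r = max((i + 1 for i in range(m) if s[i] <= (i + 1) * alpha / m), default=0)
        thresh = s[r - 1] if r else -1.0
        classic = {i for i in range(m) if p[i] <= thresh}
        assert {i for i in range(m) if adj[i] <= alpha} == classic


class TestKappa:
    def test_identical_subsets_give_one(self):
        assert kappa_score({"a", "b"}, {"a", "b"}, {"a", "b", "c"}) == 1.0

    def test_hand_worked_contingency(self):
        # a=2, b=1, c=1, d=0: p_o = 0.5, p_e = 0.625
        k = kappa_score({"g1", "g2", "g3"}, {"g1", "g2", "g4"}, {"g1", "g2", "g3", "g4"})
        assert k == pytest.approx(-1 / 3)

    def test_matches_sklearn_on_indicator_vectors(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(3)
        ref = [f"g{i}" for i in range(30)]
        for _ in range(10):
            a = {g for g in ref if rng.random() < 0.4}
            b = {g for g in ref if rng.random() < 0.4}
            va = [g in a for g in ref]
            vb = [g in b for g in ref]
            if len(set(va)) == 1 and va == vb:
                continue
            expected = sklearn_metrics.cohen_kappa_score(va, vb)
            assert kappa_score(a, b, ref) == pytest.approx(expected, abs=1e-10)

    @given(
        st.sets(st.integers(0, 15), max_size=10),
        st.sets(st.integers(0, 15), max_size=10),
    )
    def test_symmetric_and_bounded_above_by_one(self, a, b):
        ref = set(range(16))
        try:
            k1 = kappa_score(a, b, ref)
        except UndefinedKappaError:
            return
        assert k1 == pytest.approx(kappa_score(b, a, ref))
        assert k1 <= 1.0 + 1e-12
        if k1 == pytest.approx(1.0):
            assert a == b

    def test_undefined_when_chance_agreement_is_one(self):
        with pytest.raises(UndefinedKappaError):
            kappa_score(set(), set(), {"a", "b"})


def _collection(specs):
    return [GeneSet(set_id=sid, name=sid, genes=frozenset(genes)) for sid, genes in specs]


class TestORA:
    def test_planted_set_attains_minimum_adj_p_and_significance(self):
        sets, query, truth = synthetic_data.simulate_genesets(
            planted_set_overlap=15, query_size=30, seed=4
        )
        results = run_ora(query, sets)
        planted = truth.planted_enriched_sets[0]["set_id"]
        assert results.iloc[0]["set_id"] == planted
        assert results.iloc[0]["significant"]

    def test_query_disjoint_from_universe_gives_no_significance(self):
        coll = _collection([("s1", {"a", "b"}), ("s2", {"c", "d"})])
        results = run_ora({"zz1", "zz2"}, coll)
        assert (results["k"] == 0).all()
        assert (results["p_value"] == 1.0).all()
        assert not results["significant"].any()

    def test_one_result_per_collection_set(self):
        coll = _collection([(f"s{i}", {f"g{i}", "g0"}) for i in range(8)])
        assert len(run_ora({"g0"}, coll)) == 8


class TestClusterTerms:
    def test_single_significant_term_is_its_own_leader(self):
        coll = _collection([("s1", {"a", "b"}), ("s2", {"c"})])
        results = run_ora({"a", "b"}, coll).assign(significant=[True, False])
        (cluster,) = cluster_terms(results, coll)
        assert cluster.member_terms == ["s1"] and cluster.leading_term == "s1"

    def test_identical_gene_sets_merge_into_one_group(self):
        coll = _collection([("s1", {"a", "b"}), ("s2", {"a", "b"}), ("s3", {"x", "y", "z"})])
        results = run_ora({"a", "b"}, coll)
        results["significant"] = results["set_id"].isin(["s1", "s2"])
        (cluster,) = cluster_terms(results, coll)
        assert cluster.member_terms == ["s1", "s2"]

    def test_two_disjoint_blocks_recovered_as_two_groups(self):
        # within-block kappa high (near-identical sets), across-block kappa <= 0
        block1 = {"a1", "a2", "a3", "a4", "a5"}
        block2 = {"b1", "b2", "b3", "b4", "b5"}
        coll = _collection(
            [
                ("t1", block1),
                ("t2", block1 | {"a6"}),
                ("u1", block2),
                ("u2", block2 | {"b6"}),
            ]
        )
        results = run_ora(block1 | block2, coll)
        results["significant"] = True
        clusters = cluster_terms(results, coll)
        groups = {frozenset(c.member_terms) for c in clusters}
        assert groups == {frozenset({"t1", "t2"}), frozenset({"u1", "u2"})}

    def test_order_independence_of_grouping(self):
        sets, query, _ = synthetic_data.simulate_genesets(
            n_sets=12, planted_set_overlap=12, query_size=25, seed=5
        )
        results = run_ora(query, sets)
        results["significant"] = results["adj_p"] < 0.9  # widen to get several terms
        ref = cluster_terms(results, sets)
        shuffled = results.sample(frac=1.0, random_state=1)
        out = cluster_terms(shuffled, list(reversed(sets)))
        assert [c.member_terms for c in ref] == [c.member_terms for c in out]
        assert [c.leading_term for c in ref] == [c.leading_term for c in out]

    def test_no_significant_terms_gives_empty_list(self):
        coll = _collection([("s1", {"a"})])
        results = run_ora({"zz"}, coll)
        assert cluster_terms(results, coll) == []
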