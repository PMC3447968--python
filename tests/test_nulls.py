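import math

import numpy as np
import pytest

from interolog import (
    HomologyMap,
    Interactome,
    PairScore,
    TransferResult,
    homolog_pair_propensity,
    infer_across,
    likelihood_ratio,
    rewire,
    rewiring_ratio,
    score,
)

from conftest import random_cross_map, random_interactome
from oracles import brute_likelihood_across


def _map(pairs):
    return HomologyMap("curated", "S", "T",
                       {p: PairScore(None, None) for p in pairs})


def _result(f_obs, n=3):
    n_correct = round(f_obs * n)
    return TransferResult("across", n, n_correct, f_obs)


class TestLikelihood:
    def test_hand_computed_example(self):
        # 3 homolog-bearing target proteins -> 6 possible pairs with self;
        # one target edge between homolog-bearing proteins -> prior odds 1/5;
        # f_obs = 1/3 -> posterior odds 1/2; L = 2.5
        source = Interactome.from_pairs("S", [("a1", "a2"), ("a2", "a3")])
        target = Interactome.from_pairs("T", [("b1", "b2"), ("b4", "b5")])
        hmap = _map([("a1", "b1"), ("a2", "b2"), ("a3", "b3")])
        res = likelihood_ratio(_result(1 / 3), target, hmap, source)
        assert res.n_homolog_bearing == 3
        assert res.n_possible == 6
        assert res.n_possible_positive == 1
        assert res.o_prior == pytest.approx(1 / 5)
        assert res.L == pytest.approx(2.5)

    def test_odds_cancel_at_prior_rate(self):
        source = Interactome.from_pairs("S", [("a1", "a2")])
        target = Interactome.from_pairs("T", [("b1", "b2"), ("b1", "b1")])
        hmap = _map([("a1", "b1"), ("a2", "b2")])
        # prior: 3 possible pairs, 2 positives -> o_prior = 2; f_obs = 2/3
        res = likelihood_ratio(_result(2 / 3), target, hmap, source)
        assert res.L == pytest.approx(1.0)

    def test_flags(self):
        source = Interactome.from_pairs("S", [("a1", "a2")])
        target = Interactome.from_pairs("T", [("b1", "b2")])
        hmap = _map([("a1", "b1"), ("a2", "b2")])
        assert likelihood_ratio(_result(0.0), target, hmap, source).L == 0.0
        assert math.isinf(likelihood_ratio(_result(1.0), target, hmap, source).L)
        no_positive = Interactome.from_pairs("T", [("z1", "z2")])
        res = likelihood_ratio(_result(0.5), no_positive, hmap, source)
        assert res.L is None and res.flagged

    def test_matches_enumeration_on_random_worlds(self):
        rng = np.random.default_rng(21)
        for _ in range(40):
            source = random_interactome(rng, "S", 6, int(rng.integers(1, 8)))
            target = random_interactome(rng, "T", 6, int(rng.integers(1, 8)), prefix="q")
            hmap = random_cross_map(rng, 6, 6, int(rng.integers(1, 10)))
            res = score(infer_across(source, hmap), target)
            if not res.defined or res.f_obs == 1.0:
                continue
            got = likelihood_ratio(res, target, hmap, source)
            lookup = hmap.oriented("T")
            bearing = {
                p for p in set(target.proteins) | set(lookup)
                if any(q in source.proteins for q, _ in lookup.get(p, ()))
            }
            expected = brute_likelihood_across(
                res.f_obs, target.edges, set(target.proteins) | set(lookup), bearing
            )
            if expected is None:
                assert got.L is None
            else:
                assert got.L == pytest.approx(expected)


class TestRewire:
    def test_two_edges_valid_outcomes(self):
        inter = Interactome.from_pairs("S", [("a", "b"), ("c", "d")])
        outcomes = set()
        for seed in range(20):
            outcomes.add(rewire(inter, seed).edges)
        valid = {
            frozenset({("a", "b"), ("c", "d")}),
            frozenset({("a", "c"), ("b", "d")}),
            frozenset({("a", "d"), ("b", "c")}),
        }
        assert outcomes <= valid and len(outcomes) > 1

    def test_star_graph_unchanged(self):
        inter = Interactome.from_pairs("S", [("h", "x"), ("h", "y"), ("h", "z")])
        assert rewire(inter, 3).edges == inter.edges

    def test_self_edges_held_fixed(self):
        inter = Interactome.from_pairs(
            "S", [("s", "s"), ("a", "b"), ("c", "d"), ("a", "d")]
        )
        rewired = rewire(inter, 0)
        assert ("s", "s") in rewired.edges

    def test_degree_multiset_preserved_on_random_graphs(self):
        rng = np.random.default_rng(9)
        for trial in range(50):
            n = int(rng.integers(4, 20))
            inter = random_interactome(rng, "S", n, int(rng.integers(2, 3 * n)))
            rewired = rewire(inter, trial)
            assert sorted(inter.degrees().values()) == sorted(rewired.degrees().values())
            assert rewired.n_edges == inter.n_edges


class TestRewiringRatio:
    def test_conserved_world_beats_random(self):
        rng = np.random.default_rng(3)
        source = random_interactome(rng, "S", 60, 150)
        hmap = HomologyMap(
            "curated", "S", "T",
            {(f"p{i}", f"q{i}"): PairScore(None, None) for i in range(60)},
        )
        target = Interactome.from_pairs(
            "T", [(f"q{a[1:]}", f"q{b[1:]}") for a, b in list(source.edges)[:100]]
        )
        res = rewiring_ratio(source, hmap, target, n_rewirings=5, seed=1)
        assert res.ratio is not None and res.ratio > 1.5

    def test_no_signal_world_near_one(self):
        # random target edges over homolog-bearing proteins: rewiring the
        # source should not change the success rate beyond noise
        rng = np.random.default_rng(4)
        source = random_interactome(rng, "S", 40, 120)
        hmap = HomologyMap(
            "curated", "S", "T",
            {(f"p{i}", f"q{i}"): PairScore(None, None) for i in range(40)},
        )
        target = random_interactome(rng, "T", 40, 200, prefix="q")
        res = rewiring_ratio(source, hmap, target, n_rewirings=10, seed=2)
        assert res.ratio == pytest.approx(1.0, abs=max(3 * res.sd, 0.3))

    def test_empty_map_propagates_undefined(self):
        source = Interactome.from_pairs("S", [("a", "b"), ("c", "d")])
        target = Interactome.from_pairs("T", [("x", "y")])
        with pytest.raises(ValueError, match="undefined"):
            rewiring_ratio(source, HomologyMap("curated", "S", "T", {}), target)

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        source = random_interactome(rng, "S", 30, 80)
        hmap = HomologyMap(
            "curated", "S", "T",
            {(f"p{i}", f"q{i}"): PairScore(None, None) for i in range(30)},
        )
        target = random_interactome(rng, "T", 30, 80, prefix="q")
        r1 = rewiring_ratio(source, hmap, target, n_rewirings=4, seed=11)
        r2 = rewiring_ratio(source, hmap, target, n_rewirings=4, seed=11)
        assert r1.f_obs_rewired == r2.f_obs_rewired


class TestPropensity:
    def test_hand_fractions(self):
        # proteins q0..q3; homolog-bearing = {q0, q1}; all 10 self-inclusive
        # pairs vs 3 homolog-bearing pairs; 1 edge total, between q0 and q1
        target = Interactome.from_pairs("T", [("q0", "q1"), ("q2", "q3")])
        source = Interactome.from_pairs("S", [("p0", "p1")])
        hmap = _map([("p0", "q0"), ("p1", "q1")])
        ratio = homolog_pair_propensity(target, hmap, source)
        assert ratio == pytest.approx((1 / 3) / (2 / 10))

    def test_full_coverage_map_gives_one(self):
        target = Interactome.from_pairs("T", [("q0", "q1"), ("q1", "q2")])
        source = Interactome.from_pairs("S", [("p0", "p1"), ("p1", "p2")])
        hmap = _map([(f"p{i}", f"q{i}") for i in range(3)])
        assert homolog_pair_propensity(target, hmap, source) == pytest.approx(1.0)

    def test_no_homolog_bearing_edges(self):
        target = Interactome.from_pairs("T", [("q0", "q2"), ("q2", "q3")])
        source = Interactome.from_pairs("S", [("p0", "p1")])
        hmap = _map([("p0", "q0"), ("p1", "q3")])
        # q0 and q3 are homolog-bearing but share no edge
        assert homolog_pair_propensity(target, hmap, source) == 0.0

    def test_empty_homolog_bearing_set_is_undefined(self):
        target = Interactome.from_pairs("T", [("q2", "q3")])
        source = Interactome.from_pairs("S", [("p0", "p1")])
        hmap = _map([("p0", "q0"), ("p1", "q1")])
        assert homolog_pair_propensity(target, hmap, source) is None
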