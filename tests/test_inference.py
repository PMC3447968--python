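import numpy as np
import pytest

from interolog import (
    HomologyMap,
    Interactome,
    PairScore,
    family_size_filter,
    infer_across,
    infer_within,
    score,
)

from conftest import random_interactome, random_within_map
from oracles import brute_across, brute_f_obs, brute_within


class TestAcross:
    def test_all_substitutions_enumerated(self, toy_source, toy_map):
        inferences = infer_across(toy_source, toy_map)
        assert inferences.pairs == {("b1", "b2"), ("b1", "b4"), ("b1", "b3")}
        # (b1, b2) uses a1->b1 (1e-30) and a2->b2 (1e-20): route E is the max
        assert inferences.predictions[("b1", "b2")].best_evalue == 1e-20

    def test_self_edge_transfer(self):
        source = Interactome.from_pairs("S", [("a1", "a1")])
        hmap = HomologyMap("curated", "S", "T", {("a1", "b1"): PairScore(None, None)})
        assert infer_across(source, hmap).pairs == {("b1", "b1")}

    def test_empty_map(self, toy_source):
        hmap = HomologyMap("curated", "S", "T", {})
        assert len(infer_across(toy_source, hmap)) == 0

    def test_reverse_direction_uses_target_side(self, toy_map):
        source = Interactome.from_pairs("T", [("b1", "b2")])
        assert infer_across(source, toy_map).pairs == {("a1", "a2")}

    def test_relabeling_equivariance(self):
        rng = np.random.default_rng(11)
        source = random_interactome(rng, "S", 8, 10)
        hmap = HomologyMap("reciprocal_hits", "S", "T", {
            (f"p{i}", f"q{(i * 3) % 8}"): PairScore(1e-20, None) for i in range(8)
        })
        base = infer_across(source, hmap).pairs
        rename = {f"q{i}": f"Z{i:02d}" for i in range(8)}
        renamed_map = HomologyMap("reciprocal_hits", "S", "T", {
            (a, rename[b]): s for (a, b), s in hmap.pairs.items()
        })
        renamed = infer_across(source, renamed_map).pairs
        expected = {tuple(sorted((rename[a], rename[b]))) for a, b in base}
        assert renamed == expected


class TestWithin:
    def test_one_same_single_substitution(self):
        inter = Interactome.from_pairs("S", [("p1", "p2")])
        hmap = HomologyMap("reciprocal_hits", "S", "S",
                           {("p2", "p3"): PairScore(1e-20, None)})
        inf = infer_within(inter, hmap, "one_same")
        assert inf.pairs == {("p1", "p3")}
        assert inf.predictions[("p1", "p3")].best_evalue == 1e-20

    def test_both_different_uses_max_rule(self):
        inter = Interactome.from_pairs("S", [("p1", "p2")])
        hmap = HomologyMap("reciprocal_hits", "S", "S", {
            ("p1", "p4"): PairScore(1e-8, None),
            ("p2", "p3"): PairScore(1e-20, None),
        })
        inf = infer_within(inter, hmap, "both_different_1")
        assert inf.pairs == {("p3", "p4")}
        assert inf.predictions[("p3", "p4")].best_evalue == 1e-8

    def test_both_different_2_drops_one_same_closest(self):
        # (p1, p3) is reachable one-same from (p1, p2) at E 1e-20 and
        # both-different from (p2, p3) at E 1e-8: the closest route is
        # one-same, so both-different-2 excludes the prediction.
        inter = Interactome.from_pairs("S", [("p1", "p2"), ("p2", "p3")])
        hmap = HomologyMap("reciprocal_hits", "S", "S", {
            ("p2", "p3"): PairScore(1e-20, None),
            ("p1", "p4"): PairScore(1e-8, None),
        })
        bd2 = infer_within(inter, hmap, "both_different_2")
        assert ("p1", "p3") not in bd2.pairs

    def test_prediction_never_equals_source_edge(self):
        inter = Interactome.from_pairs("S", [("p1", "p2")])
        hmap = HomologyMap("reciprocal_hits", "S", "S",
                           {("p1", "p2"): PairScore(1e-9, None)})
        for mode in ("one_same", "both_different_1", "both_different_2"):
            assert ("p1", "p2") not in infer_within(inter, hmap, mode).pairs

    @pytest.mark.parametrize("mode", ["one_same", "both_different_1", "both_different_2"])
    def test_matches_brute_force(self, mode):
        rng = np.random.default_rng(5)
        for _ in range(40):
            inter = random_interactome(rng, "S", 6, int(rng.integers(1, 8)))
            hmap = random_within_map(rng, 6, int(rng.integers(1, 8)))
            got = infer_within(inter, hmap, mode).pairs
            expected = brute_within(
                sorted(inter.edges),
                {k: v.evalue for k, v in hmap.pairs.items()},
                mode,
            )
            assert got == expected

    def test_bd2_subset_of_bd1(self):
        rng = np.random.default_rng(6)
        for _ in range(40):
            inter = random_interactome(rng, "S", 7, int(rng.integers(1, 10)))
            hmap = random_within_map(rng, 7, int(rng.integers(1, 10)))
            bd1 = infer_within(inter, hmap, "both_different_1").pairs
            bd2 = infer_within(inter, hmap, "both_different_2").pairs
            assert bd2 <= bd1


class TestScore:
    def test_intersection_counting(self, toy_source, toy_map, toy_target):
        res = score(infer_across(toy_source, toy_map), toy_target)
        assert (res.n_predictions, res.n_correct) == (3, 1)
        assert res.f_obs == pytest.approx(1 / 3)

    def test_undefined_on_empty_predictions(self, toy_target):
        empty = infer_across(Interactome.from_pairs("S", [("a9", "a8")]),
                             HomologyMap("curated", "S", "T", {}))
        res = score(empty, toy_target)
        assert not res.defined and res.f_obs is None

    def test_perfect_transfer(self, toy_source):
        hmap = HomologyMap("curated", "S", "T", {
            ("a1", "b1"): PairScore(None, None),
            ("a2", "b2"): PairScore(None, None),
            ("a3", "b3"): PairScore(None, None),
        })
        target = Interactome.from_pairs("T", [("b1", "b2"), ("b1", "b3")])
        assert score(infer_across(toy_source, hmap), target).f_obs == 1.0

    def test_against_brute_force_random_worlds(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            source = random_interactome(rng, "S", 6, int(rng.integers(1, 8)))
            target = random_interactome(rng, "T", 6, int(rng.integers(1, 8)), prefix="q")
            n_pairs = int(rng.integers(1, 10))
            pairs = {}
            for _ in range(n_pairs):
                pairs[(f"p{rng.integers(0, 6)}", f"q{rng.integers(0, 6)}")] = PairScore(
                    float(10.0 ** -rng.integers(3, 40)), None
                )
            hmap = HomologyMap("reciprocal_hits", "S", "T", pairs)
            inferences = infer_across(source, hmap)
            expected = brute_across(
                sorted(source.edges), {k: v.evalue for k, v in pairs.items()}
            )
            assert inferences.pairs == set(expected)
            for pair, routes in expected.items():
                pred = inferences.predictions[pair]
                assert pred.n_provenance == len(routes)
                assert pred.best_evalue == min(routes)
            res = score(inferences, target)
            assert res.f_obs == brute_f_obs(set(expected), target.edges)


def test_family_size_filter():
    pairs = {(f"a1", f"b{i}"): PairScore(1e-20, None) for i in range(11)}
    hmap = HomologyMap("reciprocal_hits", "S", "T", pairs)
    assert len(family_size_filter(hmap, 10)) == 0
    assert len(family_size_filter(hmap, 11)) == 11

    mixed = HomologyMap("reciprocal_hits", "S", "T", {
        **{(f"a{i}", "b9"): PairScore(1e-20, None) for i in range(12)},
        ("a1", "b1"): PairScore(1e-20, None),
        ("a1", "b2"): PairScore(1e-20, None),
    })
    kept = family_size_filter(mixed, 10)
    # b9 is in 12 pairs, so every (a*, b9) pair goes; a1's other pairs stay
    assert set(kept.pairs) == {("a1", "b1"), ("a1", "b2")}


def test_inference_set_serialization(tmp_path, toy_source, toy_map, toy_target):
    inferences = infer_across(toy_source, toy_map)
    inferences.to_tsv(tmp_path / "inf.tsv", toy_target)
    lines = (tmp_path / "inf.tsv").read_text().splitlines()
    assert lines[0].startswith("protein_a\tprotein_b")
    assert len(lines) == 4  # header + 3 unique predictions
    assert lines[1].split("\t")[5] == "1"  # (b1, b2) confirmed in target
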