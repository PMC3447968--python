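import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from interolog import (
    HomologyMap,
    PairScore,
    collapse_hsps,
    load_curated_orthologs,
    reciprocal_best_hits,
    reciprocal_hits,
)


def _raw(rows):
    return pd.DataFrame(
        rows, columns=["query", "subject", "pident", "length", "evalue", "bitscore"]
    )


def _table(rows, sp_q="S", sp_s="T"):
    return collapse_hsps(_raw(rows), sp_q, sp_s)


class TestCollapseHsps:
    def test_minimum_evalue_wins(self):
        table = _table([("q", "s", 50.0, 100, 1e-30, 120.0),
                        ("q", "s", 40.0, 80, 1e-5, 60.0)])
        assert len(table.hits) == 1
        assert table.hits.iloc[0].evalue == 1e-30

    def test_tie_broken_by_bitscore_then_length(self):
        table = _table([("q", "s", 50.0, 100, 1e-10, 200.0),
                        ("q", "s", 45.0, 90, 1e-10, 250.0)])
        assert table.hits.iloc[0].bitscore == 250.0
        table = _table([("q", "s", 50.0, 100, 1e-10, 200.0),
                        ("q", "s", 60.0, 150, 1e-10, 200.0)])
        assert table.hits.iloc[0].pident == 60.0

    def test_one_record_per_pair(self):
        rows = [(f"q{i}", f"s{i}", 50.0, 100, e, 100.0)
                for i in range(3) for e in (1e-20, 1e-10)]
        assert len(_table(rows).hits) == 3

    def test_malformed_rows_rejected(self):
        table = _table([("q", "s", 50.0, 100, -1.0, 100.0),
                        ("q", "s", 150.0, 100, 1e-10, 100.0),
                        ("q", "s", 50.0, 100, 1e-10, 100.0)])
        assert table.n_rejected == 2
        assert len(table.hits) == 1

    def test_within_species_self_hits_dropped(self):
        table = _table([("p", "p", 100.0, 100, 0.0, 500.0),
                        ("p", "r", 50.0, 100, 1e-20, 100.0)], "S", "S")
        assert list(table.hits["subject"]) == ["r"]


class TestReciprocalHits:
    def test_reciprocal_pair_with_max_evalue(self):
        ab = _table([("a1", "b1", 50.0, 100, 1e-30, 100.0)])
        ba = _table([("b1", "a1", 50.0, 100, 1e-28, 100.0)], "T", "S")
        hmap = reciprocal_hits(ab, ba, 1e-10)
        assert hmap.pairs == {("a1", "b1"): PairScore(1e-28, 50.0)}
        assert reciprocal_hits(ab, ba, 1e-50).pairs == {}

    def test_many_to_many_kept(self):
        ab = _table([("a1", "b1", 50.0, 100, 1e-30, 100.0),
                     ("a1", "b2", 50.0, 100, 1e-12, 100.0)])
        ba = _table([("b1", "a1", 50.0, 100, 1e-28, 100.0),
                     ("b2", "a1", 50.0, 100, 1e-11, 100.0)], "T", "S")
        assert set(reciprocal_hits(ab, ba, 1e-10).pairs) == {("a1", "b1"), ("a1", "b2")}

    def test_non_reciprocal_dropped(self):
        ab = _table([("a1", "b1", 50.0, 100, 1e-30, 100.0)])
        ba = _table([("b9", "a7", 50.0, 100, 1e-28, 100.0)], "T", "S")
        assert reciprocal_hits(ab, ba, 1e-5).pairs == {}

    def test_underflowed_evalue_passes_any_threshold(self):
        ab = _table([("a1", "b1", 99.0, 500, 0.0, 900.0)])
        ba = _table([("b1", "a1", 99.0, 500, 0.0, 900.0)], "T", "S")
        assert ("a1", "b1") in reciprocal_hits(ab, ba, 1e-70).pairs


class TestReciprocalBestHits:
    def test_mutual_best_pair(self):
        ab = _table([("a1", "b1", 50.0, 100, 1e-30, 100.0),
                     ("a1", "b2", 50.0, 100, 1e-12, 90.0)])
        ba = _table([("b1", "a1", 50.0, 100, 1e-28, 100.0),
                     ("b2", "a1", 50.0, 100, 1e-11, 90.0)], "T", "S")
        hmap = reciprocal_best_hits(ab, ba, 1e-10)
        assert hmap.pairs == {("a1", "b1"): PairScore(1e-28, 50.0)}

    def test_non_mutual_best_excluded(self):
        ab = _table([("a2", "b3", 50.0, 100, 1e-40, 100.0)])
        ba = _table([("b3", "a7", 50.0, 100, 1e-45, 100.0),
                     ("b3", "a2", 50.0, 100, 1e-40, 90.0)], "T", "S")
        assert reciprocal_best_hits(ab, ba, 1e-10).pairs == {}

    def test_cap_rejects_weak_mutual_best(self):
        ab = _table([("a1", "b1", 50.0, 100, 1e-4, 100.0)])
        ba = _table([("b1", "a1", 50.0, 100, 1e-30, 100.0)], "T", "S")
        assert reciprocal_best_hits(ab, ba, 1e-10).pairs == {}

    def test_ambiguous_best_hit_dropped(self):
        ab = _table([("a1", "b1", 50.0, 100, 1e-30, 100.0),
                     ("a1", "b2", 50.0, 100, 1e-30, 100.0)])
        ba = _table([("b1", "a1", 50.0, 100, 1e-30, 100.0)], "T", "S")
        assert reciprocal_best_hits(ab, ba, 1e-10).pairs == {}


def test_curated_orthologs(tmp_path):
    path = tmp_path / "orthologs.tsv"
    path.write_text("s1\tc1\ns1\tc2\ns2\tc3\ns2\tc3\n\t c4\n", encoding="utf-8")
    hmap = load_curated_orthologs(path, "SP", "SC")
    assert set(hmap.pairs) == {("s1", "c1"), ("s1", "c2"), ("s2", "c3")}
    assert all(score.evalue is None for score in hmap.pairs.values())


def test_filter_by_identity():
    hmap = HomologyMap("reciprocal_hits", "S", "T", {
        ("a", "x"): PairScore(1e-20, 30.0),
        ("b", "y"): PairScore(1e-20, 55.0),
    })
    assert set(hmap.filter_by_identity(40).pairs) == {("b", "y")}
    assert len(hmap.filter_by_identity(0)) == 2
    assert len(hmap.filter_by_identity(100)) == 0
    curated = HomologyMap("curated", "S", "T", {("a", "x"): PairScore(None, None)})
    with pytest.raises(ValueError, match="identity"):
        curated.filter_by_identity(40)


def test_within_map_rejects_identity_pair():
    with pytest.raises(ValueError, match="identity pair"):
        HomologyMap("curated", "S", "S", {("p", "p"): PairScore(None, None)})


def test_serialization_roundtrip(tmp_path):
    hmap = HomologyMap("reciprocal_hits", "S", "T", {
        ("a", "x"): PairScore(1e-20, 30.0),
        ("b", "y"): PairScore(None, None),
    })
    hmap.to_tsv(tmp_path / "map.tsv")
    again = HomologyMap.from_tsv(tmp_path / "map.tsv", "S", "T")
    assert again.pairs == hmap.pairs and again.kind == hmap.kind


@st.composite
def hit_table_pairs(draw):
    """A consistent pair of directional hit tables over small namespaces."""
    n_a, n_b = draw(st.integers(2, 5)), draw(st.integers(2, 5))
    rows_ab, rows_ba = [], []
    for i in range(n_a):
        for j in range(n_b):
            if draw(st.booleans()):
                e1 = 10.0 ** -draw(st.integers(0, 40))
                rows_ab.append((f"a{i}", f"b{j}", 50.0, 100, e1, 100.0 + i))
            if draw(st.booleans()):
                e2 = 10.0 ** -draw(st.integers(0, 40))
                rows_ba.append((f"b{j}", f"a{i}", 50.0, 100, e2, 100.0 + j))
    return rows_ab, rows_ba


@given(hit_table_pairs(), st.integers(0, 40), st.integers(0, 40))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_threshold_monotonicity_and_rbh_subset(tables, k1, k2):
    rows_ab, rows_ba = tables
    if not rows_ab or not rows_ba:
        return
    ab, ba = _table(rows_ab), _table(rows_ba, "T", "S")
    e_lo, e_hi = sorted((10.0 ** -k1, 10.0 ** -k2))
    strict = set(reciprocal_hits(ab, ba, e_lo).pairs)
    lax = set(reciprocal_hits(ab, ba, e_hi).pairs)
    assert strict <= lax
    rbh = set(reciprocal_best_hits(ab, ba, e_lo).pairs)
    assert rbh <= set(reciprocal_hits(ab, ba, e_lo).pairs)
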