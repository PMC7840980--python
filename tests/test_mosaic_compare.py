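import random

import pytest

import oracles
from subtelo.mosaic_compare import (
    MosaicString,
    MosaicSymbol,
    classify_end_architecture,
    same_pattern,
    shared_runs,
    to_mosaic_string,
)
from subtelo.seq_core import Interval
from subtelo.shp_segmenter import FLAG_PARTIAL, MosaicAnnotation, Tile


def _string(seq_id, symbols):
    return MosaicString(
        seq_id=seq_id,
        symbols=[MosaicSymbol(lab, var, frozenset()) for lab, var in symbols],
    )


def _random_string(rng, n, alphabet="ABCDE"):
    return _string(
        "s", [(c, f"{c}{rng.randint(1, 2)}")
              for c in (rng.choice(alphabet) for _ in range(n))]
    )


def _ann(seq_id, labels, flags_at=()):
    tiles = []
    pos = 0
    for i, lab in enumerate(labels):
        flags = frozenset({FLAG_PARTIAL}) if i in flags_at else frozenset()
        tiles.append(Tile(Interval(seq_id, pos, pos + 10), lab, f"{lab}1",
                          flags))
        pos += 10
    return MosaicAnnotation(seq_id=seq_id, tiles=tiles)


class TestProjection:
    def test_symbols_follow_tile_order(self):
        ann = _ann("x", ["A", "B", "C"])
        ms = to_mosaic_string(ann)
        assert [s.label for s in ms.symbols] == ["A", "B", "C"]
        assert [s.variant for s in ms.symbols] == ["A1", "B1", "C1"]

    def test_round_trip_order_on_random_annotations(self):
        rng = random.Random(0)
        for _ in range(50):
            labels = [rng.choice("ABCDEF") for _ in range(rng.randint(1, 9))]
            ms = to_mosaic_string(_ann("x", labels))
            assert [s.label for s in ms.symbols] == labels


class TestSharedRuns:
    def test_identical_strings_single_full_run(self):
        a = _string("a", [(c, c + "1") for c in "ABCDEFGHIJ"])
        runs = shared_runs(a, a, "class")
        full = [r for r in runs if r.length == 10]
        assert len(full) == 1
        assert full[0].a_start == 0 and full[0].b_start == 0

    def test_variant_difference_splits_variant_level_runs(self):
        a = _string("a", [("A", "A1"), ("B", "B1"), ("C", "C1")])
        b = _string("b", [("A", "A1"), ("B", "B2"), ("C", "C1")])
        class_runs = shared_runs(a, b, "class")
        assert max(r.length for r in class_runs) == 3
        var_runs = shared_runs(a, b, "variant")
        assert sorted(r.length for r in var_runs) == [1, 1]

    def test_matches_brute_force_enumeration(self):
        rng = random.Random(1)
        for _ in range(200):
            a = _random_string(rng, rng.randint(1, 12))
            b = _random_string(rng, rng.randint(1, 12))
            got = {(r.a_start, r.b_start, r.length)
                   for r in shared_runs(a, b, "variant")}
            expected = oracles.brute_common_runs(
                [s.key("variant") for s in a.symbols],
                [s.key("variant") for s in b.symbols],
            )
            assert got == expected

    def test_symmetry_under_swap(self):
        rng = random.Random(2)
        for _ in range(50):
            a = _random_string(rng, 8)
            b = _random_string(rng, 8)
            ab = {(r.a_start, r.b_start, r.length)
                  for r in shared_runs(a, b, "class")}
            ba = {(r.b_start, r.a_start, r.length)
                  for r in shared_runs(b, a, "class")}
            assert ab == ba

    def test_class_runs_cover_variant_runs(self):
        rng = random.Random(3)
        for _ in range(50):
            a = _random_string(rng, 10)
            b = _random_string(rng, 10)
            cls_cells = set()
            for r in shared_runs(a, b, "class"):
                cls_cells.update(
                    (r.a_start + k, r.b_start + k) for k in range(r.length))
            for r in shared_runs(a, b, "variant"):
                for k in range(r.length):
                    assert (r.a_start + k, r.b_start + k) in cls_cells


class TestSamePattern:
    def test_reflexive(self):
        a = _string("a", [("A", "A1"), ("B", "B2")])
        assert same_pattern(a, a, "class")
        assert same_pattern(a, a, "variant")

    def test_class_equal_variant_different(self):
        a = _string("a", [("C", "C1"), ("D", "D1")])
        b = _string("b", [("C", "C2"), ("D", "D3")])
        assert same_pattern(a, b, "class")
        assert not same_pattern(a, b, "variant")

    def test_equivalence_relation_on_random_strings(self):
        rng = random.Random(4)
        pool = [_random_string(rng, 4, "AB") for _ in range(12)]
        for level in ("class", "variant"):
            for x in pool:
                assert same_pattern(x, x, level)
            for x in pool:
                for y in pool:
                    assert same_pattern(x, y, level) == \
                        same_pattern(y, x, level)
            for x in pool:
                for y in pool:
                    for z in pool:
                        if same_pattern(x, y, level) and \
                                same_pattern(y, z, level):
                            assert same_pattern(x, z, level)


class TestEndArchitecture:
    def test_two_archetypes_two_groups(self):
        anns = [
            _ann("end1", ["A", "B", "C"]),
            _ann("end2", ["F", "G", "C"], flags_at={0}),
        ]
        archs = classify_end_architecture(anns, k=2)
        assert archs["end1"].signature == ("A", "B")
        assert archs["end2"].signature == ("∆F", "G")

    def test_identical_prefixes_one_group(self):
        anns = [_ann(f"e{i}", ["A", "B", "X" if i else "Y"])
                for i in range(4)]
        archs = classify_end_architecture(anns, k=2)
        assert len({a.signature for a in archs.values()}) == 1

    def test_grouping_matches_prefix_oracle(self):
        rng = random.Random(5)
        anns = [
            _ann(f"e{i}", [rng.choice("AB") for _ in range(4)])
            for i in range(12)
        ]
        archs = classify_end_architecture(anns, k=2)
        for ann in anns:
            expected = tuple(t.label for t in ann.tiles[:2])
            assert archs[ann.seq_id].signature == expected
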