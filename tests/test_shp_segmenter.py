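import random

import pytest

from subtelo.seq_core import Interval, SeqRecord
from subtelo.shp_segmenter import (
    FLAG_LOWID,
    FLAG_PARTIAL,
    SegmentClass,
    SegmentParams,
    annotate_mosaic,
    build_segment_library,
    classify_variants,
    decompose_subtype,
    find_shared_segments,
)
from subtelo.synth_data import (
    _is_aperiodic,
    _mutate_substitutions,
    _rand_dna,
    gen_patterns,
    gen_segment_library,
    gen_shp,
)


def _recovered_tiles(ann):
    return [(t.label, t.interval.start, t.interval.end)
            for t in ann.tiles if t.label != "unmatched"]


class TestSharedSegments:
    def test_single_exact_block(self):
        rng = random.Random(0)
        blk = _rand_dna(rng, 100)
        a = SeqRecord("a", _rand_dna(rng, 150) + blk + _rand_dna(rng, 150))
        b = SeqRecord("b", _rand_dna(rng, 80) + blk + _rand_dna(rng, 220))
        hits = find_shared_segments([a, b])
        assert len(hits) == 1
        assert hits[0].n_columns >= 100

    @pytest.mark.parametrize("blk_len,expected", [(49, 0), (50, 1)])
    def test_minimum_length_boundary(self, blk_len, expected):
        # the discovery criterion is a >=50 bp shared stretch
        rng = random.Random(1)
        blk = _rand_dna(rng, blk_len)
        a = SeqRecord("a", _rand_dna(rng, 200) + blk + _rand_dna(rng, 200))
        b = SeqRecord("b", _rand_dna(rng, 120) + blk + _rand_dna(rng, 280))
        hits = [h for h in find_shared_segments([a, b])
                if h.n_columns <= blk_len + 6]
        assert len(hits) == expected

    def test_single_sequence_warns_empty(self):
        rng = random.Random(2)
        with pytest.warns(UserWarning):
            assert find_shared_segments(
                [SeqRecord("a", _rand_dna(rng, 300))]) == []


class TestLibraryRecovery:
    def test_class_count_matches_truth(self, mosaic_case):
        assert len(mosaic_case["library"].classes) == 6

    def test_tile_boundaries_within_tolerance(self, mosaic_case):
        for ann in mosaic_case["annotations"]:
            truth = mosaic_case["mosaic_truth"].mosaics[ann.seq_id]["tiles"]
            rec = _recovered_tiles(ann)
            assert len(rec) == len(truth)
            for (label, s, e), t in zip(rec, truth):
                assert abs(s - t["start"]) <= 5
                assert abs(e - t["end"]) <= 5

    def test_class_labels_bijective_with_truth(self, mosaic_case):
        mapping = {}
        for ann in mosaic_case["annotations"]:
            truth = mosaic_case["mosaic_truth"].mosaics[ann.seq_id]["tiles"]
            for (label, _, _), t in zip(_recovered_tiles(ann), truth):
                mapping.setdefault(label, set()).add(t["label"])
        assert all(len(v) == 1 for v in mapping.values())
        assert len({next(iter(v)) for v in mapping.values()}) == len(mapping)

    def test_noiseless_variant_partition_is_single(self, mosaic_case):
        for c in mosaic_case["library"].classes:
            assert len(c.variants) == 1

    def test_tiling_is_partition(self, mosaic_case):
        for ann, seq in zip(mosaic_case["annotations"],
                            mosaic_case["seqs"]):
            prev = 0
            for t in ann.tiles:
                assert t.interval.start >= prev
                prev = t.interval.end
            assert prev <= len(seq.seq)

    def test_determinism(self, mosaic_case):
        lib2, anns2 = build_segment_library(mosaic_case["seqs"])
        lib1 = mosaic_case["library"]
        assert [(c.label, c.exemplar, c.occurrences, c.variants)
                for c in lib1.classes] == \
            [(c.label, c.exemplar, c.occurrences, c.variants)
             for c in lib2.classes]

    def test_raising_min_len_never_adds_classes(self, mosaic_case):
        lib_strict, _ = build_segment_library(
            mosaic_case["seqs"], SegmentParams(min_seg_len=120,
                                              min_gap_len=14))
        base_big = sum(1 for c in mosaic_case["library"].classes
                       if len(c.exemplar) >= 120)
        strict_big = sum(1 for c in lib_strict.classes
                         if len(c.exemplar) >= 120)
        assert strict_big <= base_big + 1  # boundary jitter tolerance
        assert len(lib_strict.classes) <= len(
            mosaic_case["library"].classes)


def test_gap_pass_finds_short_shared_motif():
    # a 20 bp motif between long segments is below the 50 bp first-pass
    # floor and must be recovered by the 14 bp gap pass
    rng = random.Random(3)
    long1, long2, long3 = (_rand_dna(rng, 300) for _ in range(3))
    motif = _rand_dna(rng, 20)
    seqs = [
        SeqRecord("a", long1 + motif + long2),
        SeqRecord("b", long2 + long1),
        SeqRecord("c", long3 + motif + long1),
    ]
    library, anns = build_segment_library(seqs)
    assert any(14 <= len(c.exemplar) <= 26 for c in library.classes)


class TestVariants:
    def test_identical_occurrences_single_variant(self):
        seg = _rand_dna(random.Random(4), 120)
        seq_map = {"a": seg, "b": seg, "c": seg}
        cls = SegmentClass(
            label="A",
            occurrences=[Interval(k, 0, 120) for k in "abc"],
            exemplar=seg,
        )
        from subtelo.shp_segmenter import SegmentLibrary

        lib = classify_variants(
            SegmentLibrary([cls], SegmentParams()), seq_map)
        assert len(lib.classes[0].variants) == 1

    def test_two_substitutions_two_variants(self):
        rng = random.Random(5)
        seg = _rand_dna(rng, 120)
        mutated, _ = _mutate_substitutions(rng, seg, 2 / 120)
        assert mutated != seg
        seq_map = {"a": seg, "b": mutated}
        cls = SegmentClass(
            label="A",
            occurrences=[Interval("a", 0, 120), Interval("b", 0, 120)],
            exemplar=seg,
        )
        from subtelo.shp_segmenter import SegmentLibrary

        lib = classify_variants(
            SegmentLibrary([cls], SegmentParams()), seq_map)
        assert len(lib.classes[0].variants) == 2

    def test_variant_partition_equals_string_equality(self):
        rng = random.Random(6)
        seg = _rand_dna(rng, 200)
        strings = [_mutate_substitutions(rng, seg, 0.005)[0]
                   for _ in range(8)]
        seq_map = {f"s{i}": s for i, s in enumerate(strings)}
        cls = SegmentClass(
            label="A",
            occurrences=[Interval(f"s{i}", 0, 200) for i in range(8)],
            exemplar=seg,
        )
        from subtelo.shp_segmenter import SegmentLibrary

        lib = classify_variants(
            SegmentLibrary([cls], SegmentParams()), seq_map)
        got = {}
        for iv, var in zip(cls.occurrences,
                           lib.classes[0].variant_by_occurrence):
            got.setdefault(var, set()).add(seq_map[iv.seq_id])
        # each variant holds exactly one distinct string
        assert all(len(v) == 1 for v in got.values())
        assert len(got) == len(set(strings))


class TestSubtypes:
    def test_planted_tandem_copy_numbers(self):
        rng = random.Random(7)
        for trial in range(10):
            while True:
                p = rng.randint(20, 60)
                unit = _rand_dna(rng, p)
                if _is_aperiodic(unit):
                    break
            k1, k2 = rng.randint(2, 8), rng.randint(2, 8)
            seq_map = {"a": unit * k1, "b": unit * k2}
            cls = SegmentClass(
                label="S",
                occurrences=[Interval("a", 0, p * k1),
                             Interval("b", 0, p * k2)],
                exemplar=unit * k1,
            )
            dec = decompose_subtype(cls, seq_map)
            assert dec.period == p
            assert sorted(dec.copy_number_by_occurrence.values()) == \
                sorted([k1, k2])

    def test_divergent_unit_family_accepted_above_floor(self):
        rng = random.Random(8)
        unit = _rand_dna(rng, 40)
        # units at ~0.9 identity to each other: one family above the
        # 0.82 floor
        units = [unit] + [_mutate_substitutions(rng, unit, 0.05)[0]
                          for _ in range(3)]
        occ = "".join(units)
        seq_map = {"a": occ, "b": "".join(units[:2])}
        cls = SegmentClass(
            label="C",
            occurrences=[Interval("a", 0, len(occ)),
                         Interval("b", 0, 80)],
            exemplar=occ,
        )
        dec = decompose_subtype(cls, seq_map)
        assert not dec.is_empty()
        assert dec.period == 40
        assert all(row_v >= 0.82 for row in dec.unit_identity_matrix
                   for row_v in row)

    def test_aperiodic_class_yields_empty_decomposition(self):
        rng = random.Random(9)
        seq_map = {"a": _rand_dna(rng, 200), "b": _rand_dna(rng, 150)}
        cls = SegmentClass(
            label="P",
            occurrences=[Interval("a", 0, 200), Interval("b", 0, 150)],
            exemplar=seq_map["a"],
        )
        assert decompose_subtype(cls, seq_map).is_empty()


class TestAnnotateAgainstLibrary:
    def test_exemplar_is_plain_tile(self, mosaic_case):
        lib = mosaic_case["library"]
        c = max(lib.classes, key=lambda c: len(c.exemplar))
        ann = annotate_mosaic(SeqRecord("probe", c.exemplar), lib)
        tiles = [t for t in ann.tiles if t.label == c.label]
        assert len(tiles) == 1
        assert tiles[0].flags == frozenset()

    def test_truncation_sets_partial_flag(self, mosaic_case):
        lib = mosaic_case["library"]
        c = max(lib.classes, key=lambda c: len(c.exemplar))
        ann = annotate_mosaic(SeqRecord("probe", c.exemplar[:-15]), lib)
        tiles = [t for t in ann.tiles if t.label == c.label]
        assert tiles and FLAG_PARTIAL in tiles[0].flags

    def test_low_identity_sets_question_flag(self, mosaic_case):
        lib = mosaic_case["library"]
        c = max(lib.classes, key=lambda c: len(c.exemplar))
        rng = random.Random(10)
        # gapped identity sits above the substitution rate, so mutate
        # hard enough to land inside the [0.75, 0.90) question band
        mutated, _ = _mutate_substitutions(rng, c.exemplar, 0.16)
        ann = annotate_mosaic(SeqRecord("probe", mutated), lib)
        tiles = [t for t in ann.tiles if t.label == c.label]
        assert tiles and FLAG_LOWID in tiles[0].flags
        assert 0.75 <= tiles[0].identity < 0.90
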