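import random

import pytest

from subtelo.seq_core import Interval, SeqCoreError, SeqRecord, revcomp
from subtelo.shd_blocks import (
    build_block_map,
    call_indels,
    detect_flanking_homology,
    detect_foreign_insertions,
    indel_conservation_check,
    size_class_of,
    total_region_length,
)
from subtelo.shp_segmenter import MosaicAnnotation, Tile
from subtelo.synth_data import (
    _mutate_substitutions,
    _rand_dna,
    gen_shd,
)


@pytest.fixture(scope="module")
def shd_case():
    events = [
        {"kind": "deletion", "pos": 3600, "size": 34},
        {"kind": "insertion", "pos": 7500, "size": 27},
        {"kind": "deletion", "pos": 10500, "size": 26},
        {"kind": "box_deletion", "pos": 16800, "size": 3700,
         "box_len": 300, "box_identity": 0.95},
    ]
    ref, query, blocks, foreign, truth = gen_shd(
        ref_len=30000, n_blocks=8, planted_events=events, seed=2)
    block_hits = build_block_map(query, ref, blocks)
    return {"ref": ref, "query": query, "blocks": blocks,
            "foreign": foreign, "truth": truth, "hits": block_hits}


class TestBlockMap:
    def test_identity_query_maps_all_blocks_forward(self):
        rng = random.Random(0)
        ref = SeqRecord("ref", _rand_dna(rng, 8000))
        blocks = [("I", 0, 4000), ("II", 4000, 8000)]
        hits = build_block_map(ref, ref, blocks)
        assert [h.block_id for h in hits] == ["I", "II"]
        assert all(h.orientation == "forward" and h.identity == 1.0
                   and h.length_delta == 0 for h in hits)

    def test_inverted_block_flagged(self):
        ref, query, blocks, _, truth = gen_shd(
            ref_len=30000, n_blocks=8, seed=2)
        hits = build_block_map(query, ref, blocks)
        inverted = [h.block_id for h in hits if h.orientation == "inverted"]
        assert inverted == [t["block"] for t in truth.distal["inversions"]]

    def test_duplicated_block_reported_twice(self):
        rng = random.Random(1)
        blk = _rand_dna(rng, 900)
        ref = SeqRecord("ref", blk + _rand_dna(rng, 1200))
        query = SeqRecord(
            "q", _rand_dna(rng, 150) + blk + _rand_dna(rng, 400) + blk
            + _rand_dna(rng, 150))
        hits = build_block_map(query, ref, [("I", 0, 900)])
        assert sum(1 for h in hits if h.block_id == "I") == 2

    def test_absent_block_not_reported(self):
        rng = random.Random(2)
        blk1, blk2 = _rand_dna(rng, 800), _rand_dna(rng, 800)
        ref = SeqRecord("ref", blk1 + blk2)
        query = SeqRecord("q", _rand_dna(rng, 200) + blk2
                          + _rand_dna(rng, 200))
        hits = build_block_map(query, ref,
                               [("I", 0, 800), ("II", 800, 1600)])
        assert [h.block_id for h in hits] == ["II"]


class TestIndelCalls:
    def test_identity_case_empty(self):
        rng = random.Random(3)
        x = SeqRecord("x", _rand_dna(rng, 5000))
        assert call_indels(x, x) == []

    def test_planted_small_indels_exact(self, shd_case):
        calls = call_indels(shd_case["query"], shd_case["ref"],
                            blocks=shd_case["blocks"],
                            block_hits=shd_case["hits"])
        small = {(c.kind, c.ref_position, c.size)
                 for c in calls if c.size_class == "small"}
        truth_small = {
            (e["kind"], e["pos"], e["size"])
            for e in shd_case["truth"].distal["events"]
            if 10 <= e["size"] <= 40
        }
        assert small == truth_small

    def test_structural_deletion_size_class(self, shd_case):
        calls = call_indels(shd_case["query"], shd_case["ref"],
                            blocks=shd_case["blocks"],
                            block_hits=shd_case["hits"])
        big = [c for c in calls if c.size_class == "structural"]
        assert len(big) == 1
        assert big[0].kind == "deletion" and big[0].size == 3700

    def test_conservation_of_lengths(self, shd_case):
        calls = call_indels(shd_case["query"], shd_case["ref"],
                            blocks=shd_case["blocks"],
                            block_hits=shd_case["hits"])
        assert indel_conservation_check(calls, shd_case["query"],
                                        shd_case["ref"])

    def test_swap_mirrors_insertions_and_deletions(self):
        rng = random.Random(4)
        events = [{"kind": "deletion", "pos": 2000, "size": 25},
                  {"kind": "insertion", "pos": 5000, "size": 18}]
        ref, query, _, _, _ = gen_shd(ref_len=8000, n_blocks=2,
                                      planted_events=events, seed=4)
        fwd = call_indels(query, ref)
        rev = call_indels(ref, query)
        assert sorted((c.kind, c.size) for c in fwd if c.size >= 10) == \
            sorted(
                ({"insertion": "deletion",
                  "deletion": "insertion"}[c.kind], c.size)
                for c in rev if c.size >= 10)

    def test_size_class_bounds(self):
        assert size_class_of(9) == "micro"
        assert size_class_of(10) == "small"
        assert size_class_of(40) == "small"
        assert size_class_of(41) == "structural"


class TestFlankingHomology:
    def test_box_pair_attached_to_structural_deletion(self, shd_case):
        calls = call_indels(shd_case["query"], shd_case["ref"],
                            blocks=shd_case["blocks"],
                            block_hits=shd_case["hits"])
        big = next(c for c in calls if c.size_class == "structural")
        big = detect_flanking_homology(big, shd_case["query"],
                                       shd_case["ref"])
        assert big.flanking_boxes is not None
        a, _ = big.flanking_boxes
        box = shd_case["truth"].distal["box_deletions"][0]
        # left box straddles the telomere-proximal end of the change
        assert abs(a.query.start - box["pos"]) <= 30
        assert a.identity >= 0.83

    def test_random_flanks_attach_nothing(self):
        rng = random.Random(5)
        events = [{"kind": "deletion", "pos": 4000, "size": 3000}]
        ref, query, _, _, _ = gen_shd(ref_len=12000, n_blocks=2,
                                      planted_events=events, seed=5)
        calls = call_indels(query, ref)
        big = next(c for c in calls if c.size_class == "structural")
        big = detect_flanking_homology(big, query, ref)
        assert big.flanking_boxes is None

    def test_identity_floor_at_0p83(self):
        # a pair at ~0.84 identity must be accepted by the default floor
        events = [{"kind": "box_deletion", "pos": 4000, "size": 2500,
                   "box_len": 250, "box_identity": 0.86}]
        ref, query, _, _, truth = gen_shd(ref_len=12000, n_blocks=2,
                                          planted_events=events, seed=6)
        calls = call_indels(query, ref)
        big = next(c for c in calls if c.size_class == "structural")
        big = detect_flanking_homology(big, query, ref)
        assert big.flanking_boxes is not None


class TestForeignInsertions:
    def test_planted_mitochondrial_fragment_found(self):
        ref, query, blocks, foreign, truth = gen_shd(
            ref_len=30000, n_blocks=8, seed=2)
        fis = detect_foreign_insertions(query, foreign)
        assert any(f.source_label == "mitochondrial-like" for f in fis)
        f = next(f for f in fis if f.source_label == "mitochondrial-like")
        assert len(f.query) >= 380

    def test_no_foreign_sequence_empty(self):
        rng = random.Random(6)
        query = SeqRecord("q", _rand_dna(rng, 5000))
        lib = [SeqRecord("mito", _rand_dna(rng, 2000))]
        assert detect_foreign_insertions(query, lib) == []

    def test_partial_ltr_embed_labelled(self):
        rng = random.Random(7)
        ltr = SeqRecord("ltr", _rand_dna(rng, 500))
        query = SeqRecord("q", _rand_dna(rng, 2000) + ltr.seq[:150]
                          + _rand_dna(rng, 2000))
        fis = detect_foreign_insertions(query, [ltr], min_len=100)
        assert [f.source_label for f in fis] == ["LTR-like"]

    def test_empty_library_warns(self):
        rng = random.Random(8)
        with pytest.warns(UserWarning):
            assert detect_foreign_insertions(
                SeqRecord("q", _rand_dna(rng, 1000)), []) == []


class TestTotalRegionLength:
    def _ann(self, seq_id, start, end):
        return MosaicAnnotation(
            seq_id=seq_id,
            tiles=[Tile(Interval(seq_id, start, end), "A", "A1")])

    def test_span_arithmetic(self):
        from subtelo.shd_blocks import BlockHit

        ann = self._ann("end", 0, 5000)
        hits = [BlockHit("I", Interval("end", 5000, 40000), "forward",
                         1.0, 0)]
        assert total_region_length(ann, hits) == 40000

    def test_disjoint_inputs_error(self):
        from subtelo.shd_blocks import BlockHit

        ann = self._ann("end", 30000, 31000)
        hits = [BlockHit("I", Interval("end", 5000, 20000), "forward",
                         1.0, 0)]
        with pytest.raises(SeqCoreError):
            total_region_length(ann, hits)

    def test_matches_coordinate_recomputation(self):
        from subtelo.shd_blocks import BlockHit

        rng = random.Random(9)
        for _ in range(20):
            s = rng.randint(0, 100)
            mid = rng.randint(2000, 8000)
            end = mid + rng.randint(10000, 40000)
            ann = self._ann("e", s, mid)
            hits = [BlockHit("I", Interval("e", mid, end), "forward",
                             1.0, 0)]
            assert total_region_length(ann, hits) == end - s
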