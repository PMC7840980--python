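import random

import pytest

import oracles
from subtelo.orf_scan import (
    OrfCall,
    diff_coding,
    find_orfs,
    find_upstream_inframe_start,
    insertion_repeat_context,
    kozak_match,
)
from subtelo.seq_core import Interval, SeqCoreError, SeqRecord
from subtelo.synth_data import _rand_dna, gen_tlh


def _rotations(unit):
    return {unit[i:] + unit[:i] for i in range(len(unit))}


class TestFindOrfs:
    def test_minimal_orf(self):
        orfs = find_orfs(SeqRecord("s", "ATGAAATGA"), min_aa=1)
        fwd = [o for o in orfs if o.interval.strand == "+"]
        assert len(fwd) == 1
        assert fwd[0].aa_length == 2
        assert (fwd[0].interval.start, fwd[0].interval.end) == (0, 9)

    def test_no_atg_no_orfs(self):
        orfs = find_orfs(SeqRecord("s", "CCCCCCCCTAACCCCCC"), min_aa=1)
        assert orfs == []

    def test_agrees_with_six_frame_oracle(self):
        rng = random.Random(0)
        for _ in range(6):
            seq = _rand_dna(rng, 10000)
            got = {
                (o.interval.start, o.interval.end, o.interval.strand)
                for o in find_orfs(SeqRecord("s", seq), min_aa=25)
            }
            assert got == oracles.six_frame_orfs(seq, 25)


class TestUpstreamStart:
    def test_planted_543_base_upstream_start(self):
        ref, _, truth = gen_tlh(seed=1)
        rep = find_upstream_inframe_start(ref, truth.coding["dM"])
        far = rep.candidates[-1]
        assert far.distance_bp == 543
        assert far.distance_codons == 181
        assert far.kozak
        assert rep.chosen.distance_bp == 543

    def test_stop_barrier_limits_scan(self):
        # in-frame stop 30 bases upstream: no candidate beyond it
        seq = ("G" * 60 + "TAA" + "GCAATGGCA" * 3 + "ATG" + "GGC" * 20
               + "TAA")
        start = 60 + 3 + 27
        rep = find_upstream_inframe_start(SeqRecord("s", seq), start)
        assert all(c.distance_bp <= 30 for c in rep.candidates)

    def test_distance_codons_always_thirds(self):
        rng = random.Random(1)
        checked = 0
        for _ in range(100):
            seq = _rand_dna(rng, 2000)
            starts = [i for i in range(900, 1100)
                      if seq[i:i + 3] == "ATG"]
            if not starts:
                continue
            rep = find_upstream_inframe_start(SeqRecord("s", seq),
                                              starts[0])
            for c in rep.candidates:
                assert c.distance_bp % 3 == 0
                assert c.distance_codons == c.distance_bp // 3
            checked += 1
        assert checked > 30

    def test_agrees_with_brute_force_scan(self):
        rng = random.Random(2)
        for _ in range(40):
            seq = _rand_dna(rng, 1500)
            starts = [i for i in range(600, 900) if seq[i:i + 3] == "ATG"]
            if not starts:
                continue
            a = starts[0]
            rep = find_upstream_inframe_start(SeqRecord("s", seq), a)
            expected = []
            p = a - 3
            while p >= 0:
                codon = seq[p:p + 3]
                if codon in {"TAA", "TAG", "TGA"}:
                    break
                if codon == "ATG":
                    expected.append(a - p)
                p -= 3
            assert [c.distance_bp for c in rep.candidates] == expected


class TestKozak:
    @pytest.mark.parametrize(
        "context,expected",
        [("GCCATGG", True), ("ACCATGG", True), ("TCCATGG", False),
         ("CCCATGG", False), ("GCCATGA", False), ("GCCATGC", False),
         ("ANNATGG", False)],
    )
    def test_consensus_rule(self, context, expected):
        if "N" in context:
            with pytest.warns(UserWarning):
                assert kozak_match(context) is expected
        else:
            assert kozak_match(context) is expected

    def test_rule_on_random_contexts(self):
        rng = random.Random(3)
        for _ in range(200):
            ctx = _rand_dna(rng, 3) + "ATG" + rng.choice("ACGT")
            assert kozak_match(ctx) == (ctx[0] in "AG" and ctx[6] == "G")


class TestDiffCoding:
    def _orf_call(self, truth, ref):
        c = truth.coding
        return OrfCall(
            interval=Interval(ref.id, c["orf_start"], c["orf_end"]),
            frame=c["orf_start"] % 3,
            aa_length=(c["orf_end"] - c["orf_start"]) // 3 - 1,
        )

    def test_identical_loci_empty_ledger(self):
        ref, _, truth = gen_tlh(seed=2)
        diff = diff_coding(ref, ref, self._orf_call(truth, ref))
        assert diff.events == []
        assert not diff.frame_shift and not diff.premature_stop

    def test_planted_inframe_events_recovered(self):
        ref, query, truth = gen_tlh(seed=3)
        diff = diff_coding(query, ref, self._orf_call(truth, ref))
        indels = sorted((e.kind, e.size) for e in diff.events
                        if e.kind != "point")
        assert indels == [("deletion", 6), ("insertion", 6),
                          ("insertion", 18)]
        assert sum(1 for e in diff.events if e.kind == "point") == 5
        assert not diff.frame_shift
        assert not diff.premature_stop
        contexts = {e.size: e.repeat_context for e in diff.events
                    if e.kind == "insertion"}
        assert contexts[6] in _rotations("ATGACA")
        assert contexts[18] in _rotations("CGACAA")

    def test_seven_bp_insertion_shifts_frame(self):
        ref, query, truth = gen_tlh(
            seed=4, events=[{"kind": "insertion", "codon": 50, "size": 7}])
        diff = diff_coding(query, ref, self._orf_call(truth, ref))
        assert diff.frame_shift
        assert diff.premature_stop  # a shifted frame hits a stop quickly

    def test_frame_shift_agrees_with_translation_oracle(self):
        for seed, events in [
            (5, [{"kind": "insertion", "codon": 40, "size": 6}]),
            (6, [{"kind": "insertion", "codon": 40, "size": 7}]),
            (7, [{"kind": "deletion", "codon": 60, "size": 6}]),
            (8, [{"kind": "deletion", "codon": 60, "size": 5}]),
        ]:
            ref, query, truth = gen_tlh(seed=seed, events=events)
            diff = diff_coding(query, ref, self._orf_call(truth, ref))
            net = sum(e["size"] if e["kind"] == "insertion"
                      else -e["size"]
                      for e in truth.coding["events"])
            assert diff.frame_shift == bool(net % 3)
            # translation oracle: premature stop iff translating the
            # query from its start codon stops before the expected end
            c = truth.coding
            q_orf_start = c["orf_start"]
            # an in-frame net indel moves the stop by net/3 codons
            expected_aa = c["orf_len_aa"] + (net // 3 if net % 3 == 0
                                             else 0)
            coding = query.seq[q_orf_start:]
            assert diff.premature_stop == oracles.translate_premature(
                coding, expected_aa)


class TestInsertionRepeatContext:
    def test_six_bp_unit_at_tandem_site(self):
        ref = "CCCCC" + "ATGACA" * 2 + "GGGGG"
        assert insertion_repeat_context(ref, 5, "ATGACA") == "ATGACA"

    def test_three_unit_insertion_at_tandem_site(self):
        ref = "CCCCC" + "CGACAA" * 2 + "GGGGG"
        assert insertion_repeat_context(
            ref, 11, "CGACAACGACAACGACAA") == "CGACAA"

    def test_random_context_returns_none(self):
        rng = random.Random(9)
        ref = _rand_dna(rng, 100)
        assert insertion_repeat_context(ref, 50, "GATTACA") is None

    def test_requires_two_adjacent_reference_copies(self):
        ref = "CCCCC" + "ATGACA" + "GGGGG"  # single copy only
        assert insertion_repeat_context(ref, 5, "ATGACA") is None
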