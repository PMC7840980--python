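import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from subtelo.seq_core import (
    AlignmentHit,
    Interval,
    SeqCoreError,
    SeqRecord,
    edits_stats,
    global_align,
    local_align,
    percent_identity,
    read_fasta,
    revcomp,
    sw_align,
    write_fasta,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)


def _rand(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def _mutate(rng, s, rate):
    return "".join(
        rng.choice([b for b in "ACGT" if b != c]) if rng.random() < rate
        else c
        for c in s
    )


class TestFasta:
    def test_minimal_record(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nACGT\n")
        (rec,) = read_fasta(p)
        assert rec.id == "a" and rec.seq == "ACGT"

    def test_round_trip_identity(self, tmp_path):
        rng = random.Random(0)
        recs = [SeqRecord(f"r{i}", _rand(rng, 1000), f"desc {i}")
                for i in range(10)]
        p = tmp_path / "x.fasta"
        write_fasta(recs, p)
        back = read_fasta(p)
        assert [(r.id, r.seq) for r in back] == \
            [(r.id, r.seq) for r in recs]
        # independent line-by-line parse agrees on lengths
        lengths, cur = {}, None
        for line in p.read_text().splitlines():
            if line.startswith(">"):
                cur = line[1:].split()[0]
                lengths[cur] = 0
            else:
                lengths[cur] += len(line.strip())
        assert lengths == {r.id: len(r.seq) for r in recs}

    @pytest.mark.parametrize(
        "content,match",
        [("", "no FASTA"), (">a\nACGU\n", "non-DNA"),
         (">a\nACGT\n>a\nTTTT\n", "duplicate")],
    )
    def test_errors(self, tmp_path, content, match):
        p = tmp_path / "bad.fasta"
        p.write_text(content)
        with pytest.raises(SeqCoreError, match=match):
            read_fasta(p)

    def test_fastq_sniffed_and_qualities_ignored(self, tmp_path):
        from subtelo.seq_core import read_sequences

        p = tmp_path / "r.fastq"
        p.write_text("@r1\nACGT\n+\nIIII\n@r2\nGGTTAC\n+\nIIIIII\n")
        assert [(r.id, r.seq) for r in read_sequences(p)] == \
            [("r1", "ACGT"), ("r2", "GGTTAC")]


class TestGlobalAlign:
    def test_identical(self):
        hit = global_align("ACGTACGT", "ACGTACGT")
        assert hit.identity == 1.0 and set(hit.edits) == {"="}

    def test_single_mismatch(self):
        hit = global_align("ACGT", "AGGT")
        assert hit.identity == 0.75
        assert hit.edits.count("X") == 1

    def test_matches_edit_distance_oracle(self):
        rng = random.Random(1)
        for _ in range(40):
            a = _rand(rng, rng.randint(50, 300))
            b = _mutate(rng, a, 0.05)
            hit = global_align(a, b)
            dist = oracles.levenshtein(a, b)
            assert hit.n_columns - hit.edits.count("=") == dist


class TestLocalAlign:
    def test_self_alignment_full_length(self):
        rng = random.Random(2)
        rec = SeqRecord("s", _rand(rng, 500))
        hits = local_align(rec, rec, min_len=400, min_identity=0.99)
        best = max(hits, key=lambda h: h.score)
        assert best.identity == 1.0
        assert len(best.query) == 500 and len(best.subject) == 500

    def test_planted_exact_substring(self):
        rng = random.Random(3)
        seg = _rand(rng, 60)
        a = SeqRecord("a", _rand(rng, 70) + seg + _rand(rng, 70))
        b = SeqRecord("b", _rand(rng, 40) + seg + _rand(rng, 100))
        hits = local_align(a, b, min_len=50, min_identity=0.9)
        assert any(
            h.identity >= (60 - 2) / 62  # allow tiny chance extension
            and abs(h.query.start - 70) <= 3 and abs(h.query.end - 130) <= 3
            for h in hits
        )

    def test_identity_matches_dp_oracle(self):
        rng = random.Random(4)
        for _ in range(15):
            seg = _rand(rng, 80)
            a = SeqRecord("a", _rand(rng, 110) + seg
                          + _rand(rng, 110))
            b = SeqRecord("b", _rand(rng, 60) + _mutate(rng, seg, 0.03)
                          + _rand(rng, 140))
            hits = local_align(a, b, min_len=40, min_identity=0.5,
                               inclusive_identity=True)
            best = max(hits, key=lambda h: h.score)
            score, ident = oracles.sw_score_and_identity(a.seq, b.seq)
            assert best.score == score
            assert abs(best.identity - ident) <= 0.001

    def test_reverse_strand_hit(self):
        rng = random.Random(5)
        seg = _rand(rng, 80)
        a = SeqRecord("a", _rand(rng, 50) + seg + _rand(rng, 50))
        b = SeqRecord("b", _rand(rng, 30) + revcomp(seg) + _rand(rng, 30))
        hits = local_align(a, b, min_len=60, min_identity=0.9)
        assert any(h.subject.strand == "-" for h in hits)

    def test_strand_symmetry(self):
        rng = random.Random(6)
        seg = _rand(rng, 70)
        a = SeqRecord("a", _rand(rng, 40) + seg + _rand(rng, 40))
        b = SeqRecord("b", _rand(rng, 40) + _mutate(rng, seg, 0.02)
                      + _rand(rng, 40))
        fwd = local_align(a, b, min_len=50, min_identity=0.8)
        rev = local_align(a.reverse_complement(), b.reverse_complement(),
                          min_len=50, min_identity=0.8)
        assert sorted((h.identity, h.n_columns) for h in fwd) == \
            sorted((h.identity, h.n_columns) for h in rev)


class TestPercentIdentity:
    def _hit(self, edits):
        q = sum(1 for c in edits if c in "=XI")
        s = sum(1 for c in edits if c in "=XD")
        return AlignmentHit(
            query=Interval("q", 0, q),
            subject=Interval("s", 0, s),
            identity=edits.count("=") / len(edits),
            n_columns=len(edits),
            score=0,
            edits=edits,
        )

    def test_all_match(self):
        assert percent_identity(self._hit("=" * 100)) == 1.0

    def test_mixed_columns(self):
        # 95 matches, 3 mismatches, 2 gap columns -> 0.95
        assert percent_identity(self._hit("=" * 95 + "XXX" + "ID")) == 0.95

    def test_recount_matches_stored_identity(self):
        rng = random.Random(7)
        for _ in range(200):
            edits = "".join(rng.choices("=XID", weights=[20, 2, 1, 1],
                                        k=rng.randint(10, 120)))
            hit = self._hit(edits)
            assert percent_identity(hit) == pytest.approx(hit.identity)

    def test_invariant_under_edit_reversal(self):
        rng = random.Random(8)
        for _ in range(50):
            edits = "".join(rng.choices("=XID", weights=[20, 2, 1, 1], k=60))
            assert edits_stats(edits)[1] == edits_stats(edits[::-1])[1]


@given(dna)
@settings(max_examples=50, deadline=None)
def test_revcomp_involution(s):
    assert revcomp(revcomp(s)) == s


@given(dna, dna)
@settings(max_examples=25, deadline=None)
def test_global_distance_strand_symmetric(a, b):
    # the optimal edit distance is strand-symmetric (identity can vary
    # slightly between co-optimal alignments, distance cannot)
    fwd = global_align(a, b)
    rev = global_align(revcomp(a), revcomp(b))
    assert fwd.n_columns - fwd.edits.count("=") == \
        rev.n_columns - rev.edits.count("=")


def test_hit_swap_preserves_identity_and_columns():
    rng = random.Random(9)
    seg = _rand(rng, 60)
    a = SeqRecord("a", _rand(rng, 30) + seg + _rand(rng, 30))
    b = SeqRecord("b", _rand(rng, 20) + _mutate(rng, seg, 0.03)
                  + _rand(rng, 40))
    for h in local_align(a, b, min_len=40, min_identity=0.7,
                         inclusive_identity=True):
        s = h.swapped()
        assert s.identity == h.identity
        assert s.n_columns == h.n_columns
        assert s.query == h.subject.__class__(h.subject.seq_id,
                                              h.subject.start,
                                              h.subject.end, "+")
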