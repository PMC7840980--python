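"""Sequence records, intervals and pairwise-alignment primitives.

Everything downstream (segment discovery, block maps, indel calls, ORF
diffs, read consensus) is built on the three types defined here:

* :class:`SeqRecord` — a named DNA sequence over ``{A,C,G,T,N}``.
* :class:`Interval` — a 0-based half-open stranded span on a sequence.
  Reports convert to 1-based inclusive coordinates to match genome-database
  conventions.
* :class:`AlignmentHit` — a pairwise alignment between two intervals with a
  per-column edit string over ``=`` (match), ``X`` (mismatch), ``I``
  (column consuming query only) and ``D`` (column consuming subject only).

Identity is defined throughout as matched columns divided by *all*
alignment columns, gap columns included — the convention of the blastn
tool family, whose thresholds (>95 % for shared segments, >90 % for
blocks) this package inherits.

Local alignment uses exact affine-gap Smith–Waterman on small inputs and
k-mer seeding with windowed Smith–Waterman refinement on large ones;
global alignment uses edit-distance alignment (edlib) and reports the
resulting column-wise identity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Smith-Waterman scoring defaults, matching the blastn gap-cost regime
# (existence 5, extension 2). Gap extension must be expensive enough that
# a local alignment cannot profitably bridge two shared segments across an
# unrelated insertion; cheap extensions merge mosaic tiles.
MATCH = 1
MISMATCH = -2
GAP_OPEN = -5  # cost of the first gap column
GAP_EXTEND = -2


class SeqCoreError(ValueError):
    pass


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeqRecord:
    """A DNA sequence with an identifier.

    By convention all subtelomeric sequences are stored telomere-left
    (telomere at position 0, centromere-proximal end last).
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise SeqCoreError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.seq) if c in bad)
            raise SeqCoreError(
                f"record {self.id!r}: non-DNA character {self.seq[pos]!r} "
                f"at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self, new_id: str | None = None) -> "SeqRecord":
        return SeqRecord(new_id or self.id, revcomp(self.seq), self.description)


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open span on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise SeqCoreError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end}"
            )
        if self.strand not in "+-":
            raise SeqCoreError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def start1(self) -> int:
        """1-based inclusive start for reports."""
        return self.start + 1

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class AlignmentHit:
    """A pairwise alignment between a query and a subject interval.

    ``edits`` is one character per alignment column: ``=`` match, ``X``
    mismatch, ``I`` query-only column, ``D`` subject-only column. A
    subject strand of ``-`` means the query aligns to the reverse
    complement of the subject span; subject coordinates stay forward.
    """

    query: Interval
    subject: Interval
    identity: float
    n_columns: int
    score: float
    edits: str

    def __post_init__(self) -> None:
        if self.n_columns != len(self.edits):
            raise SeqCoreError("n_columns inconsistent with edit string")
        q_cols = sum(1 for c in self.edits if c in "=XI")
        s_cols = sum(1 for c in self.edits if c in "=XD")
        if q_cols != len(self.query) or s_cols != len(self.subject):
            raise SeqCoreError("edit string inconsistent with intervals")
        if not (0.0 <= self.identity <= 1.0):
            raise SeqCoreError("identity outside [0, 1]")

    def swapped(self) -> "AlignmentHit":
        """The same alignment seen from the subject's side."""
        edits = self.edits.translate(str.maketrans("ID", "DI"))
        if self.subject.strand == "-":
            edits = edits[::-1]
        return AlignmentHit(
            query=replace(self.subject, strand="+"),
            subject=replace(self.query, strand=self.subject.strand),
            identity=self.identity,
            n_columns=self.n_columns,
            score=self.score,
            edits=edits,
        )


def percent_identity(hit: AlignmentHit) -> float:
    """Matched columns / all columns (gap columns included)."""
    if hit.n_columns == 0:
        raise SeqCoreError("zero-column hit has no identity")
    return hit.edits.count("=") / hit.n_columns


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a multi-record FASTA into :class:`SeqRecord` objects.

    Sequences are uppercased; ``U`` and other non-DNA characters are
    rejected with their position; duplicate ids are an error.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqCoreError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SeqRecord(rec.id, str(rec.seq).upper(), desc))
    if not records:
        raise SeqCoreError(f"no FASTA records in {path}")
    return records


def read_sequences(path: str | Path) -> list[SeqRecord]:
    """Read FASTA or FASTQ (sniffed from the first byte; FASTQ
    qualities are ignored)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        records = []
        seen: set[str] = set()
        for rec in SeqIO.parse(str(path), "fastq"):
            if rec.id in seen:
                raise SeqCoreError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)
            records.append(SeqRecord(rec.id, str(rec.seq).upper()))
        if not records:
            raise SeqCoreError(f"no FASTQ records in {path}")
        return records
    return read_fasta(path)


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> None:
    """Write records as 60-column-wrapped FASTA."""
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# Edit-string helpers
# ---------------------------------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


def expand_cigar(cigar: str) -> str:
    """Expand an extended cigar (``3=1X2D``) to one char per column."""
    return "".join(op * int(n) for n, op in _CIGAR_RE.findall(cigar))


def edits_stats(edits: str) -> tuple[int, float]:
    n = len(edits)
    if n == 0:
        raise SeqCoreError("empty edit string")
    return n, edits.count("=") / n


def score_edits(
    edits: str,
    match: int = MATCH,
    mismatch: int = MISMATCH,
    gap_open: int = GAP_OPEN,
    gap_extend: int = GAP_EXTEND,
) -> int:
    """Affine-gap score of an edit string."""
    score = 0
    prev = ""
    for c in edits:
        if c == "=":
            score += match
        elif c == "X":
            score += mismatch
        else:
            score += gap_extend if c == prev else gap_open
        prev = c
    return score


# ---------------------------------------------------------------------------
# Global alignment
# ---------------------------------------------------------------------------

def global_align(a: SeqRecord | str, b: SeqRecord | str) -> AlignmentHit:
    """End-to-end alignment of two sequences.

    Uses edit-distance-optimal alignment; identity is matched columns over
    all columns of that alignment. The edit string covers both sequences
    fully.
    """
    a_id, a_seq = (a.id, a.seq) if isinstance(a, SeqRecord) else ("query", a)
    b_id, b_seq = (b.id, b.seq) if isinstance(b, SeqRecord) else ("subject", b)
    if not a_seq or not b_seq:
        raise SeqCoreError("global_align requires non-empty sequences")
    res = edlib.align(a_seq, b_seq, mode="NW", task="path")
    edits = expand_cigar(res["cigar"])
    n, ident = edits_stats(edits)
    return AlignmentHit(
        query=Interval(a_id, 0, len(a_seq)),
        subject=Interval(b_id, 0, len(b_seq)),
        identity=ident,
        n_columns=n,
        score=score_edits(edits),
        edits=edits,
    )


# ---------------------------------------------------------------------------
# Affine-gap Smith-Waterman (exact local alignment)
# ---------------------------------------------------------------------------

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_CODE[c] for c in seq), dtype=np.int8, count=len(seq))


def sw_align(
    a: str,
    b: str,
    match: int = MATCH,
    mismatch: int = MISMATCH,
    gap_open: int = GAP_OPEN,
    gap_extend: int = GAP_EXTEND,
) -> tuple[int, int, int, int, int, str] | None:
    """Best local alignment of ``a`` vs ``b`` under affine-gap scoring.

    Returns ``(score, a_start, a_end, b_start, b_end, edits)`` or ``None``
    if no positive-scoring alignment exists. Exact (full dynamic
    programming, anti-diagonal vectorised); quadratic memory, intended for
    inputs up to a few kb. ``N`` never matches anything.
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return None
    ea, eb = _encode(a), _encode(b)
    NEG = np.int32(-(10 ** 8))
    H = np.full((n + 1, m + 1), 0, dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in a (consumes b)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in b (consumes a)
    # anti-diagonal sweep: cells (i, j) with i + j = d
    for d in range(2, n + m + 1):
        lo = max(1, d - m)
        hi = min(n, d - 1)
        if lo > hi:
            continue
        i = np.arange(lo, hi + 1)
        j = d - i
        sub = np.where(
            (ea[i - 1] == eb[j - 1]) & (ea[i - 1] != 4), match, mismatch
        ).astype(np.int32)
        E[i, j] = np.maximum(H[i, j - 1] + gap_open, E[i, j - 1] + gap_extend)
        F[i, j] = np.maximum(H[i - 1, j] + gap_open, F[i - 1, j] + gap_extend)
        H[i, j] = np.maximum.reduce(
            [np.zeros_like(sub), H[i - 1, j - 1] + sub, E[i, j], F[i, j]]
        )
    best = int(H.max())
    if best <= 0:
        return None
    # deterministic tie-break: smallest i, then smallest j
    flat = int(np.flatnonzero(H == best)[0])
    bi, bj = divmod(flat, m + 1)
    # traceback
    ops: list[str] = []
    i, j = bi, bj
    state = "H"
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            sub = match if (ea[i - 1] == eb[j - 1] and ea[i - 1] != 4) else mismatch
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + sub:
                ops.append("=" if sub == match else "X")
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            ops.append("D")  # column consumes b only
            if E[i, j] == H[i, j - 1] + gap_open:
                state = "H"
            j -= 1
        else:
            ops.append("I")  # column consumes a only
            if F[i, j] == H[i - 1, j] + gap_open:
                state = "H"
            i -= 1
    edits = "".join(reversed(ops))
    return best, i, bi, j, bj, edits


_MAX_HIT_GAP = 10  # a gap run longer than this splits a local hit


def _low_identity_runs(
    edits: str, window: int = 40, min_window_id: float = 0.75
) -> list[tuple[int, int]]:
    """Maximal runs of columns whose centred window identity falls below
    ``min_window_id``."""
    n = len(edits)
    if n < window:
        return []
    is_match = np.frombuffer(edits.encode(), dtype=np.uint8) == ord("=")
    csum = np.concatenate([[0], np.cumsum(is_match)])
    half = window // 2
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half, n)
    wid = (csum[hi] - csum[lo]) / (hi - lo)
    bad = wid < min_window_id
    runs = []
    i = 0
    while i < n:
        if bad[i]:
            j = i
            while j < n and bad[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _split_local_hit(
    res: tuple[int, int, int, int, int, str], max_gap: int = _MAX_HIT_GAP
) -> list[tuple[int, int, int, int, int, str]]:
    """See docstring below; ``max_gap`` > 40 also disables the
    windowed-identity split (large tolerated gaps imply block-scale
    alignment where local identity dips are expected)."""
    return _split_local_hit_impl(res, max_gap)


def _split_local_hit_impl(
    res: tuple[int, int, int, int, int, str], max_gap: int = _MAX_HIT_GAP
) -> list[tuple[int, int, int, int, int, str]]:
    """Split a local alignment at gap runs longer than ``max_gap``.

    A high-scoring alignment can bridge two genuinely shared segments
    across an unrelated insertion whenever the gap cost is below the
    bridged segment's score; such merged hits fail per-segment identity
    thresholds. Each returned piece is end-trimmed to match columns and
    rescored.
    """
    _, qs, qe, ss, se, edits = res
    breaks = [
        (m.start(), m.end())
        for m in re.finditer("I{%d,}|D{%d,}" % (max_gap + 1, max_gap + 1),
                             edits)
    ]
    # low-identity stretches (an unrelated region aligned as ~50 % "mush"
    # instead of one long gap) also split the hit
    if max_gap <= 40:
        breaks.extend(_low_identity_runs(edits))
    breaks.sort()
    merged_breaks: list[tuple[int, int]] = []
    for b in breaks:
        if merged_breaks and b[0] <= merged_breaks[-1][1]:
            merged_breaks[-1] = (merged_breaks[-1][0],
                                 max(merged_breaks[-1][1], b[1]))
        else:
            merged_breaks.append(b)
    breaks = merged_breaks
    if not breaks:
        return [res]
    bounds = []
    last = 0
    for b0, b1 in breaks:
        bounds.append((last, b0))
        last = b1
    bounds.append((last, len(edits)))
    # per-column offsets
    qoff, soff = [], []
    q = s = 0
    for op in edits:
        qoff.append(q)
        soff.append(s)
        q += op in "=XI"
        s += op in "=XD"
    qoff.append(q)
    soff.append(s)
    pieces = []
    for k0, k1 in bounds:
        sub = edits[k0:k1]
        lead = len(sub) - len(sub.lstrip("XID"))
        tail = len(sub) - len(sub.rstrip("XID"))
        k0 += lead
        sub = sub[lead:len(sub) - tail or None]
        if not sub:
            continue
        k1 = k0 + len(sub)
        pieces.append((
            score_edits(sub),
            qs + qoff[k0], qs + qoff[k1],
            ss + soff[k0], ss + soff[k1],
            sub,
        ))
    return pieces


def _sw_all_hits(
    a: str,
    b: str,
    min_len: int,
    min_identity: float,
    max_hits: int = 64,
    inclusive_identity: bool = False,
    max_gap: int = _MAX_HIT_GAP,
) -> list[tuple[int, int, int, int, int, str]]:
    """All disjoint positive local alignments, best first, by iterated
    masking of the query span of each accepted hit."""
    hits = []
    cur = a
    min_score = min_len * MATCH + GAP_OPEN  # permissive floor for iteration
    for _ in range(max_hits):
        res = sw_align(cur, b)
        if res is None or res[0] < min_score:
            break
        score, qs, qe, ss, se, edits = res
        for piece in _split_local_hit(res, max_gap):
            p_edits = piece[5]
            _, ident = edits_stats(p_edits)
            ok = (ident >= min_identity if inclusive_identity
                  else ident > min_identity)
            if len(p_edits) >= min_len and ok:
                hits.append(piece)
        cur = cur[:qs] + "N" * (qe - qs) + cur[qe:]
        if qe - qs == 0:
            break
    return hits


# ---------------------------------------------------------------------------
# Seeded local alignment for large sequences
# ---------------------------------------------------------------------------

def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        idx.setdefault(kmer, []).append(i)
    return idx


def _seed_chains(
    a: str, b: str, k: int = 12, band: int = 40, max_gap: int = 80
) -> list[tuple[int, int, int, int]]:
    """Chain exact k-mer matches into candidate regions.

    Returns ``(a_start, a_end, b_start, b_end)`` bounding boxes of chains
    of seeds on nearby diagonals. Deterministic.
    """
    idx = _kmer_index(b, k)
    seeds: list[tuple[int, int]] = []  # (a_pos, b_pos)
    for i in range(len(a) - k + 1):
        kmer = a[i : i + k]
        if "N" in kmer:
            continue
        for j in idx.get(kmer, ()):
            seeds.append((i, j))
    if not seeds:
        return []
    # sort by diagonal then a-position; greedy chain
    seeds.sort(key=lambda s: (s[0] - s[1], s[0]))
    chains: list[list[tuple[int, int]]] = []
    for s in seeds:
        placed = False
        for ch in reversed(chains[-50:]):
            last = ch[-1]
            if (
                abs((s[0] - s[1]) - (last[0] - last[1])) <= band
                and 0 <= s[0] - last[0] <= max_gap + k
                and s[1] >= last[1] - band
            ):
                ch.append(s)
                placed = True
                break
        if not placed:
            chains.append([s])
    boxes = []
    for ch in chains:
        a0 = min(s[0] for s in ch)
        a1 = max(s[0] for s in ch) + k
        b0 = min(s[1] for s in ch)
        b1 = max(s[1] for s in ch) + k
        if a1 - a0 >= k:
            boxes.append((a0, a1, b0, b1))
    # merge overlapping boxes (same region found by several chains)
    boxes.sort()
    merged: list[list[int]] = []
    for box in boxes:
        if merged and box[0] <= merged[-1][1] and not (
            box[3] < merged[-1][2] - band or box[2] > merged[-1][3] + band
        ):
            merged[-1][1] = max(merged[-1][1], box[1])
            merged[-1][2] = min(merged[-1][2], box[2])
            merged[-1][3] = max(merged[-1][3], box[3])
        else:
            merged.append(list(box))
    return [tuple(m) for m in merged]


_SW_EXACT_LIMIT = 2048  # full DP below this size; seeded above


def _span_overlap(a0: int, a1: int, b0: int, b1: int) -> float:
    """Reciprocal overlap fraction of two spans."""
    ov = min(a1, b1) - max(a0, b0)
    if ov <= 0:
        return 0.0
    return ov / max(a1 - a0, b1 - b0)


def _local_align_oriented(
    a_seq: str, b_seq: str, min_len: int, min_identity: float,
    inclusive_identity: bool, max_gap: int = _MAX_HIT_GAP,
) -> list[tuple[int, int, int, int, int, str]]:
    if len(a_seq) <= _SW_EXACT_LIMIT and len(b_seq) <= _SW_EXACT_LIMIT:
        # iterative masking is one-sided: a single query region matching
        # two subject locations yields only one hit per direction, so
        # search both directions and merge
        fwd = _sw_all_hits(a_seq, b_seq, min_len, min_identity,
                           inclusive_identity=inclusive_identity,
                           max_gap=max_gap)
        swap_tr = str.maketrans("ID", "DI")
        rev = [
            (sc, ss, se, qs, qe, ed.translate(swap_tr))
            for sc, qs, qe, ss, se, ed in _sw_all_hits(
                b_seq, a_seq, min_len, min_identity,
                inclusive_identity=inclusive_identity, max_gap=max_gap)
        ]
        merged = list(fwd)
        for h in rev:
            dup = any(
                _span_overlap(h[1], h[2], k[1], k[2]) >= 0.8
                and _span_overlap(h[3], h[4], k[3], k[4]) >= 0.8
                for k in merged
            )
            if not dup:
                merged.append(h)
        return merged
    pad = 32
    raw: list[tuple[int, int, int, int, int, str]] = []
    chain_gap = max(80, max_gap)
    for a0, a1, b0, b1 in _seed_chains(a_seq, b_seq, band=max(40, max_gap),
                                       max_gap=chain_gap):
        if a1 - a0 < min_len - pad:
            continue
        qa0, qa1 = max(0, a0 - pad), min(len(a_seq), a1 + pad)
        sb0, sb1 = max(0, b0 - pad), min(len(b_seq), b1 + pad)
        res = sw_align(a_seq[qa0:qa1], b_seq[sb0:sb1])
        if res is None:
            continue
        for score, qs, qe, ss, se, edits in _split_local_hit(res, max_gap):
            _, ident = edits_stats(edits)
            ok = (ident >= min_identity if inclusive_identity
                  else ident > min_identity)
            if len(edits) >= min_len and ok:
                raw.append(
                    (score, qa0 + qs, qa0 + qe, sb0 + ss, sb0 + se, edits)
                )
    # drop hits nested in a better hit (same pair of regions seen twice)
    raw.sort(key=lambda h: (-h[0], h[1], h[3]))
    kept: list[tuple[int, int, int, int, int, str]] = []
    for h in raw:
        dominated = any(
            h[1] >= k[1] and h[2] <= k[2] and h[3] >= k[3] and h[4] <= k[4]
            for k in kept
        )
        if not dominated:
            kept.append(h)
    return kept


def local_align(
    a: SeqRecord,
    b: SeqRecord,
    min_len: int = 50,
    min_identity: float = 0.95,
    inclusive_identity: bool = False,
    max_gap: int = _MAX_HIT_GAP,
) -> list[AlignmentHit]:
    """All local alignments of ``a`` vs ``b`` on both strands passing the
    length and identity thresholds.

    Identity is compared strictly (``>``) by default, matching the
    criteria phrasing ">95 % identity"; set ``inclusive_identity`` for
    "no less than" semantics. Hits are reported sorted by query position;
    overlapping hits are allowed. Exact full dynamic programming is used
    when both sequences are at most ~2 kb, k-mer seeding with windowed
    exact refinement above that.
    """
    if min_len < 1:
        raise SeqCoreError("min_len must be >= 1")
    if not (0.0 < min_identity <= 1.0):
        raise SeqCoreError("min_identity must be in (0, 1]")
    hits: list[AlignmentHit] = []
    for strand, b_seq in (("+", b.seq), ("-", revcomp(b.seq))):
        for score, qs, qe, ss, se, edits in _local_align_oriented(
            a.seq, b_seq, min_len, min_identity, inclusive_identity, max_gap
        ):
            if strand == "-":
                ss, se = len(b.seq) - se, len(b.seq) - ss
            n, ident = edits_stats(edits)
            hits.append(
                AlignmentHit(
                    query=Interval(a.id, qs, qe),
                    subject=Interval(b.id, ss, se, strand),
                    identity=ident,
                    n_columns=n,
                    score=score,
                    edits=edits,
                )
            )
    hits.sort(key=lambda h: (h.query.start, h.query.end, h.subject.start,
                             h.subject.strand))
    return hits


def hits_to_tsv(hits: Sequence[AlignmentHit], path: str | Path) -> None:
    """Write hits as TSV with 1-based inclusive coordinates."""
    import pandas as pd

    rows = [
        {
            "query_id": h.query.seq_id,
            "qstart": h.query.start1,
            "qend": h.query.end,
            "subject_id": h.subject.seq_id,
            "sstart": h.subject.start1,
            "send": h.subject.end,
            "strand": h.subject.strand,
            "identity": round(h.identity, 4),
            "columns": h.n_columns,
            "score": h.score,
        }
        for h in hits
    ]
    pd.DataFrame(
        rows,
        columns=["query_id", "qstart", "qend", "subject_id", "sstart",
                 "send", "strand", "identity", "columns", "score"],
    ).to_csv(path, sep="\t", index=False)
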