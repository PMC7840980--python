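"""Telomere-anchored read harvesting, clustering and consensus.

Long reads that end in a tract of telomere-repeat units carry, next to
that tract, the very sequence that assemblers struggle with most — the
chromosome end. The procedure here: find the repeat tract (allowing one
edit per unit copy), orient every read telomere-left and trim the tract,
cluster reads by the identity of their telomere-adjacent window
(single linkage), and collapse each cluster to a majority-vote consensus
against its longest member (star alignment). Clusters with fewer than
five members are flagged unreliable, following the convention that
sequence supported by fewer than five reads is not trusted.

The telomere repeat unit is organism-specific and degenerate in vivo;
it is a required configuration value for real data (default
``GGTTAC`` with up to one edit per copy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import edlib

from .seq_core import (
    Interval,
    SeqCoreError,
    SeqRecord,
    expand_cigar,
    global_align,
    revcomp,
)


@dataclass(frozen=True)
class TelomereTract:
    read_id: str
    end: str          # "5prime" | "3prime"
    interval: Interval
    copy_count: int


@dataclass(frozen=True)
class HarvestedRead:
    """A read oriented telomere-left with its repeat tract trimmed."""

    id: str
    seq: str
    source_id: str
    source_strand: str     # strand of the source read kept
    tract: TelomereTract


@dataclass
class ReadCluster:
    member_ids: list[str]
    representative: str    # id of the longest member
    reliable: bool         # False iff fewer than 5 members

    def __post_init__(self) -> None:
        assert self.reliable == (len(self.member_ids) >= RELIABLE_MIN_READS)


@dataclass
class ConsensusResult:
    sequence: str
    support: list[float]   # per-column agreement fraction
    n_members: int


RELIABLE_MIN_READS = 5


# ---------------------------------------------------------------------------
# tract detection
# ---------------------------------------------------------------------------

def _copy_step(seq: str, pos: int, motif: str) -> int | None:
    """Length consumed by one motif copy at ``pos`` (edit distance <= 1),
    or None."""
    m = len(motif)
    best = None
    for step in (m, m - 1, m + 1):
        if step <= 0 or pos + step > len(seq):
            continue
        d = edlib.align(seq[pos:pos + step], motif, mode="NW",
                        task="distance")["editDistance"]
        if d <= 1 and (best is None or d < best[0]):
            best = (d, step)
    return best[1] if best else None


def _count_copies(seq: str, start: int, motif: str) -> tuple[int, int]:
    """Rightward count of motif copies from ``start``, each within edit
    distance 1; a corrupted copy may be skipped (resynchronising within
    two unit lengths) without being counted. Returns (copies, end)."""
    m = len(motif)
    pos = start
    copies = 0
    end = start
    prev_end = start
    streak = 0       # copies since the last resync
    resynced = False
    while pos < len(seq):
        step = _copy_step(seq, pos, motif)
        if step is not None:
            copies += 1
            streak += 1
            prev_end = end
            pos += step
            end = pos
            continue
        # resync across a corrupted copy (not counted)
        for d in range(1, 2 * m + 5):
            if _copy_step(seq, pos + d, motif) is not None:
                pos += d
                streak = 0
                resynced = True
                break
        else:
            break
    # a lone copy reached only by resync is more likely a chance
    # motif-like k-mer in the adjacent unique sequence than tract; keep
    # the count permissive but do not let it extend the trim point
    if resynced and streak == 1:
        end = prev_end
        copies -= 1
    return copies, end


def find_telomere_tract(
    read: SeqRecord,
    motif: str = "GGTTAC",
    min_copies: int = 5,
    max_offset: int = 100,
) -> TelomereTract | None:
    """Longest terminal run of telomere-motif copies, either strand.

    The run must contain at least ``min_copies`` copies (each matching
    the motif within edit distance 1) and begin within ``max_offset`` bp
    of one read end. Returns the best tract or None.
    """
    if not motif:
        raise SeqCoreError("empty telomere motif")
    best: TelomereTract | None = None
    n = len(read.seq)
    for variant in (motif, revcomp(motif)):
        m = len(variant)
        # 5' end: scan candidate start offsets
        for start in range(0, min(max_offset, n)):
            copies, end = _count_copies(read.seq, start, variant)
            if copies >= min_copies:
                if best is None or copies > best.copy_count:
                    best = TelomereTract(
                        read.id, "5prime",
                        Interval(read.id, start, end), copies)
                break
        # 3' end: scan on the reverse complement and map back
        rc = revcomp(read.seq)
        for start in range(0, min(max_offset, n)):
            copies, end = _count_copies(rc, start, variant)
            if copies >= min_copies:
                if best is None or copies > best.copy_count:
                    best = TelomereTract(
                        read.id, "3prime",
                        Interval(read.id, n - end, n - start), copies)
                break
    return best


# ---------------------------------------------------------------------------
# harvest
# ---------------------------------------------------------------------------

def harvest(
    reads: Sequence[SeqRecord | HarvestedRead],
    motif: str = "GGTTAC",
    min_copies: int = 5,
    max_offset: int = 100,
) -> list[HarvestedRead]:
    """Keep reads with a terminal telomere tract, oriented telomere-left
    and with the tract trimmed off.

    Already-harvested reads pass through unchanged, making the operation
    idempotent.
    """
    out: list[HarvestedRead] = []
    for read in reads:
        if isinstance(read, HarvestedRead):
            out.append(read)
            continue
        tract = find_telomere_tract(read, motif, min_copies, max_offset)
        if tract is None:
            continue
        if tract.end == "5prime":
            seq = read.seq[tract.interval.end:]
            strand = "+"
        else:
            seq = revcomp(read.seq[: tract.interval.start])
            strand = "-"
        if not seq:
            continue
        out.append(
            HarvestedRead(
                id=read.id,
                seq=seq,
                source_id=read.id,
                source_strand=strand,
                tract=tract,
            )
        )
    return out


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _window_identity(a: str, b: str, window: int) -> float:
    wa, wb = a[:window], b[:window]
    if not wa or not wb:
        return 0.0
    return global_align(wa, wb).identity


def cluster_reads(
    reads: Sequence[HarvestedRead],
    window: int = 1000,
    cluster_min_id: float = 0.80,
) -> list[ReadCluster]:
    """Single-linkage clustering on telomere-adjacent window identity.

    Deterministic: reads are processed in id order and clusters reported
    with members sorted by id. Reliability requires at least five
    members.
    """
    if window < 200:
        raise SeqCoreError("window must be >= 200 bp")
    ordered = sorted(reads, key=lambda r: r.id)
    n = len(ordered)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if find(i) == find(j):
                continue
            if _window_identity(ordered[i].seq, ordered[j].seq,
                                window) >= cluster_min_id:
                parent[find(j)] = find(i)
    groups: dict[int, list[HarvestedRead]] = {}
    for i, r in enumerate(ordered):
        groups.setdefault(find(i), []).append(r)
    clusters = []
    for root in sorted(groups, key=lambda r: ordered[r].id):
        members = groups[root]
        rep = max(members, key=lambda r: (len(r.seq), r.id))
        clusters.append(
            ReadCluster(
                member_ids=sorted(r.id for r in members),
                representative=rep.id,
                reliable=len(members) >= RELIABLE_MIN_READS,
            )
        )
    return clusters


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def _insert_slot_consensus(counts: dict[str, int]) -> str:
    """Consensus of the insertion strings recorded at one slot.

    Longer insertions carry per-member noise, so identical-string voting
    fragments; instead take the weighted modal length and a per-position
    weighted plurality over the strings.
    """
    total = sum(counts.values())
    best = max(sorted(counts), key=lambda s: counts[s])
    if counts[best] * 2 > total:
        return best
    length_votes: dict[int, int] = {}
    for s, c in counts.items():
        length_votes[len(s)] = length_votes.get(len(s), 0) + c
    L = max(sorted(length_votes), key=lambda k: length_votes[k])
    out = []
    for i in range(L):
        col: dict[str, int] = {}
        for s, c in counts.items():
            if i < len(s):
                col[s[i]] = col.get(s[i], 0) + c
        out.append(max(sorted(col), key=lambda b: col[b]))
    return "".join(out)

def build_consensus(
    cluster: ReadCluster, reads: Sequence[HarvestedRead]
) -> ConsensusResult:
    """Majority-vote star-alignment consensus, polished in two rounds.

    Round one aligns every member to the longest member and takes the
    per-column majority (ties to the reference base, majority-gap
    columns dropped, insertions emitted where more than half the
    members carry one). Round two repeats the vote against the
    round-one consensus, which resolves alignment ambiguity caused by
    the representative's own errors.
    """
    by_id = {r.id: r for r in reads}
    members = [by_id[i] for i in cluster.member_ids]
    if not members:
        raise SeqCoreError("empty cluster")
    rep = by_id[cluster.representative]
    if len(members) == 1:
        return ConsensusResult(rep.seq, [1.0] * len(rep.seq), 1)
    round1 = _consensus_round(rep.seq, members)
    round2 = _consensus_round(round1.sequence, members)
    return round2


def _consensus_round(
    ref_seq: str, members: Sequence[HarvestedRead]
) -> ConsensusResult:
    rep = SeqRecord("__ref__", ref_seq)
    L = len(rep.seq)
    # votes[c] maps base (or "-") to count among members covering column
    # c; inserts[c] collects insertion strings members carry immediately
    # before rep column c. Members are telomere-left and generally
    # shorter than the representative, so they align as prefixes (free
    # trailing gap) and only vote over the columns they cover.
    votes: list[dict[str, int]] = [dict() for _ in range(L)]
    inserts: list[dict[str, int]] = [dict() for _ in range(L + 1)]
    coverage = [0] * (L + 1)
    from .seq_core import sw_align

    for mem in members:
        if mem.seq == rep.seq:
            for c, base in enumerate(rep.seq):
                votes[c][base] = votes[c].get(base, 0) + 1
                coverage[c] += 1
            coverage[L] += 1
            continue
        # tract trimming jitters read starts by a few bases; anchor each
        # member by a local alignment of its head before the end-to-end
        # alignment so leftover junk cannot shear the first columns
        m_off = r_off = 0
        head = sw_align(mem.seq[:200], rep.seq[:240])
        if head is not None and head[0] >= 50:
            # anchor the diagonal: if the representative's start is
            # behind the member's (its trim overshot), start its columns
            # later; member head bases always stay in play (as leading
            # insertions when the representative lacks them)
            diag = head[1] - head[3]
            r_off = max(-diag, 0)
        res = edlib.align(mem.seq, rep.seq[r_off:], mode="SHW",
                          task="path")
        edits = expand_cigar(res["cigar"])

        def record_insert(c: int, pend: str) -> None:
            # canonicalise: equivalent placements of an insertion next
            # to a repeated base must all vote in the same column
            while c > 0 and rep.seq[c - 1] == pend[-1]:
                pend = pend[-1] + pend[:-1]
                c -= 1
            inserts[c][pend] = inserts[c].get(pend, 0) + 1

        q, c = 0, r_off
        pend = ""
        for op in edits:
            if op == "I":
                pend += mem.seq[q]
                q += 1
                continue
            if pend:
                record_insert(c, pend)
                pend = ""
            if op in "=X":
                votes[c][mem.seq[q]] = votes[c].get(mem.seq[q], 0) + 1
                coverage[c] += 1
                q += 1
                c += 1
            else:  # D: member lacks this rep base
                votes[c]["-"] = votes[c].get("-", 0) + 1
                coverage[c] += 1
                c += 1
        if pend:
            record_insert(c, pend)

    n = len(members)
    cols: list[tuple[str, float, int]] = []  # (base(s), support, coverage)
    for c in range(L + 1):
        cov = max(coverage[c], 1)
        ins_total = sum(inserts[c].values())
        # 0.4, not a strict majority: a true base lost by the reference
        # inside a homopolymer draws votes away via members' own
        # deletion errors, while independent insertion errors cannot
        # concentrate on one canonical slot at anywhere near this rate
        if ins_total >= max(2, 0.4 * cov):
            ins = _insert_slot_consensus(inserts[c])
            for b in ins:
                cols.append((b, ins_total / cov, cov))
        if c == L:
            break
        v = votes[c]
        top = max(v.values(), default=0)
        if v.get(rep.seq[c], 0) == top:
            base = rep.seq[c]  # ties go to the representative
        else:
            base = max(sorted(v), key=lambda k: v[k])
        if base == "-":
            continue
        cols.append((base, v.get(base, 0) / cov, coverage[c]))
    # trim end columns supported by fewer than half the members: these
    # are the representative's private trim-jitter overhangs
    need = max(2, (n + 1) // 2)
    lo = 0
    while lo < len(cols) and cols[lo][2] < need:
        lo += 1
    hi = len(cols)
    while hi > lo and cols[hi - 1][2] < need:
        hi -= 1
    cols = cols[lo:hi] or cols
    return ConsensusResult(
        "".join(b for b, _, _ in cols),
        [s for _, s, _ in cols],
        n,
    )
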