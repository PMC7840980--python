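"""Block/box annotation of telomere-distal subtelomere regions.

Telomere-distal regions are long (tens of kb) and, unlike the proximal
mosaics, keep a stable order of large homologous blocks (>90 % identity
between copies of the same block). This module:

* places a set of reference-defined blocks on a query sequence
  (:func:`build_block_map`), reporting orientation (inversions),
  identity, length change, absent blocks and duplicated blocks;
* calls insertions and deletions between the query and the reference by
  anchored global alignment (:func:`call_indels`), with the reference
  coordinate reported as the base immediately telomere-proximal to the
  change and size classes micro (<10 bp), small (10–40 bp, the range
  highlighted in strain comparisons) and structural (>40 bp);
* searches the two ends of a large change for a pair of homologous boxes
  (:func:`detect_flanking_homology`) — the recombination-substrate
  signature observed at multi-kb deletions, with box identities observed
  down to 83–85 %;
* flags insertions of foreign sequence such as LTR or mitochondrial
  fragments (:func:`detect_foreign_insertions`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

from .seq_core import (
    AlignmentHit,
    Interval,
    SeqCoreError,
    SeqRecord,
    global_align,
    local_align,
)
from .shp_segmenter import MosaicAnnotation


@dataclass(frozen=True)
class BlockDef:
    """A named reference span; ``kind`` distinguishes the large ordered
    blocks from the shorter box elements."""

    block_id: str
    interval: Interval
    kind: str = "block"  # or "box"


@dataclass(frozen=True)
class BlockHit:
    block_id: str
    query: Interval
    orientation: str  # "forward" | "inverted"
    identity: float
    length_delta: int  # query occurrence length minus reference length
    low_confidence: bool = False  # "?": sub-threshold identity, long hit
    ref_interval: Interval | None = None  # block portion actually aligned


@dataclass
class IndelCall:
    ref_position: int  # 1-based ref base immediately telomere-proximal
    kind: str  # "insertion" | "deletion"
    size: int
    size_class: str  # micro | small | structural
    evidence: str = ""
    flanking_boxes: tuple[AlignmentHit, AlignmentHit] | None = None
    query_position: int = 0  # 1-based query base before the change

    def __post_init__(self) -> None:
        if self.size < 1:
            raise SeqCoreError("indel size must be >= 1")
        expected = size_class_of(self.size)
        if self.size_class != expected:
            raise SeqCoreError(
                f"size_class {self.size_class!r} inconsistent with "
                f"size {self.size}"
            )


@dataclass(frozen=True)
class ForeignInsertion:
    query: Interval
    source_label: str  # "LTR-like" | "mitochondrial-like" | "unknown"
    source_id: str
    identity: float


def size_class_of(size: int) -> str:
    if size < 10:
        return "micro"
    if size <= 40:
        return "small"
    return "structural"


@dataclass(frozen=True)
class IndelParams:
    min_report_size: int = 10   # micro calls kept in data, not reports
    max_unanchored: int = 50000
    box_window: int = 2000
    box_min_len: int = 100
    box_min_id: float = 0.83
    low_conf_min_len: int = 100  # "?" annotation floor
    low_conf_min_id: float = 0.75


# ---------------------------------------------------------------------------
# block maps
# ---------------------------------------------------------------------------

def build_block_map(
    query: SeqRecord,
    ref: SeqRecord,
    blocks: Sequence[BlockDef] | Sequence[tuple[str, int, int]],
    min_id: float = 0.90,
) -> list[BlockHit]:
    """Best non-overlapping placement of each reference block on the
    query, both strands.

    Missing blocks are simply absent from the result; a block placed more
    than once (duplication) yields multiple hits. Hits below ``min_id``
    but above the low-confidence floor are reported flagged rather than
    dropped, mirroring the "?" annotation for sub-threshold but
    substantial similarity.
    """
    defs = [
        b if isinstance(b, BlockDef)
        else BlockDef(b[0], Interval(ref.id, b[1], b[2]))
        for b in blocks
    ]
    params = IndelParams()
    candidates: list[tuple[float, BlockHit]] = []
    for d in defs:
        bseq = ref.seq[d.interval.start:d.interval.end]
        brec = SeqRecord(d.block_id, bseq)
        min_len = max(30, int(len(bseq) * 0.5))
        # blocks legitimately contain small indels between strains, so a
        # hit is only split at gaps beyond the structural threshold
        hits = local_align(brec, query, min_len=min_len,
                           min_identity=params.low_conf_min_id,
                           inclusive_identity=True, max_gap=150)
        for h in hits:
            low = not h.identity > min_id
            if low and h.n_columns < params.low_conf_min_len:
                continue
            bh = BlockHit(
                block_id=d.block_id,
                query=h.subject,
                orientation="forward" if h.subject.strand == "+"
                else "inverted",
                identity=h.identity,
                length_delta=len(h.subject) - len(d.interval),
                low_confidence=low,
                ref_interval=Interval(ref.id,
                                      d.interval.start + h.query.start,
                                      d.interval.start + h.query.end),
            )
            candidates.append((h.score, bh))
    candidates.sort(key=lambda sb: (-sb[0], sb[1].query.start,
                                    sb[1].block_id))
    placed: list[BlockHit] = []
    occupied: list[tuple[int, int]] = []
    for _score, bh in candidates:
        s, e = bh.query.start, bh.query.end
        # tolerate small chance-extension overlaps by trimming
        for os, oe in occupied:
            if s < oe and os < e:
                ov = min(e, oe) - max(s, os)
                if ov > 30:
                    s = e  # give up this candidate
                    break
                if os - s >= e - oe:
                    e = min(e, os)
                else:
                    s = max(s, oe)
        if e - s < 30:
            continue
        if (s, e) != (bh.query.start, bh.query.end):
            bh = replace(bh, query=Interval(bh.query.seq_id, s, e,
                                            bh.query.strand))
        placed.append(bh)
        occupied.append((s, e))
    placed.sort(key=lambda b: b.query.start)
    return placed


# ---------------------------------------------------------------------------
# indel calling
# ---------------------------------------------------------------------------

def _left_normalize(seq_gap_in: str, a: int, b: int) -> tuple[int, int]:
    """Shift a gap [a, b) left while the base before it equals its last
    base (the standard left-alignment of equivalent indels)."""
    while a > 0 and seq_gap_in[a - 1] == seq_gap_in[b - 1]:
        a -= 1
        b -= 1
    return a, b


def _calls_from_alignment(
    qseq: str, sseq: str, edits: str, q_off: int, s_off: int
) -> list[IndelCall]:
    calls: list[IndelCall] = []
    q = s = 0
    i = 0
    n = len(edits)
    while i < n:
        op = edits[i]
        if op in "=X":
            q += 1
            s += 1
            i += 1
            continue
        j = i
        while j < n and edits[j] == op:
            j += 1
        run = j - i
        if op == "I":  # extra bases in query: insertion
            qa, qb = _left_normalize(qseq, q, q + run)
            shift = q - qa
            calls.append(IndelCall(
                ref_position=s_off + s - shift,  # 1-based flank base
                kind="insertion",
                size=run,
                size_class=size_class_of(run),
                evidence=qseq[qa:qb],
                query_position=q_off + qa,
            ))
            q += run
        else:  # "D": bases only in ref: deletion
            sa, sb = _left_normalize(sseq, s, s + run)
            shift = s - sa
            calls.append(IndelCall(
                ref_position=s_off + sa,  # 0-based start == 1-based flank
                kind="deletion",
                size=run,
                size_class=size_class_of(run),
                evidence=sseq[sa:sb],
                query_position=q_off + q - shift,
            ))
            s += run
        i = j
    return calls


def _renormalize_call(call: IndelCall, ref_seq: str) -> IndelCall:
    """Left-align a call against the reference context (an indel whose
    last base equals the base before its position shifts left, rotating
    the changed string — the standard normalisation of equivalent
    indels)."""
    p = call.ref_position
    e = call.evidence
    q = call.query_position
    if not e:
        return call
    while p > 0 and ref_seq[p - 1] == e[-1]:
        e = e[-1] + e[:-1]
        p -= 1
        q -= 1
    if p == call.ref_position:
        return call
    return IndelCall(
        ref_position=p, kind=call.kind, size=call.size,
        size_class=call.size_class, evidence=e,
        query_position=max(0, q),
    )


def _refine_call(
    call: IndelCall, qseq: str, sseq: str, margin: int = 40
) -> IndelCall:
    """Re-derive a call from exact flank matching in a local window.

    Co-optimal alignment paths can report an indel with off-rotation
    content (a flank base traded into the gap). When the query and
    reference windows around the call differ by exactly one contiguous
    stretch, that stretch is the canonical call.
    """
    def resolve(long: str, short: str, size: int):
        """Split positions p where long == short[:p] + long[p:p+size]
        + short[p:]; tries the prefix- and suffix-derived candidates."""
        p = _common_prefix(long, short)
        t = _common_prefix(long[::-1], short[::-1])
        for cand in (p, len(long) - t - size):
            if 0 <= cand <= len(short) and \
                    long[:cand] == short[:cand] and \
                    long[cand + size:] == short[cand:]:
                return cand
        return None

    # merged co-optimal pieces can pair query and reference positions a
    # few bp inconsistently, so slide the reference window slightly
    shifts = [0, 1, -1, 2, -2, 3, -3, 4, -4, 5, -5, 6, -6]
    if call.kind == "insertion":
        a, b = call.query_position, call.query_position + call.size
        q0, q1 = max(0, a - margin), min(len(qseq), b + margin)
        qwin = qseq[q0:q1]
        for d in shifts:
            s0 = call.ref_position - (a - q0) + d
            s1 = call.ref_position + (q1 - b) + d
            if s0 < 0 or s1 > len(sseq):
                continue
            swin = sseq[s0:s1]
            if len(qwin) - len(swin) != call.size:
                continue
            p = resolve(qwin, swin, call.size)
            if p is not None:
                return IndelCall(
                    ref_position=s0 + p, kind="insertion",
                    size=call.size, size_class=call.size_class,
                    evidence=qwin[p:p + call.size],
                    query_position=q0 + p)
        return call
    a, b = call.ref_position, call.ref_position + call.size
    s0, s1 = max(0, a - margin), min(len(sseq), b + margin)
    swin = sseq[s0:s1]
    for d in shifts:
        q0 = call.query_position - (a - s0) + d
        q1 = call.query_position + (s1 - b) + d
        if q0 < 0 or q1 > len(qseq):
            continue
        qwin = qseq[q0:q1]
        if len(swin) - len(qwin) != call.size:
            continue
        p = resolve(swin, qwin, call.size)
        if p is not None:
            return IndelCall(
                ref_position=s0 + p, kind="deletion", size=call.size,
                size_class=call.size_class,
                evidence=swin[p:p + call.size], query_position=q0 + p)
    return call


def _merge_nearby_calls(
    calls: list[IndelCall], max_sep: int = 20, ref_seq: str | None = None,
    query_seq: str | None = None,
) -> list[IndelCall]:
    """Merge same-kind calls separated by at most ``max_sep`` bp.

    Edit-distance alignment has co-optimal paths; a single planted indel
    can come back as two gap runs separated by a few chance-matched
    bases. Merging reunites them (sizes add; the position stays at the
    left-most, telomere-proximal run). With ``ref_seq`` given, merged
    calls are re-left-normalised against the reference.
    """
    calls = sorted(calls, key=lambda c: (c.ref_position, c.kind))
    out: list[IndelCall] = []
    chain_end: list[int] = []  # rightmost extent of each merged chain
    for c in calls:
        c_end = c.ref_position + (c.size if c.kind == "deletion" else 0)
        if out:
            p = out[-1]
            if c.kind == p.kind and \
                    c.ref_position - chain_end[-1] <= max_sep:
                size = p.size + c.size
                out[-1] = IndelCall(
                    ref_position=p.ref_position,
                    kind=p.kind,
                    size=size,
                    size_class=size_class_of(size),
                    evidence=p.evidence + c.evidence,
                    query_position=p.query_position,
                )
                chain_end[-1] = max(chain_end[-1], c_end)
                continue
        out.append(c)
        chain_end.append(c_end)
    if ref_seq is not None:
        if query_seq is not None:
            out = [_refine_call(c, query_seq, ref_seq) for c in out]
        out = [_renormalize_call(c, ref_seq) for c in out]
        out.sort(key=lambda c: (c.ref_position, c.kind))
    return out


def call_indels(
    query: SeqRecord,
    ref: SeqRecord,
    params: IndelParams | None = None,
    blocks: Sequence[BlockDef] | Sequence[tuple[str, int, int]] | None = None,
    block_hits: Sequence[BlockHit] | None = None,
) -> list[IndelCall]:
    """Indel calls between a query and a syntenic reference.

    Without anchors the two sequences are aligned end to end, which is
    appropriate for spans up to a few tens of kb without inversions.
    With ``blocks`` + ``block_hits`` the alignment is anchored: each
    syntenic span between consecutive forward block anchors is aligned
    separately (inverted anchors and the spans flanking them are
    skipped — an inversion is not an indel).

    Gap runs become calls, left-normalised (pushed telomere-proximal
    under the telomere-left convention) and positioned by the 1-based
    reference base immediately before the change; nearby same-kind runs
    are re-merged (co-optimal path splits). Micro calls (<10 bp) are
    retained in the data; report writers suppress them by default.
    """
    params = params or IndelParams()
    if blocks is not None and block_hits is not None:
        spans = _anchored_spans(query, ref, blocks, block_hits)
    else:
        if abs(len(query) - len(ref)) > params.max_unanchored or \
                max(len(query), len(ref)) > 10 * params.max_unanchored:
            raise SeqCoreError(
                "sequences too divergent for direct alignment; build a "
                "block map first and pass it as anchors"
            )
        spans = [(0, len(query.seq), 0, len(ref.seq))]
    calls: list[IndelCall] = []
    for q0, q1, s0, s1 in spans:
        calls.extend(_call_span(query.seq, ref.seq, q0, q1, s0, s1))
    return _merge_nearby_calls(calls, ref_seq=ref.seq, query_seq=query.seq)


def _common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


_STRUCTURAL_NW_LIMIT = 100  # beyond this length difference, NW smears


def _call_span(
    qseq: str, sseq: str, q0: int, q1: int, s0: int, s1: int,
    depth: int = 0,
) -> list[IndelCall]:
    """Indel calls for one syntenic span.

    Edit-distance alignment scatters a multi-kb indel across chance
    matches with the flank, so large length differences are resolved
    structurally first: exact common prefix/suffix trimming isolates a
    single contiguous change where possible, and otherwise the span is
    bisected at a strong unique internal anchor. Small residual spans
    go through ordinary global alignment.
    """
    q, s = qseq[q0:q1], sseq[s0:s1]
    if q == s:
        return []
    # trim exact common prefix and suffix (non-overlapping)
    p = _common_prefix(q, s)
    t = _common_prefix(q[::-1], s[::-1])
    t = min(t, min(len(q), len(s)) - p)
    mq0, mq1 = q0 + p, q1 - t
    ms0, ms1 = s0 + p, s1 - t
    if mq1 <= mq0 and ms1 <= ms0:
        return []
    if mq1 <= mq0 or ms1 <= ms0:
        # single contiguous indel; left-normalise within the carrier
        if mq1 <= mq0:
            size = ms1 - ms0
            a, b = _left_normalize(sseq, ms0, ms1)
            return [IndelCall(
                ref_position=a, kind="deletion", size=size,
                size_class=size_class_of(size), evidence=sseq[a:b],
                query_position=mq0 - (ms0 - a))]
        size = mq1 - mq0
        a, b = _left_normalize(qseq, mq0, mq1)
        return [IndelCall(
            ref_position=ms0 - (mq0 - a), kind="insertion", size=size,
            size_class=size_class_of(size), evidence=qseq[a:b],
            query_position=a)]
    if abs((mq1 - mq0) - (ms1 - ms0)) <= _STRUCTURAL_NW_LIMIT or depth >= 12:
        hit = global_align(qseq[mq0:mq1], sseq[ms0:ms1])
        return _calls_from_alignment(qseq[mq0:mq1], sseq[ms0:ms1],
                                     hit.edits, mq0, ms0)
    # big messy middle: bisect at a strong unique internal anchor
    qrec = SeqRecord("q", qseq[mq0:mq1])
    srec = SeqRecord("s", sseq[ms0:ms1])
    hits = [
        h for h in local_align(qrec, srec, min_len=64, min_identity=0.90,
                               inclusive_identity=True, max_gap=150)
        if h.subject.strand == "+"
    ]
    hits = [
        h for h in hits
        if not (h.query.start == 0 and h.subject.start == 0)
        and not (h.query.end == mq1 - mq0 and h.subject.end == ms1 - ms0)
    ]
    if not hits:
        hit = global_align(qseq[mq0:mq1], sseq[ms0:ms1])
        return _calls_from_alignment(qseq[mq0:mq1], sseq[ms0:ms1],
                                     hit.edits, mq0, ms0)
    best = max(hits, key=lambda h: h.score)
    qm = mq0 + (best.query.start + best.query.end) // 2
    sm = ms0 + (best.subject.start + best.subject.end) // 2
    if (qm, sm) in ((mq0, ms0), (mq1, ms1)):
        hit = global_align(qseq[mq0:mq1], sseq[ms0:ms1])
        return _calls_from_alignment(qseq[mq0:mq1], sseq[ms0:ms1],
                                     hit.edits, mq0, ms0)
    return (
        _call_span(qseq, sseq, mq0, qm, ms0, sm, depth + 1)
        + _call_span(qseq, sseq, qm, mq1, sm, ms1, depth + 1)
    )


def _anchored_spans(
    query: SeqRecord,
    ref: SeqRecord,
    blocks: Sequence[BlockDef] | Sequence[tuple[str, int, int]],
    block_hits: Sequence[BlockHit],
) -> list[tuple[int, int, int, int]]:
    """Syntenic (query, ref) span pairs between consecutive forward
    block anchors, covering the whole sequences except spans adjacent to
    inverted blocks."""
    defs = {
        (b.block_id if isinstance(b, BlockDef) else b[0]):
        (b.interval if isinstance(b, BlockDef)
         else Interval(ref.id, b[1], b[2]))
        for b in blocks
    }
    anchors = []  # matched (query, ref) endpoints of forward blocks
    skip_spans = []
    for bh in sorted(block_hits, key=lambda b: b.query.start):
        iv = bh.ref_interval or defs.get(bh.block_id)
        if iv is None:
            continue
        if bh.orientation != "forward":
            skip_spans.append((bh.query.start, bh.query.end))
            continue
        anchors.append((bh.query.start, iv.start))
        anchors.append((bh.query.end, iv.end))
    anchors.sort()
    # keep anchors monotone in both coordinates
    mono = []
    last_s = -1
    for qa, sa in anchors:
        if sa > last_s:
            mono.append((qa, sa))
            last_s = sa
    pts = [(0, 0)] + mono + [(len(query.seq), len(ref.seq))]
    spans = []
    for (q0, s0), (q1, s1) in zip(pts, pts[1:]):
        if q1 < q0 or s1 < s0:
            continue
        if any(q0 < e and s < q1 for s, e in skip_spans):
            continue
        spans.append((q0, q1, s0, s1))
    return spans


def indel_conservation_check(
    calls: Sequence[IndelCall], query: SeqRecord, ref: SeqRecord
) -> bool:
    """Net inserted minus deleted bases must equal the length difference."""
    net = sum(c.size if c.kind == "insertion" else -c.size for c in calls)
    return net == len(query) - len(ref)


# ---------------------------------------------------------------------------
# flanking homology (box) detection
# ---------------------------------------------------------------------------

def detect_flanking_homology(
    call: IndelCall,
    query: SeqRecord,
    ref: SeqRecord,
    box_min_len: int | None = None,
    box_min_id: float | None = None,
    window: int | None = None,
    params: IndelParams | None = None,
) -> IndelCall:
    """Search the two ends of a changed region for a homologous box pair.

    For a deletion the changed region lives on the reference; for an
    insertion, on the query. Windows of ``window`` bp (default 2 kb) at
    either end of the region are locally aligned against each other; the
    best pair of spans at >= ``box_min_len`` and >= ``box_min_id``
    (defaults 100 bp, 0.83 — the floor of observed box identities) is
    attached to the call, or none.
    """
    params = params or IndelParams()
    box_min_len = box_min_len or params.box_min_len
    box_min_id = box_min_id if box_min_id is not None else params.box_min_id
    window = window or params.box_window

    if call.kind == "deletion":
        carrier, a = ref, call.ref_position  # 0-based change start
    else:
        carrier, a = query, call.query_position
    b = a + call.size
    seq = carrier.seq
    wl0, wl1 = max(0, a - window), min(b, a + window)
    wr0, wr1 = max(a, b - window), min(len(seq), b + window)
    if wl1 - wl0 < box_min_len or wr1 - wr0 < box_min_len:
        return call
    left = SeqRecord(f"{carrier.id}|L", seq[wl0:wl1])
    right = SeqRecord(f"{carrier.id}|R", seq[wr0:wr1])
    # boxes near the identity floor dip below the mosaic-scale window
    # threshold; only split at structural gaps
    hits = local_align(left, right, min_len=box_min_len,
                       min_identity=box_min_id, inclusive_identity=True,
                       max_gap=150)
    best = None
    for h in hits:
        l_iv = Interval(carrier.id, wl0 + h.query.start, wl0 + h.query.end)
        r_iv = Interval(carrier.id, wr0 + h.subject.start,
                        wr0 + h.subject.end, h.subject.strand)
        if l_iv.overlaps(replace(r_iv, strand="+")):
            continue
        if best is None or h.score > best[0]:
            best = (h.score, h, l_iv, r_iv)
    if best is None:
        return call
    _, h, l_iv, r_iv = best
    box_a = AlignmentHit(query=l_iv, subject=r_iv, identity=h.identity,
                         n_columns=h.n_columns, score=h.score, edits=h.edits)
    call.flanking_boxes = (box_a, box_a.swapped())
    return call


# ---------------------------------------------------------------------------
# foreign insertions
# ---------------------------------------------------------------------------

_SOURCE_LABELS = {"ltr": "LTR-like", "mito": "mitochondrial-like",
                  "mt": "mitochondrial-like"}


def source_label_for(exemplar_id: str) -> str:
    key = exemplar_id.lower()
    for prefix, label in _SOURCE_LABELS.items():
        if key.startswith(prefix):
            return label
    return "unknown"


def detect_foreign_insertions(
    query: SeqRecord,
    foreign_lib: Sequence[SeqRecord],
    min_id: float = 0.90,
    min_len: int = 100,
) -> list[ForeignInsertion]:
    """Local hits of foreign exemplars (LTR-like, mitochondrial-like …)
    within the query, labelled by exemplar."""
    if not foreign_lib:
        warnings.warn("empty foreign library: nothing to detect")
        return []
    out: list[ForeignInsertion] = []
    for ex in foreign_lib:
        for h in local_align(ex, query, min_len=min_len, min_identity=min_id,
                             inclusive_identity=True):
            out.append(
                ForeignInsertion(
                    query=h.subject,
                    source_label=source_label_for(ex.id),
                    source_id=ex.id,
                    identity=h.identity,
                )
            )
    out.sort(key=lambda f: (f.query.start, f.source_id))
    return out


# ---------------------------------------------------------------------------
# region length
# ---------------------------------------------------------------------------

def total_region_length(
    shp: MosaicAnnotation, block_hits: Sequence[BlockHit]
) -> int:
    """Full subtelomeric-homology span: from the first proximal tile to
    the end of the last accepted block hit, telomere-left coordinates."""
    if not shp.tiles or not block_hits:
        raise SeqCoreError("need both a proximal annotation and block hits")
    start = shp.tiles[0].interval.start
    end = max(b.query.end for b in block_hits)
    if end <= start:
        raise SeqCoreError("proximal annotation and block map are disjoint")
    return end - start
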