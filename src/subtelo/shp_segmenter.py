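"""Shared-segment library construction and mosaic annotation of
telomere-proximal subtelomeric regions.

Telomere-proximal subtelomere regions (a few kb each) are mosaics of
shared sequence segments: stretches that recur, nearly identically,
across chromosome ends. This module discovers those segments from a set
of regions and tiles each region with them:

* pass 1 finds all pairwise local alignments of at least ``min_seg_len``
  bp (default 50) above ``min_seg_id`` identity (default >0.95) and tiles
  the sequences greedily, longest hit first;
* pass 2 re-searches the remaining inter-tile gaps at a lower length
  floor (``min_gap_len``, default 14 bp, same identity threshold); gap
  segments must recur in at least two sequences;
* segment classes are then split into *variants* (byte-identical
  occurrence strings, labelled ``A1, A2, …``) and, where a class is a
  tandem array of a short unit, decomposed into its motif *subtype*
  structure (units, copy numbers, unit-family identities).

A library built from one strain set can then annotate sequences from
another strain via :func:`annotate_mosaic`, which marks tiles with
``low_id`` (75–90 % identity to the class exemplar, rendered "?"),
``partial_delta`` (at least 10 bp shorter than the exemplar, rendered
"∆") and ``unmatched`` flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from .seq_core import (
    AlignmentHit,
    Interval,
    SeqCoreError,
    SeqRecord,
    global_align,
    local_align,
    revcomp,
)

FLAG_PARTIAL = "partial_delta"  # rendered "∆"
FLAG_LOWID = "low_id"           # rendered "?"
FLAG_UNMATCHED = "unmatched"
UNMATCHED_LABEL = "unmatched"


@dataclass(frozen=True)
class SegmentParams:
    """Thresholds of the segment classification.

    ``min_seg_id`` and the gap-pass identity are strict (">95 %") by
    default; ``inclusive_identity`` switches to "no less than" semantics.
    """

    min_seg_len: int = 50
    min_seg_id: float = 0.95
    min_gap_len: int = 14
    variant_id: float = 1.0
    motif_min_id: float = 0.82
    inclusive_identity: bool = False
    lowid_lo: float = 0.75   # inclusive
    lowid_hi: float = 0.90   # exclusive; >= this is a plain tile
    partial_delta_bp: int = 10
    subtype_min_coverage: float = 0.80

    def __post_init__(self) -> None:
        if self.min_gap_len > self.min_seg_len:
            raise ValueError("min_gap_len must not exceed min_seg_len")
        for name in ("min_seg_id", "variant_id", "motif_min_id"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass
class MotifDecomposition:
    """Tandem-unit structure of a subtype segment class."""

    units: list[str]
    copy_number_by_occurrence: dict[str, int]
    unit_identity_matrix: list[list[float]]

    @property
    def period(self) -> int:
        return len(self.units[0]) if self.units else 0

    def is_empty(self) -> bool:
        return not self.units


@dataclass
class SegmentClass:
    label: str
    occurrences: list[Interval]
    exemplar: str
    variants: dict[str, str] = field(default_factory=dict)
    variant_by_occurrence: list[str] = field(default_factory=list)
    subtype: MotifDecomposition | None = None


@dataclass
class SegmentLibrary:
    classes: list[SegmentClass]
    params: SegmentParams

    def by_label(self, label: str) -> SegmentClass:
        for c in self.classes:
            if c.label == label:
                return c
        raise KeyError(label)

    def exemplar_records(self) -> list[SeqRecord]:
        return [SeqRecord(c.label, c.exemplar) for c in self.classes]


@dataclass(frozen=True)
class Tile:
    interval: Interval
    label: str
    variant: str | None = None
    flags: frozenset[str] = frozenset()
    identity: float | None = None


@dataclass
class MosaicAnnotation:
    """Ordered, non-overlapping labelled tiles on one sequence."""

    seq_id: str
    tiles: list[Tile]

    def __post_init__(self) -> None:
        prev_end = -1
        for t in sorted(self.tiles, key=lambda t: t.interval.start):
            if t.interval.start < prev_end:
                raise ValueError(f"overlapping tiles on {self.seq_id}")
            prev_end = t.interval.end
        self.tiles.sort(key=lambda t: t.interval.start)


def _label_for(index: int) -> str:
    """A, B, …, Z, AA, AB, … in discovery order."""
    letters = ""
    index += 1
    while index:
        index, rem = divmod(index - 1, 26)
        letters = chr(ord("A") + rem) + letters
    return letters


# ---------------------------------------------------------------------------
# pass 1: all-vs-all shared-segment search
# ---------------------------------------------------------------------------

def find_shared_segments(
    seqs: list[SeqRecord], params: SegmentParams | None = None
) -> list[AlignmentHit]:
    """All-vs-all local hits passing the segment thresholds, both strands.

    The trivial full-span self hit of each sequence is excluded; partial
    self hits (internal duplications) are kept.
    """
    params = params or SegmentParams()
    if len(seqs) < 2:
        warnings.warn("fewer than two sequences: no shared segments")
        return []
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise SeqCoreError("duplicate sequence ids")
    hits: list[AlignmentHit] = []
    for i, a in enumerate(seqs):
        for b in seqs[i + 1:]:
            hits.extend(
                local_align(a, b, params.min_seg_len, params.min_seg_id,
                            params.inclusive_identity)
            )
    return hits


# ---------------------------------------------------------------------------
# alignment-column bookkeeping for trimming hits to subranges
# ---------------------------------------------------------------------------

def _column_positions(hit: AlignmentHit) -> tuple[list[int], list[int]]:
    """Per-column query and subject offsets (within the hit intervals).

    Subject offsets are in the *aligned orientation* (reverse-complement
    coordinates for minus-strand hits).
    """
    q, s = hit.query.start, 0
    qpos, spos = [], []
    for op in hit.edits:
        qpos.append(q)
        spos.append(s)
        if op in "=XI":
            q += 1
        if op in "=XD":
            s += 1
    return qpos, spos


def _trim_hit_to_query(hit: AlignmentHit, lo: int, hi: int):
    """Restrict a hit to query span [lo, hi); returns
    (q_interval, s_interval, edits) or None if empty."""
    qpos, spos = _column_positions(hit)
    cols = [k for k, qp in enumerate(qpos) if lo <= qp < hi and hit.edits[k] != "D"]
    if not cols:
        return None
    k0, k1 = cols[0], cols[-1]
    edits = hit.edits[k0:k1 + 1].strip("ID")
    if not edits:
        return None
    # recompute spans from the stripped window
    off = hit.edits[k0:k1 + 1]
    lead = len(off) - len(off.lstrip("ID"))
    k0 += lead
    k1 = k0 + len(edits) - 1
    q0 = qpos[k0] if hit.edits[k0] != "D" else qpos[k0]
    q1 = q0 + sum(1 for c in edits if c in "=XI")
    s0_aln = spos[k0]
    s1_aln = s0_aln + sum(1 for c in edits if c in "=XD")
    s_len = len(hit.subject)
    if hit.subject.strand == "+":
        s0 = hit.subject.start + s0_aln
        s1 = hit.subject.start + s1_aln
    else:
        s1 = hit.subject.end - s0_aln
        s0 = hit.subject.end - s1_aln
    if q1 <= q0 or s1 <= s0:
        return None
    return (
        Interval(hit.query.seq_id, q0, q1),
        Interval(hit.subject.seq_id, s0, s1, hit.subject.strand),
        edits,
    )


# ---------------------------------------------------------------------------
# greedy tiling engine
# ---------------------------------------------------------------------------

class _Occupied:
    """Per-sequence occupied-interval bookkeeping."""

    def __init__(self) -> None:
        self.spans: dict[str, list[tuple[int, int, int]]] = {}  # (+ tile idx)

    def free_subspans(self, iv: Interval) -> list[tuple[int, int]]:
        spans = sorted(self.spans.get(iv.seq_id, []))
        out = []
        cur = iv.start
        for s, e, _ in spans:
            if e <= cur or s >= iv.end:
                continue
            if s > cur:
                out.append((cur, min(s, iv.end)))
            cur = max(cur, e)
        if cur < iv.end:
            out.append((cur, iv.end))
        return out

    def covering_tile(self, iv: Interval, min_frac: float = 0.8) -> int | None:
        """Index of a single placed tile covering >= min_frac of iv."""
        best, best_ov = None, 0
        for s, e, idx in self.spans.get(iv.seq_id, []):
            ov = min(e, iv.end) - max(s, iv.start)
            if ov > best_ov:
                best, best_ov = idx, ov
        if best is not None and best_ov >= min_frac * len(iv):
            return best
        return None

    def covered_frac(self, iv: Interval) -> float:
        cov = sum(
            max(0, min(e, iv.end) - max(s, iv.start))
            for s, e, _ in self.spans.get(iv.seq_id, [])
        )
        return cov / len(iv)

    def add(self, iv: Interval, tile_idx: int) -> None:
        self.spans.setdefault(iv.seq_id, []).append((iv.start, iv.end, tile_idx))


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[int, int] = {}

    def make(self, x: int) -> None:
        self.parent.setdefault(x, x)

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # keep the smaller (earlier-created) root for determinism
            lo, hi = min(ra, rb), max(ra, rb)
            self.parent[hi] = lo


def _hit_order_key(h: AlignmentHit):
    # longest first; ties leftmost, then lexicographic seq ids
    return (-h.n_columns, h.query.start, h.query.seq_id,
            h.subject.seq_id, h.subject.start)


def _greedy_tile(
    seqs: dict[str, str],
    hits: list[AlignmentHit],
    min_len: int,
    occupied: _Occupied | None = None,
    placements: list[tuple[Interval, int]] | None = None,
    uf: _UnionFind | None = None,
    next_class: int = 0,
) -> tuple[_Occupied, list[tuple[Interval, int]], _UnionFind, int]:
    """Greedy longest-first placement of hit intervals as class occurrences.

    ``placements`` is a list of (interval, class id); class ids are
    union-find members. Later hits that coincide with already-placed
    tiles merge their classes; partially overlapping hits are trimmed to
    the free span (dropped below ``min_len``).
    """
    occupied = occupied or _Occupied()
    placements = placements if placements is not None else []
    uf = uf or _UnionFind()

    def longest_free(iv: Interval) -> tuple[int, int] | None:
        spans = occupied.free_subspans(iv)
        if not spans:
            return None
        return max(spans, key=lambda se: (se[1] - se[0], -se[0]))

    def place(iv: Interval, cls: int) -> None:
        idx = len(placements)
        placements.append((iv, cls))
        occupied.add(replace(iv, strand="+"), idx)

    for hit in sorted(hits, key=_hit_order_key):
        q_iv, s_iv = hit.query, replace(hit.subject, strand="+")
        q_tile = occupied.covering_tile(q_iv)
        s_tile = occupied.covering_tile(s_iv)
        if q_tile is not None and s_tile is not None:
            uf.union(placements[q_tile][1], placements[s_tile][1])
            continue
        if q_tile is not None:
            # query side already a tile: subject side joins its class
            cls = uf.find(placements[q_tile][1])
            free = longest_free(s_iv)
            if free and free[1] - free[0] >= min_len:
                strand = hit.subject.strand
                place(Interval(s_iv.seq_id, free[0], free[1], strand), cls)
            continue
        if s_tile is not None:
            cls = uf.find(placements[s_tile][1])
            free = longest_free(q_iv)
            if free and free[1] - free[0] >= min_len:
                place(Interval(q_iv.seq_id, free[0], free[1]), cls)
            continue
        # both sides (mostly) new: trim to the free query span, project to
        # the subject and re-check the subject side
        free = longest_free(q_iv)
        if not free or free[1] - free[0] < min_len:
            continue
        trimmed = _trim_hit_to_query(hit, free[0], free[1])
        if trimmed is None:
            return_none = True
            continue
        tq, ts, _ = trimmed
        s_free = longest_free(replace(ts, strand="+"))
        if not s_free or s_free[1] - s_free[0] < min_len:
            continue
        ts = Interval(ts.seq_id, s_free[0], s_free[1], ts.strand)
        if len(tq) < min_len or len(ts) < min_len:
            continue
        cls = next_class
        next_class += 1
        uf.make(cls)
        place(tq, cls)
        place(ts, cls)
    return occupied, placements, uf, next_class


def _occurrence_string(seqs: dict[str, str], iv: Interval) -> str:
    s = seqs[iv.seq_id][iv.start:iv.end]
    return revcomp(s) if iv.strand == "-" else s


def build_segment_library(
    seqs: list[SeqRecord], params: SegmentParams | None = None
) -> tuple[SegmentLibrary, list[MosaicAnnotation]]:
    """Two-pass shared-segment discovery and mosaic tiling.

    Pass 1 tiles with hits of at least ``min_seg_len``; pass 2 re-searches
    the inter-tile gaps at ``min_gap_len``, keeping only gap segments that
    recur in at least two sequences. Residual gaps of at least
    ``min_gap_len`` become ``unmatched`` tiles. Deterministic for fixed
    input order and parameters.
    """
    params = params or SegmentParams()
    seq_map = {s.id: s.seq for s in seqs}
    hits = find_shared_segments(seqs, params)
    occupied, placements, uf, next_class = _greedy_tile(
        seq_map, hits, params.min_seg_len
    )
    n_pass1 = len(placements)

    # ---- pass 2: search the gaps -------------------------------------
    gap_records: list[SeqRecord] = []
    gap_origin: dict[str, tuple[str, int]] = {}
    for s in seqs:
        for gi, (g0, g1) in enumerate(
            occupied.free_subspans(Interval(s.id, 0, len(s.seq)))
        ):
            if g1 - g0 < params.min_gap_len:
                continue
            gid = f"{s.id}\x00gap{gi}"
            gap_records.append(SeqRecord(gid.replace("\x00", "__"),
                                         s.seq[g0:g1]))
            gap_origin[gid.replace("\x00", "__")] = (s.id, g0)
    if len(gap_records) >= 2:
        gap_params = replace(params, min_seg_len=params.min_gap_len)
        gap_hits = []
        for i, a in enumerate(gap_records):
            for b in gap_records[i + 1:]:
                if gap_origin[a.id][0] == gap_origin[b.id][0]:
                    continue  # gap segments must be shared across sequences
                gap_hits.extend(
                    local_align(a, b, params.min_gap_len, params.min_seg_id,
                                params.inclusive_identity)
                )
        # translate gap coordinates back to the source sequences
        translated = []
        for h in gap_hits:
            qs_id, q_off = gap_origin[h.query.seq_id]
            ss_id, s_off = gap_origin[h.subject.seq_id]
            translated.append(
                AlignmentHit(
                    query=Interval(qs_id, h.query.start + q_off,
                                   h.query.end + q_off),
                    subject=Interval(ss_id, h.subject.start + s_off,
                                     h.subject.end + s_off,
                                     h.subject.strand),
                    identity=h.identity,
                    n_columns=h.n_columns,
                    score=h.score,
                    edits=h.edits,
                )
            )
        occupied, placements, uf, next_class = _greedy_tile(
            seq_map, translated, params.min_gap_len,
            occupied, placements, uf, next_class,
        )

    # ---- consolidate classes -----------------------------------------
    groups: dict[int, list[Interval]] = {}
    for iv, cls in placements:
        groups.setdefault(uf.find(cls), []).append(iv)
    # drop pass-2 singletons that lost their partner to trimming
    roots = sorted(groups)
    classes: list[SegmentClass] = []
    for root in roots:
        ivs = groups[root]
        seq_ids = {iv.seq_id for iv in ivs}
        if len(ivs) < 2:
            continue
        if len(seq_ids) < 2 and any(
            i >= n_pass1 for i, (piv, pcls) in enumerate(placements)
            if uf.find(pcls) == root
        ):
            continue  # pass-2 class confined to one sequence
        ivs_sorted = sorted(ivs, key=lambda iv: (iv.seq_id, iv.start))
        exemplar = _occurrence_string(seq_map, ivs[0])
        classes.append(
            SegmentClass(label="", occurrences=ivs_sorted, exemplar=exemplar)
        )
    for idx, c in enumerate(classes):
        c.label = _label_for(idx)
    _refine_class_boundaries(classes, seq_map)
    _consensus_trim_extend(classes, seq_map)
    _resolve_tile_conflicts(classes, seq_map)
    library = SegmentLibrary(classes=classes, params=params)
    library = classify_variants(library, seq_map)

    annotations = _annotations_from_library(seqs, library, params)
    return library, annotations


def _annotations_from_library(
    seqs: list[SeqRecord], library: SegmentLibrary, params: SegmentParams
) -> list[MosaicAnnotation]:
    tiles_by_seq: dict[str, list[Tile]] = {s.id: [] for s in seqs}
    seq_map = {s.id: s.seq for s in seqs}
    for c in library.classes:
        for iv, var in zip(c.occurrences, c.variant_by_occurrence):
            occ = _occurrence_string(seq_map, iv)
            ident = global_align(occ, c.exemplar).identity
            flags = set()
            if len(c.exemplar) - len(occ) >= params.partial_delta_bp:
                flags.add(FLAG_PARTIAL)
            if params.lowid_lo <= ident < params.lowid_hi:
                flags.add(FLAG_LOWID)
            tiles_by_seq[iv.seq_id].append(
                Tile(iv, c.label, var, frozenset(flags), ident)
            )
    out = []
    for s in seqs:
        tiles = sorted(tiles_by_seq[s.id], key=lambda t: t.interval.start)
        tiles = _add_unmatched(tiles, s, params)
        out.append(MosaicAnnotation(seq_id=s.id, tiles=tiles))
    return out


def _add_unmatched(
    tiles: list[Tile], seq: SeqRecord, params: SegmentParams
) -> list[Tile]:
    full = []
    cur = 0
    for t in tiles:
        if t.interval.start - cur >= params.min_gap_len:
            full.append(
                Tile(Interval(seq.id, cur, t.interval.start), UNMATCHED_LABEL,
                     None, frozenset({FLAG_UNMATCHED}))
            )
        full.append(t)
        cur = max(cur, t.interval.end)
    if len(seq.seq) - cur >= params.min_gap_len:
        full.append(
            Tile(Interval(seq.id, cur, len(seq.seq)), UNMATCHED_LABEL,
                 None, frozenset({FLAG_UNMATCHED}))
        )
    return full


# ---------------------------------------------------------------------------
# boundary refinement
# ---------------------------------------------------------------------------

def _aligned_block(occ: str, exemplar: str) -> tuple[int, int, int, int] | None:
    """Local alignment footprint of an occurrence on the exemplar:
    (occ_start, occ_end, ex_start, ex_end). Junk at the occurrence ends
    is trimmed by the local alignment."""
    from .seq_core import sw_align

    res = sw_align(occ, exemplar)
    if res is None:
        return None
    _, a0, a1, b0, b1, _edits = res
    return a0, a1, b0, b1


def _refine_class_boundaries(
    classes: list[SegmentClass], seq_map: dict[str, str]
) -> None:
    """Snap occurrence boundaries to the cross-occurrence consensus.

    A local hit extends a base or two past the true segment boundary
    whenever the flanking bases of two contexts match by chance, so
    independently placed occurrences of the same class jitter at the
    ends. Each occurrence is aligned to the class exemplar, its claimed
    start/end in exemplar coordinates collected, and the modal claim
    adopted by every occurrence (ties resolved inward). On clean data
    this makes all occurrences of a class string-identical again.
    """
    from collections import Counter

    MARGIN = 16  # flank context so votes can see past a trimmed placement

    def with_margin(iv: Interval) -> tuple[str, int]:
        """Strand-normalised occurrence string extended by MARGIN on
        both genomic sides; returns (string, left-margin actually
        available in string orientation)."""
        seq = seq_map[iv.seq_id]
        g0, g1 = max(0, iv.start - MARGIN), min(len(seq), iv.end + MARGIN)
        s = seq[g0:g1]
        if iv.strand == "-":
            s = revcomp(s)
            lead = g1 - iv.end
        else:
            lead = iv.start - g0
        return s, lead

    for c in classes:
        e, _e_lead = with_margin(c.occurrences[0])
        blocks = []
        for iv in c.occurrences:
            s, _lead = with_margin(iv)
            blk = _aligned_block(s, e)
            blocks.append(blk if blk is not None else (0, len(s), 0, len(e)))
        # consensus class extent in exemplar coordinates: the modal
        # footprint end (ties break inward). Chance-matched junk that
        # survives the mode is removed afterwards by column-consensus
        # trimming.
        start_votes = Counter(b[2] for b in blocks)
        end_votes = Counter(b[3] for b in blocks)
        mode_start = max(start_votes, key=lambda v: (start_votes[v], v))
        mode_end = min(end_votes, key=lambda v: (-end_votes[v], v))
        if mode_end - mode_start < 1:
            continue
        new_occ = []
        for iv, (a0, a1, b0, b1) in zip(c.occurrences, blocks):
            # desired boundaries in margin-string coordinates
            s_start = a0 + (mode_start - b0)
            s_end = a1 + (mode_end - b1)
            seq = seq_map[iv.seq_id]
            if iv.strand == "+":
                g0 = max(0, iv.start - MARGIN)
                ns, ne = g0 + s_start, g0 + s_end
            else:
                g1 = min(len(seq), iv.end + MARGIN)
                ns, ne = g1 - s_end, g1 - s_start
            ns = max(0, ns)
            ne = min(len(seq), ne)
            new_occ.append(
                Interval(iv.seq_id, ns, ne, iv.strand) if ne > ns else iv
            )
        c.occurrences = new_occ
        c.exemplar = _occurrence_string(seq_map, new_occ[0])


def _shift_interval(iv: Interval, d_start: int, d_end: int,
                    seq_len: int) -> Interval:
    """Apply start/end deltas given in occurrence (strand-normalised)
    orientation."""
    if iv.strand == "+":
        ns, ne = iv.start + d_start, iv.end + d_end
    else:
        ns, ne = iv.start - d_end, iv.end - d_start
    ns, ne = max(0, ns), min(seq_len, ne)
    return Interval(iv.seq_id, ns, ne, iv.strand) if ne > ns else iv


def _consensus_trim_extend(
    classes: list[SegmentClass], seq_map: dict[str, str], cap: int = 12
) -> None:
    """Column-consensus boundary correction across a class's occurrences.

    True segment columns agree across occurrences; a chance-matched
    flank extension agrees only pairwise and disagrees with the other
    contexts. Each class end is trimmed back to the first run of ten
    consensus columns (one dissenting occurrence tolerated for classes
    with four or more copies), and then extended while the next flanking
    base is unanimous across all occurrences and unowned — reclaiming
    bases a neighbouring class's junk extension stole during greedy
    placement.
    """
    def top_count(col: list[str]) -> int:
        return max(col.count(b) for b in set(col)) if col else 0

    # ---- trims -------------------------------------------------------
    for c in classes:
        occs = [_occurrence_string(seq_map, iv) for iv in c.occurrences]
        n = len(occs)
        min_len = min(len(s) for s in occs)
        if n < 2 or min_len < 3 * cap:  # short gap-pass segments: leave
            continue
        need = n if n <= 3 else n - 1
        run_need = 10

        def first_good(strings: list[str]) -> int:
            for k in range(0, min(cap, min_len - run_need) + 1):
                if all(
                    top_count([s[k + j] for s in strings]) >= need
                    for j in range(run_need)
                ):
                    return k
            return 0

        t_start = first_good(occs)
        t_end = first_good([s[::-1] for s in occs])
        if t_start or t_end:
            c.occurrences = [
                _shift_interval(iv, t_start, -t_end,
                                len(seq_map[iv.seq_id]))
                for iv in c.occurrences
            ]

    # ---- ownership map ----------------------------------------------
    def owned() -> dict[str, set[int]]:
        m: dict[str, set[int]] = {}
        for c in classes:
            for iv in c.occurrences:
                m.setdefault(iv.seq_id, set()).update(
                    range(iv.start, iv.end))
        return m

    ownership = owned()

    # ---- extensions (strict unanimity) ------------------------------
    for c in classes:
        if len(c.occurrences) < 2:
            continue
        for direction in ("end", "start"):
            for _ in range(cap):
                nxt = []
                ok = True
                for iv in c.occurrences:
                    seq = seq_map[iv.seq_id]
                    if direction == "end":
                        pos = iv.end if iv.strand == "+" else iv.start - 1
                    else:
                        pos = iv.start - 1 if iv.strand == "+" else iv.end
                    if not (0 <= pos < len(seq)) or \
                            pos in ownership.get(iv.seq_id, ()):
                        ok = False
                        break
                    base = seq[pos]
                    if iv.strand == "-":
                        base = revcomp(base)
                    nxt.append(base)
                if not ok or len(set(nxt)) != 1:
                    break
                new_occ = []
                for iv in c.occurrences:
                    seq_len = len(seq_map[iv.seq_id])
                    if direction == "end":
                        niv = _shift_interval(iv, 0, 1, seq_len)
                    else:
                        niv = _shift_interval(iv, -1, 0, seq_len)
                    new_occ.append(niv)
                    pos = niv.end - 1 if (direction == "end") == \
                        (niv.strand == "+") else niv.start
                    ownership.setdefault(niv.seq_id, set()).add(pos)
                c.occurrences = new_occ
    for c in classes:
        if c.occurrences:
            c.exemplar = _occurrence_string(seq_map, c.occurrences[0])


def _resolve_tile_conflicts(
    classes: list[SegmentClass], seq_map: dict[str, str]
) -> None:
    """Trim any overlaps refinement may have introduced (later class in
    discovery order yields)."""
    by_seq: dict[str, list[tuple[Interval, int, int]]] = {}
    for ci, c in enumerate(classes):
        for oi, iv in enumerate(c.occurrences):
            by_seq.setdefault(iv.seq_id, []).append((iv, ci, oi))
    for seq_id, items in by_seq.items():
        items.sort(key=lambda x: (x[0].start, x[1]))
        prev_end = 0
        for iv, ci, oi in items:
            if iv.start < prev_end:
                ns = min(prev_end, iv.end - 1)
                classes[ci].occurrences[oi] = Interval(
                    iv.seq_id, ns, iv.end, iv.strand
                )
            prev_end = max(prev_end, iv.end)


# ---------------------------------------------------------------------------
# variants and subtypes
# ---------------------------------------------------------------------------

def classify_variants(
    library: SegmentLibrary, seq_map: dict[str, str]
) -> SegmentLibrary:
    """Partition each class's occurrences into byte-identical variants.

    Occurrence strings are strand-normalised first; variants are numbered
    in order of first appearance (``A1``, ``A2``, …).
    """
    for c in library.classes:
        variants: dict[str, str] = {}
        labels: list[str] = []
        string_to_label: dict[str, str] = {}
        for iv in c.occurrences:
            s = _occurrence_string(seq_map, iv)
            if s not in string_to_label:
                v = f"{c.label}{len(string_to_label) + 1}"
                string_to_label[s] = v
                variants[v] = s
            labels.append(string_to_label[s])
        c.variants = variants
        c.variant_by_occurrence = labels
    return library


def _find_period(s: str, min_agree: float, min_p: int = 5,
                 max_p: int = 200) -> int | None:
    """Smallest period p with s[i] == s[i+p] agreement >= min_agree and
    integer copy number."""
    n = len(s)
    for p in range(min_p, min(max_p, n // 2) + 1):
        if n % p:
            continue
        agree = sum(1 for i in range(n - p) if s[i] == s[i + p])
        if agree / (n - p) >= min_agree:
            return p
    return None


def decompose_subtype(
    cls: SegmentClass,
    seq_map: dict[str, str],
    params: SegmentParams | None = None,
) -> MotifDecomposition:
    """Tandem-unit decomposition of a segment class.

    Detects the smallest self-alignment period of each occurrence and
    reports unit strings, per-occurrence copy numbers and the pairwise
    identity matrix of the distinct units. Unit families may diverge down
    to ``motif_min_id`` (default 0.82). Returns an empty decomposition if
    no occurrence is periodic.
    """
    params = params or SegmentParams()
    occs = {
        f"{iv.seq_id}:{iv.start1}-{iv.end}": _occurrence_string(seq_map, iv)
        for iv in cls.occurrences
    }
    periods = {
        key: _find_period(s, params.motif_min_id) for key, s in occs.items()
    }
    valid = [p for p in periods.values() if p]
    if not valid:
        return MotifDecomposition([], {}, [])
    p = min(valid)
    units: list[str] = []
    copy_numbers: dict[str, int] = {}
    for key, s in occs.items():
        if len(s) % p:
            continue
        k = len(s) // p
        occ_units = [s[i * p:(i + 1) * p] for i in range(k)]
        # occurrence must really be a tandem of this unit family
        if any(
            global_align(u, occ_units[0]).identity < params.motif_min_id
            for u in occ_units[1:]
        ):
            continue
        copy_numbers[key] = k
        for u in occ_units:
            if u not in units:
                units.append(u)
    if not copy_numbers:
        return MotifDecomposition([], {}, [])
    matrix = [
        [round(global_align(u, v).identity, 4) for v in units] for u in units
    ]
    dec = MotifDecomposition(units, copy_numbers, matrix)
    cls.subtype = dec
    return dec


# ---------------------------------------------------------------------------
# annotating new sequences against an existing library
# ---------------------------------------------------------------------------

def annotate_mosaic(
    seq: SeqRecord,
    library: SegmentLibrary,
    params: SegmentParams | None = None,
) -> MosaicAnnotation:
    """Tile ``seq`` with the library exemplars.

    Placements at >= 90 % identity to the exemplar are plain tiles;
    75–90 % get the ``low_id`` ("?") flag; occurrences at least 10 bp
    shorter than their exemplar get ``partial_delta`` ("∆"). Unplaced
    stretches of at least ``min_gap_len`` become ``unmatched`` tiles.
    """
    params = params or (library.params if library else SegmentParams())
    candidates: list[tuple[float, Tile]] = []
    for c in library.classes:
        ex = SeqRecord(c.label, c.exemplar)
        min_len = max(params.min_gap_len,
                      int(len(c.exemplar) * 0.5))
        hits = local_align(ex, seq, min_len=min_len,
                           min_identity=params.lowid_lo,
                           inclusive_identity=True)
        for h in hits:
            iv = replace(h.subject, strand=h.subject.strand)
            occ = _occurrence_string({seq.id: seq.seq}, iv)
            ident = global_align(occ, c.exemplar).identity
            if ident < params.lowid_lo:
                continue
            flags = set()
            if params.lowid_lo <= ident < params.lowid_hi:
                flags.add(FLAG_LOWID)
            if len(c.exemplar) - len(occ) >= params.partial_delta_bp:
                flags.add(FLAG_PARTIAL)
            candidates.append(
                (h.score,
                 Tile(iv, c.label, _variant_for(c, occ), frozenset(flags),
                      ident))
            )
    candidates.sort(
        key=lambda st: (-st[0], st[1].interval.start, st[1].label)
    )
    placed: list[Tile] = []
    occupied: list[tuple[int, int]] = []
    for _, tile in candidates:
        iv = tile.interval
        s, e = iv.start, iv.end
        for os, oe in occupied:
            if s < oe and os < e:  # trim to the free side
                if os - s >= e - oe:
                    e = min(e, os)
                else:
                    s = max(s, oe)
        if e - s < params.min_gap_len or (e - s) < 0.5 * len(iv):
            continue
        if (s, e) != (iv.start, iv.end):
            tile = replace(tile, interval=Interval(iv.seq_id, s, e, iv.strand))
        placed.append(tile)
        occupied.append((s, e))
    placed.sort(key=lambda t: t.interval.start)
    tiles = _add_unmatched(placed, seq, params)
    return MosaicAnnotation(seq_id=seq.id, tiles=tiles)


def _variant_for(cls: SegmentClass, occ: str) -> str | None:
    for label, s in cls.variants.items():
        if s == occ:
            return label
    return None
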