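"""ORF analysis for subtelomeric helicase-like (tlh-family) loci.

The annotated start codon of a subtelomeric helicase gene is not
necessarily the true one: an in-frame ATG can sit hundreds of bases
upstream with no intervening stop (the observed case is 543 bases,
i.e. 181 codons, upstream) and a translation-initiation context matching
the Kozak consensus A/GNNATGG. This module finds ORFs, scans upstream of
an annotated start for in-frame ATG candidates with Kozak evaluation,
and builds a coding-change ledger between a query locus and a reference
ORF: substitutions, insertions and deletions with codon positions,
frame-shift and premature-stop status, and — for insertions — the
tandem-repeat context they arise in (e.g. [ATGACA]n gaining a unit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .seq_core import (
    Interval,
    SeqCoreError,
    SeqRecord,
    global_align,
    local_align,
    revcomp,
)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class OrfCall:
    """An open reading frame: ATG through stop codon (stop included in
    the interval), strand-aware, on the standard nuclear code."""

    interval: Interval
    frame: int
    aa_length: int

    def __post_init__(self) -> None:
        if len(self.interval) % 3:
            raise SeqCoreError("ORF length must be a codon multiple")
        if self.aa_length != len(self.interval) // 3 - 1:
            raise SeqCoreError("aa_length inconsistent with interval")


@dataclass(frozen=True)
class StartCandidate:
    position: int        # 0-based position of the A of the ATG
    distance_bp: int     # upstream distance from the annotated start
    distance_codons: int
    kozak: bool


@dataclass
class StartSiteReport:
    annotated_start: int
    candidates: list[StartCandidate]   # nearest first
    chosen: StartCandidate | None      # policy: farthest Kozak match,
                                       # else farthest


@dataclass
class CodingEvent:
    kind: str            # "point" | "insertion" | "deletion"
    ref_codon: int       # 1-based codon index in the reference ORF
    size: int            # bp (1 for point)
    repeat_context: str | None = None  # tandem unit for insertions


@dataclass
class CodingDiff:
    events: list[CodingEvent]
    frame_shift: bool
    premature_stop: bool
    query_span: Interval | None = None


# ---------------------------------------------------------------------------
# ORF discovery
# ---------------------------------------------------------------------------

def find_orfs(seq: SeqRecord, min_aa: int = 1) -> list[OrfCall]:
    """All maximal ORFs on both strands (leftmost ATG per stop-bounded
    frame region, standard code, stop codon required)."""
    if min_aa < 1:
        raise SeqCoreError("min_aa must be >= 1")
    out: list[OrfCall] = []
    n = len(seq.seq)
    for strand, s in (("+", seq.seq), ("-", revcomp(seq.seq))):
        for frame in range(3):
            start = None
            for p in range(frame, n - 2, 3):
                codon = s[p:p + 3]
                if codon in STOP_CODONS:
                    if start is not None:
                        aa = (p - start) // 3
                        if aa >= min_aa:
                            out.append(_make_orf(seq.id, start, p + 3,
                                                 strand, frame, aa, n))
                        start = None
                elif codon == "ATG" and start is None:
                    start = p
    out.sort(key=lambda o: (o.interval.start, o.interval.strand))
    return out


def _make_orf(seq_id: str, s: int, e: int, strand: str, frame: int,
              aa: int, n: int) -> OrfCall:
    if strand == "+":
        iv = Interval(seq_id, s, e, "+")
    else:
        iv = Interval(seq_id, n - e, n - s, "-")
    return OrfCall(interval=iv, frame=frame, aa_length=aa)


def translate(seq: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(seq[: len(seq) - len(seq) % 3]).translate())


# ---------------------------------------------------------------------------
# upstream start scan and Kozak context
# ---------------------------------------------------------------------------

def kozak_match(context: str) -> bool:
    """Kozak consensus A/GNNATGG: position −3 is A or G and +4 is G.

    ``context`` is the 7-mer from −3 to +4 with the ATG at positions
    4–6 (1-based). A context containing N is reported False with a
    warning.
    """
    if len(context) != 7:
        raise SeqCoreError("Kozak context must be 7 characters (-3..+4)")
    context = context.upper()
    if context[3:6] != "ATG":
        raise SeqCoreError("positions 4-6 of the context must be ATG")
    if "N" in context:
        warnings.warn("ambiguous base in Kozak context; reporting False")
        return False
    return context[0] in "AG" and context[6] == "G"


def _kozak_at(seq: str, atg_pos: int) -> bool:
    if atg_pos < 3 or atg_pos + 4 > len(seq):
        return False
    return kozak_match(seq[atg_pos - 3:atg_pos + 4])


def find_upstream_inframe_start(
    seq: SeqRecord, annotated_start: int
) -> StartSiteReport:
    """In-frame ATG candidates upstream of an annotated start.

    Scans codon by codon upstream until the first in-frame stop; each
    ATG found is a candidate with its distance (bp and codons) and Kozak
    flag. The chosen upstream start is the farthest Kozak-positive
    candidate, else simply the farthest.
    """
    s = seq.seq
    if s[annotated_start:annotated_start + 3] != "ATG":
        raise SeqCoreError(
            f"annotated start at {annotated_start} is not an ATG")
    candidates: list[StartCandidate] = []
    p = annotated_start - 3
    while p >= 0:
        codon = s[p:p + 3]
        if codon in STOP_CODONS:
            break
        if codon == "ATG":
            d = annotated_start - p
            candidates.append(
                StartCandidate(p, d, d // 3, _kozak_at(s, p)))
        p -= 3
    chosen = None
    if candidates:
        kozak_ones = [c for c in candidates if c.kozak]
        chosen = (kozak_ones or candidates)[-1]  # farthest
    return StartSiteReport(annotated_start=annotated_start,
                           candidates=candidates, chosen=chosen)


# ---------------------------------------------------------------------------
# coding-change ledger
# ---------------------------------------------------------------------------

def insertion_repeat_context(
    ref: SeqRecord | str, pos: int, inserted: str, max_unit: int = 6
) -> str | None:
    """The tandem unit an insertion duplicates, or None.

    Returns the unit u (length <= ``max_unit``) iff the inserted string
    is an integer number of copies of u and u occurs tandemly (at least
    2 adjacent copies) at ``pos`` in the reference.
    """
    if not inserted:
        raise SeqCoreError("empty insertion")
    s = ref.seq if isinstance(ref, SeqRecord) else ref
    for u_len in range(1, max_unit + 1):
        if len(inserted) % u_len:
            continue
        unit = inserted[:u_len]
        if inserted != unit * (len(inserted) // u_len):
            continue
        copies = 0
        p = pos
        while s[p:p + u_len] == unit:
            copies += 1
            p += u_len
        p = pos
        while p - u_len >= 0 and s[p - u_len:p] == unit:
            copies += 1
            p -= u_len
        if copies >= 2:
            return unit
    return None


def diff_coding(
    query_locus: SeqRecord,
    ref: SeqRecord,
    ref_orf: OrfCall,
    min_homolog_id: float = 0.60,
) -> CodingDiff:
    """Event ledger between a query locus and a reference ORF.

    The reference ORF span is located in the query by local alignment
    (homolog required at >60 % identity), then globally aligned. Events
    are recorded with 1-based reference codon positions; the frame shift
    flag is true iff the running net indel size is ever not a multiple
    of 3; the premature-stop flag is evaluated by translating the query
    in its own resulting frame from the aligned start.
    """
    if ref_orf.interval.strand != "+":
        raise SeqCoreError("orient the reference ORF forward first")
    orf_seq = ref.seq[ref_orf.interval.start:ref_orf.interval.end]
    orf_rec = SeqRecord(f"{ref.id}|orf", orf_seq)
    # max_gap large enough that planted in-frame insertions do not split
    # the homolog hit
    hits = local_align(orf_rec, query_locus,
                       min_len=max(30, len(orf_seq) // 3),
                       min_identity=min_homolog_id,
                       inclusive_identity=True, max_gap=150)
    if not hits:
        raise SeqCoreError("no homolog of the reference ORF in the query")
    best = max(hits, key=lambda h: h.score)
    # widen the query span by exactly what the local hit left uncovered
    pad_l = best.query.start
    pad_r = len(orf_seq) - best.query.end
    if best.subject.strand == "+":
        q0 = max(0, best.subject.start - pad_l)
        q1 = min(len(query_locus.seq), best.subject.end + pad_r)
    else:
        q0 = max(0, best.subject.start - pad_r)
        q1 = min(len(query_locus.seq), best.subject.end + pad_l)
    qseq = query_locus.seq[q0:q1]
    if best.subject.strand == "-":
        qseq = revcomp(qseq)
    aln = global_align(qseq, orf_seq)
    edits = aln.edits

    # left-normalised, re-merged indels (co-optimal paths split runs)
    from .shd_blocks import _calls_from_alignment, _merge_nearby_calls

    indels = _merge_nearby_calls(
        _calls_from_alignment(qseq, orf_seq, edits, 0, 0), max_sep=6,
        ref_seq=orf_seq, query_seq=qseq,
    )
    events: list[CodingEvent] = []
    frame_shift = False
    net = 0
    for c in indels:
        if not 0 < c.ref_position < len(orf_seq):
            continue
        if c.kind == "insertion":
            ctx = insertion_repeat_context(orf_seq, c.ref_position,
                                           c.evidence)
            events.append(CodingEvent("insertion", c.ref_position // 3 + 1,
                                      c.size, repeat_context=ctx))
            net += c.size
        else:
            events.append(CodingEvent("deletion", c.ref_position // 3 + 1,
                                      c.size))
            net -= c.size
        if net % 3:
            frame_shift = True
    # substitutions
    q = s = 0
    for op in edits:
        if op == "X" and 0 < s < len(orf_seq):
            events.append(CodingEvent("point", s // 3 + 1, 1))
        if op in "=XI":
            q += 1
        if op in "=XD":
            s += 1
    events.sort(key=lambda e: e.ref_codon)

    premature = _premature_stop(qseq, edits, len(orf_seq))
    return CodingDiff(
        events=events,
        frame_shift=frame_shift,
        premature_stop=premature,
        query_span=Interval(query_locus.id, q0, q1, best.subject.strand),
    )


def _premature_stop(qseq: str, edits: str, orf_len: int) -> bool:
    """Translate the query from the base aligned to the reference start
    codon; a stop before the column aligned to the reference stop codon
    is premature."""
    # query positions aligned to ref coords 0 and orf_len-3 (stop start)
    q = s = 0
    q_at_start = None
    q_at_stop = None
    for op in edits:
        if s == 0 and op in "=X" and q_at_start is None:
            q_at_start = q
        if s == orf_len - 3 and op in "=X" and q_at_stop is None:
            q_at_stop = q
        if op in "=XI":
            q += 1
        if op in "=XD":
            s += 1
    if q_at_start is None:
        return True  # start lost entirely
    if q_at_stop is None:
        q_at_stop = len(qseq)
    coding = qseq[q_at_start:]
    for p in range(0, len(coding) - 2, 3):
        if coding[p:p + 3] in STOP_CODONS:
            return q_at_start + p < q_at_stop - 2
    return False
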