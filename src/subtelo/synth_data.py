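"""Synthetic subtelomere data with explicit truth sets.

Every generator is a pure function of its parameters and a seed, and
returns both the sequences and a :class:`TruthSet` recording every
planted feature, sufficient to recompute the expected output of every
analysis stage. Background composition is uniform over ``{A,C,G,T}``
(GC skew can be dialled in but is off by default).

The generators emulate the observed structure of fission-yeast
subtelomeres: telomere-proximal regions as mosaics of shared segments
(including tandem-motif subtype classes), telomere-distal regions as
ordered homologous blocks with planted indels (10–40 bp and multi-kb,
the latter bounded by homologous box pairs at 83–100 % identity),
inversions and foreign (LTR- or mitochondrial-like) insertions,
helicase-like loci with upstream in-frame starts and repeat-context
insertions, and long reads carrying terminal telomere-repeat tracts with
uniform sequencing errors (substitution:insertion:deletion = 2:1:1).
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

from .seq_core import SeqRecord, global_align, local_align, revcomp

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class TruthSet:
    """Serializable record of every planted synthetic feature."""

    seed: int
    library: dict[str, Any] = field(default_factory=dict)
    mosaics: dict[str, Any] = field(default_factory=dict)
    distal: dict[str, Any] = field(default_factory=dict)
    coding: dict[str, Any] = field(default_factory=dict)
    reads: dict[str, Any] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TruthSet":
        if isinstance(source, Path) or "\n" not in str(source):
            p = Path(source)
            if p.exists():
                source = p.read_text()
        return cls(**json.loads(str(source)))


def _rand_dna(rng: random.Random, n: int, gc: float = 0.5) -> str:
    w = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choices("ACGT", weights=w, k=n))


def _mutate_substitutions(
    rng: random.Random, seq: str, rate: float
) -> tuple[str, list[int]]:
    out = list(seq)
    positions = []
    for i, c in enumerate(out):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in "ACGT" if b != c])
            positions.append(i)
    return "".join(out), positions


def _ungapped_identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    return sum(1 for x, y in zip(a, b) if x == y) / n if n else 0.0


def _is_aperiodic(s: str) -> bool:
    return all(s != s[p:] + s[:p] for p in range(1, len(s)))


# ---------------------------------------------------------------------------
# segment library
# ---------------------------------------------------------------------------

def gen_segment_library(
    seed: int,
    n_classes: int = 8,
    len_range: tuple[int, int] = (80, 600),
    n_subtype_classes: int = 2,
    unit_len_range: tuple[int, int] = (20, 60),
    copies_range: tuple[int, int] = (3, 5),
    gc: float = 0.5,
) -> tuple[list[SeqRecord], TruthSet]:
    """Random, mutually dissimilar segment-class exemplars.

    The last ``n_subtype_classes`` classes are tandem arrays of an
    aperiodic 20–60 bp unit, emulating the motif-subtype segment classes.
    Guarantees: no shared-segment local hit between any two exemplars at
    the discovery thresholds, and pairwise ungapped identity < 0.5.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if not (14 <= len_range[0] <= len_range[1] <= 5000):
        raise ValueError("len_range must lie within [14, 5000]")
    if n_subtype_classes > n_classes:
        raise ValueError("more subtype classes than classes")
    rng = random.Random(seed)
    exemplars: list[SeqRecord] = []
    truth: dict[str, Any] = {}
    for i in range(n_classes):
        label = f"seg{i:02d}"
        for _attempt in range(200):
            if i >= n_classes - n_subtype_classes:
                p = rng.randint(*unit_len_range)
                unit = _rand_dna(rng, p, gc)
                if not _is_aperiodic(unit):
                    continue
                k = rng.randint(*copies_range)
                seq = unit * k
                info = {"seq": seq, "unit": unit, "copies": k}
            else:
                n = rng.randint(*len_range)
                seq = _rand_dna(rng, n, gc)
                if _find_self_period(seq):
                    continue
                info = {"seq": seq, "unit": None, "copies": None}
            rec = SeqRecord(label, seq)
            ok = all(
                _ungapped_identity(seq, e.seq) < 0.5
                and not local_align(rec, e, min_len=14, min_identity=0.8)
                for e in exemplars
            )
            if ok:
                exemplars.append(rec)
                truth[label] = info
                break
        else:
            raise ValueError("could not generate dissimilar classes; relax "
                             "constraints")
    return exemplars, TruthSet(seed=seed, library=truth)


def _find_self_period(s: str, min_agree: float = 0.9) -> int | None:
    for p in range(5, len(s) // 2 + 1):
        agree = sum(1 for i in range(len(s) - p) if s[i] == s[i + p])
        if agree / (len(s) - p) >= min_agree:
            return p
    return None


# ---------------------------------------------------------------------------
# mosaic telomere-proximal regions
# ---------------------------------------------------------------------------

def gen_patterns(
    labels: Sequence[str],
    n_seqs: int,
    pattern_len_range: tuple[int, int] = (5, 7),
    seed: int = 0,
) -> list[list[str]]:
    """Mosaic patterns with no repeated ordered adjacency.

    No class is adjacent to itself, no ordered pair of adjacent classes
    occurs twice anywhere in the set, and every class is used at least
    twice. Without distinct adjacencies, a shared two-segment run is
    indistinguishable from a single longer shared segment, so single-
    segment truth would be unrecoverable by construction.
    """
    rng = random.Random(seed)
    for _attempt in range(500):
        used_adj: set[tuple[str, str]] = set()
        usage = {lb: 0 for lb in labels}
        patterns: list[list[str]] = []
        ok = True
        for _ in range(n_seqs):
            k = rng.randint(*pattern_len_range)
            pat: list[str] = []
            for _pos in range(k):
                cands = [
                    lb for lb in labels
                    if (not pat or (lb != pat[-1]
                                    and (pat[-1], lb) not in used_adj))
                ]
                if not cands:
                    break
                cands.sort(key=lambda lb: (usage[lb], rng.random()))
                lb = cands[0]
                if pat:
                    used_adj.add((pat[-1], lb))
                pat.append(lb)
                usage[lb] += 1
            if len(pat) < pattern_len_range[0]:
                ok = False
                break
            patterns.append(pat)
        if ok and all(u >= 2 for u in usage.values()):
            return patterns
    raise ValueError("could not build adjacency-distinct patterns; use more "
                     "classes or shorter patterns")


def gen_shp(
    library: list[SeqRecord] | dict[str, str],
    patterns: Sequence[Sequence[str]],
    point_mut_rate: float = 0.0,
    partial_spec: dict[tuple[int, int], int] | None = None,
    seed: int = 0,
    seq_prefix: str = "shp",
) -> tuple[list[SeqRecord], TruthSet]:
    """Concatenate segment copies into mosaic sequences.

    ``partial_spec`` maps ``(sequence index, tile index)`` to the number
    of bp (>= 10) truncated from the right end of that tile copy.
    Substitutions are applied per tile at ``point_mut_rate``. The truth
    set records every tile's span, mutated positions and truncation.
    """
    lib = ({r.id: r.seq for r in library}
           if not isinstance(library, dict) else dict(library))
    partial_spec = partial_spec or {}
    rng = random.Random(seed)
    records: list[SeqRecord] = []
    truth: dict[str, Any] = {}
    for si, pat in enumerate(patterns):
        sid = f"{seq_prefix}{si:02d}"
        parts: list[str] = []
        tiles = []
        pos = 0
        for ti, label in enumerate(pat):
            seg = lib[label]
            cut = partial_spec.get((si, ti), 0)
            if cut:
                if cut < 10:
                    raise ValueError("partial truncation must be >= 10 bp")
                seg = seg[:-cut]
            seg, muts = _mutate_substitutions(rng, seg, point_mut_rate)
            tiles.append({
                "label": label, "start": pos, "end": pos + len(seg),
                "truncated_bp": cut,
                "mut_positions": [pos + m for m in muts],
            })
            parts.append(seg)
            pos += len(seg)
        records.append(SeqRecord(sid, "".join(parts)))
        truth[sid] = {"pattern": list(pat), "tiles": tiles}
    return records, TruthSet(seed=seed, mosaics=truth)


# ---------------------------------------------------------------------------
# block-structured telomere-distal regions with planted events
# ---------------------------------------------------------------------------

def default_distal_events(ref_len: int = 30000,
                          seed: int = 0) -> list[dict[str, Any]]:
    """A representative event set: three 10–40 bp indels, one multi-kb
    box-bounded deletion, one inversion, one foreign insertion."""
    rng = random.Random(seed ^ 0x5D)
    return [
        {"kind": "deletion", "pos": int(ref_len * 0.12),
         "size": rng.randint(10, 40)},
        {"kind": "insertion", "pos": int(ref_len * 0.25),
         "size": rng.randint(10, 40)},
        {"kind": "deletion", "pos": int(ref_len * 0.35),
         "size": rng.randint(10, 40)},
        {"kind": "box_deletion", "pos": int(ref_len * 0.55), "size": 3700,
         "box_len": 300, "box_identity": 0.95},
        {"kind": "inversion", "block": 6},
        {"kind": "foreign", "pos": int(ref_len * 0.92), "source": "mito",
         "size": 400},
    ]


def gen_shd(
    ref_len: int = 30000,
    n_blocks: int = 8,
    planted_events: list[dict[str, Any]] | None = None,
    seed: int = 0,
    gc: float = 0.5,
) -> tuple[SeqRecord, SeqRecord, list[tuple[str, int, int]],
           list[SeqRecord], TruthSet]:
    """A reference distal region, a query derived from it by planted
    events, the block definitions, and the foreign-sequence library.

    Blocks are consecutive spans tiling the reference, labelled with
    roman numerals. Box-bounded deletions plant a pair of homologous
    boxes (identity configurable, emulating the observed 83–100 % range)
    at the two ends of the deleted span. Events must not overlap.
    Returns ``(ref, query, blocks, foreign_lib, truth)``.
    """
    rng = random.Random(seed)
    if planted_events is None:
        planted_events = default_distal_events(ref_len, seed)

    foreign_lib = [
        SeqRecord("mito", _rand_dna(rng, 2000, gc),
                  "mitochondrial-like exemplar"),
        SeqRecord("ltr", _rand_dna(rng, 500, gc), "LTR-like exemplar"),
    ]
    foreign_map = {r.id: r.seq for r in foreign_lib}

    ref = list(_rand_dna(rng, ref_len, gc))
    # plant homologous box pairs for box_deletion events into the ref
    box_truth = []
    for ev in planted_events:
        if ev["kind"] != "box_deletion":
            continue
        pos, size = ev["pos"], ev["size"]
        blen = ev.get("box_len", 300)
        ident = ev.get("box_identity", 0.95)
        box_a = _rand_dna(rng, blen, gc)
        box_b, _ = _mutate_substitutions(rng, box_a, 1.0 - ident)
        # layout in ref: [... box_a | interior | box_b ...]; the deleted
        # span is interior + box_b, so homologous boxes flank both ends
        # of the change
        if size <= blen:
            raise ValueError("box_deletion size must exceed box_len")
        ref[pos:pos + blen] = box_a
        ref[pos + size:pos + size + blen] = box_b
        box_truth.append({"pos": pos, "size": size, "box_len": blen,
                          "box_identity": ident})
    ref_seq = "".join(ref)

    # block definitions tile the (final) reference
    bl = ref_len // n_blocks
    blocks = [
        (_roman(i + 1), i * bl, min(ref_len, (i + 1) * bl))
        for i in range(n_blocks)
    ]

    # sort events right-to-left and apply to build the query
    pos_events = [e for e in planted_events if e["kind"] != "inversion"]
    spans = []
    for e in pos_events:
        if e["kind"] == "deletion":
            spans.append((e["pos"], e["pos"] + e["size"]))
        elif e["kind"] == "box_deletion":
            spans.append((e["pos"] + e.get("box_len", 300),
                          e["pos"] + e["size"] + e.get("box_len", 300)))
        else:
            spans.append((e["pos"], e["pos"]))
    for (a1, b1), (a2, b2) in zip(sorted(spans), sorted(spans)[1:]):
        if b1 > a2:
            raise ValueError("planted events overlap")

    query = ref_seq
    applied = []
    for ev in sorted(pos_events, key=lambda e: -e["pos"]):
        kind, pos = ev["kind"], ev["pos"]
        if kind == "deletion":
            query = query[:pos] + query[pos + ev["size"]:]
            applied.append({"kind": "deletion", "pos": pos,
                            "size": ev["size"]})
        elif kind == "box_deletion":
            blen = ev.get("box_len", 300)
            a = pos + blen
            b = a + ev["size"]
            query = query[:a] + query[b:]
            applied.append({"kind": "deletion", "pos": a, "size": ev["size"],
                            "box": True})
        elif kind == "insertion":
            ins = _rand_dna(rng, ev["size"], gc)
            query = query[:pos] + ins + query[pos:]
            applied.append({"kind": "insertion", "pos": pos,
                            "size": ev["size"], "seq": ins})
        elif kind == "foreign":
            src = foreign_map[ev["source"]]
            size = min(ev["size"], len(src))
            off = ev.get("source_offset", 0)
            ins = src[off:off + size]
            query = query[:pos] + ins + query[pos:]
            applied.append({"kind": "foreign", "pos": pos, "size": size,
                            "source": ev["source"]})
        else:
            raise ValueError(f"unknown event kind {kind!r}")

    # inversions operate on block coordinates of the *query*; apply after
    # computing the query offset of the block span
    inv_truth = []
    for ev in (e for e in planted_events if e["kind"] == "inversion"):
        bi = ev["block"]
        name, bs, be = blocks[bi]
        qs = bs + _offset_at(applied, bs)
        qe = be + _offset_at(applied, be)
        query = query[:qs] + revcomp(query[qs:qe]) + query[qe:]
        inv_truth.append({"block": name, "ref_start": bs, "ref_end": be})

    truth = TruthSet(
        seed=seed,
        distal={
            "ref_len": ref_len,
            "events": applied[::-1],
            "inversions": inv_truth,
            "box_deletions": box_truth,
            "blocks": [
                {"name": n, "start": s, "end": e} for n, s, e in blocks
            ],
            "query_len": len(query),
        },
    )
    return (
        SeqRecord("ref_shd", ref_seq),
        SeqRecord("query_shd", query),
        blocks,
        foreign_lib,
        truth,
    )


def _offset_at(applied: list[dict[str, Any]], ref_pos: int) -> int:
    """Net query-minus-ref offset accumulated left of ``ref_pos``."""
    off = 0
    for ev in applied:
        if ev["pos"] < ref_pos:
            off += ev["size"] if ev["kind"] in ("insertion", "foreign") \
                else -ev["size"]
    return off


def apply_distal_events(ref: str, truth: TruthSet) -> str:
    """Re-apply the recorded events to the reference (oracle for the
    generator itself); inversions are not re-applied here."""
    query = ref
    for ev in sorted(truth.distal["events"], key=lambda e: -e["pos"]):
        pos = ev["pos"]
        if ev["kind"] == "deletion":
            query = query[:pos] + query[pos + ev["size"]:]
        else:
            query = query[:pos] + ev.get("seq", "") + query[pos:]
    return query


_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
          "XI", "XII", "XIII", "XIV", "XV"]


def _roman(i: int) -> str:
    return _ROMAN[i - 1] if i <= len(_ROMAN) else f"B{i}"


# ---------------------------------------------------------------------------
# helicase-like locus pairs
# ---------------------------------------------------------------------------

_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


def _random_orf_codons(rng: random.Random, n_codons: int) -> str:
    return "".join(rng.choice(_NONSTOP_CODONS) for _ in range(n_codons))


def _has_inframe_stop(coding: str) -> bool:
    return any(coding[i:i + 3] in STOP_CODONS
               for i in range(0, len(coding) - 2, 3))


def gen_tlh(
    ref_orf_len_aa: int = 400,
    events: list[dict[str, Any]] | None = None,
    seed: int = 0,
    upstream_start_bp: int = 543,
    flank: int = 300,
    motif_contexts: Sequence[str] = ("ATGACA", "CGACAA", "TGATGG"),
) -> tuple[SeqRecord, SeqRecord, TruthSet]:
    """A helicase-like locus pair with an upstream in-frame start.

    The reference locus contains, 5'→3': a flank ending in an in-frame
    stop, an upstream ATG (Kozak-positive context) ``upstream_start_bp``
    bases before the annotated ATG, a stop-free in-frame spacer, the
    annotated ORF of ``ref_orf_len_aa`` codons with tandem motif contexts
    planted inside it, a stop codon, and a 3' flank. The query applies the
    planted events (substitutions and in-frame or frame-shifting indels,
    insertions optionally at the tandem contexts).

    Default events: five substitutions, a 6 bp insertion at the first
    motif context, an 18 bp insertion at the second, and an in-frame 6 bp
    deletion — none creating a premature stop.
    """
    if upstream_start_bp % 3:
        raise ValueError("upstream_start_bp must be a codon multiple")
    rng = random.Random(seed)
    # uM ATG (3) + spacer codons + A,C,C Kozak codon (3) must add to the
    # upstream distance
    n_spacer = upstream_start_bp // 3 - 2
    if n_spacer < 0 or ref_orf_len_aa < 40:
        raise ValueError("locus too short")

    # ORF body with tandem motif contexts planted at stop-free phases
    body_str = "".join(rng.choice(_NONSTOP_CODONS)
                       for _ in range(ref_orf_len_aa))
    ctx_pos_bp: dict[str, int] = {}
    slot = 3 * (ref_orf_len_aa // (len(motif_contexts) + 1))
    for mi, motif in enumerate(motif_contexts):
        tandem = motif * 2
        for shift in range(3):
            pos = (mi + 1) * slot + shift
            cand = body_str[:pos] + tandem + body_str[pos + len(tandem):]
            if not _has_inframe_stop(cand):
                body_str = cand
                ctx_pos_bp[motif] = pos
                break
        else:
            raise ValueError(f"cannot plant motif {motif} without a stop")

    kozak_a = "A"  # -3 position of both starts
    spacer = _random_orf_codons(rng, n_spacer)
    # +4 must be G: force the first base of the codon after each ATG
    spacer = "G" + spacer[1:]
    if ctx_pos_bp and min(ctx_pos_bp.values()) < 1:
        raise ValueError("motif context too close to the start")
    body_str = "G" + body_str[1:]
    if _has_inframe_stop(spacer) or _has_inframe_stop(body_str):
        spacer = spacer.replace("TGA", "TCA")  # same-frame safety net
    five_flank = _rand_dna(rng, flank)
    # in-frame stop two codons above uM, then the -3 A of uM's context
    five_flank = five_flank[:-6] + "TAA" + kozak_a + "CA"
    uM = len(five_flank)
    dM = uM + upstream_start_bp
    ref_seq = (five_flank + "ATG" + spacer + kozak_a + "CC" + "ATG"
               + body_str + "TAA" + _rand_dna(rng, flank))
    # layout check: dM - uM must equal upstream_start_bp
    assert ref_seq[uM:uM + 3] == "ATG" and ref_seq[dM:dM + 3] == "ATG"
    assert (dM - uM) % 3 == 0

    orf_start, orf_end = dM, dM + 3 * ref_orf_len_aa + 3  # incl. stop

    if events is None:
        events = []
        for i in range(5):
            cp = 10 + i * (ref_orf_len_aa // 7)
            events.append({"kind": "point", "codon": cp})
        events.append({"kind": "insertion",
                       "motif": motif_contexts[0], "units": 1})
        events.append({"kind": "insertion",
                       "motif": motif_contexts[1], "units": 3})
        events.append({"kind": "deletion",
                       "codon": ref_orf_len_aa - 20, "size": 6})

    query = ref_seq
    applied = []
    norm = []
    for ev in events:
        if ev["kind"] == "insertion" and "motif" in ev:
            motif = ev["motif"]
            # +3: the ORF begins with its ATG, the body follows it
            at = orf_start + 3 + ctx_pos_bp[motif]
            norm.append({"kind": "insertion", "pos": at + len(motif) * 2,
                         "seq": motif * ev["units"], "motif": motif})
        elif ev["kind"] == "insertion":
            at = orf_start + 3 * ev["codon"]
            seq = ev.get("seq") or _random_orf_codons(
                rng, ev["size"] // 3 + 1)[:ev["size"]]
            norm.append({"kind": "insertion", "pos": at, "seq": seq})
        elif ev["kind"] == "deletion":
            at = orf_start + 3 * ev["codon"]
            norm.append({"kind": "deletion", "pos": at, "size": ev["size"]})
        elif ev["kind"] == "point":
            at = orf_start + 3 * ev["codon"] + 1
            norm.append({"kind": "point", "pos": at})
        else:
            raise ValueError(f"unknown coding event {ev['kind']!r}")
    for ev in sorted(norm, key=lambda e: -e["pos"]):
        pos = ev["pos"]
        if ev["kind"] == "point":
            old = query[pos]
            # transversion within the codon middle; avoid creating a stop
            for new in "ACGT":
                if new != old:
                    cand = query[:pos] + new + query[pos + 1:]
                    cod0 = pos - (pos - orf_start) % 3
                    if cand[cod0:cod0 + 3] not in STOP_CODONS:
                        query = cand
                        ev["from"], ev["to"] = old, new
                        break
        elif ev["kind"] == "insertion":
            query = query[:pos] + ev["seq"] + query[pos:]
            ev["size"] = len(ev["seq"])
        else:
            query = query[:pos] + query[pos + ev["size"]:]
        applied.append(dict(ev))

    truth = TruthSet(
        seed=seed,
        coding={
            "uM": uM, "dM": dM,
            "upstream_start_bp": upstream_start_bp,
            "orf_start": orf_start, "orf_end": orf_end,
            "orf_len_aa": ref_orf_len_aa,
            "motif_contexts": {m: orf_start + 3 + p
                               for m, p in ctx_pos_bp.items()},
            "events": applied[::-1],
        },
    )
    return (SeqRecord("tlh_ref", ref_seq), SeqRecord("tlh_query", query),
            truth)


# ---------------------------------------------------------------------------
# telomere-anchored long reads
# ---------------------------------------------------------------------------

def gen_reads(
    end_seqs: Sequence[SeqRecord],
    motif: str = "GGTTAC",
    tract_copies: int = 10,
    coverage: int = 20,
    error_rate: float = 0.08,
    seed: int = 0,
    read_len_range: tuple[int, int] = (2000, 5000),
) -> tuple[list[SeqRecord], TruthSet]:
    """Reads sampled from chromosome-end templates, telomere tract first.

    Each read is the repeat tract plus a template prefix, with uniform
    errors at ``error_rate`` split substitution:insertion:deletion =
    2:1:1, on a random strand. The truth set records provenance.
    """
    if not (0 <= error_rate < 0.2):
        raise ValueError("error_rate must be < 0.2")
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    rng = random.Random(seed)
    reads: list[SeqRecord] = []
    truth: dict[str, Any] = {}
    for tmpl in end_seqs:
        for ri in range(coverage):
            rid = f"read_{tmpl.id}_{ri:03d}"
            L = min(len(tmpl.seq), rng.randint(*read_len_range))
            clean = motif * tract_copies + tmpl.seq[:L]
            noisy, n_err = _apply_read_errors(rng, clean, error_rate)
            strand = "+" if rng.random() < 0.5 else "-"
            seq = noisy if strand == "+" else revcomp(noisy)
            reads.append(SeqRecord(rid, seq))
            truth[rid] = {"template": tmpl.id, "strand": strand,
                          "template_bp": L, "tract_copies": tract_copies,
                          "n_errors": n_err}
    order = list(range(len(reads)))
    rng.shuffle(order)
    reads = [reads[i] for i in order]
    return reads, TruthSet(seed=seed, reads=truth)


def _apply_read_errors(
    rng: random.Random, seq: str, rate: float
) -> tuple[str, int]:
    out = []
    n = 0
    for c in seq:
        r = rng.random()
        if r >= rate:
            out.append(c)
            continue
        n += 1
        kind = rng.random()
        if kind < 0.5:  # substitution
            out.append(rng.choice([b for b in "ACGT" if b != c]))
        elif kind < 0.75:  # insertion
            out.append(rng.choice("ACGT"))
            out.append(c)
        # else deletion: emit nothing
    return "".join(out), n
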