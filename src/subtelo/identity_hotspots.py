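"""Per-locus identity profiling and mutation-hotspot ranking.

Comparing a strain's loci against a reference genome, subtelomeric loci
accumulate changes much faster than chromosome arms: most differences
are point mutations, but a recurring class is the change in copy number
of a short tandem repeat (e.g. a homopolymer [T]n gaining or losing
units). This module computes per-locus identity with an event breakdown
(point / repeat-number / other indel) and orders loci into a categorical
profile (hotspot / intermediate / preserved) along the
telomere-to-centromere axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seq_core import SeqCoreError, SeqRecord, global_align, revcomp


@dataclass(frozen=True)
class EditEvent:
    kind: str        # "point" | "insertion" | "deletion"
    ref_pos: int     # 0-based position in ref (event start; for an
                     # insertion, the ref base after which it occurs)
    qry_pos: int     # 0-based position in query
    seq: str         # substituted/inserted/deleted bases


@dataclass
class LocusIdentity:
    locus_id: str
    order_key: int          # chromosome-position order, telomere first
    identity: float         # percentage in [0, 100]
    n_point: int
    n_repeat_number: int
    n_other_indel: int
    events: list[EditEvent] = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return self.n_point + self.n_repeat_number + self.n_other_indel


@dataclass(frozen=True)
class HotspotThresholds:
    """Category bounds on percent identity: loci at ``preserved_min`` or
    above are preserved, below ``hotspot_below`` are hotspots."""

    preserved_min: float = 100.0
    hotspot_below: float = 99.9


@dataclass
class HotspotProfile:
    loci: list[LocusIdentity]
    categories: dict[str, str]
    thresholds: HotspotThresholds


MIN_REPEAT_COPIES = 3  # tandem copies required in the ref context
MAX_REPEAT_UNIT = 6


def repeat_unit_of(
    ref_seq: str,
    pos: int,
    changed: str,
    max_unit: int = MAX_REPEAT_UNIT,
    min_copies: int = MIN_REPEAT_COPIES,
) -> str | None:
    """The tandem unit a repeat-number change is made of, or None.

    ``changed`` must be an integer number of copies of a unit (1–6 bp)
    that is tandemly present (at least ``min_copies`` adjacent copies)
    at ``pos`` in the reference. Requiring three adjacent copies keeps
    arbitrary 1 bp indels from being classified as repeat slippage.
    """
    for u_len in range(1, max_unit + 1):
        if len(changed) % u_len:
            continue
        unit = changed[:u_len]
        if changed != unit * (len(changed) // u_len):
            continue
        copies = 0
        p = pos
        while ref_seq[p:p + u_len] == unit:
            copies += 1
            p += u_len
        p = pos
        while p - u_len >= 0 and ref_seq[p - u_len:p] == unit:
            copies += 1
            p -= u_len
        if copies >= min_copies:
            return unit
    return None


def classify_variant_type(event: EditEvent, query: SeqRecord,
                          ref: SeqRecord) -> str:
    """point / repeat_number / other_indel for one alignment event."""
    if event.kind == "point":
        return "point"
    if repeat_unit_of(ref.seq, event.ref_pos, event.seq) is not None:
        return "repeat_number"
    return "other_indel"


def enumerate_events(query: SeqRecord, ref: SeqRecord) -> list[EditEvent]:
    """Alignment events between homologous loci (gap runs merged, each
    substitution its own event)."""
    hit = global_align(query, ref)
    events: list[EditEvent] = []
    q = s = i = 0
    edits = hit.edits
    while i < len(edits):
        op = edits[i]
        if op == "=":
            q += 1
            s += 1
            i += 1
            continue
        if op == "X":
            events.append(EditEvent("point", s, q, query.seq[q]))
            q += 1
            s += 1
            i += 1
            continue
        j = i
        while j < len(edits) and edits[j] == op:
            j += 1
        run = j - i
        if op == "I":
            events.append(
                EditEvent("insertion", s, q, query.seq[q:q + run]))
            q += run
        else:
            events.append(
                EditEvent("deletion", s, q, ref.seq[s:s + run]))
            s += run
        i = j
    return events


def locus_identity(
    query: SeqRecord,
    ref: SeqRecord,
    locus_id: str | None = None,
    order_key: int = 0,
) -> LocusIdentity:
    """Percent identity and event breakdown for one homologous locus pair.

    Raises if identity falls below 60 % — that signals a mispaired locus
    rather than divergence.
    """
    hit = global_align(query, ref)
    if hit.identity < 0.60:
        raise SeqCoreError(
            f"identity {hit.identity:.0%} below 60%: check locus pairing "
            f"({query.id} vs {ref.id})"
        )
    events = enumerate_events(query, ref)
    n_point = n_rep = n_other = 0
    for ev in events:
        cls = classify_variant_type(ev, query, ref)
        if cls == "point":
            n_point += 1
        elif cls == "repeat_number":
            n_rep += 1
        else:
            n_other += 1
    return LocusIdentity(
        locus_id=locus_id or query.id,
        order_key=order_key,
        identity=100.0 * hit.identity,
        n_point=n_point,
        n_repeat_number=n_rep,
        n_other_indel=n_other,
        events=events,
    )


def strand_flip_pair(query: SeqRecord, ref: SeqRecord
                     ) -> tuple[SeqRecord, SeqRecord]:
    return query.reverse_complement(), ref.reverse_complement()


def hotspot_profile(
    loci: list[LocusIdentity],
    thresholds: HotspotThresholds | None = None,
) -> HotspotProfile:
    """Ordered categorical profile of loci by identity.

    Loci are ordered by their chromosome-position key (telomere first);
    each is categorised as preserved (identity at 100 %), hotspot
    (below the hotspot bound) or intermediate.
    """
    thresholds = thresholds or HotspotThresholds()
    ordered = sorted(loci, key=lambda l: l.order_key)
    cats = {}
    for l in ordered:
        if l.identity >= thresholds.preserved_min:
            cats[l.locus_id] = "preserved"
        elif l.identity < thresholds.hotspot_below:
            cats[l.locus_id] = "hotspot"
        else:
            cats[l.locus_id] = "intermediate"
    return HotspotProfile(loci=ordered, categories=cats,
                          thresholds=thresholds)


def profile_table(profile: HotspotProfile) -> "pandas.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "locus": l.locus_id,
                "order": l.order_key,
                "identity_pct": round(l.identity, 4),
                "n_point": l.n_point,
                "n_repeat_number": l.n_repeat_number,
                "n_other_indel": l.n_other_indel,
                "category": profile.categories[l.locus_id],
            }
            for l in profile.loci
        ]
    )


def plot_profile(profile: HotspotProfile, path: str) -> None:
    """Bar plot of identity by locus order (optional output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"hotspot": "#c0392b", "intermediate": "#e67e22",
              "preserved": "#27ae60"}
    fig, ax = plt.subplots(figsize=(max(4, len(profile.loci) * 0.5), 3))
    xs = range(len(profile.loci))
    ax.bar(
        xs,
        [l.identity for l in profile.loci],
        color=[colors[profile.categories[l.locus_id]]
               for l in profile.loci],
    )
    ax.set_xticks(list(xs))
    ax.set_xticklabels([l.locus_id for l in profile.loci], rotation=90,
                       fontsize=6)
    ax.set_ylim(min(95.0, min(l.identity for l in profile.loci) - 1), 100.5)
    ax.set_ylabel("% identity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
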