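"""Desk-checkable arithmetic on published subtelomere landmarks.

The reference distal region of the right subtelomere of chromosome 2
(PomBase coordinates) carries large strain-specific deletions whose
breakpoints are reported as chromosome positions, telomere-proximal end
first (the right arm runs telomere→centromere in decreasing
coordinates). The helicase-like gene at that locus has an in-frame ATG
543 bases upstream of its annotated start. These functions reproduce
the span and codon arithmetic from those coordinates.
"""

from __future__ import annotations

# Deletion breakpoints on PomBase chromosome 2 (1-based, inclusive;
# telomere-proximal coordinate first).
DELETION_BREAKPOINTS = {
    # the large deletion present in the right subtelomere of Ch1
    "SH1R_large": (4514836, 4507710),
    # the deletion present in the left subtelomere of Ch1
    "SH1L_large": (4500309, 4498438),
}

# Upstream in-frame start: distance from the annotated ATG in bases.
UPSTREAM_START_BP = 543


def deletion_span_bp(proximal: int, distal: int) -> int:
    """Inclusive span of a deletion given its two breakpoint positions."""
    return abs(proximal - distal) + 1


def deletion_span_kb(proximal: int, distal: int) -> float:
    """Deletion span rounded to 0.1 kb, the reporting precision."""
    return round(deletion_span_bp(proximal, distal) / 1000, 1)


def upstream_codons(distance_bp: int = UPSTREAM_START_BP) -> int:
    """Amino acids gained by starting ``distance_bp`` bases upstream."""
    if distance_bp % 3:
        raise ValueError("in-frame distance must be a codon multiple")
    return distance_bp // 3


def all_worked_examples() -> dict[str, float]:
    """Every desk check in one mapping (kb spans and codon count)."""
    out: dict[str, float] = {}
    for name, (p, d) in DELETION_BREAKPOINTS.items():
        out[f"{name}_deletion_kb"] = deletion_span_kb(p, d)
    out["upstream_start_aa"] = upstream_codons()
    return out
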