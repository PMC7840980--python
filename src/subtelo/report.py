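"""Report writers: BED, GFF3, minimal VCF 4.2, TSV tables and the text
mosaic diagram.

All writers convert the package's internal 0-based half-open intervals
to each format's native convention (BED stays 0-based; GFF3, VCF and
TSV tables are 1-based inclusive). The text diagram mirrors the figure
style of mosaic comparisons: one row per sequence, telomere on the
left, ``∆`` marking partial segments and ``?`` marking 75–90 %-identity
segments.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .seq_core import AlignmentHit, Interval, SeqRecord
from .shd_blocks import BlockHit, ForeignInsertion, IndelCall
from .shp_segmenter import (
    FLAG_LOWID,
    FLAG_PARTIAL,
    MosaicAnnotation,
    SegmentLibrary,
    UNMATCHED_LABEL,
)


def write_bed(
    rows: Iterable[tuple[Interval, str]] , path: str | Path
) -> None:
    """(interval, name) pairs as 6-column BED (0-based half-open)."""
    with open(path, "w") as fh:
        for iv, name in rows:
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{name}\t0\t"
                     f"{iv.strand}\n")


def mosaics_to_bed(anns: Sequence[MosaicAnnotation],
                   path: str | Path) -> None:
    rows = []
    for ann in anns:
        for t in ann.tiles:
            name = t.variant or t.label
            if FLAG_PARTIAL in t.flags:
                name += "_partial"
            if FLAG_LOWID in t.flags:
                name += "_lowid"
            rows.append((t.interval, name))
    write_bed(rows, path)


def mosaics_to_json(anns: Sequence[MosaicAnnotation]) -> list[dict]:
    return [
        {
            "seq_id": ann.seq_id,
            "tiles": [
                {
                    "start": t.interval.start,
                    "end": t.interval.end,
                    "strand": t.interval.strand,
                    "label": t.label,
                    "variant": t.variant,
                    "flags": sorted(t.flags),
                    "identity": t.identity,
                }
                for t in ann.tiles
            ],
        }
        for ann in anns
    ]


def library_tables(
    library: SegmentLibrary,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """(exemplar records, occurrence table with 1-based coordinates)."""
    recs = library.exemplar_records()
    rows = []
    for c in library.classes:
        for iv, var in zip(c.occurrences, c.variant_by_occurrence):
            rows.append({
                "class": c.label,
                "variant": var,
                "seq_id": iv.seq_id,
                "start": iv.start1,
                "end": iv.end,
                "strand": iv.strand,
                "length": len(iv),
            })
    return recs, pd.DataFrame(rows)


def render_mosaic_text(anns: Sequence[MosaicAnnotation]) -> str:
    """One aligned row per sequence: ``tel–A1–∆B2–C?``."""
    lines = []
    width = max((len(a.seq_id) for a in anns), default=0)
    for ann in anns:
        parts = []
        for t in ann.tiles:
            if t.label == UNMATCHED_LABEL:
                sym = "■"
            else:
                sym = t.variant or t.label
                if FLAG_PARTIAL in t.flags:
                    sym = "∆" + sym
                if FLAG_LOWID in t.flags:
                    sym += "?"
            parts.append(sym)
        lines.append(f"{ann.seq_id:<{width}}  tel–" + "–".join(parts))
    return "\n".join(lines)


def blocks_to_tsv(hits: Sequence[BlockHit], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "block": b.block_id,
                "seq_id": b.query.seq_id,
                "start": b.query.start1,
                "end": b.query.end,
                "orientation": b.orientation,
                "identity": round(b.identity, 4),
                "length_delta": b.length_delta,
                "low_confidence": b.low_confidence,
            }
            for b in hits
        ]
    ).to_csv(path, sep="\t", index=False)


def indels_to_tsv(
    calls: Sequence[IndelCall], ref_id: str, path: str | Path,
    min_size: int = 10,
) -> None:
    """VCF-like TSV; micro calls below ``min_size`` are suppressed, the
    convention for figure-level reporting."""
    rows = []
    for c in calls:
        if c.size < min_size:
            continue
        row = {
            "CHROM": ref_id,
            "POS": c.ref_position,  # 1-based telomere-proximal flank
            "SVTYPE": "INS" if c.kind == "insertion" else "DEL",
            "SVLEN": c.size if c.kind == "insertion" else -c.size,
            "SIZE_CLASS": c.size_class,
            "BOXA": "",
            "BOXB": "",
        }
        if c.flanking_boxes:
            a, b = c.flanking_boxes
            row["BOXA"] = f"{a.query.start1}-{a.query.end}"
            row["BOXB"] = f"{a.subject.start1}-{a.subject.end}"
        rows.append(row)
    pd.DataFrame(
        rows, columns=["CHROM", "POS", "SVTYPE", "SVLEN", "SIZE_CLASS",
                       "BOXA", "BOXB"]
    ).to_csv(path, sep="\t", index=False)


def indels_to_vcf(
    calls: Sequence[IndelCall], ref: SeqRecord, path: str | Path,
    min_size: int = 1,
) -> None:
    """Minimal VCF 4.2 with anchor-base REF/ALT encoding."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={ref.id},length={len(ref.seq)}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,'
                 'Description="Type of change">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,'
                 'Description="Signed length of change">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: c.ref_position):
            if c.size < min_size:
                continue
            anchor_i = c.ref_position - 1  # 0-based anchor base
            if anchor_i < 0:
                continue
            anchor = ref.seq[anchor_i]
            if c.kind == "deletion":
                ref_a = anchor + ref.seq[anchor_i + 1:anchor_i + 1 + c.size]
                alt = anchor
                svlen = -c.size
            else:
                ref_a = anchor
                alt = anchor + c.evidence
                svlen = c.size
            fh.write(
                f"{ref.id}\t{c.ref_position}\t.\t{ref_a}\t{alt}\t.\tPASS\t"
                f"SVTYPE={'DEL' if svlen < 0 else 'INS'};SVLEN={svlen}\n"
            )


def foreign_to_gff3(
    fis: Sequence[ForeignInsertion], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in fis:
            fh.write(
                f"{f.query.seq_id}\tsubtelo\tmobile_genetic_element\t"
                f"{f.query.start1}\t{f.query.end}\t.\t{f.query.strand}\t.\t"
                f"Name={f.source_id};label={f.source_label};"
                f"identity={f.identity:.3f}\n"
            )


def orfs_to_gff3(orfs, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, o in enumerate(orfs):
            iv = o.interval
            fh.write(
                f"{iv.seq_id}\tsubtelo\tORF\t{iv.start1}\t{iv.end}\t.\t"
                f"{iv.strand}\t0\tID=orf{i};aa_length={o.aa_length}\n"
            )


def consensus_support_tsv(support: Sequence[float],
                          path: str | Path) -> None:
    pd.DataFrame({"position": range(1, len(support) + 1),
                  "support": [round(s, 4) for s in support]}
                 ).to_csv(path, sep="\t", index=False)
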