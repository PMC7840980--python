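#!/usr/bin/env python
"""Annotate the simulated distal pair: block map with orientation,
anchored indel calls with flanking-homology boxes on structural
changes, and foreign-insertion flags. Writes results/distal/."""

import pandas as pd
from pathlib import Path

from subtelo import report
from subtelo.seq_core import read_fasta
from subtelo.shd_blocks import (
    build_block_map,
    call_indels,
    detect_flanking_homology,
    detect_foreign_insertions,
)

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "distal"
OUT.mkdir(parents=True, exist_ok=True)

ref, query = read_fasta(BASE / "simulated" / "shd_pair.fasta")
foreign = read_fasta(BASE / "simulated" / "foreign_library.fasta")
blocks = [
    (r["block"], int(r["start"]), int(r["end"]))
    for _, r in pd.read_csv(BASE / "simulated" / "blocks.tsv",
                            sep="\t").iterrows()
]

hits = build_block_map(query, ref, blocks)
report.blocks_to_tsv(hits, OUT / "block_map.tsv")
report.write_bed([(b.query, b.block_id) for b in hits],
                 OUT / "block_map.bed")

calls = call_indels(query, ref, blocks=blocks, block_hits=hits)
calls = [detect_flanking_homology(c, query, ref)
         if c.size_class == "structural" else c for c in calls]
report.indels_to_tsv(calls, ref.id, OUT / "indel_calls.tsv")
report.indels_to_vcf(calls, ref, OUT / "indel_calls.vcf")

fis = detect_foreign_insertions(query, foreign)
report.foreign_to_gff3(fis, OUT / "foreign_insertions.gff3")

print("block map:")
for b in hits:
    print(f"  {b.block_id:>4} {b.query.start1}-{b.query.end} "
          f"{b.orientation} id={b.identity:.3f} delta={b.length_delta}")
print("indels >=10 bp:")
for c in calls:
    if c.size >= 10:
        boxes = " +boxes" if c.flanking_boxes else ""
        print(f"  {c.kind:>9} at {c.ref_position} size {c.size} "
              f"({c.size_class}){boxes}")
print(f"foreign insertions: "
      f"{[(f.source_label, f.query.start1, f.query.end) for f in fis]}")
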