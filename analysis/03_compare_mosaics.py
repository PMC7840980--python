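#!/usr/bin/env python
"""Compare the mosaic patterns across regions: pairwise same-pattern
table at class and variant level, shared runs, and chromosome-end
architecture groups. Writes results/comparisons/."""

import json
from pathlib import Path

from subtelo.mosaic_compare import (
    architecture_groups,
    classify_end_architecture,
    pairwise_pattern_table,
    shared_runs,
    to_mosaic_string,
)
from subtelo.seq_core import read_fasta
from subtelo.shp_segmenter import build_segment_library

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "comparisons"
OUT.mkdir(parents=True, exist_ok=True)

seqs = read_fasta(BASE / "simulated" / "shp_regions.fasta")
library, anns = build_segment_library(seqs)
strings = [to_mosaic_string(a) for a in anns]

table = pairwise_pattern_table(strings)
table.to_csv(OUT / "pattern_comparison.tsv", sep="\t")

runs_out = {}
for i, a in enumerate(strings):
    for b in strings[i + 1:]:
        rs = shared_runs(a, b, level="class", min_run=2)
        if rs:
            runs_out[f"{a.seq_id}|{b.seq_id}"] = [
                {"a_start": r.a_start, "b_start": r.b_start,
                 "length": r.length} for r in rs
            ]
(OUT / "shared_runs.json").write_text(json.dumps(runs_out, indent=1))

groups = architecture_groups(classify_end_architecture(anns))
lines = [f"Tel-{'-'.join(sig)}: {', '.join(ids)}"
         for sig, ids in groups.items()]
(OUT / "end_architectures.txt").write_text("\n".join(lines) + "\n")

print(table.to_string())
print(f"\n{len(runs_out)} region pairs share a run of >=2 consecutive "
      f"segments; {len(groups)} distinct end architectures:")
print("\n".join(lines))
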