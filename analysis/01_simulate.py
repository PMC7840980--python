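#!/usr/bin/env python
"""Generate the synthetic study inputs with their truth sets.

Writes FASTA inputs and JSON truth files under results/simulated/:
a shared-segment library, five mosaic telomere-proximal regions, a
30 kb telomere-distal reference/query pair with planted events, a
helicase-like locus pair, and 40 telomere-anchored long reads from two
chromosome-end templates.
"""

import random
import sys
from pathlib import Path

from subtelo.seq_core import SeqRecord, write_fasta
from subtelo.synth_data import (
    _rand_dna,
    gen_patterns,
    gen_reads,
    gen_segment_library,
    gen_shd,
    gen_shp,
    gen_tlh,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"
OUT.mkdir(parents=True, exist_ok=True)

exemplars, lib_truth = gen_segment_library(seed=SEED)
patterns = gen_patterns([r.id for r in exemplars], 5, seed=SEED)
shp, shp_truth = gen_shp(exemplars, patterns, seed=SEED)
ref, query, blocks, foreign, shd_truth = gen_shd(seed=SEED)
tlh_ref, tlh_query, tlh_truth = gen_tlh(seed=SEED)
rng = random.Random(SEED ^ 0xE11D)
ends = [SeqRecord(f"end{i}", _rand_dna(rng, 5000)) for i in range(2)]
reads, read_truth = gen_reads(ends, coverage=20, error_rate=0.08,
                              seed=SEED, read_len_range=(5000, 5000))

write_fasta(exemplars, OUT / "segment_library.fasta")
write_fasta(shp, OUT / "shp_regions.fasta")
write_fasta([ref, query], OUT / "shd_pair.fasta")
write_fasta(foreign, OUT / "foreign_library.fasta")
write_fasta([tlh_ref, tlh_query], OUT / "tlh_pair.fasta")
write_fasta(ends + reads, OUT / "reads.fasta")
(OUT / "blocks.tsv").write_text(
    "block\tstart\tend\n" + "\n".join(f"{n}\t{s}\t{e}"
                                      for n, s, e in blocks) + "\n")
for name, truth in (("library", lib_truth), ("shp", shp_truth),
                    ("shd", shd_truth), ("tlh", tlh_truth),
                    ("reads", read_truth)):
    truth.to_json(OUT / f"truth_{name}.json")

print(f"seed {SEED}: {len(exemplars)} segment classes, "
      f"{len(shp)} mosaic regions ({sum(len(s.seq) for s in shp)} bp), "
      f"distal pair {len(ref.seq)}/{len(query.seq)} bp, "
      f"{len(reads)} reads -> {OUT}")
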