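#!/usr/bin/env python
"""Per-locus identity profile along a synthetic chromosome arm whose
mutation rate decays away from the telomere, demonstrating how
subtelomeric loci surface as hotspots. Writes results/hotspots/."""

import random
from pathlib import Path

from subtelo.identity_hotspots import (
    hotspot_profile,
    locus_identity,
    plot_profile,
    profile_table,
)
from subtelo.seq_core import SeqRecord
from subtelo.synth_data import _mutate_substitutions, _rand_dna

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "hotspots"
OUT.mkdir(parents=True, exist_ok=True)

rng = random.Random(0)
# mutation rate decays telomere -> centromere; one distal outlier locus
rates = [0.02, 0.012, 0.006, 0.002, 0.0, 0.0, 0.0, 0.008, 0.0, 0.0]
loci = []
for i, rate in enumerate(rates):
    ref = _rand_dna(rng, 2000)
    query, _ = _mutate_substitutions(rng, ref, rate)
    loci.append(
        locus_identity(SeqRecord(f"locus{i:02d}", query),
                       SeqRecord("ref", ref),
                       locus_id=f"locus{i:02d}", order_key=i))

profile = hotspot_profile(loci)
table = profile_table(profile)
table.to_csv(OUT / "locus_identity.tsv", sep="\t", index=False)
plot_profile(profile, str(OUT / "identity_profile.png"))

print(table.to_string(index=False))
n_hot = sum(1 for c in profile.categories.values() if c == "hotspot")
print(f"\n{n_hot} hotspot loci; telomere-proximal loci carry the "
      f"highest point-mutation loads, plus one distal outlier "
      f"(locus07, emulating an arm-internal variable gene).")
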