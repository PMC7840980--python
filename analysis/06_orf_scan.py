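#!/usr/bin/env python
"""Helicase-like locus analysis of the simulated pair: upstream
in-frame start candidates with Kozak context, ORF calls, and the
coding-change ledger (point/indel events, repeat contexts, frame and
stop status). Writes results/orf/."""

import json
from pathlib import Path

from subtelo import report
from subtelo.orf_scan import (
    OrfCall,
    diff_coding,
    find_orfs,
    find_upstream_inframe_start,
)
from subtelo.seq_core import Interval, read_fasta
from subtelo.synth_data import TruthSet

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "orf"
OUT.mkdir(parents=True, exist_ok=True)

ref, query = read_fasta(BASE / "simulated" / "tlh_pair.fasta")
truth = TruthSet.from_json(BASE / "simulated" / "truth_tlh.json")
c = truth.coding

orfs = find_orfs(ref, min_aa=100)
report.orfs_to_gff3(orfs, OUT / "ref_orfs.gff3")

rep = find_upstream_inframe_start(ref, c["dM"])
print("upstream in-frame start candidates (from the annotated ATG):")
for cand in rep.candidates:
    mark = " <- chosen" if cand is rep.chosen else ""
    print(f"  -{cand.distance_bp} bp ({cand.distance_codons} codons), "
          f"Kozak={'yes' if cand.kozak else 'no'}{mark}")

oc = OrfCall(interval=Interval(ref.id, c["orf_start"], c["orf_end"]),
             frame=c["orf_start"] % 3,
             aa_length=(c["orf_end"] - c["orf_start"]) // 3 - 1)
diff = diff_coding(query, ref, oc)
print("\ncoding-change ledger (vs the reference ORF):")
for e in diff.events:
    sym = {"point": "*", "insertion": "^", "deletion": "v"}[e.kind]
    ctx = f"  [{e.repeat_context}]n context" if e.repeat_context else ""
    print(f"  {sym} codon {e.ref_codon:>4}: {e.kind} {e.size} bp{ctx}")
print(f"frame shift: {diff.frame_shift}; "
      f"premature stop: {diff.premature_stop}")

(OUT / "orf_report.json").write_text(json.dumps({
    "upstream_candidates": [
        {"distance_bp": x.distance_bp, "codons": x.distance_codons,
         "kozak": x.kozak} for x in rep.candidates],
    "chosen_distance_bp": rep.chosen.distance_bp if rep.chosen else None,
    "events": [
        {"kind": e.kind, "ref_codon": e.ref_codon, "size": e.size,
         "repeat_context": e.repeat_context} for e in diff.events],
    "frame_shift": diff.frame_shift,
    "premature_stop": diff.premature_stop,
}, indent=1))
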