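"""End-to-end orchestration of the subtelomere annotation stages.

A :class:`RunConfig` (usually loaded from YAML) names the inputs and
parameters; :func:`run_all` executes the enabled stages in dependency
order and writes a :class:`ReportBundle` — segment library, mosaics,
comparisons, block map, indel calls, hotspot profile, ORF reports and
read clusters/consensus — plus a manifest recording parameters, seed
and every output file. Given the same config and seed the bundle is
byte-identical (timestamps are excluded by design).

The ``demo`` entry point runs the full pipeline on internally generated
synthetic data with a known truth set, which doubles as an end-to-end
self-check.
"""

from __future__ import annotations

import json
import logging
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import report, synth_data
from .identity_hotspots import hotspot_profile, locus_identity, profile_table
from .mosaic_compare import (
    architecture_groups,
    classify_end_architecture,
    pairwise_pattern_table,
    to_mosaic_string,
)
from .orf_scan import OrfCall, diff_coding, find_orfs, find_upstream_inframe_start
from .seq_core import Interval, SeqRecord, read_fasta, write_fasta
from .shd_blocks import (
    build_block_map,
    call_indels,
    detect_flanking_homology,
    detect_foreign_insertions,
)
from .shp_segmenter import SegmentParams, annotate_mosaic, build_segment_library
from .telomere_harvest import build_consensus, cluster_reads, harvest

log = logging.getLogger("subtelo")


@dataclass
class RunConfig:
    out_dir: str = "subtelo_out"
    seed: int = 0
    # inputs (absent input disables the stage)
    shp_fasta: str | None = None
    shd_query_fasta: str | None = None
    shd_ref_fasta: str | None = None
    blocks_tsv: str | None = None
    foreign_fasta: str | None = None
    reads_fasta: str | None = None
    loci_query_fasta: str | None = None
    loci_ref_fasta: str | None = None
    tlh_query_fasta: str | None = None
    tlh_ref_fasta: str | None = None
    simulate: bool = False
    # parameters
    min_seg_len: int = 50
    min_seg_id: float = 0.95
    min_gap_len: int = 14
    block_min_id: float = 0.90
    telomere_motif: str = "GGTTAC"
    cluster_window: int = 1000
    cluster_min_id: float = 0.80

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def segment_params(self) -> SegmentParams:
        return SegmentParams(min_seg_len=self.min_seg_len,
                             min_seg_id=self.min_seg_id,
                             min_gap_len=self.min_gap_len)


@dataclass
class ReportBundle:
    out_dir: Path
    files: dict[str, str] = field(default_factory=dict)
    summary: dict[str, Any] = field(default_factory=dict)

    def add(self, key: str, path: Path) -> None:
        self.files[key] = str(path)

    def write_manifest(self, config: RunConfig) -> None:
        manifest = {
            "config": asdict(config),
            "files": self.files,
            "summary": self.summary,
        }
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        self.files["manifest"] = str(path)


def _simulate_inputs(config: RunConfig, out: Path) -> dict[str, Any]:
    """Generate the full synthetic input suite under the output dir."""
    seed = config.seed
    exemplars, lib_truth = synth_data.gen_segment_library(seed)
    patterns = synth_data.gen_patterns([r.id for r in exemplars], 5,
                                       seed=seed)
    shp, shp_truth = synth_data.gen_shp(exemplars, patterns, seed=seed)
    ref, query, blocks, foreign, shd_truth = synth_data.gen_shd(seed=seed)
    tlh_ref, tlh_query, tlh_truth = synth_data.gen_tlh(seed=seed)
    rng = random.Random(seed ^ 0xE11D)
    ends = [
        SeqRecord(f"end{i}", synth_data._rand_dna(rng, 5000))
        for i in range(2)
    ]
    reads, read_truth = synth_data.gen_reads(
        ends, motif=config.telomere_motif, seed=seed)

    sim = out / "simulated"
    sim.mkdir(parents=True, exist_ok=True)
    write_fasta(shp, sim / "shp.fasta")
    write_fasta([ref, query], sim / "shd.fasta")
    write_fasta(foreign, sim / "foreign.fasta")
    write_fasta([tlh_ref, tlh_query], sim / "tlh.fasta")
    write_fasta(reads, sim / "reads.fasta")
    for name, truth in (("library", lib_truth), ("shp", shp_truth),
                        ("shd", shd_truth), ("tlh", tlh_truth),
                        ("reads", read_truth)):
        truth.to_json(sim / f"truth_{name}.json")
    return {
        "shp": shp, "shd_ref": ref, "shd_query": query, "blocks": blocks,
        "foreign": foreign, "tlh_ref": tlh_ref, "tlh_query": tlh_query,
        "tlh_truth": tlh_truth, "reads": reads, "ends": ends,
    }


def run_all(config: RunConfig) -> ReportBundle:
    """Execute every stage enabled by the config, in dependency order."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(out_dir=out)
    data: dict[str, Any] = {}

    if config.simulate:
        log.info("simulating inputs (seed %d)", config.seed)
        data = _simulate_inputs(config, out)
    if config.shp_fasta:
        data["shp"] = read_fasta(config.shp_fasta)
    if config.shd_ref_fasta:
        data["shd_ref"] = read_fasta(config.shd_ref_fasta)[0]
    if config.shd_query_fasta:
        data["shd_query"] = read_fasta(config.shd_query_fasta)[0]
    if config.foreign_fasta:
        data["foreign"] = read_fasta(config.foreign_fasta)
    if config.reads_fasta:
        data["reads"] = read_fasta(config.reads_fasta)
    if config.tlh_ref_fasta:
        data["tlh_ref"] = read_fasta(config.tlh_ref_fasta)[0]
    if config.tlh_query_fasta:
        data["tlh_query"] = read_fasta(config.tlh_query_fasta)[0]
    if config.blocks_tsv:
        import pandas as pd

        tbl = pd.read_csv(config.blocks_tsv, sep="\t")
        data["blocks"] = [
            (r["block"], int(r["start"]), int(r["end"]))
            for _, r in tbl.iterrows()
        ]

    # ---- proximal mosaics -------------------------------------------
    if "shp" in data:
        log.info("segmenting %d proximal regions", len(data["shp"]))
        params = config.segment_params()
        library, anns = build_segment_library(data["shp"], params)
        recs, occ = report.library_tables(library)
        write_fasta(recs, out / "segment_exemplars.fasta")
        occ.to_csv(out / "segment_occurrences.tsv", sep="\t", index=False)
        report.mosaics_to_bed(anns, out / "mosaics.bed")
        (out / "mosaics.json").write_text(
            json.dumps(report.mosaics_to_json(anns), indent=1))
        (out / "mosaics.txt").write_text(report.render_mosaic_text(anns)
                                         + "\n")
        for key in ("segment_exemplars.fasta", "segment_occurrences.tsv",
                    "mosaics.bed", "mosaics.json", "mosaics.txt"):
            bundle.add(key, out / key)
        bundle.summary["n_segment_classes"] = len(library.classes)
        strings = [to_mosaic_string(a) for a in anns]
        pairwise_pattern_table(strings).to_csv(
            out / "pattern_comparison.tsv", sep="\t")
        archs = classify_end_architecture(anns)
        groups = architecture_groups(archs)
        (out / "end_architectures.txt").write_text(
            "\n".join(f"{'-'.join(sig)}: {', '.join(ids)}"
                      for sig, ids in groups.items()) + "\n")
        bundle.add("pattern_comparison.tsv", out / "pattern_comparison.tsv")
        bundle.add("end_architectures.txt", out / "end_architectures.txt")
        bundle.summary["n_end_architectures"] = len(groups)
        data["library"] = library

    # ---- distal blocks and indels -----------------------------------
    if "shd_ref" in data and "shd_query" in data and "blocks" in data:
        log.info("mapping blocks and calling indels")
        hits = build_block_map(data["shd_query"], data["shd_ref"],
                               data["blocks"], config.block_min_id)
        report.blocks_to_tsv(hits, out / "block_map.tsv")
        report.write_bed([(b.query, b.block_id) for b in hits],
                         out / "block_map.bed")
        calls = call_indels(data["shd_query"], data["shd_ref"],
                            blocks=data["blocks"], block_hits=hits)
        calls = [
            detect_flanking_homology(c, data["shd_query"], data["shd_ref"])
            if c.size_class == "structural" else c
            for c in calls
        ]
        report.indels_to_tsv(calls, data["shd_ref"].id,
                             out / "indel_calls.tsv")
        report.indels_to_vcf(calls, data["shd_ref"], out / "indel_calls.vcf")
        for key in ("block_map.tsv", "block_map.bed", "indel_calls.tsv",
                    "indel_calls.vcf"):
            bundle.add(key, out / key)
        bundle.summary["n_blocks_placed"] = len(hits)
        bundle.summary["n_indels_ge10bp"] = sum(
            1 for c in calls if c.size >= 10)
        if "foreign" in data:
            fis = detect_foreign_insertions(data["shd_query"],
                                            data["foreign"])
            report.foreign_to_gff3(fis, out / "foreign_insertions.gff3")
            bundle.add("foreign_insertions.gff3",
                       out / "foreign_insertions.gff3")
            bundle.summary["n_foreign_insertions"] = len(fis)

    # ---- ORF analysis ------------------------------------------------
    if "tlh_ref" in data and "tlh_query" in data:
        log.info("scanning helicase-like locus")
        orfs = find_orfs(data["tlh_ref"], min_aa=100)
        report.orfs_to_gff3(orfs, out / "ref_orfs.gff3")
        bundle.add("ref_orfs.gff3", out / "ref_orfs.gff3")
        if orfs:
            main = max(orfs, key=lambda o: o.aa_length)
            start_rep = None
            truth = data.get("tlh_truth")
            annotated = (truth.coding["dM"] if truth
                         else main.interval.start)
            if data["tlh_ref"].seq[annotated:annotated + 3] == "ATG":
                start_rep = find_upstream_inframe_start(
                    data["tlh_ref"], annotated)
            diff = diff_coding(data["tlh_query"], data["tlh_ref"], main)
            orf_report = {
                "main_orf": {
                    "start": main.interval.start1,
                    "end": main.interval.end,
                    "aa_length": main.aa_length,
                },
                "upstream_start": (
                    {
                        "candidates": [
                            {"distance_bp": c.distance_bp,
                             "distance_codons": c.distance_codons,
                             "kozak": c.kozak}
                            for c in start_rep.candidates
                        ],
                        "chosen_distance_bp":
                            start_rep.chosen.distance_bp
                            if start_rep.chosen else None,
                    } if start_rep else None
                ),
                "coding_diff": {
                    "events": [
                        {"kind": e.kind, "ref_codon": e.ref_codon,
                         "size": e.size,
                         "repeat_context": e.repeat_context}
                        for e in diff.events
                    ],
                    "frame_shift": diff.frame_shift,
                    "premature_stop": diff.premature_stop,
                },
            }
            (out / "orf_report.json").write_text(
                json.dumps(orf_report, indent=1))
            bundle.add("orf_report.json", out / "orf_report.json")
            bundle.summary["n_coding_events"] = len(diff.events)

    # ---- read harvest -----------------------------------------------
    if "reads" in data:
        log.info("harvesting %d reads", len(data["reads"]))
        hv = harvest(data["reads"], motif=config.telomere_motif)
        clusters = cluster_reads(hv, window=config.cluster_window,
                                 cluster_min_id=config.cluster_min_id)
        rows = []
        cons_records = []
        for i, cl in enumerate(clusters):
            cons = build_consensus(cl, hv)
            cons_records.append(
                SeqRecord(f"cluster{i:02d}", cons.sequence,
                          f"members={len(cl.member_ids)} "
                          f"reliable={cl.reliable}"))
            rows.append({
                "cluster": f"cluster{i:02d}",
                "n_members": len(cl.member_ids),
                "reliable": cl.reliable,
                "members": ",".join(cl.member_ids),
            })
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "read_clusters.tsv", sep="\t",
                                  index=False)
        write_fasta(cons_records, out / "consensus.fasta")
        bundle.add("read_clusters.tsv", out / "read_clusters.tsv")
        bundle.add("consensus.fasta", out / "consensus.fasta")
        bundle.summary["n_read_clusters"] = len(clusters)

    bundle.write_manifest(config)
    log.info("bundle written to %s", out)
    return bundle


def demo(out_dir: str = "subtelo_demo", seed: int = 0) -> ReportBundle:
    """Full synthetic run: simulate every input, run every stage."""
    return run_all(RunConfig(out_dir=out_dir, seed=seed, simulate=True))
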