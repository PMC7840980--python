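# Methods

This package annotates fission-yeast–style subtelomeres. A chromosome
end is modelled as a telomere-repeat tract, a telomere-proximal region
(a few kb) that is a **mosaic of shared segments** recurring across
ends at >95 % identity, and a telomere-distal region (tens of kb) of
large **homologous blocks** in conserved order (>90 % identity between
copies) punctuated by indels, inversions and foreign insertions.
Subtelomeric helicase-like genes and repeat-slippage mutation
signatures get dedicated treatment. Every stage can be exercised on
synthetic data with a complete truth set.

## Alignment primitives

Identity is always matched columns divided by all alignment columns,
gap columns included — the convention of the blastn tool family, whose
thresholds (>95 % segments, >90 % blocks) the classification inherits.
Strict/inclusive comparison of thresholds is configurable
(`inclusive_identity`); ">" is treated as strict by default, "no less
than" as inclusive.

Local alignment is affine-gap Smith–Waterman with match +1, mismatch
−2, gap open −5, gap extension −2 (the blastn gap-cost regime). Gap
extension must be expensive enough that an alignment cannot profitably
bridge two genuinely shared segments across an unrelated insertion;
with cheap extensions, mosaic tiles merge. The implementation is exact
(full anti-diagonal-vectorised DP) for inputs up to ~2 kb and k-mer
seeded (k = 12, chained on diagonals, each chain refined by exact DP in
a window) above that. "All hits" on small inputs come from iterated
masking run in both directions, because one-sided masking misses the
second of two subject copies of one query region. Raw hits are split at
gap runs longer than `max_gap` (default 10 bp; 150 bp at block scale,
where internal small indels are expected) and at windows whose local
identity falls below 0.75 — an unrelated region otherwise rides along
as ~50 %-identity "mush" instead of a clean gap.

Global alignment uses edit-distance-optimal alignment (edlib) and
reports the column identity of that alignment. Edit distance is unique;
column identity can differ slightly between co-optimal paths, which is
why property tests pin the distance, not the identity.

## Segment library construction (proximal mosaics)

Pass 1 finds all pairwise local hits of ≥50 bp above 95 % identity and
tiles the sequences greedily, longest hit first (ties: leftmost, then
lexicographic id). A later hit that lands ≥80 % inside an existing tile
merges classes (union–find) instead of re-placing; partially
overlapping hits are trimmed to free sequence. Pass 2 re-searches the
inter-tile gaps at ≥14 bp, keeping only gap segments that recur in at
least two different sequences. Residual gaps ≥14 bp become `unmatched`
tiles.

Greedy placement leaves two systematic artefacts that are corrected by
three refinement phases, all driven by cross-occurrence consensus:

1. **Footprint voting.** Chance matches between the flanks of two
   occurrences extend a hit a few bp past the true boundary. Each
   occurrence (with a 16 bp genomic margin) is locally aligned to the
   class exemplar and the modal footprint start/end adopted (ties break
   inward). The margin lets the vote see past a placement that was
   trimmed short, e.g. by a noisy founding occurrence.
2. **Column-consensus trim.** Junk that survives the mode (it can be
   shared pairwise when both occurrences derive from the same founding
   hit) disagrees across the remaining contexts: each class end is
   trimmed back to the first run of ten consensus columns (one
   dissenting occurrence tolerated for classes with ≥4 copies; trims
   capped at 12 bp and skipped for segments shorter than 36 bp).
3. **Consensus extension.** Bases a neighbouring class's junk stole
   during placement are reclaimed by extending a class end while the
   next flanking base is unanimous across all occurrences and unowned.

On clean data these phases make all occurrences of a class
string-identical again, so the 100 %-identity *variant* partition
(A1, A2, …) is exact; with ≤1 % substitution noise, boundaries stay
within ±5 bp (measured 100 % of tiles at two seeds).

*Variants* are byte-identical occurrence strings after strand
normalisation, numbered by first appearance. *Subtype* classes (tandem
arrays of a 20–60 bp unit) are detected by self-alignment periodicity:
the smallest period p with ≥82 % positional agreement and an integer
copy number; unit families may diverge down to 0.82 pairwise identity
(motif families are observed down to >82 %).

Annotating a foreign sequence against a built library places exemplar
hits greedily; a tile at ≥90 % identity to its exemplar is plain,
75–90 % carries the `low_id` ("?") flag, and a length deficit ≥10 bp
carries `partial_delta` ("∆"). Note the gapped identity of a sequence
with substitution rate r is noticeably above 1−r (gaps rescue
mismatches), so e.g. a 12 % substitution rate lands near 0.92, not
0.88.

### What the generator must guarantee

`gen_patterns` enforces that no ordered pair of adjacent classes occurs
twice anywhere in a mosaic set (and no class neighbours itself). If two
sequences shared the adjacency A–B, the maximal shared run would
legitimately span both segments and no alignment-based method could
recover the single-segment truth; the published decompositions faced
the same ambiguity and resolved it by hand. Exemplars are mutually
dissimilar: no shared-segment hit at the discovery thresholds and
positionwise identity <0.5. (Gapped NW identity of unrelated random DNA
is ~0.52, so a gapped-identity bound of 0.5 is unattainable for any
random-sequence generator; the guarantee is therefore stated
ungapped.)

## Distal blocks, indels and boxes

Blocks are reference-defined spans placed on the query by local
alignment on both strands (best non-overlapping placement; overlaps up
to 30 bp from chance extensions trimmed; duplications yield multiple
hits; inverted placements flagged). Hits below the >90 % identity bound
but above 0.75 over ≥100 bp are reported with a low-confidence "?"
flag rather than dropped, a stand-in for E-value-based rescue of
clearly homologous but diverged copies.

Indel calling aligns syntenic spans between consecutive forward block
anchors (each hit records the block portion it actually covers, so a
truncated hit anchors correctly; spans adjacent to inverted blocks are
skipped — an inversion is not an indel). Within a span, edit-distance
alignment scatters a multi-kb indel across chance matches, so large
length differences are resolved structurally first: exact common
prefix/suffix trimming isolates a single contiguous change where
possible, otherwise the span is bisected at a strong unique internal
anchor and recursed; only residual spans with ≤100 bp length difference
go through ordinary global alignment. Gap runs become calls with size
classes micro (<10 bp, suppressed in reports), small (10–40 bp) and
structural (>40 bp). Calls are left-normalised (pushed
telomere-proximal, the convention for reporting one position per
change), re-merged across co-optimal splits (≤20 bp apart; ≤6 bp for
coding ledgers) and re-derived from exact flank matching in a ±40 bp
window, which repairs off-rotation gap content. The conservation
invariant — net inserted minus deleted bases equals the length
difference — holds by construction.

Flanking-homology boxes: the two ends of a structural change are
searched (2 kb windows) for a pair of spans ≥100 bp aligning to each
other at ≥0.83 — the floor of the observed box-identity range (83–85 %
at the most diverged pair). A pair planted exactly at the floor can
realise below it by binomial wobble (sd ≈ 0.02 at 300 bp), so the
recovery tests plant at ≥0.89; the detector itself is unchanged.

Foreign insertions are local hits of supplied exemplars (labelled
LTR-like / mitochondrial-like / unknown from the exemplar id).

## Locus identity and hotspots

Per-locus identity is the global-alignment column identity (as a
percentage), with every event classified: substitutions are points; an
indel is a repeat-number change iff the changed string is an integer
number of copies of a 1–6 bp unit present in ≥3 adjacent copies at the
site in the reference (three copies, not two, so that arbitrary 1 bp
indels do not count as slippage); everything else is `other_indel`.
Loci at 100 % are preserved, below 99.9 % hotspots, in between
intermediate; the thresholds are configuration, as the source material
uses qualitative categories only.

## ORF analysis

ORFs are maximal (leftmost ATG per stop-bounded frame region, stop
codon required, standard nuclear code, both strands). The upstream-start
scan walks in frame from an annotated ATG until the first in-frame
stop, reporting every ATG with distance (bp and codons) and Kozak
status (A/GNNATGG: −3 ∈ {A,G} and +4 = G); the chosen upstream start is
the farthest Kozak-positive candidate, else the farthest (all
candidates are reported, since the underlying biology does not dictate
a selection rule). The coding ledger aligns the located homolog
(≥60 % identity required) of a reference ORF and reports events with
1-based reference codon positions; the frame-shift flag is true iff the
running net indel size is ever ≢ 0 (mod 3); the premature-stop flag is
decided by translating the query from the base aligned to the reference
start. Insertions get a repeat context: the tandem unit (≤6 bp, ≥2
adjacent reference copies) the insertion duplicates. Left-normalisation
reports the canonical (leftmost) placement, so the unit may be a
rotation of the planted motif — `[AATGAC]n` and `[ATGACA]n` describe
the same array.

## Telomere-anchored reads

Tract detection counts motif copies (default unit `GGTTAC`, one edit
allowed per copy) from candidate offsets within 100 bp of either read
end, resynchronising across a corrupted copy; a lone copy reached only
by resynchronisation never extends the trim point, because a chance
motif-like k-mer at the start of the unique sequence would otherwise be
swallowed systematically on every read. Harvested reads are oriented
telomere-left, trimmed, and clustered by single linkage on the global
identity of their first 1 kb (≥0.80). Clusters of fewer than five reads
are flagged unreliable, following the convention that sequence
supported by fewer than five reads is not trusted.

Consensus is a star alignment against the longest member, polished in
two rounds (the second vote runs against the round-one consensus, which
removes ambiguity caused by the representative's own errors). Member
starts are anchored by a local head alignment (trim jitter of a few bp
would otherwise shear the first columns), insertion votes are
left-normalised to a canonical column and aggregated by per-position
plurality (identical-string voting fragments on longer insertions), and
low-coverage end columns are dropped. At 8 % uniform error
(substitution:insertion:deletion = 2:1:1) and coverage 20 the consensus
reaches ≥99.9 % identity to the template, improving monotonically with
coverage.

## Synthetic data and study conditions

All generators are pure functions of (parameters, seed), with defaults
chosen to match the observed regime: segment classes of 80–600 bp (gap
pass down to 14 bp), five mosaic regions of 5–7 segments; a 30 kb
distal reference in 8 blocks with 10–40 bp indels, a 3.7 kb box-bounded
deletion (box pair 300 bp), one inverted block and a 400 bp
mitochondrial-like insertion; a helicase-like locus with the upstream
start 543 bases (181 codons) above the annotated ATG and in-frame 6 and
18 bp insertions at planted tandem contexts; reads at coverage 20 with
10-copy tracts and 8 % error. Background composition is uniform
(GC-skew knobs exist but are off). The generators emulate mosaic
structure, not the phylogeny that produced it: passing recovery tests
shows the annotation machinery is correct on data obeying the model's
assumptions (segments dissimilar between classes, adjacencies
distinct), not that real strain histories are identifiable.

## Problem sizes used in checks

The recovery and oracle checks run at deliberately desk-scale sizes:
exact-DP oracle comparisons on pairs up to ~500 bp (plus spot checks at
2 kb), 50 random 10 kb sequences for ORF enumeration, 200 random
symbol-string pairs for shared runs, one full mosaic set per run for
library recovery, 20 box-bounded deletion plants, and 40 reads for the
cluster/consensus checks. These sizes were chosen so the whole battery
runs in minutes on one core while still exercising every code path at
the regime the defaults describe.

## Known limitations

- Segment discovery assumes mosaics; tandem duplications of the same
  class adjacent to itself merge into one occurrence.
- Boundary refinement needs ≥2 occurrences per class; singletons are
  not reported as classes at all (sharing is definitional).
- The structural indel caller assumes collinearity between anchors;
  nested or overlapping rearrangements within one span fall back to
  edit-distance alignment and may be fragmented.
- Box detection reports the best pair only, and a pair whose realised
  identity is below 0.83 is (correctly) not attached even if it was
  planted as one.
- Read clustering is single-linkage on a fixed window: ends more
  similar than the identity threshold over their first kilobase merge.
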