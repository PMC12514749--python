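# Methods

## Problem and scope

Pediatric low-grade gliomas (pLGG) are driven overwhelmingly by structural
RNA events that converge on the MAPK pathway: gene fusions whose 3' partner
contributes an intact kinase domain (the KIAA1549::BRAF fusion of pilocytic
astrocytoma being the archetype), intragenic internal tandem duplications of
kinase-domain exons (FGFR1 KDD, typical of DNET), and splice isoforms that
skip regulatory exons (MET exon 14). All three leave the same raw footprint
in RNA-seq: a *chimeric junction* — a donor→acceptor breakpoint pair joining
two positions that are not adjacent in any annotated transcript, supported
by split reads and by read pairs whose mates straddle the junction.

`junctionscope` implements that analysis as a self-contained, testable
pipeline: a synthetic-data generator whose toy genomes reproduce the gene
geometries the detection problem depends on; a deterministic junction
classifier; a multi-caller harmonizer for heterogeneous fusion-caller
output; and cohort analytics over packaged published-cohort fixtures.
Re-running external aligners and fusion callers is out of scope — their
documented parameters (a chimeric-score drop cutoff of 30 for the aligner,
a minimum expected supporting-read count of 0.8 for the Arriba-style
caller) are carried in the run configuration as provenance metadata only.

## Coordinate and naming conventions

All coordinates are 1-based inclusive. Exons are numbered in *transcript*
order (exon 1 = 5'-most exon of the mRNA), so '-'-strand genes have
strictly decreasing genomic starts with increasing exon number. A junction
is written donor→acceptor: the donor position is the last transcribed base
before the junction, the acceptor position the first after it. Exon-junction
labels follow the field's shorthand — `KIAA1549::BRAF 16–9` means donor
exon 16 of the 5' gene joined to acceptor exon 9 of the 3' gene. Intragenic
labels keep the junction reading order, so the duplication of exons 10..17
is `KDD FGFR1 17–10` and a skip of exon 14 is `SKIP MET 13–15`.

## Synthetic data generator

`build_toy_genome` samples random A/C/G/T chromosomes and plants gene
models per a declarative `GenomeSpec`. Exon sequences are
rejection-resampled so that no two exons anywhere in the genome share a
31-mer; this makes split mapping with a 31-bp exact seed provably
unambiguous on toy data, which is what lets the whole pipeline be tested
without an external aligner. The default roster mirrors the recurrent pLGG
players: a 19-exon KIAA1549-like 5' partner, an 18-exon BRAF-like gene on
the '-' strand (autoinhibitory exons 1–6, kinase exons 11–18), FGFR1/2-like
receptor kinases (kinase exons 10–17), a 21-exon MET-like gene, NTRK-like
kinases and several small 5' partners, spread over three 30-kb chromosomes.
The default truth set holds 20 breakpoint-distinct events: the nine
observed KIAA1549::BRAF junctions (16–9 … 19–9), six further fusions, two
kinase-domain duplications and three exon skips.

Event transcripts are exact exon concatenations (reverse-complemented for
'-' genes): a fusion is exons 1..donor of the 5' gene plus acceptor..last
of the 3' gene; a KDD is exons 1..donor plus acceptor..last of the same
gene, duplicating the acceptor..donor span; a skip omits exons
donor+1..acceptor−1. Lengths are therefore conserved sums of exon lengths,
which the tests assert.

### Read simulation and the FFPE degradation model

Read pairs are sampled uniformly over the event transcript: pair count
Poisson with mean `depth · L / (2 · read_length)` (defaults: 100-bp reads,
fragment mean 250 ± 30 bp, depth 50×). Degradation `d ∈ [0, 1]` models
formalin-fixed archival RNA in two ways: the effective fragment mean
shrinks to `fragment_mean · (1 − 0.5 d)`, and each sampled fragment is
discarded with probability `1 − exp(−0.005 · d · frag)` — a per-base nick
rate of 0.005·d, representing strand breaks that abort library conversion.
The second term is what makes the junction-spanning read yield genuinely
monotone in `d`; fragment-size shrinkage alone is coverage-preserving at
fixed pair count and barely moves the crossing probability. The truth
sidecar records, per event, the number of reads crossing the junction with
at least 31 aligned bases on both sides — exactly the reads the toy mapper
can recover, which is what makes split-read support conservation an exact,
testable identity rather than an approximation.

The generator emulates uniform coverage, substitution errors, FFPE
fragment-size and yield loss, and decoy junctions. It does *not* emulate
indels, library-prep chimera artifacts, expression variation, multi-mapping
repeat structure or real intron/exon sequence composition; passing tests
therefore demonstrate the correctness of the junction logic, not caller
performance on real tissue.

`emit_truth_junctions` bypasses reads entirely: one junction record per
truth event plus decoy records whose positions are rejection-sampled to be
at least `tolerance + 1` bases from every exon boundary, making them
unambiguous negatives for the detector.

## Toy split mapper and junction extraction

The mapper is an exact 31-mer-seed, ungapped-extension aligner over the toy
genome (both strands; ambiguous seeds drop the read and are counted). A
read crossing one junction yields a primary plus a supplementary SAM
record whose soft-clip lengths partition the read. Two numerical details
matter:

- **Micro-homology overrun.** When the base after a junction happens to
  match the reference continuation, extension overruns the true breakpoint
  by a few bases and the breakpoint pair jitters by the same offset on
  both sides. When the overrun leaves a remainder shorter than the seed,
  the remainder is rescued with a seed anchored at the read end and the
  overlap trimmed — so any read with ≥ 31 matchable bases per side is
  always recovered as a split pair.
- **Mate orientation.** Under the FR layout, mate 2 is sequenced antisense
  to the transcript, so its raw junction reads acceptor→donor; extraction
  flips mate-2 junctions back into transcript orientation before
  aggregation.

`split_reads` counts reads whose segments flank an identical breakpoint
pair; `spanning_pairs` counts non-split pairs whose mates fall on opposite
sides of an already-evidenced junction within a 500-bp window.

## Junction classification

Each side of a junction is matched against exon boundaries of the loaded
gene models — the donor side against transcript-3' boundaries, the
acceptor side against transcript-5' boundaries, requiring strand agreement
— within a boundary tolerance (default 5 bp, absorbing end-trimming and
micro-homology jitter without colliding with neighbor exons on toy
geometries). Signed offsets run along the transcript direction, so a donor
3 bp inside its exon has offset −3. Ties break deterministically: nearest
boundary, then lexicographically smaller gene symbol, then lower exon
number.

Classification applies one rule ladder, so every junction gets exactly one
type: same gene with acceptor = donor + 1 → `canonical`; acceptor ≥
donor + 2 → `exon_skip`; acceptor ≤ donor → `kdd`; two different genes,
both sides assigned → `fusion` (donor gene is the 5' partner); one side
assigned → `truncation`; neither → `unclassified`.

Domain flags are set for fusions and duplications: a fusion retains the 3'
gene's kinase domain iff all kinase exons lie at or after the acceptor
exon, and loses the autoinhibitory domain iff that range lies entirely
before the acceptor exon (the BRAF-fusion activation logic: acceptor exon
9 with kinase exons 11–18 and autoinhibitory exons 1–6 gives
retained/lost); a KDD duplicates the domain intact iff the duplicated span
covers the whole kinase-exon range.

Filtering keeps events with ≥ 2 split reads, ≥ 0 spanning pairs and ≥ 3
total support by default — the published workflow states no thresholds, so
these are declared package defaults chosen to pass pristine simulations
while rejecting single-read artifacts; all are configurable. Canonical
junctions (the transcript's own splice structure) and unclassified
junctions (no exon context on either side) are never reported: support
thresholds alone cannot separate decoys whose simulated support is drawn
from the same range as true events, and neither category is a finding.
Junctions classifying to the same event label (breakpoint jitter within
tolerance) are merged with summed support before filtering.

## Multi-caller harmonization

Parsers cover an Arriba-style TSV, a STAR-Fusion-style TSV (`A--B` fusion
names, `chr:pos:strand` breakpoints) and an anchored-multiplex-PCR-style
CSV that reports exon labels and the GSP2-control unique-start-sites QC
metric (pass requires strictly more than 10; failing samples keep their
calls, flagged, since fusions remain detectable in degraded libraries).
Each dialect is defined bit-exactly by its writer, and parse→write→parse
is asserted to be the identity. Malformed rows are collected into an error
report, never silently dropped; missing mandatory columns are a format
error naming them.

Gene symbols are canonicalized through an idempotent alias table (shipping
the legacy KIAA1598 → SHTN1 mapping); the 5'→3' order is never sorted,
because fusion direction is meaningful and reciprocal pairs are distinct
events. Two reports match iff they share the ordered gene pair and either
both breakpoints agree within a tolerance (default 10 bp) or, when
breakpoints are unavailable, their exon labels are equal. Matching is
closed transitively; a cluster chaining breakpoints beyond the tolerance
carries a warning flag rather than being split, trading cluster purity for
simplicity. Consensus policies: `union` (≥ 1 caller), `majority`
(≥ ⌈k/2⌉ of k), `intersection` (all k); the three sets nest by
construction, and the union set never loses an event any caller detected.

## Cohort analytics

The packaged fixtures carry the published cohort tables: the 31-case
discordance table (three callers plus RT-PCR validation), per-class
alteration counts out of the 342 profiled patients, and the nine
KIAA1549::BRAF junction counts. Shapes and vocabularies are validated at
load. The full 88-case fusion-positive call matrix is reconstructed as the
31 discordant rows plus 57 concordant rows detected by all three callers;
the padding rows carry an explicit `synthetic_padding` flag because they
are a reconstruction, not data. Sensitivities, Venn-cell overlaps and
frequencies are integer computations; every percentage is recomputed from
its count with half-up rounding at the class's printed precision, because
published rounding is not always reconstructible from the counts (the
fixture's `note` column records such cases — e.g. a partner list that
names 13 entries but contains a duplicate). Counts are always displayed
beside percents.

The triage planner encodes the cost-effective diagnostic route: posterior
fossa, spinal, midline, optic-pathway (and cerebellar) tumors get the
KIAA1549::BRAF RT-PCR and V600E mutation-specific PCR first with NGS as
the fallback; hemispheric tumors go straight to NGS; a DNET histology
prepends the FGFR1-KDD RT-PCR; a positive prior result terminates the
plan, a negative one skips its step. `cerebellum` is routed with the
targeted-first group (it is part of the posterior fossa clinically);
`other` falls through to NGS-first.

## Determinism and problem sizes

Every stochastic operation takes an explicit seed and produces
byte-identical output on reruns; pipeline artifacts carry a provenance
header (version, seed, configuration hash) and contain no timestamps. The
shipped test suite and the acceptance script run the full read-based
pipeline at depth 50 over the 20-event toy genome (≈ 13 000 read pairs,
three 30-kb chromosomes) — sizes chosen so the whole analysis re-runs in
seconds while still exercising every code path, including '-'-strand
genes, micro-homology jitter and mate-orientation handling.

## Known limitations

- The toy mapper requires the exon-uniqueness guarantee of generated
  genomes; it is not a general-purpose aligner and will drop reads on
  repetitive references.
- Spanning-pair attribution uses a fixed genomic window and can credit a
  pair to several nearby junctions of the same intragenic event.
- The published in-house workflow's thresholds, tolerances and input form
  are not stated anywhere; the defaults here are declared choices, not
  reconstructions, and truncation calling covers the generic
  single-side-assigned case.
- Frame/ORF consequences, fusion transcript assembly and expression
  quantification are out of scope.
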