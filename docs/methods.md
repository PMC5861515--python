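# Methods

## Problem and model

A chimeric RNA joins two genomic loci that are not collinear within one
annotated gene — by genomic rearrangement (translocation, inversion,
duplication) or by transcriptional mechanisms (read-through, cis/trans
splicing). chimscan detects such junctions from stranded paired-end RNA-seq
by split-read analysis inside single reads, classifies them into four
geometry classes, filters them through an annotation-driven cascade, and
counts junction tags in raw FASTQ for recurrence screening. Coordinates are
1-based inclusive throughout; a junction is the pair (Pos1, Pos2) where Pos1
is the last transcribed base of the 5′ fragment and Pos2 the first
transcribed base of the 3′ fragment, each with a chromosome and strand
(+1/−1).

## Break detection and error discrimination

Reads are profiled against an exact k-mer index of the reference
(canonical-key hash, both strands queryable). The caller anchors the longest
collinear location chain starting at the first mapped k-mer (prefix anchor)
and the longest chain ending at the last mapped k-mer (suffix anchor). A
break exists when the prefix chain ends before the read does.

Two signals separate substitution errors from junctions. A substitution
produces a gap whose flanking anchors are *genomically contiguous* (the
suffix anchor equals the extrapolation of the prefix anchor), and whose gap
k-mers are private to the read: their collection-wide support drops to
`error_support` (default 1) while the flanks stay at local coverage. Such
calls get the `error` verdict and emit nothing. All other breaks are typed by
anchor geometry — different chromosomes, strand switch, collinear downstream
jump, or non-collinear arrangement — and the collinear case is deliberately
*not* resolved into splice-vs-chimera here: annotation decides downstream
(same gene → splice, removed; different genes → class 2). No distance rule
can make that split at detection time, since genuine collinear chimeras range
from a few kb to near-megabase separations.

Breakpoints are inferred by maximal base-by-base extension: the 5′ anchor is
extended rightward along its locus as far as the read matches, assigning
micro-homologous bases to the 5′ side. This canonicalization makes every
spanning read of one event yield the same (Pos1, Pos2). Reads observed
antisense to the transcript (mate 1 under the dUTP protocol) are flipped into
sense orientation and re-canonicalized before merging, so both mates
aggregate to one key. Anchors shorter than `anchor_min` (default k) reject
the candidate; consequently a break within k bases of a read end is not
callable, and a read containing two breaks (two junctions, or a junction plus
an error inside an anchor) is not resolved — with 100-bp reads and the exon
sizes used here, multi-break reads are negligible.

## Classification

`classify(left, right)` is total and deterministic: different chromosomes →
class 1; same chromosome, different strands → class 4; same chromosome and
strand in transcriptional order (ascending positions on +, descending on −)
→ class 2; otherwise class 3. Position ties fall into class 3: a zero-length
gap is the degenerate limit of the overlapping-fragment (tandem-duplication)
geometry.

## Support counting and the confidence score

Records aggregate per exact (left, right) key — canonicalization upstream
makes fuzzy merging unnecessary. `spanning_junction_raw` counts distinct
junction-crossing reads; `spanning_pe_raw` counts pairs whose sense mate maps
collinearly within `fragment_max` (default 1000 bases) upstream of Pos1 on
the 5′ locus and whose antisense mate maps within `fragment_max` downstream
of Pos2 on the 3′ locus, in the orientation of one fused transcript, with
neither mate crossing the junction. Normalized values are raw × 10⁹ /
total reads, counting individual mates in the denominator.

The confidence score is `ChimValue = 100 · P_loc · P_support` with
`P_loc = 1/(n_L·n_R)` (genomic hit counts of the two junction-flanking anchor
k-mers — multi-mapping anchors, e.g. pseudogene-like loci, drive the score
toward 0) and `P_support = min(1, 2s/(c_L+c_R))` (spanning reads against the
coverage of the two anchors). The published procedure defines ChimValue only
through its ingredients — mapping ambiguity and read coverage; this concrete
formula is **this package's own construction** within those semantics, chosen
to be threshold-compatible: a unique, well-supported junction scores near
100, and the standard cutoffs (60 for filtering, 75 for clustering) apply to
it. It is not a machine-learned calibration fitted to curated events. When
coverage
information is unavailable the score is computed with `P_support = 1` and the
record flagged. One known bias: a tandem duplication doubles coverage at its
own anchors, halving `P_support` — tandem events are therefore surfaced by
their subtype flag rather than expected to clear the 60 cutoff.

## Annotation and filtering

GFF3 gene models (ENSEMBL dialect, gene → mRNA → exon) are parsed with
gffutils and indexed with interval trees. A junction side annotates to the
closest-facing exon among strand-matching overlapping exons (exon priority),
falls back to a strand-matching gene (intronic), and otherwise reports
`NONE`; a position covered only by an opposite-strand gene is `NONE` with an
antisense note, so antisense fusions are not mis-assigned to the sense gene.
The exon-end distance is measured to the boundary facing the junction: the
exon's transcript-3′ end for a left side, its 5′ start for a right side.

The cascade keeps a record iff spanning reads ≥ 1, paired-end support ≥ 1, at
least one side gene-annotated, ChimValue ≥ 60, not a same-gene collinear
event (splice), and not a collinear fusion of distinct genes with junction
gap (|Pos2 − Pos1| − 1) below 3000 bases. The rejection log names the first
failing rule per record and preserves rejected records for inspection. The
ChimValue rule is a lower bound: the score measures confidence and the filter
removes low-confidence candidates. The adjacency cutoff is config-exposed
because genuine read-through chimeras can sit inside the 3 kb window — a
validated event at 2,377 bp separation exists — so the default discards it by
design while the log keeps it recoverable.

Read-through: class 2, junction gap ≤ 300 kb, and exon-end distance ≤ 20 bp
on **both** sides (the stricter of the two possible readings; configurable).
Tandem-repeat: class 3, genomically overlapping fragment intervals, both
fragments contained in a single exon of one gene. The two flags are mutually
exclusive by class. Gene selection for expression clustering keeps events
with ChimValue strictly > 75 and ≥ 3 spanning reads and selects genes
participating in ≥ 2 distinct events of one subtype across samples; the gene
list is the boundary — quantification and clustering are out of scope.

## Tag counting

A 30-nt tag (15 bases per side, even lengths only, no silent shifting when a
flank is short) is cut from the reconstructed junction sequence of each kept
record. Counting streams each FASTQ once, comparing every 30-nt window
against the tag set and its reverse complements; a palindromic window counts
once. The denominator is the file's window count (Σ max(0, len − 29)), and
windows containing N count toward it but can never match; normalization is
raw × 5·10⁹ / total windows.

## Synthetic data

The simulator emulates the study conditions the pipeline targets: a uniform
random A/C/G/T genome (default 3 × 50 kb), non-overlapping genes on both
strands with large (≥ 560 bp) terminal exons, short interior exons and
intergenic gaps cycling below and above 3 kb; fusion transcripts planting
every class geometry — class 2 in adjacent (< 3 kb) and most-distant flavors
(on a 50 kb chromosome the distant flavor is tens of kb, recorded per event;
a > 300 kb separation needs a correspondingly larger chromosome), class 3 as
intra-exonic inversion and as tandem duplication with 60 bp fragment overlap;
and stranded 100-bp paired-end reads (dUTP orientation by default,
configurable), fragment length N(250, 25) truncated to [read length,
transcript length], 30× depth, substitution errors only, fixed Q30 qualities.
Junction micro-homology is removed at planting (the 3′ fragment start is
nudged by ≤ 20 bases) so truth coordinates coincide with the caller's
canonical form and junctions stay on exon boundaries. A per-pair truth table
records fragment coordinates and whether mate 1, mate 2, both, neither, or
only the insert covers the junction.

What the simulator does **not** emulate: expression-level variation, indels,
PCR duplicates, polyA selection, intron signal, repeat families and
paralogy, base-quality structure. Passing tests therefore demonstrate the
correctness of the algorithms under clean mappability — not performance on
real tissue RNA-seq, where mapping ambiguity and library artefacts dominate
the error budget.

## Numerical and design choices

* k = 22 by default: two anchors fit in a 100-bp read with margin, and
  random 22-mer collisions are negligible at desk-genome scale. k ≥ 12 is
  enforced.
* Canonical k-mer form (lexicographic min of k-mer and reverse complement)
  for counting; location lookups stay strand-explicit.
* k-mers containing non-ACGT characters are skipped: empty locations, zero
  support contribution.
* Exact-coordinate record grouping; ties and degenerate overlaps resolve to
  class 3.
* The normalization denominator counts individual mates (2 per pair).
* Problem sizes in the test suite — 3 × 50 kb genome, 24 genes, ~450 read
  pairs, 10⁴-read tag screens — are chosen as the smallest sizes at which
  every code path (all four classes, both class-2 and class-3 flavors, error
  discrimination at 0.5% substitution rate) is exercised with unambiguous
  k-mer mappings.

## Known limitations

* In-memory index only; desk-scale genomes, not mammalian references.
* One break per read; breaks within k of a read end are invisible.
* Spanning-pair counting requires exact collinear mate alignment, so
  error-bearing mates are conservatively ignored; for intra-genic class-3
  events with partner loci closer than the fragment size, orientation-
  consistent pairs that do not bridge the junction can be over-counted.
* ChimValue is a local construction (above), not a trained score; its
  absolute scale is only guaranteed to order candidates sensibly and to put
  unique well-supported junctions near 100.
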