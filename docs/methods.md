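# Methods

This note documents the models, conventions and design choices behind
txome-atlas, in the spirit of a methods appendix: what each statistic is,
which knobs matter, what the synthetic generator does and does not emulate,
and where genuinely open design points were resolved.

## Coordinates and formats

All internal coordinates are 0-based half-open intervals on the forward
genomic strand (BED convention). GFF3/GTF input and output are 1-based
inclusive and are converted exactly once, at the I/O boundary. Junctions
are stored as intron intervals: `[first intronic base, one past the last)`,
so border dinucleotides are `seq[start:start+2]` and `seq[end-2:end]`.
Junction files are accepted in two dialects, auto-detected by column count:
BED12 whose two blocks flank the intron, and a direct 3–6-column
intron-interval record; ambiguous column counts are rejected rather than
guessed. Per-tissue read support comes either from one file per tissue or
from a junction × tissue sidecar TSV.

## Transcript merging and overlap labels

Merging collapses multi-exon transcripts with identical intron chains (same
chromosome and strand) into one record whose terminal exons are the union
of the inputs' terminal exons; mono-exon transcripts on the same strand
merge transitively when they overlap by at least one base. The operation is
idempotent, which the suite checks as a property.

"Complete" overlap is not a standard notion for a CDS-only annotation, so
it is defined strictly: the transcript covers every CDS base of the gene
*and* its intron chain restricted to the CDS span equals the gene's intron
chain. This is exactly the condition under which UTRs can be read off the
transcript, which is what complete transcripts are used for. Any other
exonic overlap is "partial"; "novel" requires no exonic overlap with any
gene model on either strand. An antisense-only overlap is therefore *not*
novel by default (conservative NTR discovery); `antisense_novel=True`
relaxes this. Whether "partial" should require same-strand overlap is
genuinely ambiguous; the default counts antisense-only overlaps as partial
so that the three labels partition any transcript set, which the suite
enforces as an invariant.

## ORF scanning

Novel transcribed regions are screened with a six-frame longest-ORF scan
(the transcribed strand of an NTR is unknown). An ORF is an ATG followed by
in-frame sense codons up to the first in-frame stop, wholly inside the
sequence. The amino-acid count includes the initiator methionine and
excludes the stop codon (`aa = nt/3 − 1`), the standard residue count; a
transcript is flagged coding when `aa > 100`. Ties between equally long
ORFs resolve to the plus strand.

## UTRs and uORFs

UTR lengths are measured in mature (spliced) transcript coordinates,
strand-aware: the 5′ UTR is the mature sequence upstream of the CDS start
on the coding strand. The invariant `utr5 + CDS + utr3 = mature length`
holds for every call and is asserted in the tests. Transcripts not labeled
complete for a gene yield an explicit "undefined" result (`None`), never a
zero — absence of evidence is not a zero-length UTR.

A uORF is an ATG-initiated ORF terminating at its first in-frame stop,
entirely within the 5′ UTR (it may not extend into or past the CDS start),
with total length between 10 and 50 nt *including* the stop codon — the
window is stated in nucleotides, so the effective lengths are the multiples
of 3 in that window: 12, 15, …, 48. Overlapping and nested uORFs are all
reported.

Category comparisons of UTR lengths use a two-sided Wilcoxon rank-sum
(Mann–Whitney) test of each category against the *full* background
(category included, mirroring a category-vs-total design), exact where
sample sizes and ties permit (scipy's `method="auto"`), with categories
flagged longer/shorter at P < 0.05 by their median relative to the
background median. Categories with fewer than two observations are skipped
with a warning.

## Expression atlas

A gene is expressed in a tissue iff the lower bound of the 95% confidence
interval of its FPKM is strictly greater than zero; constitutive means
expressed in every tissue. Tiers: low ≤ 5 < medium ≤ 50 < high (FPKM).
Housekeeping genes have FPKM strictly above 50 in every tissue.

The tissue-specificity index is τ = Σ_j (1 − S_ij/S_max) / (n − 1) with n
the number of surveyed tissues; replicate samples of one tissue should be
averaged before applying it (the formula is per-tissue). τ is undefined
(raises) for an all-zero profile or fewer than two tissues. Tissue-specific
genes are those with τ ≥ 0.9 that are expressed in their argmax tissue;
**the 0.9 cutoff is this package's default** — the source analysis states
no threshold — and is a parameter everywhere it appears.

Tissue clustering uses 1 − Pearson correlation between tissue columns of
log2(FPKM + 1) — the pseudo-count is our choice (only "log2-transformed"
is specified) and avoids −∞ at zero — restricted to constitutive genes,
with average linkage. A constant column makes correlation undefined and
raises an error naming the tissue. Leaf order in the emitted newick is made
deterministic by sorting children on their smallest tissue name; distances
within 1e-12 of 0 or 2 are snapped to the exact value so that identical and
perfectly anti-correlated columns behave reproducibly.

## Alternative splicing

Junction detection is per tissue: support ≥ 3 in that tissue (configurable)
with no pooling across tissues; a junction is retained iff detected in at
least one tissue. Known junctions are exactly the annotated introns; all
other retained junctions are novel.

Event definitions, per gene locus (junctions fully inside the gene span):

* **ES** — a junction whose ends equal the donor of annotated intron i and
  the acceptor of intron i+1, skipping the single internal exon between
  them. A junction explained as ES is excluded from alternative-splice-site
  pairing (it necessarily also shares one end with each flanking intron).
* **A5SS / A3SS** — an unordered pair of junctions sharing exactly one
  genomic end; the shared end is mapped to donor or acceptor through the
  gene strand (shared acceptor ⇒ A5SS, shared donor ⇒ A3SS). The event
  anchor is the non-annotated member of the pair; the annotated partner is
  recorded alongside.
* **IR** — an intron (annotated or junction-defined) wholly contained,
  strictly, within a single exon of a merged transcript at the locus while
  its spliced junction is also detected. Both isoforms must be in evidence;
  read-coverage-based IR calling is out of scope because the pipeline
  consumes junctions and transcripts, not alignments.

An event's tissue set intersects the detection tissues of its defining
evidence (both junctions of a pair; junction ∩ transcript tissues for IR).
Junctions assignable to no locus are reported as orphans, never silently
dropped. Tissue-breadth summaries emit both readings of "shared by more
than two tissues" (breadth ≥ k and breadth > k, default k = 2) because
published usage of the phrase is inconsistent. Retained-intron size is
compared against all annotated introns with a two-sided rank-sum test.

Multiple events per gene are counted per event and per type; "genes with
AS" deduplicates genes, so per-type gene counts need not sum to the total —
only event counts must (and the suite asserts they do).

## Enrichment

For study hits k of a category with K background members (study n,
background M), the 2×2 table is tested with a one-sided Fisher's exact test
(hypergeometric upper tail — "enriched" semantics) when the minimum
*expected* cell count is ≤ 5, else a Pearson chi-square with 1 df and no
continuity correction. The switching rule's "N" is not precisely defined in
the source; the minimum expected cell count is the standard chi-square
validity criterion and is exposed in the output so the decision is
auditable. P-values are BH-adjusted (step-up, order-preserving). The Fisher
path is checked against exhaustive fixed-margin enumeration for every
consistent table with M ≤ 25, and the null calibration test verifies that
random category assignment yields ≤ 6% of q < 0.05 over 1,000 replicates.
Categories are flat labels; no ontology DAG propagation.

## The synthetic world

The generator's defaults state the simulated conditions: 200 genes on one
chromosome, the six surveyed tissues (callus, root, stem, leaf, flower,
silique), 2–8 exons per gene, introns of 60–400 bp, planted events
{IR: 40, ES: 20, A5SS: 20, A3SS: 20} (at most one per gene), 50 NTRs (half
coding), 150 UTR-extended genes of which 100 carry one uORF, expression
classes 15% housekeeping / 15% tissue-specific / 10% silent / 60% graded,
and zero junction noise.

Sequence content is uniform-random A/C/G/T with splice motifs and start/
stop codons overwritten at planted positions; content beyond motifs is
never interpreted, so no attempt is made at realistic composition. Regions
whose *reading* matters — 5′ UTRs and NTR bodies — are rewritten over the
{C, G, T} alphabet: without an A no ATG can occur on the forward reading
and without a T none on the reverse, so the only ORFs and uORFs present
are the planted ones and recovery can be scored exactly.

Evidence is planted to match the detector contracts: every annotated
intron gets a junction supported in all tissues (10–60 reads); each event
adds its extra junction (ES/A5SS/A3SS, 5–30 reads in the event's random
tissue subset) or its intron-spanning transcript (IR); alternative splice
sites are shifted 6–40 bp into the intron with canonical borders written at
the new site. IR is planted in each gene's shortest intron by default
(`ir_prefer_short_introns`), emulating the biology of intron-definition
splicing, which is what makes the retained-vs-all intron size comparison
significant on synthetic data. Junction noise, when enabled, independently
degrades each junction's support below threshold with the stated
probability and scrambles a matching fraction of annotated splice borders.

Expression per class: housekeeping = base ∈ (60, 400) ± 15% per tissue
(always > 50); tissue-specific = one tissue ∈ (20, 120), zero elsewhere;
graded = independent per-tissue values in (5.5, 40); silent = zero. These
ranges are chosen so the classes are exactly recoverable by the downstream
rules at zero noise (graded genes cannot reach τ ≥ 0.9; housekeeping genes
cannot drop below 50). The 95% CI lower bound is
`max(0, FPKM·(1 − 1.96/√(c+1)))` with `c` a Poisson fragment count
(mean 20·FPKM, floored at 3 for expressed entries): the source never
states how the interval estimates arise, and only the bound's sign is
consumed downstream, so a count-driven width is sufficient.

What a green recovery test establishes: the pipeline's rules are exact
inverses of the generator's planting rules under the stated world. What it
does not establish: robustness to assembler artifacts (fragmented or
chimeric transcripts), soft-clipped junction alignments, overlapping gene
models, paralogy, or FPKM estimation error — none of which the generator
emulates. The noise model perturbs junction support and splice motifs
only.

## Numerical and reporting conventions

Percentages are rounded half-up to one decimal and always carried with
their integer numerator/denominator pair. Identical samples short-circuit
the rank-sum test to p = 1 (the asymptotic formula would return slightly
less). All randomness flows from a single integer seed through named
per-stage `numpy` generator streams, so every output file is byte-identical
across reruns of the same configuration; the test suite asserts this at
file level.

## Known limitations

* The AS detector considers single-exon skips only (donor of intron i to
  acceptor of intron i+1); multi-exon skips would surface as an
  alternative-site pair, not ES.
* IR requires transcript-level evidence; depth-based IR from alignments is
  not implemented.
* Mutually-exclusive-exon and alternative first/last-exon events are not
  classified.
* Enrichment treats categories as flat labels; no GO DAG handling.
* The expression model draws tissues independently; it does not emulate
  correlated tissue blocks, so dendrogram topology on synthetic data is
  only meaningful when correlation structure is planted explicitly (as the
  clustering tests do).
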