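# Methods

## Coordinates, strands, and channel conventions

All coordinates are 1-based inclusive, matching VCF. Substitutions are
reported in the pyrimidine-strand convention: when the reference base is
A or G, the substitution and its trinucleotide context are
reverse-complemented before classification, so every event is a C>N or
T>N change. The 96 SBS channels are ordered by substitution type (C>A,
C>G, C>T, T>A, T>C, T>G) and, within a type, by 5' then 3' flanking
base, each in A,C,G,T order — channel 1 is A[C>A]A, channel 96 is
T[T>G]T. Every serialized spectrum carries channel labels so a
row-order bug in an input file is detected on load rather than silently
misassigned.

Genome-wide trinucleotide proportions use the same collapsing: every
width-3 window with both flanks present is counted, windows centered on
A or G count toward their reverse complement, and windows containing N
are skipped (an ambiguous base cannot be assigned to a motif). Windows
at positions 1 and L are excluded rather than padded — no context is
defined there, and any padding rule would be an invention. The counter
accepts an exclusion list of chromosome names (e.g. a mitochondrial
contig or an engineered cassette); by default every chromosome in the
FASTA is counted. On FASTA input, lowercase is uppercased and U is
mapped to T; any other non-ACGTN character is a hard error, because a
silently coerced base would corrupt motif counts.

## Variant filtering and unique-variant merging

Per-sample calls are filtered first (QUAL >= 30 AND INFO/DP >= 10 by
default; records missing either annotation carry sentinels that fail
the filter), then samples are merged. The identity of a variant is the
4-tuple (chrom, pos, ref, alt); the merged record's carrier set is the
union of samples, and its qual/depth is the per-sample maximum — used
for reporting only, since filtering already happened per sample.
Filtering before merging matters: a variant well-supported in one
isolate and marginal in another should survive through the isolate that
supports it. Unique counting (each merged variant contributes once to
every spectrum) is the anti-selection-bias choice for reporter-selected
isolates; a per-occurrence weighting mode exists for sensitivity
analysis but is off by default. Calls are haploid; genotype columns are
ignored, and presence of a record in a sample's VCF defines carriage.

A reference-allele mismatch between a VCF record and the genome is a
hard error naming the site, never a skip: silent skips would mask a
wrong-reference pairing.

## Indel classification

Indels are first stripped of their VCF anchor base and left-aligned by
the standard rotate-and-shift rule over repeated sequence; every
equivalent VCF representation of an event therefore classifies
identically. Classification follows the COSMIC ID83 layout:

1. 1 bp events, strand-collapsed to the pyrimidine base (T/C), binned
   by homopolymer run length (deletions: the run containing the deleted
   base, 1..6+; insertions: the adjacent matching run, 0..5+).
2. >=2 bp events binned by length (2, 3, 4, 5+) and by the number of
   tandem copies of the indel unit immediately 3' of the event in the
   reference (the deleted copy itself counts, so deletions have >= 1
   unit; insertions count reference copies only and may have 0).
3. Deletions with exactly one unit are tested for breakpoint
   microhomology: the longer of the deleted sequence's longest prefix
   matching the reference immediately 3' of the deletion and its
   longest suffix matching immediately 5', capped at length − 1.
   MH >= 1 sends the event to the MH channels; repeat context (>= 2
   tandem copies) always takes precedence over microhomology, making
   the two classes mutually exclusive by construction.
4. Everything else stays in its length bin at repeat bin 1 (deletions)
   or its measured repeat bin (insertions, 0..5+).

Microhomology is computed two-sided because breakpoint homology can sit
on either flank; after left-alignment the 5'-suffix case is always
rotated into a 3'-prefix match, so the two-sided maximum is a
conservative, representation-independent definition. The terminal
repeat bin for the repeat-unit view is 6+ for deletions and 5+ for
insertions, per ID83. The 83 channels collapse exactly onto the
16-category view (1 bp del/ins C/T; del/ins 2/3/4/5+; MH-del 2/3/4/5+)
used for plotting; collapse preserves totals.

Insertions are binned at their measured adjacent-copy count rather than
forced to bin 0 when only one copy is present: the one-copy case is
repeat information the ID83 layout is designed to carry, and collapsing
it to 0 would discard it without changing any 16-category total.

## Cross-species correction

For channel c with pyrimidine motif m(c), the corrected frequency is
f'_c = f_c · p_target(m(c)) / p_source(m(c)), renormalized to sum to 1.
Renormalization is a positive scalar, so every downstream cosine
comparison is unchanged by it; it is applied so outputs remain
interpretable as frequencies. A motif with zero source proportion but
nonzero spectrum mass is an error (the ratio is undefined); a motif
with zero target proportion has its channels zeroed with a warning,
since such a motif cannot mutate in the target genome. The correction
composes: source→mid then mid→target equals source→target exactly,
because the ratios telescope.

## Comparison and clustering

Cosine similarity is dot(a,b)/(‖a‖‖b‖) on non-negative vectors; zero
vectors are rejected. Catalog matching sorts by similarity descending
with ties broken by catalog order. Heatmap ordering uses agglomerative
clustering with average linkage on distance 1 − cosine; the linkage
choice affects only display order, never a similarity value, and is
documented as such. The dendrogram is exported as newick. Catalog files
are accepted in the one-column ("A[C>A]A") or Type/Subtype dialect,
reordered to canonical channel order on load, and renormalized so
count-scale catalogs are accepted; the catalog release used for any
comparison is the user's input and should be recorded alongside
results.

## Synthetic-data generator

The generator emulates the statistical structure of an ssDNA
mutagenesis experiment, not its read-level physics: a random i.i.d.
genome at a configurable GC fraction (no repeat landscape, no real
chromatin or replication-timing structure), per-sample VCFs, and a
truth table. Defaults describe a scaled-down yeast-like setting chosen
once: 16 chromosomes × 50 kb at 38% GC (the approximate *S. cerevisiae*
GC content), tenfold mutation-rate enrichment within 5 kb of chromosome
ends (standing in for subtelomeric ssDNA exposure), 10 isolates, 300
substitutions and 30 indels per isolate (the per-genome yield of a
strongly mutagenized ssDNA reporter), 5% cross-sample recurrence, and
5% of raw calls failing each of the QUAL and DP cutoffs.

Substitutions are drawn channel-first: the per-channel event counts are
a multinomial draw from the signature, and sites matching each
channel's motif are then drawn position-weighted (weight =
`subtelomere_enrichment` inside the end windows, 1 elsewhere) and
without replacement within the channel. Channel-first sampling makes
the realized spectrum converge to the signature regardless of genome
composition — a site-first scheme would convolve the signature with the
genome's motif abundances — and sampling without replacement makes
every generated event a distinct unique variant, so parameter-recovery
tests are sharp multinomial checks rather than collision-distorted
ones. Recurrence is injected explicitly by copying an event into a
second isolate with the configured probability. A channel whose demand
exceeds the genome's matching sites raises a clear error.

Indels are placed by rejection sampling of reference sites realizing
each drawn 16-category label (e.g. an MH deletion requires the 3' flank
to already share the deleted segment's first base while excluding a
full tandem copy). The genome is never edited, so REF always matches
the FASTA; the placement checks are direct string comparisons written
independently of the classifier they are later tested against. The
truth table records every event's channel or category per carrying
sample.

What passing the closed-loop tests shows: the classifiers invert the
generator exactly, and recovery behaves as multinomial sampling
predicts. What it does not show: performance on real data with
alignment artifacts, clustered complex events, repeat-dense genomes, or
caller-specific representation quirks beyond the left-alignment
handled here.

## Numerical choices and degenerate inputs

Spectra store float counts; frequencies are computed on demand and an
empty spectrum cannot be normalized (error, not NaN). Trinucleotide
tables are validated to 32 motifs summing to 1 within 1e-9 and
renormalized on file load so raw counts are accepted. Similarity
matrices are validated symmetric within 1e-8 and symmetrized before
linkage to absorb float round-off. Rainfall series deduplicate
positions within a chromosome (two alleles at one site have distance 0
to each other, which would break the positive-distance invariant) and
never concatenate chromosomes. The end-proximity window has no default
in the library API: no principled value exists a priori, so it is an
explicit parameter (the CLI uses 5 kb, matching the simulator's
subtelomere window).

## Problem sizes

The test suite and acceptance script run entirely on synthetic data:
oracle suites use >= 1,000–3,000 randomized cases each; signature
recovery uses 50,000 substitutions on a 16 × 50 kb genome across 5
seeds; indel recovery uses 5,000 events (and 2 × 2,000 for the
long-deletion contrast). These sizes give binomial standard errors
small enough for 3-sigma category checks while keeping a full run in
tens of seconds.

## Known limitations

- No NMF/refitting signature extraction; comparison is cosine-based
  against supplied catalogs only.
- MNVs and complex substitutions are excluded with a diagnostics count
  rather than decomposed.
- The simulator does not model read-level noise, mapping bias, or
  caller error (its contract starts at variant calls), and its genomes
  lack real repeat structure — rejection placement of repeat/MH indels
  is therefore easier than on a real genome.
- Whole genomes are held in memory; appropriate for ~12 Mb yeast-scale
  references, not mammalian ones.
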