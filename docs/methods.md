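# Methods

This note documents the conventions, models and design choices behind
`mitocomp`, in the order an analysis flows through the package.

## Coordinates and geometry

All external coordinates are 1-based inclusive, the convention of
published mitogenome annotation tables; internal containers keep the
same convention to avoid conversion bugs. On a circular genome a
feature with `end < start` spans the replication origin and has length
`L − start + 1 + end` (genome length `L`); on a linear genome this is an
error.

Adjacency between features is defined by start-coordinate order around
the circle, not by strand or transcription order. The spacer between
consecutive features is `gap = next.start − prev.end − 1`; a circular
genome has exactly one spacer per feature (including the wrap-around
pair), a linear genome one fewer. Negative gaps are overlaps, and
*overlap count* counts adjacent pairs only — containment of one feature
inside a non-adjacent one is logged as a warning but not counted, so the
count matches how annotation tables report overlaps. These conventions
reproduce the packaged annotation's printed intergenic column
bit-for-bit, including its −10 (nad4/trnH), 57 (trnD/trnM) and the
wrap-around 0.

Noncoding regions are the positive spacers. Published counts of
"noncoding regions" sometimes treat the annotated control region as a
feature and sometimes as noncoding; `noncoding_regions` exposes this as
`include_cr_feature`. With the control region treated as noncoding
(`include_cr_feature=False`, also the convention of
`identify_control_region`) it merges with its flanking gaps: on the
packaged annotation this yields 20 regions of 1–703 bp with the 703 bp
region between trnT and trnP; keeping it as a feature yields 19 regions
of 1–130 bp.

Control-region identification returns the longest noncoding region
(ties broken toward the lower start). When a sequence is supplied the
region's A+T fraction is reported and checked against a threshold,
default 0.60 — low enough that any genuinely AT-rich vertebrate or
invertebrate control region passes, high enough to flag GC-balanced
candidates; a failing candidate is still returned, with a warning,
because the positional criterion alone is often what published
annotations used.

## Composition and skews

Base composition excludes non-ACGT characters from percentages (they
are tallied separately). Skews are `(x − y)/(x + y)` — GC-skew with
(G, C), AT-skew with (A, T) — and therefore scale-invariant: printed
percentages are as valid an input as raw counts. Minus-strand features
in the per-feature composition report are composed on their coding
strand (reverse complement); aggregate rows concatenate the coding-
strand sequences (all PCGs; all control regions) before tallying, which
is equivalent to summing counts but shares the single code path.

Display rounding is half-up (0.425 → 0.43), matching published tables,
at 2 decimals for percentages and RSCU and 3 for skews. Note that
recomputing a 3-decimal skew from 2-decimal printed percentages carries
an intrinsic uncertainty of a few units in the third decimal; exact
agreement with a value derived from unprinted raw counts cannot be
guaranteed beyond one unit in the last printed digit.

## Codon usage and genetic codes

Codon counting tallies frame-0 triplets across a CDS set; trailing
partial codons are dropped and ambiguous triplets skipped, each with a
warning. Stop codons are ordinary citizens throughout: they are
counted, they form their own synonymous family in RSCU, and they stay
in the denominator of amino-acid usage (reported as a separate row) —
the convention under which the packaged codon table's printed
percentages are reproduced.

RSCU is `count(c) × s / n_F` within a synonymous family F of size s and
total n_F; a family with n_F = 0 reports 0 for all members, and family
sums equal family sizes otherwise (property-tested). The genetic code
appears in two independent roles — amino-acid labels versus family
partition — because published invertebrate mitogenome codon tables
sometimes label codons with the mitochondrial code (AGR = Ser,
AUA = Met, AAA = Lys, UGA = Trp) while their RSCU values arithmetically
follow standard-code families (AGR pooled with CGN into six-codon Arg,
UGA pooled with UAA/UAG into a three-codon stop family, AUA in
three-codon Ile). The packaged codon table is exactly such a case:
its printed RSCU column is reproduced to ±0.005 for all 64 codons only
with standard-code families, while its labels and its amino-acid usage
percentages follow invertebrate-mitochondrial labels. Tests therefore
compare RSCU at ±0.005 and skews at ±0.0005, half the last printed
digit. Codes are built from the NCBI translation tables via Biopython
(standard = 1, invertebrate mitochondrial = 5, echinoderm mitochondrial
= 9) or from user mappings; codons display in RNA alphabet, compute in
DNA.

## Gene orders

A gene order is a signed circular permutation over the canonical
37-gene alphabet (one-letter tRNA symbols with S1/S2 and L1/L2 split by
codon family; a synonym table normalises free-text names, e.g.
cytb → cob, 16S → rrnL, trna-ser(gct) → S1). A circular DNA molecule
has no canonical origin or strand, so all comparisons are invariant
under rotation and under reflection-with-sign-flip; this is implemented
by storing, for each adjacency, both its reading directions.

Genes x, y are adjacent-conserved between orders a and b when the
signed pair (x, y) or its reverse reading (−y, −x) is adjacent in both
circles. Conserved blocks are the maximal chains of conserved
adjacencies (for n ≥ 3 distinct labels these chains are exactly the
maximal runs contiguous and co-oriented-or-fully-reversed in both
orders — the test suite verifies this against an independent exhaustive
run-search oracle on hundreds of random signed permutations of up to 8
genes); runs of size 1 are reported as singletons, and blocks are
listed in a's circular order starting from the block containing cox1,
the convention of linear gene-map figures. The breakpoint distance is
the number of non-conserved adjacencies of a (symmetric for equal gene
sets). When gene sets differ the comparison restricts to the
intersection with a warning (strict mode raises): duplicated control
regions and similar extras are excluded upstream, since orders contain
genes only. Differences between two arbitrary orders are reported
descriptively (blocks, singletons, breakpoints) — minimal rearrangement
scenarios are deliberately out of scope.

Forward simulation covers the four classical event types: inversion
(reverse a contiguous run, flipping orientations), transposition (move
a run), reverse transposition (move and flip), and tandem
duplication–random loss (duplicate a run in tandem, then delete one
copy of each duplicated gene; the surviving copies are drawn from the
seeded generator and recorded in the event, keeping the label set
closed). Event spans are given by label so logs are self-describing.

## Synthetic genomes

The generator emulates the structure of the focal genome: by default
its exact annotation geometry (15 969 bp, 38 features, both strands,
including its seven overlapping pairs), a target base composition equal
to its printed whole-genome composition (renormalised from 99.99%), an
AT boost of +0.10 inside control regions (a modest version of the AT
richness of real control regions), and two rearrangement events drawn
uniformly from the four kinds. All stochastic choices flow from the
single mandatory integer seed through one named generator in fixed
order, so outputs are byte-reproducible.

Intergenic, tRNA and rRNA positions are i.i.d. draws from the target
composition. Protein-coding spans are overwritten in start order with
an in-frame CDS: the annotated (or default ATG) start codon, interior
codons drawn from the codon distribution, and the annotated (or default
TAA) stop codon; minus-strand genes are written as the reverse
complement. The default codon distribution is the per-position product
of the target composition — stops included in interior draws — so
planted coding sequence does not distort genome-wide composition; for
minus-strand genes the default draws from the complemented composition
so the *written* strand also matches the target. Where planted
features overlap, the later write wins, and the recorded ground-truth
CDS are re-extracted from the finished sequence, keeping the
extraction-closure oracle exact.

What the generator does not emulate: substitution processes, rate
heterogeneity, codon autocorrelation, realistic tRNA/rRNA structure, or
sequence similarity between genomes. Tests that pass on synthetic data
therefore validate bookkeeping (coordinates, strands, frames, wrapping,
rounding, event algebra), not biological inference on real sequences.

At 16 kb, multinomial sampling concentrates measured composition within
about one percentage point of target (±1 point is also the band the
closure tests assert at their fixed seeds); the AT-boosted control
region and sampling noise dominate the residual deviation.

## Problem sizes and determinism

Everything here is desk-scale: the reference tables are a 38-row
annotation and a 64-row codon table, synthetic genomes are ~16 kb, and
the brute-force oracle sweep uses 500 random order pairs of ≤ 8 genes —
the full test suite runs in a few seconds on one CPU. All randomised
tests are seeded or derandomised (hypothesis profile), and the CLI's
reports are deterministic given inputs and seed.

## Known limitations

* Gene prediction, tRNA structure prediction, phylogenetics and GFF3
  are out of scope; annotations come from GenBank flat files or the TSV
  dialect.
* Annotated start/stop codons are stored verbatim and never validated
  against sequence (published tables occasionally print
  strand-inconsistent triplets, e.g. plus-strand triplets for a
  minus-strand gene).
* Minimal rearrangement distances (Hannenhalli–Pevzner and kin) are not
  computed; block decompositions are descriptive.
* Per-gene composition of minus-strand genes follows the coding-strand
  convention; against published per-gene tables whose convention is
  unstated, agreement on such genes is not guaranteed.
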