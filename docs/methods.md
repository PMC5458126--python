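# Methods

## Coordinate conventions

All internal coordinates are 0-based, half-open. The predicted SpCas9 cut is
blunt and lies between protospacer positions 17 and 18 (3 bp upstream of the
PAM); `cleavage_coord` is the region coordinate of the base immediately left
of the cut, on either strand, so the two cut-flanking bases are always
`cleavage_coord` and `cleavage_coord + 1` and the cut as an insertion point is
`cleavage_coord + 1`. Human-readable tables report 1-based coordinates and say
so in their comment headers.

## Alignment model

Reads are amplicon-sized and the reference is a handful of amplicon regions,
so alignment is affine-gap semi-global dynamic programming (Gotoh): the read
must align end to end, both reference ends are free. Default scores are
match +2, mismatch −4, gap open −6 (first gap base), gap extend −1; `N`
matches nothing. The production path anchors a diagonal band (half-width 25,
wider than any indel the generators produce) on an exact 16-mer seed tried at
the read's start, middle and end; reads with no seed hit fall back to the
full matrix. Both kernels are numba-compiled. Ties in the DP prefer the
aligned (diagonal) state, and after traceback every indel is shifted
maximally left within runs of identical bases, so positional rules see one
deterministic coordinate per event. This left-alignment convention is the
same one mainstream aligners and variant normalisers use.

Mapping quality is a proxy, not BWA's formula: `min(60, best − second_best)`
over region scores, 60 for a unique candidate, 0 for a perfect tie. Only the
threshold semantics of mapping-quality filtering are reproducible across
aligners — exact MAPQ distributions are aligner-specific — which is why the
import path accepts external SAM files and uses their MAPQ verbatim. Reads
whose best score falls below `0.3 · match · read_length` are unmapped; the
floor only matters for junk input, since a read matching anywhere scores far
above it.

## Indel qualification rule

A read is edited when ≥ 1 of its indels qualifies (reads counted once,
however many events they carry; substitutions never qualify):

* size 1 bp: directly adjacent to the cut. "Directly adjacent" is read
  narrowly — a deleted base must be one of the two cut-flanking bases, an
  inserted base must sit exactly in the cut. Because adjacency is not
  self-defining, the radius is a config value (`adjacency_radius`, default 0)
  recorded in every report, so wider readings are auditable rather than
  implicit.
* size ≥ 2 bp: the event must intersect the closed window of `flank`
  (default 5) reference bases on each side of the cut — 12 bases total
  including the two cut-flanking bases. An insertion intersects iff its
  insertion point lies within the window's closed coordinate range.

The rule is defined in region coordinates after strand mapping, so
'−'-strand protospacers need no special casing. Window arithmetic is exposed
in outputs for audit.

The T7E1 conversion `100·(1 − √(1 − fc))` inverts the heteroduplex fraction
`1 − (1 − p)²` expected when a pool with modified fraction p is denatured and
re-annealed.

## GUIDE-seq site calling

PCR duplicates are consolidated by exact sequence identity (the generators do
not model molecular indexes; when UMIs exist they would simply refine the
identity key). The dsODN tag is located by infix edit-distance search
(edlib, ≤ 3 edits); the longer genomic flank is placed via an exact 20-mer
index of the genome — unique placement maps to MAPQ 60, ambiguous to 0 — and
the junction coordinate is the flank's genome-side end. After filtering
junctions below MAPQ 50, junctions within a ±10 bp collapse window merge into
one site whose coordinate is the most-supported junction (lowest on ties) and
whose support is the consolidated read count, thresholded at `min_reads = 2`.
The collapse window and support threshold are not dictated by the assay
itself; they are config values logged per run. Each site is then annotated
with the best PAM-valid protospacer placement within ±25 bp on either strand
(PAM matched IUPAC-degenerately, mismatches counted over the 20 protospacer
positions only, ties broken to the lower coordinate then '+') and retained
when ≤ 8 mismatches; finally any site within the collapse window of a
background-control site is subtracted. Background site lists are built with
`min_reads = 1` so subtraction errs on the conservative side.

`scan_offtargets` is deliberately brute force — every position, both strands,
vectorised over numpy windows — because at desk scale exhaustiveness is
cheaper than cleverness and it doubles as a reference for any seeded scanner.

## Specificity statistics

On/off ratio: `on% / off%` after replacing exact zeros with a floor
(default 1e−05); substitutions are counted and reported. The floor is applied
before any downstream statistic, including the quartiles. Fold improvement:
ratio of on/off ratios (test over control). Summary: median and 25th/75th
percentiles by linear interpolation between order statistics (the default of
mainstream numeric stacks; the convention is printed in every report since
quartile conventions differ at n this small). "Improved" means F.I.
strictly > 1. No untreated-background subtraction is applied by default:
background editing is a readout to report alongside, not a component to
remove; a subtract flag exists for users who disagree.

## Synthetic data: what it does and does not emulate

The amplicon generator draws single-end reads (150 bp default, constant
quality) from a region, gives an `editing_fraction` of them exactly one indel
anchored at the cut (uniform jitter up to `position_jitter`), and applies
independent per-base substitution errors. The default indel size spectrum is
deletion-dominated with a minority of small insertions — a generic NHEJ-like
shape; real loci have sequence-dependent spectra (microhomology-biased
deletions, templated +1 insertions) that are deliberately not modelled. Truth
tables record each planted indel in its left-aligned representation and
whether it qualifies, so ground truth and pipeline share one coordinate
convention. Read-start positions keep the cut and the largest configured
indel at least 10 bp inside the read.

The GUIDE-seq generator plants, at every true site, a protospacer-like 23-mer
with a chosen number of mismatches whose predicted cut coincides with the
integration coordinate, then emits junction reads (genomic flank ≥ 15 bp +
dsODN + genomic remainder), exact-copy PCR duplicates at the configured rate,
and a background sample tagged only at background loci. It is single-end and
junction-centric: the paired-end, bidirectional-evidence logic of full
GUIDE-seq informatics is out of scope, so passing tests demonstrate correct
consolidation/filter/cluster/match/subtract semantics, not performance on
real paired-end libraries. The dsODN default is an arbitrary 34-mer; real
experiments must supply their own tag sequence.

Passing recovery tests on these generators shows the pipeline is an unbiased
estimator of planted editing fractions and site sets under idealised noise;
it does not certify behaviour under real error profiles, structural variation
or repetitive genomes.

## Problem sizes and numerical choices

Recovery checks use 10,000 reads per condition (binomial 3σ at 20 % editing
is ±1.2 points), alignment-kernel agreement uses 500 random read/region pairs
at 150 × 250 bp, GUIDE-seq end-to-end equivalence uses 20 seeds of 2 × 8 kb
genomes with 4 true + 1 background site, and the scanner check uses 100 kb.
Parameter-recovery runs use an indel spectrum of sizes ≥ 2 only, so the
planted qualifying fraction equals the editing fraction by construction
(1 bp insertions whose base repeats the cut-flanking base left-shift away
from the cut and stop qualifying under the narrow adjacency reading — a
property of the rule, not an estimator error). Degenerate inputs are defined,
not special-cased: zero retained reads yield 0 % with a logged warning; empty
fold lists are errors; `filter_by_mapq` is idempotent and order-preserving.

## Known limitations

No genome-scale seeded alignment (regions are amplicons; GUIDE-seq mode uses
mini-genomes), no paired-end handling, no base-quality-aware scoring, no
significance testing across replicates, and no modelling of sequencing error
structure beyond uniform substitutions. The mapping-quality proxy is
contractually different from BWA's; only threshold behaviour, not MAPQ
distributions, transfers between the two.
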