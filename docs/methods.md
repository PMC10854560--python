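# Methods notes

## Scope and data model

The package analyses annotated circular mitochondrial genomes
(13 protein-coding genes, 22 tRNAs, 2 rRNAs, a control region, and
replication origins). Internally all coordinates are 0-based half-open
on the forward strand; GenBank I/O stays 1-based inclusive and is
delegated to Biopython. Features wrapping the circular origin are
stored as two segments, and sequence access never wraps implicitly.
Gene labels from heterogeneous annotations are normalized to one
vocabulary (`nad1..nad6, nad4l, cox1-3, atp6, atp8, cob, trnX, rrnS,
rrnL, CR, OL, OH_n`); unknown labels are kept verbatim and flagged
rather than dropped. The two leucine and serine tRNA copies follow the
vertebrate convention (trnL2 = Leu(UUR) adjacent to rrnL;
trnS1 = Ser(AGY), the isoform lacking the dihydrouridine arm).

## Genetic-code layouts

Two code tables ship. The vertebrate mitochondrial code (NCBI table 2)
drives CDS validation: AGA/AGG are stops, TGA is Trp, and incomplete
terminal stops ("T--", "TA-") are recognized as the
polyadenylation-completed stops typical of mito annotations. Codon-usage
statistics (RSCU/ENC/CAI) default to the *standard* code's family
layout, because that is what the classic tools (CodonW, EMBOSS
chips/cai) use and what the conventional 59-codon RSCU vector presumes
(64 − ATG − TGG − TAA/TAG/TGA). The mito layout is available behind the
same interface for users who prefer biological families; results are
then 60-dimensional.

Consequences worth knowing: under the standard layout TGA is treated as
a stop (it is excluded from the 59-codon set either way) and ATA counts
as Ile. Both match the behaviour of the historical tooling this package
is meant to be comparable with.

## Statistics

- **RSCU**: `count * k / family_total` per family of size `k`; families
  with zero usage yield 0 for all members and are flagged rather than
  becoming NaN.
- **ENC**: Wright's estimator with per-family homozygosity
  `F = (n * sum(p^2) - 1) / (n - 1)` over families with `n >= 2`.
  Families with fewer than two observations are excluded from their
  class average; a missing three-fold class average is replaced by the
  mean of the two- and four-fold averages (Wright's own patch). A class
  with no usable families — or a class average of zero — contributes its
  uniform-usage maximum, which biases tiny genes toward "no evidence of
  bias" instead of failing; the result is capped at the layout's
  uniform-usage value (61). Per-class contributions are also capped at
  `class_size * k`, so finite-sample homozygosities marginally below
  `1/k` cannot push ENC above its ceiling.
- **CAI**: count-weighted geometric mean of `w(c) = ref(c) / max_family
  ref`, over sense codons in multi-codon families. Zero reference
  counts receive a fixed 0.5 pseudo-count *before* `w`; this is the
  only deviation from strict scale invariance in the reference. The
  default reference is the genome's own concatenated 13 PCGs, which is
  deterministic and avoids importing an external expression dataset; any
  count table can be substituted.

## ΔRSCU optimal-codon screen

Pipeline: per-gene ENC → extreme groups of size
`max(1, floor(0.10 * n_genes))` (one gene per group for 13 PCGs) →
*pooled* codon counts per group → group RSCU → per-codon
ΔRSCU = RSCU_high − RSCU_low. A codon is optimal iff ΔRSCU > 0.08,
RSCU_high > 1, and RSCU_low < 1, all strict. Pooling (rather than
averaging per-gene RSCU) is the standard reading of group usage and is
equivalent for single-gene groups.

Direction is configurable because the two conventions disagree: the
source convention assigns the *highest*-ENC genes to the
high-expression group, while the broader codon-bias literature treats
strongly biased (low-ENC) genes as highly expressed. The default
follows the former; `direction="conventional"` flips it, and explicit
`high=`/`low=` gene overrides bypass ENC ranking entirely. Ties in ENC
break by ascending gene name for determinism.

A statistical property of this rule worth stating plainly: for a
low-expression gene with *unbiased* synonymous usage the expected RSCU
of every codon is exactly 1, so the strict `RSCU_low < 1` condition is
satisfied only by the downward half of the sampling fluctuation —
roughly a coin flip per codon regardless of how strong the bias in the
high gene is. Per-run recall of truly preferred codons therefore
plateaus near 0.5 under those conditions, which the planted-truth
acceptance measurements reproduce; it is a property of the screening
rule itself, not of the implementation. Precision, by contrast, is high:
codons that are not preferred in the high-expression gene essentially
never pass `RSCU_high > 1` when every family has a planted preference.

## Clustering

Taxa are embedded as the RSCU vector of their concatenated PCGs
(59 columns, alphabetical). Hierarchical clustering uses scipy's
agglomerative linkage; defaults are Euclidean distance with average
linkage — a common default for interval data in desktop statistics
packages — and both are recorded in the result object. Input rows are
sorted by label before linkage so equal inputs give identical trees;
with generic (tie-free) data the result is row-order invariant. The
dendrogram exports to Newick with branch lengths equal to merge-height
differences.

## Control-region motifs

Motif hits are Hamming-distance matches, reported sorted by
(mismatches, start); the partition anchors at the best CSB-F and CSB-1
hits and tiles the region exactly as TAS = [0, CSB-F), central
conserved domain = [CSB-F, CSB-1), CSB = [CSB-1, end). Default
patterns are the consensus key sequences for hillstream-loach control
regions with mismatch allowances reflecting observed inter-species
variants (2 for the CSB-E GTGGG-box, 1 for CSB-2, 0 elsewhere). The
TAS core is detected as (TACAT, downstream ATGTA) pairs only;
stem-loop thermodynamics are deliberately not modelled — no energy
model is part of the contract.

## Gene order

Signatures rotate the coordinate-sorted feature list to start at trnF
(falling back to the smallest name), making them invariant under
rotation of the circular genome. Diffs align signatures by longest
common subsequence; shared-but-displaced elements are reported as
translocations. Spacer/overlap tallies walk circularly consecutive
features; the control region is excluded from the chain by default
since published spacer counts treat it as a feature, not a gap — the
option records which convention was used.

## Synthetic genomes

The generator emulates the study conditions: ~16.6 kb genomes, target
A+T of 54.5% (the middle of the observed 54.1–55.0% band), realistic
gene lengths (total PCG length 11,436 bp; tRNA total 1,560 bp; control
region 890 bp), canonical vertebrate gene order, cox1 starting GTG and
all other PCGs ATG with TAA stops, and an optional OH_1 origin between
trnE and cob overlapping trnE by 45 bp (the rearrangement marker).

Codon sampling draws each internal codon from a weight vector: the
planted preferred codon of its family has weight `1 + bias`, everything
else 1, with AGA/AGG and all stops excluded so generated PCGs validate
under the mito code. Within-family frequencies therefore follow the
`(1+b)/(k+b)` model exactly; family *choice* is proportional to summed
weights, a deliberate simplification (no attempt at realistic amino-acid
composition). The default planted map covers all 18 multi-codon
families and includes CTA, GTA, CCA, CAA, GAA, AGC and GGC among the
preferred codons; default bias is 1.5 (moderate, producing per-gene ENC
well inside the observed mitochondrial range). Non-coding filler is
i.i.d. with base frequencies solved analytically so the expected
genome-wide A+T hits the target (observed spread across seeds is well
under ±1.5 points), with fixed mild skews (AT-skew +0.08, GC-skew
−0.25) mimicking heavy-strand asymmetry.

What the generator does *not* emulate — and hence what passing tests do
not establish for real data: realistic amino-acid composition, tRNA/rRNA
secondary structure, gene overlaps other than trnE/OH_1 (real genomes
overlap atp8/atp6 by ~10 bp; synthetic genomes keep coding regions
disjoint so per-gene codon counts stay exact), sequence evolution along
a phylogeny, and indels. Cross-genome cluster tests use explicitly
divergent preference profiles, not an evolutionary model.

## Numerical and reporting choices

Percentages serialize to 2 decimals and skews to 4 (full precision
internally). N-containing codons are excluded from codon statistics and
counted as `skipped`; N bases are excluded from both numerator and
denominator of composition metrics. Empty inputs raise domain errors;
degenerate-but-valid inputs (zero-usage families, missing ENC classes,
single-genome batches) degrade with flags or logged notices rather than
exceptions. Batch runs write a manifest (config, package version, input
checksums) and contain no timestamps, so identical runs are
byte-identical.

## Sizes used by the test and acceptance runs

Synthetic checks use full-size genomes (~16.6 kb): 20 seeds for
planted-codon recovery and for composition calibration, 20 seeds × 12
genomes for cluster recovery, 500 random constructions for partition
tiling, and 1000 random count tables for RSCU conservation. The whole
suite and the acceptance script each complete in seconds on one CPU.

## Known limitations

Regression against the eleven deposited GenBank records requires
fetching them first (`scripts/fetch_accessions.py`); the library never
touches the network itself, and the corresponding test skips when the
files are absent. ENC and CAI reproduce published ranges only
approximately, since the historical tools differ in rare-amino-acid
handling and reference-set choice; published GC-skew extrema for these
genomes are internally inconsistent and are not asserted anywhere.
tRNA secondary structure, mismatch tallies, phylogenetic inference and
divergence-time estimation are out of scope.
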