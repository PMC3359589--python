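# Methods

This note documents the models, rules and numerical choices behind each
module, what the synthetic-data generator does and does not emulate, and the
design decisions taken where the procedure was genuinely open.

## Sequence primitives

**Coordinates** are 0-based half-open everywhere in memory; GFF3 output is
1-based closed, BED output 0-based half-open, VCF positions 1-based.

**ORFs.** An ORF is a maximal stop-free in-frame run that begins at ATG *or*
at the transcript boundary and ends at a stop codon (included in the span)
or at the boundary. Boundary-open ends are allowed because assembled
transcripts are frequently partial; runs consisting only of a stop codon are
not reported. All six frames on both strands are scanned.

**Pairwise alignment** is a k-mer-seeded (k = 15 by default), banded local
Smith–Waterman with integer scores (match +2, mismatch −3, gap −5, linear
gaps). Seeds choose a diagonal window (densest window of width ≤ 200,
padded by 32); when no seeds exist and the problem is at most ~2 M cells the
band covers the whole matrix, so small-pair results equal an exhaustive
dynamic program — the test suite checks this equivalence against an
independently written Smith–Waterman. Identity is
`matches / (matches + mismatches + indels)` with gap columns counted and `N`
never counting as a match; for minus-strand chains, block coordinates refer
to the reverse-complemented query so both axes stay strictly increasing.
Strand ties resolve to '+'. Clustering callers disable the full-matrix
fallback (seedless pairs at near-identity thresholds cannot be relevant),
which keeps merging roughly O(n·reps) in practice.

**Spliced alignment** chains maximal exact diagonal runs co-linearly,
allowing large target-only gaps. Query overlaps at junctions are slid to a
split whose intron boundaries are canonical (GT..AG preferred, then CT..AC,
else the leftmost split), blocks shorter than the minimum exon size
(30 nt by default) are then discarded, and target gaps of at least 20 nt are
treated as candidate introns (excluded from the identity denominator);
smaller target gaps and internal unaligned query bases count as indels.
Same-diagonal runs separated by at most 12 mismatch columns are bridged, so
lightly diverged exons still form single blocks.

**N50** follows the cumulative rule: the length of the shortest sequence in
the smallest set of longest sequences jointly covering at least half the
total bases. Gap bases (`N`) are excluded from the gap-free total only.

## Synthetic data

One RNG stream per component (genome, strain, reads, transcripts,
expression), each seeded from `(master_seed, component_tag)`, so regenerating
one stage never perturbs another and everything is byte-stable per seed.

* **Genomes**: uniform random scaffolds with non-overlapping genes placed
  sequentially; each coding gene is a single complete ORF (ATG … stop) split
  across 1–4 exons; every intron begins GT and ends AG on the gene strand;
  genes land on either strand with equal probability.
* **Strains**: diploid; fixed substitutions are planted on both haplotypes,
  heterozygous sites on one haplotype chosen at random per site, with a
  truth table of every planted site. Duplications append a copy (the spliced
  transcript for processed copies — hence intron-less — or the genomic span
  otherwise) beyond the reference coordinate range of a different scaffold,
  so reference-coordinate truth stays valid. Pseudogenizing frameshifts
  delete one base and therefore shift downstream strain coordinates; they
  are not combined with coordinate-sensitive truth checks.
* **Reads**: uniform sampling over both haplotypes; fragments never straddle
  scaffold boundaries; FR orientation for short-insert libraries and RF for
  mate-pair libraries; sequencing errors are uniform substitutions;
  duplicates are exact copies of already-emitted pairs (errors included);
  qualities are constant Q37 with an optional low-quality tail to exercise
  the truncation rule. "Unmated" mate-pair contaminants are emitted as FR
  pairs with short effective inserts and are drawn from the short-insert
  fragment pool when one is supplied — modelling short-insert carry-over
  through circularization, which is also what makes containment-based
  removal effective; without a pool they are sampled fresh.
* **Transcript sets**: per assembly label, each gene is emitted as its
  spliced sequence on a random strand, optionally split into two fragments
  sharing an exact terminal overlap (60 nt by default); chimeras concatenate
  a gene head-to-head with a partner of comparable length (neither
  constituent may exceed ~65% of the merged length), since only
  similarly-sized head-to-head merges are plausible terminal-overlap
  artifacts — and only those are detectable by the single-hit-coverage rule.
* **Expression**: negative-binomial counts (variance μ + φμ²; φ = 0.1 by
  default) for two strains across four tissues. Trichome genes get a
  12-fold mid-flower boost over their vegetative level (comfortably above
  the 10-fold design floor) and strain A's mid-flower additionally carries
  the trichome-enrichment factor (default 4); pathway genes multiply
  further per-gene fold-changes on top. Bulk baseline abundances are
  heavy-tailed lognormal (σ = 2) while trichome/pathway genes get modest
  fixed baselines, which keeps the boosted genes a small fraction of the
  library: RPKM's per-sample library normalization then distorts the planted
  ratios by well under 0.15 log2 units. Default library depth is a few
  million assigned reads per sample, in line with real tissue libraries.

What the generator does **not** emulate: repeat landscapes and segmental
duplications (unique mapping is nearly always unambiguous here), indel
sequencing errors, machine-specific error and quality profiles, GC and
3'-coverage bias, splice isoform diversity within a gene, and linkage
between planted variants. Passing recovery tests therefore demonstrates the
correctness of the rules and estimators under clean mapping conditions, not
robustness to repetitive or biased real data.

## Read QC

The low-quality rule is implemented as 3' truncation immediately before the
base at which the running count of sub-Q30 bases would exceed 10, with the
pair kept only if both truncated reads remain longer than 55 nt. Whole-read
discard is available behind `mode="discard"`, but truncation is the default:
a discard reading would make the "both reads larger than 55 bp" condition
vacuous for fixed-length reads. The filter order is fixed —
quality → adapter → unmated → duplicate — so the report categories are
disjoint and partition the input exactly (asserted by tests). Unmated
removal requires each mate read to be fully contained, in either
orientation and at ≥ 97% identity, within the reads of a single short-insert
pair; candidate placements come from exact 20-mer lookups at both read ends,
so up to one mismatch per ~20 bp is tolerated at the verification step. The
unmated-fraction estimator is FR/(FR+RF) over pairs placed on a single
contig longer than 10 kb.

## Orientation and merging

Translated homology uses a word-4 seeded, ungapped X-drop extension over
BLOSUM62 with the Karlin–Altschul approximation
`E = K·m·N·exp(−λS)`, λ = 0.267, K = 0.041 (ungapped BLOSUM62 constants);
any monotone surrogate of the e-value preserves the decision boundary on
synthetic data, and the constants are configurable. The splice vote
requires at least one canonical junction, strictly more canonical than
non-canonical junctions, and a single canonical polarity; the vote's sign
composes the chain strand with the junction polarity. The consensus is
conservative: one supporting method with no opposition orients; any
opposition (or a homology conflict) drops the transcript; no votes leave it
unoriented and excluded from the oriented set.

Near-identical clustering is greedy longest-first with deterministic
tie-breaks (the order of the external tool it stands in for is unspecified);
"similarity" for isoform clustering is alignment identity over the aligned
region, and single linkage is used (complete linkage would only split
borderline chains; the choice is documented rather than load-bearing).
Blunt overlaps require exact base match — "blunt" is read as exact terminal
identity — applied transitively, longest overlap first, ties by id. The
chimera filter applies only to assembly labels configured as chimera-prone,
mirroring its origin as a correction for one assembler's behaviour.
Re-running the full curation on its own output is a no-op (tested), and
reverse-complementing every input changes nothing up to strand
normalization.

## Concordance

Scaffold redundancy collapse unions all pairs at ≥ 98% identity over ≥ 95%
of the smaller scaffold (either strand) and keeps the largest member of each
transitive group. The foreign screen removes a scaffold only on joint
evidence: a foreign-db alignment score strictly above 150 (the aligner's
integer score; a 75-nt exact match scores exactly 150) *and* median read
coverage more than 2 standard deviations from the mean of validated host
scaffolds — "2 SDs outside the range" is operationalized as a z-score
against the validated-scaffold coverage distribution, since a range-based
reading is undefined for the two-sided case. Transcript-to-genome mapping
keeps, per transcript, a greedy non-overlapping (in transcript coordinates)
set of spliced chains at ≥ 98% identity, so every base is counted at most
once and mapped fractions cannot exceed 1; per-bin mapped+unmapped bases sum
exactly to the transcriptome size.

## Expression

RPKM is exact: `count / ((length/1e3) · (library/1e6))` with the library
size the column sum of assigned counts; recomputing counts from the matrix
inverts exactly. log2 transforms use a declared pseudocount of 0.25 RPKM
(configurable; zero handling is otherwise undefined). Hierarchical
clustering is average linkage on 1−Pearson of log2 RPKM rows; constant rows
get zero distance to each other, maximal distance elsewhere, and are
reported. Trichome selection takes the 1000 most abundant transcripts in an
explicit trichome-enriched reference sample (which sample to rank in is a
parameter, not a guess) and keeps the 100 with the greatest
log2(mid-flower) − log2(max of root/shoot/stem) difference, ties broken by
id; the adjustment factor is the median log2 strain ratio over the selection
minus the excluded pathway genes, and adjusted fold-changes subtract it.
Adding a constant to every strain-A log2 value moves the factor by exactly
that constant and leaves adjusted ratios unchanged (tested).

## Strain variation

Reads for depth and pileup go through minimap2 (short-read preset, one
thread); a read is "uniquely mapped" when the aligner reports non-zero
mapping quality, i.e. its best alignment is strictly better than the second
best. External alignments can be substituted — the pileup accumulator
consumes any SAM.

The caller scores {RR, RA, AA} per strain per site under binomial read
sampling with symmetric error e (default 0.01): an alt read has probability
e/3 under RR, (1−e)/2 + e/6 under RA, 1−e under AA. With uniform genotype
priors the per-strain posterior is the normalized likelihood, the site
quality is −10·log10 of the product of all strains' RR posteriors, and a
call is emitted iff any strain's maximum-likelihood genotype is non-RR.
Genotype posteriors match exhaustive enumeration at depth ≤ 12 (tested).
The published thresholds do the real work: quality ≥ 30, ≥ 5 unique reads
per strain, ≤ 150 reads total, with the same depth conditions defining the
callable region used as the denominator for heterozygosity
(RA sites / callable, as %) and pairwise rates (genotype-difference sites /
callable, as %; an allele-sharing variant of the rate is a one-line change
since full genotypes are retained in the calls table).

Concatenated SNV pseudo-sequences take one character per filtered site per
strain: homozygous genotypes contribute their allele, heterozygous sites the
majority-supported allele with ties to the reference (IUPAC codes would fall
outside the {A,C,G,T} domain of the distance model). The pairwise distance
maximizes the multinomial composite likelihood of (purine transitions,
pyrimidine transitions, transversions, identities) under TN93 with empirical
base frequencies, via L-BFGS-B plus a Nelder–Mead polish over the three
rate×time products (tolerance 1e-9); the distance is the implied expected
substitutions per site across both lineages, and it agrees with the TN93
closed form to ~1e-9 on well-conditioned tables (tested at 1e-6). Saturated
tables (any closed-form log argument ≤ 0) raise rather than return a
number. Neighbor joining is standard Saitou–Nei with lowest-index
tie-breaking; a negative branch length is clamped to zero with the deficit
moved to its sibling (preserving the path length) and logged.

MRD uses reads truncated to 32 nt placed by exact 32-mer lookup on the
transcriptome in either orientation; a read counts only when its sequence
occurs at exactly one transcriptome location. Reads carrying a sequencing
error in their first 32 nt simply fail to place, which attenuates both
strains equally and leaves MRD ratios unbiased. Transcripts shorter than
32 nt are flagged with an undefined MRD.

In the four-strain genealogy simulation, each strain also carries
heterozygous sites at a realistic 0.2%: concatenated variant columns then
include many near-invariant het sites, keeping the column-wise divergence of
SNV-only pseudo-sequences well below substitution saturation (without them,
75% of variant columns differ between groups and TN93 is undefined — a real
property of SNV-concatenation distances, not an implementation artifact).

## Gene families and chemotype

Homolog screening reports subjects strictly above the identity threshold
(65% by default) over the aligned region — the right measure for partial
hits such as pseudogene fragments split across scaffolds — with a 100-nt
aligned-span floor to keep trivial short exact matches out. Coding-status
classification projects the reference frame through the alignment: indels
whose length is not a multiple of three are frameshifts; candidate codons
aligned to reference codons that are stops more than 15 codons upstream of
the reference stop (a configurable 3' tolerance) are premature. The
classification is reflexive (an intact reference classifies as intact) and,
by construction of the generator, has sensitivity 1 for planted frameshifts
and early premature stops. The chemotype call requires an intact copy in
one family and no intact copy in the other; both intact is "mixed", neither
"undetermined".

## Problem sizes

Recovery runs use a 2-Mb reference at 30× per strain for the rate
estimators (≈4 000 planted het sites, so the binomial sampling error on a
0.20% rate is ~1.6% relative), 100-kb genomes at 20× for the 20-seed
genealogy replicates, 5 000 transcripts for expression recovery and 200-kb
genomes for duplication MRD. These sizes put estimator noise well inside
the stated recovery tolerances while keeping any single workflow to a few
minutes on one CPU.

## Known limitations

The aligner is a desk-scale tool: it is quadratic within its band, has no
affine gap distinction, and is not intended to compete with production
mappers (the variant pipeline uses minimap2 for exactly that reason). The
caller models substitutions only (no indels) and assumes position-
independent error. The chimera filter cannot detect merges where one
constituent covers most of the product — a genuine blind spot of the
single-hit-coverage rule, shared with its original use. TN93 distances on
concatenated SNV sites measure divergence *conditional on the polymorphic
site set*, so they are comparable within an analysis but not across
different strain panels.
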