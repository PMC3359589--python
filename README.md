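# cannaseq

Post-assembly computational analyses for draft plant genomes and
transcriptomes, built around the *Cannabis sativa* marijuana/hemp comparison:
short-read quality control and mate-pair hygiene, three-evidence transcript
orientation and multi-assembly merging, genome–transcriptome concordance,
RPKM expression profiling with a trichome-density adjustment, read-depth
copy-number proxies, multi-strain SNV calling with heterozygosity and
pairwise divergence rates, composite-likelihood strain trees, and
cannabinoid gene-family / pseudogene classification.

Every stage is exercisable on ground-truthed synthetic data produced by the
built-in simulator, so the whole pipeline can be validated without any
sequencing download.

## Who it is for

Bioinformaticians curating de novo assemblies of heterozygous plant genomes
and their companion transcriptomes, and anyone who wants a small, fully
tested reference implementation of the classic post-assembly rule set:

* **Read QC** — reads are truncated at the point where more than 10 bases
  fall below Q30, pairs kept only when both reads stay > 55 nt; adapter
  screening; mate pairs discarded when fully contained in a single
  short-insert pair ("unmated" removal) or duplicated in their first 30 bp.
* **Transcript orientation** — a transcript is oriented by (1) translated
  homology at e-value < 1e-6, (2) an ORF ≥ 240 nt spanning ≥ 70% of its
  length and twice the opposite strand's best ORF, and (3) canonical splice
  junctions (GT..AG / CT..AC) from spliced alignment with exon blocks
  ≥ 30 nt at ≥ 95% identity; any two opposing votes drop the transcript.
* **Merging** — near-identical clustering (≥ 97% identity over ≥ 95% of the
  shorter transcript, largest kept), chimera filtering (a single protein hit
  must cover > 70%), blunt-overlap joining (exact terminal overlaps
  ≥ 50 nt), isoform clustering (≥ 95% similarity over ≥ 100 nt) with
  largest-ORF representatives.
* **Strain variation** — a minimal multi-sample genotype caller
  (binomial read sampling with symmetric error; site quality
  `-10·log10 P(all strains hom-ref)`), filtered at quality ≥ 30, ≥ 5 unique
  reads per strain and ≤ 150 total; heterozygosity and pairwise SNV rates
  per callable base; Tamura–Nei (TN93) composite-likelihood distances over
  concatenated SNV pseudo-sequences; Saitou–Nei neighbor joining.
* **Copy number** — median read depth (MRD) of genomic reads trimmed to
  32 nt and placed uniquely on the transcriptome.
* **Chemotype** — family homologs above 65% nucleotide identity are
  classified intact vs pseudogenic (frameshifts, premature stops); an intact
  THCAS-family gene with only pseudogenic CBDAS-family copies calls a strain
  THCA-dominant, and symmetrically for hemp.

## Worked example

`examples/` contains one short script per capability. For instance, the
orientation/merging pipeline on two simulated assembler outputs
(`python examples/03_orient_and_merge_transcripts.py`) prints:

```
{'asmA': 41, 'asmB': 42} input transcripts
asmA: consensus {'-': 25, '+': 16}
asmB: consensus {'+': 20, '-': 19, 'dropped': 3}
after cross-assembly merging: 37
after blunt-overlap joining:  30 (7 joins)
final representatives:        30 (genome has 30 genes)
representative N50: 909 nt over 22131 bases
orientation accuracy vs truth: 80/80
```

i.e. 83 strand-scrambled, fragmented, partly chimeric transcripts collapse to
exactly one representative per underlying gene, every orientation call agrees
with the simulator's truth table, and the three chimeras in `asmB` are the
transcripts dropped for conflicting evidence. The strain-comparison example
(`python examples/06_snv_calling_and_strain_tree.py`) builds the four-strain
tree from planted genealogy `((mj1,mj2),(hemp1,hemp2))` and prints the TN93
distance matrix and a newick tree separating the two pairs.

A thin CLI covers the shell-friendly tasks:

```bash
cannaseq simulate --seed 5 --out-prefix demo      # FASTA + GFF3 + gene table
cannaseq stats demo.fa                            # N50 and totals
cannaseq orient transcripts.fa --genome demo.fa --proteins prots.fa --out calls.tsv
cannaseq merge asmA.fa asmB.fa --out reps.fa
cannaseq family --queries synthases.fa --subjects demo.fa --out hits.tsv
cannaseq nj distances.tsv --out tree.nwk
```

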