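"""Build a ground-truthed synthetic genome and derive a diploid strain.

Prints the genome layout, the planted variant counts, and verifies every
intron is canonical (GT..AG).  All downstream examples start from objects
like these.
"""

from cannaseq.seqcore import revcomp
from cannaseq.simulate import GenomeSpec, StrainSpec, derive_strain, generate_genome

genome = generate_genome(
    GenomeSpec(n_scaffolds=2, scaffold_length=40_000, n_genes=10), seed=11
)
print(f"genome: {len(genome.scaffolds)} scaffolds, {len(genome.genes)} genes")
print(genome.genes_df().head().to_string(index=False))

canonical = 0
total = 0
for gene in genome.genes:
    sc = genome.scaffold(gene.scaffold_id).seq
    for (a, b), (c, d) in zip(gene.exons, gene.exons[1:]):
        intron = sc[b:c] if gene.strand == "+" else revcomp(sc[b:c])
        total += 1
        canonical += intron[:2] == "GT" and intron[-2:] == "AG"
print(f"introns canonical GT..AG: {canonical}/{total}")

strain = derive_strain(
    genome, StrainSpec("cultivarA", fixed_snv_rate=0.004, het_rate=0.002), seed=11
)
counts = strain.variants.zygosity.value_counts()
print(
    f"planted variants in cultivarA: {counts.get('fixed', 0)} fixed, "
    f"{counts.get('het', 0)} heterozygous over 80 kb"
)
# fixed sites sit on both haplotypes, het sites on exactly one
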