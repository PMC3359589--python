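"""End-to-end recovery workflows on synthetic data.

These functions wire the simulator to the analysis stages under the study
conditions the package models: a multi-megabase reference, ~30x short-read
coverage per strain at ~0.5% sequencing error, heterozygosity around 0.2%,
between-strain divergence up to ~0.64%, a fourfold trichome-density
difference between strains, and single-gene duplications.  They exist so
that parameter-recovery checks (tests and the acceptance script) and the
examples share one code path.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import expression as xp
from . import variants as vr
from .simulate import (
    ExpressionSpec,
    GenomeModel,
    GenomeSpec,
    ReadSimSpec,
    StrainGenome,
    StrainSpec,
    component_rng,
    derive_strain,
    generate_genome,
    mutate_sequences,
    simulate_assembled_transcripts,
    simulate_expression_counts,
    simulate_reads,
)


def _align_and_pileup(
    strain_name: str,
    haplotypes,
    reference_fasta: Path,
    workdir: Path,
    coverage: float,
    error_rate: float,
    seed: int,
    read_len: int = 100,
) -> vr.StrainPileup:
    reads = simulate_reads(
        haplotypes,
        ReadSimSpec(coverage=coverage, read_len=read_len, paired=False,
                    error_rate=error_rate),
        seed=seed,
        name=strain_name,
    )
    fq = workdir / f"{strain_name}.fastq"
    sam = workdir / f"{strain_name}.sam"
    reads.to_fastq(fq)
    vr.run_minimap2(reference_fasta, fq, sam)
    return vr.pileup_from_sam(sam, strain_name)


def call_strain_panel(
    genome: GenomeModel,
    strains: list[StrainGenome],
    seed: int,
    coverage: float = 30.0,
    error_rate: float = 0.005,
) -> tuple[pd.DataFrame, dict[str, np.ndarray], vr.CallSet]:
    """Simulate reads for each strain, align to the reference, run the
    multi-sample caller and the published filters.

    Returns (filtered calls, callable mask, full call set)."""
    reference = {sc.id: sc.seq for sc in genome.scaffolds}
    with tempfile.TemporaryDirectory() as td:
        workdir = Path(td)
        ref_fa = workdir / "ref.fa"
        genome.write_fasta(ref_fa)
        pileups = []
        for i, st in enumerate(strains):
            pileups.append(
                _align_and_pileup(
                    st.name, st.haplotypes, ref_fa, workdir,
                    coverage, error_rate, seed=seed * 131 + i,
                )
            )
    callset = vr.pileup_and_call(pileups, reference)
    filtered, mask = vr.filter_variants(callset)
    return filtered, mask, callset


def recover_heterozygosity(
    seed: int,
    genome_bp: int = 2_000_000,
    het_rate: float = 0.002,
    coverage: float = 30.0,
    error_rate: float = 0.005,
) -> dict:
    """Plant heterozygous sites in a diploid strain, run the full calling
    pipeline against a homozygous companion, and report the recovered
    heterozygosity as a percentage of callable bases."""
    spec = GenomeSpec(
        n_scaffolds=2, scaffold_length=genome_bp // 2, n_genes=20,
    )
    genome = generate_genome(spec, seed)
    het = derive_strain(genome, StrainSpec("het_strain", het_rate=het_rate), seed)
    comp = derive_strain(genome, StrainSpec("companion"), seed + 1)
    filtered, mask, callset = call_strain_panel(
        genome, [het, comp], seed, coverage, error_rate
    )
    rate = vr.heterozygosity_rate(filtered, mask, "het_strain")
    return {
        "het_pct": rate,
        "planted_pct": 100.0 * len(het.variants[het.variants.zygosity == "het"]) / genome_bp,
        "callable_bases": vr.callable_bases(mask),
        "n_filtered_calls": len(filtered),
    }


def recover_pairwise_rate(
    seed: int,
    genome_bp: int = 2_000_000,
    divergence: float = 0.0064,
    coverage: float = 30.0,
    error_rate: float = 0.005,
) -> dict:
    """Plant fixed differences between two strains at ``divergence`` per base
    and report the recovered pairwise SNV rate (percent of callable bases
    where the called genotypes differ)."""
    spec = GenomeSpec(n_scaffolds=2, scaffold_length=genome_bp // 2, n_genes=20)
    genome = generate_genome(spec, seed)
    a = derive_strain(genome, StrainSpec("strainA"), seed)
    b = derive_strain(genome, StrainSpec("strainB", fixed_snv_rate=divergence), seed + 1)
    filtered, mask, _ = call_strain_panel(genome, [a, b], seed, coverage, error_rate)
    rate = vr.pairwise_snv_rate(filtered, mask, "strainA", "strainB")
    return {
        "pairwise_pct": rate,
        "planted_pct": 100.0 * len(b.variants[b.variants.zygosity == "fixed"]) / genome_bp,
        "callable_bases": vr.callable_bases(mask),
    }


def four_strain_tree(
    seed: int,
    genome_bp: int = 100_000,
    branch_rates: tuple[float, float] = (0.002, 0.002),
    het_rate: float = 0.002,
    coverage: float = 20.0,
    error_rate: float = 0.002,
) -> tuple[str, pd.DataFrame]:
    """Simulate the planted genealogy ((mj1,mj2),(hemp1,hemp2)), run the full
    pipeline (reads -> align -> call -> filter -> concatenated SNV
    pseudo-sequences -> TN93 composite-likelihood distances -> NJ) and return
    the newick tree plus the distance matrix.

    ``branch_rates`` are the substitution rates on the internal (shared) and
    terminal (private) branches; each strain additionally carries
    heterozygous sites at ``het_rate`` (as real cultivars do), which keeps
    the concatenated variant columns far from substitution saturation.
    """
    spec = GenomeSpec(n_scaffolds=2, scaffold_length=genome_bp // 2, n_genes=10)
    genome = generate_genome(spec, seed)
    reference = {sc.id: sc.seq for sc in genome.scaffolds}
    rng = component_rng(seed, "strain")
    internal, private = branch_rates
    mj_anc, _ = mutate_sequences(reference, internal, rng)
    hemp_anc, _ = mutate_sequences(reference, internal, rng)
    strains = []
    for name, anc in (
        ("mj1", mj_anc), ("mj2", mj_anc), ("hemp1", hemp_anc), ("hemp2", hemp_anc)
    ):
        seqs, _ = mutate_sequences(anc, private, rng)
        hap1, _ = mutate_sequences(seqs, het_rate, rng)
        strains.append(StrainGenome(name, (hap1, seqs), pd.DataFrame(), {}))
    with tempfile.TemporaryDirectory() as td:
        workdir = Path(td)
        ref_fa = workdir / "ref.fa"
        genome.write_fasta(ref_fa)
        pileups = [
            _align_and_pileup(st.name, st.haplotypes, ref_fa, workdir,
                              coverage, error_rate, seed=seed * 977 + i)
            for i, st in enumerate(strains)
        ]
    callset = vr.pileup_and_call(pileups, reference)
    filtered, mask = vr.filter_variants(callset)
    pseudo = vr.concatenate_variant_sequences(filtered, [s.name for s in strains])
    dm = vr.distance_matrix(pseudo)
    tree, _ = vr.neighbor_joining(dm)
    return tree, dm


def tree_separates_pairs(newick: str) -> bool:
    """True when the unrooted topology splits {mj1,mj2} from {hemp1,hemp2}."""
    import re

    inner = re.findall(r"\(([A-Za-z0-9_]+):[0-9.eE+-]+,([A-Za-z0-9_]+):[0-9.eE+-]+\)", newick)
    for a, b in inner:
        if {a, b} == {"mj1", "mj2"} or {a, b} == {"hemp1", "hemp2"}:
            return True
    return False


def recover_trichome_enrichment(
    seed: int,
    n_transcripts: int = 5000,
    n_trichome: int = 120,
    enrichment: float = 4.0,
    dispersion: float = 0.1,
    pathway_fold: float = 15.0,
    n_pathway: int = 19,
) -> dict:
    """Simulate two-strain expression with a planted trichome-density ratio
    and pathway up-regulation; recover the adjustment factor and adjusted
    pathway fold-changes."""
    gene_ids = [f"t{i:05d}" for i in range(n_transcripts)]
    trichome = gene_ids[:n_trichome]
    pathway = trichome[:n_pathway]
    espec = ExpressionSpec(
        gene_ids=gene_ids,
        trichome_gene_ids=trichome,
        trichome_enrichment=enrichment,
        pathway_fold={g: pathway_fold for g in pathway},
        dispersion=dispersion,
        library_scale=8.0,
        strains=("PK", "Finola"),
    )
    counts = simulate_expression_counts(espec, seed)
    rng = component_rng(seed, "expression")
    lengths = pd.Series(
        rng.integers(500, 3000, n_transcripts).astype(float), index=gene_ids
    )
    roles = {"mid_flower": "mid_flower", "root": "root", "shoot": "shoot", "stem": "stem"}
    m_a = xp.compute_rpkm(counts["PK"], lengths, roles)
    m_b = xp.compute_rpkm(counts["Finola"], lengths, roles)
    adj = xp.select_trichome_genes(m_a, reference_sample="mid_flower")
    factor = xp.trichome_adjustment_factor(
        adj, m_a.rpkm["mid_flower"], m_b.rpkm["mid_flower"], exclude=pathway
    )
    adjusted = xp.adjusted_fold_changes(
        m_a.rpkm["mid_flower"], m_b.rpkm["mid_flower"], factor, pathway
    )
    n_selected_true = len(set(adj.selected_ids) & set(trichome))
    return {
        "factor_log2": factor,
        "planted_log2": float(np.log2(enrichment)),
        "n_selected_trichome": n_selected_true,
        "median_adjusted_pathway_log2": float(np.median(adjusted)),
        "planted_pathway_log2": float(np.log2(pathway_fold)),
    }


def orientation_accuracy(
    seed: int,
    n_genes: int = 40,
    frag_prob: float = 0.3,
) -> dict:
    """Emit assembler-like transcripts on random strands, orient them with
    the three-method consensus, and score the calls against the truth table.

    Reported accuracy is over transcripts receiving a consensus strand."""
    from .curation import ProteinIndex, orient_transcripts

    spec = GenomeSpec(n_scaffolds=4, scaffold_length=60_000, n_genes=n_genes)
    genome = generate_genome(spec, seed)
    sets, truth = simulate_assembled_transcripts(
        genome, seed, frag_prob=frag_prob, chimera_rate=0.0
    )
    idx = ProteinIndex(genome.protein_seqs())
    tt = truth.set_index("transcript_id")
    n_called = n_correct = n_uncalled = 0
    for label, transcripts in sets.items():
        _, calls = orient_transcripts(transcripts, idx, genome.scaffolds)
        for call in calls:
            if call.consensus in "+-":
                n_called += 1
                n_correct += call.consensus == tt.loc[call.transcript_id, "emitted_strand"]
            else:
                n_uncalled += 1
    return {
        "accuracy": n_correct / n_called if n_called else float("nan"),
        "n_called": n_called,
        "n_uncalled": n_uncalled,
    }


def recover_duplication_mrd(
    seed: int,
    genome_bp: int = 200_000,
    coverage: float = 20.0,
    duplicated_gene_index: int = 0,
) -> dict:
    """Plant one extra gene copy in strain A only and recover the
    log2 MRD(A)/MRD(B) copy-number signal over the transcriptome."""
    spec = GenomeSpec(n_scaffolds=2, scaffold_length=genome_bp // 2, n_genes=12)
    genome = generate_genome(spec, seed)
    gid = genome.genes[duplicated_gene_index].id
    a = derive_strain(
        genome, StrainSpec("dupA", duplications=[(gid, 1, True)]), seed
    )
    b = derive_strain(genome, StrainSpec("plainB"), seed + 1)
    transcriptome = genome.transcripts()
    out = {}
    for st in (a, b):
        reads = simulate_reads(
            st, ReadSimSpec(coverage=coverage, read_len=44, paired=False),
            seed=seed * 31 + (0 if st is a else 1), name=st.name,
        )
        seqs = (reads.r1[i].tobytes().decode() for i in range(reads.n_pairs))
        out[st.name] = vr.mrd_per_transcript(seqs, transcriptome, strain=st.name)
    ratios = {}
    for t in transcriptome:
        ma, mb = out["dupA"][t.id].mrd, out["plainB"][t.id].mrd
        if ma and mb:
            ratios[t.id] = float(np.log2(ma / mb))
    return {
        "log2_mrd_duplicated": ratios.get(gid),
        "median_log2_mrd_background": float(
            np.median([v for k, v in ratios.items() if k != gid])
        ),
        "duplicated_gene": gid,
    }
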