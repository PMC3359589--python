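"""Ground-truthed synthetic data: genomes, strains, reads, assembler-like
transcript sets and expression counts.

Every generator is deterministic for a fixed seed and emits a machine-readable
truth table alongside its sequences, so downstream recovery tests consume only
truth tables, never generator internals.  Independent RNG streams are derived
per component from the master seed, so changing one stage leaves the others
byte-stable.

The defaults describe the study conditions the analyses assume: diploid
strains with heterozygous sites at a few tenths of a percent, fixed
between-strain differences up to ~0.6%, canonical GT..AG introns, short-read
libraries with exact duplicate pairs and forward-reverse "unmated" mate-pair
contamination, and negative-binomial expression with flower/trichome-dominant
genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .seqcore import NucSequence, revcomp, write_fasta

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]

# fixed per-component entropy tags so sub-streams are independent
_STREAMS = {"genome": 1, "strain": 2, "reads": 3, "transcripts": 4, "expression": 5}


def component_rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STREAMS[component])))


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


# ---------------------------------------------------------------------------
# Genome model
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    id: str
    scaffold_id: str
    strand: str
    exons: list[tuple[int, int]]  # forward-strand, sorted, non-overlapping
    coding: bool = True
    family_id: str | None = None


@dataclass
class GenomeModel:
    scaffolds: list[NucSequence]
    genes: list[GeneModel]
    seed: int

    def scaffold(self, sid: str) -> NucSequence:
        return self._index()[sid]

    def _index(self) -> dict[str, NucSequence]:
        if not hasattr(self, "_scmap"):
            self._scmap = {s.id: s for s in self.scaffolds}
        return self._scmap

    def gene(self, gid: str) -> GeneModel:
        return next(g for g in self.genes if g.id == gid)

    def transcript_seq(self, gene: GeneModel | str) -> str:
        """Spliced transcript on the coding strand of the gene."""
        g = self.gene(gene) if isinstance(gene, str) else gene
        sc = self.scaffold(g.scaffold_id).seq
        s = "".join(sc[a:b] for a, b in g.exons)
        return s if g.strand == "+" else revcomp(s)

    def transcripts(self) -> list[NucSequence]:
        return [NucSequence(g.id, self.transcript_seq(g)) for g in self.genes]

    def transcript_lengths(self) -> pd.Series:
        return pd.Series({g.id: sum(b - a for a, b in g.exons) for g in self.genes})

    def protein_seqs(self) -> list[tuple[str, str]]:
        """(id, aa) pairs for coding genes (terminal stop removed)."""
        from Bio.Seq import Seq

        out = []
        for g in self.genes:
            if g.coding:
                aa = str(Seq(self.transcript_seq(g)).translate()).rstrip("*")
                out.append((g.id, aa))
        return out

    def genes_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": g.id,
                    "scaffold": g.scaffold_id,
                    "strand": g.strand,
                    "n_exons": len(g.exons),
                    "start": g.exons[0][0],
                    "end": g.exons[-1][1],
                    "coding": g.coding,
                    "family_id": g.family_id or g.id,
                }
                for g in self.genes
            ]
        )

    def write_fasta(self, path: str | Path) -> None:
        write_fasta(self.scaffolds, path)

    def write_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.genes:
                start = g.exons[0][0] + 1
                end = g.exons[-1][1]
                fh.write(
                    f"{g.scaffold_id}\tcannaseq\tgene\t{start}\t{end}\t.\t"
                    f"{g.strand}\t.\tID={g.id}\n"
                )
                for i, (a, b) in enumerate(g.exons, 1):
                    fh.write(
                        f"{g.scaffold_id}\tcannaseq\texon\t{a + 1}\t{b}\t.\t"
                        f"{g.strand}\t.\tID={g.id}.exon{i};Parent={g.id}\n"
                    )


@dataclass
class GenomeSpec:
    """Sizes and gene counts for a synthetic multi-scaffold genome."""

    n_scaffolds: int = 4
    scaffold_length: int = 50_000
    n_genes: int = 30
    exons_per_gene: tuple[int, int] = (1, 4)
    exon_length: tuple[int, int] = (150, 400)
    intron_length: tuple[int, int] = (80, 300)
    intergenic: tuple[int, int] = (200, 800)


def generate_genome(spec: GenomeSpec, seed: int) -> GenomeModel:
    """Deterministic synthetic genome with intron-containing coding genes.

    Coding genes are single complete ORFs (ATG .. stop) split across exons;
    every intron begins GT and ends AG on the gene strand.  Raises ValueError
    when the requested genes do not fit on the scaffolds.
    """
    rng = component_rng(seed, "genome")
    scaffolds = [
        NucSequence(f"scaffold{i + 1}", _random_dna(rng, spec.scaffold_length))
        for i in range(spec.n_scaffolds)
    ]
    arrays = [bytearray(s.seq.encode()) for s in scaffolds]
    cursors = [int(rng.integers(*spec.intergenic)) for _ in scaffolds]
    genes: list[GeneModel] = []
    for gi in range(spec.n_genes):
        si = gi % spec.n_scaffolds
        n_ex = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
        exon_lens = [int(rng.integers(*spec.exon_length)) for _ in range(n_ex)]
        total = sum(exon_lens)
        exon_lens[-1] -= total % 3
        total = sum(exon_lens)
        n_codons = total // 3
        cds = "ATG" + "".join(
            rng.choice(_NONSTOP_CODONS) for _ in range(n_codons - 2)
        ) + str(rng.choice(_STOPS))
        introns = [
            "GT" + _random_dna(rng, int(rng.integers(*spec.intron_length)) - 4) + "AG"
            for _ in range(n_ex - 1)
        ]
        pieces = []
        off = 0
        exon_seqs = []
        for L in exon_lens:
            exon_seqs.append(cds[off : off + L])
            off += L
        for i, es in enumerate(exon_seqs):
            pieces.append(es)
            if i < len(introns):
                pieces.append(introns[i])
        gene_seq = "".join(pieces)
        strand = "+" if rng.random() < 0.5 else "-"
        placed = gene_seq if strand == "+" else revcomp(gene_seq)
        start = cursors[si]
        end = start + len(placed)
        if end + spec.intergenic[1] > spec.scaffold_length:
            raise ValueError(
                f"infeasible spec: gene {gi + 1} does not fit on "
                f"{scaffolds[si].id} (need {end} of {spec.scaffold_length} bp)"
            )
        arrays[si][start:end] = placed.encode()
        # exon intervals in forward coordinates
        exon_iv = []
        off = 0
        for i, es in enumerate(exon_seqs):
            exon_iv.append((off, off + len(es)))
            off += len(es)
            if i < len(introns):
                off += len(introns[i])
        if strand == "+":
            exons = [(start + a, start + b) for a, b in exon_iv]
        else:
            L = len(gene_seq)
            exons = sorted((start + L - b, start + L - a) for a, b in exon_iv)
        genes.append(
            GeneModel(f"gene{gi + 1:04d}", scaffolds[si].id, strand, exons,
                      coding=True, family_id=f"gene{gi + 1:04d}")
        )
        cursors[si] = end + int(rng.integers(*spec.intergenic))
    scaffolds = [
        NucSequence(s.id, a.decode(), s.description)
        for s, a in zip(scaffolds, arrays)
    ]
    return GenomeModel(scaffolds=scaffolds, genes=genes, seed=seed)


# ---------------------------------------------------------------------------
# Strains
# ---------------------------------------------------------------------------

@dataclass
class StrainSpec:
    name: str
    fixed_snv_rate: float = 0.0
    het_rate: float = 0.0
    duplications: list[tuple[str, int, bool]] = field(default_factory=list)
    pseudogenize: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for r in (self.fixed_snv_rate, self.het_rate):
            if not 0.0 <= r <= 0.05:
                raise ValueError("SNV rates must be within [0, 0.05]")


@dataclass
class StrainGenome:
    name: str
    haplotypes: tuple[dict[str, str], dict[str, str]]
    variants: pd.DataFrame  # scaffold, pos, ref, alt, zygosity
    reference_lengths: dict[str, int]

    def haplotype_fastas(self) -> tuple[list[NucSequence], list[NucSequence]]:
        return tuple(
            [NucSequence(f"{sid}|{self.name}|hap{h + 1}", seq) for sid, seq in hap.items()]
            for h, hap in enumerate(self.haplotypes)
        )


def _plant_snvs(arr: bytearray, rate: float, rng: np.random.Generator,
                limit: int, taken: set[int]) -> list[tuple[int, str, str]]:
    n = rng.binomial(limit, rate)
    out = []
    positions = rng.choice(limit, size=min(n, limit), replace=False)
    for pos in sorted(int(p) for p in positions):
        if pos in taken:
            continue
        taken.add(pos)
        ref = chr(arr[pos])
        alts = [b for b in "ACGT" if b != ref]
        alt = alts[int(rng.integers(0, 3))]
        out.append((pos, ref, alt))
    return out


def derive_strain(g: GenomeModel, s: StrainSpec, seed: int) -> StrainGenome:
    """Diploid strain genome: planted fixed and heterozygous SNVs plus
    optional gene duplications (processed copies lack introns) and
    pseudogenizing mutations.

    Fixed differences land on both haplotypes, heterozygous sites on one
    (chosen at random per site).  Duplicated copies are appended to scaffolds
    other than the source gene's, beyond the reference coordinate range, so
    reference-coordinate truth stays valid.  Frameshift pseudogenization
    deletes one base and therefore shifts downstream strain coordinates on
    that scaffold; avoid combining it with coordinate-sensitive truth checks.
    """
    rng = component_rng(seed, "strain")
    hap1 = {sc.id: bytearray(sc.seq.encode()) for sc in g.scaffolds}
    hap2 = {sc.id: bytearray(sc.seq.encode()) for sc in g.scaffolds}
    ref_lengths = {sc.id: len(sc) for sc in g.scaffolds}
    rows = []
    for sc in g.scaffolds:
        taken: set[int] = set()
        for pos, ref, alt in _plant_snvs(hap1[sc.id], s.fixed_snv_rate, rng,
                                         ref_lengths[sc.id], taken):
            hap1[sc.id][pos] = ord(alt)
            hap2[sc.id][pos] = ord(alt)
            rows.append((sc.id, pos, ref, alt, "fixed"))
        for pos, ref, alt in _plant_snvs(hap1[sc.id], s.het_rate, rng,
                                         ref_lengths[sc.id], taken):
            target = hap1 if rng.random() < 0.5 else hap2
            target[sc.id][pos] = ord(alt)
            rows.append((sc.id, pos, ref, alt, "het"))
    # pseudogenization (both haplotypes)
    for gid, mode in s.pseudogenize:
        gene = g.gene(gid)
        _apply_pseudogenization(g, gene, mode, hap1, hap2)
    # duplications appended to other scaffolds
    other = [sc.id for sc in g.scaffolds]
    for gid, extra_copies, processed in s.duplications:
        gene = g.gene(gid)
        if processed:
            copy_seq = g.transcript_seq(gene)
        else:
            sc = g.scaffold(gene.scaffold_id).seq
            copy_seq = sc[gene.exons[0][0] : gene.exons[-1][1]]
        targets = [sid for sid in other if sid != gene.scaffold_id]
        if not targets:
            raise ValueError("duplications require at least two scaffolds")
        for c in range(extra_copies):
            sid = targets[c % len(targets)]
            for hap in (hap1, hap2):
                hap[sid].extend(copy_seq.encode())
    variants = pd.DataFrame(rows, columns=["scaffold", "pos", "ref", "alt", "zygosity"])
    return StrainGenome(
        name=s.name,
        haplotypes=(
            {k: v.decode() for k, v in hap1.items()},
            {k: v.decode() for k, v in hap2.items()},
        ),
        variants=variants,
        reference_lengths=ref_lengths,
    )


def _apply_pseudogenization(g, gene, mode, hap1, hap2) -> None:
    sid = gene.scaffold_id
    total = sum(b - a for a, b in gene.exons)
    n_codons = total // 3
    target_codon = n_codons // 2
    # transcript-coordinate position of the codon start
    tpos = target_codon * 3
    # map transcript coordinate -> forward scaffold coordinate
    if gene.strand == "+":
        off = tpos
        for a, b in gene.exons:
            if off < b - a:
                fwd = a + off
                break
            off -= b - a
    else:
        off = tpos
        for a, b in reversed(gene.exons):
            if off < b - a:
                fwd = b - 1 - off
                break
            off -= b - a
    if mode == "premature_stop":
        stop = "TAA" if gene.strand == "+" else revcomp("TAA")
        if gene.strand == "+":
            sl = slice(fwd, fwd + 3)
        else:
            sl = slice(fwd - 2, fwd + 1)
        for hap in (hap1, hap2):
            hap[sid][sl] = stop.encode()
    elif mode == "frameshift":
        for hap in (hap1, hap2):
            del hap[sid][fwd]
    else:
        raise ValueError(f"unknown pseudogenization mode {mode!r}")


def mutate_sequences(seqs: dict[str, str], rate: float,
                     rng: np.random.Generator) -> tuple[dict[str, str], pd.DataFrame]:
    """Plant fixed substitutions at ``rate`` per base; used to build nested
    strain genealogies (shared branch mutations, then private ones)."""
    out = {}
    rows = []
    for sid, seq in seqs.items():
        arr = bytearray(seq.encode())
        taken: set[int] = set()
        for pos, ref, alt in _plant_snvs(arr, rate, rng, len(arr), taken):
            arr[pos] = ord(alt)
            rows.append((sid, pos, ref, alt))
        out[sid] = arr.decode()
    return out, pd.DataFrame(rows, columns=["scaffold", "pos", "ref", "alt"])


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

@dataclass
class ReadSimSpec:
    coverage: float = 30.0
    read_len: int = 100
    paired: bool = True
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    error_rate: float = 0.0
    duplicate_frac: float = 0.0
    unmated_frac: float = 0.0
    unmated_insert_mean: float = 220.0
    unmated_insert_sd: float = 25.0
    orientation: str = "FR"  # FR for short-insert, RF for mate-pair libraries
    quality: int = 37
    lowq_tail_frac: float = 0.0
    lowq_tail_len: int = 20
    lowq_quality: int = 2


@dataclass
class ReadSet:
    """Simulated reads held as byte matrices, with a per-pair truth table."""

    r1: np.ndarray  # (n, read_len) uint8 ASCII
    r2: np.ndarray | None
    q1: np.ndarray
    q2: np.ndarray | None
    truth: pd.DataFrame
    orientation: str
    name: str = "sim"

    @property
    def n_pairs(self) -> int:
        return self.r1.shape[0]

    def read1_str(self, i: int) -> str:
        return self.r1[i].tobytes().decode()

    def read2_str(self, i: int) -> str:
        return self.r2[i].tobytes().decode()

    def pairs(self):
        """Yield :class:`cannaseq.read_qc.ReadPair` objects (small scales)."""
        from .read_qc import ReadPair

        for i in range(self.n_pairs):
            yield ReadPair(
                id=f"{self.name}:{i:07d}",
                seq1=self.read1_str(i),
                qual1=self.q1[i] - 33,
                seq2=self.read2_str(i) if self.r2 is not None else None,
                qual2=(self.q2[i] - 33) if self.q2 is not None else None,
            )

    def to_fastq(self, path1: str | Path, path2: str | Path | None = None) -> None:
        def dump(path, mat, qmat, suffix):
            with open(path, "w") as fh:
                for i in range(mat.shape[0]):
                    fh.write(
                        f"@{self.name}:{i:07d}{suffix}\n{mat[i].tobytes().decode()}\n"
                        f"+\n{qmat[i].tobytes().decode()}\n"
                    )

        if self.r2 is None:
            dump(path1, self.r1, self.q1, "")
        else:
            dump(path1, self.r1, self.q1, "/1")
            dump(path2, self.r2, self.q2, "/2")


_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
_DEC = np.frombuffer(b"ACGT", dtype=np.uint8)
_RC = np.array([3, 2, 1, 0], dtype=np.uint8)  # complement in code space


def _concat_template(haplotypes: Sequence[dict[str, str]]):
    names, offsets, parts = [], [], []
    off = 0
    for h, hap in enumerate(haplotypes):
        for sid, seq in hap.items():
            names.append((h, sid))
            offsets.append(off)
            parts.append(np.frombuffer(seq.encode(), dtype=np.uint8))
            off += len(seq)
    return names, np.array(offsets), np.concatenate(parts)


def simulate_reads(
    haplotypes: StrainGenome | Sequence[dict[str, str]] | dict[str, str],
    spec: ReadSimSpec,
    seed: int,
    short_insert_pool: ReadSet | None = None,
    name: str = "sim",
) -> ReadSet:
    """Sample reads uniformly from the haplotypes of a (diploid) template.

    Pairs are FR (short-insert convention) or RF (mate-pair convention);
    ``unmated_frac`` of an RF library is emitted as FR short-insert
    contamination, drawn from ``short_insert_pool`` pairs when provided
    (modelling short-insert carry-over) or freshly sampled otherwise.
    ``duplicate_frac`` of the final pairs are exact copies of earlier pairs.
    """
    if isinstance(haplotypes, StrainGenome):
        haps = list(haplotypes.haplotypes)
    elif isinstance(haplotypes, dict):
        haps = [haplotypes]
    else:
        haps = list(haplotypes)
    rng = component_rng(seed, "reads")
    names, offsets, template = _concat_template(haps)
    total_len = len(template)
    code = _ENC[template]
    rl = spec.read_len
    if rl > min(len(s) for h in haps for s in h.values()):
        raise ValueError("read_len exceeds template length")
    bases_per_pair = 2 * rl if spec.paired else rl
    n_total = int(round(spec.coverage * (total_len / len(haps)) / bases_per_pair))
    n_dup = int(round(spec.duplicate_frac * n_total))
    n_unm = int(round(spec.unmated_frac * (n_total - n_dup)))
    n_base = n_total - n_dup - n_unm

    comp_end = np.array([offsets[i] + (offsets[i + 1] - offsets[i]) if i + 1 < len(offsets)
                         else total_len for i in range(len(offsets))])

    def sample_pairs(n, insert_mean, insert_sd, orientation):
        ins = np.maximum(
            rng.normal(insert_mean, insert_sd, n).astype(np.int64), rl + 2
        ) if spec.paired else np.full(n, rl, dtype=np.int64)
        start = (rng.random(n) * (total_len - ins)).astype(np.int64)
        # resample fragments that would straddle a scaffold boundary
        for _ in range(64):
            comp = np.searchsorted(offsets, start, side="right") - 1
            bad = start + ins > comp_end[comp]
            if not bad.any():
                break
            start[bad] = (rng.random(int(bad.sum())) * (total_len - ins[bad])).astype(np.int64)
        idx1 = start[:, None] + np.arange(rl)
        m1 = code[idx1]
        if spec.paired:
            idx2 = (start + ins - rl)[:, None] + np.arange(rl)
            m2 = _RC[code[idx2]][:, ::-1]
        else:
            m2 = None
        if orientation == "RF" and spec.paired:
            m1, m2 = _RC[m1][:, ::-1], _RC[m2][:, ::-1]
        return m1, m2, start, ins

    m1, m2, start, ins = sample_pairs(n_base, spec.insert_mean, spec.insert_sd,
                                      spec.orientation)
    kind = ["base"] * n_base
    if n_unm:
        if short_insert_pool is not None:
            pick = rng.integers(0, short_insert_pool.n_pairs, n_unm)
            u1 = _ENC[short_insert_pool.r1[pick][:, :rl]]
            u2 = _ENC[short_insert_pool.r2[pick][:, :rl]]
            us = np.full(n_unm, -1, dtype=np.int64)
            ui = np.full(n_unm, -1, dtype=np.int64)
        else:
            u1, u2, us, ui = sample_pairs(n_unm, spec.unmated_insert_mean,
                                          spec.unmated_insert_sd, "FR")
        m1 = np.vstack([m1, u1])
        m2 = np.vstack([m2, u2]) if m2 is not None else None
        start = np.concatenate([start, us])
        ins = np.concatenate([ins, ui])
        kind += ["unmated"] * n_unm
    # sequencing errors on originals, then exact duplicates
    if spec.error_rate > 0:
        for m in (m1, m2) if m2 is not None else (m1,):
            mask = rng.random(m.shape) < spec.error_rate
            shift = rng.integers(1, 4, m.shape).astype(np.uint8)
            m[mask] = (m[mask] + shift[mask]) % 4
    if n_dup:
        pick = rng.integers(0, m1.shape[0], n_dup)
        m1 = np.vstack([m1, m1[pick]])
        if m2 is not None:
            m2 = np.vstack([m2, m2[pick]])
        start = np.concatenate([start, start[pick]])
        ins = np.concatenate([ins, ins[pick]])
        kind += ["duplicate"] * n_dup
    q = np.full(m1.shape, spec.quality + 33, dtype=np.uint8)
    q2 = np.full(m1.shape, spec.quality + 33, dtype=np.uint8) if m2 is not None else None
    if spec.lowq_tail_frac > 0:
        for qm in (q, q2) if q2 is not None else (q,):
            sel = rng.random(qm.shape[0]) < spec.lowq_tail_frac
            qm[sel, rl - spec.lowq_tail_len :] = spec.lowq_quality + 33
    # truth: map concatenated start back to (haplotype, scaffold, pos)
    comp = np.searchsorted(offsets, start, side="right") - 1
    comp[start < 0] = -1
    truth = pd.DataFrame(
        {
            "pair": np.arange(m1.shape[0]),
            "haplotype": [names[c][0] if c >= 0 else -1 for c in comp],
            "scaffold": [names[c][1] if c >= 0 else "" for c in comp],
            "pos": np.where(start >= 0, start - np.where(comp >= 0, offsets[np.maximum(comp, 0)], 0), -1),
            "insert_size": ins,
            "kind": kind,
        }
    )
    return ReadSet(
        r1=_DEC[m1],
        r2=_DEC[m2] if m2 is not None else None,
        q1=q,
        q2=q2,
        truth=truth,
        orientation=spec.orientation,
        name=name,
    )


# ---------------------------------------------------------------------------
# Assembler-like transcript sets
# ---------------------------------------------------------------------------

def simulate_assembled_transcripts(
    g: GenomeModel,
    seed: int,
    frag_prob: float = 0.3,
    chimera_rate: float = 0.0,
    overlap: int = 60,
    assemblies: tuple[str, ...] = ("asmA", "asmB"),
    chimera_in: tuple[str, ...] = ("asmB",),
) -> tuple[dict[str, list[NucSequence]], pd.DataFrame]:
    """Emulate two assemblers' transcript sets with a per-transcript truth table.

    Each emitted transcript is a spliced gene sequence, possibly split into two
    fragments sharing an exact ``overlap``-nt terminal overlap, emitted on a
    random strand.  With probability ``chimera_rate`` (in the assemblies listed
    in ``chimera_in``) a head-to-head chimera of two genes is emitted instead.
    """
    if not (0 <= frag_prob <= 1) or not (0 <= chimera_rate < 1):
        raise ValueError("rates must be within [0, 1)")
    rng = component_rng(seed, "transcripts")
    sets: dict[str, list[NucSequence]] = {}
    rows = []
    for label in assemblies:
        out: list[NucSequence] = []
        counter = 0
        for gene in g.genes:
            t = g.transcript_seq(gene)
            if label in chimera_in and rng.random() < chimera_rate:
                # pick a partner of comparable length so neither constituent
                # dominates the merged sequence (head-to-head overlap artifacts
                # merge transcripts of neighbouring, similarly-sized genes)
                other = g.genes[int(rng.integers(0, len(g.genes)))]
                t2 = g.transcript_seq(other)
                for _ in range(20):
                    if max(len(t), len(t2)) / (len(t) + len(t2)) <= 0.65:
                        break
                    other = g.genes[int(rng.integers(0, len(g.genes)))]
                    t2 = g.transcript_seq(other)
                seq = t + revcomp(t2)
                counter += 1
                tid = f"{label}.{counter:05d}"
                out.append(NucSequence(tid, seq))
                rows.append((tid, label, gene.id, other.id, None, 0, len(seq), True))
                continue
            fragments: list[tuple[str, int, int]]
            if rng.random() < frag_prob and len(t) >= 2 * overlap + 60:
                lo = max(30, overlap)
                cut = int(rng.integers(lo, len(t) - overlap - 30))
                fragments = [(t[: cut + overlap], 0, cut + overlap),
                             (t[cut:], cut, len(t))]
            else:
                fragments = [(t, 0, len(t))]
            for fseq, fs, fe in fragments:
                counter += 1
                tid = f"{label}.{counter:05d}"
                emit_fwd = rng.random() < 0.5
                out.append(NucSequence(tid, fseq if emit_fwd else revcomp(fseq)))
                rows.append((tid, label, gene.id, None,
                             "+" if emit_fwd else "-", fs, fe, False))
        sets[label] = out
    truth = pd.DataFrame(
        rows,
        columns=["transcript_id", "assembly", "gene_id", "gene2_id",
                 "emitted_strand", "frag_start", "frag_end", "is_chimera"],
    )
    return sets, truth


# ---------------------------------------------------------------------------
# Expression counts
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSpec:
    """Two-strain, multi-tissue negative-binomial expression model.

    Trichome genes are flower-predominant (mid-flower mean ``flower_boost``
    times their other-tissue mean) and additionally scaled by
    ``trichome_enrichment`` in strain A's mid-flower sample, emulating a
    trichome-density difference between strains.  Pathway genes (a subset of
    the trichome set) carry further per-gene strain-A fold-changes.
    """

    tissues: tuple[str, ...] = ("mid_flower", "root", "shoot", "stem")
    strains: tuple[str, str] = ("strainA", "strainB")
    gene_ids: Sequence[str] | None = None
    base_abundance: pd.Series | None = None
    trichome_gene_ids: Sequence[str] = ()
    trichome_enrichment: float = 4.0
    pathway_fold: dict[str, float] = field(default_factory=dict)
    flower_boost: float = 12.0
    trichome_base: float = 8.0
    pathway_base: float = 2.0
    dispersion: float = 0.1
    library_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.trichome_enrichment <= 0:
            raise ValueError("trichome_enrichment must be > 0")
        if any(f <= 0 for f in self.pathway_fold.values()):
            raise ValueError("fold-changes must be > 0")


def simulate_expression_counts(
    e: ExpressionSpec, seed: int, genome: GenomeModel | None = None
) -> dict[str, pd.DataFrame]:
    """Counts tables (genes x tissues) per strain, deterministic per seed."""
    rng = component_rng(seed, "expression")
    if e.gene_ids is not None:
        gene_ids = list(e.gene_ids)
    elif genome is not None:
        gene_ids = [g.id for g in genome.genes]
    else:
        raise ValueError("provide gene_ids or a genome")
    n = len(gene_ids)
    if e.base_abundance is not None:
        base = e.base_abundance.reindex(gene_ids).to_numpy(dtype=float)
    else:
        # heavy-tailed bulk so that boosted trichome genes stay a modest
        # fraction of the library (library composition near-neutral)
        base = np.exp(rng.normal(3.0, 2.0, n))
    tri = np.isin(gene_ids, list(e.trichome_gene_ids))
    if e.base_abundance is None:
        base[tri] = e.trichome_base
        for gid in e.pathway_fold:
            base[gene_ids.index(gid)] = e.pathway_base
    means = {}
    for strain in e.strains:
        mat = np.tile(base[:, None], (1, len(e.tissues))) * e.library_scale
        fi = e.tissues.index("mid_flower")
        mat[tri, fi] *= e.flower_boost
        if strain == e.strains[0]:
            mat[tri, fi] *= e.trichome_enrichment
            for gid, fold in e.pathway_fold.items():
                gi = gene_ids.index(gid)
                mat[gi, fi] *= fold
        means[strain] = mat
    out = {}
    for strain in e.strains:
        mu = means[strain]
        if e.dispersion > 0:
            r = 1.0 / e.dispersion
            p = r / (r + mu)
            counts = rng.negative_binomial(r, p)
        else:
            counts = rng.poisson(mu)
        out[strain] = pd.DataFrame(counts, index=gene_ids, columns=list(e.tissues))
    return out
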