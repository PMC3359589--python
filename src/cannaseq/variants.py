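"""Genomic-read strain comparison: read-depth copy number, multi-sample SNV
calling and filtering, heterozygosity and pairwise SNV rates, composite-
likelihood (TN93) distances and neighbor-joining strain trees.

The variant caller is intentionally minimal: per site and per strain it
scores the three diploid genotypes {RR, RA, AA} under a binomial
read-sampling model with a symmetric sequencing-error rate, and emits a
Phred-scaled site quality ``-10 log10 P(all strains homozygous-reference)``
under uniform genotype priors.  The published analysis hinges on the
*filters* (site quality >= 30, >= 5 uniquely-mapped reads per strain, <= 150
reads total, with the same depth conditions defining the callable region used
as the rate denominator); the caller is the smallest model supporting a
meaningful Phred scale for those filters.

Short-read alignment is delegated to minimap2 (parsed with pysam); a read
counts as uniquely mapped when the aligner assigns a non-zero mapping
quality (best alignment strictly better than the second best).
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import xlogy

from .seqcore import NucSequence, revcomp

_CODE = {b: i for i, b in enumerate("ACGT")}
_BASE = "ACGT"

# ---------------------------------------------------------------------------
# Alignment + pileup
# ---------------------------------------------------------------------------


def run_minimap2(
    reference_fasta: str | Path,
    fastq: str | Path,
    out_sam: str | Path,
    preset: str = "sr",
    threads: int = 1,
) -> None:
    """Align short reads with minimap2 (SAM output, single-threaded for
    determinism)."""
    exe = shutil.which("minimap2")
    if exe is None:
        raise RuntimeError("minimap2 not found on PATH")
    with open(out_sam, "w") as out:
        subprocess.run(
            [exe, "-ax", preset, "-t", str(threads), "--sam-hit-only",
             str(reference_fasta), str(fastq)],
            stdout=out,
            stderr=subprocess.DEVNULL,
            check=True,
        )


@dataclass
class StrainPileup:
    """Per-scaffold base counts and unique-read depth for one strain."""

    strain: str
    counts: dict[str, np.ndarray]  # scaffold -> (4, L) int32
    depth: dict[str, np.ndarray]  # scaffold -> (L,) int32


def pileup_from_sam(
    sam_path: str | Path, strain: str, min_mapq: int = 1
) -> StrainPileup:
    """Accumulate base counts over uniquely-mapped reads (mapq >= min_mapq)."""
    import pysam

    af = pysam.AlignmentFile(str(sam_path), "r")
    names = list(af.references)
    lengths = list(af.lengths)
    offsets = {}
    off = 0
    for name, length in zip(names, lengths):
        offsets[name] = off
        off += length
    total = off
    flat = np.zeros(4 * total, dtype=np.int32)  # base-major flattened counts
    code_tab = np.full(256, 4, dtype=np.int64)
    for b, c in _CODE.items():
        code_tab[ord(b)] = c
    pend_seq: list[bytes] = []
    pend_pos: list[tuple[int, int]] = []  # (global start, length) per segment

    def flush():
        if not pend_seq:
            return
        codes = code_tab[np.frombuffer(b"".join(pend_seq), dtype=np.uint8)]
        pos = np.concatenate(
            [np.arange(s, s + ln, dtype=np.int64) for s, ln in pend_pos]
        )
        ok = codes < 4
        np.add.at(flat, codes[ok] * total + pos[ok], 1)
        pend_seq.clear()
        pend_pos.clear()

    pending = 0
    for read in af.fetch(until_eof=True):
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if read.mapping_quality < min_mapq:
            continue
        seq = read.query_sequence
        if seq is None:
            continue
        base_off = offsets[read.reference_name]
        qpos = 0
        tpos = read.reference_start
        for op, ln in read.cigartuples:
            if op in (0, 7, 8):  # M/=/X
                pend_seq.append(seq[qpos : qpos + ln].encode())
                pend_pos.append((base_off + tpos, ln))
                pending += ln
                qpos += ln
                tpos += ln
            elif op == 1 or op == 4:  # I, S
                qpos += ln
            elif op in (2, 3):  # D, N
                tpos += ln
        if pending > 2_000_000:
            flush()
            pending = 0
    flush()
    af.close()
    counts = {}
    for name, length in zip(names, lengths):
        o = offsets[name]
        counts[name] = np.stack(
            [flat[b * total + o : b * total + o + length] for b in range(4)]
        )
    depth = {name: mat.sum(axis=0).astype(np.int32) for name, mat in counts.items()}
    return StrainPileup(strain, counts, depth)


# ---------------------------------------------------------------------------
# Multi-sample genotype calling
# ---------------------------------------------------------------------------

@dataclass
class CallSet:
    """Variant calls plus the per-strain depth context needed for filters."""

    strains: list[str]
    calls: pd.DataFrame  # scaffold,pos,ref,alt,qual + per-strain gt/dp/ad columns
    pileups: dict[str, StrainPileup]
    reference: dict[str, str]


def _genotype_loglik(ref_n: np.ndarray, alt_n: np.ndarray, e: float) -> np.ndarray:
    """Log-likelihoods (3, n) of RR, RA, AA from ref/alt read counts.

    Error model: a read reports a specific wrong base with probability e/3
    and the true base with probability 1-e; under RA each chromosome is
    sampled with probability 1/2.
    """
    p_alt = np.array([e / 3.0, 0.5 * (1 - e) + 0.5 * (e / 3.0), 1.0 - e])
    p_ref = np.array([1.0 - e, 0.5 * (1 - e) + 0.5 * (e / 3.0), e / 3.0])
    out = np.empty((3, len(ref_n)))
    for g in range(3):
        out[g] = xlogy(alt_n, p_alt[g]) + xlogy(ref_n, p_ref[g])
    return out


def pileup_and_call(
    pileups: Sequence[StrainPileup],
    reference: dict[str, str],
    error_rate: float = 0.01,
) -> CallSet:
    """Joint genotype calling across strains at every site with alternate
    evidence.

    Per strain the genotype posterior is the normalized likelihood over
    {RR, RA, AA} (uniform priors); the site quality is
    ``-10 log10 prod_s P(RR | data_s)``, and a call is emitted iff the most
    likely joint configuration contains a non-RR genotype.  Sites with zero
    depth in every strain are skipped; a strain with zero reads at a called
    site gets a missing genotype.
    """
    if len(pileups) < 2:
        raise ValueError("multi-sample calling needs at least two strains")
    strains = [p.strain for p in pileups]
    rows: dict[str, list] = {
        "scaffold": [], "pos": [], "ref": [], "alt": [], "qual": [],
    }
    for s in strains:
        rows[f"gt_{s}"] = []
        rows[f"dp_{s}"] = []
        rows[f"ad_{s}"] = []
    for scaffold, refseq in reference.items():
        L = len(refseq)
        ref_codes = np.frombuffer(refseq.encode(), dtype=np.uint8)
        ref_idx = np.full(L, 4, dtype=np.int64)
        for b, c in _CODE.items():
            ref_idx[ref_codes == ord(b)] = c
        stack = np.stack([p.counts[scaffold] for p in pileups])  # (S,4,L)
        pooled = stack.sum(axis=0)
        pos_all = np.arange(L)
        valid = ref_idx < 4
        pooled_nonref = pooled.copy()
        pooled_nonref[ref_idx[valid], pos_all[valid]] = 0
        alt_idx = pooled_nonref.argmax(axis=0)
        has_alt = (pooled_nonref.max(axis=0) > 0) & valid
        cand = np.where(has_alt)[0]
        if len(cand) == 0:
            continue
        S = len(strains)
        ref_n = stack[:, ref_idx[cand], cand]  # (S, n)
        alt_n = stack[:, alt_idx[cand], cand]
        gls = np.stack(
            [_genotype_loglik(ref_n[s], alt_n[s], error_rate) for s in range(S)]
        )  # (S, 3, n)
        # per-strain posterior over genotypes
        mx = gls.max(axis=1, keepdims=True)
        post = np.exp(gls - mx)
        post /= post.sum(axis=1, keepdims=True)
        ml = gls.argmax(axis=1)  # (S, n)
        nonref = (ml != 0) & ((ref_n + alt_n) > 0)
        emit = nonref.any(axis=0)
        log10_rr = np.log10(np.clip(post[:, 0, :], 1e-300, 1.0))
        qual = -10.0 * log10_rr.sum(axis=0)
        gt_names = np.array(["RR", "RA", "AA"])
        for j in np.where(emit)[0]:
            p = int(cand[j])
            rows["scaffold"].append(scaffold)
            rows["pos"].append(p)
            rows["ref"].append(_BASE[ref_idx[p]])
            rows["alt"].append(_BASE[int(alt_idx[p])])
            rows["qual"].append(float(qual[j]))
            for s, name in enumerate(strains):
                n_here = int(ref_n[s, j] + alt_n[s, j])
                dp = int(pileups[s].depth[scaffold][p])
                if n_here == 0:
                    rows[f"gt_{name}"].append(".")
                else:
                    rows[f"gt_{name}"].append(str(gt_names[ml[s, j]]))
                rows[f"dp_{name}"].append(dp)
                rows[f"ad_{name}"].append((int(ref_n[s, j]), int(alt_n[s, j])))
    calls = pd.DataFrame(rows)
    return CallSet(strains, calls, {p.strain: p for p in pileups}, dict(reference))


def filter_variants(
    callset: CallSet,
    min_quality: float = 30.0,
    min_depth_per_strain: int = 5,
    max_total_depth: int = 150,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Apply the published site filters and build the callable-region mask.

    A site passes iff quality >= ``min_quality``, every strain has unique
    depth >= ``min_depth_per_strain`` and summed depth <= ``max_total_depth``.
    The mask marks *all* positions passing the depth conditions (variant or
    not): the denominator for heterozygosity and pairwise SNV rates.
    """
    mask: dict[str, np.ndarray] = {}
    for scaffold, refseq in callset.reference.items():
        depths = np.stack(
            [callset.pileups[s].depth[scaffold] for s in callset.strains]
        )
        mask[scaffold] = (depths >= min_depth_per_strain).all(axis=0) & (
            depths.sum(axis=0) <= max_total_depth
        )
    df = callset.calls
    if df.empty:
        return df, mask
    keep = df.qual >= min_quality
    for s in callset.strains:
        keep &= df[f"dp_{s}"] >= min_depth_per_strain
    keep &= sum(df[f"dp_{s}"] for s in callset.strains) <= max_total_depth
    return df[keep].reset_index(drop=True), mask


def callable_bases(mask: dict[str, np.ndarray]) -> int:
    return int(sum(m.sum() for m in mask.values()))


def heterozygosity_rate(
    filtered: pd.DataFrame, mask: dict[str, np.ndarray], strain: str
) -> float:
    """Percent of callable positions where ``strain`` is heterozygous."""
    denom = callable_bases(mask)
    if denom == 0:
        raise ValueError("empty callable mask")
    het = int((filtered[f"gt_{strain}"] == "RA").sum())
    return 100.0 * het / denom


def pairwise_snv_rate(
    filtered: pd.DataFrame, mask: dict[str, np.ndarray], strain_a: str, strain_b: str
) -> float:
    """Percent of callable positions where the two strains' most likely
    genotypes differ (in at least one allele)."""
    denom = callable_bases(mask)
    if denom == 0:
        raise ValueError("empty callable mask")
    ga, gb = filtered[f"gt_{strain_a}"], filtered[f"gt_{strain_b}"]
    informative = (ga != ".") & (gb != ".")
    diff = int(((ga != gb) & informative).sum())
    return 100.0 * diff / denom


def concatenate_variant_sequences(
    filtered: pd.DataFrame, strains: Sequence[str]
) -> dict[str, str]:
    """Per-strain pseudo-sequences over the filtered SNV sites, ordered by
    (scaffold, pos): homozygous genotypes contribute their base, heterozygous
    sites the majority-supported allele (ties to the reference)."""
    df = filtered.sort_values(["scaffold", "pos"], kind="mergesort")
    out = {s: [] for s in strains}
    for _, row in df.iterrows():
        for s in strains:
            gt = row[f"gt_{s}"]
            if gt == "RR" or gt == ".":
                out[s].append(row["ref"])
            elif gt == "AA":
                out[s].append(row["alt"])
            else:
                ref_n, alt_n = row[f"ad_{s}"]
                out[s].append(row["alt"] if alt_n > ref_n else row["ref"])
    return {s: "".join(v) for s, v in out.items()}


def write_vcf(
    filtered: pd.DataFrame, strains: Sequence[str], path: str | Path
) -> None:
    """Minimal VCF 4.2 with per-strain GT:DP."""
    gt_map = {"RR": "0/0", "RA": "0/1", "AA": "1/1", ".": "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(strains)
            + "\n"
        )
        for _, row in filtered.sort_values(["scaffold", "pos"]).iterrows():
            cols = [
                row["scaffold"], str(row["pos"] + 1), ".", row["ref"], row["alt"],
                f"{row['qual']:.1f}", "PASS", ".", "GT:DP",
            ]
            for s in strains:
                cols.append(f"{gt_map[row[f'gt_{s}']]}:{row[f'dp_{s}']}")
            fh.write("\t".join(cols) + "\n")


def write_mask_bed(mask: dict[str, np.ndarray], path: str | Path) -> None:
    """Callable region mask as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for scaffold in sorted(mask):
            m = mask[scaffold]
            diff = np.diff(m.astype(np.int8), prepend=0, append=0)
            starts = np.where(diff == 1)[0]
            ends = np.where(diff == -1)[0]
            for s, e in zip(starts, ends):
                fh.write(f"{scaffold}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# Median read depth copy-number proxy
# ---------------------------------------------------------------------------

@dataclass
class DepthProfile:
    transcript_id: str
    strain: str
    depth: np.ndarray | None
    mrd: float | None


def mrd_per_transcript(
    reads: Iterable[str],
    transcriptome: Sequence[NucSequence],
    strain: str = "",
    trim_to: int = 32,
) -> dict[str, DepthProfile]:
    """Median per-base depth of uniquely-placed, length-trimmed genomic reads
    over each transcript — the copy-number proxy.

    Reads are truncated to ``trim_to`` nt (so they can map close to exon
    junctions) and placed by exact ``trim_to``-mer lookup against the
    transcriptome (both orientations); a read counts only when its sequence
    occurs at exactly one transcriptome location.  Transcripts shorter than
    ``trim_to`` are flagged with ``mrd=None``.
    """
    index: dict[str, tuple[int, int] | None] = {}
    for ti, t in enumerate(transcriptome):
        for pos in range(len(t) - trim_to + 1):
            kmer = t.seq[pos : pos + trim_to]
            index[kmer] = None if kmer in index else (ti, pos)
    diffs = [np.zeros(len(t) + 1, dtype=np.int64) for t in transcriptome]
    for read in reads:
        if len(read) < trim_to:
            continue
        probe = read[:trim_to]
        hit = index.get(probe)
        rc_hit = index.get(revcomp(probe))
        if hit is not None and rc_hit is not None and hit != rc_hit:
            continue  # ambiguous between orientations
        placement = hit if hit is not None else rc_hit
        if placement is None:
            continue
        ti, pos = placement
        diffs[ti][pos] += 1
        diffs[ti][pos + trim_to] -= 1
    out = {}
    for ti, t in enumerate(transcriptome):
        if len(t) < trim_to:
            out[t.id] = DepthProfile(t.id, strain, None, None)
            continue
        depth = np.cumsum(diffs[ti][:-1])
        out[t.id] = DepthProfile(t.id, strain, depth, float(np.median(depth)))
    return out


# ---------------------------------------------------------------------------
# Composite-likelihood (TN93) distance
# ---------------------------------------------------------------------------

def _pair_table(a: str, b: str) -> np.ndarray:
    """4x4 nucleotide pair-count table between two equal-length sequences."""
    if len(a) != len(b) or len(a) == 0:
        raise ValueError("sequences must be equal-length and non-empty")
    ca = np.frombuffer(a.encode(), dtype=np.uint8)
    cb = np.frombuffer(b.encode(), dtype=np.uint8)
    table = np.zeros((4, 4), dtype=np.int64)
    ia = np.full(len(ca), 4)
    ib = np.full(len(cb), 4)
    for base, c in _CODE.items():
        ia[ca == ord(base)] = c
        ib[cb == ord(base)] = c
    ok = (ia < 4) & (ib < 4)
    np.add.at(table, (ia[ok], ib[ok]), 1)
    return table


def _tn93_expected(u: np.ndarray, pi: np.ndarray) -> tuple[float, float, float]:
    """(P1, P2, Q) expected proportions under TN93 for u = (a1 t, a2 t, b t)."""
    pa, pc, pg, pt = pi
    pr, py = pa + pg, pc + pt
    u1, u2, u3 = u
    x1 = np.exp(-2 * (u1 * pr + u3 * py))
    x2 = np.exp(-2 * (u2 * py + u3 * pr))
    x3 = np.exp(-2 * u3)
    p1 = 2 * pa * pg / pr * (pr + py * x3 - x1) if pr > 0 else 0.0
    p2 = 2 * pt * pc / py * (py + pr * x3 - x2) if py > 0 else 0.0
    q = 2 * pr * py * (1 - x3)
    return float(p1), float(p2), float(q)


def mcl_distance(seq_a: str, seq_b: str, tol: float = 1e-9) -> float:
    """Pairwise distance maximizing the composite likelihood of the observed
    nucleotide pair counts under the Tamura-Nei (TN93) substitution model.

    The multinomial likelihood of (purine transitions, pyrimidine
    transitions, transversions, identities) is maximized numerically over the
    three rate-time products; the distance is the implied expected number of
    substitutions per site.  Saturated pairs raise ``ValueError``.
    """
    table = _pair_table(seq_a, seq_b)
    n = table.sum()
    pi = (table.sum(axis=0) + table.sum(axis=1)) / (2.0 * n)
    pa, pc, pg, pt = pi
    pr, py = pa + pg, pc + pt
    p1_obs = (table[0, 2] + table[2, 0]) / n
    p2_obs = (table[1, 3] + table[3, 1]) / n
    q_obs = (
        table[0, 1] + table[1, 0] + table[0, 3] + table[3, 0]
        + table[2, 1] + table[1, 2] + table[2, 3] + table[3, 2]
    ) / n
    if p1_obs + p2_obs + q_obs == 0:
        return 0.0
    # saturation guards (the closed-form log arguments must stay positive)
    if 2 * pr * py > 0 and 1 - q_obs / (2 * pr * py) <= 0:
        raise ValueError("distance undefined (saturation)")
    if pa * pg > 0 and pr > 0:
        if 1 - p1_obs / (2 * pa * pg / pr) - q_obs / (2 * pr) <= 0:
            raise ValueError("distance undefined (saturation)")
    if pt * pc > 0 and py > 0:
        if 1 - p2_obs / (2 * pt * pc / py) - q_obs / (2 * py) <= 0:
            raise ValueError("distance undefined (saturation)")
    obs = np.array([p1_obs, p2_obs, q_obs, 1 - p1_obs - p2_obs - q_obs]) * n

    def nll(u):
        p1, p2, q = _tn93_expected(u, pi)
        probs = np.clip(np.array([p1, p2, q, 1 - p1 - p2 - q]), 1e-300, 1.0)
        return -float(np.dot(obs, np.log(probs)))

    p_dist = p1_obs + p2_obs + q_obs
    x0 = np.array([max(p1_obs, 1e-4), max(p2_obs, 1e-4), max(q_obs / 2, 1e-4)]) / max(
        1e-3, 1 - 4 * p_dist / 3
    )
    res = minimize(
        nll,
        x0,
        method="L-BFGS-B",
        bounds=[(0.0, 60.0)] * 3,
        options={"ftol": tol * 1e-6, "gtol": 1e-14, "maxiter": 5000},
    )
    res2 = minimize(
        nll,
        res.x,
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-13, "maxiter": 5000},
    )
    if res2.fun <= res.fun:
        res = res2
    u1, u2, u3 = res.x
    if max(res.x) >= 59.0:
        raise ValueError("distance undefined (saturation)")
    # u holds rate x per-lineage time; the pairwise distance spans both lineages
    d = 2.0 * (2 * pa * pg * u1 + 2 * pt * pc * u2 + 2 * pr * py * u3)
    return float(d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def distance_matrix(pseudo_seqs: dict[str, str]) -> pd.DataFrame:
    labels = list(pseudo_seqs)
    d = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            dist = mcl_distance(pseudo_seqs[a], pseudo_seqs[b])
            d.loc[a, b] = d.loc[b, a] = dist
    return d


def neighbor_joining(dm: pd.DataFrame) -> tuple[str, list[str]]:
    """Saitou-Nei neighbor joining with deterministic lowest-index
    tie-breaking; negative branch lengths are clamped to zero with the
    deficit transferred to the sibling edge (logged).

    Returns (newick string with an unrooted trifurcating root, clamp log).
    """
    labels = list(dm.index)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    D = dm.to_numpy(dtype=float).copy()
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    nodes = [f"{l}" for l in labels]
    log: list[str] = []
    active = list(range(len(labels)))
    Dd = {(i, j): D[i, j] for i in range(len(labels)) for j in range(len(labels))}
    next_id = len(labels)
    newick = {i: lab for i, lab in enumerate(nodes)}
    while len(active) > 3:
        n = len(active)
        r = {i: sum(Dd[(i, k)] for k in active if k != i) for i in active}
        best = None
        for ai in range(n):
            for bj in range(ai + 1, n):
                i, j = active[ai], active[bj]
                q = (n - 2) * Dd[(i, j)] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * Dd[(i, j)] + (r[i] - r[j]) / (2 * (len(active) - 2))
        lj = Dd[(i, j)] - li
        if li < 0:
            lj += li
            log.append(f"clamped negative branch to node {i} ({li:.6g})")
            li = 0.0
        if lj < 0:
            li += lj
            log.append(f"clamped negative branch to node {j} ({lj:.6g})")
            lj = 0.0
        u = next_id
        next_id += 1
        newick[u] = f"({newick[i]}:{li:.10g},{newick[j]}:{lj:.10g})"
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (Dd[(i, k)] + Dd[(j, k)] - Dd[(i, j)])
            Dd[(u, k)] = Dd[(k, u)] = duk
        Dd[(u, u)] = 0.0
        active = [k for k in active if k not in (i, j)] + [u]
    i, j, k = active
    li = 0.5 * (Dd[(i, j)] + Dd[(i, k)] - Dd[(j, k)])
    lj = 0.5 * (Dd[(i, j)] + Dd[(j, k)] - Dd[(i, k)])
    lk = 0.5 * (Dd[(i, k)] + Dd[(j, k)] - Dd[(i, j)])
    for val in (li, lj, lk):
        if val < 0:
            log.append(f"clamped negative terminal branch ({val:.6g})")
    li, lj, lk = max(li, 0.0), max(lj, 0.0), max(lk, 0.0)
    tree = f"({newick[i]}:{li:.10g},{newick[j]}:{lj:.10g},{newick[k]}:{lk:.10g});"
    return tree, log
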