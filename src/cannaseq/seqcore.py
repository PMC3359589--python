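"""Core sequence types and primitives shared by every analysis stage.

This module provides the in-memory sequence container, an open-reading-frame
finder, a light-weight k-mer-seeded local aligner (plain and intron-aware),
identity bookkeeping on gapless block chains, and assembly summary statistics
(N50 and friends).  The aligner is deliberately small: it is meant for
desk-scale curation tasks (transcript clustering, homolog screens, scaffold
redundancy) where determinism and an explicit identity definition matter more
than raw throughput.  Any aligner producing :class:`AlignmentBlockChain`
objects can be substituted upstream.

Conventions
-----------
* All coordinates are 0-based, half-open.
* Identity is ``matches / (matches + mismatches + indels)`` where ``indels``
  counts gap columns; an ``N`` base never counts as a match.
* For minus-strand chains, query coordinates refer to the reverse-complemented
  query sequence (so block coordinates are strictly increasing on both axes
  regardless of strand).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# default local-alignment scoring (integers keep the traceback exact)
MATCH_SCORE = 2
MISMATCH_SCORE = -3
GAP_SCORE = -5


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class NucSequence:
    """A named nucleotide sequence over the alphabet {A, C, G, T, N}."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        if not set(self.seq) <= DNA_ALPHABET:
            bad = sorted(set(self.seq) - DNA_ALPHABET)
            raise ValueError(f"sequence {self.id!r} contains non-DNA symbols {bad}")

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "NucSequence":
        return NucSequence(self.id, revcomp(self.seq), self.description)


@dataclass(frozen=True)
class OrfHit:
    """A maximal open reading frame on either strand of a transcript.

    ``start``/``end`` are forward-strand coordinates of the transcript; the
    span includes the terminal stop codon when one is present.  ``complete5``
    means the ORF begins with ATG, ``complete3`` that it ends at a stop codon;
    boundary-open ends are allowed because assembled transcripts are often
    partial.
    """

    strand: str
    frame: int
    start: int
    end: int
    length_nt: int
    complete5: bool
    complete3: bool


@dataclass
class AlignmentBlockChain:
    """An ordered chain of gapless aligned blocks between query and target.

    Blocks are ``(q_start, q_end, t_start, t_end)`` tuples, non-overlapping and
    strictly increasing on both axes; within a block the two spans have equal
    length (mismatches are allowed inside blocks, gaps are not).
    """

    query_id: str
    target_id: str
    strand: str
    blocks: list[tuple[int, int, int, int]]
    matches: int
    mismatches: int
    indels: int
    score: int = 0

    @property
    def identity(self) -> float:
        denom = self.matches + self.mismatches + self.indels
        return self.matches / denom if denom else 0.0

    @property
    def aligned_query_bases(self) -> int:
        return sum(qe - qs for qs, qe, _, _ in self.blocks)

    @property
    def q_span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]

    @property
    def t_span(self) -> tuple[int, int]:
        return self.blocks[0][2], self.blocks[-1][3]

    def query_interval_forward(self, query_length: int) -> tuple[int, int]:
        """Aligned query span in forward-strand coordinates of the query."""
        s, e = self.q_span
        if self.strand == "+":
            return s, e
        return query_length - e, query_length - s

    def target_gaps(self, min_gap: int = 1) -> list[tuple[int, int]]:
        """Target-side gaps between consecutive blocks (candidate introns)."""
        gaps = []
        for (q0, q1, t0, t1), (q2, q3, t2, t3) in zip(self.blocks, self.blocks[1:]):
            if t2 - t1 >= min_gap:
                gaps.append((t1, t2))
        return gaps


@dataclass(frozen=True)
class AssemblyStats:
    n_sequences: int
    total_bases_with_gaps: int
    total_bases_without_gaps: int
    n50: int
    max_length: int


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[NucSequence]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(NucSequence(rec.id, str(rec.seq), rec.description))
    return records


def write_fasta(seqs: Iterable[NucSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.seq), id=s.id, description=s.description) for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


def chains_to_tsv(chains: Iterable[AlignmentBlockChain], path: str | Path) -> None:
    """Serialize chains to a PSL-like TSV (one row per chain)."""
    with open(path, "w") as fh:
        fh.write(
            "query_id\ttarget_id\tstrand\tmatches\tmismatches\tindels\t"
            "identity\tscore\tblocks\n"
        )
        for c in chains:
            blocks = ";".join(
                ",".join(map(str, b)) for b in c.blocks
            )
            fh.write(
                f"{c.query_id}\t{c.target_id}\t{c.strand}\t{c.matches}\t"
                f"{c.mismatches}\t{c.indels}\t{c.identity:.6f}\t{c.score}\t{blocks}\n"
            )


# ---------------------------------------------------------------------------
# ORF discovery
# ---------------------------------------------------------------------------

def _orfs_one_strand(seq: str, strand: str, length: int) -> list[OrfHit]:
    hits: list[OrfHit] = []
    n = len(seq)
    for frame in range(3):
        # stop codon codon-start positions in this frame
        stops = [i for i in range(frame, n - 2, 3) if seq[i : i + 3] in STOP_CODONS]
        seg_start = frame
        at_boundary = True
        for stop in [*stops, None]:
            if stop is None:
                seg_end = frame + ((n - frame) // 3) * 3
                complete3 = False
            else:
                seg_end = stop + 3
                complete3 = True
            start = None
            if at_boundary:
                start = seg_start
            else:
                coding_end = seg_end - 3 if complete3 else seg_end
                for i in range(seg_start, coding_end - 2, 3):
                    if seq[i : i + 3] == "ATG":
                        start = i
                        break
            if start is not None:
                length_nt = seg_end - start
                coding_nt = length_nt - 3 if complete3 else length_nt
                if coding_nt >= 3:
                    complete5 = seq[start : start + 3] == "ATG"
                    if strand == "+":
                        fwd_start, fwd_end = start, seg_end
                    else:
                        fwd_start, fwd_end = length - seg_end, length - start
                    hits.append(
                        OrfHit(strand, frame, fwd_start, fwd_end, length_nt,
                               complete5, complete3)
                    )
            if stop is not None:
                seg_start = stop + 3
                at_boundary = False
    return hits


def find_orfs(t: NucSequence) -> list[OrfHit]:
    """All maximal ORFs of ``t`` on both strands in all six frames.

    An ORF is a maximal stop-free in-frame run that begins at ATG or at the
    transcript boundary and ends at a stop codon (included in the span) or at
    the boundary.  Runs consisting solely of a stop codon are not reported.
    Results are sorted by length descending (ties: '+' before '-', then start).
    """
    if len(t) < 3:
        return []
    fwd = _orfs_one_strand(t.seq, "+", len(t))
    rev = _orfs_one_strand(revcomp(t.seq), "-", len(t))
    return sorted(fwd + rev, key=lambda h: (-h.length_nt, h.strand, h.start))


# ---------------------------------------------------------------------------
# Banded local alignment
# ---------------------------------------------------------------------------

_NEG_INF = np.int32(-(10 ** 8))


def _encode(seq: str) -> np.ndarray:
    table = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        table[ord(b)] = i
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _banded_sw(
    q: np.ndarray,
    t: np.ndarray,
    lo: int,
    hi: int,
    match: int = MATCH_SCORE,
    mismatch: int = MISMATCH_SCORE,
    gap: int = GAP_SCORE,
):
    """Banded Smith-Waterman over diagonals ``lo <= j - i <= hi``.

    Returns ``(score, path)`` where path is a list of moves from alignment
    start to end; each move is ``('D', qi, tj, is_match)`` for a diagonal step
    or ``('U'/'L', qi, tj, False)`` for query/target gaps.  Scores are integer
    so the traceback is exact.
    """
    n, m = len(q), len(t)
    lo = max(lo, -n)
    hi = min(hi, m)
    W = hi - lo + 1
    H = np.full((n + 1, W), _NEG_INF, dtype=np.int32)
    idx = np.arange(W)
    # row 0: j = lo + k must be within [0, m]
    j0 = lo + idx
    valid0 = (j0 >= 0) & (j0 <= m)
    H[0, valid0] = 0
    gap_ramp = gap * idx
    for i in range(1, n + 1):
        j = i + lo + idx  # target column for each band slot
        valid = (j >= 1) & (j <= m)
        sub = np.full(W, _NEG_INF, dtype=np.int32)
        jv = j[valid] - 1
        eq = (t[jv] == q[i - 1]) & (t[jv] < 4) & (q[i - 1] < 4)
        sub[valid] = np.where(eq, match, mismatch)
        diag = H[i - 1] + sub
        up = np.concatenate([H[i - 1, 1:], [_NEG_INF]]) + gap
        cand = np.maximum(diag, up)
        cand[~valid] = _NEG_INF
        # left-gap propagation within the row: running max of cand - gap*(k-k')
        ramped = cand - gap_ramp  # gap is negative; subtracting makes it additive
        run = np.maximum.accumulate(ramped)
        left = run + gap_ramp
        row = np.maximum(cand, left)
        row = np.maximum(row, 0)
        row[~valid] = _NEG_INF
        # band slot for j == i (query-only prefix): alignment may start here
        k_start = -lo  # j - i = 0
        if 0 <= k_start < W and i + lo + k_start <= m:
            row[k_start] = max(row[k_start], 0)
        H[i] = row
    best = int(H.max())
    if best <= 0:
        return 0, []
    i, k = np.unravel_index(int(H.argmax()), H.shape)
    i = int(i)
    k = int(k)
    path: list[tuple[str, int, int, bool]] = []
    while i > 0 or k != -lo:
        s = int(H[i, k])
        if s == 0:
            break
        j = i + lo + k
        if k - 1 >= 0 and H[i, k - 1] != _NEG_INF and s == int(H[i, k - 1]) + gap:
            path.append(("L", i, j, False))
            k -= 1
            continue
        if (
            i > 0
            and k + 1 < W
            and H[i - 1, k + 1] != _NEG_INF
            and s == int(H[i - 1, k + 1]) + gap
        ):
            path.append(("U", i, j, False))
            i -= 1
            k += 1
            continue
        if i > 0 and j > 0 and H[i - 1, k] != _NEG_INF:
            is_match = q[i - 1] == t[j - 1] and q[i - 1] < 4 and t[j - 1] < 4
            if s == int(H[i - 1, k]) + (match if is_match else mismatch):
                path.append(("D", i, j, bool(is_match)))
                i -= 1
                continue
        break  # alignment start (score came from the 0 floor)
    path.reverse()
    return best, path


def _path_to_blocks(path) -> tuple[list[tuple[int, int, int, int]], int, int, int]:
    """Convert a traceback path into blocks plus match/mismatch/indel counts."""
    blocks: list[tuple[int, int, int, int]] = []
    matches = mismatches = indels = 0
    cur = None  # [q_start, t_start, length]
    for move, i, j, is_match in path:
        if move == "D":
            if cur is None:
                cur = [i - 1, j - 1, 1]
            else:
                cur[2] += 1
            if is_match:
                matches += 1
            else:
                mismatches += 1
        else:
            if cur is not None:
                blocks.append((cur[0], cur[0] + cur[2], cur[1], cur[1] + cur[2]))
                cur = None
            indels += 1
    if cur is not None:
        blocks.append((cur[0], cur[0] + cur[2], cur[1], cur[1] + cur[2]))
    return blocks, matches, mismatches, indels


from functools import lru_cache


@lru_cache(maxsize=32)
def _target_kmer_index(t: str, k: int) -> dict[str, list[int]]:
    """Position index of all k-mers of a target sequence (cached: genome
    scaffolds are queried by many transcripts in a row)."""
    index: dict[str, list[int]] = {}
    for pos in range(len(t) - k + 1):
        index.setdefault(t[pos : pos + k], []).append(pos)
    return index


def _seed_diagonals(q: str, t: str, k: int, max_per_kmer: int = 64):
    """Shared-k-mer diagonals (t_pos - q_pos) between two sequences."""
    if len(q) < k or len(t) < k:
        return []
    index = _target_kmer_index(t, k)
    diags: list[int] = []
    step = 1 if len(q) < 5000 else 3
    for qpos in range(0, len(q) - k + 1, step):
        hits = index.get(q[qpos : qpos + k])
        if hits and len(hits) <= max_per_kmer:
            diags.extend(h - qpos for h in hits)
    return diags


def _best_diag_window(diags: Sequence[int], width: int) -> tuple[int, int]:
    ds = sorted(diags)
    best_count, best_lo, best_hi = 0, ds[0], ds[0]
    j = 0
    for i in range(len(ds)):
        while ds[i] - ds[j] > width:
            j += 1
        if i - j + 1 > best_count:
            best_count, best_lo, best_hi = i - j + 1, ds[j], ds[i]
    return best_lo, best_hi


def align_pair(
    query: NucSequence,
    target: NucSequence,
    min_identity: float,
    k: int = 15,
    band_pad: int = 32,
    max_band_width: int = 200,
    full_dp_limit: int = 2_000_000,
) -> AlignmentBlockChain | None:
    """Seeded, gap-tolerant local alignment of ``query`` against ``target``.

    Both strands are tried; the highest-scoring chain is returned provided its
    overall identity reaches ``min_identity``, else ``None``.  When no k-mer
    seeds are found and the problem is small, a full (unbanded) matrix is used
    so the result equals an exhaustive dynamic-programming alignment.
    Deterministic: strand ties resolve to '+'.
    """
    if not (0.0 < min_identity <= 1.0):
        raise ValueError("min_identity must be in (0, 1]")
    if not query.seq or not target.seq:
        raise ValueError("empty input")
    t_arr = _encode(target.seq)
    best = None
    for strand in "+-":
        qseq = query.seq if strand == "+" else revcomp(query.seq)
        q_arr = _encode(qseq)
        diags = _seed_diagonals(qseq, target.seq, k)
        if diags:
            lo, hi = _best_diag_window(diags, max_band_width)
            lo -= band_pad
            hi += band_pad
        elif len(qseq) * len(target.seq) <= full_dp_limit:
            lo, hi = -len(qseq), len(target.seq)
        else:
            continue
        score, path = _banded_sw(q_arr, t_arr, lo, hi)
        if not path:
            continue
        blocks, matches, mismatches, indels = _path_to_blocks(path)
        if not blocks:
            continue
        chain = AlignmentBlockChain(
            query.id, target.id, strand, blocks, matches, mismatches, indels, score
        )
        if best is None or chain.score > best.score:
            best = chain
    if best is None or best.identity < min_identity:
        return None
    return best


# ---------------------------------------------------------------------------
# Spliced (intron-aware) alignment
# ---------------------------------------------------------------------------

def _exact_runs(q: str, t: str, k: int, max_per_kmer: int = 16):
    """Maximal exact match runs grouped by diagonal: list of (qs, qe, diag)."""
    if len(q) < k or len(t) < k:
        return []
    index = _target_kmer_index(t, k)
    by_diag: dict[int, set[int]] = {}
    for qpos in range(len(q) - k + 1):
        hits = index.get(q[qpos : qpos + k])
        if hits and len(hits) <= max_per_kmer:
            for h in hits:
                by_diag.setdefault(h - qpos, set()).add(qpos)
    runs = []
    for diag, starts in by_diag.items():
        merged: list[list[int]] = []
        for s in sorted(starts):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], s + k)
            else:
                merged.append([s, s + k])
        for s, e in merged:
            # extend to the maximal exact run
            while s > 0 and s + diag > 0 and q[s - 1] == t[s - 1 + diag] and q[s - 1] != "N":
                s -= 1
            while e < len(q) and e + diag < len(t) and q[e] == t[e + diag] and q[e] != "N":
                e += 1
            runs.append((s, e, diag))
    return sorted(set(runs))


def spliced_align(
    transcript: NucSequence,
    genome: NucSequence,
    min_block: int = 30,
    min_identity: float = 0.95,
    k: int = 15,
    min_intron: int = 20,
    max_mismatch_bridge: int = 12,
) -> AlignmentBlockChain | None:
    """Align a transcript to genomic sequence allowing large target-only gaps.

    Exact-match runs are chained co-linearly; target gaps >= ``min_intron``
    between consecutive blocks are treated as candidate introns (excluded from
    the identity denominator), smaller target gaps and unaligned internal query
    bases count as indels.  Query overlaps at junctions are resolved by sliding
    the junction to a position whose intron boundaries are canonical (GT..AG,
    then CT..AC) when possible.  Blocks shorter than ``min_block`` after
    junction resolution are discarded.
    """
    if min_block < 1:
        raise ValueError("min_block must be >= 1")
    if not transcript.seq or not genome.seq:
        raise ValueError("empty input")
    best = None
    for strand in "+-":
        qseq = transcript.seq if strand == "+" else revcomp(transcript.seq)
        chain = _spliced_one_strand(
            qseq, genome.seq, transcript.id, genome.id, strand,
            min_block, k, min_intron, max_mismatch_bridge,
        )
        if chain is not None and (best is None or chain.matches > best.matches):
            best = chain
    if best is None or best.identity < min_identity:
        return None
    return best


def _spliced_one_strand(
    q: str, t: str, qid: str, tid: str, strand: str,
    min_block: int, k: int, min_intron: int, bridge: int,
) -> AlignmentBlockChain | None:
    runs = _exact_runs(q, t, k)
    if not runs:
        return None
    # merge same-diagonal runs separated by few mismatch columns
    merged: list[tuple[int, int, int, int]] = []  # (qs, qe, diag, mismatches)
    by_diag: dict[int, list[tuple[int, int]]] = {}
    for qs, qe, d in runs:
        by_diag.setdefault(d, []).append((qs, qe))
    for d, items in by_diag.items():
        items.sort()
        cur_s, cur_e = items[0]
        mm = 0
        for s, e in items[1:]:
            gap = s - cur_e
            if 0 < gap <= bridge:
                mm += gap
                cur_e = max(cur_e, e)
            elif gap <= 0:
                cur_e = max(cur_e, e)
            else:
                merged.append((cur_s, cur_e, d, mm))
                cur_s, cur_e, mm = s, e, 0
        merged.append((cur_s, cur_e, d, mm))
    cands = sorted(merged, key=lambda r: (r[0], r[2]))
    # co-linear chain DP maximising matched bases (small penalty per junction)
    n = len(cands)
    score = [0.0] * n
    prev = [-1] * n
    for i, (qs, qe, d, mm) in enumerate(cands):
        score[i] = (qe - qs - mm) - 0.01
        for j in range(i):
            pqs, pqe, pd, pmm = cands[j]
            if pd == d:
                continue
            if qe <= pqe:  # contained in the previous block: adds nothing
                continue
            ov = max(0, pqe - qs)
            # target consistency after trimming the overlap
            if (qs + d) + ov - (pqe + pd) < 0:
                continue
            if ov > min(pqe - pqs, qe - qs) - 1:
                continue
            s_here = score[j] + (qe - max(qs, pqe) - mm) - 0.01
            if s_here > score[i] + 1e-9:
                score[i] = s_here
                prev[i] = j
    end = int(np.argmax(score))
    chain_idx = []
    i = end
    while i != -1:
        chain_idx.append(i)
        i = prev[i]
    chain_idx.reverse()
    picked = [list(cands[i]) for i in chain_idx]  # [qs, qe, diag, mm]
    # resolve query overlaps at junctions, preferring canonical introns
    for a, b in zip(picked, picked[1:]):
        ov = a[1] - b[0]
        if ov <= 0:
            continue
        choice = None
        fallback = 0
        for polarity in (("GT", "AG"), ("CT", "AC")):
            for x in range(ov + 1):
                i0 = a[1] - x + a[2]
                i1 = b[0] + (ov - x) + b[2]
                if i1 - i0 >= 4 and t[i0 : i0 + 2] == polarity[0] and t[i1 - 2 : i1] == polarity[1]:
                    choice = x
                    break
            if choice is not None:
                break
        x = choice if choice is not None else fallback
        a[1] -= x
        b[0] += ov - x
    picked = [p for p in picked if p[1] - p[0] >= min_block]
    if not picked:
        return None
    blocks = []
    matches = mismatches = indels = 0
    for qs, qe, d, mm in picked:
        blocks.append((qs, qe, qs + d, qe + d))
        matches += (qe - qs) - mm
        mismatches += mm
    for (q0, q1, t0, t1), (q2, q3, t2, t3) in zip(blocks, blocks[1:]):
        qgap = q2 - q1
        tgap = t2 - t1
        if qgap > 0:
            indels += qgap
        if 0 < tgap < min_intron:
            indels += tgap
    return AlignmentBlockChain(qid, tid, strand, blocks, matches, mismatches, indels,
                               score=matches * MATCH_SCORE + mismatches * MISMATCH_SCORE)


# ---------------------------------------------------------------------------
# Assembly statistics
# ---------------------------------------------------------------------------

def assembly_stats(seqs: Sequence[NucSequence]) -> AssemblyStats:
    """Summary statistics of an assembly; N50 by the cumulative-length rule."""
    if not seqs:
        raise ValueError("assembly_stats requires a non-empty sequence list")
    lengths = sorted((len(s) for s in seqs), reverse=True)
    total = sum(lengths)
    total_no_gaps = total - sum(s.seq.count("N") for s in seqs)
    acc = 0
    n50 = lengths[-1]
    for L in lengths:
        acc += L
        if acc * 2 >= total:
            n50 = L
            break
    return AssemblyStats(
        n_sequences=len(lengths),
        total_bases_with_gaps=total,
        total_bases_without_gaps=total_no_gaps,
        n50=n50,
        max_length=lengths[0],
    )
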