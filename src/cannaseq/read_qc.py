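"""Illumina read filtering and mate-pair hygiene.

Implements the short-read quality rules used ahead of de novo assembly:
running-count quality truncation (at most ``max_lowq`` bases below Q30, the
remainder of the read discarded), adapter screening, removal of "unmated"
mate pairs that are fully contained within a single short-insert pair, and
first-30-bp duplicate-pair removal.  A :class:`FilterReport` partitions the
input exactly into kept plus per-rule dropped categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .seqcore import NucSequence, revcomp


@dataclass
class ReadPair:
    id: str
    seq1: str
    qual1: Sequence[int]
    seq2: str | None = None
    qual2: Sequence[int] | None = None
    orientation_tag: str = "unknown"

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1):
            raise ValueError(f"{self.id}: read1 sequence/quality length mismatch")
        if self.seq2 is not None and len(self.seq2) != len(self.qual2):
            raise ValueError(f"{self.id}: read2 sequence/quality length mismatch")


@dataclass
class FilterReport:
    input_pairs: int = 0
    kept_pairs: int = 0
    dropped_quality: int = 0
    dropped_adapter: int = 0
    dropped_duplicate: int = 0
    dropped_unmated: int = 0
    unmated_fraction_estimate: float | None = None

    def check_partition(self) -> bool:
        return (
            self.kept_pairs
            + self.dropped_quality
            + self.dropped_adapter
            + self.dropped_duplicate
            + self.dropped_unmated
            == self.input_pairs
        )

    def as_tsv(self) -> str:
        fields = [
            "input_pairs", "kept_pairs", "dropped_quality", "dropped_adapter",
            "dropped_unmated", "dropped_duplicate", "unmated_fraction_estimate",
        ]
        head = "\t".join(fields)
        vals = "\t".join(str(getattr(self, f)) for f in fields)
        return f"{head}\n{vals}\n"


def _truncate_read(seq: str, qual: Sequence[int], max_lowq: int, q_thresh: int) -> int:
    """Return the kept prefix length under the running low-quality count rule.

    The read is cut immediately before the base at which the running count of
    bases below ``q_thresh`` would exceed ``max_lowq``.
    """
    lowq = 0
    for i, q in enumerate(qual):
        if q < q_thresh:
            lowq += 1
            if lowq > max_lowq:
                return i
    return len(seq)


def quality_trim_pair(
    p: ReadPair,
    max_lowq: int = 10,
    q_thresh: int = 30,
    min_len: int = 55,
    mode: str = "truncate",
) -> ReadPair | None:
    """Apply the low-quality rule to both reads; keep the pair only if both
    trimmed reads remain longer than ``min_len``.

    ``mode='truncate'`` (default) cuts the read at the offending base;
    ``mode='discard'`` drops the whole pair as soon as either read exceeds
    ``max_lowq`` sub-threshold bases.
    """
    if max_lowq < 0 or q_thresh <= 0 or min_len <= 0:
        raise ValueError("thresholds must be positive")
    reads = [(p.seq1, p.qual1)]
    if p.seq2 is not None:
        reads.append((p.seq2, p.qual2))
    cut = [_truncate_read(s, q, max_lowq, q_thresh) for s, q in reads]
    if mode == "discard" and any(c < len(s) for c, (s, _) in zip(cut, reads)):
        return None
    if any(c <= min_len for c in cut):
        return None
    if all(c == len(s) for c, (s, _) in zip(cut, reads)):
        return p
    new = ReadPair(
        p.id,
        p.seq1[: cut[0]],
        list(p.qual1[: cut[0]]),
        p.seq2[: cut[1]] if p.seq2 is not None else None,
        list(p.qual2[: cut[1]]) if p.qual2 is not None else None,
        p.orientation_tag,
    )
    return new


def screen_adapters(
    p: ReadPair, adapters: Sequence[NucSequence], min_match: int = 12
) -> bool:
    """True when the pair is adapter-free (kept); a pair is dropped when either
    read contains the first ``min_match`` bases of any adapter."""
    if not adapters:
        raise ValueError("adapters must be non-empty")
    for ad in adapters:
        probe = ad.seq[:min_match]
        if len(probe) < min_match:
            continue
        if probe in p.seq1 or (p.seq2 is not None and probe in p.seq2):
            return False
    return True


def _dedup_key(p: ReadPair, k: int = 30) -> tuple[str, str]:
    return (p.seq1[:k], (p.seq2 or "")[:k])


def dedup_mate_pairs(pairs: Iterable[ReadPair]) -> list[ReadPair]:
    """Keep the first pair of every (read1[0:30], read2[0:30]) key."""
    seen: set[tuple[str, str]] = set()
    out = []
    for p in pairs:
        key = _dedup_key(p)
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out


# ---------------------------------------------------------------------------
# Unmated mate-pair removal and estimation
# ---------------------------------------------------------------------------

def _kmer_index(reads: list[tuple[int, int, str]], k: int):
    idx: dict[str, list[tuple[int, int, int]]] = {}
    for pid, rid, seq in reads:
        for pos in range(0, len(seq) - k + 1):
            idx.setdefault(seq[pos : pos + k], []).append((pid, rid, pos))
    return idx


def _contained_in(needle: str, hay: str, offset: int, max_mismatch: int) -> bool:
    if offset < 0 or offset + len(needle) > len(hay):
        return False
    mism = 0
    for a, b in zip(needle, hay[offset : offset + len(needle)]):
        if a != b:
            mism += 1
            if mism > max_mismatch:
                return False
    return True


def remove_unmated_pairs(
    mate_pairs: Sequence[ReadPair],
    short_insert_pairs: Sequence[ReadPair],
    min_identity: float = 0.97,
    seed_k: int = 20,
) -> tuple[list[ReadPair], list[ReadPair]]:
    """Split mate pairs into (retained, removed-as-unmated).

    A mate pair is removed when read1 and read2 each align — in either
    orientation, at >= ``min_identity`` — fully within the two reads of a
    single short-insert pair.  Candidate placements come from exact
    ``seed_k``-mer lookups at both ends of each mate read.
    """
    if not mate_pairs or not short_insert_pairs:
        raise ValueError("both read collections must be non-empty")
    flat = []
    for pid, sp in enumerate(short_insert_pairs):
        flat.append((pid, 0, sp.seq1))
        if sp.seq2 is not None:
            flat.append((pid, 1, sp.seq2))
    idx = _kmer_index(flat, seed_k)
    hay = {(pid, rid): seq for pid, rid, seq in flat}

    def candidate_pids(read: str) -> set[int]:
        found = set()
        for seq in (read, revcomp(read)):
            for probe_off in (0, max(0, len(seq) - seed_k)):
                probe = seq[probe_off : probe_off + seed_k]
                for pid, rid, pos in idx.get(probe, ()):
                    off = pos - probe_off
                    max_mm = int((1 - min_identity) * len(seq))
                    if _contained_in(seq, hay[(pid, rid)], off, max_mm):
                        found.add(pid)
        return found

    retained, removed = [], []
    for mp in mate_pairs:
        c1 = candidate_pids(mp.seq1)
        hit = False
        if c1 and mp.seq2 is not None:
            c2 = candidate_pids(mp.seq2)
            hit = bool(c1 & c2)
        elif c1 and mp.seq2 is None:
            hit = True
        (removed if hit else retained).append(mp)
    return retained, removed


@dataclass(frozen=True)
class PairPlacement:
    """Where a mate pair landed on an assembly contig."""

    pair_id: str
    contig: str
    contig_length: int
    strand1: str
    pos1: int
    strand2: str
    pos2: int

    @property
    def orientation(self) -> str:
        left_strand = self.strand1 if self.pos1 <= self.pos2 else self.strand2
        right_strand = self.strand2 if self.pos1 <= self.pos2 else self.strand1
        if left_strand == "+" and right_strand == "-":
            return "FR"
        if left_strand == "-" and right_strand == "+":
            return "RF"
        return "unknown"


def estimate_unmated_fraction(
    placements: Iterable[PairPlacement], min_contig: int = 10_000
) -> float:
    """FR / (FR + RF) over pairs placed on a single contig > ``min_contig``.

    Mate-pair libraries map reverse-forward when properly mated, so the
    forward-reverse fraction estimates short-insert contamination.
    """
    fr = rf = 0
    for pl in placements:
        if pl.contig_length <= min_contig:
            continue
        o = pl.orientation
        if o == "FR":
            fr += 1
        elif o == "RF":
            rf += 1
    if fr + rf == 0:
        raise ValueError("no informative pairs")
    return fr / (fr + rf)


def place_pairs(
    pairs: Sequence[ReadPair], contigs: Sequence[NucSequence], k: int = 25
) -> list[PairPlacement]:
    """Exact-seed placement of read pairs onto contigs (plumbing for
    :func:`estimate_unmated_fraction`); ambiguous or unplaced reads are
    skipped."""
    idx: dict[str, tuple[str, int] | None] = {}
    lengths = {}
    for c in contigs:
        lengths[c.id] = len(c)
        for pos in range(len(c) - k + 1):
            kmer = c.seq[pos : pos + k]
            idx[kmer] = None if kmer in idx else (c.id, pos)

    def place(read: str):
        hit = idx.get(read[:k])
        if hit:
            return hit[0], hit[1], "+"
        hit = idx.get(revcomp(read)[:k])
        if hit:
            return hit[0], hit[1] + len(read) - k, "-"
        return None

    out = []
    for p in pairs:
        if p.seq2 is None:
            continue
        h1, h2 = place(p.seq1), place(p.seq2)
        if h1 is None or h2 is None or h1[0] != h2[0]:
            continue
        out.append(
            PairPlacement(p.id, h1[0], lengths[h1[0]], h1[2], h1[1], h2[2], h2[1])
        )
    return out


def filter_paired_reads(
    pairs: Sequence[ReadPair],
    adapters: Sequence[NucSequence] | None = None,
    short_insert_pairs: Sequence[ReadPair] | None = None,
    placements: Iterable[PairPlacement] | None = None,
    max_lowq: int = 10,
    q_thresh: int = 30,
    min_len: int = 55,
    adapter_min_match: int = 12,
    quality_mode: str = "truncate",
) -> tuple[list[ReadPair], FilterReport]:
    """Full hygiene pipeline: quality -> adapter -> unmated -> duplicate.

    The fixed order keeps the report categories disjoint so they partition the
    input exactly.  The unmated stage runs only when ``short_insert_pairs`` is
    given (mate-pair libraries); ``placements`` feeds the optional
    forward-reverse fraction estimate.
    """
    report = FilterReport(input_pairs=len(pairs))
    stage = []
    for p in pairs:
        t = quality_trim_pair(p, max_lowq, q_thresh, min_len, quality_mode)
        if t is None:
            report.dropped_quality += 1
        else:
            stage.append(t)
    if adapters:
        nxt = []
        for p in stage:
            if screen_adapters(p, adapters, adapter_min_match):
                nxt.append(p)
            else:
                report.dropped_adapter += 1
        stage = nxt
    if short_insert_pairs is not None and stage:
        stage, removed = remove_unmated_pairs(stage, short_insert_pairs)
        report.dropped_unmated = len(removed)
    deduped = dedup_mate_pairs(stage)
    report.dropped_duplicate = len(stage) - len(deduped)
    report.kept_pairs = len(deduped)
    if placements is not None:
        report.unmated_fraction_estimate = estimate_unmated_fraction(placements)
    return deduped, report
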