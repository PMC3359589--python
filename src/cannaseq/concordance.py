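"""Genome assembly post-processing and genome-transcriptome concordance.

After scaffolding, draft assemblies of heterozygous genomes carry
near-identical scaffold pairs (each haplotype assembled separately) and the
odd foreign contaminant.  This module collapses redundant scaffolds, screens
scaffolds that look foreign by both homology and read-coverage evidence, and
quantifies how much of an assembled transcriptome the genome accounts for:
per-transcript mapped fractions at high identity, binned base totals, and the
global fractions (mapped over half the length, fully represented, bases
accounted, single-scaffold).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .seqcore import AlignmentBlockChain, NucSequence, align_pair, spliced_align


@dataclass
class ConcordanceReport:
    per_transcript: pd.DataFrame  # id, length, mapped_bases, mapped_fraction, fully_represented, single_scaffold
    per_bin: pd.DataFrame  # bin_start, bin_end, mapped_bases, unmapped_bases
    frac_mapped_half: float
    frac_fully_represented: float
    frac_bases_accounted: float
    frac_single_scaffold: float

    def to_json_dict(self) -> dict:
        return {
            "frac_mapped_half": self.frac_mapped_half,
            "frac_fully_represented": self.frac_fully_represented,
            "frac_bases_accounted": self.frac_bases_accounted,
            "frac_single_scaffold": self.frac_single_scaffold,
        }


# ---------------------------------------------------------------------------
# Redundancy collapse
# ---------------------------------------------------------------------------

def collapse_redundant_scaffolds(
    scaffolds: Sequence[NucSequence],
    min_id: float = 0.98,
    min_cov: float = 0.95,
) -> tuple[list[NucSequence], list[tuple[str, str]]]:
    """Collapse near-identical scaffold pairs (>= ``min_id`` identity over
    >= ``min_cov`` of the shorter scaffold, either strand), keeping the
    largest scaffold of each transitive group.

    Such pairs typically arise when heterozygosity splits a locus into two
    haplotype assemblies.  Returns (retained, collapse log of
    (removed_id, representative_id))."""
    order = sorted(scaffolds, key=lambda s: (-len(s), s.id))
    parent: dict[str, str] = {s.id: s.id for s in order}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(order):
        for b in order[i + 1 :]:
            if find(a.id) == find(b.id):
                continue
            chain = align_pair(b, a, min_identity=min_id)
            if chain is None:
                continue
            cov = (chain.matches + chain.mismatches) / min(len(a), len(b))
            if cov >= min_cov:
                parent[find(b.id)] = find(a.id)
    groups: dict[str, list[NucSequence]] = {}
    for s in order:
        groups.setdefault(find(s.id), []).append(s)
    retained = []
    log = []
    for root, members in groups.items():
        members.sort(key=lambda s: (-len(s), s.id))
        retained.append(members[0])
        for m in members[1:]:
            log.append((m.id, members[0].id))
    retained.sort(key=lambda s: s.id)
    return retained, log


# ---------------------------------------------------------------------------
# Foreign-scaffold screen
# ---------------------------------------------------------------------------

def _best_alignment_score(
    scaffold: NucSequence, db: Sequence[NucSequence], min_identity: float = 0.5
) -> int:
    best = 0
    for ref in db:
        chain = align_pair(ref, scaffold, min_identity=min_identity)
        if chain is not None:
            best = max(best, chain.score)
    return best


def screen_foreign_scaffolds(
    scaffolds: Sequence[NucSequence],
    foreign_db: Sequence[NucSequence],
    host_db: Sequence[NucSequence],
    coverage: dict[str, float],
    min_score: int = 150,
    sd_mult: float = 2.0,
) -> tuple[list[NucSequence], list[NucSequence]]:
    """Remove scaffolds with a strong foreign-db alignment (score >
    ``min_score``) AND a median read coverage more than ``sd_mult`` standard
    deviations away from the mean coverage of validated host scaffolds
    (scaffolds with a host-db hit above the same score).

    ``coverage`` maps scaffold id to its median read depth.  Raises when no
    scaffold validates against the host db.
    """
    host_scores = {s.id: _best_alignment_score(s, host_db) for s in scaffolds}
    validated = [s.id for s in scaffolds if host_scores[s.id] > min_score]
    if not validated:
        raise ValueError("no validated host scaffolds")
    cov = np.array([coverage[sid] for sid in validated], dtype=float)
    mean, sd = float(cov.mean()), float(cov.std(ddof=1)) if len(cov) > 1 else 0.0
    retained, removed = [], []
    for s in scaffolds:
        foreign_score = _best_alignment_score(s, foreign_db)
        z_out = (
            abs(coverage[s.id] - mean) > sd_mult * sd if sd > 0
            else coverage[s.id] != mean
        )
        if foreign_score > min_score and z_out:
            removed.append(s)
        else:
            retained.append(s)
    return retained, removed


# ---------------------------------------------------------------------------
# Transcript-to-genome mapping and concordance statistics
# ---------------------------------------------------------------------------

def map_transcripts_to_genome(
    transcripts: Sequence[NucSequence],
    scaffolds: Sequence[NucSequence],
    min_identity: float = 0.98,
    min_block: int = 30,
) -> dict[str, list[AlignmentBlockChain]]:
    """Best spliced alignments per transcript, greedily chosen non-overlapping
    in transcript coordinates by aligned bases descending (so each transcript
    base is counted at most once, possibly split across scaffolds)."""
    out: dict[str, list[AlignmentBlockChain]] = {}
    for t in transcripts:
        chains = []
        for sc in scaffolds:
            chain = spliced_align(t, sc, min_block=min_block, min_identity=min_identity)
            if chain is not None:
                chains.append(chain)
        chains.sort(key=lambda c: (-c.aligned_query_bases, c.target_id))
        covered = np.zeros(len(t), dtype=bool)
        chosen = []
        for chain in chains:
            s, e = chain.query_interval_forward(len(t))
            if covered[s:e].any():
                continue
            covered[s:e] = True
            chosen.append(chain)
        out[t.id] = chosen
    return out


def concordance_stats(
    mappings: dict[str, list[AlignmentBlockChain]],
    transcripts: Sequence[NucSequence],
    bin_nt: int = 300,
) -> ConcordanceReport:
    """Concordance summary; per-bin mapped+unmapped bases sum exactly to the
    transcriptome size."""
    rows = []
    for t in transcripts:
        chains = mappings.get(t.id, [])
        covered = np.zeros(len(t), dtype=bool)
        scaffold_ids = set()
        for chain in chains:
            scaffold_ids.add(chain.target_id)
            L = len(t)
            for qs, qe, _, _ in chain.blocks:
                if chain.strand == "+":
                    covered[qs:qe] = True
                else:
                    covered[L - qe : L - qs] = True
        mapped = int(covered.sum())
        fully = mapped == len(t)
        rows.append(
            {
                "transcript_id": t.id,
                "length": len(t),
                "mapped_bases": mapped,
                "mapped_fraction": mapped / len(t),
                "fully_represented": fully,
                "single_scaffold": fully and len(scaffold_ids) == 1,
            }
        )
    per_t = pd.DataFrame(rows)
    per_t["bin"] = (per_t["length"] - 1) // bin_nt
    per_bin = (
        per_t.groupby("bin")
        .apply(
            lambda d: pd.Series(
                {
                    "bin_start": d.name * bin_nt,
                    "bin_end": (d.name + 1) * bin_nt,
                    "mapped_bases": int(d.mapped_bases.sum()),
                    "unmapped_bases": int((d.length - d.mapped_bases).sum()),
                }
            ),
            include_groups=False,
        )
        .reset_index(drop=True)
    )
    total_bases = int(per_t.length.sum())
    return ConcordanceReport(
        per_transcript=per_t.drop(columns="bin"),
        per_bin=per_bin,
        frac_mapped_half=float((per_t.mapped_fraction >= 0.5).mean()),
        frac_fully_represented=float(per_t.fully_represented.mean()),
        frac_bases_accounted=float(per_t.mapped_bases.sum() / total_bases),
        frac_single_scaffold=float(per_t.single_scaffold.mean()),
    )
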