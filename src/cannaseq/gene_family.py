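"""Cannabinoid gene-family screening and coding-status classification.

The THCA and CBDA synthases are closely related oxidocyclases; which of them
is intact in a strain's genome determines its chemotype (THCA-dominant
marijuana versus CBDA-dominant hemp), and disabled family copies survive as
pseudogenes carrying premature stop codons and frameshift indels.  This
module screens genome scaffolds and transcripts for family homologs above a
nucleotide-identity threshold, classifies each candidate against an intact
reference coding sequence, and calls the chemotype from the joint evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .seqcore import NucSequence, STOP_CODONS, align_pair, find_orfs, revcomp


@dataclass(frozen=True)
class HomologHit:
    query_id: str
    subject_id: str
    identity_pct: float  # over the aligned region
    aligned_span: int
    subject_kind: str  # genome_scaffold or transcript
    score: int


@dataclass
class PseudogeneReport:
    candidate_id: str
    reference_id: str
    frameshifts: list[tuple[int, int]]  # (reference position, indel length)
    premature_stops: list[int]  # reference positions of stop codon starts
    intact: bool


def search_homologs(
    queries: Sequence[NucSequence],
    subjects: Sequence[NucSequence],
    min_identity: float = 65.0,
    min_span: int = 100,
    subject_kind: str = "transcript",
    seed_k: int = 11,
) -> list[HomologHit]:
    """Subjects with an alignment to any query at nucleotide identity
    *strictly greater than* ``min_identity`` percent (either strand) over at
    least ``min_span`` aligned columns, ranked by identity then score.

    Identity is computed over the aligned region, which is what matters for
    partial hits such as pseudogene fragments split across scaffolds; the
    span floor keeps trivial short exact matches out.
    """
    if not (0.0 < min_identity <= 100.0):
        raise ValueError("min_identity must be in (0, 100]")
    hits = []
    for subject in subjects:
        best = None
        for query in queries:
            chain = align_pair(query, subject, min_identity=0.4, k=seed_k)
            if chain is None or chain.matches + chain.mismatches < min_span:
                continue
            if best is None or (chain.identity, chain.score) > (
                best[1].identity, best[1].score
            ):
                best = (query.id, chain)
        if best is None:
            continue
        qid, chain = best
        pct = 100.0 * chain.identity
        if pct > min_identity:
            hits.append(
                HomologHit(
                    qid, subject.id, pct,
                    chain.matches + chain.mismatches, subject_kind, chain.score,
                )
            )
    return sorted(hits, key=lambda h: (-h.identity_pct, -h.score, h.subject_id))


def classify_coding_status(
    candidate: NucSequence,
    reference_cds: NucSequence,
    min_identity: float = 0.5,
    min_span: int = 100,
    stop_tolerance_codons: int = 15,
    seed_k: int = 11,
) -> PseudogeneReport:
    """Classify a family candidate as intact or pseudogenic against an intact
    reference CDS.

    The candidate is aligned to the reference; indels whose length is not a
    multiple of three are frameshifts, and candidate codons aligned in the
    reference frame that are stop codons more than ``stop_tolerance_codons``
    codons upstream of the reference stop are premature stops.  Raises when
    the best alignment falls below ``min_identity`` (too diverged to
    classify).
    """
    chain = align_pair(candidate, reference_cds, min_identity=0.0001, k=seed_k)
    if (
        chain is None
        or chain.identity < min_identity
        or chain.matches + chain.mismatches < min_span
    ):
        raise ValueError(
            f"{candidate.id}: too diverged to classify against {reference_cds.id}"
        )
    qseq = candidate.seq if chain.strand == "+" else revcomp(candidate.seq)
    n_codons = len(reference_cds.seq) // 3
    last_codon = n_codons - 1  # the reference's own stop codon
    frameshifts: list[tuple[int, int]] = []
    premature: list[int] = []
    for (q0, q1, t0, t1), (q2, q3, t2, t3) in zip(chain.blocks, chain.blocks[1:]):
        dq = q2 - q1
        dt = t2 - t1
        indel = abs(dq - dt)
        if indel and indel % 3 != 0:
            frameshifts.append((t1, indel))
    for qs, qe, ts, te in chain.blocks:
        first = ts + ((3 - ts % 3) % 3)
        for p in range(first, te - 2, 3):
            codon = qseq[qs + (p - ts) : qs + (p - ts) + 3]
            if codon in STOP_CODONS:
                codon_idx = p // 3
                if codon_idx < last_codon - stop_tolerance_codons:
                    premature.append(p)
    intact = not frameshifts and not premature
    return PseudogeneReport(candidate.id, reference_cds.id, frameshifts, premature, intact)


def chemotype_call(
    genome_scaffolds: Sequence[NucSequence],
    transcripts: Sequence[NucSequence],
    thcas_family: Sequence[NucSequence],
    cbdas_family: Sequence[NucSequence],
    min_identity: float = 65.0,
) -> tuple[str, pd.DataFrame]:
    """Call the strain chemotype from family homolog screens plus coding
    status.

    THCA_dominant: an intact THCAS-family copy exists and no CBDAS-family
    copy is intact (and symmetrically for CBDA_dominant); both families
    intact -> mixed; neither -> undetermined.  Returns (call, evidence table
    listing every hit with its coding status).
    """
    subjects = [("genome_scaffold", s) for s in genome_scaffolds] + [
        ("transcript", t) for t in transcripts
    ]
    families = {"THCAS": list(thcas_family), "CBDAS": list(cbdas_family)}
    rows = []
    intact_by_family = {"THCAS": False, "CBDAS": False}
    for fam, refs in families.items():
        for kind, group in (
            ("genome_scaffold", genome_scaffolds),
            ("transcript", transcripts),
        ):
            for hit in search_homologs(refs, group, min_identity, subject_kind=kind):
                ref = next(r for r in refs if r.id == hit.query_id)
                subject = next(s for s in group if s.id == hit.subject_id)
                try:
                    rep = classify_coding_status(subject, ref)
                    status = "intact" if rep.intact else "pseudogene"
                    n_fs, n_stop = len(rep.frameshifts), len(rep.premature_stops)
                except ValueError:
                    status, n_fs, n_stop = "unclassified", None, None
                if status == "intact":
                    intact_by_family[fam] = True
                rows.append(
                    {
                        "family": fam,
                        "reference": hit.query_id,
                        "subject": hit.subject_id,
                        "subject_kind": kind,
                        "identity_pct": hit.identity_pct,
                        "aligned_span": hit.aligned_span,
                        "status": status,
                        "n_frameshifts": n_fs,
                        "n_premature_stops": n_stop,
                    }
                )
    evidence = pd.DataFrame(rows)
    thca, cbda = intact_by_family["THCAS"], intact_by_family["CBDAS"]
    if thca and not cbda:
        call = "THCA_dominant"
    elif cbda and not thca:
        call = "CBDA_dominant"
    elif thca and cbda:
        call = "mixed"
    else:
        call = "undetermined"
    return call, evidence
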