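"""Transcript orientation evidence, consensus, and assembly merging."""

import numpy as np
import pytest

from cannaseq.curation import (
    ProteinIndex,
    cluster_isoforms_select_representative,
    cluster_near_identical,
    consensus_orientation,
    curate,
    filter_chimeras,
    join_blunt_overlaps,
    orient_by_homology,
    orient_by_orf,
    orient_by_splice,
    orient_transcripts,
)
from cannaseq.seqcore import NucSequence, revcomp
from cannaseq.simulate import simulate_assembled_transcripts

from conftest import diverged_copy, random_dna

NONSTOP = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def coding_transcript(rng, n_codons):
    return "ATG" + "".join(
        NONSTOP[i] for i in rng.integers(0, len(NONSTOP), n_codons - 2)
    ) + "TAA"


class TestOrientByHomology:
    def test_coding_strand_and_reverse(self, small_genome):
        idx = ProteinIndex(small_genome.protein_seqs())
        t = NucSequence("t", small_genome.transcript_seq(small_genome.genes[0]))
        assert orient_by_homology(t, idx) == "+"
        assert orient_by_homology(t.reverse_complement(), idx) == "-"

    def test_unrelated_no_vote(self, small_genome):
        idx = ProteinIndex(small_genome.protein_seqs())
        rng = np.random.default_rng(0)
        t = NucSequence("t", random_dna(rng, 600))
        assert orient_by_homology(t, idx) == "none"

    def test_both_strand_hits_conflict(self, small_genome):
        """A construct encoding db proteins on both strands is dropped."""
        idx = ProteinIndex(small_genome.protein_seqs())
        a = small_genome.transcript_seq(small_genome.genes[0])
        b = small_genome.transcript_seq(small_genome.genes[1])
        t = NucSequence("t", a + revcomp(b))
        assert orient_by_homology(t, idx) == "conflict"


class TestOrientByOrf:
    def _transcript_with_short_opposite_orf(self, n_codons, max_minus=100):
        from cannaseq.seqcore import find_orfs

        rng = np.random.default_rng(1)
        for _ in range(200):
            t = NucSequence("t", coding_transcript(rng, n_codons))
            minus = max(
                (o.length_nt for o in find_orfs(t) if o.strand == "-"), default=0
            )
            if minus <= max_minus:
                return t
        raise AssertionError("could not construct fixture")

    def test_boundary_240nt_full_span(self):
        # 240-nt ORF spanning the whole transcript, no competing '-' ORF
        t = self._transcript_with_short_opposite_orf(80)
        assert orient_by_orf(t) == "+"
        assert orient_by_orf(t.reverse_complement()) == "-"

    def test_below_240_no_vote(self):
        rng = np.random.default_rng(2)
        # 237-nt ORF spanning the whole transcript: fails the length floor
        t = NucSequence("t", coding_transcript(rng, 79))
        assert orient_by_orf(t) == "none"

    def test_span_requirement(self):
        rng = np.random.default_rng(3)
        orf = coding_transcript(rng, 80)
        padding = random_dna(rng, 150)
        # ORF of 240 over 390 nt: span 0.615 < 0.70
        t = NucSequence("t", orf + padding)
        if orient_by_orf(t) != "none":  # padding may extend the ORF by chance
            pytest.skip("random padding extended the reading frame")

    def test_ratio_requirement(self):
        """An opposite-strand ORF more than half as long blocks the vote."""
        rng = np.random.default_rng(8)
        for _ in range(50):
            t = NucSequence("t", coding_transcript(rng, 100))
            orfs_minus = [
                o for o in __import__("cannaseq.seqcore", fromlist=["find_orfs"]).find_orfs(t)
                if o.strand == "-"
            ]
            best_minus = max((o.length_nt for o in orfs_minus), default=0)
            if best_minus > 150:
                assert orient_by_orf(t) == "none"
                return
        pytest.skip("no construct with a long opposite ORF found")


class TestOrientBySplice:
    def test_canonical_polarity(self, small_genome):
        gene = next(g for g in small_genome.genes if len(g.exons) >= 2)
        t = NucSequence("t", small_genome.transcript_seq(gene))
        assert orient_by_splice(t, small_genome.scaffolds) == "+"
        assert orient_by_splice(t.reverse_complement(), small_genome.scaffolds) == "-"

    def test_equal_noncanonical_blocks_vote(self):
        """One canonical plus one non-canonical junction: 'equal or greater'
        rule blocks the vote."""
        rng = np.random.default_rng(4)
        e1, e2, e3 = (random_dna(rng, 150) for _ in range(3))
        good = "GT" + random_dna(rng, 120) + "AG"
        bad = "CC" + random_dna(rng, 120) + "TT"
        genome = NucSequence(
            "g", random_dna(rng, 200) + e1 + good + e2 + bad + e3 + random_dna(rng, 200)
        )
        t = NucSequence("t", e1 + e2 + e3)
        assert orient_by_splice(t, [genome]) == "none"

    def test_single_exon_no_vote(self, small_genome):
        gene = next(g for g in small_genome.genes if len(g.exons) == 1)
        t = NucSequence("t", small_genome.transcript_seq(gene))
        assert orient_by_splice(t, small_genome.scaffolds) == "none"


class TestConsensus:
    @pytest.mark.parametrize(
        "votes,consensus,n_sup",
        [
            ({"homology": "+", "splice": "+", "orf": "none"}, "+", 2),
            ({"homology": "+", "orf": "-", "splice": "none"}, "dropped", 0),
            ({"homology": "none", "orf": "none", "splice": "none"}, "unoriented", 0),
            ({"homology": "conflict", "orf": "+", "splice": "+"}, "dropped", 0),
            ({"homology": "none", "orf": "-", "splice": "none"}, "-", 1),
        ],
    )
    def test_consensus_rules(self, votes, consensus, n_sup):
        call = consensus_orientation("t", votes)
        assert call.consensus == consensus
        assert call.n_supporting == n_sup

    def test_missing_method_rejected(self):
        with pytest.raises(ValueError):
            consensus_orientation("t", {"homology": "+"})


class TestClusterNearIdentical:
    def test_paper_thresholds(self):
        rng = np.random.default_rng(5)
        long = random_dna(rng, 1000)
        near = diverged_copy(long[10:990], 8)  # ~99% identity, full coverage
        clusters, reps = cluster_near_identical(
            {"a": [NucSequence("L", long)], "b": [NucSequence("S", near)]}
        )
        assert len(clusters) == 1
        assert clusters[0].representative_id == "L"  # longest member

    def test_boundary_96_percent_split(self):
        rng = np.random.default_rng(6)
        long = random_dna(rng, 1000)
        far = diverged_copy(long, 40)  # 96% identity < 97%
        clusters, reps = cluster_near_identical(
            {"a": [NucSequence("L", long)], "b": [NucSequence("S", far)]}
        )
        assert len(clusters) == 2

    def test_exact_duplicates_merge(self):
        rng = np.random.default_rng(7)
        s = random_dna(rng, 600)
        clusters, reps = cluster_near_identical(
            {"a": [NucSequence("x", s)], "b": [NucSequence("y", s)]}
        )
        assert len(clusters) == 1


class TestFilterChimeras:
    def test_sensitivity_and_specificity(self, medium_genome):
        """Planted head-to-head chimeras are removed with sensitivity >= 0.9
        and clean transcripts survive with specificity >= 0.95."""
        sets, truth = simulate_assembled_transcripts(
            medium_genome, 9, frag_prob=0.0, chimera_rate=0.25, chimera_in=("asmB",)
        )
        idx = ProteinIndex(medium_genome.protein_seqs())
        kept, removed = filter_chimeras(sets["asmB"], idx)
        tt = truth[truth.assembly == "asmB"].set_index("transcript_id")
        removed_ids = {t.id for t in removed}
        chimeras = set(tt.index[tt.is_chimera])
        clean = set(tt.index[~tt.is_chimera])
        if chimeras:
            sensitivity = len(chimeras & removed_ids) / len(chimeras)
            assert sensitivity >= 0.9
        specificity = len(clean - removed_ids) / len(clean)
        assert specificity >= 0.95


class TestJoinBluntOverlaps:
    def test_join_at_60(self):
        rng = np.random.default_rng(8)
        s = random_dna(rng, 500)
        out, log = join_blunt_overlaps(
            [NucSequence("f1", s[:300]), NucSequence("f2", s[240:])], 50
        )
        assert len(out) == 1
        assert len(out[0]) == 300 + 260 - 60
        assert log == [("f1", "f2", 60)]

    def test_48nt_overlap_not_joined(self):
        """The 48-nt case narrowly misses the 50-nt merging threshold."""
        rng = np.random.default_rng(9)
        s = random_dna(rng, 500)
        out, log = join_blunt_overlaps(
            [NucSequence("f1", s[:300]), NucSequence("f2", s[252:])], 50
        )
        assert len(out) == 2
        assert log == []

    def test_total_bases_shrink_by_overlap_sum(self):
        rng = np.random.default_rng(10)
        s = random_dna(rng, 900)
        frags = [
            NucSequence("a", s[:400]),
            NucSequence("b", s[330:700]),  # 70-nt overlap with a
            NucSequence("c", s[640:]),  # 60-nt overlap with b
        ]
        before = sum(len(f) for f in frags)
        out, log = join_blunt_overlaps(frags, 50)
        after = sum(len(f) for f in out)
        assert before - after == sum(ov for _, _, ov in log) == 130
        assert len(out) == 1


class TestIsoformClustering:
    def test_shared_exon_clusters(self):
        rng = np.random.default_rng(11)
        exon = random_dna(rng, 500)
        iso1 = NucSequence("iso1", exon + random_dna(rng, 300))
        iso2 = NucSequence("iso2", random_dna(rng, 200) + exon)
        clusters, reps = cluster_isoforms_select_representative([iso1, iso2])
        assert len(clusters) == 1

    def test_short_overlap_splits(self):
        """95% identity over only 90 nt does not link isoforms."""
        rng = np.random.default_rng(12)
        shared = random_dna(rng, 90)
        iso1 = NucSequence("iso1", shared + random_dna(rng, 400))
        iso2 = NucSequence("iso2", random_dna(rng, 400) + shared)
        clusters, _ = cluster_isoforms_select_representative(
            [iso1, iso2], min_overlap_nt=100
        )
        assert len(clusters) == 2

    def test_representative_is_largest_orf(self, small_genome):
        full = NucSequence("full", small_genome.transcript_seq(small_genome.genes[0]))
        frag = NucSequence("frag", full.seq[: len(full.seq) // 2])
        longer_junk = NucSequence("junk", frag.seq + "T" * 40)
        clusters, reps = cluster_isoforms_select_representative(
            [frag, full, longer_junk]
        )
        assert len(clusters) == 1
        assert clusters[0].representative_id == "full"


@pytest.fixture(scope="module")
def pipeline_run(medium_genome):
    sets, truth = simulate_assembled_transcripts(
        medium_genome, 15, frag_prob=0.4, chimera_rate=0.1, chimera_in=("asmB",)
    )
    idx = ProteinIndex(medium_genome.protein_seqs())
    result = curate(sets, idx, medium_genome.scaffolds, chimera_labels=("asmB",))
    return sets, truth, idx, result


class TestPipelineInvariants:
    def test_monotone_shrinkage(self, pipeline_run):
        sets, truth, idx, result = pipeline_run
        n_oriented = sum(len(v) for v in result["oriented_sets"].values())
        assert n_oriented >= len(result["merged"]) >= len(result["joined"]) >= len(
            result["representatives"]
        )

    def test_idempotence(self, medium_genome, pipeline_run):
        """Re-running curation on its own output changes nothing."""
        sets, truth, idx, result = pipeline_run
        reps = result["representatives"]
        rerun = curate({"final": reps}, idx, medium_genome.scaffolds)
        assert sorted(t.id for t in rerun["representatives"]) == sorted(
            t.id for t in reps
        )
        rep_seqs = {t.id: t.seq for t in reps}
        for t in rerun["representatives"]:
            assert t.seq == rep_seqs[t.id]

    def test_input_strand_invariance(self, medium_genome, pipeline_run):
        """Reverse-complementing every input transcript leaves the final
        representative set identical up to strand normalization."""
        sets, truth, idx, result = pipeline_run
        flipped = {
            label: [t.reverse_complement() for t in ts] for label, ts in sets.items()
        }
        result2 = curate(flipped, idx, medium_genome.scaffolds, chimera_labels=("asmB",))
        s1 = sorted(t.seq for t in result["representatives"])
        s2 = sorted(t.seq for t in result2["representatives"])
        assert s1 == s2

    def test_orientation_recovery(self, pipeline_run):
        sets, truth, idx, result = pipeline_run
        tt = truth.set_index("transcript_id")
        called = correct = 0
        for label, calls in result["orientation_calls"].items():
            for call in calls:
                if call.consensus in "+-" and not tt.loc[call.transcript_id, "is_chimera"]:
                    called += 1
                    correct += call.consensus == tt.loc[call.transcript_id, "emitted_strand"]
        assert called > 0
        assert correct / called >= 0.99
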