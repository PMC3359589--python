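"""Variant calling, filters, rates, distances and neighbor joining."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cannaseq.variants import (
    StrainPileup,
    _pair_table,
    concatenate_variant_sequences,
    filter_variants,
    heterozygosity_rate,
    mcl_distance,
    mrd_per_transcript,
    neighbor_joining,
    pairwise_snv_rate,
    pileup_and_call,
    write_mask_bed,
    write_vcf,
)
from cannaseq.seqcore import NucSequence

from conftest import random_dna


# ---------------------------------------------------------------------------
# Caller with hand-built pileups
# ---------------------------------------------------------------------------

def make_pileup(strain, ref, site_counts):
    """site_counts: {pos: {base: n}} over a single scaffold 'sc'."""
    L = len(ref)
    counts = np.zeros((4, L), dtype=np.int32)
    code = {b: i for i, b in enumerate("ACGT")}
    for pos, bases in site_counts.items():
        for b, n in bases.items():
            counts[code[b], pos] = n
    return StrainPileup(strain, {"sc": counts}, {"sc": counts.sum(axis=0).astype(np.int32)})


def genotype_posterior_oracle(ref_n, alt_n, e=0.01):
    """Direct enumeration of the binomial-error genotype likelihoods."""
    p_alt = {"RR": e / 3, "RA": 0.5 * (1 - e) + 0.5 * e / 3, "AA": 1 - e}
    liks = {}
    for g, pa in p_alt.items():
        pr = {"RR": 1 - e, "RA": 0.5 * (1 - e) + 0.5 * e / 3, "AA": e / 3}[g]
        liks[g] = (pa ** alt_n) * (pr ** ref_n)
    total = sum(liks.values())
    return {g: v / total for g, v in liks.items()}


class TestCaller:
    def _ref(self, rng, L=60):
        return {"sc": random_dna(rng, L)}

    def test_balanced_site_called_het(self):
        rng = np.random.default_rng(0)
        ref = self._ref(rng)
        pos, rb = 10, ref["sc"][10]
        alt = "A" if rb != "A" else "C"
        p1 = make_pileup("s1", ref["sc"], {pos: {rb: 5, alt: 5}})
        p2 = make_pileup("s2", ref["sc"], {pos: {rb: 10}})
        cs = pileup_and_call([p1, p2], ref)
        assert len(cs.calls) == 1
        row = cs.calls.iloc[0]
        assert row.gt_s1 == "RA" and row.gt_s2 == "RR"
        assert row.alt == alt

    def test_all_reference_no_call(self):
        rng = np.random.default_rng(1)
        ref = self._ref(rng)
        pileups = [
            make_pileup(s, ref["sc"], {7: {ref["sc"][7]: 12}}) for s in ("a", "b")
        ]
        cs = pileup_and_call(pileups, ref)
        assert cs.calls.empty

    def test_homozygous_alt_high_quality(self):
        rng = np.random.default_rng(2)
        ref = self._ref(rng)
        rb = ref["sc"][20]
        alt = "G" if rb != "G" else "T"
        p1 = make_pileup("a", ref["sc"], {20: {alt: 10}})
        p2 = make_pileup("b", ref["sc"], {20: {rb: 10}})
        cs = pileup_and_call([p1, p2], ref)
        row = cs.calls.iloc[0]
        assert row.gt_a == "AA"
        assert row.qual > 30

    def test_single_strain_rejected(self):
        rng = np.random.default_rng(3)
        ref = self._ref(rng)
        with pytest.raises(ValueError):
            pileup_and_call([make_pileup("a", ref["sc"], {})], ref)

    @pytest.mark.parametrize("e", [0.01, 0.005])
    def test_posteriors_match_enumeration_oracle(self, e):
        """For all (ref_n, alt_n) with total depth <= 12 the caller's most
        likely genotype and RR posterior match exhaustive enumeration."""
        rng = np.random.default_rng(4)
        ref = self._ref(rng, 400)
        cases = [
            (r, a)
            for r, a in itertools.product(range(13), repeat=2)
            if 0 < r + a <= 12 and a > 0
        ]
        site_counts_1 = {}
        alts = {}
        for i, (r, a) in enumerate(cases):
            pos = i * 2 + 1
            rb = ref["sc"][pos]
            alt = "A" if rb != "A" else "C"
            site_counts_1[pos] = {rb: r, alt: a}
            alts[pos] = (r, a)
        p1 = make_pileup("x", ref["sc"], site_counts_1)
        p2 = make_pileup("y", ref["sc"],
                         {pos: {ref["sc"][pos]: 10} for pos in site_counts_1})
        cs = pileup_and_call([p1, p2], ref, error_rate=e)
        called = cs.calls.set_index("pos")
        for pos, (r, a) in alts.items():
            oracle = genotype_posterior_oracle(r, a, e)
            ml = max(oracle, key=oracle.get)
            if ml == "RR":
                assert pos not in called.index
            else:
                assert pos in called.index
                assert called.loc[pos, "gt_x"] == ml
                # site quality: -10 log10 of the joint all-RR posterior
                oracle_y = genotype_posterior_oracle(10, 0, e)
                expect_q = -10 * (
                    math.log10(oracle["RR"]) + math.log10(oracle_y["RR"])
                )
                assert called.loc[pos, "qual"] == pytest.approx(expect_q, rel=1e-6)


class TestFilters:
    def _callset(self, qual, depths, ref_len=200):
        rng = np.random.default_rng(5)
        ref = {"sc": random_dna(rng, ref_len)}
        rb = ref["sc"][50]
        alt = "A" if rb != "A" else "C"
        pileups = []
        for s, d in depths.items():
            # uniform coverage d everywhere; alt reads at site 50 for strain 1
            counts = np.zeros((4, ref_len), dtype=np.int32)
            code = {b: i for i, b in enumerate("ACGT")}
            for pos in range(ref_len):
                counts[code[ref["sc"][pos]], pos] = d
            if s == "s1":
                counts[code[rb], 50] = 0
                counts[code[alt], 50] = d
            pileups.append(StrainPileup(s, {"sc": counts},
                                        {"sc": counts.sum(axis=0).astype(np.int32)}))
        cs = pileup_and_call(pileups, ref)
        if qual is not None and len(cs.calls):
            cs.calls.loc[:, "qual"] = qual
        return cs

    def test_quality_29_removed(self):
        cs = self._callset(qual=29.0, depths={"s1": 10, "s2": 10})
        filtered, mask = filter_variants(cs)
        assert filtered.empty

    def test_depth_4_in_one_strain_removed(self):
        cs = self._callset(qual=None, depths={"s1": 10, "s2": 4})
        filtered, mask = filter_variants(cs)
        assert filtered.empty
        assert mask["sc"].sum() == 0  # callable region needs >= 5 everywhere

    def test_total_depth_151_removed(self):
        cs = self._callset(qual=None, depths={"s1": 80, "s2": 71})
        filtered, mask = filter_variants(cs)
        assert filtered.empty
        cs2 = self._callset(qual=None, depths={"s1": 80, "s2": 70})
        filtered2, mask2 = filter_variants(cs2)
        assert len(filtered2) == 1
        assert mask2["sc"].all()

    def test_vcf_and_bed_roundtrip(self, tmp_path):
        cs = self._callset(qual=None, depths={"s1": 10, "s2": 10})
        filtered, mask = filter_variants(cs)
        vcf = tmp_path / "out.vcf"
        bed = tmp_path / "mask.bed"
        write_vcf(filtered, cs.strains, vcf)
        write_mask_bed(mask, bed)
        lines = [l for l in vcf.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == 1
        chrom, pos, _, ref, alt, qual, *_rest = lines[0].split("\t")
        assert (chrom, pos) == ("sc", "51")  # VCF is 1-based
        assert bed.read_text() == "sc\t0\t200\n"


class TestRates:
    def _two_strain_calls(self):
        df = pd.DataFrame(
            {
                "scaffold": ["sc"] * 4,
                "pos": [3, 9, 14, 20],
                "ref": list("ACGT"),
                "alt": list("GTAC"),
                "qual": [99.0] * 4,
                "gt_a": ["RA", "RR", "AA", "RA"],
                "gt_b": ["RR", "RR", "AA", "AA"],
                "dp_a": [10] * 4,
                "dp_b": [10] * 4,
                "ad_a": [(6, 4), (10, 0), (0, 10), (4, 6)],
                "ad_b": [(10, 0), (10, 0), (0, 10), (0, 10)],
            }
        )
        mask = {"sc": np.ones(100, dtype=bool)}
        return df, mask

    def test_heterozygosity_rate(self):
        df, mask = self._two_strain_calls()
        assert heterozygosity_rate(df, mask, "a") == pytest.approx(2.0)
        assert heterozygosity_rate(df, mask, "b") == pytest.approx(0.0)

    def test_pairwise_symmetric(self):
        df, mask = self._two_strain_calls()
        r1 = pairwise_snv_rate(df, mask, "a", "b")
        r2 = pairwise_snv_rate(df, mask, "b", "a")
        assert r1 == r2 == pytest.approx(2.0)  # sites 3 and 20 differ

    def test_identical_strains_zero(self):
        df, mask = self._two_strain_calls()
        df["gt_b"] = df["gt_a"]
        assert pairwise_snv_rate(df, mask, "a", "b") == 0.0

    def test_empty_mask_error(self):
        df, _ = self._two_strain_calls()
        with pytest.raises(ValueError):
            heterozygosity_rate(df, {"sc": np.zeros(5, dtype=bool)}, "a")


class TestConcatenation:
    def test_pseudo_sequences(self):
        df = pd.DataFrame(
            {
                "scaffold": ["sc"] * 3,
                "pos": [5, 1, 9],
                "ref": ["A", "C", "G"],
                "alt": ["G", "T", "A"],
                "qual": [99.0] * 3,
                "gt_a": ["RR", "AA", "RA"],
                "gt_b": ["RR", "RR", "RR"],
                "ad_a": [(9, 0), (0, 9), (2, 7)],
                "ad_b": [(9, 0), (9, 0), (9, 0)],
                "dp_a": [9] * 3,
                "dp_b": [9] * 3,
            }
        )
        seqs = concatenate_variant_sequences(df, ["a", "b"])
        # ordered by (scaffold,pos): 1,5,9; het site 9 takes the majority (alt)
        assert seqs["a"] == "TAA"
        assert seqs["b"] == "CAG"
        assert len(set(map(len, seqs.values()))) == 1

    def test_order_invariance(self):
        df = pd.DataFrame(
            {
                "scaffold": ["sc"] * 4,
                "pos": [7, 2, 30, 11],
                "ref": list("ACGT"),
                "alt": list("GTAC"),
                "qual": [99.0] * 4,
                "gt_a": ["AA", "RR", "AA", "RR"],
                "ad_a": [(0, 9)] * 4,
                "dp_a": [9] * 4,
            }
        )
        s1 = concatenate_variant_sequences(df, ["a"])
        s2 = concatenate_variant_sequences(df.sample(frac=1, random_state=3), ["a"])
        assert s1 == s2


class TestMclDistance:
    def tn93_closed_form(self, a, b):
        T = _pair_table(a, b).astype(float)
        n = T.sum()
        pi = (T.sum(0) + T.sum(1)) / (2 * n)
        pa, pc, pg, pt = pi
        pr, py = pa + pg, pc + pt
        P1 = (T[0, 2] + T[2, 0]) / n
        P2 = (T[1, 3] + T[3, 1]) / n
        Q = (T.sum() - np.trace(T)) / n - P1 - P2
        k1 = 2 * pa * pg / pr
        k2 = 2 * pt * pc / py
        k3 = 2 * (pr * py - pa * pg * py / pr - pt * pc * pr / py)
        w1 = 1 - P1 / k1 - Q / (2 * pr)
        w2 = 1 - P2 / k2 - Q / (2 * py)
        w3 = 1 - Q / (2 * pr * py)
        return -k1 * np.log(w1) - k2 * np.log(w2) - k3 * np.log(w3)

    def test_identical_zero(self):
        s = random_dna(np.random.default_rng(0), 500)
        assert mcl_distance(s, s) == 0.0

    def test_jukes_cantor_limit(self):
        """Under uniform substitution at p=0.1 the distance approaches the
        JC closed form -(3/4)ln(1-4p/3)."""
        rng = np.random.default_rng(1)
        n = 30000
        a = rng.integers(0, 4, n)
        b = a.copy()
        mask = rng.random(n) < 0.1
        b[mask] = (b[mask] + rng.integers(1, 4, mask.sum())) % 4
        sa = "".join("ACGT"[i] for i in a)
        sb = "".join("ACGT"[i] for i in b)
        d = mcl_distance(sa, sb)
        jc = -0.75 * np.log(1 - 4 * 0.1 / 3)
        assert abs(d - jc) / jc < 0.05

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_tn93_closed_form(self, seed):
        """Numerical composite-likelihood maximization agrees with the TN93
        closed-form estimate to 1e-6."""
        rng = np.random.default_rng(seed)
        n = 20000
        freqs = rng.dirichlet([8, 5, 6, 7])
        a = rng.choice(4, n, p=freqs)
        b = a.copy()
        ts_map = np.array([2, 3, 0, 1])
        m1 = rng.random(n) < 0.06
        b[m1] = ts_map[b[m1]]
        m2 = (rng.random(n) < 0.02) & ~m1
        for i in np.where(m2)[0]:
            tv = [j for j in range(4) if j != b[i] and j != ts_map[b[i]]]
            b[i] = tv[rng.integers(0, 2)]
        sa = "".join("ACGT"[i] for i in a)
        sb = "".join("ACGT"[i] for i in b)
        assert mcl_distance(sa, sb) == pytest.approx(
            self.tn93_closed_form(sa, sb), abs=1e-6
        )

    def test_symmetry_and_monotonicity(self):
        rng = np.random.default_rng(5)
        n = 20000
        a = rng.integers(0, 4, n)
        prev = -1.0
        for p in (0.001, 0.005, 0.01, 0.02):
            b = a.copy()
            mask = rng.random(n) < p
            b[mask] = (b[mask] + rng.integers(1, 4, mask.sum())) % 4
            sa = "".join("ACGT"[i] for i in a)
            sb = "".join("ACGT"[i] for i in b)
            d_ab = mcl_distance(sa, sb)
            assert d_ab == pytest.approx(mcl_distance(sb, sa), abs=1e-9)
            assert d_ab > prev
            prev = d_ab

    def test_saturation_error(self):
        # every aligned pair is an A<->G transition: the purine-transition
        # log argument is non-positive and the distance is undefined
        a = "A" * 1000 + "G" * 1000
        b = "G" * 1000 + "A" * 1000
        with pytest.raises(ValueError, match="saturation"):
            mcl_distance(a, b)


class TestNeighborJoining:
    def additive_matrix(self):
        # ((A:1,B:2):3,(C:4,D:5):0) style additive tree
        labels = list("ABCD")
        D = pd.DataFrame(0.0, index=labels, columns=labels)
        d = {
            ("A", "B"): 3, ("A", "C"): 8, ("A", "D"): 9,
            ("B", "C"): 9, ("B", "D"): 10, ("C", "D"): 9,
        }
        for (i, j), v in d.items():
            D.loc[i, j] = D.loc[j, i] = v
        return D

    def test_additive_tree_recovered(self):
        tree, log = neighbor_joining(self.additive_matrix())
        assert log == []
        # A,B must be cherries with branch lengths 1 and 2
        assert "(A:1,B:2)" in tree or "(B:2,A:1)" in tree

    def test_three_taxa_closed_form(self):
        labels = list("XYZ")
        D = pd.DataFrame(
            [[0, 5, 9], [5, 0, 10], [9, 10, 0]], index=labels, columns=labels,
            dtype=float,
        )
        tree, log = neighbor_joining(D)
        # closed form: x=(5+9-10)/2=2, y=(5+10-9)/2=3, z=(9+10-5)/2=7
        assert "X:2" in tree and "Y:3" in tree and "Z:7" in tree

    def test_matches_skbio(self):
        """Cross-check topology and branch lengths against scikit-bio's NJ."""
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj

        rng = np.random.default_rng(7)
        n = 6
        # random additive tree distances via random positive branch caterpillar
        base = rng.uniform(0.05, 0.5, size=(n, n))
        D = (base + base.T) / 2
        np.fill_diagonal(D, 0.0)
        labels = [f"t{i}" for i in range(n)]
        dm = pd.DataFrame(D, index=labels, columns=labels)
        ours, _ = neighbor_joining(dm)
        theirs = nj(SkDM(D, labels))
        import dendropy

        taxa = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=ours, schema="newick", taxon_namespace=taxa)
        t2 = dendropy.Tree.get(data=str(theirs).strip(), schema="newick",
                               taxon_namespace=taxa)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        rf = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
        assert rf == 0

    def test_asymmetric_rejected(self):
        D = pd.DataFrame(
            [[0, 1, 2], [1.5, 0, 2], [2, 2, 0]], index=list("abc"),
            columns=list("abc"), dtype=float,
        )
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(D)

    def test_negative_branch_clamped(self):
        labels = list("abcd")
        D = pd.DataFrame(0.0, index=labels, columns=labels)
        vals = {("a", "b"): 0.1, ("a", "c"): 0.3, ("a", "d"): 0.35,
                ("b", "c"): 0.35, ("b", "d"): 0.3, ("c", "d"): 0.05}
        for (i, j), v in vals.items():
            D.loc[i, j] = D.loc[j, i] = v
        tree, log = neighbor_joining(D)
        assert ":-" not in tree  # no negative branch lengths serialized


class TestMrd:
    def test_zero_reads_zero_mrd(self):
        rng = np.random.default_rng(8)
        t = NucSequence("t", random_dna(rng, 300))
        out = mrd_per_transcript([], [t])
        assert out["t"].mrd == 0.0

    def test_short_transcript_flagged(self):
        t = NucSequence("t", "ACGTACGTAC")
        out = mrd_per_transcript([], [t], trim_to=32)
        assert out["t"].mrd is None

    def test_trim_to_32_depth_pattern(self):
        """Reads longer than 32 nt contribute exactly 32 bases of depth."""
        rng = np.random.default_rng(9)
        t = NucSequence("t", random_dna(rng, 200))
        read = t.seq[50:150]  # 100-nt read
        out = mrd_per_transcript([read], [t], trim_to=32)
        depth = out["t"].depth
        assert depth[50:82].sum() == 32  # only the first 32 bases counted
        assert depth.sum() == 32

    def test_duplication_recovery(self):
        """A planted single extra copy in one strain yields log2 MRD ratio of
        about 1 for the duplicated gene and about 0 elsewhere."""
        from cannaseq.pipelines import recover_duplication_mrd

        r = recover_duplication_mrd(1)
        assert abs(r["log2_mrd_duplicated"] - 1.0) <= 0.3
        assert abs(r["median_log2_mrd_background"]) <= 0.15
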