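"""Seed extraction, site scanning and family grouping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirisc_shift.io import GeneModel
from mirisc_shift.seedmatch import (
    EclipPeak, Mirna, SeedFamily, annotate_peaks, genome_to_utr, group_families,
    revcomp_dna, seed_of, site_match, sites_for_seed, utr_site_peak_counts,
)

from _oracles import oracle_sites

LET7A = "UGAGGUAGUAGGUUGUAUAGUU"

dna = st.text(alphabet="ACGT", min_size=30, max_size=120)
rna22 = st.text(alphabet="ACGU", min_size=22, max_size=22)


class TestSeedOf:
    def test_slice_convention(self):
        assert seed_of("UGAGGUAGUAGGUUGU") == "GAGGUAG"

    def test_too_short(self):
        with pytest.raises(ValueError):
            seed_of("UGAGGUA")

    def test_dna_input_normalized(self):
        assert seed_of("TGAGGTAGTAGGTTGT") == "GAGGUAG"

    @given(rna22, st.text(alphabet="ACGU", min_size=0, max_size=30))
    @settings(max_examples=50, derandomize=True)
    def test_depends_only_on_first_eight(self, seq, extension):
        assert seed_of(seq + extension) == seed_of(seq)

    @given(rna22)
    @settings(max_examples=50, derandomize=True)
    def test_equals_independent_indexing(self, seq):
        # independent oracle: 1-based character indexing
        assert seed_of(seq) == "".join(seq[i - 1] for i in range(2, 9))


class TestSiteMatch:
    mir = Mirna("let-7a", LET7A)  # seed GAGGUAG

    @pytest.mark.parametrize(
        "insert,expected_type",
        [("CTACCTCA", "8mer"), ("CTACCTCG", "7mer-m8"), ("GTACCTCA", "7mer-A1")],
    )
    def test_constructed_sites(self, insert, expected_type):
        utr = "GGGG" + insert + "GGGG"
        sites = site_match(utr, self.mir)
        assert [s.site_type for s in sites] == [expected_type]
        assert sites[0].start >= 4

    def test_no_match_in_g_run(self):
        assert site_match("G" * 40, self.mir) == []

    def test_ambiguous_bases_never_match(self):
        utr = "GGGG" + "CTACCTCA".replace("T", "N", 1) + "GGGG"
        assert site_match(utr, self.mir) == []

    def test_case_and_ut_invariance(self):
        utr = "ggggCTacctcagggg".replace("T", "u", 1)
        sites = site_match(utr, self.mir)
        assert len(sites) == 1 and sites[0].site_type == "8mer"

    def test_interval_lengths_match_types(self):
        utr = "GGCTACCTCAGGCTACCTCGGGTACCTCAGG"
        for s in site_match(utr, self.mir):
            assert s.end - s.start == (8 if s.site_type == "8mer" else 7)

    def test_matches_bruteforce_oracle_on_random_pairs(self):
        rng = np.random.default_rng(123)
        for _ in range(300):
            utr = "".join(rng.choice(list("ACGT"), size=rng.integers(30, 200)))
            mir = Mirna("m", "".join(rng.choice(list("ACGU"), size=22)))
            got = [(s.start, s.end, s.site_type) for s in site_match(utr, mir)]
            assert got == oracle_sites(utr, mir.sequence)

    @given(dna, rna22)
    @settings(max_examples=100, derandomize=True)
    def test_reported_sites_repair_base_by_base(self, utr, mir_seq):
        """Every reported site re-checks antiparallel Watson-Crick pairing."""
        pair = {"A": "T", "C": "G", "G": "C", "U": "A"}
        mir = Mirna("m", mir_seq)
        offsets = set()
        for s in site_match(utr, mir):
            assert s.start not in offsets  # one type per offset
            offsets.add(s.start)
            seg = utr.upper()[s.start:s.end]
            if s.site_type == "8mer":
                assert seg[7] == "A"
                core, top = seg[:7], 8
            elif s.site_type == "7mer-m8":
                core, top = seg, 8
            else:
                assert seg[6] == "A"
                core, top = seg[:6], 7
            for k, ch in enumerate(core):
                assert pair[mir.sequence[top - k - 1]] == ch


class TestGroupFamilies:
    def two_member_setup(self):
        m1 = Mirna("a", "U" + "GAGGUAG" + "A" * 12)
        m2 = Mirna("b", "C" + "GAGGUAG" + "C" * 12)
        counts = pd.DataFrame({"s1": [10, 5]}, index=["a", "b"])
        counts["s1"] = (counts["s1"] * 1e5).astype(int)  # lib 1.5e6
        return [m1, m2], counts

    def test_same_seed_cpm_adds(self):
        mirnas, counts = self.two_member_setup()
        fams = group_families(mirnas, counts)
        assert len(fams) == 1
        fam = fams[0]
        assert fam.seed == "GAGGUAG" and fam.members == ["a", "b"]
        assert fam.expression_cpm["s1"] == pytest.approx(1e6)

    def test_all_distinct_seeds(self):
        mirnas = [Mirna(f"m{i}", "U" + s + "A" * 12)
                  for i, s in enumerate(["AAAAAAA", "CCCCCCC", "GGGGGGG"])]
        assert len(group_families(mirnas)) == 3

    def test_counts_missing_from_fasta_excluded(self, caplog):
        mirnas, counts = self.two_member_setup()
        counts.loc["ghost"] = 999
        fams = group_families(mirnas, counts)
        assert all("ghost" not in f.members for f in fams)

    def test_recovers_planted_families(self, small_sim):
        mirnas = [Mirna(n, s) for n, s in small_sim.mirnas.items()]
        fams = group_families(mirnas, small_sim.smallrna)
        got = {f.seed: sorted(f.members) for f in fams}
        want = {s: sorted(m) for s, m in small_sim.truth.family_members.items()}
        assert got == want

    def test_ranking_matches_planted_abundance(self, small_sim):
        mirnas = [Mirna(n, s) for n, s in small_sim.mirnas.items()]
        fams = group_families(mirnas, small_sim.smallrna, top_k=10)
        assert [f.seed for f in fams] == small_sim.truth.top_family_seeds[:10]


class TestAnnotatePeaks:
    def _gene(self, strand="+"):
        # exon1 0..100, intron 100..200, exon2 200..400 with UTR 300..400 (+)
        if strand == "+":
            return GeneModel("G1", "c", 0, 400, "+", [(0, 100), (200, 400)], (300, 400))
        return GeneModel("G1", "c", 0, 400, "-", [(0, 200), (300, 400)], (0, 100))

    def test_intronic_peak_has_no_sites(self):
        gene = self._gene()
        genome = {"c": "G" * 400}
        peaks = pd.DataFrame(
            [["c", 110, 160, "G1", 0, "+", "cyto"]],
            columns=["chrom", "start", "end", "name", "score", "strand", "compartment"],
        )
        fam = [SeedFamily(seed="GAGGUAG", members=["m"])]
        out = annotate_peaks(peaks, [gene], {"G1": gene.utr_sequence(genome)}, fam)
        assert out[0].region == "intron" and out[0].sites == []

    def test_unannotated_gene_skipped(self):
        peaks = pd.DataFrame(
            [["c", 0, 10, "NOPE", 0, "+", "cyto"]],
            columns=["chrom", "start", "end", "name", "score", "strand", "compartment"],
        )
        assert annotate_peaks(peaks, [self._gene()], {}, []) == []

    def test_minus_strand_equals_plus_on_revcomp_utr(self):
        """A site found on a minus-strand gene appears at the position that
        plus-strand scanning of the reverse-complemented UTR predicts."""
        motif = "CTACCTCA"  # 8mer for seed GAGGUAG
        fam = [SeedFamily(seed="GAGGUAG", members=["m"])]
        utr_fwd = "G" * 20 + motif + "G" * 72  # 100 nt, site at offset 20

        plus = self._gene("+")
        genome_plus = {"c": "A" * 300 + utr_fwd}
        minus = self._gene("-")
        genome_minus = {"c": revcomp_dna(utr_fwd) + "A" * 300}
        assert minus.utr_sequence(genome_minus) == utr_fwd

        def scan(gene, genome, start, end):
            peaks = pd.DataFrame(
                [[gene.chrom, start, end, "G1", 0, gene.strand, "cyto"]],
                columns=["chrom", "start", "end", "name", "score", "strand", "compartment"],
            )
            return annotate_peaks(peaks, [gene], {"G1": gene.utr_sequence(genome)}, fam)[0]

        pk_plus = scan(plus, genome_plus, 300, 400)
        pk_minus = scan(minus, genome_minus, 0, 100)
        assert [(s.start, s.end, s.site_type) for s in pk_plus.sites] == [
            (s.start, s.end, s.site_type) for s in pk_minus.sites
        ] == [(20, 28, "8mer")]

    def test_genome_to_utr_strandedness(self):
        plus, minus = self._gene("+"), self._gene("-")
        assert genome_to_utr(310, 330, plus) == (10, 30)
        assert genome_to_utr(10, 30, minus) == (70, 90)

    def test_recovers_planted_sites(self, small_sim):
        mirnas = [Mirna(n, s) for n, s in small_sim.mirnas.items()]
        fams = group_families(mirnas, small_sim.smallrna, top_k=20)
        out = annotate_peaks(small_sim.peaks, small_sim.annotation.genes,
                             small_sim.annotation.utr_seqs(), fams)
        tallies = utr_site_peak_counts(out)
        for gid, planted in small_sim.truth.planted_peaks.items():
            assert tallies.get(gid, 0) >= len(planted)

    def test_sites_lie_within_peaks(self, small_sim):
        mirnas = [Mirna(n, s) for n, s in small_sim.mirnas.items()]
        fams = group_families(mirnas, small_sim.smallrna, top_k=20)
        by_id = {g.gene_id: g for g in small_sim.annotation.genes}
        for pk in annotate_peaks(small_sim.peaks, small_sim.annotation.genes,
                                 small_sim.annotation.utr_seqs(), fams):
            if pk.region != "3'UTR":
                continue
            us, ue = genome_to_utr(pk.start, pk.end, by_id[pk.gene_id])
            for s in pk.sites:
                assert us <= s.start and s.end <= ue
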