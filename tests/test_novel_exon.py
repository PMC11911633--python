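import numpy as np
import pytest

from neoexon.core import (
    CoverageTrack,
    GeneAnnotation,
    GenomeSequence,
    Interval,
    reverse_complement,
)
from neoexon.novel_exon import (
    NovelExonCandidate,
    ThresholdConfig,
    cross_species_identity,
    filter_candidates,
    find_new_boundary_exons,
    flanking_exon_ratio,
    funnel_counts,
    intronic_background,
    mean_exon_coverage,
    orf_consequence,
    splice_site_check,
)

from conftest import make_transcript


def reference_one_gene(strand="+"):
    """One gene, two exons [100,200) and [800,900), intron [200,800)."""
    ann = GeneAnnotation()
    ann.add_transcript(make_transcript("ref.t1", "host", [(100, 200), (800, 900)], strand))
    return ann


def candidate(start, end, strand="+", host="host", intron=(200, 800)):
    return NovelExonCandidate(
        interval=Interval("chr1", start, end, strand),
        host_gene=host,
        transcript_id="asm.t1",
        boundary_status="both_new",
        fully_novel=True,
        host_intron=Interval("chr1", *intron, strand) if intron else None,
    )


class TestNewBoundaryDetection:
    def assembled(self, exons, strand="+"):
        ann = GeneAnnotation()
        ann.add_transcript(make_transcript("asm.t1", "asm_host", exons, strand))
        return ann

    def test_known_exon_not_a_candidate(self):
        ref = reference_one_gene()
        asm = self.assembled([(100, 200), (800, 900)])
        assert find_new_boundary_exons(asm, ref) == []

    def test_intronic_exon_is_fully_novel(self):
        ref = reference_one_gene()
        asm = self.assembled([(100, 200), (400, 462), (800, 900)])
        cands = find_new_boundary_exons(asm, ref)
        assert len(cands) == 1
        c = cands[0]
        assert c.boundary_status == "both_new"
        assert c.fully_novel
        assert (c.host_intron.start, c.host_intron.end) == (200, 800)

    def test_boundary_extension_is_one_new(self):
        ref = reference_one_gene()
        # middle exon shares the annotated start 100 but ends 30 nt late
        asm = self.assembled([(0, 50), (100, 230), (800, 900)])
        cands = find_new_boundary_exons(asm, ref)
        assert len(cands) == 1
        assert cands[0].boundary_status == "one_new"
        assert not cands[0].fully_novel

    def test_terminal_exons_skipped(self):
        ref = reference_one_gene()
        asm = self.assembled([(300, 362), (800, 900)])  # novel exon is terminal
        assert find_new_boundary_exons(asm, ref) == []

    def test_intergenic_exon_excluded(self):
        ref = reference_one_gene()
        asm = self.assembled([(5000, 5100), (5300, 5400), (5800, 5900)])
        assert find_new_boundary_exons(asm, ref) == []

    def test_opposite_strand_gene_not_a_host(self):
        ref = reference_one_gene(strand="-")
        asm = self.assembled([(100, 200), (400, 462), (800, 900)], strand="+")
        assert find_new_boundary_exons(asm, ref) == []

    def test_identical_annotations_yield_nothing(self, sim):
        assert find_new_boundary_exons(sim.reference, sim.reference) == []


class TestCoverageFilters:
    def track(self, depths):
        return CoverageTrack({"chr1": np.asarray(depths, dtype=float)})

    def test_uniform_mean(self):
        t = self.track([7.0] * 1000)
        assert mean_exon_coverage(Interval("chr1", 10, 60), t) == 7.0

    def test_two_base_mean(self):
        t = self.track([0.0, 10.0] + [0.0] * 98)
        assert mean_exon_coverage(Interval("chr1", 0, 2), t) == 5.0

    def test_hand_written_track_mean(self, rng):
        depths = np.zeros(1000)
        depths[400:462] = rng.integers(0, 30, 62)
        t = self.track(depths)
        assert mean_exon_coverage(Interval("chr1", 400, 462), t) == pytest.approx(
            depths[400:462].mean()
        )

    def test_flat_intron_background(self):
        depths = np.zeros(1000)
        depths[200:800] = 2.0
        ref = reference_one_gene()
        bg = intronic_background(candidate(400, 462), self.track(depths), ref)
        assert bg == pytest.approx(2.0)

    def test_window_clipped_to_intron(self):
        # candidate 10 nt from the intron end: downstream window is 10 nt
        depths = np.zeros(1000)
        depths[200:790] = 1.0   # upstream-side intron
        depths[790:800] = 9.0   # the short downstream side
        ref = reference_one_gene()
        bg = intronic_background(candidate(728, 790), self.track(depths), ref)
        # pooled: 200 nt at depth 1 upstream + 10 nt at depth 9 downstream
        assert bg == pytest.approx((200 * 1.0 + 10 * 9.0) / 210)

    def test_exons_masked_out_of_windows(self):
        depths = np.zeros(1000)
        depths[200:800] = 1.0
        depths[300:350] = 50.0  # an annotated exon inside the upstream window
        ref = reference_one_gene()
        ref.add_transcript(make_transcript("ref.t2", "host2", [(150, 250), (300, 350)]))
        bg = intronic_background(candidate(400, 462), self.track(depths), ref, ref)
        assert bg == pytest.approx(1.0)

    def test_zero_background_uses_floor_in_ratio(self):
        depths = np.zeros(1000)
        depths[400:462] = 8.0
        ref = reference_one_gene()
        genome = GenomeSequence("chr1", "A" * 1000)
        cands = [candidate(400, 462)]
        filter_candidates(cands, self.track(depths), {"chr1": genome}, ref)
        assert cands[0].background_coverage == 0.0
        assert cands[0].background_ratio == pytest.approx(8.0 / 0.1)


def genome_with_sites(exon=(400, 462), donor="GT", acceptor="AG", strand="+"):
    seq = list("A" * 1000)
    s, e = exon
    if strand == "+":
        seq[s - 2 : s] = list(acceptor)
        seq[e : e + 2] = list(donor)
    else:
        seq[s - 2 : s] = list(reverse_complement(donor))
        seq[e : e + 2] = list(reverse_complement(acceptor))
    return GenomeSequence("chr1", "".join(seq))


class TestSpliceSites:
    def test_plus_strand_canonical(self):
        g = genome_with_sites()
        donor, acceptor, ok = splice_site_check(candidate(400, 462), g)
        assert (donor, acceptor, ok) == ("GT", "AG", True)

    def test_minus_strand_canonical_from_revcomp(self):
        g = genome_with_sites(strand="-")
        # genomically: AC left of exon, CT right of exon
        assert g.seq[398:400] == "AC" and g.seq[462:464] == "CT"
        donor, acceptor, ok = splice_site_check(candidate(400, 462, strand="-"), g)
        assert (donor, acceptor, ok) == ("GT", "AG", True)

    def test_gc_ag_not_canonical_by_default(self):
        g = genome_with_sites(donor="GC")
        donor, acceptor, ok = splice_site_check(candidate(400, 462), g)
        assert (donor, acceptor, ok) == ("GC", "AG", False)

    def test_gc_ag_accepted_when_configured(self):
        g = genome_with_sites(donor="GC")
        cfg = ThresholdConfig(canonical_pairs=frozenset({("GT", "AG"), ("GC", "AG")}))
        assert splice_site_check(candidate(400, 462), g, cfg)[2]

    def test_strand_consistency_under_genome_revcomp(self, rng):
        # reverse-complementing the genome and flipping coordinates/strand
        # must preserve the canonical flag
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1000)])
        g = GenomeSequence("chr1", seq)
        g_rc = GenomeSequence("chr1", reverse_complement(seq))
        n = len(seq)
        for start, end, strand in [(400, 462, "+"), (300, 366, "-"), (100, 200, "+")]:
            flipped = candidate(n - end, n - start, strand="-" if strand == "+" else "+")
            d1, a1, c1 = splice_site_check(candidate(start, end, strand), g)
            d2, a2, c2 = splice_site_check(flipped, g_rc)
            assert (d1, a1, c1) == (d2, a2, c2)


class TestFilterFunnel:
    def build(self, mean_cov, background, donor="GT", acceptor="AG"):
        depths = np.zeros(1000)
        depths[200:800] = background
        depths[400:462] = mean_cov
        ref = reference_one_gene()
        genome = genome_with_sites(donor=donor, acceptor=acceptor)
        cands = [candidate(400, 462)]
        filter_candidates(
            cands, CoverageTrack({"chr1": depths}), {"chr1": genome}, ref
        )
        return cands[0]

    def test_coverage_exactly_five_fails(self):
        c = self.build(5.0, 0.1)
        assert dict(c.filter_trail)["coverage"] is False
        assert not c.verdict

    def test_ratio_exactly_ten_passes(self):
        c = self.build(50.0, 5.0)
        assert c.background_ratio == pytest.approx(10.0)
        assert dict(c.filter_trail)["background_ratio"] is True

    def test_all_filters_pass(self):
        c = self.build(20.0, 1.0)
        assert c.verdict
        assert c.filter_trail == [
            ("coverage", True),
            ("background_ratio", True),
            ("canonical_sites", True),
        ]

    def test_trail_complete_after_first_failure(self):
        c = self.build(2.0, 0.1, donor="CC")
        assert [name for name, _ in c.filter_trail] == [
            "coverage",
            "background_ratio",
            "canonical_sites",
        ]
        assert not c.verdict

    def test_pass_count_monotone_in_thresholds(self, sim):
        genomes = {g.name: g for g in sim.genomes}
        prev_by_ratio = None
        for min_cov in (3.0, 5.0, 8.0):
            prev = None
            for min_ratio in (5.0, 10.0, 15.0):
                cands = find_new_boundary_exons(sim.assembled, sim.reference)
                cfg = ThresholdConfig(
                    min_mean_coverage=min_cov, min_background_ratio=min_ratio
                )
                filter_candidates(
                    cands, sim.pooled_coverage, genomes, sim.reference, cfg, sim.assembled
                )
                n_pass = sum(c.verdict for c in cands)
                if prev is not None:
                    assert n_pass <= prev
                prev = n_pass
            if prev_by_ratio is not None:
                assert prev <= prev_by_ratio
            prev_by_ratio = prev

    def test_funnel_counts_monotone(self, sim):
        genomes = {g.name: g for g in sim.genomes}
        cands = find_new_boundary_exons(sim.assembled, sim.reference)
        filter_candidates(
            cands, sim.pooled_coverage, genomes, sim.reference, ThresholdConfig(), sim.assembled
        )
        funnel = funnel_counts(cands)
        values = [
            funnel["new_boundary"],
            funnel["post_coverage"],
            funnel["post_background_ratio"],
            funnel["post_canonical_sites"],
        ]
        assert values == sorted(values, reverse=True)


class TestFlankingRatio:
    def track_with(self, exon_depth, left, right):
        depths = np.zeros(1000)
        depths[100:200] = left
        depths[800:900] = right
        depths[400:462] = exon_depth
        return CoverageTrack({"chr1": depths})

    def test_equal_flanks_give_unity(self):
        ref = reference_one_gene()
        r = flanking_exon_ratio(candidate(400, 462), self.track_with(30, 30, 30), ref)
        assert r == pytest.approx(1.0)

    def test_arithmetic_mean_of_flanks(self):
        ref = reference_one_gene()
        r = flanking_exon_ratio(candidate(400, 462), self.track_with(15, 20, 40), ref)
        assert r == pytest.approx(0.5)

    def test_uncovered_flanks_reported_missing(self):
        ref = reference_one_gene()
        r = flanking_exon_ratio(candidate(400, 462), self.track_with(15, 0, 0), ref)
        assert np.isnan(r)


class TestOrfConsequence:
    def build_coding(self, insert, exon1_len=60, exon2_len=60):
        """Two-exon CDS gene with `insert` planted mid-intron."""
        from neoexon.simulate import random_nonstop_codons

        rng = np.random.default_rng(11)
        total = exon1_len + exon2_len
        cds_seq = "ATG" + random_nonstop_codons(rng, total // 3 - 2) + "TAA"
        seq = list("A" * 2000)
        seq[100 : 100 + exon1_len] = list(cds_seq[:exon1_len])
        seq[800 : 800 + exon2_len] = list(cds_seq[exon1_len:])
        ins_start = 400
        seq[ins_start : ins_start + len(insert)] = list(insert)
        genome = GenomeSequence("chr1", "".join(seq))
        tx = make_transcript(
            "t", "host",
            [(100, 100 + exon1_len), (800, 800 + exon2_len)],
            cds=[(100, 100 + exon1_len), (800, 800 + exon2_len)],
        )
        cand = candidate(ins_start, ins_start + len(insert), intron=(160, 800))
        return cand, tx, genome

    def test_62nt_insert_stops_after_14_aa(self):
        from neoexon.simulate import design_stop_insert

        insert = design_stop_insert(np.random.default_rng(3), 62, 14)
        cand, tx, genome = self.build_coding(insert)
        orf = orf_consequence(cand, tx, genome)
        assert orf.premature_stop
        assert orf.novel_aa_before_stop == 14
        assert not orf.frame_preserving

    def test_stop_free_3n_insert_preserves_frame(self):
        cand, tx, genome = self.build_coding("GCT" * 21)  # 63 nt, no stop
        orf = orf_consequence(cand, tx, genome)
        assert orf.frame_preserving and not orf.premature_stop

    def test_62nt_is_never_frame_preserving(self):
        cand, tx, genome = self.build_coding("GCA" * 20 + "GC")  # 62 nt
        orf = orf_consequence(cand, tx, genome)
        assert not orf.frame_preserving

    def test_utr_intron_flagged_non_coding(self):
        cand, tx, genome = self.build_coding("GCT" * 21)
        utr_cand = candidate(50, 80, intron=None)
        orf = orf_consequence(utr_cand, tx, genome)
        assert orf.non_coding_region

    def test_planted_cds_exon_in_simulation(self, sim):
        row = sim.truth["novel_exons"].query("in_cds").iloc[0]
        cand = candidate(row.start, row.end, host=row.host_gene)
        host = sim.reference.genes[row.host_gene]
        tx = next(t for t in host.transcripts.values() if t.cds)
        orf = orf_consequence(cand, tx, sim.genomes[0])
        assert orf.premature_stop and orf.novel_aa_before_stop == 14


class TestCrossSpeciesIdentity:
    def test_identical_sequences(self):
        r = cross_species_identity("ACGT" * 10, "ACGT" * 10)
        assert r["percent_identity"] == 100.0

    def test_six_mismatches_over_66_nt_round_to_91(self, rng):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 66)])
        from neoexon.simulate import mutate_sequence

        other = mutate_sequence(seq, 6, rng)
        r = cross_species_identity(seq, other)
        assert r["alignment_length"] == 66
        assert r["mismatches"] == 6
        assert r["percent_identity"] == pytest.approx(90.9)
        assert r["percent_identity_int"] == 91

    def test_single_differing_base(self):
        assert cross_species_identity("A", "C")["percent_identity"] == 0.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            cross_species_identity("", "ACGT")
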