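"""Simulator contracts: genome determinism, region partitions, editing model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import editome as ed
from editome import sim
from editome.genes import REGION_3UTR, REGION_5UTR, REGION_CDS, REGION_INTRON


def _intervals_cover(span, intervals):
    """Independent interval arithmetic: do the intervals tile span exactly?"""
    covered = sorted(intervals)
    cursor = span[0]
    for s, e in covered:
        if s != cursor:
            return False
        cursor = e + 1
    return cursor == span[1] + 1


class TestSimulateGenome:
    def test_deterministic_regeneration(self):
        g1, m1 = ed.simulate_genome(1, 10000, seed=7)
        g2, m2 = ed.simulate_genome(1, 10000, seed=7)
        assert g1.chromosomes == g2.chromosomes
        assert [t for t in m1.transcripts] == [t for t in m2.transcripts]

    def test_different_seed_changes_sequence(self):
        g1, _ = ed.simulate_genome(1, 10000, seed=7)
        g2, _ = ed.simulate_genome(1, 10000, seed=8)
        assert g1.chromosomes != g2.chromosomes

    def test_each_chromosome_has_multi_exon_genes_on_both_strands(self):
        _, models = ed.simulate_genome(3, 12000, seed=2)
        for chrom in ("chr1", "chr2", "chr3"):
            strands = set()
            for t in models.transcripts:
                if t.chrom == chrom:
                    strands.add(t.strand)
                    assert len(t.exons) >= 2
                    regions = t.regions()
                    assert regions[REGION_5UTR] and regions[REGION_3UTR]
                    assert regions[REGION_CDS] and regions[REGION_INTRON]
            assert strands == {"+", "-"}

    def test_regions_partition_transcript_span(self):
        _, models = ed.simulate_genome(2, 20000, seed=1)
        for t in models.transcripts:
            regions = t.regions()
            all_ivs = [iv for ivs in regions.values() for iv in ivs]
            assert _intervals_cover(t.span, all_ivs)

    def test_regions_match_independent_interval_oracle(self):
        # re-derive region intervals from exon/CDS lists with set arithmetic
        _, models = ed.simulate_genome(1, 10000, seed=3)
        for t in models.transcripts:
            exonic = set()
            for s, e in t.exons:
                exonic.update(range(s, e + 1))
            span_pos = set(range(t.start, t.end + 1))
            cds = set(range(t.cds[0], t.cds[1] + 1)) & exonic
            left = {p for p in exonic if p < t.cds[0]}
            right = {p for p in exonic if p > t.cds[1]}
            utr5, utr3 = (left, right) if t.strand == "+" else (right, left)
            intronic = span_pos - exonic
            regions = t.regions()

            def positions(label):
                return {
                    p for s, e in regions[label] for p in range(s, e + 1)
                }

            assert positions(REGION_CDS) == cds
            assert positions(REGION_5UTR) == utr5
            assert positions(REGION_3UTR) == utr3
            assert positions(REGION_INTRON) == intronic

    def test_too_small_chromosome_rejected(self):
        with pytest.raises(ValueError):
            ed.simulate_genome(1, 4000, seed=0)

    def test_gtf_round_trip(self, small_study, tmp_path):
        models = small_study["models"]
        path = tmp_path / "models.gtf"
        models.write_gtf(str(path))
        back = type(models).read_gtf(str(path))
        assert models.transcripts == back.transcripts


class TestRealizedRatio:
    def test_single_enzyme_double_ko(self):
        assert ed.realized_ratio({"p150": 0.7}, ed.DOUBLE_KO) == pytest.approx(0.7)

    def test_absent_enzyme_contributes_nothing(self):
        assert ed.realized_ratio({"p110": 0.5}, ed.ADAR1_P110_KO) == 0.0

    def test_independent_action_combination(self):
        value = ed.realized_ratio({"p110": 0.4, "ADAR2": 0.5}, ed.WT)
        assert value == pytest.approx(1 - 0.6 * 0.5)  # 0.70

    @given(
        c=st.tuples(*[st.floats(0, 1) for _ in range(3)]),
        bump=st.floats(0.0, 0.2),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_present_enzymes_invariant_to_absent(self, c, bump):
        contributions = dict(zip(sim.ENZYMES, c))
        for genotype in ed.GENOTYPES.values():
            base = ed.realized_ratio(contributions, genotype)
            for enzyme in sim.ENZYMES:
                bumped = dict(contributions)
                bumped[enzyme] = min(1.0, bumped[enzyme] + bump)
                new = ed.realized_ratio(bumped, genotype)
                if enzyme in genotype:
                    assert new >= base - 1e-12
                else:
                    assert new == pytest.approx(base)

    @given(c=st.tuples(*[st.floats(0, 1) for _ in range(3)]))
    @settings(max_examples=200, deadline=None)
    def test_wild_type_is_maximal(self, c):
        contributions = dict(zip(sim.ENZYMES, c))
        wt = ed.realized_ratio(contributions, ed.WT)
        for genotype in ed.GENOTYPES.values():
            assert wt >= ed.realized_ratio(contributions, genotype) - 1e-12


class TestPlantTruthSites:
    def test_truth_sites_are_gene_strand_adenosines(self, small_study):
        genome, truth = small_study["genome"], small_study["truth"]
        for row in truth.itertuples():
            base = genome.base(row.chrom, row.pos)
            assert base == ("A" if row.strand == "+" else "T")

    def test_region_labels_match_gene_models(self, small_study):
        models, truth = small_study["models"], small_study["truth"]
        from editome.annotation import classify_region

        for row in truth.itertuples():
            assert classify_region(row.chrom, row.pos, models,
                                   row.gene_id) == row.region

    def test_class_fractions_apportioned_exactly(self, small_study):
        truth = small_study["truth"]
        counts = truth.enzyme_class.value_counts()
        assert counts["p150_only"] == round(0.02 * len(truth)) or \
            counts["p150_only"] in (1, 2)
        assert len(truth) == 60


class TestSimulateReads:
    def test_identical_seed_gives_byte_identical_sam(self, small_study, tmp_path):
        a, b = str(tmp_path / "a.sam"), str(tmp_path / "b.sam")
        args = (small_study["genome"], small_study["models"],
                small_study["truth"], ed.WT)
        ed.simulate_reads(*args, a, depth=10, seed=11)
        ed.simulate_reads(*args, b, depth=10, seed=11)
        assert open(a, "rb").read() == open(b, "rb").read()

    def test_noiseless_full_editing_gives_all_g(self, tmp_path):
        genome, models = ed.simulate_genome(1, 10000, seed=4)
        truth = ed.plant_truth_sites(genome, models, 5, seed=4)
        truth["c_p110"] = 1.0
        truth["c_p150"] = 0.0
        truth["c_ADAR2"] = 0.0
        sam = str(tmp_path / "full.sam")
        ed.simulate_reads(genome, models, truth, ed.WT, sam,
                          depth=80, error_rate=0.0, seed=9)
        reads, _ = ed.read_sam(sam)
        cols = {
            c.pos: c
            for c in ed.build_pileup(reads, "chr1", 1, 10000,
                                     genome.chromosomes)
        }
        for row in truth.itertuples():
            col = cols[row.pos]
            edited_base = "G" if row.strand == "+" else "C"
            assert set(col.bases) == {edited_base}

    def test_g_fraction_matches_binomial_expectation(self, tmp_path):
        # law of large numbers at high depth: G fraction within 3 binomial SD
        genome, models = ed.simulate_genome(1, 10000, seed=4)
        truth = ed.plant_truth_sites(genome, models, 4, seed=4)
        truth["c_p110"] = 0.5
        truth["c_p150"] = 0.0
        truth["c_ADAR2"] = 0.0
        # keep only exonic sites so they see full depth
        truth = truth[truth.region != "intron"].reset_index(drop=True)
        sam = str(tmp_path / "half.sam")
        ed.simulate_reads(genome, models, truth, ed.WT, sam,
                          depth=400, error_rate=0.0, seed=13)
        reads, _ = ed.read_sam(sam)
        ed.mark_duplicates(reads)
        cols = {
            c.pos: c
            for c in ed.build_pileup(reads, "chr1", 1, 10000,
                                     genome.chromosomes)
        }
        for row in truth.itertuples():
            col = cols[row.pos]
            edited_base = "G" if row.strand == "+" else "C"
            n_g = col.bases[edited_base].count if edited_base in col.bases else 0
            n = col.depth
            assert n > 80
            assert abs(n_g / n - 0.5) < 3 * math.sqrt(0.25 / n)

    def test_round_trip_through_alignment_parser(self, small_study, wt_reads):
        reads, ref_lengths = wt_reads
        assert len(reads) == small_study["n_reads"]
        assert ref_lengths == small_study["genome"].lengths()

    def test_zero_transcripts_rejected(self, small_study, tmp_path):
        from editome.genes import GeneModels

        with pytest.raises(ValueError):
            ed.simulate_reads(small_study["genome"], GeneModels([]),
                              small_study["truth"], ed.WT,
                              str(tmp_path / "x.sam"), seed=1)


class TestAmpliconAndChromatogramSim:
    DESIGN = sim.AmpliconDesign(
        "amp1",
        "CCTGATCGTACGTAGCTAGCATGCAGATCGAATCGTACGATCGATCGTAC",
        target_offset=26,
    )

    def test_extremes_are_pure(self):
        for ratio, base in ((1.0, "G"), (0.0, "A")):
            reads = ed.simulate_amplicon_reads(self.DESIGN, ratio, 50, 0.0, seed=3)
            off = len(self.DESIGN.adaptor5) + len(self.DESIGN.barcode) + 26
            assert all(seq[off] == base for _n, seq, _q in reads)

    def test_binomial_count_bound(self):
        n, p = 10000, 0.7
        reads = ed.simulate_amplicon_reads(self.DESIGN, p, n, 0.0, seed=21)
        off = len(self.DESIGN.adaptor5) + len(self.DESIGN.barcode) + 26
        n_g = sum(seq[off] == "G" for _n, seq, _q in reads)
        assert abs(n_g - n * p) < 3 * math.sqrt(n * p * (1 - p))

    def test_chromatogram_noiseless_and_reproducible(self):
        peaks = ed.simulate_chromatogram(0.7, scale=100, noise_sd=0.0)
        assert (peaks.G, peaks.A) == (pytest.approx(70.0), pytest.approx(30.0))
        assert ed.simulate_chromatogram(0.0, noise_sd=0.0).G == 0.0
        p1 = ed.simulate_chromatogram(0.4, noise_sd=5.0, seed=8)
        p2 = ed.simulate_chromatogram(0.4, noise_sd=5.0, seed=8)
        assert p1 == p2
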