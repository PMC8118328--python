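"""Orientation, region classification, liftover and database intersection."""

import numpy as np
import pytest

import editome as ed
from editome.annotation import KnownSiteDB, classify_region, intersect_known
from editome.chain import ChainMap, ChainParseError, liftover_point
from editome.discovery import VariantCall
from editome.genes import GeneModels, Transcript


def call_at(chrom, pos, ref, alt):
    return VariantCall(chrom, pos, ref, alt, (10, 10), 20, qual=100.0,
                       fs=0.0, qd=5.0)


@pytest.fixture(scope="module")
def toy_models():
    plus = Transcript("tp.1", "gplus", "chr1", "+",
                      ((101, 200), (301, 400), (501, 600)), (151, 550))
    minus = Transcript("tm.1", "gminus", "chr1", "-",
                       ((1001, 1100), (1201, 1300)), (1051, 1250))
    return GeneModels([plus, minus])


class TestOrientVariant:
    def test_a_to_g_in_plus_gene_accepted(self, toy_models):
        cand, status = ed.orient_variant(call_at("chr1", 150, "A", "G"),
                                         toy_models)
        assert status == "ok"
        assert cand.gene_strand == "+" and cand.gene_id == "gplus"

    def test_t_to_c_in_minus_gene_accepted_as_a_to_i(self, toy_models):
        cand, status = ed.orient_variant(call_at("chr1", 1060, "T", "C"),
                                         toy_models)
        assert status == "ok"
        assert cand.gene_strand == "-" and cand.gene_id == "gminus"

    def test_g_to_a_in_plus_gene_rejected(self, toy_models):
        cand, status = ed.orient_variant(call_at("chr1", 150, "G", "A"),
                                         toy_models)
        assert cand is None and status == "not_a_to_g"

    def test_intergenic_rejected(self, toy_models):
        cand, status = ed.orient_variant(call_at("chr1", 700, "A", "G"),
                                         toy_models)
        assert cand is None and status == "intergenic"

    def test_overlapping_opposite_strand_genes_ambiguous(self):
        plus = Transcript("tp.1", "gplus", "chr1", "+", ((100, 400),), (150, 350))
        minus = Transcript("tm.1", "gminus", "chr1", "-", ((200, 500),), (250, 450))
        models = GeneModels([plus, minus])
        # A>G fits '+', and at the same position T>C would fit '-';
        # a single A>G call only fits '+', so it is assigned
        cand, status = ed.orient_variant(call_at("chr1", 300, "A", "G"), models)
        assert status == "ok" and cand.gene_id == "gplus"
        # T>C also only fits '-'
        cand, status = ed.orient_variant(call_at("chr1", 300, "T", "C"), models)
        assert status == "ok" and cand.gene_id == "gminus"


class TestClassifyRegion:
    def test_unique_3utr(self, toy_models):
        assert classify_region("chr1", 580, toy_models, "gplus") == "3'UTR"

    def test_intron_and_utr5(self, toy_models):
        assert classify_region("chr1", 250, toy_models, "gplus") == "intron"
        assert classify_region("chr1", 120, toy_models, "gplus") == "5'UTR"

    def test_intergenic_is_others(self, toy_models):
        assert classify_region("chr1", 700, toy_models) == "others"

    def test_exonic_label_beats_intronic_across_isoforms(self):
        # intronic in isoform 1, 3'UTR-exonic in isoform 2 of the same gene
        iso1 = Transcript("g.t1", "g", "chr1", "+",
                          ((100, 200), (401, 500)), (150, 450))
        iso2 = Transcript("g.t2", "g", "chr1", "+",
                          ((100, 350), (401, 500)), (150, 250))
        models = GeneModels([iso1, iso2])
        assert classify_region("chr1", 300, models, "g") == "3'UTR"

    def test_agrees_with_membership_oracle_on_random_models(self):
        rng = np.random.default_rng(17)
        precedence = ("CDS", "3'UTR", "5'UTR", "intron")
        for trial in range(100):
            _, models = ed.simulate_genome(1, 10000, seed=int(rng.integers(2**31)))
            gene_id = models.transcripts[0].gene_id
            transcripts = models.by_gene[gene_id]
            for pos in rng.integers(1, 10000, size=30):
                pos = int(pos)
                labels = set()
                for t in transcripts:
                    for label, ivs in t.regions().items():
                        if any(s <= pos <= e for s, e in ivs):
                            labels.add(label)
                expected = next((l for l in precedence if l in labels), "others")
                assert classify_region("chr1", pos, models, gene_id) == expected


CHAIN_PLUS = """chain 900 chrA 1000 + 100 400 chrB 2000 + 110 390
100 50 30
150
"""

CHAIN_MINUS = """chain 800 chrA 1000 + 500 600 chrB 400 - 40 140
100
"""


class TestLiftover:
    def test_offset_arithmetic(self, tmp_path):
        path = tmp_path / "c.chain"
        path.write_text(CHAIN_PLUS + "\n")
        cm = ChainMap.from_file(str(path))
        # first block maps source 101..200 (1-based) to target 111..210
        assert liftover_point("chrA", 150, cm) == ("chrB", 160, False)
        assert liftover_point("chrA", 101, cm) == ("chrB", 111, False)
        # second block starts at source 251 (0-based 250), target offset 280
        assert liftover_point("chrA", 251, cm) == ("chrB", 241, False)

    def test_gap_unmapped(self, tmp_path):
        path = tmp_path / "c.chain"
        path.write_text(CHAIN_PLUS + "\n")
        cm = ChainMap.from_file(str(path))
        assert liftover_point("chrA", 210, cm) is None  # inside the 50-gap
        assert liftover_point("chrA", 900, cm) is None  # outside any chain

    def test_minus_strand_reverse_coordinates(self, tmp_path):
        path = tmp_path / "c.chain"
        path.write_text(CHAIN_MINUS + "\n")
        cm = ChainMap.from_file(str(path))
        # source block start (0-based 500 -> 1-based 501) maps to q0=40 on
        # the '-' strand of a 400-base chromosome: plus-strand 400-40 = 360
        assert liftover_point("chrA", 501, cm) == ("chrB", 360, True)
        # source block end maps to the target block's other extreme
        assert liftover_point("chrA", 600, cm) == ("chrB", 261, True)

    def test_highest_scoring_covering_chain_wins(self, tmp_path):
        path = tmp_path / "c.chain"
        path.write_text(
            "chain 500 chrA 1000 + 0 100 chrB 1000 + 0 100\n100\n\n"
            "chain 900 chrA 1000 + 0 100 chrC 1000 + 500 600\n100\n\n"
        )
        cm = ChainMap.from_file(str(path))
        assert liftover_point("chrA", 50, cm) == ("chrC", 550, False)

    def test_malformed_chain_reports_line(self, tmp_path):
        path = tmp_path / "bad.chain"
        path.write_text("chain 1 chrA 1000 +\n")
        with pytest.raises(ChainParseError, match="bad.chain:1"):
            ChainMap.from_file(str(path))

    def test_agrees_with_per_base_chain_walk(self, tmp_path):
        # brute force: walk the chain base by base and record the mapping
        path = tmp_path / "c.chain"
        path.write_text(CHAIN_PLUS + "\n" + CHAIN_MINUS + "\n")
        cm = ChainMap.from_file(str(path))
        walk = {}
        for chain in cm.chains:
            for t_bs, q_bs, size in chain.blocks:
                for i in range(size):
                    src = t_bs + i + 1
                    q0 = q_bs + i
                    if chain.q_strand == "-":
                        walk.setdefault(src, (chain.q_name,
                                              chain.q_size - q0, True))
                    else:
                        walk.setdefault(src, (chain.q_name, q0 + 1, False))
        rng = np.random.default_rng(5)
        for pos in rng.integers(1, 1000, size=1000):
            pos = int(pos)
            assert liftover_point("chrA", pos, cm) == walk.get(pos)


class TestKnownSiteDB:
    def _db(self, tmp_path, rows, name="db.tsv"):
        path = tmp_path / name
        lines = ["chromosome\tposition\tstrand\tsource\tassembly"]
        lines += ["\t".join(map(str, r)) for r in rows]
        path.write_text("\n".join(lines) + "\n")
        return str(path)

    def test_round_trip_and_duplicate_rejection(self, tmp_path):
        path = self._db(tmp_path, [("chr1", 100, "+", "DARNED", "mm10"),
                                   ("chr1", 100, "+", "RADAR", "mm10")])
        db = KnownSiteDB.from_tsv(path)
        assert db.entries[("chr1", 100, "+")] == {"DARNED", "RADAR"}
        bad = self._db(tmp_path, [("chr1", 100, "+", "DARNED", "mm10")] * 2,
                       name="dup.tsv")
        with pytest.raises(ValueError, match="duplicate"):
            KnownSiteDB.from_tsv(bad)

    def test_intersection_requires_position_and_strand(self, tmp_path,
                                                       toy_models):
        db = KnownSiteDB(
            {("chr1", 150, "+"): {"DARNED"}, ("chr1", 1060, "+"): {"RADAR"}},
            "simG1",
        )
        cands = []
        for pos, ref, alt in ((150, "A", "G"), (1060, "T", "C")):
            cand, _ = ed.orient_variant(call_at("chr1", pos, ref, alt),
                                        toy_models)
            cands.append(cand)
        records = intersect_known(cands, db, toy_models, "simG1")
        # 1060 is a '-'-gene candidate but the db entry is '+': dropped
        assert [r.pos for r in records] == [150]
        assert records[0].sources == frozenset({"DARNED"})
        assert records[0].region == "5'UTR"  # 150 sits just before the CDS

    def test_assembly_mismatch_without_chain_refused(self, tmp_path,
                                                     toy_models):
        db = KnownSiteDB({("chr1", 150, "+"): {"RADAR"}}, "simG0")
        with pytest.raises(ValueError, match="assembly"):
            intersect_known([], db, toy_models, "simG1")

    def test_lift_then_intersect(self, tmp_path, toy_models):
        chain = tmp_path / "lift.chain"
        chain.write_text(
            "chain 100 chr1 3000 + 1000 2000 chr1 2000 + 0 1000\n1000\n\n"
        )
        cm = ChainMap.from_file(str(chain))
        db = KnownSiteDB({("chr1", 1150, "+"): {"RADAR"}}, "simG0")
        cand, _ = ed.orient_variant(call_at("chr1", 150, "A", "G"), toy_models)
        records = intersect_known([cand], db, toy_models, "simG1",
                                  chain_map=cm)
        assert [r.pos for r in records] == [150]

    def test_union_pools_sources(self):
        a = KnownSiteDB({("chr1", 5, "+"): {"DARNED"}}, "simG1")
        b = KnownSiteDB({("chr1", 5, "+"): {"REDIportal"},
                         ("chr2", 9, "-"): {"RADAR"}}, "simG1")
        u = KnownSiteDB.union([a, b])
        assert u.entries[("chr1", 5, "+")] == {"DARNED", "REDIportal"}
        assert len(u) == 2


class TestRecordInvariants:
    def test_gene_strand_base_is_a_for_all_pipeline_records(self, small_study,
                                                            wt_reads):
        genome = small_study["genome"]
        models = small_study["models"]
        truth = small_study["truth"]
        db = KnownSiteDB(
            {(r.chrom, r.pos, r.strand): {"DARNED"} for r in truth.itertuples()},
            "simG1",
        )
        reads, _ = wt_reads
        config = ed.RunConfig()
        res = ed.discover_sample("wt", "WT", small_study["sam"], genome,
                                 models, db, config)
        assert res.records
        for rec in res.records:
            base = genome.base(rec.chrom, rec.pos)
            expected = "A" if rec.gene_strand == "+" else "T"
            assert base == expected
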