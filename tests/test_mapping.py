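"""Alignment, MIB classification, the multimap consensus rule and prior
4-mer extraction."""

import numpy as np
import pytest

import rindseq as rs
from rindseq.mapping import (
    GenomeIndex,
    MappingParams,
    align_read,
    classify_mapping,
    prior4,
    retain_multimapped,
)
from conftest import pipeline_on_library, plant_genome, random_seq


@pytest.fixture(scope="module")
def toy():
    genome = rs.ReferenceGenome({"chr1": random_seq(5000, 42)})
    return genome, GenomeIndex(genome)


class TestAlignRead:
    def test_exact_substring_single_hit(self, toy):
        genome, index = toy
        query = genome["chr1"][1000:1040]
        hits = align_read(query, index)
        assert len(hits) == 1
        h = hits[0]
        assert (h.chromosome, h.strand, h.reference_start) == ("chr1", "+", 1000)
        assert h.query_start == 0 and h.aligned_length == 40 and h.identity == 1.0

    def test_unaligned_prefix_sets_query_start(self, toy):
        genome, index = toy
        seq = genome["chr1"]
        # pick a start whose upstream base is not T so the TTTT prefix
        # cannot extend the alignment
        p = next(i for i in range(1000, 2000) if seq[i - 1] != "T")
        hits = align_read("TTTT" + seq[p : p + 40], index)
        best = hits[0]
        assert best.query_start == 4 and best.reference_start == p

    def test_reverse_strand_hit(self, toy):
        genome, index = toy
        query = rs.reverse_complement(genome["chr1"][2000:2040])
        h = align_read(query, index)[0]
        assert h.strand == "-" and h.reference_start == 2000
        assert h.break_position == 2039  # rightmost aligned base

    def test_duplicated_sequence_yields_equal_scores(self):
        core = random_seq(40, 3)
        genome, positions = plant_genome([("ACCA", core), ("ACCA", core)])
        hits = align_read(core, GenomeIndex(genome))
        assert len(hits) == 2
        assert hits[0].score == hits[1].score
        assert sorted(h.reference_start for h in hits) == positions

    def test_short_query_returns_nothing(self, toy):
        _, index = toy
        assert align_read("ACGTACGT", index) == []

    def test_mismatch_lowers_identity(self, toy):
        genome, index = toy
        q = list(genome["chr1"][1000:1060])
        q[30] = "A" if q[30] != "A" else "C"
        h = align_read("".join(q), index)[0]
        assert h.identity == pytest.approx(59 / 60)
        assert h.aligned_length == 60

    def test_min_identity_monotonicity(self, tmp_path):
        """Raising the identity floor never increases the number of
        break calls."""
        c = rs.SimulationConfig(genome_length=10_000, n_reads=400, error_rate=0.03,
                                corrupt_linker_rate=0.0, mib_rate=0.1, seed=31)
        genome, truths = rs.simulate_library(c, tmp_path)
        counts = []
        for ident in (0.85, 0.90, 0.95, 1.0):
            params = MappingParams(min_identity=ident)
            _, _, calls, _ = pipeline_on_library(genome, truths, c, tmp_path, params)
            counts.append(len(calls))
        assert counts == sorted(counts, reverse=True)


class TestPrior4:
    def test_plus_strand_window(self):
        g = rs.ReferenceGenome({"c": "AAACGTA"})
        # break between index 3 and 4: the 4 bases 5' of position 4
        assert prior4(g, "c", 4, "+") == "AAAC"

    def test_minus_strand_window_is_reverse_complement(self):
        g = rs.ReferenceGenome({"c": "AAACGTA"})
        # break at 2 on '-': upstream bases are 3..6 read on the minus strand
        assert prior4(g, "c", 2, "-") == rs.reverse_complement("CGTA")

    def test_strand_symmetry(self):
        seq = random_seq(50, 5)
        g = rs.ReferenceGenome({"c": seq})
        grc = rs.ReferenceGenome({"c": rs.reverse_complement(seq)})
        for pos in range(5, 40):
            mirrored = len(seq) - 1 - pos
            assert prior4(g, "c", pos, "-") == prior4(grc, "c", mirrored, "+")

    def test_out_of_range_returns_none(self):
        g = rs.ReferenceGenome({"c": "ACGTACGTAC"})
        assert prior4(g, "c", 3, "+") is None
        assert prior4(g, "c", 7, "-") is None


class TestMultimapRule:
    def make_hits(self, genome, positions, core_len):
        index = GenomeIndex(genome)
        core = genome["chr1"][positions[0] : positions[0] + core_len]
        hits = align_read(core, index)
        tier = [h for h in hits if h.score >= hits[0].score - 1]
        return core, tier

    def test_nine_of_ten_consensus_accepted(self):
        core = random_seq(30, 11)
        plants = [("TACA", core)] * 9 + [("GGGG", core)]
        genome, positions = plant_genome(plants)
        _, tier = self.make_hits(genome, positions, 30)
        assert len(tier) == 10
        accepted = retain_multimapped(tier, genome)
        assert accepted is not None
        assert prior4(genome, "chr1", accepted.break_position, accepted.strand) == "TACA"
        # representative is the lexicographically smallest consensus locus
        assert accepted.break_position == positions[0]

    def test_eight_of_ten_consensus_rejected(self):
        core = random_seq(30, 12)
        plants = [("TACA", core)] * 8 + [("GGGG", core), ("CCCC", core)]
        genome, positions = plant_genome(plants)
        _, tier = self.make_hits(genome, positions, 30)
        assert len(tier) == 10
        assert retain_multimapped(tier, genome) is None

    def test_two_locations_divergent_context_rejected(self):
        core = random_seq(30, 13)
        genome, positions = plant_genome([("AAAA", core), ("CCCC", core)])
        _, tier = self.make_hits(genome, positions, 30)
        assert retain_multimapped(tier, genome) is None

    def test_five_identical_contexts_accepted_divergent_rejected(self):
        core = random_seq(34, 14)
        same, _ = plant_genome([("GGAT", core)] * 5, seed=8)
        _, tier = self.make_hits(same, [same["chr1"].find(core)], 34)
        assert len(tier) == 5
        assert retain_multimapped(tier, same) is not None
        mixed, _ = plant_genome(
            [("GGAT", core)] * 3 + [("TTGA", core), ("ACCA", core)], seed=9
        )
        _, tier = self.make_hits(mixed, [mixed["chr1"].find(core)], 34)
        assert retain_multimapped(tier, mixed) is None

    def test_single_hit_accepted_outright(self, toy):
        genome, index = toy
        hits = align_read(genome["chr1"][300:340], index)
        assert retain_multimapped(hits, genome) is hits[0]


class TestClassifyMapping:
    def test_mapped_from_first_base(self, toy):
        genome, index = toy
        q = genome["chr1"][600:640]
        hit = align_read(q, index)[0]
        call = classify_mapping(hit, q, genome, "r1")
        assert call.insertion == "" and not call.is_mib
        assert call.break_position == 600
        assert call.prior4 == genome["chr1"][596:600]

    def test_unaligned_prefix_becomes_insertion(self, toy):
        genome, index = toy
        seq = genome["chr1"]
        p = next(i for i in range(800, 2000) if seq[i - 1] != "T")
        q = "TTTT" + seq[p : p + 40]
        hit = align_read(q, index)[0]
        call = classify_mapping(hit, q, genome, "r2")
        assert call.insertion == "TTTT" and call.is_mib
        assert call.break_position == p

    def test_simulated_mib_recovers_planted_insert(self):
        core = random_seq(40, 15)
        genome, positions = plant_genome([("CCTT", core)], seed=10)
        p = positions[0]
        # plant an insert that cannot extend into the reference
        prev = genome["chr1"][p - 1]
        ins = ("GGA" if prev != "A" else "GGC")
        q = ins + core
        index = GenomeIndex(genome)
        hit = align_read(q, index)[0]
        call = classify_mapping(hit, q, genome, "r3")
        assert call.insertion == ins
        assert call.break_position == p

    def test_break_too_close_to_chromosome_start_dropped(self):
        seq = random_seq(100, 16)
        genome = rs.ReferenceGenome({"chr1": seq})
        q = seq[2:40]
        hit = align_read(q, GenomeIndex(genome))[0]
        assert hit.reference_start == 2
        assert classify_mapping(hit, q, genome, "r4") is None


class TestEndToEndRecovery:
    def test_breaks_and_inserts_recovered_exactly(self, enriched_calls):
        """Error-free pipeline: every emitted call matches its truth
        record (position, strand, prior 4-mer, insert)."""
        truths = {t.read_id: t for t in enriched_calls["truths"]}
        calls = enriched_calls["calls"]
        assert calls, "pipeline produced no calls"
        for c in calls:
            t = truths[c.read_id]
            assert (c.chromosome, c.break_position, c.strand) == (
                t.chrom, t.break_pos, t.strand,
            )
            assert c.prior4 == t.prior4
            assert c.insertion == t.insertion

    def test_reconstruction_identity(self, enriched_calls):
        """insertion + reference substring reproduces the post-linker
        sequence exactly in the error-free setting."""
        genome = enriched_calls["genome"]
        posts = {r.read_id: r.post_linker_sequence for r in enriched_calls["retained"]}
        for c in enriched_calls["calls"][:500]:
            post = posts[c.read_id]
            aligned_len = len(post) - len(c.insertion)
            seq = genome[c.chromosome]
            if c.strand == "+":
                ref = seq[c.break_position : c.break_position + aligned_len]
            else:
                ref = rs.reverse_complement(
                    seq[c.break_position - aligned_len + 1 : c.break_position + 1]
                )
            assert c.insertion + ref == post

    def test_mib_partition(self, enriched_calls):
        for c in enriched_calls["calls"]:
            assert c.is_mib == bool(c.insertion)
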