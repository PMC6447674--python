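"""Discordant contigs, synteny chaining, event classification, karyotypes."""

import numpy as np
import pytest

from chromostruct import datasets
from chromostruct.model import AlignmentRecord, RepeatAnnotation, SyntenyBlock
from chromostruct.rearrangement import (
    CentromereCall,
    blocks_to_records,
    chain_synteny_blocks,
    classify_karyotype,
    classify_rearrangements,
    detect_centromere_repositioning,
    detect_interchromosomal_differences,
    locate_centromeres,
)


class TestInterchromosomalDifferences:
    def test_published_discordant_contig_table(self):
        per_map, sizes, notes = datasets.discordant_assignment_inputs()
        recs, agg = detect_interchromosomal_differences(per_map, sizes, notes)
        assert agg["count"] == 9
        assert agg["total_bp"] == 10_141_919  # 10.1 Mbp
        assert round(agg["total_bp"] / 1e6, 1) == 10.1
        assert agg["n_single_marker"] == 7
        by_name = {r.contig: r for r in recs}
        # the three-marker minority assignment is not single-marker support
        assert by_name["000201F"].single_marker_support is False
        assert by_name["000223F"].single_marker_support is False
        assert by_name["000223F"].repeat_note == "Repetitive markers on LG3"

    def test_concordant_maps_empty(self):
        per_map = {
            "A": {"c1": ("LG1", 3), "c2": ("LG2", 2)},
            "B": {"c1": ("LG1", 1), "c2": ("LG2", 5)},
        }
        recs, agg = detect_interchromosomal_differences(per_map, {"c1": 10, "c2": 20})
        assert recs == [] and agg["count"] == 0

    def test_aggregate_is_exact_integer_sum(self):
        per_map, sizes, _ = datasets.discordant_assignment_inputs()
        _, agg = detect_interchromosomal_differences(per_map, sizes)
        assert agg["total_bp"] == sum(sizes.values())


def _rec(r0, r1, q0, q1, strand="+", ident=95.0, ref="chrR", query="chrQ"):
    return AlignmentRecord(ref, query, r0, r1, q0, q1, ident, strand)


class TestChainSyntenyBlocks:
    def test_short_record_dropped(self):
        assert chain_synteny_blocks([_rec(0, 4_999, 0, 4_999)]) == []
        assert len(chain_synteny_blocks([_rec(0, 5_000, 0, 5_000)])) == 1

    def test_low_identity_dropped(self):
        assert chain_synteny_blocks([_rec(0, 10_000, 0, 10_000, ident=9.0)]) == []

    def test_two_forward_records_merge(self):
        recs = [
            _rec(0, 1_000_000, 0, 1_000_000),
            _rec(1_050_000, 2_000_000, 1_050_000, 2_000_000),
        ]
        (b,) = chain_synteny_blocks(recs)
        assert (b.query_start, b.query_end) == (0, 2_000_000)
        assert b.aligned_bp == 1_950_000

    def test_strand_change_breaks_chain(self):
        recs = [
            _rec(0, 1_000_000, 0, 1_000_000),
            _rec(1_050_000, 2_000_000, 1_050_000, 2_000_000, strand="-"),
        ]
        assert len(chain_synteny_blocks(recs)) == 2

    def test_large_gap_breaks_chain(self):
        recs = [
            _rec(0, 1_000_000, 0, 1_000_000),
            _rec(1_500_000, 2_000_000, 1_500_000, 2_000_000),
        ]
        assert len(chain_synteny_blocks(recs)) == 2

    def test_overlap_resolved_keeping_larger(self):
        recs = [
            _rec(0, 100_000, 0, 100_000),
            _rec(50_000, 60_000, 500_000, 510_000),  # overlaps first on ref
        ]
        (b,) = chain_synteny_blocks(recs)
        assert b.aligned_bp == 100_000

    def test_conservation_and_idempotence(self):
        rng = np.random.default_rng(5)
        recs = []
        pos = 0
        for _ in range(30):
            n = int(rng.integers(6_000, 400_000))
            gap = int(rng.integers(0, 200_000))
            strand = "+-"[int(rng.integers(2))]
            recs.append(_rec(pos + gap, pos + gap + n, pos + gap, pos + gap + n, strand))
            pos += gap + n
        blocks = chain_synteny_blocks(recs)
        assert sum(b.aligned_bp for b in blocks) <= sum(
            min(r.ref_len, r.query_len) for r in recs
        )
        again = chain_synteny_blocks(blocks_to_records(blocks), min_length=0)
        assert [(b.query_start, b.query_end, b.strand) for b in again] == [
            (b.query_start, b.query_end, b.strand) for b in blocks
        ]


def _block(ref, q0, q1, r0, r1, strand="+", query="chrQ"):
    return SyntenyBlock(
        ref_chrom=ref, query_chrom=query, ref_start=r0, ref_end=r1,
        query_start=q0, query_end=q1, strand=strand,
        aligned_bp=min(q1 - q0, r1 - r0), mean_identity=90.0,
    )


class TestClassifyRearrangements:
    def test_terminal_halves_are_fusion_partners(self):
        # the two-ancestral-chromosome pattern: ~32 Mbp to one reference
        # chromosome and ~31 Mbp to another, in terminal halves
        blocks = [
            _block("med6", 0, 32_000_000, 0, 32_000_000),
            _block("med12", 32_000_000, 63_000_000, 0, 31_000_000),
        ]
        events, table = classify_rearrangements(blocks)
        fusion_refs = {e.ref_chroms[0] for e in events if e.type == "fusion_partner"}
        assert fusion_refs == {"med6", "med12"}
        assert table["chrQ"][0] == ("med6", 32_000_000)

    def test_interleaved_secondary_is_translocation(self):
        blocks = [
            _block("refA", 0, 10_000_000, 0, 10_000_000),
            _block("refB", 10_000_000, 16_000_000, 0, 6_000_000),
            _block("refA", 16_000_000, 30_000_000, 10_000_000, 24_000_000),
        ]
        events, _ = classify_rearrangements(blocks)
        assert [e.type for e in events if e.ref_chroms == ("refB",)] == ["translocation"]

    def test_fully_forward_single_ref_collinear(self):
        blocks = [_block("refA", 0, 10_000_000, 0, 10_000_000)]
        events, _ = classify_rearrangements(blocks)
        assert [e.type for e in events] == ["collinear"]

    def test_small_secondary_not_a_fusion(self):
        blocks = [
            _block("refA", 0, 30_000_000, 0, 30_000_000),
            _block("refB", 30_000_000, 31_000_000, 0, 1_000_000),
        ]
        events, _ = classify_rearrangements(blocks)
        assert [e.type for e in events] == ["collinear"]

    def test_reverse_run_is_inversion_with_span(self):
        blocks = [
            _block("refA", 0, 10_000_000, 0, 10_000_000),
            _block("refA", 10_000_000, 25_000_000, 10_000_000, 25_000_000, "-"),
            _block("refA", 25_000_000, 40_000_000, 25_000_000, 40_000_000),
        ]
        events, _ = classify_rearrangements(blocks)
        (inv,) = [e for e in events if e.type == "inversion"]
        assert inv.span_bp == 15_000_000

    def test_small_reverse_run_below_floor_ignored(self):
        blocks = [
            _block("refA", 0, 10_000_000, 0, 10_000_000),
            _block("refA", 10_000_000, 11_000_000, 10_000_000, 11_000_000, "-"),
            _block("refA", 11_000_000, 20_000_000, 11_000_000, 20_000_000),
        ]
        events, _ = classify_rearrangements(blocks)
        assert [e.type for e in events] == ["collinear"]

    def test_planted_truth_recovery_via_divergence(self):
        from chromostruct.simulate import (
            PlantedEvent, SimConfig, diverge_species, simulate_genome,
        )

        g = simulate_genome(
            SimConfig(
                chrom_lengths=(40_000_000, 30_000_000, 30_000_000, 28_000_000), seed=51
            )
        )
        planted = [
            PlantedEvent("fusion", ("chr2", "chr3")),
            PlantedEvent("inversion", ("chr1",), ((10_000_000, 25_000_000),)),
        ]
        pair = diverge_species(g, planted, seed=52)
        blocks = chain_synteny_blocks(pair.alignments)
        events, _ = classify_rearrangements(blocks)
        fusions = {e.ref_chroms[0] for e in events if e.type == "fusion_partner"}
        assert fusions == {"chr2", "chr3"}
        (inv,) = [e for e in events if e.type == "inversion"]
        assert inv.query_chrom == "chr1"
        assert abs(inv.blocks[0].query_start - 10_000_000) <= 1
        assert abs(inv.blocks[-1].query_end - 25_000_000) <= 1

    def test_no_events_on_event_free_simulation(self):
        from chromostruct.simulate import SimConfig, diverge_species, simulate_genome

        g = simulate_genome(SimConfig(chrom_lengths=(30_000_000, 25_000_000), seed=53))
        pair = diverge_species(g, [], seed=54)
        events, _ = classify_rearrangements(chain_synteny_blocks(pair.alignments))
        assert {e.type for e in events} == {"collinear"}


def _sat(chrom, s, e, family="ONSATA"):
    return RepeatAnnotation(chrom, s, e, family, "Satellite", 1.0)


class TestLocateCentromeres:
    def test_single_cluster_interval(self):
        hits = [
            _sat("chr1", 20_000_000, 20_150_000),
            _sat("chr1", 20_200_000, 20_400_000),
        ]
        (call,) = locate_centromeres(hits)
        assert call.interval == (20_000_000, 20_400_000)
        assert call.cluster_bp == 350_000
        assert call.ambiguous is False

    def test_no_satellite_hits_no_call(self):
        hits = [RepeatAnnotation("chr1", 0, 1_000, "TcMar", "DNA", 1.0)]
        assert locate_centromeres(hits) == []

    def test_two_distant_clusters_ambiguous(self):
        hits = [
            _sat("chr1", 5_000_000, 5_200_000),
            _sat("chr1", 30_000_000, 30_300_000),
        ]
        (call,) = locate_centromeres(hits)
        assert call.interval == (30_000_000, 30_300_000)  # larger cluster wins
        assert call.ambiguous is True

    def test_nearby_clusters_merge_not_ambiguous(self):
        hits = [
            _sat("chr1", 5_000_000, 5_200_000),
            _sat("chr1", 5_400_000, 5_600_000),  # 200-kbp gap < cluster gap
        ]
        (call,) = locate_centromeres(hits)
        assert call.interval == (5_000_000, 5_600_000) and not call.ambiguous

    def test_non_satellite_families_ignored(self):
        hits = [
            _sat("chr1", 5_000_000, 5_200_000),
            RepeatAnnotation("chr1", 30_000_000, 30_500_000, "TcMar", "DNA", 1.0),
        ]
        (call,) = locate_centromeres(hits)
        assert call.interval == (5_000_000, 5_200_000)


class TestClassifyKaryotype:
    @pytest.mark.parametrize(
        "frac,expect_ratio,expect_class",
        [
            (0.50, 1.0, "metacentric"),
            (0.70, 2.3333, "submetacentric"),
            (0.85, 5.6667, "subtelocentric"),
            (0.90, 9.0, "acrocentric"),
        ],
    )
    def test_arm_ratio_classes(self, frac, expect_ratio, expect_class):
        L = 40_000_000
        mid = int(frac * L)
        call = CentromereCall("chr1", (mid - 50_000, mid + 50_000), "ONSATA", 100_000)
        assert classify_karyotype(call, L) == expect_class
        assert call.arm_ratio == pytest.approx(expect_ratio, rel=1e-3)

    def test_terminal_centromere_acrocentric(self):
        call = CentromereCall("chr1", (0, 100), "ONSATA", 100)
        assert classify_karyotype(call, 40_000_000) == "acrocentric"

    def test_invariant_under_mirroring(self):
        L = 40_000_000
        for frac in (0.1, 0.3, 0.45, 0.8):
            mid = int(frac * L)
            c1 = CentromereCall("c", (mid - 1000, mid + 1000), "ONSATA", 2000)
            c2 = CentromereCall("c", (L - mid - 1000, L - mid + 1000), "ONSATA", 2000)
            assert classify_karyotype(c1, L) == classify_karyotype(c2, L)


class TestCentromereRepositioning:
    def _call(self, chrom, frac, L=40_000_000):
        mid = int(frac * L)
        call = CentromereCall(chrom, (mid - 1000, mid + 1000), "ONSATA", 2000)
        classify_karyotype(call, L)
        return call

    def test_group_change_reported(self):
        a = [self._call("LG23", 0.9)]   # acrocentric
        b = [self._call("LG23", 0.5)]   # metacentric
        (rec,) = detect_centromere_repositioning(a, b)
        assert rec["chrom_pair"] == ("LG23", "LG23")
        assert rec["class_a"] == "acrocentric" and rec["class_b"] == "metacentric"

    def test_identical_classes_empty(self):
        a = [self._call("LG1", 0.9)]
        b = [self._call("LG1", 0.88)]
        assert detect_centromere_repositioning(a, b) == []

    def test_planted_centromere_move_recovered(self):
        from chromostruct.simulate import (
            PlantedEvent, SimConfig, diverge_species, simulate_genome,
        )

        # reference: centromere near the end (acrocentric); query: moved to mid
        g = simulate_genome(
            SimConfig(chrom_lengths=(40_000_000, 30_000_000),
                      centromere_positions=(0.08, 0.08), seed=61)
        )
        ev = PlantedEvent("centromere_move", ("chr1",), detail={"new_fraction": 0.5})
        pair = diverge_species(g, [ev], seed=62)
        calls_ref = locate_centromeres(g.repeats)
        calls_query = locate_centromeres(pair.query_repeats)
        for c in calls_ref:
            classify_karyotype(c, g.contigs.lengths[c.chrom])
        for c in calls_query:
            classify_karyotype(c, pair.query_contigs.lengths[c.chrom])
        recs = detect_centromere_repositioning(calls_ref, calls_query)
        assert [r["chrom_pair"][0] for r in recs] == ["chr1"]
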