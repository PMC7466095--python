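"""Breakpoint inference, genome merging, lift-over and gene-order checks."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from introdissect import fixtures
from introdissect.ancestry import AncestryCall, GeneVariantCounts
from introdissect.io_formats import GeneModel, VariantRecord
from introdissect.reconstruct import (
    BreakpointInterval,
    MapSegment,
    MultipleBlocksError,
    NoIntrogressionError,
    ReconstructionMap,
    gene_accounting,
    infer_breakpoints,
    liftover,
    longest_increasing_subsequence,
    merge_genomes,
    one_to_one_pairs,
    segment_order_check,
)


def call(gene_id, verdict):
    nb, nd = {"donor": (10, 0), "background": (0, 10),
              "unknown": (0, 0)}[verdict]
    return AncestryCall(gene_id, verdict, GeneVariantCounts(gene_id, nb, nd))


def toy_genes(n=5, chrom="c"):
    return [
        GeneModel(f"g{i}", chrom, 100 + 200 * i, 200 + 200 * i)
        for i in range(n)
    ]


def bg_var(pos, chrom="c"):
    return VariantRecord(chrom, pos, "A", "T", "homozygous", 30.0)


class TestInferBreakpoints:
    def test_hand_enumerated_toy(self):
        genes = toy_genes()  # spans: 100-200, 300-400, 500-600, 700-800, 900-1000
        calls = [call("g0", "background"), call("g1", "background"),
                 call("g2", "donor"), call("g3", "donor"),
                 call("g4", "background")]
        variants = [bg_var(520), bg_var(590), bg_var(710), bg_var(750)]
        (iv,) = infer_breakpoints(calls, genes, variants)
        assert iv.last_background_pos == 400   # end of g1
        assert iv.first_donor_pos == 520
        assert iv.last_donor_pos == 750
        assert iv.first_background_pos == 900  # start of g4
        assert iv.block_gene_ids == ["g2", "g3"]

    def test_all_donor_degenerates_to_chromosome_edges(self):
        genes = toy_genes(3)
        calls = [call(f"g{i}", "donor") for i in range(3)]
        variants = [bg_var(110), bg_var(910)]
        (iv,) = infer_breakpoints(calls, genes, variants)
        assert iv.last_background_pos is None
        assert iv.first_background_pos is None

    def test_zero_donor_calls_is_an_error(self):
        genes = toy_genes(2)
        calls = [call("g0", "background"), call("g1", "background")]
        with pytest.raises(NoIntrogressionError):
            infer_breakpoints(calls, genes, [bg_var(110)])

    def test_two_blocks_rejected_in_strict_mode(self):
        genes = toy_genes(5)
        calls = [call("g0", "donor"), call("g1", "background"),
                 call("g2", "donor"), call("g3", "donor"),
                 call("g4", "background")]
        variants = [bg_var(110), bg_var(520), bg_var(710)]
        with pytest.raises(MultipleBlocksError):
            infer_breakpoints(calls, genes, variants)
        blocks = infer_breakpoints(calls, genes, variants,
                                   strict_single_block=False)
        assert len(blocks) == 2

    def test_unknowns_bridge_up_to_the_configured_gap(self):
        genes = toy_genes(5)
        calls = [call("g0", "donor"), call("g1", "unknown"),
                 call("g2", "unknown"), call("g3", "donor"),
                 call("g4", "background")]
        variants = [bg_var(110), bg_var(750)]
        (iv,) = infer_breakpoints(calls, genes, variants)
        assert iv.block_gene_ids == ["g0", "g1", "g2", "g3"]
        with pytest.raises(MultipleBlocksError):
            infer_breakpoints(calls, genes, variants,
                              max_bridged_unknowns=1)


class TestMergeGenomes:
    BG = {"c": "A" * 50 + "C" * 50, "d": "G" * 30}
    DONOR = {"c": "T" * 120, "d": "G" * 30}

    def _interval(self):
        return BreakpointInterval("c", 20, 31, 70, 81)

    def test_empty_donor_span_returns_background(self):
        iv = self._interval()
        target, rmap = merge_genomes(self.BG, self.DONOR, ("c", 5, 4), iv)
        assert target == self.BG
        assert len(rmap) == 2  # one pass-through segment per chromosome

    def test_length_conservation(self):
        iv = self._interval()
        target, rmap = merge_genomes(self.BG, self.DONOR, ("c", 10, 49), iv)
        lower, upper = iv.cut_points(100)
        replaced = upper - lower
        inserted = 40
        assert len(target["c"]) == 100 - replaced + inserted
        assert len(rmap) == 4  # 3 on the merged chromosome + 1 pass-through

    def test_cut_midpoints(self):
        iv = self._interval()
        assert iv.cut_points(100) == ((20 + 31) // 2, (70 + 81) // 2)

    def test_overlapping_cuts_rejected(self):
        iv = BreakpointInterval("c", 60, 62, 63, 65)
        bad = {"c": "A" * 40}  # upper cut beyond the chromosome
        with pytest.raises(ValueError):
            merge_genomes(bad, self.DONOR, ("c", 1, 10), iv)

    def test_target_sequence_composition(self):
        iv = self._interval()
        target, _ = merge_genomes(self.BG, self.DONOR, ("c", 10, 49), iv)
        lower, upper = iv.cut_points(100)
        assert target["c"] == (
            self.BG["c"][:lower] + self.DONOR["c"][9:49] + self.BG["c"][upper:]
        )


def random_map(rng, n_segments=4):
    """A contiguous target built from alternating random source segments."""
    segs = []
    target_pos = 1
    src_pos = {"background": 1, "donor": 1}
    for i in range(n_segments):
        source = "background" if i % 2 == 0 else "donor"
        length = int(rng.integers(50, 500))
        s = src_pos[source]
        segs.append(MapSegment(source, "c", s, s + length - 1,
                               "t", target_pos, target_pos + length - 1))
        src_pos[source] += length + int(rng.integers(0, 100))
        target_pos += length
    return ReconstructionMap(segs)


class TestLiftover:
    def test_identity_map_leaves_genes_unchanged(self):
        rmap = ReconstructionMap(
            [MapSegment("background", "c", 1, 1000, "c", 1, 1000)]
        )
        genes = toy_genes(3)
        res = liftover(rmap, genes, "background")
        assert res.lifted == genes
        assert not res.chimeric_candidates and not res.unmapped

    def test_round_trip_lift_then_invert(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            rmap = random_map(rng)
            for seg in rmap:
                for pos in (seg.source_start, seg.source_end):
                    t_chrom, t_pos = rmap.lift(seg.source, "c", pos)
                    assert rmap.invert(t_chrom, t_pos) == (
                        seg.source, "c", pos,
                    )

    def test_junction_spanning_gene_is_flagged_not_lifted(self):
        rmap = ReconstructionMap([
            MapSegment("background", "c", 1, 500, "t", 1, 500),
            MapSegment("donor", "c", 1, 500, "t", 501, 1000),
        ])
        spanning = GeneModel("gx", "c", 400, 600)
        res = liftover(rmap, [spanning], "background")
        assert res.lifted == []
        assert res.chimeric_candidates == [spanning]

    def test_uncovered_gene_is_unmapped(self):
        rmap = ReconstructionMap(
            [MapSegment("background", "c", 1, 100, "t", 1, 100)]
        )
        res = liftover(rmap, [GeneModel("gx", "c", 500, 600)], "background")
        assert res.unmapped != []


def brute_force_lis_length(seq):
    best = 0
    for r in range(len(seq), 0, -1):
        for combo in itertools.combinations(seq, r):
            if all(a < b for a, b in zip(combo, combo[1:])):
                return r
    return best


class TestGeneOrder:
    @given(st.lists(st.integers(0, 20), max_size=8))
    @settings(max_examples=150, derandomize=True)
    def test_lis_matches_exhaustive_search(self, seq):
        idx = longest_increasing_subsequence(seq)
        picked = [seq[i] for i in idx]
        assert all(a < b for a, b in zip(picked, picked[1:]))
        assert len(idx) == brute_force_lis_length(seq)

    def test_collinear_input_has_no_translocations(self):
        donor = [f"d{i}" for i in range(6)]
        background = [f"b{i}" for i in range(6)]
        pairs = list(zip(donor, background))
        report = segment_order_check(pairs, donor, background)
        assert report.translocated_blocks == []
        ranks = [d for _, d in report.collinear]
        assert ranks == sorted(ranks)

    def test_reversed_order_keeps_one_pair(self):
        donor = [f"d{i}" for i in range(6)]
        background = [f"b{i}" for i in range(6)]
        pairs = list(zip(donor, reversed(background)))
        report = segment_order_check(pairs, donor, background)
        assert len(report.collinear) == 1
        assert sum(len(b) for b in report.translocated_blocks) == 5

    def test_homology_table_shows_one_translocated_block(self):
        relations, donor_genes, background_genes, _ = fixtures.load_table3()
        report = segment_order_check(
            one_to_one_pairs(relations),
            [g.gene_id for g in donor_genes],
            [g.gene_id for g in background_genes],
        )
        assert len(report.translocated_blocks) == 1


class TestGeneAccounting:
    def test_published_gene_accounting(self):
        _, donor_genes, background_genes, _ = fixtures.load_table3()
        acc = gene_accounting(donor_genes, background_genes)
        assert acc.n_donor == 39
        assert acc.n_background == 33
        assert acc.donor_segment_sizes == [23, 16]
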