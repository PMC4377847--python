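"""Syntenic disruptions, lineage polarization and gene placement."""

from __future__ import annotations

import pytest

from conftest import make_pairs
from oscinova.breakpoints import (
    Lineage,
    Placement,
    SyntenicDisruption,
    find_sds,
    place_genes,
    polarize_all,
    polarize_sd,
)
from oscinova.model import GeneLocus, OrthologPair, Strand
from oscinova.simulate import simulate_genomes
from oscinova.synteny import build_hsbs

M = 100_000


def inversion_instance(config):
    """10 markers with markers 4-7 inverted; returns (blocks, sds)."""
    tgt_pos = [0, 1, 2, 6, 5, 4, 3, 7, 8, 9]
    markers = [("chr1", i * M, "chrA", tgt_pos[i] * M,
                "-" if i in (3, 4, 5, 6) else "+") for i in range(10)]
    res = build_hsbs(make_pairs(markers), config)
    return res.blocks, find_sds(res.blocks, config)


class TestFindSds:
    def test_one_block_per_chromosome_yields_none(self, config):
        markers = [("chr1", i * M, "chrA", i * M) for i in range(5)] + \
                  [("chr2", i * M, "chrB", i * M) for i in range(5)]
        blocks = build_hsbs(make_pairs(markers), config).blocks
        assert find_sds(blocks, config) == []

    def test_planted_inversion_yields_two_boundary_sds(self, config):
        blocks, sds = inversion_instance(config)
        assert len(sds) == 2
        assert all(sd.lineage is Lineage.AMBIGUOUS for sd in sds)
        # the inverted block sits between the two SDs
        inv = [b for b in blocks if b.orientation is Strand.MINUS][0]
        assert sds[0].right_block == inv.block_id
        assert sds[1].left_block == inv.block_id

    def test_marker_sparsity_alone_yields_no_sd(self, config):
        # collinear on the target; only a large reference gap splits the blocks
        markers = [("chr1", i * M + (1_500_000 if i >= 5 else 0),
                    "chrA", i * M) for i in range(10)]
        blocks = build_hsbs(make_pairs(markers), config).blocks
        assert len(blocks) == 2
        assert find_sds(blocks, config) == []

    def test_interchromosomal_sd_is_flagged(self, config):
        markers = [("chr1", i * M, "chrA", i * M) for i in range(4)] + \
                  [("chr1", (5 + i) * M, "chrB", i * M) for i in range(4)]
        blocks = build_hsbs(make_pairs(markers), config).blocks
        sds = find_sds(blocks, config)
        assert len(sds) == 1 and sds[0].interchrom

    def test_sd_spans_disjoint_from_block_spans(self, config):
        _, _, pairs, _ = simulate_genomes(n_genes=200, n_chroms=2,
                                          n_inversions=3, n_translocations=1,
                                          seed=11)
        blocks = build_hsbs(pairs, config).blocks
        for sd in find_sds(blocks, config):
            for b in blocks:
                if b.ref_chrom != sd.ref_chrom:
                    continue
                s, e = sd.sd_span
                assert e <= b.ref_span[0] or b.ref_span[1] <= s

    def test_tandem_groups_mark_runs_of_adjacent_sds(self, config):
        # two inversions separated by one short block -> 4 SDs in a row
        tgt = [0, 1, 4, 3, 2, 5, 6, 9, 8, 7, 10, 11]
        rel = ["+", "+", "-", "-", "-", "+", "+", "-", "-", "-", "+", "+"]
        markers = [("chr1", i * M, "chrA", tgt[i] * M, rel[i])
                   for i in range(12)]
        blocks = build_hsbs(make_pairs(markers), config).blocks
        sds = find_sds(blocks, config)
        assert len(sds) == 4
        groups = {sd.tandem_group for sd in sds}
        assert groups == {0}  # one tandem run of adjacent SDs


class TestPolarize:
    SD = SyntenicDisruption(sd_id=0, ref_chrom="chr1", sd_span=(10, 20),
                            left_block=0, right_block=1)

    def test_outgroups_matching_reference_imply_target_break(self):
        out = polarize_sd(self.SD, ("a", "b"), ("a", "c"),
                          {"og1": [("a", "b")], "og2": [("b", "a")]})
        assert out.lineage is Lineage.TARGET_LINEAGE

    def test_outgroups_matching_target_imply_reference_break(self):
        out = polarize_sd(self.SD, ("a", "b"), ("a", "c"),
                          {"og1": [("a", "c")], "og2": [("c", "a")]})
        assert out.lineage is Lineage.REFERENCE_LINEAGE

    @pytest.mark.parametrize("og1,og2,expected", [
        (("a", "b"), ("a", "b"), Lineage.TARGET_LINEAGE),
        (("a", "c"), ("a", "c"), Lineage.REFERENCE_LINEAGE),
        (("a", "b"), ("a", "c"), Lineage.AMBIGUOUS),
        (("a", "c"), ("a", "b"), Lineage.AMBIGUOUS),
        (("x", "y"), ("x", "y"), Lineage.AMBIGUOUS),  # nothing resolvable
        (("a", "b"), ("x", "y"), Lineage.TARGET_LINEAGE),  # 1 of 1 resolved
    ])
    def test_every_two_outgroup_vote_pattern(self, og1, og2, expected):
        out = polarize_sd(self.SD, ("a", "b"), ("a", "c"),
                          {"og1": [og1], "og2": [og2]})
        assert out.lineage is expected

    def test_polarity_antisymmetry_under_role_swap(self, config):
        ref, tgt, pairs, truth = simulate_genomes(
            n_genes=200, n_chroms=2, n_inversions=2, n_translocations=1,
            seed=5)
        outgroups = {"og1": truth.ancestor_orders, "og2": truth.ancestor_orders}

        def run(pair_list, tgt_orders):
            blocks = build_hsbs(pair_list, config).blocks
            sds = find_sds(blocks, config)
            return polarize_all(sds, blocks, tgt_orders, outgroups)

        fwd = run(pairs, truth.tgt_orders)
        swapped = [OrthologPair(ref=p.tgt, tgt=p.ref) for p in pairs]
        rev = run(swapped, truth.ref_orders)
        assert fwd and rev
        assert all(sd.lineage is Lineage.REFERENCE_LINEAGE for sd in fwd)
        assert all(sd.lineage is Lineage.TARGET_LINEAGE for sd in rev)


class TestPlaceGenes:
    def gene(self, start, end, chrom="chr1", gid="g"):
        return GeneLocus(species="finch", chrom=chrom, start=start, end=end,
                         strand=Strand.PLUS, gene_id=gid)

    def test_gene_inside_sd_span_is_within(self, config):
        blocks, sds = inversion_instance(config)
        s, e = sds[0].sd_span
        assert s < e
        g = self.gene(s + 1, e - 1, gid="novel")
        [p] = place_genes([g], sds, blocks, config)
        assert p.placement is Placement.WITHIN and p.sd_id == sds[0].sd_id

    def test_terminal_block_markers_are_start_and_end(self, config):
        blocks, sds = inversion_instance(config)
        left = [b for b in blocks if b.block_id == sds[0].left_block][0]
        right = [b for b in blocks if b.block_id == sds[0].right_block][0]
        pls = place_genes([left.members[-1].ref, right.members[0].ref],
                          sds, blocks, config)
        assert pls[0].placement is Placement.START
        assert pls[1].placement is Placement.END

    def test_gene_far_from_all_block_termini_is_none(self, config):
        # long collinear block before the inversion: its early markers sit
        # more than flank_genes markers away from any SD-adjacent terminus
        tgt_pos = list(range(8)) + [11, 10, 9, 8] + list(range(12, 16))
        rel = ["+"] * 8 + ["-"] * 4 + ["+"] * 4
        markers = [("chr1", i * M, "chrA", tgt_pos[i] * M, rel[i])
                   for i in range(16)]
        blocks = build_hsbs(make_pairs(markers), config).blocks
        sds = find_sds(blocks, config)
        assert len(sds) == 2
        inner = blocks[0].members[2].ref  # 6 markers from the block terminus
        [p] = place_genes([inner], sds, blocks, config)
        assert p.placement is Placement.NONE

    def test_gene_in_flank_window(self, config):
        blocks, sds = inversion_instance(config)
        left = [b for b in blocks if b.block_id == sds[0].left_block][0]
        # between the 2nd-to-last marker and the terminus of the left block
        anchor = left.members[-2].ref
        g = self.gene(anchor.end + 10, anchor.end + 20, gid="near")
        [p] = place_genes([g], sds, blocks, config)
        assert p.placement is Placement.FLANK

    def test_gene_on_blockless_chromosome_is_none(self, config):
        blocks, sds = inversion_instance(config)
        g = self.gene(0, 100, chrom="chrUn0")
        [p] = place_genes([g], sds, blocks, config)
        assert p.placement is Placement.NONE and p.sd_id is None

    def test_ties_resolve_to_lower_sd_id(self, config):
        blocks, sds = inversion_instance(config)
        # the inverted block lies between the two SDs; its midpoint is
        # equidistant -> nearest() tie -> lower sd id
        inv = [b for b in blocks if b.block_id == sds[0].right_block][0]
        mid = sum(inv.ref_span) // 2
        g = self.gene(mid - 5, mid + 5, gid="tie")
        [p] = place_genes([g], sds, blocks, config)
        assert p.sd_id == sds[0].sd_id
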