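"""Syntenic disruptions (SDs), lineage polarization and gene placement.

An SD is the reference-genome gap between two consecutive HSBs whose
*target* context changes across the junction — a different target
chromosome, an orientation flip, or a target-side displacement beyond
``jump_distance``.  Adjacent collinear blocks separated only by marker
sparsity (a long reference gap with an unremarkable target side) do not
yield an SD.

Each SD is polarized to the lineage in which the underlying
rearrangement occurred by comparing the gene adjacency at the junction
against outgroup genomes: outgroups that share the *reference*
adjacency imply the arrangement is ancestral in the reference, hence
the break happened on the *target* branch, and vice versa.  Votes are
taken by majority over resolvable outgroups; ties are AMBIGUOUS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from .model import GeneLocus, PipelineConfig, Strand
from .synteny import HSB, _expected_displacement

log = logging.getLogger(__name__)

__all__ = [
    "Lineage",
    "SyntenicDisruption",
    "Placement",
    "GenePlacement",
    "find_sds",
    "polarize_sd",
    "polarize_all",
    "place_genes",
    "adjacency_set",
]


class Lineage(str, Enum):
    REFERENCE_LINEAGE = "REFERENCE_LINEAGE"
    TARGET_LINEAGE = "TARGET_LINEAGE"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class SyntenicDisruption:
    sd_id: int
    ref_chrom: str
    sd_span: tuple[int, int]
    left_block: int
    right_block: int
    lineage: Lineage = Lineage.AMBIGUOUS
    interchrom: bool = False
    tandem_group: Optional[int] = None

    @property
    def length(self) -> int:
        return self.sd_span[1] - self.sd_span[0]


class Placement(str, Enum):
    START = "START"
    END = "END"
    WITHIN = "WITHIN"
    FLANK = "FLANK"
    NONE = "NONE"

    @property
    def sd_associated(self) -> bool:
        """A gene counts as SD-associated when it sits at the start,
        end, or within an SD region (FLANK is near, not at)."""
        return self in (Placement.START, Placement.END, Placement.WITHIN)


@dataclass(frozen=True)
class GenePlacement:
    gene_id: str
    sd_id: Optional[int]
    placement: Placement


def _context_changes(left: HSB, right: HSB, config: PipelineConfig) -> bool:
    if left.tgt_chrom != right.tgt_chrom:
        return True
    if left.orientation != right.orientation:
        return True
    return _expected_displacement(left, right) > config.jump_distance


def find_sds(hsbs: Sequence[HSB],
             config: Optional[PipelineConfig] = None) -> list[SyntenicDisruption]:
    """One SD per adjacent block pair (same reference chromosome) whose
    target context changes.  Lineage starts AMBIGUOUS; runs of adjacent
    SDs separated by short blocks share a ``tandem_group``."""
    config = config or PipelineConfig()
    by_chrom: dict[str, list[HSB]] = {}
    for b in hsbs:
        by_chrom.setdefault(b.ref_chrom, []).append(b)

    sds: list[SyntenicDisruption] = []
    for chrom in sorted(by_chrom):
        blocks = sorted(by_chrom[chrom], key=lambda b: b.ref_span[0])
        for left, right in zip(blocks, blocks[1:]):
            if not _context_changes(left, right, config):
                continue
            start = left.ref_span[1]
            end = max(start, right.ref_span[0])
            sds.append(
                SyntenicDisruption(
                    sd_id=len(sds),
                    ref_chrom=chrom,
                    sd_span=(start, end),
                    left_block=left.block_id,
                    right_block=right.block_id,
                    interchrom=left.tgt_chrom != right.tgt_chrom,
                )
            )
    # tandem groups: consecutive SDs sharing a short intervening block
    block_len = {b.block_id: b.ref_length for b in hsbs}
    group = -1
    prev: Optional[SyntenicDisruption] = None
    out: list[SyntenicDisruption] = []
    for sd in sds:
        tandem = (
            prev is not None
            and prev.ref_chrom == sd.ref_chrom
            and prev.right_block == sd.left_block
            and block_len[sd.left_block] < config.min_report_length
        )
        if tandem:
            if out[-1].tandem_group is None:
                group += 1
                out[-1] = replace(out[-1], tandem_group=group)
            out.append(replace(sd, tandem_group=group))
        else:
            out.append(sd)
        prev = sd
    return out


def adjacency_set(orders: Mapping[str, Sequence[str]]) -> set[frozenset]:
    """All unordered adjacent gene-id pairs of a genome given as
    chromosome -> ordered gene-id list."""
    adj: set[frozenset] = set()
    for genes in orders.values():
        for a, b in zip(genes, genes[1:]):
            adj.add(frozenset((a, b)))
    return adj


def polarize_sd(
    sd: SyntenicDisruption,
    ref_adj: tuple[str, str],
    tgt_adj: Optional[tuple[str, str]],
    outgroup_adjs: Mapping[str, Iterable[tuple[str, str]]],
) -> SyntenicDisruption:
    """Assign the SD's lineage by majority vote over outgroups.

    ``ref_adj``/``tgt_adj`` are the ordered junction gene pairs in the
    reference and target genomes (gene ids in the shared ortholog
    namespace); ``outgroup_adjs`` maps each outgroup to its adjacency
    pairs around the region.  Matching is order- and strand-agnostic.
    An outgroup showing the reference adjacency votes for a break on
    the target branch, and vice versa; outgroups showing both or
    neither are unresolved.
    """
    ref_key = frozenset(ref_adj)
    tgt_key = frozenset(tgt_adj) if tgt_adj else None
    ref_votes = tgt_votes = resolved = 0
    for adjs in outgroup_adjs.values():
        keys = {frozenset(a) for a in adjs}
        has_ref = ref_key in keys
        has_tgt = tgt_key in keys if tgt_key else False
        if has_ref == has_tgt:
            continue
        resolved += 1
        if has_ref:
            ref_votes += 1
        else:
            tgt_votes += 1
    if resolved == 0:
        log.warning("SD %d on %s: no resolvable outgroup adjacency; AMBIGUOUS",
                    sd.sd_id, sd.ref_chrom)
        return replace(sd, lineage=Lineage.AMBIGUOUS)
    if ref_votes > tgt_votes:
        return replace(sd, lineage=Lineage.TARGET_LINEAGE)
    if tgt_votes > ref_votes:
        return replace(sd, lineage=Lineage.REFERENCE_LINEAGE)
    return replace(sd, lineage=Lineage.AMBIGUOUS)


def _junction_genes(left: HSB, right: HSB) -> tuple[str, str]:
    return left.members[-1].ref.gene_id, right.members[0].ref.gene_id


def _tgt_neighbour_outside_block(gene_id: str, block: HSB,
                                 tgt_orders: Mapping[str, Sequence[str]]
                                 ) -> Optional[str]:
    in_block = {p.ref.gene_id for p in block.members}
    for genes in tgt_orders.values():
        if gene_id in genes:
            i = genes.index(gene_id)
            for j in (i - 1, i + 1):
                if 0 <= j < len(genes) and genes[j] not in in_block:
                    return genes[j]
    return None


def polarize_all(
    sds: Sequence[SyntenicDisruption],
    hsbs: Sequence[HSB],
    tgt_orders: Mapping[str, Sequence[str]],
    outgroup_orders: Mapping[str, Mapping[str, Sequence[str]]],
) -> list[SyntenicDisruption]:
    """Polarize every SD from genome gene orders.

    ``tgt_orders`` is the target genome's marker order (chromosome ->
    gene ids in the reference/ortholog namespace); ``outgroup_orders``
    maps outgroup name -> the same structure.
    """
    by_id = {b.block_id: b for b in hsbs}
    out_adj = {name: adjacency_set(orders)
               for name, orders in outgroup_orders.items()}
    result = []
    for sd in sds:
        left, right = by_id[sd.left_block], by_id[sd.right_block]
        gl, gr = _junction_genes(left, right)
        ref_adj = (gl, gr)
        partner = _tgt_neighbour_outside_block(gl, left, tgt_orders)
        tgt_adj = (gl, partner) if partner else None
        result.append(polarize_sd(sd, ref_adj, tgt_adj, out_adj))
    return result


def _overlaps_point(g: GeneLocus, point: int) -> bool:
    return g.start <= point < g.end or g.start == point


def place_genes(
    genes: Sequence[GeneLocus],
    sds: Sequence[SyntenicDisruption],
    hsbs: Sequence[HSB],
    config: Optional[PipelineConfig] = None,
) -> list[GenePlacement]:
    """One deterministic placement per gene relative to the SD map.

    WITHIN: the gene interval lies inside the SD span.  START/END: the
    gene overlaps the SD boundary or is the terminal marker of the
    adjacent block.  FLANK: the gene lies within the reference span of
    the ``flank_genes`` markers nearest a block terminus adjacent to an
    SD.  NONE otherwise (including genes on chromosomes without
    blocks).  A gene matching several SDs goes to the nearest (ties:
    lower sd_id).
    """
    config = config or PipelineConfig()
    by_id = {b.block_id: b for b in hsbs}
    sds_by_chrom: dict[str, list[SyntenicDisruption]] = {}
    for sd in sds:
        sds_by_chrom.setdefault(sd.ref_chrom, []).append(sd)

    placements = []
    for g in genes:
        cands = sds_by_chrom.get(g.chrom, [])
        if not cands:
            placements.append(GenePlacement(g.gene_id, None, Placement.NONE))
            continue

        def dist(sd: SyntenicDisruption) -> int:
            s, e = sd.sd_span
            if g.end <= s:
                return s - g.end
            if g.start >= e:
                return g.start - e
            return 0

        sd = min(cands, key=lambda sd: (dist(sd), sd.sd_id))
        placements.append(GenePlacement(g.gene_id, sd.sd_id,
                                        _classify_placement(g, sd, by_id, config)))
    return placements


def _classify_placement(g: GeneLocus, sd: SyntenicDisruption,
                        blocks: Mapping[int, HSB],
                        config: PipelineConfig) -> Placement:
    s, e = sd.sd_span
    left, right = blocks[sd.left_block], blocks[sd.right_block]
    if s <= g.start and g.end <= e and g.length > 0:
        return Placement.WITHIN
    is_left_terminal = g.gene_id == left.members[-1].ref.gene_id
    is_right_terminal = g.gene_id == right.members[0].ref.gene_id
    if is_left_terminal or (g.start < s <= g.end and g.end <= e):
        return Placement.START
    if is_right_terminal or (g.start < e < g.end or (s <= g.start < e < g.end)):
        return Placement.END
    if g.start < s and g.end > e:  # spans the whole (possibly empty) SD
        return Placement.WITHIN if s == e else Placement.START
    k = config.flank_genes
    left_flank_start = left.members[-min(k, len(left.members))].ref.start
    if left_flank_start <= g.start and g.end <= s:
        return Placement.FLANK
    right_flank_end = right.members[min(k, len(right.members)) - 1].ref.end
    if e <= g.start and g.end <= right_flank_end:
        return Placement.FLANK
    return Placement.NONE
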