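"""Homologous synteny block (HSB) construction and rearrangement labels.

An HSB is a run of two or more adjacent one-to-one ortholog markers
that appear without interruption and on the same chromosome pair in the
two genomes compared.  Within a block, markers are strictly increasing
on the reference and strictly monotone on the target (increasing for
orientation ``+``, decreasing for ``-``), and consecutive markers lie
within ``max_marker_gap`` of each other on *both* genomes.

Blocks are built by a greedy left-to-right sweep per reference
chromosome.  Because block validity is prefix-closed (every prefix of a
valid run is itself valid), the sweep produces, at each starting
marker, the longest valid run beginning there — i.e. a partition into
maximal blocks with ties resolved toward the upstream (lower reference
coordinate) block.  Runs shorter than ``min_block_genes`` are reported
as singletons, never as blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from .model import OrthologPair, PipelineConfig, Strand

__all__ = [
    "HSB",
    "RearrangementKind",
    "RearrangementLabel",
    "BlockBuildResult",
    "build_hsbs",
    "label_rearrangements",
]


@dataclass(frozen=True)
class HSB:
    """An ordered, orientation-consistent run of ortholog markers."""

    block_id: int
    ref_chrom: str
    tgt_chrom: str
    ref_span: tuple[int, int]
    tgt_span: tuple[int, int]
    orientation: Strand
    members: tuple[OrthologPair, ...]

    @property
    def n_genes(self) -> int:
        return len(self.members)

    @property
    def ref_length(self) -> int:
        return self.ref_span[1] - self.ref_span[0]

    @property
    def tgt_length(self) -> int:
        return self.tgt_span[1] - self.tgt_span[0]


class RearrangementKind(str, Enum):
    COLLINEAR = "COLLINEAR"
    INVERSION = "INVERSION"
    TRANSLOCATION = "TRANSLOCATION"
    TRANSPOSITION = "TRANSPOSITION"


@dataclass(frozen=True)
class RearrangementLabel:
    block_id: int
    kind: RearrangementKind


@dataclass
class BlockBuildResult:
    blocks: list[HSB]
    singletons: list[OrthologPair]


def _ref_key(p: OrthologPair) -> tuple:
    return (p.ref.chrom, p.ref.start, p.ref.gene_id)


def _relative_orientation(p: OrthologPair) -> int:
    """+1 when the marker keeps its strand between the genomes, -1 when
    it is flipped (the signature of lying inside an inverted segment)."""
    return 1 if p.ref.strand == p.tgt.strand else -1


def _pair_extends(prev: OrthologPair, nxt: OrthologPair, direction: int,
                  config: PipelineConfig) -> Optional[int]:
    """Whether ``nxt`` may follow ``prev`` inside one block.

    Returns the (possibly updated) target direction (+1 up, -1 down,
    0 still undecided), or None when the extension is invalid.
    ``direction`` 0 means no non-zero target step has been seen yet.
    Orientation consistency requires both the target coordinates to
    stay monotone and the markers' relative strands to agree — a
    strand-flipped marker never extends an unflipped run, which keeps
    block boundaries on the true inversion breakpoints instead of
    absorbing the first inverted marker into the upstream block.
    """
    if nxt.ref.chrom != prev.ref.chrom or nxt.tgt.chrom != prev.tgt.chrom:
        return None
    if _relative_orientation(nxt) != _relative_orientation(prev):
        return None
    ref_gap = nxt.ref.start - prev.ref.end
    if ref_gap > config.max_marker_gap:
        return None
    delta = nxt.tgt.start - prev.tgt.start
    step = 0 if delta == 0 else (1 if delta > 0 else -1)
    if step and direction and step != direction:
        return None
    # inter-marker distance on the target genome
    if step >= 0:
        tgt_gap = nxt.tgt.start - prev.tgt.end
    else:
        tgt_gap = prev.tgt.start - nxt.tgt.end
    if tgt_gap > config.max_marker_gap:
        return None
    return step or direction


def _finish_block(members: list[OrthologPair], direction: int,
                  block_id: int) -> HSB:
    ref_start = min(p.ref.start for p in members)
    ref_end = max(p.ref.end for p in members)
    tgt_start = min(p.tgt.start for p in members)
    tgt_end = max(p.tgt.end for p in members)
    # degenerate (no non-zero target step): orientation defaults to '+'
    orientation = Strand.MINUS if direction < 0 else Strand.PLUS
    return HSB(
        block_id=block_id,
        ref_chrom=members[0].ref.chrom,
        tgt_chrom=members[0].tgt.chrom,
        ref_span=(ref_start, ref_end),
        tgt_span=(tgt_start, tgt_end),
        orientation=orientation,
        members=tuple(members),
    )


def build_hsbs(pairs: Sequence[OrthologPair],
               config: Optional[PipelineConfig] = None) -> BlockBuildResult:
    """Partition ortholog markers into maximal HSBs plus singletons.

    Input row order is irrelevant (markers are sorted internally by
    reference coordinate).  Only one-to-one pairs are admitted; others
    are reported among the singletons.
    """
    config = config or PipelineConfig()
    admitted = sorted((p for p in pairs if p.one_to_one), key=_ref_key)
    rejected = [p for p in pairs if not p.one_to_one]

    blocks: list[HSB] = []
    singletons: list[OrthologPair] = list(rejected)
    run: list[OrthologPair] = []
    direction = 0

    def close_run() -> None:
        nonlocal run, direction
        if len(run) >= config.min_block_genes:
            blocks.append(_finish_block(run, direction, len(blocks)))
        else:
            singletons.extend(run)
        run, direction = [], 0

    for p in admitted:
        if not run:
            run.append(p)
            continue
        new_dir = _pair_extends(run[-1], p, direction, config)
        if new_dir is None:
            close_run()
            run.append(p)
        else:
            direction = new_dir
            run.append(p)
    if run:
        close_run()

    blocks.sort(key=lambda b: (b.ref_chrom, b.ref_span[0]))
    blocks = [
        HSB(block_id=i, ref_chrom=b.ref_chrom, tgt_chrom=b.tgt_chrom,
            ref_span=b.ref_span, tgt_span=b.tgt_span,
            orientation=b.orientation, members=b.members)
        for i, b in enumerate(blocks)
    ]
    singletons.sort(key=_ref_key)
    return BlockBuildResult(blocks=blocks, singletons=singletons)


def reportable_blocks(result: BlockBuildResult,
                      config: Optional[PipelineConfig] = None) -> list[HSB]:
    """Reporting view: blocks at least ``min_report_length`` long on the
    reference.  Short blocks stay in ``result.blocks`` so that syntenic
    disruption positions are not lost."""
    config = config or PipelineConfig()
    return [b for b in result.blocks if b.ref_length >= config.min_report_length]


def _expected_displacement(left: HSB, right: HSB) -> int:
    """Absolute target-side displacement of ``right`` relative to where
    a perfectly collinear continuation of ``left`` would put it."""
    ref_gap = right.ref_span[0] - left.ref_span[1]
    if left.orientation is Strand.PLUS:
        expected = left.tgt_span[1] + ref_gap
        return abs(right.tgt_span[0] - expected)
    expected = left.tgt_span[0] - ref_gap
    return abs(right.tgt_span[1] - expected)


def label_rearrangements(hsbs: Sequence[HSB],
                         config: Optional[PipelineConfig] = None
                         ) -> list[RearrangementLabel]:
    """Label each block relative to its chromosome-pair context.

    Per reference chromosome: blocks whose target chromosome differs
    from the marker-weighted majority are TRANSLOCATION; blocks whose
    orientation is the minority among the remaining blocks are
    INVERSION; blocks in the majority orientation but displaced on the
    target by more than ``jump_distance`` from both neighbours are
    TRANSPOSITION; everything else is COLLINEAR.
    """
    config = config or PipelineConfig()
    labels: dict[int, RearrangementKind] = {}
    by_chrom: dict[str, list[HSB]] = {}
    for b in hsbs:
        by_chrom.setdefault(b.ref_chrom, []).append(b)

    for chrom_blocks in by_chrom.values():
        chrom_blocks = sorted(chrom_blocks, key=lambda b: b.ref_span[0])
        # marker-weighted majority target chromosome
        weight: dict[str, int] = {}
        for b in chrom_blocks:
            weight[b.tgt_chrom] = weight.get(b.tgt_chrom, 0) + b.n_genes
        major_tgt = max(sorted(weight), key=lambda c: weight[c])
        same = [b for b in chrom_blocks if b.tgt_chrom == major_tgt]
        for b in chrom_blocks:
            if b.tgt_chrom != major_tgt:
                labels[b.block_id] = RearrangementKind.TRANSLOCATION
        # majority orientation among blocks on the majority chromosome
        plus = sum(b.n_genes for b in same if b.orientation is Strand.PLUS)
        minus = sum(b.n_genes for b in same if b.orientation is Strand.MINUS)
        major_orient = Strand.MINUS if minus > plus else Strand.PLUS
        collinear = []
        for b in same:
            if b.orientation is not major_orient and len(same) > 1:
                labels[b.block_id] = RearrangementKind.INVERSION
            else:
                collinear.append(b)
        for i, b in enumerate(collinear):
            if len(collinear) == 1:
                labels.setdefault(b.block_id, RearrangementKind.COLLINEAR)
                continue
            disps = []
            if i > 0:
                disps.append(_expected_displacement(collinear[i - 1], b))
            if i + 1 < len(collinear):
                disps.append(_expected_displacement(b, collinear[i + 1]))
            if disps and min(disps) > config.jump_distance:
                labels[b.block_id] = RearrangementKind.TRANSPOSITION
            else:
                labels.setdefault(b.block_id, RearrangementKind.COLLINEAR)

    return [RearrangementLabel(block_id=b.block_id, kind=labels[b.block_id])
            for b in sorted(hsbs, key=lambda b: b.block_id)]
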