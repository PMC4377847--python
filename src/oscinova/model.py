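"""Core domain types shared by every stage of the pipeline.

Coordinate convention
---------------------
All coordinates held in memory are 0-based, half-open ``[start, end)`` —
the convention of BED and of Python slicing.  External tables (gene
annotation TSVs, GFF3, the coordinates printed in genome browsers) are
1-based inclusive; conversion happens exactly once, at the I/O boundary
(:mod:`oscinova.io`).  ``GeneLocus.length`` is therefore simply
``end - start``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

__all__ = [
    "Strand",
    "Clade",
    "GeneLocus",
    "OrthologPair",
    "AlignmentHit",
    "CladePanel",
    "PipelineConfig",
]


class Strand(str, Enum):
    PLUS = "+"
    MINUS = "-"

    def flipped(self) -> "Strand":
        return Strand.MINUS if self is Strand.PLUS else Strand.PLUS


class Clade(str, Enum):
    """Clade labels of the comparative panel.

    The panel mirrors the 52-organism screen used to establish
    phylogenetic origin: 3 songbirds, 1 suboscine, 1 basal passerine
    (New Zealand wren), 1 parrot, 42 further avians (two of them
    galliforms) and 4 non-avian vertebrates.
    """

    SONGBIRD = "SONGBIRD"
    SUBOSCINE = "SUBOSCINE"
    BASAL_PASSERINE = "BASAL_PASSERINE"
    PARROT = "PARROT"
    OTHER_NEOAVES = "OTHER_NEOAVES"
    GALLIFORM = "GALLIFORM"
    NON_AVIAN = "NON_AVIAN"


# chromosome names that indicate unplaced or unreliable sequence
_UNPLACED_RE = re.compile(r"(_random$)|(^chrUn)|(^Un$)|(^chromosome[_ ]?Unknown$)", re.I)


def is_unplaced_chrom(chrom: str) -> bool:
    """True for ``*_random``, ``chrUn*`` and "chromosome Unknown" names.

    Loci on such sequences are accepted by the readers but flagged, and
    are excluded from novelty calls (they frequently hold allelic
    variants rather than real paralogs).
    """
    return bool(_UNPLACED_RE.search(chrom))


@dataclass(frozen=True)
class GeneLocus:
    """A placed gene or gene model on one species' assembly.

    ``start``/``end`` are 0-based half-open.  ``is_model`` marks
    automated predictions (as opposed to curated genes); ``gap_flanked``
    marks loci abutting assembly gaps, which weakens absence/identity
    arguments made about them.
    """

    species: str
    chrom: str
    start: int
    end: int
    strand: Strand
    gene_id: str
    symbol: Optional[str] = None
    is_model: bool = False
    gap_flanked: bool = False

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(
                f"invalid interval for {self.gene_id}: [{self.start}, {self.end})"
            )
        if not isinstance(self.strand, Strand):
            object.__setattr__(self, "strand", Strand(self.strand))

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    @property
    def unplaced(self) -> bool:
        return is_unplaced_chrom(self.chrom)

    def with_position(self, chrom: str, start: int, end: int) -> "GeneLocus":
        return replace(self, chrom=chrom, start=start, end=end)


@dataclass(frozen=True)
class OrthologPair:
    """A one-to-one ortholog marker linking the reference genome (the
    zebra-finch role) to the target genome (the chicken role)."""

    ref: GeneLocus
    tgt: GeneLocus
    one_to_one: bool = True

    def __post_init__(self) -> None:
        if self.ref.species == self.tgt.species:
            raise ValueError(
                f"ortholog pair {self.ref.gene_id}/{self.tgt.gene_id} links a "
                "species to itself"
            )


@dataclass(frozen=True)
class AlignmentHit:
    """One alignment of a candidate model to a subject genome.

    ``blocks`` is the ordered list of aligned segments,
    ``((q_start, q_end), (s_start, s_end))`` in 0-based half-open
    coordinates, non-overlapping and ascending on the query.
    """

    query_id: str
    subject_species: str
    subject_chrom: str
    subject_start: int
    subject_end: int
    subject_strand: Strand
    score: float
    percent_identity: float
    blocks: tuple = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError(
                f"percent identity {self.percent_identity} out of [0, 100] "
                f"for hit of {self.query_id}"
            )
        prev_end = -1
        for (qs, qe), _ in self.blocks:
            if qs < prev_end:
                raise ValueError(
                    f"blocks of {self.query_id} overlap or are out of order on the query"
                )
            prev_end = qe
        if not isinstance(self.subject_strand, Strand):
            object.__setattr__(self, "subject_strand", Strand(self.subject_strand))

    @property
    def aligned_span(self) -> int:
        return self.subject_end - self.subject_start

    @property
    def query_coverage_bp(self) -> int:
        return sum(qe - qs for (qs, qe), _ in self.blocks)


@dataclass
class CladePanel:
    """Ordered species panel with one clade label per species.

    ``finch_species`` names the songbird subset forming the finch
    lineage (used to distinguish finch-specific duplications, present in
    both finches but not the crow, from single-species suspects).
    ``required_counts`` allows completeness checks against an expected
    design, e.g. ``{Clade.SONGBIRD: 3}``.
    """

    species: list[str]
    clade_of: dict[str, Clade]
    required_counts: dict[Clade, int] = field(default_factory=dict)
    finch_species: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        missing = [s for s in self.species if s not in self.clade_of]
        if missing:
            raise ValueError(f"species without a clade label: {missing}")
        extra = set(self.clade_of) - set(self.species)
        if extra:
            raise ValueError(f"clade labels for unknown species: {sorted(extra)}")
        self.clade_of = {s: Clade(c) for s, c in self.clade_of.items()}
        for c, n in self.required_counts.items():
            have = len(self.of_clade(c))
            if have != n:
                raise ValueError(f"expected {n} species of clade {c}, found {have}")
        if len(self.of_clade(Clade.SONGBIRD)) < 2:
            raise ValueError("a panel needs >= 2 songbird species for origin calls")

    def of_clade(self, clade: Clade) -> list[str]:
        clade = Clade(clade)
        return [s for s in self.species if self.clade_of[s] == clade]

    @property
    def songbirds(self) -> list[str]:
        return self.of_clade(Clade.SONGBIRD)

    @property
    def passerines(self) -> list[str]:
        out = []
        for s in self.species:
            if self.clade_of[s] in (
                Clade.SONGBIRD,
                Clade.SUBOSCINE,
                Clade.BASAL_PASSERINE,
            ):
                out.append(s)
        return out

    @property
    def galliforms(self) -> list[str]:
        return self.of_clade(Clade.GALLIFORM)

    @property
    def non_avians(self) -> list[str]:
        return self.of_clade(Clade.NON_AVIAN)

    @property
    def avians(self) -> list[str]:
        return [s for s in self.species if self.clade_of[s] != Clade.NON_AVIAN]


@dataclass
class PipelineConfig:
    """Tunable thresholds of the whole pipeline.

    Defaults follow the synteny-block and curation parameterization the
    analysis was designed around: markers more than ``max_marker_gap``
    (1 Mb) apart never share a block; a block needs at least
    ``min_block_genes`` (2) markers; blocks shorter than
    ``min_report_length`` (2 Mb) are hidden from *reporting* views only;
    a collinear block displaced by more than ``jump_distance`` (2 Mb) is
    treated as transposed; alignment hits must score strictly above
    ``min_hit_score`` (50); syntenic context uses ``flank_genes`` (3)
    genes on each side; tandem duplicates above ``allele_identity``
    (95%) identity flanked by gaps are assembly suspects.
    """

    max_marker_gap: int = 1_000_000
    min_block_genes: int = 2
    min_report_length: int = 2_000_000
    jump_distance: int = 2_000_000
    min_hit_score: float = 50.0
    flank_genes: int = 3
    allele_identity: float = 95.0
    context_threshold: float = 0.5
    query_coverage_floor: float = 0.3
    tandem_max_spacing: int = 100_000
    large_family_cap: int = 8
    identity_margin: float = 1.0
    max_missing: int = 0
    split_on_jump: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("max_marker_gap", "min_report_length", "jump_distance",
                     "tandem_max_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.flank_genes < 1:
            raise ValueError("flank_genes must be >= 1")
        if self.min_block_genes < 2:
            raise ValueError("min_block_genes must be >= 2 (a block is >= 2 genes)")


def check_unique_gene_ids(loci: Sequence[GeneLocus]) -> None:
    """Raise if (species, gene_id) repeats within a table."""
    seen: set[tuple[str, str]] = set()
    dups = []
    for g in loci:
        key = (g.species, g.gene_id)
        if key in seen:
            dups.append(g.gene_id)
        seen.add(key)
    if dups:
        raise ValueError(f"duplicate gene ids in table: {sorted(set(dups))}")
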