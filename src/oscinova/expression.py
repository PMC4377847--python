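"""EST/cDNA locus assignment and tissue-expression categories.

ESTs that cross-align to several paralogous loci are only informative
when they can be pinned to one locus: by a single passing hit, by an
exon present at only one locus, or by a decisive identity margin.
Locus-specific brain clones are the only admissible brain evidence;
non-brain evidence comes from non-brain clones and RNA-seq tissue
presence calls (which are inputs here, not computed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

from .model import AlignmentHit, PipelineConfig

__all__ = [
    "TISSUES",
    "ExpressionEvidence",
    "ExpressionCategory",
    "EstAssignment",
    "assign_est_to_locus",
    "expression_category",
]

TISSUES = frozenset({"embryo", "liver", "muscle", "skin", "spleen", "testes"})


@dataclass(frozen=True)
class EstAssignment:
    clone_id: str
    locus_id: Optional[str]          # None when ambiguous
    candidates: tuple[str, ...]      # tied loci when ambiguous
    rule: str                        # which rule decided

    @property
    def ambiguous(self) -> bool:
        return self.locus_id is None


def assign_est_to_locus(
    clone_id: str,
    hits: Sequence[AlignmentHit],
    loci_exon_models: Mapping[str, Sequence[tuple[str, int, int]]],
    config: Optional[PipelineConfig] = None,
) -> EstAssignment:
    """Assign a clone to a unique locus, or declare it ambiguous.

    ``hits`` are the clone's filtered alignments; each hit's
    ``subject_chrom`` is taken as the locus id it aligns to (paralogs
    are distinct loci).  ``loci_exon_models`` maps locus id -> labelled
    exons ``(label, start, end)`` in that locus' subject coordinates;
    exon labels shared across paralogs denote homologous exons.

    Decision order: (a) exactly one passing hit; (b) the clone covers
    an exon whose label occurs at only one candidate locus; (c) one
    hit's percent identity beats all others by at least
    ``identity_margin``.  Otherwise AMBIGUOUS with the tied loci.
    """
    config = config or PipelineConfig()
    passing = [h for h in hits if h.score > config.min_hit_score]
    loci = sorted({h.subject_chrom for h in passing})
    if not passing:
        return EstAssignment(clone_id, None, (), "no_passing_hit")
    if len(loci) == 1:
        return EstAssignment(clone_id, loci[0], tuple(loci), "single_hit")

    # (b) unique-exon rule
    label_sites: dict[str, set[str]] = {}
    for locus, exons in loci_exon_models.items():
        for label, _s, _e in exons:
            label_sites.setdefault(label, set()).add(locus)
    best_by_locus = {
        locus: max(
            (h for h in passing if h.subject_chrom == locus),
            key=lambda h: (h.score, h.aligned_span),
        )
        for locus in loci
    }
    for locus in loci:
        hit = best_by_locus[locus]
        covered = _covered_exons(hit, loci_exon_models.get(locus, ()))
        for label in covered:
            if label_sites.get(label, set()) == {locus}:
                return EstAssignment(clone_id, locus, tuple(loci),
                                     f"unique_exon:{label}")

    # (c) identity margin
    ranked = sorted(
        best_by_locus.items(), key=lambda kv: -kv[1].percent_identity
    )
    if len(ranked) > 1:
        top, second = ranked[0][1], ranked[1][1]
        if top.percent_identity - second.percent_identity >= config.identity_margin:
            return EstAssignment(clone_id, ranked[0][0], tuple(loci),
                                 "identity_margin")
    return EstAssignment(clone_id, None, tuple(loci), "ambiguous")


def _covered_exons(hit: AlignmentHit,
                   exons: Sequence[tuple[str, int, int]]) -> list[str]:
    blocks = [sub for _q, sub in hit.blocks] or [(hit.subject_start, hit.subject_end)]
    out = []
    for label, s, e in exons:
        if any(bs < e and s < be for bs, be in blocks):
            out.append(label)
    return out


@dataclass
class ExpressionEvidence:
    """Assembled expression evidence for one locus."""

    locus_id: str
    brain_clones: list[tuple[str, bool]] = field(default_factory=list)
    non_brain_clones: list[tuple[str, bool]] = field(default_factory=list)
    rnaseq_tissues: frozenset = frozenset()
    in_situ_note: Optional[str] = None  # qualitative annotation only

    def __post_init__(self) -> None:
        unknown = set(self.rnaseq_tissues) - TISSUES
        if unknown:
            raise ValueError(f"{self.locus_id}: unknown tissues {sorted(unknown)}")
        self.rnaseq_tissues = frozenset(self.rnaseq_tissues)


class ExpressionCategory(str, Enum):
    NONE = "NONE"
    NON_BRAIN_ONLY = "NON_BRAIN_ONLY"
    BRAIN_AND_OTHER = "BRAIN_AND_OTHER"
    BRAIN_ONLY = "BRAIN_ONLY"


def expression_category(ev: ExpressionEvidence) -> ExpressionCategory:
    """Fold evidence into one of four tissue-expression classes.

    Brain evidence requires a locus-specific brain clone; any non-brain
    clone or RNA-seq tissue counts as non-brain evidence.
    """
    brain = any(specific for _cid, specific in ev.brain_clones)
    other = bool(ev.non_brain_clones) or bool(ev.rnaseq_tissues)
    if brain and other:
        return ExpressionCategory.BRAIN_AND_OTHER
    if brain:
        return ExpressionCategory.BRAIN_ONLY
    if other:
        return ExpressionCategory.NON_BRAIN_ONLY
    return ExpressionCategory.NONE
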