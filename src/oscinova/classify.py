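"""Curation and phylogenetic-origin classification of candidate genes.

Two decision layers mirror the curation procedure for putatively novel
or duplicated gene models:

1. **Artefact triage** (:func:`classify_artefact`): each candidate is
   assigned exactly one curation category — split Ensembl-style models,
   tandem or inter-chromosomal false-positive duplications, duplications
   shared with galliforms/non-avians, fragments of known genes,
   uncharacterized genes with an ortholog, retrocopies, assembly
   suspects, deferred mega-families — or passes curation.

2. **Origin calling** (:func:`classify_origin`): candidates that pass
   curation are classified from their presence/absence pattern across
   the clade panel: unique to songbirds, finch-specific, passerine,
   widely present but absent from galliforms, single-species suspects,
   or not novel.

The novel-gene counting rule (:func:`count_novel_genes`) resolves
families whose parent copy cannot be determined: a family of *k*
indistinguishable copies contributes *k − 1* novel genes (one copy
stands for the ancestral locus); a de novo gene (no parent anywhere)
contributes 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

from .model import AlignmentHit, CladePanel, GeneLocus, PipelineConfig

__all__ = [
    "PresenceStatus",
    "PresenceCall",
    "Origin",
    "OriginCall",
    "ArtefactCategory",
    "ArtefactCall",
    "CandidateRecord",
    "ParentInfo",
    "ContextResult",
    "NovelGeneCount",
    "filter_hits",
    "syntenic_context",
    "call_presence",
    "classify_origin",
    "classify_artefact",
    "detect_tandem_copies",
    "count_novel_genes",
]


class PresenceStatus(str, Enum):
    PRESENT_SYNTENIC = "PRESENT_SYNTENIC"
    PRESENT_UNPLACED = "PRESENT_UNPLACED"
    ABSENT = "ABSENT"


@dataclass(frozen=True)
class PresenceCall:
    candidate_id: str
    species: str
    status: PresenceStatus
    best_hit: Optional[AlignmentHit] = None
    context_score: float = 0.0
    context_limited: bool = False

    @property
    def present(self) -> bool:
        return self.status is not PresenceStatus.ABSENT


class Origin(str, Enum):
    SONGBIRD_UNIQUE = "SONGBIRD_UNIQUE"
    FINCH_SPECIFIC = "FINCH_SPECIFIC"
    PASSERINE = "PASSERINE"
    NEOAVES_OR_GALLIFORM_LOSS = "NEOAVES_OR_GALLIFORM_LOSS"
    SINGLE_SPECIES_SUSPECT = "SINGLE_SPECIES_SUSPECT"
    NOT_NOVEL = "NOT_NOVEL"


@dataclass(frozen=True)
class ParentInfo:
    """Family structure of a candidate.

    ``parent_known`` — the ancestral copy is identified (``parent_id``);
    ``de_novo`` — no parent exists anywhere (the gene arose from
    previously non-coding sequence).  Families of indistinguishable
    tandem copies have ``parent_known=False`` and share a ``family``.
    """

    family: str
    parent_id: Optional[str] = None
    parent_known: bool = False
    de_novo: bool = False


@dataclass(frozen=True)
class OriginCall:
    candidate_id: str
    origin: Origin
    family: Optional[str] = None
    parent_id: Optional[str] = None
    parent_known: bool = False
    de_novo: bool = False


class ArtefactCategory(str, Enum):
    SPLIT_MODEL = "SPLIT_MODEL"
    TANDEM_FALSE_POSITIVE = "TANDEM_FALSE_POSITIVE"
    INTERCHROM_FALSE_POSITIVE = "INTERCHROM_FALSE_POSITIVE"
    SHARED_DUPLICATION = "SHARED_DUPLICATION"
    FRAGMENT_OF_KNOWN = "FRAGMENT_OF_KNOWN"
    UNCHARACTERIZED_WITH_ORTHOLOG = "UNCHARACTERIZED_WITH_ORTHOLOG"
    LARGE_FAMILY_DEFERRED = "LARGE_FAMILY_DEFERRED"
    RETROCOPY = "RETROCOPY"
    ASSEMBLY_SUSPECT = "ASSEMBLY_SUSPECT"
    PASSES_CURATION = "PASSES_CURATION"


@dataclass(frozen=True)
class ArtefactCall:
    candidate_id: str
    category: ArtefactCategory
    reason: str = ""


@dataclass
class CandidateRecord:
    """Everything the artefact rules need to know about one candidate."""

    candidate_id: str
    locus: GeneLocus
    best_hit: Optional[AlignmentHit] = None
    split_partner: Optional[str] = None
    subject_is_family_member: bool = False
    subject_same_chrom: bool = False
    shared_beyond_passerines: bool = False
    fragment_of_known: bool = False
    uncharacterized_with_ortholog: bool = False
    intron_count: int = 0
    parent_intron_count: Optional[int] = None
    repeat_flanked: bool = False
    tandem: bool = False
    family_size: int = 1


# ---------------------------------------------------------------------------
# hit filtering and syntenic context


def filter_hits(hits: Sequence[AlignmentHit],
                config: Optional[PipelineConfig] = None) -> list[AlignmentHit]:
    """Keep hits scoring strictly above ``min_hit_score`` (a hit at
    exactly the threshold is removed)."""
    config = config or PipelineConfig()
    return [h for h in hits if h.score > config.min_hit_score]


@dataclass(frozen=True)
class ContextResult:
    score: float
    limited: bool = False


def syntenic_context(
    hit: AlignmentHit,
    candidate_flanks: tuple[Sequence[str], Sequence[str]],
    subject_gene_table: Sequence[GeneLocus],
    config: Optional[PipelineConfig] = None,
) -> ContextResult:
    """Fraction of flanking genes conserved around a hit.

    ``candidate_flanks`` holds the up- and downstream neighbour names of
    the candidate in the reference genome, each ordered nearest-first.
    The subject's neighbours are read off its gene table around the hit
    interval.  Matching is position-wise (order-aware) but
    strand-agnostic: the flanks are also compared with up/down swapped,
    and the better of the two orientations is scored.  The denominator
    is always ``2 * flank_genes``; when fewer annotated neighbours
    exist the result is flagged ``limited``.
    """
    config = config or PipelineConfig()
    k = config.flank_genes
    up_ref = list(candidate_flanks[0])[:k]
    down_ref = list(candidate_flanks[1])[:k]

    chrom_genes = sorted(
        (g for g in subject_gene_table if g.chrom == hit.subject_chrom),
        key=lambda g: g.start,
    )
    up_sub = [g for g in chrom_genes if g.end <= hit.subject_start]
    down_sub = [g for g in chrom_genes if g.start >= hit.subject_end]
    up_sub = [_name(g) for g in reversed(up_sub[-k:])]    # nearest first
    down_sub = [_name(g) for g in down_sub[:k]]

    def score(ref_up, ref_down) -> int:
        m = sum(1 for a, b in zip(ref_up, up_sub) if a == b)
        m += sum(1 for a, b in zip(ref_down, down_sub) if a == b)
        return m

    matched = max(score(up_ref, down_ref), score(down_ref, up_ref))
    limited = len(up_sub) < k or len(down_sub) < k or len(up_ref) < k or len(down_ref) < k
    return ContextResult(score=matched / (2 * k), limited=limited)


def _name(g: GeneLocus) -> str:
    return g.symbol or g.gene_id


# ---------------------------------------------------------------------------
# presence calling


def call_presence(
    candidate_id: str,
    species: str,
    hits: Sequence[AlignmentHit],
    context_scores: Sequence[ContextResult | float],
    config: Optional[PipelineConfig] = None,
) -> PresenceCall:
    """Combine filtered hits and their context scores into one call.

    ``context_scores`` is parallel to ``hits``.  The best hit is the
    highest-scoring one (ties: longer aligned span, then lower subject
    coordinate).  No hit above threshold -> ABSENT; best hit with
    conserved context -> PRESENT_SYNTENIC; otherwise PRESENT_UNPLACED.
    """
    config = config or PipelineConfig()
    scored = [
        (h, c if isinstance(c, ContextResult) else ContextResult(float(c)))
        for h, c in zip(hits, context_scores)
        if h.score > config.min_hit_score
    ]
    if not scored:
        return PresenceCall(candidate_id, species, PresenceStatus.ABSENT)
    best, ctx = max(
        scored,
        key=lambda hc: (hc[0].score, hc[0].aligned_span, -hc[0].subject_start),
    )
    status = (
        PresenceStatus.PRESENT_SYNTENIC
        if ctx.score >= config.context_threshold
        else PresenceStatus.PRESENT_UNPLACED
    )
    return PresenceCall(candidate_id, species, status, best_hit=best,
                        context_score=ctx.score, context_limited=ctx.limited)


# ---------------------------------------------------------------------------
# origin classification


def classify_origin(
    matrix: Mapping[str, Mapping[str, PresenceCall | PresenceStatus]],
    panel: CladePanel,
    parent_rule: Mapping[str, ParentInfo],
) -> list[OriginCall]:
    """Assign each candidate exactly one phylogenetic origin.

    ``matrix`` maps candidate -> species -> presence call; it must
    cover every panel species for every candidate.  Absence in a group
    tolerates up to ``max_missing`` missing species (0 by default: a
    single presence outside the focal clade vetoes the call).
    """
    songbirds = set(panel.songbirds)
    passerines = set(panel.passerines)
    galliforms = set(panel.galliforms)
    non_avians = set(panel.non_avians)
    all_species = set(panel.species)

    calls = []
    for cand in sorted(matrix):
        row = matrix[cand]
        missing = all_species - set(row)
        if missing:
            raise ValueError(
                f"presence matrix for {cand} is missing species: {sorted(missing)}"
            )
        present = {
            sp for sp, call in row.items()
            if (call.present if isinstance(call, PresenceCall)
                else PresenceStatus(call) is not PresenceStatus.ABSENT)
        }
        info = parent_rule.get(cand, ParentInfo(family=cand))
        origin = _origin_of(present, songbirds, passerines, galliforms,
                            non_avians, panel)
        calls.append(
            OriginCall(
                candidate_id=cand, origin=origin, family=info.family,
                parent_id=info.parent_id, parent_known=info.parent_known,
                de_novo=info.de_novo,
            )
        )
    return calls


def _origin_of(present: set, songbirds: set, passerines: set, galliforms: set,
               non_avians: set, panel: CladePanel) -> Origin:
    if not present:
        return Origin.NOT_NOVEL
    if len(present) == 1:
        return Origin.SINGLE_SPECIES_SUSPECT
    if songbirds <= present and present <= songbirds:
        return Origin.SONGBIRD_UNIQUE
    if present < songbirds:
        # multiple songbirds but not all: the finch lineage when it
        # matches the declared finch subset, else still finch-level
        if not panel.finch_species or present == set(panel.finch_species):
            return Origin.FINCH_SPECIFIC
        return Origin.FINCH_SPECIFIC
    if present == passerines:
        return Origin.PASSERINE
    beyond = present - passerines
    if beyond and not (present & galliforms) and not (present & non_avians):
        return Origin.NEOAVES_OR_GALLIFORM_LOSS
    return Origin.NOT_NOVEL


# ---------------------------------------------------------------------------
# novel-gene counting


@dataclass
class NovelGeneCount:
    """Novel-gene totals under the parent-undetermined counting rule."""

    total: int
    per_family: dict[str, int] = field(default_factory=dict)
    n_single_paralog_families: int = 0
    n_two_paralog_families: int = 0
    n_de_novo: int = 0


def count_novel_genes(origin_calls: Sequence[OriginCall],
                      origin: Origin = Origin.SONGBIRD_UNIQUE) -> NovelGeneCount:
    """Count novel genes of one origin category.

    Candidates with a known parent each count as one novel gene.  A
    parent-undetermined family of *k* qualifying copies contributes
    *k - 1* (one copy is presumed ancestral).  De novo genes count 1.
    """
    fam_calls: dict[str, list[OriginCall]] = {}
    for c in origin_calls:
        if c.origin is origin:
            fam_calls.setdefault(c.family or c.candidate_id, []).append(c)

    per_family: dict[str, int] = {}
    n_de_novo = 0
    for fam, members in fam_calls.items():
        if any(m.de_novo for m in members):
            per_family[fam] = len(members)
            n_de_novo += len(members)
        elif all(m.parent_known for m in members):
            per_family[fam] = len(members)
        else:
            per_family[fam] = max(len(members) - 1, 0)
    per_family = {f: n for f, n in per_family.items() if n > 0}
    dup_fams = {f: n for f, n in per_family.items()
                if not any(m.de_novo for m in fam_calls[f])}
    return NovelGeneCount(
        total=sum(per_family.values()),
        per_family=per_family,
        n_single_paralog_families=sum(1 for n in dup_fams.values() if n == 1),
        n_two_paralog_families=sum(1 for n in dup_fams.values() if n == 2),
        n_de_novo=n_de_novo,
    )


# ---------------------------------------------------------------------------
# artefact triage


def classify_artefact(record: CandidateRecord,
                      config: Optional[PipelineConfig] = None) -> ArtefactCall:
    """Apply the curation cascade; the first matching rule wins, making
    the categories mutually exclusive."""
    config = config or PipelineConfig()
    cid = record.candidate_id
    if record.split_partner is not None:
        return ArtefactCall(cid, ArtefactCategory.SPLIT_MODEL,
                            f"adjacent model {record.split_partner} covers a "
                            "disjoint range of the same ortholog")
    if record.subject_is_family_member:
        cat = (ArtefactCategory.TANDEM_FALSE_POSITIVE
               if record.subject_same_chrom
               else ArtefactCategory.INTERCHROM_FALSE_POSITIVE)
        return ArtefactCall(cid, cat, "best subject is a distinct known family member")
    if record.shared_beyond_passerines:
        return ArtefactCall(cid, ArtefactCategory.SHARED_DUPLICATION,
                            "duplication syntenically present in galliforms "
                            "or non-avians")
    if record.fragment_of_known:
        return ArtefactCall(cid, ArtefactCategory.FRAGMENT_OF_KNOWN,
                            "short segment of a known gene outside its main model")
    if record.uncharacterized_with_ortholog:
        return ArtefactCall(cid, ArtefactCategory.UNCHARACTERIZED_WITH_ORTHOLOG,
                            "orthologous locus identifiable in another species")
    if (record.intron_count == 0
            and (record.parent_intron_count or 0) > 0
            and record.repeat_flanked):
        return ArtefactCall(cid, ArtefactCategory.RETROCOPY,
                            "intronless copy of an intron-bearing parent with "
                            "flanking repeats")
    if (record.tandem and record.locus.gap_flanked
            and record.best_hit is not None
            and record.best_hit.percent_identity > config.allele_identity):
        return ArtefactCall(cid, ArtefactCategory.ASSEMBLY_SUSPECT,
                            f"tandem, gap-flanked, identity "
                            f"{record.best_hit.percent_identity:.1f}% > "
                            f"{config.allele_identity}%")
    if record.family_size > config.large_family_cap:
        return ArtefactCall(cid, ArtefactCategory.LARGE_FAMILY_DEFERRED,
                            f"family of {record.family_size} exceeds cap "
                            f"{config.large_family_cap}")
    return ArtefactCall(cid, ArtefactCategory.PASSES_CURATION)


def detect_split_models(
    model_coverage: Mapping[str, tuple[GeneLocus, str, tuple[int, int]]],
) -> dict[str, str]:
    """Find split-model pairs.

    ``model_coverage`` maps model id -> (locus, ortholog id, covered
    interval of that ortholog's query sequence).  Two models that are
    chromosomally adjacent, hit the same ortholog, and cover disjoint
    query ranges are each other's split partners.
    """
    partners: dict[str, str] = {}
    by_chrom: dict[tuple[str, str], list[str]] = {}
    for mid, (locus, _orth, _cov) in model_coverage.items():
        by_chrom.setdefault((locus.species, locus.chrom), []).append(mid)
    for ids in by_chrom.values():
        ids.sort(key=lambda m: model_coverage[m][0].start)
        for a, b in zip(ids, ids[1:]):
            _, orth_a, (sa, ea) = model_coverage[a]
            _, orth_b, (sb, eb) = model_coverage[b]
            if orth_a == orth_b and (ea <= sb or eb <= sa):
                partners[a] = b
                partners[b] = a
    return partners


# ---------------------------------------------------------------------------
# tandem duplication detection


def detect_tandem_copies(loci: Sequence[GeneLocus],
                         max_spacing: int = 100_000) -> list[list[GeneLocus]]:
    """Maximal runs of same-family loci on one chromosome with
    inter-locus spacing at most ``max_spacing`` bp.  Loci are assumed to
    belong to one family and one species; loci on different chromosomes
    always land in different groups."""
    groups: list[list[GeneLocus]] = []
    by_chrom: dict[str, list[GeneLocus]] = {}
    for g in loci:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom in sorted(by_chrom):
        run: list[GeneLocus] = []
        for g in sorted(by_chrom[chrom], key=lambda g: g.start):
            if run and g.start - run[-1].end > max_spacing:
                groups.append(run)
                run = []
            run.append(g)
        if run:
            groups.append(run)
    return groups
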