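"""Synthetic rearranged genome pairs, duplications and presence data.

The generator emulates the structure the pipeline is built to analyse:
a pair of genomes descended from a common ancestor, with inversions
and translocations applied on the reference ("songbird") branch;
duplications preferentially seeded inside the resulting breakpoint
intervals; and per-species alignment evidence down a clade panel, with
optional dropout and spurious low-score noise.  Every instance carries
a :class:`SimTruth` whose event log replays exactly, so planted
breakpoints, duplication origins and parent links are available as
ground truth to every test.

Gene-level resolution only: rearrangement breaks fall at inter-gene
positions and hits carry scores/identities drawn from configured
ranges, not from sequence alignment.

Defaults (2 chromosomes x 500 genes at 100 kb spacing) give inter-gene
gaps of 50 kb, small enough that the 1 Mb marker-gap and 2 Mb jump
thresholds are exercised while a full instance builds in well under a
second.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .classify import Origin, ParentInfo
from .model import Clade, CladePanel, GeneLocus, OrthologPair, Strand

__all__ = [
    "SimTruth",
    "simulate_genomes",
    "simulate_duplications",
    "simulate_presence",
    "default_panel",
    "species_for_origin",
    "replay_events",
]

REF_SPECIES = "zebra_finch"
TGT_SPECIES = "chicken"

GENE_FRACTION = 0.5  # fraction of the marker spacing occupied by a gene


@dataclass
class SimTruth:
    """Ground truth of one simulated instance."""

    seed: int
    marker_spacing: int
    ancestor_orders: dict[str, list[str]]
    ref_orders: dict[str, list[str]]
    tgt_orders: dict[str, list[str]]
    strands: dict[str, str]              # ancestral strand per gene
    ref_strands: dict[str, str]
    event_log: list[dict] = field(default_factory=list)
    planted_breakpoints: list[tuple[str, int, int, str]] = field(default_factory=list)
    planted_duplications: list[dict] = field(default_factory=list)


def _layout(orders: dict[str, list[str]], strands: dict[str, str],
            species: str, spacing: int) -> list[GeneLocus]:
    gene_len = int(spacing * GENE_FRACTION)
    loci = []
    for chrom, genes in orders.items():
        for i, gid in enumerate(genes):
            start = i * spacing + (spacing - gene_len) // 2
            loci.append(
                GeneLocus(species=species, chrom=chrom, start=start,
                          end=start + gene_len, strand=Strand(strands[gid]),
                          gene_id=gid)
            )
    return loci


def replay_events(ancestor_orders: dict[str, list[str]],
                  strands: dict[str, str],
                  event_log: Sequence[dict]) -> tuple[dict, dict]:
    """Re-apply an event log to the ancestor; returns (orders, strands).

    The SimTruth invariant — replay reproduces the derived genome
    exactly — is asserted on every generated instance by the tests.
    """
    orders = {c: list(g) for c, g in ancestor_orders.items()}
    strands = dict(strands)
    flip = {"+": "-", "-": "+"}
    for ev in event_log:
        if ev["kind"] == "inversion":
            c, i, j = ev["chrom"], ev["start_idx"], ev["end_idx"]
            seg = orders[c][i:j][::-1]
            orders[c][i:j] = seg
            for gid in seg:
                strands[gid] = flip[strands[gid]]
        elif ev["kind"] == "translocation":
            c_src, i, j = ev["chrom"], ev["start_idx"], ev["end_idx"]
            seg = orders[c_src][i:j]
            del orders[c_src][i:j]
            c_dst, k = ev["dest_chrom"], ev["dest_idx"]
            orders[c_dst][k:k] = seg
        else:
            raise ValueError(f"unknown event kind {ev['kind']!r}")
    return orders, strands


def _breakpoints_from_orders(
    ref_orders: dict[str, list[str]],
    ancestor_orders: dict[str, list[str]],
    spacing: int,
) -> list[tuple[str, int, int, str]]:
    """Inter-gene intervals of the reference whose gene adjacency does
    not exist in the ancestor — exactly the junctions the applied
    events created (inversion interiors keep their unordered
    adjacencies, so only event boundaries appear)."""
    ancestral = set()
    for genes in ancestor_orders.values():
        for a, b in zip(genes, genes[1:]):
            ancestral.add(frozenset((a, b)))
    gene_len = int(spacing * GENE_FRACTION)
    pad = (spacing - gene_len) // 2
    bps = []
    for chrom, genes in ref_orders.items():
        for i, (a, b) in enumerate(zip(genes, genes[1:])):
            if frozenset((a, b)) not in ancestral:
                left_end = i * spacing + pad + gene_len
                right_start = (i + 1) * spacing + pad
                bps.append((chrom, left_end, right_start, "REFERENCE_LINEAGE"))
    return bps


def simulate_genomes(
    n_genes: int = 500,
    n_chroms: int = 2,
    n_inversions: int = 3,
    n_translocations: int = 1,
    marker_spacing_bp: int = 100_000,
    seed: int = 0,
    min_segment: int = 2,
    max_segment: int = 40,
    jump_distance: int = 2_000_000,
) -> tuple[list[GeneLocus], list[GeneLocus], list[OrthologPair], SimTruth]:
    """Generate an ancestor of ``n_chroms`` x ``n_genes`` markers,
    apply disjoint inversions/translocations on the reference branch,
    and emit both gene tables, the one-to-one ortholog pairs, and the
    ground truth.  Deterministic per seed.

    Translocated segments span more than ``jump_distance`` so that the
    excision junction is detectable at marker resolution (a shorter
    excision looks like marker sparsity, not a context change, to any
    gene-order analysis); inversions may be as short as
    ``min_segment`` because their strand flip is always detectable.
    """
    if n_genes < 2:
        raise ValueError("need >= 2 genes per chromosome")
    if marker_spacing_bp <= 0:
        raise ValueError("marker spacing must be > 0")
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    ancestor = {c: [f"g_{c}_{i:04d}" for i in range(n_genes)] for c in chroms}
    strands = {
        gid: ("+" if rng.random() < 0.5 else "-")
        for genes in ancestor.values() for gid in genes
    }

    # reserve disjoint index segments per chromosome for the events
    used: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    tl_min = jump_distance // marker_spacing_bp + 1
    tl_max = max(max_segment, tl_min + 10)

    # keep >= 2 intact genes at chromosome ends and >= 3 between events,
    # so every inter-event run can itself form a synteny block
    PAD = 3

    def sample_segment(lo: int = min_segment,
                       hi: int = max_segment) -> tuple[str, int, int]:
        for _ in range(1000):
            c = chroms[int(rng.integers(n_chroms))]
            length = int(rng.integers(lo, hi + 1))
            if length >= n_genes - 2 * PAD:
                continue
            i = int(rng.integers(PAD, n_genes - length - PAD + 1))
            if all(j2 + PAD <= i or i + length + PAD <= i2
                   for i2, j2 in used[c]):
                used[c].append((i, i + length))
                return c, i, i + length
        raise ValueError("infeasible operation counts for this genome size")

    event_log: list[dict] = []
    for _ in range(n_inversions):
        c, i, j = sample_segment()
        event_log.append({"kind": "inversion", "chrom": c,
                          "start_idx": i, "end_idx": j})
    for _ in range(n_translocations):
        c, i, j = sample_segment(tl_min, tl_max)
        others = [x for x in chroms if x != c] or [c]
        c_dst = others[int(rng.integers(len(others)))]
        # destination index in c_dst, away from ends and used segments
        for _ in range(1000):
            k = int(rng.integers(PAD, n_genes - PAD + 1))
            if all(j2 + PAD <= k or k + PAD <= i2 for i2, j2 in used[c_dst]):
                used[c_dst].append((k, k))
                break
        else:
            raise ValueError("infeasible operation counts for this genome size")
        event_log.append({"kind": "translocation", "chrom": c, "start_idx": i,
                          "end_idx": j, "dest_chrom": c_dst, "dest_idx": k})

    ref_orders, ref_strands = replay_events(ancestor, strands, event_log)
    tgt_orders = {c: list(g) for c, g in ancestor.items()}

    truth = SimTruth(
        seed=seed, marker_spacing=marker_spacing_bp,
        ancestor_orders=ancestor, ref_orders=ref_orders,
        tgt_orders=tgt_orders, strands=strands, ref_strands=ref_strands,
        event_log=event_log,
        planted_breakpoints=_breakpoints_from_orders(
            ref_orders, ancestor, marker_spacing_bp),
    )
    ref_genes = _layout(ref_orders, ref_strands, REF_SPECIES, marker_spacing_bp)
    tgt_genes = _layout(tgt_orders, strands, TGT_SPECIES, marker_spacing_bp)
    tgt_by_id = {g.gene_id: g for g in tgt_genes}
    pairs = [
        OrthologPair(ref=g, tgt=tgt_by_id[g.gene_id])
        for g in sorted(ref_genes, key=lambda g: (g.chrom, g.start))
    ]
    return ref_genes, tgt_genes, pairs, truth


def simulate_duplications(
    ref_genes: Sequence[GeneLocus],
    truth: SimTruth,
    n_dups: int,
    p_at_breakpoint: float,
    clade_origins: Sequence[Origin | str],
    seed: int = 0,
) -> tuple[list[GeneLocus], dict[str, ParentInfo], SimTruth]:
    """Plant ``n_dups`` duplicated candidate loci on the reference.

    Each duplication lands inside a planted breakpoint interval with
    probability ``p_at_breakpoint``, else uniformly in a non-breakpoint
    inter-gene interval; its origin clade is drawn uniformly from
    ``clade_origins`` and its parent link recorded in the truth.  The
    input truth is not modified; an updated copy is returned.
    """
    from dataclasses import replace as _replace
    if not 0.0 <= p_at_breakpoint <= 1.0:
        raise ValueError("p_at_breakpoint must be in [0, 1]")
    rng = np.random.default_rng(seed)
    origins = [Origin(o) for o in clade_origins]
    by_chrom: dict[str, list[GeneLocus]] = {}
    for g in ref_genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for genes in by_chrom.values():
        genes.sort(key=lambda g: g.start)
    bp_set = {(c, s, e) for c, s, e, _lin in truth.planted_breakpoints}
    # non-breakpoint inter-gene intervals
    plain: list[tuple[str, int, int]] = []
    for chrom, genes in by_chrom.items():
        for a, b in zip(genes, genes[1:]):
            iv = (chrom, a.end, b.start)
            if iv not in bp_set:
                plain.append(iv)

    candidates: list[GeneLocus] = []
    parent_rule: dict[str, ParentInfo] = {}
    new_dups: list[dict] = []
    for i in range(n_dups):
        at_bp = bool(truth.planted_breakpoints) and rng.random() < p_at_breakpoint
        pool = (
            [ (c, s, e) for c, s, e, _l in truth.planted_breakpoints ]
            if at_bp else plain
        )
        chrom, s, e = pool[int(rng.integers(len(pool)))]
        width = max(min(2000, (e - s) // 2), 1)
        lo = s + (e - s - width) // 2
        parent = ref_genes[int(rng.integers(len(ref_genes)))]
        cid = f"NOVEL_{i:03d}"
        origin = origins[int(rng.integers(len(origins)))]
        candidates.append(
            GeneLocus(species=REF_SPECIES, chrom=chrom, start=lo, end=lo + width,
                      strand=parent.strand, gene_id=cid, is_model=True)
        )
        parent_rule[cid] = ParentInfo(family=parent.gene_id,
                                      parent_id=parent.gene_id, parent_known=True)
        new_dups.append(
            {"candidate_id": cid, "parent_id": parent.gene_id,
             "origin": origin.value, "at_breakpoint": at_bp,
             "chrom": chrom, "start": lo, "end": lo + width}
        )
    updated = _replace(truth,
                       planted_duplications=truth.planted_duplications + new_dups)
    return candidates, parent_rule, updated


def default_panel() -> CladePanel:
    """The 52-organism screen: 3 songbirds, a suboscine, a basal
    passerine, a parrot, 42 further avians (two galliforms) and 4
    non-avian vertebrates."""
    species: list[tuple[str, Clade]] = [
        ("zebra_finch", Clade.SONGBIRD),
        ("medium_ground_finch", Clade.SONGBIRD),
        ("american_crow", Clade.SONGBIRD),
        ("golden_collared_manakin", Clade.SUBOSCINE),
        ("rifleman", Clade.BASAL_PASSERINE),
        ("budgerigar", Clade.PARROT),
        ("chicken", Clade.GALLIFORM),
        ("turkey", Clade.GALLIFORM),
    ]
    species += [(f"avian_sp{i:02d}", Clade.OTHER_NEOAVES) for i in range(1, 41)]
    species += [
        ("lizard", Clade.NON_AVIAN),
        ("frog", Clade.NON_AVIAN),
        ("zebrafish", Clade.NON_AVIAN),
        ("mouse", Clade.NON_AVIAN),
    ]
    return CladePanel(
        species=[s for s, _ in species],
        clade_of={s: c for s, c in species},
        required_counts={Clade.SONGBIRD: 3, Clade.NON_AVIAN: 4},
        finch_species=frozenset({"zebra_finch", "medium_ground_finch"}),
    )


def species_for_origin(origin: Origin, panel: CladePanel) -> set[str]:
    """The species in which a candidate of the given origin is present."""
    origin = Origin(origin)
    if origin is Origin.SONGBIRD_UNIQUE:
        return set(panel.songbirds)
    if origin is Origin.FINCH_SPECIFIC:
        return set(panel.finch_species)
    if origin is Origin.PASSERINE:
        return set(panel.passerines)
    if origin is Origin.NEOAVES_OR_GALLIFORM_LOSS:
        return set(panel.avians) - set(panel.galliforms)
    if origin is Origin.SINGLE_SPECIES_SUSPECT:
        return {REF_SPECIES} if REF_SPECIES in panel.species else {panel.songbirds[0]}
    return set(panel.species)


def simulate_presence(
    panel: CladePanel,
    truth: SimTruth,
    dropout: float = 0.0,
    noise_unplaced: float = 0.0,
    seed: int = 0,
) -> dict[str, dict[str, tuple[list, list]]]:
    """Per-candidate, per-species alignment evidence.

    Species of a duplication's origin clade receive one syntenic,
    high-scoring hit (score 100-300, full flanking context), except
    that non-songbird species drop their evidence with probability
    ``dropout`` (emulating incomplete assemblies).  Other species
    receive a spurious sub-threshold hit (score <= 50, no context) at
    rate ``noise_unplaced``.  Returns candidate -> species ->
    (hits, context_scores), ready for presence calling.
    """
    from .classify import ContextResult
    from .model import AlignmentHit

    if not (0.0 <= dropout <= 1.0 and 0.0 <= noise_unplaced <= 1.0):
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    songbirds = set(panel.songbirds)
    tables: dict[str, dict[str, tuple[list, list]]] = {}
    for dup in truth.planted_duplications:
        cid = dup["candidate_id"]
        present = species_for_origin(Origin(dup["origin"]), panel)
        per_species: dict[str, tuple[list, list]] = {}
        for sp in panel.species:
            hits: list[AlignmentHit] = []
            ctx: list[ContextResult] = []
            if sp in present:
                dropped = sp not in songbirds and rng.random() < dropout
                if not dropped:
                    hits.append(AlignmentHit(
                        query_id=cid, subject_species=sp,
                        subject_chrom=dup["chrom"],
                        subject_start=dup["start"], subject_end=dup["end"],
                        subject_strand=Strand.PLUS,
                        score=float(100 + rng.integers(0, 201)),
                        percent_identity=float(90 + 10 * rng.random()),
                    ))
                    ctx.append(ContextResult(score=1.0))
            elif rng.random() < noise_unplaced:
                hits.append(AlignmentHit(
                    query_id=cid, subject_species=sp, subject_chrom="scaffold_0",
                    subject_start=0, subject_end=max(dup["end"] - dup["start"], 1),
                    subject_strand=Strand.PLUS,
                    score=float(10 + rng.integers(0, 41)),  # <= 50: sub-threshold
                    percent_identity=float(60 + 20 * rng.random()),
                ))
                ctx.append(ContextResult(score=0.0))
            per_species[sp] = (hits, ctx)
        tables[cid] = per_species
    return tables
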