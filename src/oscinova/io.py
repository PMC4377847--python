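"""Readers and writers for the tabular formats the pipeline touches.

External coordinates are 1-based inclusive (the convention of genome
browsers and of annotation tables); everything in memory is 0-based
half-open.  These functions are the only place the conversion happens,
so reading a table and writing it back is the identity.

Formats
-------
* gene tables: TSV with a header (``gene_id``, ``chrom``, ``start``,
  ``end``, ``strand`` required; ``symbol``, ``is_model``,
  ``gap_flanked`` optional), or GFF3 (``gene`` features only, parsed
  with :mod:`gffutils`);
* ortholog pairs: two-column TSV of gene ids, resolved against the two
  gene tables;
* alignment hits: PSL (the 21-column BLAT format) or a simplified TSV
  dialect that additionally carries the score and percent identity;
* clade panel: two/three-column TSV or a newick tree whose leaves are
  labelled ``species|CLADE`` (parsed with :mod:`dendropy`);
* pipeline config: YAML.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml

from .model import (
    AlignmentHit,
    Clade,
    CladePanel,
    GeneLocus,
    OrthologPair,
    PipelineConfig,
    Strand,
    check_unique_gene_ids,
)

log = logging.getLogger(__name__)

GENE_TABLE_COLUMNS = [
    "gene_id", "symbol", "chrom", "start", "end", "strand",
    "is_model", "gap_flanked",
]

_TRUE = {"1", "true", "yes", "y"}


def _parse_bool(s: str) -> bool:
    return s.strip().lower() in _TRUE


def _parse_coord(value: str, path, line_no: int, column: str) -> int:
    try:
        return int(value.replace(",", ""))
    except ValueError:
        raise ValueError(
            f"{path}: line {line_no}: malformed coordinate {value!r} in column {column!r}"
        ) from None


# ---------------------------------------------------------------------------
# gene tables


def read_gene_table(path, species: str) -> list[GeneLocus]:
    """Read a per-species gene annotation table (TSV or GFF3).

    Rows are validated (start <= end after conversion, known strand,
    unique gene ids) and returned sorted by (chrom, start).
    """
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        loci = _read_gff3(path, species)
    else:
        loci = _read_gene_tsv(path, species)
    check_unique_gene_ids(loci)
    loci.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return loci


def _read_gene_tsv(path: Path, species: str) -> list[GeneLocus]:
    loci: list[GeneLocus] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"gene_id", "chrom", "start", "end", "strand"}
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, expected a header line")
        missing = required - set(reader.fieldnames)
        if missing:
            raise ValueError(f"{path}: missing required columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            start1 = _parse_coord(row["start"], path, i, "start")
            end1 = _parse_coord(row["end"], path, i, "end")
            if end1 < start1:
                raise ValueError(
                    f"{path}: line {i}: end {end1} < start {start1} for "
                    f"{row['gene_id']!r}"
                )
            try:
                strand = Strand(row["strand"])
            except ValueError:
                raise ValueError(
                    f"{path}: line {i}: strand must be '+' or '-', got "
                    f"{row['strand']!r}"
                ) from None
            loci.append(
                GeneLocus(
                    species=species,
                    chrom=row["chrom"],
                    start=start1 - 1,
                    end=end1,
                    strand=strand,
                    gene_id=row["gene_id"],
                    symbol=(row.get("symbol") or None),
                    is_model=_parse_bool(row.get("is_model", "")),
                    gap_flanked=_parse_bool(row.get("gap_flanked", "")),
                )
            )
    return loci


def _read_gff3(path: Path, species: str) -> list[GeneLocus]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    loci = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        symbol = feat.attributes.get("Name", [None])[0]
        loci.append(
            GeneLocus(
                species=species,
                chrom=feat.seqid,
                start=feat.start - 1,  # gffutils keeps GFF3's 1-based coords
                end=feat.end,
                strand=Strand(feat.strand if feat.strand in "+-" else "+"),
                gene_id=gene_id,
                symbol=symbol,
                is_model=False,
                gap_flanked=False,
            )
        )
    return loci


def write_gene_table(loci: Sequence[GeneLocus], path) -> None:
    """Write loci as TSV with the stable column order of
    :data:`GENE_TABLE_COLUMNS` (1-based inclusive coordinates)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(GENE_TABLE_COLUMNS)
        for g in sorted(loci, key=lambda g: (g.chrom, g.start, g.gene_id)):
            w.writerow([
                g.gene_id, g.symbol or "", g.chrom, g.start + 1, g.end,
                g.strand.value, int(g.is_model), int(g.gap_flanked),
            ])


# ---------------------------------------------------------------------------
# ortholog pairs


def read_ortholog_pairs(
    path,
    ref_genes: Sequence[GeneLocus],
    tgt_genes: Sequence[GeneLocus],
    strict: bool = False,
) -> list[OrthologPair]:
    """Read a two-column TSV of (ref_gene_id, tgt_gene_id) pairs.

    Only pairs whose genes have known physical locations in both
    assemblies are retained; others are dropped with a warning (or, with
    ``strict=True``, raise a lookup error listing every offender).
    An optional ``one_to_one`` column restricts admission to HSB
    building; absent, every pair is taken as one-to-one.
    """
    ref_by_id = {g.gene_id: g for g in ref_genes}
    tgt_by_id = {g.gene_id: g for g in tgt_genes}
    pairs: list[OrthologPair] = []
    unresolved: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        need = {"ref_gene_id", "tgt_gene_id"}
        if need - set(reader.fieldnames):
            raise ValueError(
                f"{path}: expected columns ref_gene_id, tgt_gene_id; "
                f"found {reader.fieldnames}"
            )
        for row in reader:
            rid, tid = row["ref_gene_id"], row["tgt_gene_id"]
            ref = ref_by_id.get(rid)
            tgt = tgt_by_id.get(tid)
            if ref is None or tgt is None:
                unresolved.extend(x for x, g in ((rid, ref), (tid, tgt)) if g is None)
                continue
            one2one = _parse_bool(row.get("one_to_one", "true") or "true")
            pairs.append(OrthologPair(ref=ref, tgt=tgt, one_to_one=one2one))
    if unresolved:
        if strict:
            raise LookupError(
                f"{path}: gene ids without a physical location: {sorted(set(unresolved))}"
            )
        log.warning(
            "%s: dropped %d pair(s) without known physical locations: %s",
            path, len(unresolved), sorted(set(unresolved)),
        )
    return pairs


def write_ortholog_pairs(pairs: Sequence[OrthologPair], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["ref_gene_id", "tgt_gene_id", "one_to_one"])
        for p in pairs:
            w.writerow([p.ref.gene_id, p.tgt.gene_id, int(p.one_to_one)])


# ---------------------------------------------------------------------------
# alignment hits: PSL and simplified TSV

HIT_TSV_COLUMNS = [
    "query_id", "subject_species", "subject_chrom", "subject_start",
    "subject_end", "subject_strand", "score", "percent_identity", "blocks",
]


def read_alignment_hits(path, dialect: str = "auto",
                        subject_species: str = "") -> list[AlignmentHit]:
    """Read hits from PSL (21 standard columns) or the simplified TSV
    dialect.  ``dialect`` is ``"psl"``, ``"tsv"`` or ``"auto"``
    (decided by file suffix, ``.psl`` vs anything else)."""
    path = Path(path)
    if dialect == "auto":
        dialect = "psl" if path.suffix.lower() == ".psl" else "tsv"
    if dialect == "psl":
        return _read_psl(path, subject_species)
    return _read_hit_tsv(path)


def _read_psl(path: Path, subject_species: str) -> list[AlignmentHit]:
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("psLayout", "match", "-", " ")):
                continue  # tolerate the optional 5-line PSL header
            f = line.split("\t")
            if len(f) != 21:
                raise ValueError(
                    f"{path}: line {line_no}: expected 21 PSL columns, got {len(f)}"
                )
            (matches, mismatches, rep_matches, _n, q_num_ins, _qb, t_num_ins,
             _tb) = (int(x) for x in f[:8])
            strand = f[8][0]
            q_name = f[9]
            q_start, q_end = int(f[11]), int(f[12])
            t_name = f[13]
            t_start, t_end = int(f[15]), int(f[16])
            block_count = int(f[17])
            sizes = [int(x) for x in f[18].rstrip(",").split(",") if x]
            q_starts = [int(x) for x in f[19].rstrip(",").split(",") if x]
            t_starts = [int(x) for x in f[20].rstrip(",").split(",") if x]
            if not (len(sizes) == len(q_starts) == len(t_starts) == block_count):
                raise ValueError(
                    f"{path}: line {line_no}: block count {block_count} inconsistent "
                    f"with block lists ({len(sizes)}/{len(q_starts)}/{len(t_starts)})"
                )
            blocks = tuple(
                ((qs, qs + sz), (ts, ts + sz))
                for sz, qs, ts in zip(sizes, q_starts, t_starts)
            )
            aligned = matches + rep_matches + mismatches
            pid = 100.0 * (matches + rep_matches) / aligned if aligned else 0.0
            score = matches + rep_matches - mismatches - q_num_ins - t_num_ins
            hits.append(
                AlignmentHit(
                    query_id=q_name,
                    subject_species=subject_species,
                    subject_chrom=t_name,
                    subject_start=t_start,
                    subject_end=t_end,
                    subject_strand=Strand(strand),
                    score=float(score),
                    percent_identity=pid,
                    blocks=blocks,
                )
            )
    return hits


def _fmt_blocks(blocks) -> str:
    return ";".join(f"{qs + 1}-{qe}/{ss + 1}-{se}" for (qs, qe), (ss, se) in blocks)


def _parse_blocks(s: str):
    if not s:
        return ()
    out = []
    for part in s.split(";"):
        q, sub = part.split("/")
        qs, qe = (int(x) for x in q.split("-"))
        ss, se = (int(x) for x in sub.split("-"))
        out.append(((qs - 1, qe), (ss - 1, se)))
    return tuple(out)


def _read_hit_tsv(path: Path) -> list[AlignmentHit]:
    hits = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        for i, row in enumerate(reader, start=2):
            hits.append(
                AlignmentHit(
                    query_id=row["query_id"],
                    subject_species=row["subject_species"],
                    subject_chrom=row["subject_chrom"],
                    subject_start=_parse_coord(row["subject_start"], path, i,
                                               "subject_start") - 1,
                    subject_end=_parse_coord(row["subject_end"], path, i,
                                             "subject_end"),
                    subject_strand=Strand(row["subject_strand"]),
                    score=float(row["score"]),
                    percent_identity=float(row["percent_identity"]),
                    blocks=_parse_blocks(row.get("blocks", "")),
                )
            )
    return hits


def write_alignment_hits(hits: Sequence[AlignmentHit], path) -> None:
    """Write hits in the simplified TSV dialect (lossless round-trip)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(HIT_TSV_COLUMNS)
        for h in hits:
            w.writerow([
                h.query_id, h.subject_species, h.subject_chrom,
                h.subject_start + 1, h.subject_end, h.subject_strand.value,
                repr(h.score), repr(h.percent_identity), _fmt_blocks(h.blocks),
            ])


def write_psl(hits: Sequence[AlignmentHit], path) -> None:
    """Write hits as headerless PSL.  matches/misMatches are derived
    from the percent identity over the aligned block length, so score
    and identity survive only approximately; use the TSV dialect when a
    lossless round-trip matters."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for h in hits:
            blocks = h.blocks or (
                ((0, h.aligned_span), (h.subject_start, h.subject_end)),
            )
            sizes = [qe - qs for (qs, qe), _ in blocks]
            total = sum(sizes)
            matches = round(total * h.percent_identity / 100.0)
            mism = total - matches
            q_end = max(qe for (qs, qe), _ in blocks)
            w.writerow([
                matches, mism, 0, 0, 0, 0, 0, 0, h.subject_strand.value,
                h.query_id, q_end, min(qs for (qs, _), _s in blocks), q_end,
                h.subject_chrom, h.subject_end, h.subject_start, h.subject_end,
                len(blocks),
                ",".join(str(s) for s in sizes) + ",",
                ",".join(str(qs) for (qs, _), _s in blocks) + ",",
                ",".join(str(ss) for _q, (ss, _) in blocks) + ",",
            ])


# ---------------------------------------------------------------------------
# clade panel


def read_clade_panel(path) -> CladePanel:
    """Read a clade panel from TSV (columns ``species``, ``clade``,
    optional boolean ``finch``) or newick (leaves ``species|CLADE``)."""
    path = Path(path)
    if path.suffix.lower() in {".nwk", ".newick", ".tre", ".tree"}:
        return _read_panel_newick(path)
    species: list[str] = []
    clade_of: dict[str, Clade] = {}
    finches: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            sp = row["species"]
            species.append(sp)
            clade_of[sp] = Clade(row["clade"])
            if _parse_bool(row.get("finch", "")):
                finches.add(sp)
    return CladePanel(species=species, clade_of=clade_of,
                      finch_species=frozenset(finches))


def _read_panel_newick(path: Path) -> CladePanel:
    import dendropy

    tree = dendropy.Tree.get(path=str(path), schema="newick")
    species, clade_of = [], {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else leaf.label
        if label is None or "|" not in label:
            raise ValueError(
                f"{path}: newick leaves must be labelled 'species|CLADE', got {label!r}"
            )
        sp, clade = label.rsplit("|", 1)
        sp = sp.strip().replace(" ", "_")
        species.append(sp)
        # dendropy renders underscores in unquoted labels as spaces
        clade_of[sp] = Clade(clade.strip().replace(" ", "_"))
    return CladePanel(species=species, clade_of=clade_of)


def write_clade_panel(panel: CladePanel, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["species", "clade", "finch"])
        for sp in panel.species:
            w.writerow([sp, panel.clade_of[sp].value,
                        int(sp in panel.finch_species)])


# ---------------------------------------------------------------------------
# config


def read_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return PipelineConfig(**data)


def write_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {k: getattr(config, k) for k in PipelineConfig.__dataclass_fields__},
            fh, sort_keys=False,
        )
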