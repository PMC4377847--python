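"""Parent-vs-duplicate protein domain architecture comparison.

Architectures are consumed as tables (e.g. InterProScan-style rows);
no scanning happens here.  Domain identity is by name after an
optional vocabulary normalization map, and positions do not affect the
verdict — a duplicate that kept every named domain is COMPLETE even if
the domains shifted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

__all__ = [
    "DomainArchitecture",
    "Verdict",
    "ArchitectureComparison",
    "compare_architectures",
    "read_domain_table",
    "write_verdicts",
]


@dataclass(frozen=True)
class DomainArchitecture:
    """Ordered domain annotation of one locus' predicted protein.

    ``gap_adjacent`` marks loci next to assembly gaps, where missing
    domains may simply be unsequenced rather than lost.
    """

    locus_id: str
    domains: tuple[tuple[str, int, int], ...]
    orf_length: Optional[int] = None
    orf_complete: bool = True
    gap_adjacent: bool = False

    def __post_init__(self) -> None:
        prev = -1
        for name, start, end in self.domains:
            if start > end or start < 0:
                raise ValueError(f"{self.locus_id}: bad interval for domain {name}")
            if self.orf_length is not None and end > self.orf_length:
                raise ValueError(
                    f"{self.locus_id}: domain {name} extends past ORF length"
                )
            if start < prev:
                raise ValueError(f"{self.locus_id}: domains not ordered by start")
            prev = start

    def names(self, vocab: Optional[Mapping[str, str]] = None) -> frozenset:
        vocab = vocab or {}
        return frozenset(vocab.get(n, n) for n, _s, _e in self.domains)


class Verdict(str, Enum):
    COMPLETE = "COMPLETE"
    PARTIAL = "PARTIAL"
    EXTENDED = "EXTENDED"
    DIVERGED = "DIVERGED"


@dataclass(frozen=True)
class ArchitectureComparison:
    verdict: Verdict
    lost: tuple[str, ...]
    gained: tuple[str, ...]
    caveat_gap: bool = False


def compare_architectures(
    parent: DomainArchitecture,
    dup: DomainArchitecture,
    vocab: Optional[Mapping[str, str]] = None,
    diverged: bool = False,
) -> ArchitectureComparison:
    """Classify a duplicate against its parent architecture.

    COMPLETE: identical domain sets.  PARTIAL: domains lost (possibly
    some gained too — loss dominates).  EXTENDED: domains gained, none
    lost.  DIVERGED is only assigned when the caller supplies external
    divergence evidence (``diverged=True``); it overrides the set
    verdicts.  ``caveat_gap`` is raised when the duplicate abuts an
    assembly gap, where missing domains might be hiding.
    """
    p, d = parent.names(vocab), dup.names(vocab)
    lost = tuple(sorted(p - d))
    gained = tuple(sorted(d - p))
    if diverged:
        verdict = Verdict.DIVERGED
    elif not lost and not gained:
        verdict = Verdict.COMPLETE
    elif lost:
        verdict = Verdict.PARTIAL
    else:
        verdict = Verdict.EXTENDED
    return ArchitectureComparison(
        verdict=verdict, lost=lost, gained=gained, caveat_gap=dup.gap_adjacent
    )


def read_domain_table(path) -> dict[str, DomainArchitecture]:
    """Read a TSV of (locus, domain, start_aa, end_aa[, gap_adjacent])
    rows into one architecture per locus (coordinates 1-based
    inclusive, as printed by annotation tools)."""
    rows: dict[str, list] = {}
    gap: dict[str, bool] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rows.setdefault(row["locus"], []).append(
                (row["domain"], int(row["start_aa"]) - 1, int(row["end_aa"]))
            )
            if row.get("gap_adjacent"):
                gap[row["locus"]] = row["gap_adjacent"].lower() in {"1", "true", "yes"}
    return {
        locus: DomainArchitecture(
            locus_id=locus,
            domains=tuple(sorted(doms, key=lambda d: d[1])),
            gap_adjacent=gap.get(locus, False),
        )
        for locus, doms in rows.items()
    }


def write_verdicts(
    comparisons: Mapping[str, ArchitectureComparison], path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["locus", "verdict", "lost", "gained", "caveat_gap"])
        for locus in sorted(comparisons):
            c = comparisons[locus]
            w.writerow([locus, c.verdict.value, ";".join(c.lost),
                        ";".join(c.gained), int(c.caveat_gap)])
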