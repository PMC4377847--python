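from __future__ import annotations

import pytest

from oscinova.model import GeneLocus, OrthologPair, PipelineConfig, Strand
from oscinova.table1 import table1_fixture

GENE_LEN = 1_000


def make_pairs(markers, ref_species="finch", tgt_species="chicken",
               gene_len=GENE_LEN):
    """Build OrthologPair markers from compact tuples.

    Each marker is (ref_chrom, ref_start, tgt_chrom, tgt_start[, rel])
    where ``rel`` is '+' (strand kept between genomes, the default) or
    '-' (flipped, as inside an inverted segment).
    """
    pairs = []
    for i, m in enumerate(markers):
        rc, rs, tc, ts = m[:4]
        rel = m[4] if len(m) > 4 else "+"
        ref = GeneLocus(species=ref_species, chrom=rc, start=rs,
                        end=rs + gene_len, strand=Strand.PLUS,
                        gene_id=f"m{i:03d}")
        tgt = GeneLocus(species=tgt_species, chrom=tc, start=ts,
                        end=ts + gene_len,
                        strand=Strand.PLUS if rel == "+" else Strand.MINUS,
                        gene_id=f"m{i:03d}")
        pairs.append(OrthologPair(ref=ref, tgt=tgt))
    return pairs


def to_oracle_markers(pairs):
    return [
        (p.ref.chrom, p.ref.start, p.ref.end, p.tgt.chrom, p.tgt.start,
         p.tgt.end, 1 if p.ref.strand == p.tgt.strand else -1)
        for p in pairs
    ]


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def fixture38():
    return table1_fixture()
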