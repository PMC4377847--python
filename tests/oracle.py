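"""Independent brute-force oracle for synteny-block construction.

Operates on plain tuples, re-deriving the block rules from scratch:
a contiguous run of reference-sorted markers is valid when every
consecutive pair shares both chromosomes, keeps inter-marker gaps
within the limit on both genomes, keeps a single target direction, and
agrees in relative strand.  Validity is prefix-closed, so the maximal
partition is found by repeatedly taking the longest valid run from the
left — which is what the production sweep must equal.
"""

from __future__ import annotations

# marker: (ref_chrom, ref_start, ref_end, tgt_chrom, tgt_start, tgt_end, rel_strand)


def _consecutive_ok(a, b, direction, max_gap):
    if a[0] != b[0] or a[3] != b[3]:
        return None
    if a[6] != b[6]:
        return None
    if b[1] - a[2] > max_gap:
        return None
    delta = b[4] - a[4]
    step = 0 if delta == 0 else (1 if delta > 0 else -1)
    if step and direction and step != direction:
        return None
    gap = (b[4] - a[5]) if step >= 0 else (a[4] - b[5])
    if gap > max_gap:
        return None
    return step or direction


def longest_valid_run(markers, start, max_gap):
    """Length and final direction of the longest valid run at ``start``."""
    direction = 0
    n = 1
    while start + n < len(markers):
        d = _consecutive_ok(markers[start + n - 1], markers[start + n],
                            direction, max_gap)
        if d is None:
            break
        direction = d
        n += 1
    return n, direction


def oracle_partition(markers, max_gap, min_genes=2):
    """Partition reference-sorted markers into maximal valid runs.

    Returns (blocks, singleton_indices); each block is
    (index_list, orientation) with orientation '+' unless the target
    direction is decreasing.
    """
    markers = sorted(markers, key=lambda m: (m[0], m[1]))
    blocks, singles = [], []
    i = 0
    while i < len(markers):
        n, direction = longest_valid_run(markers, i, max_gap)
        if n >= min_genes:
            blocks.append((list(range(i, i + n)), "-" if direction < 0 else "+"))
        else:
            singles.extend(range(i, i + n))
        i += n
    return markers, blocks, singles
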