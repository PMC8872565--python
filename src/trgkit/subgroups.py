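"""V gene subgrouping by pairwise nucleotide identity.

Following the standard nomenclature criterion, V genes sharing strictly more
than 75% nucleotide identity over their coding region (L-PART1 + V-EXON)
belong to the same subgroup. Because the rule is stated pairwise, subgroups
are the connected components of the thresholded identity graph (single
linkage / transitive closure).
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np

from .model import SequenceRecord


def _nw_aligner():
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


_NW = None


def pairwise_identity(a, b) -> Tuple[float, int]:
    """Global-alignment identity between two sequences.

    Needleman-Wunsch with match +1, mismatch -1; the first residue of a gap
    scores -5 and each further residue -1. Identity = matching columns divided
    by the number of alignment columns after excluding columns where either
    sequence has a terminal (leading/trailing) gap, so length differences at
    the ends do not dominate. Returns ``(identity, aligned_columns)``.
    """
    global _NW
    if _NW is None:
        _NW = _nw_aligner()
    sa = (a.residues if isinstance(a, SequenceRecord) else str(a)).upper()
    sb = (b.residues if isinstance(b, SequenceRecord) else str(b)).upper()
    if not sa or not sb:
        raise ValueError("sequences must be non-empty")
    aln = _NW.align(sa, sb)[0]
    ra, rb = aln[0], aln[1]  # gapped rows
    n = len(ra)

    def lead(row):
        i = 0
        while i < n and row[i] == "-":
            i += 1
        return i

    def trail(row):
        i = 0
        while i < n and row[n - 1 - i] == "-":
            i += 1
        return i

    lo = max(lead(ra), lead(rb))
    hi = n - max(trail(ra), trail(rb))
    matches = 0
    cols = 0
    for i in range(lo, hi):
        cols += 1
        if ra[i] == rb[i] and ra[i] != "-":
            matches += 1
    if cols == 0:
        return 0.0, 0
    return matches / cols, cols


def identity_matrix(genes: Sequence[SequenceRecord]):
    """Symmetric identity and aligned-column matrices over L-PART1+V-EXON."""
    n = len(genes)
    ident = np.eye(n)
    cols = np.zeros((n, n), dtype=int)
    for i in range(n):
        cols[i, i] = len(genes[i].residues)
        for j in range(i + 1, n):
            d, c = pairwise_identity(genes[i], genes[j])
            ident[i, j] = ident[j, i] = d
            cols[i, j] = cols[j, i] = c
    return ident, cols


def assign_subgroups(
    genes: Sequence[SequenceRecord], threshold: float = 0.75
) -> List[List[str]]:
    """Partition V genes into subgroups at identity strictly > threshold.

    Single-linkage: the transitive closure of the pairwise relation. The
    partition is invariant under input reordering; subgroups are returned
    ordered by the first (most 5') member in the input, which follows genomic
    order when the input does.
    """
    ident, _ = identity_matrix(genes)
    return partition_from_identity(ident, [g.id for g in genes], threshold)


def partition_from_identity(
    ident: np.ndarray, ids: Sequence[str], threshold: float
) -> List[List[str]]:
    """Connected components of the identity-above-threshold graph.

    Components are ordered by their first member's input index, members keep
    input order.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    n = len(ids)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for i in range(n):
        for j in range(i + 1, n):
            if ident[i, j] > threshold:
                union(i, j)
    groups: Dict[int, List[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(ids[i])
    return [groups[r] for r in sorted(groups)]
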