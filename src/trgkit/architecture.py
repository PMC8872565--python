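"""Locus architecture: self-similarity, cassette decomposition, regulatory elements.

A cassette-organized locus betrays its duplication history in a dot-plot of
the sequence against itself: each tandem copy adds a line parallel to the main
diagonal. Annotated genes are decomposed into V* J+ C cassettes by cutting
after each C gene, cassettes are named after their nearest reference
neighbors, and the germline J promoter (PJ) and enhancer-like element (En)
are located by alignment to reference elements, together with the STAT
consensus motifs (TTCNNNGAA) they carry.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import edlib

from .model import (
    Cassette,
    GeneAnnotation,
    GenomicInterval,
    MotifHit,
    SequenceRecord,
    reverse_complement,
)

STAT_MOTIF = "TTCNNNGAA"
_STAT_RE = re.compile(r"(?=(TTC[ACGT]{3}GAA))")


@dataclass(frozen=True)
class DiagonalRun:
    """A chained run of exact k-mer self-matches along one diagonal."""

    start1: int  # 1-based
    start2: int
    length: int

    @property
    def off_diagonal_offset(self) -> int:
        return abs(self.start2 - self.start1)


@dataclass
class HomologyUnit:
    """A pair of homologous regions with the genes each side contains."""

    left: GenomicInterval
    right: GenomicInterval
    genes_left: List[str] = field(default_factory=list)
    genes_right: List[str] = field(default_factory=list)


@dataclass
class HomologyBlock:
    """A region shared by >= 2 cassette sequences (or private to one)."""

    block_id: int
    intervals: Dict[str, GenomicInterval]

    @property
    def present_in(self) -> frozenset:
        return frozenset(self.intervals)


# ---------------------------------------------------------------------------
# dot-plot


def _seed_positions(text: str, k: int) -> Dict[str, List[int]]:
    """k-mer index over unmasked (uppercase ACGT) windows only."""
    index: Dict[str, List[int]] = {}
    ok = set("ACGT")
    for i in range(len(text) - k + 1):
        kmer = text[i : i + k]
        if not set(kmer) <= ok:  # masked (lowercase) or ambiguous: no seed
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _chain_starts(starts: List[int], k: int, max_gap: int, min_run: int):
    """Chain sorted seed starts along one diagonal into runs."""
    runs = []
    lo = prev = starts[0]
    for s in starts[1:]:
        if s - (prev + k) <= max_gap:
            prev = s
        else:
            if prev + k - lo >= min_run:
                runs.append((lo, prev + k - lo))
            lo = prev = s
    if prev + k - lo >= min_run:
        runs.append((lo, prev + k - lo))
    return runs


def self_dotplot(
    seq,
    k: int = 12,
    max_gap: int = 50,
    min_run: int = 200,
    max_kmer_occurrences: int = 100,
) -> List[DiagonalRun]:
    """Self-alignment by exact k-mer seeds chained along equal diagonals.

    The main diagonal is always reported once; every off-diagonal run is
    reported together with its mirror partner (the dot-plot matrix is
    symmetric). Lowercase (masked) positions yield no seeds but keep their
    coordinates. Over-represented k-mers (simple repeats) are skipped.
    """
    text = seq.residues if isinstance(seq, SequenceRecord) else str(seq)
    if k < 8:
        raise ValueError("k must be >= 8")
    index = _seed_positions(text, k)
    by_offset: Dict[int, List[int]] = {}
    for positions in index.values():
        if len(positions) > max_kmer_occurrences:
            continue
        for ai in range(len(positions)):
            for bi in range(ai + 1, len(positions)):
                d = positions[bi] - positions[ai]
                by_offset.setdefault(d, []).append(positions[ai])
    runs = [DiagonalRun(1, 1, len(text))]
    for d in sorted(by_offset):
        starts = sorted(set(by_offset[d]))
        for lo, length in _chain_starts(starts, k, max_gap, min_run):
            runs.append(DiagonalRun(lo + 1, lo + d + 1, length))
            runs.append(DiagonalRun(lo + d + 1, lo + 1, length))
    return runs


def detect_duplication_units(
    runs: Sequence[DiagonalRun],
    annotations: Sequence[GeneAnnotation] = (),
    seq_id: str = "seq",
) -> List[HomologyUnit]:
    """Merge off-diagonal runs into homology units and list the genes covered.

    Units whose left and right regions both overlap are merged, so a block
    of fragmented runs along nearby diagonals is reported once. Gene lists
    show what each side of a unit contains (e.g. a J-C/J-C duplication).
    """
    pending = []
    for r in runs:
        if r.off_diagonal_offset == 0 or r.start2 < r.start1:
            continue  # keep one of each mirror pair
        pending.append(
            HomologyUnit(
                GenomicInterval(seq_id, r.start1, r.start1 + r.length - 1),
                GenomicInterval(seq_id, r.start2, r.start2 + r.length - 1),
            )
        )
    merged: List[HomologyUnit] = []
    for unit in sorted(pending, key=lambda u: (u.left.start, u.right.start)):
        for m in merged:
            if m.left.overlaps(unit.left) and m.right.overlaps(unit.right):
                m.left = GenomicInterval(
                    seq_id, min(m.left.start, unit.left.start), max(m.left.end, unit.left.end)
                )
                m.right = GenomicInterval(
                    seq_id, min(m.right.start, unit.right.start), max(m.right.end, unit.right.end)
                )
                break
        else:
            merged.append(unit)
    for unit in merged:
        unit.genes_left = [g.name for g in annotations if g.span.overlaps(unit.left)]
        unit.genes_right = [g.name for g in annotations if g.span.overlaps(unit.right)]
    return merged


# ---------------------------------------------------------------------------
# cassette decomposition


class StructureError(ValueError):
    pass


def build_cassettes(
    annotations: Sequence[GeneAnnotation],
) -> Tuple[List[Cassette], List[dict]]:
    """Partition position-sorted genes into V* J+ C cassettes.

    Genes are cut immediately after each C gene; each block must match the
    V* J+ C grammar. Violating blocks (e.g. an orphan trailing V) are returned
    as anomalies, never silently dropped.
    """
    genes = sorted(annotations, key=lambda g: g.span.start)
    if not any(g.gene_type == "C" for g in genes):
        raise StructureError("no C gene present; cannot decompose into cassettes")
    cassettes: List[Cassette] = []
    anomalies: List[dict] = []
    block: List[GeneAnnotation] = []
    for g in genes:
        block.append(g)
        if g.gene_type != "C":
            continue
        pattern = "".join(x.gene_type for x in block)
        if re.fullmatch(r"V*J+C", pattern):
            cassettes.append(Cassette(f"cas{len(cassettes) + 1}", list(block)))
        else:
            anomalies.append(
                {"genes": [x.name for x in block], "pattern": pattern,
                 "reason": "block does not match V*J+C"}
            )
        block = []
    if block:
        anomalies.append(
            {"genes": [x.name for x in block],
             "pattern": "".join(x.gene_type for x in block),
             "reason": "trailing genes after the last C"}
        )
    return cassettes, anomalies


def _parse_reference(reference_genes: Sequence[SequenceRecord]):
    """Reference records carry 'cassette=<label> gene_type=<V|J|C>' metadata."""
    refs = []
    for rec in reference_genes:
        meta = dict(
            tok.split("=", 1) for tok in rec.description.split() if "=" in tok
        )
        if "cassette" not in meta or "gene_type" not in meta:
            raise ValueError(
                f"reference record {rec.id!r} must carry cassette= and gene_type= tags"
            )
        refs.append((meta["cassette"], meta["gene_type"], rec))
    return refs


def name_cassettes(
    cassettes: Sequence[Cassette],
    locus,
    reference_genes: Sequence[SequenceRecord],
    min_identity: float = 0.6,
) -> List[Cassette]:
    """Name cassettes by the reference label of their C gene's nearest neighbor.

    Ties on C identity are broken by the best V-gene identity; queries with no
    reference above ``min_identity`` become "novel-1", "novel-2", ...
    """
    from .subgroups import pairwise_identity

    if not reference_genes:
        raise ValueError("reference gene set is empty")
    refs = _parse_reference(reference_genes)
    c_refs = [(label, rec) for label, gtype, rec in refs if gtype == "C"]
    v_refs = [(label, rec) for label, gtype, rec in refs if gtype == "V"]
    if not c_refs:
        raise ValueError("reference gene set has no C genes")
    text = locus.residues if isinstance(locus, SequenceRecord) else str(locus)
    novel = 0
    for cas in cassettes:
        c_seq = cas.c_gene.coding_sequence(text)
        scored = sorted(
            ((pairwise_identity(c_seq, rec.residues)[0], label) for label, rec in c_refs),
            reverse=True,
        )
        best_ident, best_label = scored[0]
        tied = [lab for ident, lab in scored if abs(ident - best_ident) < 1e-9]
        if len(tied) > 1 and v_refs and cas.v_genes:
            v_seq = cas.v_genes[0].coding_sequence(text)
            v_scored = sorted(
                ((pairwise_identity(v_seq, rec.residues)[0], label)
                 for label, rec in v_refs if label in tied),
                reverse=True,
            )
            if v_scored:
                best_label = v_scored[0][1]
        if best_ident < min_identity:
            novel += 1
            cas.name = f"novel-{novel}"
        else:
            cas.name = best_label
        for g in cas.genes:
            g.cassette = cas.name
    return list(cassettes)


# ---------------------------------------------------------------------------
# motifs and regulatory elements


def scan_stat_motifs(seq, region: Optional[GenomicInterval] = None) -> List[MotifHit]:
    """All STAT consensus (TTCNNNGAA) occurrences on both strands of a region.

    Positions are 1-based starts on the forward strand; reverse-strand hits
    report the motif text as read on the reverse strand. Overlapping
    occurrences are all reported.
    """
    if isinstance(seq, SequenceRecord):
        seq_id, text = seq.id, seq.residues
    else:
        seq_id, text = "seq", str(seq)
    if region is None:
        region = GenomicInterval(seq_id, 1, len(text))
    if region.end > len(text):
        raise ValueError("region extends beyond the sequence")
    sub = region.slice(text).upper()
    hits: List[MotifHit] = []
    for m in _STAT_RE.finditer(sub):
        start = region.start + m.start(1)
        hits.append(
            MotifHit(STAT_MOTIF, GenomicInterval(seq_id, start, start + 8, "+"), m.group(1))
        )
    rc = reverse_complement(sub)
    for m in _STAT_RE.finditer(rc):
        start = region.start + (len(sub) - (m.start(1) + 9))
        hits.append(
            MotifHit(STAT_MOTIF, GenomicInterval(seq_id, start, start + 8, "-"), m.group(1))
        )
    return sorted(hits, key=lambda h: (h.interval.start, h.interval.strand))


def _best_local_hit(ref: str, window: str):
    res = edlib.align(ref.upper(), window.upper(), mode="HW", task="path")
    if res["editDistance"] < 0:
        return None
    identity = 1.0 - res["editDistance"] / len(ref)
    s, e = res["locations"][0]
    return identity, s, e, res["cigar"]


def _conserved_core(cigar: str, min_identity: float = 0.8) -> int:
    """Length of the longest alignment stretch at >= min_identity matches."""
    flags: List[bool] = []
    for n, op in re.findall(r"(\d+)([=XIDM])", cigar):
        flags.extend([op == "="] * int(n))
    best = 0
    prefix = [0]
    for f in flags:
        prefix.append(prefix[-1] + (1 if f else 0))
    n = len(flags)
    for i in range(n):
        for j in range(n, i + best, -1):
            if prefix[j] - prefix[i] >= min_identity * (j - i):
                best = max(best, j - i)
                break
    return best


def locate_regulatory_elements(
    cassette: Cassette,
    locus,
    ref_pj: SequenceRecord,
    ref_en: SequenceRecord,
    min_identity: float = 0.6,
) -> Tuple[Cassette, Dict[str, int]]:
    """Locate PJ and En for one cassette by alignment to reference elements.

    PJ is searched in the 2 kb upstream of the C-distal J gene; En in the 4 kb
    downstream of the C gene (the elements sit "about 2 kb" away, so the
    window is generous). Returns the cassette with ``pj``/``en`` set (absent
    elements stay None) and the conserved-core length of each accepted
    element (longest aligned block at >= 80% identity).
    """
    text = locus.residues if isinstance(locus, SequenceRecord) else str(locus)
    seq_id = locus.id if isinstance(locus, SequenceRecord) else "seq"
    cores: Dict[str, int] = {}

    j_start = cassette.j_genes[0].span.start  # first J = C-distal J
    lo = max(1, j_start - 2000)
    hit = _best_local_hit(ref_pj.residues, text[lo - 1 : j_start - 1])
    if hit and hit[0] >= min_identity:
        ident, s, e, cigar = hit
        cassette.pj = GenomicInterval(seq_id, lo + s, lo + e)
        cores["PJ"] = _conserved_core(cigar)

    c_end = cassette.c_gene.span.end
    hi = min(len(text), c_end + 4000)
    hit = _best_local_hit(ref_en.residues, text[c_end : hi])
    if hit and hit[0] >= min_identity:
        ident, s, e, cigar = hit
        cassette.en = GenomicInterval(seq_id, c_end + 1 + s, c_end + 1 + e)
        cores["En"] = _conserved_core(cigar)
    return cassette, cores


# ---------------------------------------------------------------------------
# homology-block painting


def homology_block_painting(
    cassette_seqs: Sequence[SequenceRecord],
    k: int = 12,
    max_gap: int = 50,
    min_block: int = 100,
) -> List[HomologyBlock]:
    """Shared-anchor decomposition of cassette sequences into colored blocks.

    Exact k-mer anchors shared between sequence pairs are chained collinearly
    (equal diagonal, gaps <= max_gap); chained regions are merged per sequence
    and linked across sequences into blocks. Regions >= min_block covered in
    no shared block are reported as private blocks, so the output is an
    ordered block string per sequence suitable for text rendering.
    """
    if len(cassette_seqs) < 2:
        raise ValueError("need at least two sequences")
    indexes = [_seed_positions(rec.residues, k) for rec in cassette_seqs]
    # chained pair runs -> per-sequence intervals linked pairwise
    nodes: List[Tuple[int, int, int]] = []  # (seq_idx, start0, end0)
    links: List[Tuple[int, int]] = []
    for i in range(len(cassette_seqs)):
        for j in range(i + 1, len(cassette_seqs)):
            by_offset: Dict[int, List[int]] = {}
            for kmer, pi in indexes[i].items():
                pj = indexes[j].get(kmer)
                if not pj or len(pi) > 20 or len(pj) > 20:
                    continue
                for a in pi:
                    for b in pj:
                        by_offset.setdefault(b - a, []).append(a)
            for d, starts in by_offset.items():
                for lo, length in _chain_starts(sorted(set(starts)), k, max_gap, min_block):
                    ni = len(nodes)
                    nodes.append((i, lo, lo + length - 1))
                    nodes.append((j, lo + d, lo + d + length - 1))
                    links.append((ni, ni + 1))
    # union-find over nodes; also merge overlapping nodes on the same sequence
    parent = list(range(len(nodes)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for a, b in links:
        union(a, b)
    by_seq: Dict[int, List[int]] = {}
    for idx, (si, s, e) in enumerate(nodes):
        by_seq.setdefault(si, []).append(idx)
    for si, idxs in by_seq.items():
        idxs.sort(key=lambda x: nodes[x][1])
        for a, b in zip(idxs, idxs[1:]):
            # chance seed extension can nudge a run a few bases across a block
            # boundary; only a >= k overlap is evidence of the same block
            if nodes[a][2] - nodes[b][1] + 1 >= k:
                union(a, b)
    clusters: Dict[int, List[int]] = {}
    for idx in range(len(nodes)):
        clusters.setdefault(find(idx), []).append(idx)
    blocks: List[HomologyBlock] = []
    for root in sorted(clusters, key=lambda r: min(nodes[x][1] for x in clusters[r])):
        intervals: Dict[str, GenomicInterval] = {}
        for idx in clusters[root]:
            si, s, e = nodes[idx]
            rec = cassette_seqs[si]
            prev = intervals.get(rec.id)
            if prev is None:
                intervals[rec.id] = GenomicInterval(rec.id, s + 1, e + 1)
            else:
                intervals[rec.id] = GenomicInterval(
                    rec.id, min(prev.start, s + 1), max(prev.end, e + 1)
                )
        blocks.append(HomologyBlock(len(blocks) + 1, intervals))
    # private remainder blocks
    for rec in cassette_seqs:
        covered = sorted(
            (b.intervals[rec.id].start, b.intervals[rec.id].end)
            for b in blocks
            if rec.id in b.intervals
        )
        cursor = 1
        gaps = []
        for s, e in covered:
            if s - cursor >= min_block:
                gaps.append((cursor, s - 1))
            cursor = max(cursor, e + 1)
        if len(rec.residues) - cursor + 1 >= min_block:
            gaps.append((cursor, len(rec.residues)))
        for s, e in gaps:
            blocks.append(
                HomologyBlock(len(blocks) + 1, {rec.id: GenomicInterval(rec.id, s, e)})
            )
    return blocks


def block_strings(blocks: Sequence[HomologyBlock], seq_ids: Sequence[str]) -> Dict[str, List[int]]:
    """Ordered block-id string per sequence (the text form of the painting)."""
    out: Dict[str, List[int]] = {}
    for sid in seq_ids:
        mine = [(b.intervals[sid].start, b.block_id) for b in blocks if sid in b.intervals]
        out[sid] = [bid for _, bid in sorted(mine)]
    return out
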