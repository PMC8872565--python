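"""Distance-based phylogenetics: alignment, p-distance, NJ, bootstrap, dating.

The pipeline mirrors the classical distance workflow for TR gene sets:
multiple alignment (a simple deterministic progressive aligner; externally
produced alignments can be imported instead), p-distances with pairwise
deletion of gap/ambiguous columns, neighbor-joining with the Saitou-Nei
Q-criterion, bootstrap supports from column resampling, and a relative-rate
(RelTime-style) conversion of a rooted tree into node ages anchored on one
calibration interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np

from .model import SequenceRecord

_ACGT = frozenset(b"ACGT")


@dataclass
class Alignment:
    """Equal-length rows over the nucleotide alphabet plus gaps."""

    records: List[SequenceRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment needs at least one row")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.records[0].residues)

    @property
    def taxa(self) -> List[str]:
        return [r.id for r in self.records]

    def matrix(self) -> np.ndarray:
        return np.frombuffer(
            "".join(r.residues.upper() for r in self.records).encode("ascii"),
            dtype=np.uint8,
        ).reshape(len(self.records), len(self))

    def resample_columns(self, columns: np.ndarray) -> "Alignment":
        mat = self.matrix()[:, columns]
        return Alignment(
            [
                SequenceRecord(r.id, mat[i].tobytes().decode("ascii"))
                for i, r in enumerate(self.records)
            ]
        )


@dataclass
class DistanceMatrix:
    """Pairwise p-distances plus per-pair retained-site counts."""

    taxa: List[str]
    d: np.ndarray
    retained_sites: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")


# ---------------------------------------------------------------------------
# progressive alignment

_SCORE_MATCH = 1.0
_SCORE_MISMATCH = -1.0
_GAP_OPEN = -4.0  # cost of the first gap residue
_GAP_EXTEND = -1.0

_BASE_IDX = {c: i for i, c in enumerate("ACGT")}
_SUBST = np.full((4, 4), _SCORE_MISMATCH)
np.fill_diagonal(_SUBST, _SCORE_MATCH)


def _profile(rows: List[str]) -> np.ndarray:
    """Per-column base frequencies over non-gap residues (L x 4)."""
    L = len(rows[0])
    freq = np.zeros((L, 4))
    counts = np.zeros(L)
    for row in rows:
        for i, ch in enumerate(row):
            k = _BASE_IDX.get(ch.upper())
            if k is not None:
                freq[i, k] += 1
                counts[i] += 1
    nz = counts > 0
    freq[nz] /= counts[nz, None]
    return freq


def _align_profiles(rows_a: List[str], rows_b: List[str]) -> Tuple[List[str], List[str]]:
    """Gotoh affine-gap alignment of two profiles (expected-score columns)."""
    fa, fb = _profile(rows_a), _profile(rows_b)
    S = fa @ _SUBST @ fb.T  # column-vs-column expected score
    la, lb = S.shape
    NEG = -1e30
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap in B (consume A)
    Y = np.full((la + 1, lb + 1), NEG)  # gap in A (consume B)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = _GAP_OPEN + _GAP_EXTEND * (i - 1)
    for j in range(1, lb + 1):
        Y[0, j] = _GAP_OPEN + _GAP_EXTEND * (j - 1)
    for i in range(1, la + 1):
        Mprev, Xprev, Yprev = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Xi[:] = np.maximum(Mprev + _GAP_OPEN, Xprev + _GAP_EXTEND)
        row_s = S[i - 1]
        for j in range(1, lb + 1):
            Mi[j] = row_s[j - 1] + max(Mprev[j - 1], Xprev[j - 1], Yprev[j - 1])
            Yi[j] = max(Mi[j - 1] + _GAP_OPEN, Yi[j - 1] + _GAP_EXTEND)
    # traceback (diagonal preferred, then gap-in-B, then gap-in-A)
    out_a: List[str] = []
    out_b: List[str] = []
    i, j = la, lb
    state = int(np.argmax([M[la, lb], X[la, lb], Y[la, lb]]))
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            prevs = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            nxt = int(np.argmax(prevs))
            out_a.append("COL_A")
            out_b.append("COL_B")
            i, j, state = i - 1, j - 1, nxt
        elif state == 1 and i > 0:
            came_open = abs(X[i, j] - (M[i - 1, j] + _GAP_OPEN)) < 1e-9
            out_a.append("COL_A")
            out_b.append("GAP")
            i, state = i - 1, 0 if came_open else 1
        elif state == 2 and j > 0:
            came_open = abs(Y[i, j] - (M[i, j - 1] + _GAP_OPEN)) < 1e-9
            out_a.append("GAP")
            out_b.append("COL_B")
            j, state = j - 1, 0 if came_open else 2
        else:  # boundary: forced gap
            if i > 0:
                out_a.append("COL_A")
                out_b.append("GAP")
                i -= 1
            else:
                out_a.append("GAP")
                out_b.append("COL_B")
                j -= 1
    out_a.reverse()
    out_b.reverse()
    # materialize gapped rows
    new_a = ["" for _ in rows_a]
    new_b = ["" for _ in rows_b]
    ia = ib = 0
    for opa, opb in zip(out_a, out_b):
        if opa == "COL_A":
            for r, row in enumerate(rows_a):
                new_a[r] += row[ia]
            ia += 1
        else:
            for r in range(len(rows_a)):
                new_a[r] += "-"
        if opb == "COL_B":
            for r, row in enumerate(rows_b):
                new_b[r] += row[ib]
            ib += 1
        else:
            for r in range(len(rows_b)):
                new_b[r] += "-"
    return new_a, new_b


def _kmer_set(seq: str, k: int = 6) -> set:
    s = seq.upper()
    return {s[i : i + k] for i in range(len(s) - k + 1)}


def _guide_order(seqs: Sequence[SequenceRecord]) -> List[Tuple]:
    """UPGMA joins on shared-k-mer distance; lexicographic tie-breaking."""
    n = len(seqs)
    sets = [_kmer_set(r.residues) for r in seqs]
    d: Dict[Tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            shared = len(sets[i] & sets[j])
            denom = min(len(sets[i]), len(sets[j])) or 1
            d[(i, j)] = 1.0 - shared / denom
    clusters: Dict[int, List[int]] = {i: [i] for i in range(n)}
    labels: Dict[int, str] = {i: seqs[i].id for i in range(n)}
    joins: List[Tuple] = []
    nxt = n

    def dist(a: int, b: int) -> float:
        total = 0.0
        for x in clusters[a]:
            for y in clusters[b]:
                total += d[(min(x, y), max(x, y))]
        return total / (len(clusters[a]) * len(clusters[b]))

    while len(clusters) > 1:
        keys = sorted(clusters, key=lambda c: labels[c])
        best = None
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                val = dist(a, b)
                if best is None or val < best[0] - 1e-12:
                    best = (val, a, b)
        _, a, b = best
        joins.append((a, b, nxt))
        clusters[nxt] = clusters.pop(a) + clusters.pop(b)
        labels[nxt] = min(labels[a], labels[b])
        nxt += 1
    return joins


def progressive_align(seqs: Sequence[SequenceRecord]) -> Alignment:
    """Simple deterministic progressive multiple alignment.

    Guide order from UPGMA on shared-k-mer distances; profiles merged by
    affine-gap dynamic programming (match +1, mismatch -1, first gap residue
    -4, extension -1). For two sequences this reduces to plain pairwise
    Needleman-Wunsch with the same scoring. A single sequence is returned
    unchanged as a one-row alignment.
    """
    seqs = list(seqs)
    if len(seqs) == 1:
        return Alignment([SequenceRecord(seqs[0].id, seqs[0].residues)])
    profiles: Dict[int, Tuple[List[str], List[str]]] = {
        i: ([r.residues], [r.id]) for i, r in enumerate(seqs)
    }
    for a, b, new in _guide_order(seqs):
        rows_a, ids_a = profiles.pop(a)
        rows_b, ids_b = profiles.pop(b)
        new_a, new_b = _align_profiles(rows_a, rows_b)
        profiles[new] = (new_a + new_b, ids_a + ids_b)
    rows, ids = profiles.popitem()[1]
    order = {r.id: k for k, r in enumerate(seqs)}
    recs = sorted(
        (SequenceRecord(i, row) for i, row in zip(ids, rows)), key=lambda r: order[r.id]
    )
    return Alignment(recs)


# ---------------------------------------------------------------------------
# p-distance


def p_distance_matrix(aln: Alignment, pairwise_deletion: bool = True) -> DistanceMatrix:
    """p-distances (base differences per site) with pairwise deletion.

    For each pair, columns holding a gap or any non-ACGT code in either row
    are removed; the distance is differing sites / retained sites. With
    ``pairwise_deletion=False`` columns with any ambiguity in any row are
    removed once for all pairs (complete deletion).
    """
    mat = aln.matrix()
    n = len(aln.records)
    valid = np.isin(mat, np.frombuffer(b"ACGT", dtype=np.uint8))
    if not pairwise_deletion:
        keep = valid.all(axis=0)
        mat = mat[:, keep]
        valid = valid[:, keep]
    d = np.zeros((n, n))
    retained = np.zeros((n, n), dtype=int)
    for i in range(n):
        retained[i, i] = int(valid[i].sum())
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"no retained sites between {aln.taxa[i]!r} and {aln.taxa[j]!r}"
                )
            diff = int((mat[i, both] != mat[j, both]).sum())
            d[i, j] = d[j, i] = diff / m
            retained[i, j] = retained[j, i] = m
    return DistanceMatrix(aln.taxa, d, retained)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining.

    Q-criterion agglomeration; ties go to the smallest (i, j) node-index pair;
    branch lengths from the standard two-point formulas, with negative
    estimates clamped to 0 (a warning is issued). Returns an unrooted
    dendropy tree.
    """
    n = len(D.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    taxon_ns = dendropy.TaxonNamespace(D.taxa)
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    nodes: List[dendropy.Node] = []
    for name in D.taxa:
        leaf = dendropy.Node(taxon=taxon_ns.get_taxon(name))
        nodes.append(leaf)
    dist = D.d.copy()
    active = list(range(n))

    def clamp(x: float) -> float:
        if x < 0:
            warnings.warn(f"negative NJ branch length {x:.4g} clamped to 0")
            return 0.0
        return x

    while len(active) > 2:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai in range(m):
            for bi in range(ai + 1, m):
                q = (m - 2) * sub[ai, bi] - r[ai] - r[bi]
                if best is None or q < best[0] - 1e-12:
                    best = (q, ai, bi)
        _, ai, bi = best
        i, j = active[ai], active[bi]
        dij = dist[i, j]
        li = 0.5 * dij + (r[ai] - r[bi]) / (2 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        ni, nj = nodes[i], nodes[j]
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = clamp(li)
        nj.edge.length = clamp(lj)
        new_row = np.zeros(dist.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (dist[i, k] + dist[j, k] - dij)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[-1, : len(new_row) - 1] = new_row[:-1]
        dist[: len(new_row) - 1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [dist.shape[0] - 1]

    i, j = active
    a, b = nodes[i], nodes[j]
    # attach the simpler side under the other to keep the tree unrooted
    if a.is_leaf() and not b.is_leaf():
        a, b = b, a
    a.add_child(b)
    b.edge.length = clamp(dist[i, j])
    tree.seed_node = a
    tree.is_rooted = False
    tree.update_taxon_namespace()
    return tree


def tree_length(tree: dendropy.Tree) -> float:
    """Sum of all branch lengths (missing lengths count as 0)."""
    return sum(
        (nd.edge.length or 0.0)
        for nd in tree.preorder_node_iter()
        if nd is not tree.seed_node
    )


def path_distance_matrix(tree: dendropy.Tree) -> Dict[Tuple[str, str], float]:
    """Leaf-to-leaf path lengths (the additivity oracle's currency)."""
    pdm = tree.phylogenetic_distance_matrix()
    out: Dict[Tuple[str, str], float] = {}
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    for a in taxa:
        for b in taxa:
            if a.label < b.label:
                out[(a.label, b.label)] = pdm.patristic_distance(a, b)
    return out


# ---------------------------------------------------------------------------
# bipartitions, bootstrap, monophyly


def _bipartitions(tree: dendropy.Tree) -> Dict[frozenset, dendropy.Node]:
    """Non-trivial bipartitions, canonicalized to the side without taxa[0]."""
    all_taxa = frozenset(t.label for t in tree.taxon_namespace)
    ref = min(all_taxa)
    out: Dict[frozenset, dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = all_taxa - side
        if 1 < len(side) < len(all_taxa) - 1:
            out[side] = node
    return out


def bootstrap_supports(
    aln: Alignment, replicates: int = 100, seed: int = 0
) -> dendropy.Tree:
    """NJ tree with bootstrap supports from column resampling.

    Columns are resampled with replacement, NJ is rerun per replicate, and
    each internal bipartition of the full-data tree gets the percentage of
    replicates containing it (stored as the node label, an integer in
    [0, 100]). Reproducible for a fixed seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    full = neighbor_joining(p_distance_matrix(aln))
    target = _bipartitions(full)
    counts = {bp: 0 for bp in target}
    L = len(aln)
    for _ in range(replicates):
        cols = rng.integers(0, L, L)
        rep_tree = neighbor_joining(p_distance_matrix(aln.resample_columns(cols)))
        rep_bps = set(_bipartitions(rep_tree))
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    for bp, node in target.items():
        node.label = str(round(100 * counts[bp] / replicates))
    return full


def monophyly_test(tree: dendropy.Tree, taxa: Sequence[str], outgroup: str) -> bool:
    """Is ``taxa`` exactly the leaf set of one clade after rooting on outgroup?"""
    labels = {t.label for t in tree.taxon_namespace}
    subset = set(taxa)
    unknown = (subset | {outgroup}) - labels
    if unknown:
        raise ValueError(f"unknown taxa: {sorted(unknown)}")
    if len(subset) == 1:
        return True
    work = tree.clone(depth=1)
    og = work.find_node_with_taxon_label(outgroup)
    _root_on_edge(work, og)
    for node in work.preorder_node_iter():
        side = {lf.taxon.label for lf in node.leaf_iter()}
        if side == subset:
            return True
    return False


def _root_on_edge(tree: dendropy.Tree, leaf: dendropy.Node) -> None:
    """Root a tree on a leaf's edge, yielding a bifurcating root."""
    half = (leaf.edge.length or 0.0) / 2.0
    tree.reroot_at_edge(leaf.edge, length1=half, length2=half, update_bipartitions=False)
    tree.is_rooted = True


# ---------------------------------------------------------------------------
# RelTime-style dating


@dataclass
class TimeTree:
    """A rooted tree with per-branch relative rates and node ages in Ma."""

    tree: dendropy.Tree
    ages: Dict[int, float]  # node id -> absolute age (Ma)
    relative_rates: Dict[int, float]  # node id -> rate of the branch above it
    calibration: Tuple[str, str, float, float]
    calibrated_age: float = 0.0

    def age_of_mrca(self, a: str, b: str) -> float:
        node = self.tree.mrca(taxon_labels=[a, b])
        return self.ages[id(node)]

    def node_ages_table(self) -> List[Tuple[str, float, float]]:
        rows = []
        for node in self.tree.preorder_node_iter():
            if id(node) not in self.ages or node.is_leaf():
                continue
            tips = sorted(lf.taxon.label for lf in node.leaf_iter())
            rows.append(
                ("|".join(tips), self.ages[id(node)], self.relative_rates.get(id(node), 1.0))
            )
        return rows


def reltime_dating(
    tree: dendropy.Tree,
    outgroup: str,
    calibration: Tuple[str, str, float, float],
    _eps: float = 1e-12,
) -> TimeTree:
    """Relative-rate dating of a tree rooted on an outgroup.

    At every internal node the two descendant lineages must span the same
    time, so their relative rates are taken proportional to their (tip-count
    weighted) mean depths; rates compose multiplicatively toward the tips, and
    node ages follow by averaging rate-corrected branch lengths bottom-up.
    The outgroup is excluded from all rate averaging. Absolute ages scale the
    calibrated node (the MRCA of the two named taxa) to the midpoint of the
    calibration interval, then clip it into the interval.

    In the clock limit all relative rates are 1 and ages are proportional to
    node depths.
    """
    nodeA, nodeB, min_age, max_age = calibration
    work = tree.clone(depth=1)
    og = work.find_node_with_taxon_label(outgroup)
    if og is None:
        raise ValueError(f"outgroup {outgroup!r} not in tree")
    _root_on_edge(work, og)
    root_children = [c for c in work.seed_node.child_nodes() if c is not og]
    if len(root_children) != 1:
        raise ValueError("rooting on the outgroup failed to bisect the tree")
    ingroup = root_children[0]

    depth: Dict[int, float] = {}
    ntips: Dict[int, int] = {}
    for node in work.postorder_node_iter():
        if node.is_leaf():
            depth[id(node)] = 0.0
            ntips[id(node)] = 1
        else:
            kids = node.child_nodes()
            tot = sum(ntips[id(c)] for c in kids)
            depth[id(node)] = (
                sum(ntips[id(c)] * (depth[id(c)] + (c.edge.length or 0.0)) for c in kids) / tot
            )
            ntips[id(node)] = tot

    rates: Dict[int, float] = {}

    def assign_rates(node, lineage_rate: float) -> None:
        kids = node.child_nodes()
        if not kids:
            return
        lens = [depth[id(c)] + (c.edge.length or 0.0) for c in kids]
        if any(l <= 0 for l in lens):
            raise ValueError(
                "zero-length terminal subtree: relative rates are undefined"
            )
        tot = sum(ntips[id(c)] for c in kids)
        mean = sum(n_ * l for n_, l in zip((ntips[id(c)] for c in kids), lens)) / tot
        for c, l in zip(kids, lens):
            local = l / mean
            rates[id(c)] = lineage_rate * local
            assign_rates(c, lineage_rate * local)

    assign_rates(ingroup, 1.0)

    rel_age: Dict[int, float] = {}
    for node in work.postorder_node_iter():
        if id(node) not in rates and node is not ingroup:
            continue  # outgroup side
        if node.is_leaf():
            rel_age[id(node)] = 0.0
            continue
        kids = node.child_nodes()
        tot = sum(ntips[id(c)] for c in kids)
        est = (
            sum(
                ntips[id(c)]
                * (rel_age[id(c)] + (c.edge.length or 0.0) / rates[id(c)])
                for c in kids
            )
            / tot
        )
        floor = max(rel_age[id(c)] for c in kids)
        rel_age[id(node)] = max(est, floor + _eps)

    mrca = work.mrca(taxon_labels=[nodeA, nodeB])
    if mrca is None or id(mrca) not in rel_age:
        raise ValueError("calibrated node not found in the ingroup")
    target = (min_age + max_age) / 2.0
    scale = target / rel_age[id(mrca)]
    ages = {k: v * scale for k, v in rel_age.items()}
    cal = min(max(ages[id(mrca)], min_age), max_age)
    ages[id(mrca)] = cal
    return TimeTree(work, ages, rates, (nodeA, nodeB, min_age, max_age), calibrated_age=cal)
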