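"""Shared fixtures: synthetic loci and small oracle helpers."""

import numpy as np
import pytest

from trgkit.simulate import LocusSpec, generate_locus

#: one defect of every kind, spread over the pig-like locus
DEFECT_PLAN = [
    ("V1-2", "stop_codon"),
    ("V3-1", "frameshift"),
    ("V1-3", "donor_site"),
    ("V1-4", "frameshift_leader"),
    ("J2-1", "rs_heptamer_core"),
    ("J4-1", "j_motif_second_position"),
    ("C4", "frameshift"),
]


@pytest.fixture(scope="session")
def pig_like():
    """A pig-like locus: 4 cassettes, V counts [5,1,1,1], J counts [2,2,1,1]."""
    rec, truth = generate_locus(LocusSpec(seed=42))
    return rec, truth


@pytest.fixture(scope="session")
def defect_locus():
    rec, truth = generate_locus(LocusSpec(seed=42, defect_plan=DEFECT_PLAN))
    return rec, truth


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[b] for b in rng.integers(0, 4, n))


def affine_score(row_a: str, row_b: str, match=1.0, mismatch=-1.0, open_=-5.0, extend=-1.0):
    """Score a gapped alignment pair: first gap residue costs open_, rest extend."""
    score = 0.0
    in_gap_a = in_gap_b = False
    for ca, cb in zip(row_a, row_b):
        if ca == "-":
            score += extend if in_gap_a else open_
            in_gap_a, in_gap_b = True, False
        elif cb == "-":
            score += extend if in_gap_b else open_
            in_gap_b, in_gap_a = True, False
        else:
            in_gap_a = in_gap_b = False
            score += match if ca == cb else mismatch
    return score


def nw_affine_best_score(a: str, b: str, match=1.0, mismatch=-1.0, open_=-5.0, extend=-1.0):
    """Exhaustive affine-gap global alignment optimum (Gotoh, independent oracle)."""
    la, lb = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (lb + 1) for _ in range(la + 1)]
    X = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in b
    Y = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, la + 1):
        X[i][0] = open_ + extend * (i - 1)
    for j in range(1, lb + 1):
        Y[0][j] = open_ + extend * (j - 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + extend)
            Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + extend)
    return max(M[la][lb], X[la][lb], Y[la][lb])


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """Random unrooted binary tree as (edges, leaf names); lengths in [0.1, 2]."""
    # adjacency: node -> {neighbor: length}; start from a 3-leaf star
    adj = {f"L{i}": {} for i in range(3)}
    adj["I0"] = {}

    def connect(u, v, w):
        adj[u][v] = w
        adj[v][u] = w

    for i in range(3):
        connect("I0", f"L{i}", float(rng.uniform(0.1, 2.0)))
    n_internal = 1
    for i in range(3, n_leaves):
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[int(rng.integers(len(edges)))]
        w = adj[u].pop(v)
        adj[v].pop(u)
        mid = f"I{n_internal}"
        n_internal += 1
        adj[mid] = {}
        split = float(rng.uniform(0.2, 0.8))
        connect(u, mid, w * split)
        connect(mid, v, w * (1 - split))
        leaf = f"L{i}"
        adj[leaf] = {}
        connect(mid, leaf, float(rng.uniform(0.1, 2.0)))
    return adj


def tree_path_distances(adj, leaves):
    """All-pairs leaf path lengths by BFS over the explicit tree graph."""
    out = {}
    for src in leaves:
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for dst in leaves:
            if src < dst:
                out[(src, dst)] = dist[dst]
    return out
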