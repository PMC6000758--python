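"""Independent brute-force oracles used only by the tests.

Each oracle re-derives an expected result by the most direct method
available — quadratic DP, dense power iteration, exhaustive set
enumeration, direct recounting — staying independent of the package's
implementation path.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Gotoh local-alignment score; a gap of length g costs open + g·extend."""
    n, m = len(a), len(b)
    NEG = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_open - gap_extend, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open - gap_extend, F[i - 1, j] - gap_extend)
            H[i, j] = max(0.0, H[i - 1, j - 1] + _BLOSUM62[a[i - 1]][b[j - 1]], E[i, j], F[i, j])
            best = max(best, H[i, j])
    return int(best)


def dense_mcl_partition(
    nodes: list[str],
    edges: list[tuple[str, str, float]],
    inflation: float,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> set[frozenset[str]]:
    """Plain dense MCL: expansion power 2, no pruning.

    Readout follows the standard attractor convention: attractors are
    rows with positive diagonal mass, attractors reaching each other
    share a cluster, and any other node joins the cluster of the
    attractors holding mass on its column.  A node attracted by several
    clusters (possible, e.g. the bridge node of a barbell) goes to the
    largest cluster, ties broken toward the cluster with the smallest
    member name.
    """
    nodes = sorted(nodes)
    idx = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for a, b, w in edges:
        m[idx[a], idx[b]] = w
        m[idx[b], idx[a]] = w
    loops = m.max(axis=0)
    loops[loops == 0] = 1.0
    np.fill_diagonal(m, loops)
    m = m / m.sum(axis=0)
    for _ in range(max_iter):
        new = m @ m
        new = new ** inflation
        new = new / new.sum(axis=0)
        if np.max(np.abs(new - m)) < tol:
            m = new
            break
        m = new
    eps = 1e-6
    attractors = [i for i in range(n) if m[i, i] > eps]
    if not attractors:
        return {frozenset(nodes)}
    # merge attractors that hold mass on each other's columns
    parent = list(range(len(attractors)))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for p, a in enumerate(attractors):
        for q, b in enumerate(attractors):
            if m[a, b] > eps or m[b, a] > eps:
                parent[find(p)] = find(q)
    clusters: dict[int, set[str]] = {}
    owner: dict[int, int] = {}
    for p, a in enumerate(attractors):
        clusters.setdefault(find(p), set()).add(nodes[a])
        owner[a] = find(p)
    for i in range(n):
        if i in owner:
            continue
        cands = sorted({owner[a] for a in attractors if m[a, i] > eps})
        if not cands:
            clusters[-i - 1] = {nodes[i]}
        else:
            best = sorted(
                cands, key=lambda c: (-len(clusters[c]), min(clusters[c]))
            )[0]
            clusters[best].add(nodes[i])
    return {frozenset(s) for s in clusters.values()}


def classify_presence(members_by_genome: dict[str, int], panel: set[str]) -> str:
    """Direct pan-genome category from a family's per-genome counts."""
    present = {g for g, c in members_by_genome.items() if c > 0}
    size = sum(members_by_genome.values())
    if size == 1:
        return "singleton"
    if len(present) == 1:
        return "lse"
    if present == panel:
        return "core"
    return "dispensable"


def all_presence_patterns(panel: list[str]):
    """Every non-empty genome subset of the panel."""
    for r in range(1, len(panel) + 1):
        yield from (set(c) for c in itertools.combinations(panel, r))


def recount_window(seq: str, start: int, size: int) -> float:
    """GC skew of one circular window by direct character counting."""
    win = (seq + seq)[start:start + size]
    g, c = win.count("G"), win.count("C")
    return 0.0 if g + c == 0 else (g - c) / (g + c)
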