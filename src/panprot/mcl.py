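"""Markov clustering (MCL) of the weighted similarity graph.

Edges are weighted −log10(E-value) (capped when E underflows), each node
receives a self-loop equal to its maximum incident weight, and the
column-stochastic transition matrix is iterated through expansion
(matrix power) and inflation (entrywise power + column renormalisation)
with pruning until the matrix stops changing.  Clusters are read off
from attractors; because MCL never merges across zero-weight cuts, the
iteration runs independently per connected component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse import csgraph

from .align import LOG10_EVALUE_CAP, DEFAULT_SCORING, ScoringScheme
from .graph import EdgeCutoffs, SimilarityEdge, build_graph
from .records import Proteomes, iter_records


@dataclass(frozen=True)
class MCLParams:
    inflation: float = 1.5
    expansion_power: int = 2
    prune_threshold: float = 1e-5
    convergence_tol: float = 1e-6
    max_iterations: int = 200
    self_loop: str = "max"          # "max": node's max incident weight; "unit": 1.0

    def __post_init__(self) -> None:
        if self.self_loop not in ("max", "unit"):
            raise ValueError("self_loop must be 'max' or 'unit'")
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.expansion_power < 2 or int(self.expansion_power) != self.expansion_power:
            raise ValueError("expansion_power must be an integer >= 2")
        if self.prune_threshold < 0:
            raise ValueError("prune_threshold must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass(frozen=True)
class OrthologFamily:
    """A cluster of genes across genomes — the unit of pan-genome logic."""

    family_id: str
    members: tuple[str, ...]
    genome_counts: Mapping[str, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def genomes(self) -> frozenset[str]:
        return frozenset(self.genome_counts)


def edge_weight(edge: SimilarityEdge) -> float:
    """−log10(E), capped for E = 0; strictly decreasing in E."""
    if edge.evalue <= 0.0:
        return LOG10_EVALUE_CAP
    return min(-np.log10(edge.evalue), LOG10_EVALUE_CAP)


def _mcl_component(m: np.ndarray, params: MCLParams) -> np.ndarray:
    """Iterate one dense component to (near) idempotence; returns the matrix."""
    n = m.shape[0]
    col = m.sum(axis=0)
    col[col == 0] = 1.0
    m = m / col
    for _ in range(params.max_iterations):
        new = np.linalg.matrix_power(m, params.expansion_power)
        np.power(new, params.inflation, out=new)
        new[new < params.prune_threshold] = 0.0
        col = new.sum(axis=0)
        col[col == 0] = 1.0
        new /= col
        change = float(np.max(np.abs(new - m)))
        m = new
        if change < params.convergence_tol:
            break
    else:
        warnings.warn(
            f"MCL did not converge within {params.max_iterations} iterations "
            "(returning current partition)",
            RuntimeWarning,
        )
    return m


def _read_clusters(m: np.ndarray, nodes: Sequence[str]) -> list[frozenset[str]]:
    """Cluster readout from a converged MCL matrix (one component).

    Attractors are nodes with positive self-mass; attractors that reach
    each other form one cluster, every other node joins the cluster(s)
    of attractors attracting it.  A node attracted by several clusters
    goes to the largest, ties broken toward the cluster whose smallest
    member gene id sorts first.
    """
    eps = 1e-9
    n = m.shape[0]
    attractors = [i for i in range(n) if m[i, i] > eps]
    if not attractors:  # degenerate: everything in one cluster
        return [frozenset(nodes)]
    # group attractors: connected components of mutual reachability
    sub = (m[np.ix_(attractors, attractors)] > eps)
    sub = sub | sub.T
    ncomp, labels = csgraph.connected_components(sparse.csr_matrix(sub), directed=False)
    groups: dict[int, set[int]] = {}
    for a, lbl in zip(attractors, labels):
        groups.setdefault(int(lbl), set()).add(a)
    clusters = [set(g) for _, g in sorted(groups.items())]
    # attach non-attractor nodes
    attractor_cluster = {a: ci for ci, cl in enumerate(clusters) for a in cl}
    pending: list[tuple[int, list[int]]] = []
    for i in range(n):
        if i in attractor_cluster:
            continue
        cands = sorted({attractor_cluster[a] for a in attractors if m[a, i] > eps})
        if len(cands) == 1:
            clusters[cands[0]].add(i)
        elif cands:
            pending.append((i, cands))
        else:
            clusters.append({i})  # attracted by nothing: own singleton
    for i, cands in pending:
        key = lambda ci: (-len(clusters[ci]), min(nodes[j] for j in clusters[ci]))
        clusters[sorted(cands, key=key)[0]].add(i)
    return [frozenset(nodes[i] for i in cl) for cl in clusters]


def mcl(
    nodes: Sequence[str],
    weighted_edges: Iterable[tuple[str, str, float]],
    params: MCLParams = MCLParams(),
) -> list[frozenset[str]]:
    """Cluster a weighted undirected graph; returns disjoint node sets.

    Node order is fixed lexicographically for determinism.  Each node
    gets a self-loop equal to its maximum incident weight (1.0 for
    isolated nodes).  Edges listed in both directions must agree.
    """
    nodes = sorted(set(nodes))
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    if n == 0:
        return []
    w: dict[tuple[int, int], float] = {}
    for a, b, wt in weighted_edges:
        if a not in index or b not in index:
            raise ValueError(f"edge endpoint not in node list: {(a, b)}")
        if wt < 0:
            raise ValueError("edge weights must be non-negative")
        if a == b:
            continue
        i, j = sorted((index[a], index[b]))
        prev = w.get((i, j))
        if prev is not None and abs(prev - wt) > 1e-12:
            raise ValueError(f"asymmetric weights given for pair ({a}, {b})")
        w[(i, j)] = wt
    rows = [i for (i, j) in w] + [j for (i, j) in w]
    cols = [j for (i, j) in w] + [i for (i, j) in w]
    vals = list(w.values()) * 2
    adj = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    ncomp, labels = csgraph.connected_components(
        (adj > 0).astype(np.int8), directed=False
    ) if w else (n, np.arange(n))
    clusters: list[frozenset[str]] = []
    for c in range(ncomp):
        idx = np.flatnonzero(labels == c)
        if len(idx) == 1:
            clusters.append(frozenset({nodes[int(idx[0])]}))
            continue
        sub = adj[np.ix_(idx, idx)].toarray().astype(float)
        if params.self_loop == "max":
            loop = sub.max(axis=0)
            loop[loop == 0] = 1.0
        else:
            loop = np.ones(len(idx))
        np.fill_diagonal(sub, loop)
        conv = _mcl_component(sub, params)
        clusters.extend(_read_clusters(conv, [nodes[int(i)] for i in idx]))
    clusters.sort(key=lambda cl: min(cl))
    return clusters


def families_from_clusters(
    clusters: Iterable[frozenset[str]],
    gene_genomes: Mapping[str, str],
    prefix: str = "OF",
) -> list[OrthologFamily]:
    """Assign deterministic family ids (by smallest member gene id)."""
    out = []
    for k, cl in enumerate(sorted(clusters, key=min), start=1):
        members = tuple(sorted(cl))
        counts: dict[str, int] = {}
        for g in members:
            counts[gene_genomes[g]] = counts.get(gene_genomes[g], 0) + 1
        out.append(OrthologFamily(f"{prefix}{k:05d}", members, counts))
    return out


def cluster_families(
    proteomes: Proteomes,
    cutoffs: EdgeCutoffs = EdgeCutoffs(),
    params: MCLParams = MCLParams(),
    scoring: ScoringScheme = DEFAULT_SCORING,
    prescreen_min_kmers: int | None = None,
    family_prefix: str = "OF",
) -> list[OrthologFamily]:
    """End-to-end: similarity graph → MCL → ortholog families.

    Every input gene lands in exactly one family; genes with no retained
    edge become size-1 families.  Deterministic for fixed input.
    """
    records = list(iter_records(proteomes))
    gene_genomes = {r.gene_id: r.genome_id for r in records}
    if not records:
        return []
    edges = build_graph(
        proteomes, cutoffs, scoring, prescreen_min_kmers=prescreen_min_kmers
    )
    clusters = mcl(
        list(gene_genomes), [(e.gene_a, e.gene_b, edge_weight(e)) for e in edges], params
    )
    return families_from_clusters(clusters, gene_genomes, prefix=family_prefix)


def write_families(
    families: Iterable[OrthologFamily],
    path: str | Path,
    gene_genomes: Mapping[str, str] | None = None,
) -> None:
    rows = [
        {
            "family_id": f.family_id,
            "gene_id": g,
            "genome_id": gene_genomes[g] if gene_genomes else g.partition("|")[0],
        }
        for f in families
        for g in f.members
    ]
    pd.DataFrame(rows, columns=["family_id", "gene_id", "genome_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_families(path: str | Path) -> list[OrthologFamily]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    fams = []
    for fid, grp in df.groupby("family_id", sort=True):
        members = tuple(sorted(grp["gene_id"]))
        counts = grp.groupby("genome_id")["gene_id"].count().to_dict()
        fams.append(OrthologFamily(str(fid), members, counts))
    return fams


def write_mcl_text(families: Iterable[OrthologFamily], path: str | Path) -> None:
    """MCL-style output: one cluster per line, members tab-separated."""
    with open(path, "w") as fh:
        for f in families:
            fh.write("\t".join(f.members) + "\n")
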