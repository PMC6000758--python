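"""All-vs-all similarity graph with OrthoMCL-style edge retention.

An edge between two genes is kept iff the optimal local alignment passes
*all* cutoffs simultaneously — identity, coverage, E-value and score
(bitscore by default, raw-score selectable).  Edges are undirected,
stored once per unordered pair, and the E-value search space (total
residues of the full input) is fixed up front so edges do not depend on
processing order.

``build_graph`` is exact (every pair aligned) unless a shared-k-mer
prescreen is enabled; the prescreen skips pairs sharing fewer than a
minimum number of k-mers, which is safe whenever unrelated sequences sit
far below the identity cutoff (as the synthetic generator guarantees by
construction).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .align import DEFAULT_SCORING, AlignmentResult, ScoringScheme, align_local, estimate_evalue
from .records import ProteinRecord, Proteomes, iter_records

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class EdgeCutoffs:
    """Retention thresholds for similarity-graph edges."""

    min_identity_pct: float = 30.0
    min_coverage_pct: float = 50.0
    max_evalue: float = 1e-5
    min_score: float = 40.0
    score_type: str = "bit"          # "bit" or "raw"

    def __post_init__(self) -> None:
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")
        if self.score_type not in ("bit", "raw"):
            raise ValueError("score_type must be 'bit' or 'raw'")

    def passes(self, res: AlignmentResult, evalue: float) -> bool:
        score = res.bitscore if self.score_type == "bit" else res.raw_score
        return (
            res.identity_pct >= self.min_identity_pct
            and res.coverage_pct >= self.min_coverage_pct
            and evalue <= self.max_evalue
            and score >= self.min_score
        )


@dataclass(frozen=True)
class SimilarityEdge:
    """One retained pairwise hit (gene_a < gene_b lexicographically)."""

    gene_a: str
    gene_b: str
    evalue: float
    bitscore: float
    identity_pct: float
    coverage_pct: float


def _check_unique_ids(records: Sequence[ProteinRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.gene_id in seen:
            raise ValueError(f"duplicate gene id across input: {r.gene_id!r}")
        seen.add(r.gene_id)


def candidate_pairs(
    records: Sequence[ProteinRecord],
    min_shared_kmers: int,
    kmer_size: int = 4,
) -> Iterable[tuple[int, int]]:
    """Index pairs sharing at least ``min_shared_kmers`` distinct k-mers.

    Implemented as a sparse gene × k-mer incidence product, so the cost
    is governed by k-mer co-occurrence, not the quadratic pair count.
    """
    vocab: dict[str, int] = {}
    rows, cols = [], []
    for i, rec in enumerate(records):
        s = rec.sequence
        kmers = {s[j:j + kmer_size] for j in range(len(s) - kmer_size + 1)}
        for km in kmers:
            cols.append(vocab.setdefault(km, len(vocab)))
            rows.append(i)
    if not vocab:
        return
    m = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int32), (rows, cols)),
        shape=(len(records), len(vocab)),
    )
    shared = m @ m.T
    shared = sparse.triu(shared, k=1).tocoo()
    for i, j, c in zip(shared.row, shared.col, shared.data):
        if c >= min_shared_kmers:
            yield int(i), int(j)


def build_graph(
    proteomes: Proteomes,
    cutoffs: EdgeCutoffs = EdgeCutoffs(),
    scoring: ScoringScheme = DEFAULT_SCORING,
    prescreen_min_kmers: int | None = None,
    kmer_size: int = 4,
) -> list[SimilarityEdge]:
    """All-vs-all alignment, filtered to the retained edge list.

    With ``prescreen_min_kmers=None`` every distinct unordered pair is
    aligned (brute force, exact).  Self-hits are excluded; the edge list
    is sorted by (gene_a, gene_b).
    """
    records = list(iter_records(proteomes))
    if not records:
        return []
    _check_unique_ids(records)
    db_len = sum(len(r.sequence) for r in records)
    if prescreen_min_kmers is None:
        pairs: Iterable[tuple[int, int]] = itertools.combinations(range(len(records)), 2)
    else:
        pairs = candidate_pairs(records, prescreen_min_kmers, kmer_size)
    edges: list[SimilarityEdge] = []
    for i, j in pairs:
        ra, rb = records[i], records[j]
        res = align_local(ra.sequence, rb.sequence, scoring)
        if res.raw_score <= 0:
            continue
        evalue = estimate_evalue(
            res.bitscore, min(len(ra.sequence), len(rb.sequence)), db_len
        )
        if cutoffs.passes(res, evalue):
            a, b = sorted((ra.gene_id, rb.gene_id))
            edges.append(
                SimilarityEdge(a, b, evalue, res.bitscore, res.identity_pct, res.coverage_pct)
            )
    edges.sort(key=lambda e: (e.gene_a, e.gene_b))
    return edges


def edges_from_hit_table(
    hits: pd.DataFrame,
    seq_lengths: dict[str, int],
    cutoffs: EdgeCutoffs = EdgeCutoffs(),
) -> list[SimilarityEdge]:
    """Build the edge list from precomputed tabular hits (BLAST outfmt 6).

    For users with real data: accepts a 12-column table, keeps for each
    unordered pair the lower-E direction, applies the same cutoffs
    (coverage from alignment length over the shorter sequence).
    """
    missing = set(OUTFMT6_COLUMNS) - set(hits.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    best: dict[tuple[str, str], SimilarityEdge] = {}
    for row in hits.itertuples(index=False):
        q, s = str(row.qseqid), str(row.sseqid)
        if q == s:
            continue
        shorter = min(seq_lengths[q], seq_lengths[s])
        res = AlignmentResult(
            raw_score=0,
            bitscore=float(row.bitscore),
            identity_pct=float(row.pident),
            coverage_pct=100.0 * float(row.length) / shorter,
            aligned_length=int(row.length),
        )
        cut = cutoffs if cutoffs.score_type == "bit" else replace(cutoffs, score_type="bit")
        if not cut.passes(res, float(row.evalue)):
            continue
        a, b = sorted((q, s))
        edge = SimilarityEdge(
            a, b, float(row.evalue), res.bitscore, res.identity_pct, res.coverage_pct
        )
        prev = best.get((a, b))
        if prev is None or edge.evalue < prev.evalue:
            best[(a, b)] = edge
    return sorted(best.values(), key=lambda e: (e.gene_a, e.gene_b))


def write_edges(edges: Iterable[SimilarityEdge], path: str | Path) -> None:
    df = pd.DataFrame([e.__dict__ for e in edges])
    if df.empty:
        df = pd.DataFrame(
            columns=["gene_a", "gene_b", "evalue", "bitscore", "identity_pct", "coverage_pct"]
        )
    df.to_csv(path, sep="\t", index=False)


def read_edges(path: str | Path) -> list[SimilarityEdge]:
    df = pd.read_csv(path, sep="\t")
    return [
        SimilarityEdge(
            str(r.gene_a), str(r.gene_b), float(r.evalue), float(r.bitscore),
            float(r.identity_pct), float(r.coverage_pct),
        )
        for r in df.itertuples(index=False)
    ]
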