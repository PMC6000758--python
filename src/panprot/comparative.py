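"""Genus signatures, lineage-specific absences, GO losses, gains/losses.

Two complementary views of a genus panel against an outgroup panel:

* *signature* families — conserved across every ingroup genome with no
  acceptable similarity outside the genus: candidate genus markers;
* *lineage-specific absences* — families present across the outgroup
  but with zero ingroup members: evidence of gene loss in the genus,
  refined to the GO terms those families carry that no ingroup gene
  carries.

Per-strain gains and losses use presence-pattern set logic only: a
family is *gained* by a strain when all members belong to it, and *lost*
by a strain when it is present in exactly all other panel genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .align import DEFAULT_SCORING, ScoringScheme, align_local, estimate_evalue
from .graph import candidate_pairs
from .mcl import OrthologFamily
from .records import ProteinRecord, Proteomes, iter_records, split_go_terms


@dataclass(frozen=True)
class SignatureThresholds:
    """Cutoffs for the two-sided genus-signature filter.

    Default mode: a family is a signature iff every intra-family pair
    aligns at ≥ ``ingroup_min_identity_pct`` with E ≤
    ``ingroup_max_evalue``, and no member has an outgroup hit at ≥
    ``outgroup_max_identity_pct`` identity with E ≤
    ``outgroup_evalue_floor``.  With ``alt_mode`` the outgroup-hit
    acceptability test instead requires similarity > 20%, coverage >
    50% and E < 0.1 simultaneously.
    """

    ingroup_min_identity_pct: float = 60.0
    ingroup_max_evalue: float = 1e-30
    outgroup_max_identity_pct: float = 30.0
    outgroup_evalue_floor: float = 1e-1
    alt_mode: bool = False
    alt_min_similarity_pct: float = 20.0
    alt_min_coverage_pct: float = 50.0

    def __post_init__(self) -> None:
        if self.ingroup_min_identity_pct <= self.outgroup_max_identity_pct:
            raise ValueError(
                "ingroup_min_identity_pct must exceed outgroup_max_identity_pct"
            )
        if self.ingroup_max_evalue <= 0 or self.outgroup_evalue_floor <= 0:
            raise ValueError("E-value bounds must be positive")

    def outgroup_hit_acceptable(self, identity_pct: float, coverage_pct: float,
                                evalue: float) -> bool:
        """Does this outgroup alignment disqualify the family?"""
        if self.alt_mode:
            return (
                identity_pct > self.alt_min_similarity_pct
                and coverage_pct > self.alt_min_coverage_pct
                and evalue < self.outgroup_evalue_floor
            )
        return (
            identity_pct >= self.outgroup_max_identity_pct
            and evalue <= self.outgroup_evalue_floor
        )


@dataclass(frozen=True)
class AbsenceCall:
    """One family absent from the whole ingroup but present outside it."""

    family_id: str
    outgroup_prevalence: int
    outgroup_genomes: tuple[str, ...]
    lost_go_terms: tuple[str, ...] = ()


def detect_signature_families(
    core_families: Sequence[OrthologFamily],
    ingroup_proteomes: Proteomes,
    outgroup_proteomes: Proteomes,
    thresholds: SignatureThresholds = SignatureThresholds(),
    scoring: ScoringScheme = DEFAULT_SCORING,
    prescreen_min_kmers: int | None = 2,
) -> list[str]:
    """Genus-signature filter over the ingroup core.

    The E-value search space is the total residue count of both panels.
    Outgroup comparisons go through a shared-k-mer prescreen by default
    (a pair sharing no k-mers cannot reach the disqualifying identity
    and coverage levels in practice); pass ``prescreen_min_kmers=None``
    for exact all-pairs behaviour.
    """
    if not outgroup_proteomes:
        raise ValueError("outgroup panel must be non-empty")
    seqs = {r.gene_id: r.sequence for r in iter_records(ingroup_proteomes)}
    out_records = list(iter_records(outgroup_proteomes))
    db_len = sum(len(s) for s in seqs.values()) + sum(
        len(r.sequence) for r in out_records
    )

    # outgroup candidate pairs per ingroup gene (prescreen or all)
    member_ids = sorted(
        {g for fam in core_families for g in fam.members if g in seqs}
    )
    if prescreen_min_kmers is None:
        cand: dict[str, list[ProteinRecord]] = {
            g: out_records for g in member_ids
        }
    else:
        combined = [
            ProteinRecord(g, "", seqs[g]) for g in member_ids
        ] + out_records
        cand = {g: [] for g in member_ids}
        nin = len(member_ids)
        for i, j in candidate_pairs(combined, prescreen_min_kmers):
            if i < nin <= j:
                cand[member_ids[i]].append(out_records[j - nin])
            elif j < nin <= i:  # pragma: no cover - triu ordering
                cand[member_ids[j]].append(out_records[i - nin])

    signatures = []
    for fam in sorted(core_families, key=lambda f: f.family_id):
        members = [g for g in fam.members if g in seqs]
        if not members:
            continue
        ok = True
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                res = align_local(seqs[a], seqs[b], scoring)
                ev = estimate_evalue(
                    res.bitscore, min(len(seqs[a]), len(seqs[b])), db_len
                ) if res.raw_score > 0 else float("inf")
                if (
                    res.identity_pct < thresholds.ingroup_min_identity_pct
                    or ev > thresholds.ingroup_max_evalue
                ):
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        for g in members:
            for rec in cand[g]:
                res = align_local(seqs[g], rec.sequence, scoring)
                if res.raw_score <= 0:
                    continue
                ev = estimate_evalue(
                    res.bitscore, min(len(seqs[g]), len(rec.sequence)), db_len
                )
                if thresholds.outgroup_hit_acceptable(
                    res.identity_pct, res.coverage_pct, ev
                ):
                    ok = False
                    break
            if not ok:
                break
        if ok:
            signatures.append(fam.family_id)
    return signatures


def lineage_specific_absences(
    families: Sequence[OrthologFamily],
    ingroup_ids: Iterable[str],
    panel_ids: Iterable[str],
    min_outgroup_prevalence: int | None = None,
) -> list[AbsenceCall]:
    """Families with zero ingroup members and wide outgroup presence.

    *families* must come from a combined clustering over ingroup and
    outgroup panels.  By default a family must occur in every outgroup
    genome ("absent only in the ingroup", read strictly);
    ``min_outgroup_prevalence`` relaxes that down to 1.
    """
    ingroup = set(ingroup_ids)
    panel = set(panel_ids)
    if not ingroup <= panel:
        raise ValueError(f"ingroup ids not in panel: {sorted(ingroup - panel)}")
    outgroup = panel - ingroup
    need = len(outgroup) if min_outgroup_prevalence is None else min_outgroup_prevalence
    if need < 1:
        raise ValueError("min_outgroup_prevalence must be >= 1")
    calls = []
    for fam in sorted(families, key=lambda f: f.family_id):
        present = fam.genomes
        if present & ingroup:
            continue
        prev = len(present & outgroup)
        if prev >= need:
            calls.append(
                AbsenceCall(fam.family_id, prev, tuple(sorted(present & outgroup)))
            )
    return calls


def infer_lost_go_terms(
    absent_families: Sequence[OrthologFamily] | Sequence[str],
    families: Sequence[OrthologFamily],
    annotations: pd.DataFrame,
    ingroup_ids: Iterable[str],
) -> tuple[str, ...]:
    """GO terms on absent families that no ingroup gene carries.

    Literal term-set comparison (no ontology-ancestor propagation): a
    term is "lost" when it annotates ≥1 gene of an absent family and
    zero genes of any ingroup genome.
    """
    by_id = {f.family_id: f for f in families}
    fams = [
        by_id[f] if isinstance(f, str) else f for f in absent_families
    ]
    gene_go = {
        str(r.gene_id): split_go_terms(r.go_terms)
        for r in annotations.itertuples(index=False)
    }
    ingroup = set(ingroup_ids)
    ingroup_terms = {
        t
        for r in annotations.itertuples(index=False)
        if str(r.genome_id) in ingroup
        for t in split_go_terms(r.go_terms)
    }
    absent_terms = {
        t for fam in fams for g in fam.members for t in gene_go.get(g, ())
    }
    return tuple(sorted(absent_terms - ingroup_terms))


def strain_gained_families(
    families: Sequence[OrthologFamily],
    strain: str,
    panel_ids: Iterable[str],
) -> list[str]:
    """Families entirely private to *strain* (its singletons and LSEs)."""
    panel = set(panel_ids)
    if strain not in panel:
        raise ValueError(f"unknown strain: {strain!r}")
    return sorted(
        f.family_id for f in families if f.genomes == frozenset({strain})
    )


def strain_lost_families(
    families: Sequence[OrthologFamily],
    strain: str,
    panel_ids: Iterable[str],
) -> list[str]:
    """Dispensable families present in all panel genomes except *strain*."""
    panel = set(panel_ids)
    if len(panel) < 2:
        raise ValueError("panel must contain at least two genomes")
    if strain not in panel:
        raise ValueError(f"unknown strain: {strain!r}")
    rest = frozenset(panel - {strain})
    return sorted(f.family_id for f in families if f.genomes == rest)
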