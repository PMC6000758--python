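"""Synthetic multi-genome proteome sets with planted ground truth.

Every downstream stage of the pipeline (similarity graph, Markov
clustering, pan-genome partitioning, signature/absence detection,
secretome statistics, GC skew) is exercised on data from this module, so
each planted feature mirrors one analysis stage:

* **core** families — one member in every ingroup genome, plus a homolog
  in every outgroup genome (so that ordinary conserved families are not
  mistaken for genus signatures);
* **dispensable** families — members in ≥2 but not all ingroup genomes;
* **singletons** — one gene in exactly one genome, unrelated to
  everything else;
* **LSE** families — lineage-specific expansions: ≥2 paralogs, all in
  one genome;
* **signature** families — in every ingroup genome and no outgroup
  genome (genus markers);
* **outgroup-only** families — in every outgroup genome and no ingroup
  genome (material for lineage-specific-absence calls).

Protein evolution is substitution-only: each family descends from a
random ancestor, and each member is an independent mutant of it, so
pairwise identities are analytically predictable and families stay
separable from the between-family background.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._util import AMINO_ACIDS, check_protein
from .records import ProteinRecord, annotations_from_records, write_annotations, write_protein_fasta

SINGLETON = "SINGLETON"

#: MEROPS-like peptidase subfamily codes used for annotation labels.
PEPTIDASE_SUBFAMILIES = (
    "S8A", "S8B", "S9B", "S9C", "S10", "S41A", "S46",
    "M1", "M16B", "M19", "M28D", "M38", "C26", "A24A",
)

_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)


@dataclass(frozen=True)
class SynthConfig:
    """Design of one synthetic multi-genome panel.

    Defaults emulate a small genus panel — five ingroup genomes compared
    against a modest outgroup, a few hundred gene families, and ~10%
    within-family amino-acid divergence — sized so the whole pipeline
    runs in well under a minute.
    """

    n_ingroup_genomes: int = 5
    n_outgroup_genomes: int = 4
    n_core_families: int = 150
    n_dispensable_families: int = 60
    n_singletons_per_genome: int = 5
    n_lse_families: int = 5
    n_signature_families: int = 10
    n_outgroup_only_families: int = 30
    duplication_rate: float = 0.02
    within_family_divergence: float = 0.10
    cross_family_min_distance: float = 0.70
    signal_peptide_rate: float = 0.13
    peptidase_rate: float = 0.06
    tm_rate: float = 0.25
    go_terms_per_family: int = 2
    protein_length: int = 90
    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_ingroup_genomes, self.n_outgroup_genomes,
            self.n_core_families, self.n_dispensable_families,
            self.n_singletons_per_genome, self.n_lse_families,
            self.n_signature_families, self.n_outgroup_only_families,
            self.go_terms_per_family,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.n_ingroup_genomes < 1:
            raise ValueError("need at least one ingroup genome")
        rates = (
            self.duplication_rate, self.signal_peptide_rate,
            self.peptidase_rate, self.tm_rate,
        )
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("rates must lie in [0, 1]")
        if not 0.0 <= self.within_family_divergence < 1.0:
            raise ValueError("within_family_divergence must lie in [0, 1)")
        if not 0.0 < self.cross_family_min_distance <= 1.0:
            raise ValueError("cross_family_min_distance must lie in (0, 1]")
        if self.within_family_divergence >= self.cross_family_min_distance:
            raise ValueError(
                "within_family_divergence must be smaller than "
                "cross_family_min_distance (planted families must separate)"
            )
        if self.protein_length < 10:
            raise ValueError("protein_length must be >= 10")
        if self.n_dispensable_families and self.n_ingroup_genomes < 3:
            raise ValueError("dispensable families need >= 3 ingroup genomes")

    @property
    def ingroup_ids(self) -> tuple[str, ...]:
        return tuple(f"in{i + 1:02d}" for i in range(self.n_ingroup_genomes))

    @property
    def outgroup_ids(self) -> tuple[str, ...]:
        return tuple(f"out{i + 1:02d}" for i in range(self.n_outgroup_genomes))


@dataclass(frozen=True)
class FamilyTruth:
    family_id: str
    members: tuple[str, ...]
    presence: tuple[str, ...]           # genome ids containing >=1 member
    category: str                        # core/dispensable/lse/signature/outgroup_only
    is_signature: bool
    is_outgroup_only: bool
    go_terms: tuple[str, ...]


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside the synthetic data."""

    families: dict[str, FamilyTruth]
    gene_to_family: dict[str, str]       # SINGLETON for free-standing genes
    lost_go_terms: tuple[str, ...]       # GO terms attached only to outgroup-only families
    replichores: dict[str, tuple[int, int]] = field(default_factory=dict)

    def labels(self, gene_ids: list[str]) -> list[str]:
        """Cluster labels for the given genes (singletons get unique labels)."""
        out = []
        for g in gene_ids:
            fam = self.gene_to_family[g]
            out.append(f"single:{g}" if fam == SINGLETON else fam)
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "families": {
                fid: dataclasses.asdict(f) for fid, f in sorted(self.families.items())
            },
            "gene_to_family": dict(sorted(self.gene_to_family.items())),
            "lost_go_terms": list(self.lost_go_terms),
            "replichores": self.replichores,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def mutate_protein(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute each position independently with probability *divergence*.

    Substitutions always change the residue (drawn uniformly from the 19
    alternatives), so the expected fraction of differing positions equals
    *divergence* exactly; length is preserved (no indels).
    """
    check_protein(seq)
    if not 0.0 <= divergence < 1.0:
        raise ValueError("divergence must lie in [0, 1)")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < divergence
    n = int(hit.sum())
    if n:
        # draw from the 19 non-identical residues via a shifted index
        cur_idx = np.searchsorted(_AA, arr[hit])
        offs = rng.integers(1, 20, size=n)
        arr[hit] = _AA[(cur_idx + offs) % 20]
    return arr.tobytes().decode()


def _random_protein(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_AA, size=length).tobytes().decode()


def _positional_identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    xa = np.frombuffer(a[:n].encode(), dtype=np.uint8)
    xb = np.frombuffer(b[:n].encode(), dtype=np.uint8)
    return float((xa == xb).mean())


def _draw_ancestors(n: int, cfg: SynthConfig, rng: np.random.Generator) -> list[str]:
    """Random family ancestors, enforcing the separability floor.

    Each pair of ancestors must differ in at least
    ``cross_family_min_distance`` of aligned positions; offenders are
    resampled a bounded number of times before the design is declared
    infeasible.
    """
    max_ident = 1.0 - cfg.cross_family_min_distance
    ancestors: list[str] = []
    lengths = rng.integers(
        int(cfg.protein_length * 0.8), int(cfg.protein_length * 1.2) + 1, size=n
    )
    for L in lengths:
        for _attempt in range(50):
            cand = _random_protein(int(L), rng)
            if all(_positional_identity(cand, a) <= max_ident for a in ancestors):
                ancestors.append(cand)
                break
        else:
            raise ValueError(
                "infeasible design: cannot separate this many families at "
                f"cross_family_min_distance={cfg.cross_family_min_distance} "
                f"and protein_length={cfg.protein_length}"
            )
    return ancestors


def generate_pangenome(
    config: SynthConfig,
) -> tuple[dict[str, list[ProteinRecord]], pd.DataFrame, SyntheticTruth]:
    """Generate proteomes, the annotation table, and the planted truth.

    Deterministic for a fixed ``config.seed`` (one global RNG stream).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ingroup = list(config.ingroup_ids)
    outgroup = list(config.outgroup_ids)
    genomes = ingroup + outgroup
    proteomes: dict[str, list[ProteinRecord]] = {g: [] for g in genomes}
    counters = {g: 0 for g in genomes}
    families: dict[str, FamilyTruth] = {}
    gene_to_family: dict[str, str] = {}

    # family design: (category, presence genomes, n extra paralog slots)
    designs: list[tuple[str, str, list[str]]] = []
    fam_no = 0

    def new_fid() -> str:
        nonlocal fam_no
        fam_no += 1
        return f"FAM{fam_no:05d}"

    for _ in range(config.n_core_families):
        designs.append(("core", new_fid(), ingroup + outgroup))
    for _ in range(config.n_signature_families):
        designs.append(("signature", new_fid(), list(ingroup)))
    for _ in range(config.n_dispensable_families):
        k = int(rng.integers(2, config.n_ingroup_genomes))
        idx = rng.choice(config.n_ingroup_genomes, size=k, replace=False)
        designs.append(("dispensable", new_fid(), [ingroup[i] for i in sorted(idx)]))
    for _ in range(config.n_lse_families):
        g = ingroup[int(rng.integers(config.n_ingroup_genomes))]
        designs.append(("lse", new_fid(), [g]))
    for _ in range(config.n_outgroup_only_families):
        designs.append(("outgroup_only", new_fid(), list(outgroup)))

    n_singletons = config.n_singletons_per_genome * len(ingroup)
    ancestors = _draw_ancestors(len(designs) + n_singletons, config, rng)
    singleton_ancestors = ancestors[len(designs):]

    # GO vocabulary: a shared pool for ingroup-bearing families, plus one
    # private term per outgroup-only family (the plantable "lost" terms).
    shared_pool = [f"GO:{i:07d}" for i in range(1, 61)]
    lost_terms: list[str] = []
    next_private = 1000001

    # per-branch divergence: independent mutants of the ancestor at d/2 each
    # give expected pairwise substitution fraction ~ within_family_divergence
    # (1-(1-d/2)^2 - small back-substitution term ≈ d for small d).
    branch_div = config.within_family_divergence / 2.0

    for (category, fid, presence), ancestor in zip(designs, ancestors):
        signalp = bool(rng.random() < config.signal_peptide_rate)
        pept = (
            str(rng.choice(PEPTIDASE_SUBFAMILIES))
            if rng.random() < config.peptidase_rate
            else None
        )
        tm = bool(rng.random() < config.tm_rate)
        if category == "outgroup_only":
            private = f"GO:{next_private:07d}"
            next_private += 1
            lost_terms.append(private)
            extra = config.go_terms_per_family - 1
            picks = list(rng.choice(shared_pool, size=max(extra, 0), replace=False))
            go = tuple([private] + picks)
        else:
            go = tuple(
                rng.choice(shared_pool, size=config.go_terms_per_family, replace=False)
            ) if config.go_terms_per_family else ()

        members: list[str] = []
        for genome in presence:
            n_copies = 1
            if category == "lse":
                n_copies = 2 + int(rng.random() < 0.5)
            elif rng.random() < config.duplication_rate:
                n_copies = 2
            for _ in range(n_copies):
                counters[genome] += 1
                gid = f"{genome}|orf{counters[genome]:05d}"
                seq = mutate_protein(ancestor, branch_div, rng)
                proteomes[genome].append(
                    ProteinRecord(gid, genome, seq, signalp, tm, pept, go)
                )
                members.append(gid)
                gene_to_family[gid] = fid
        families[fid] = FamilyTruth(
            family_id=fid,
            members=tuple(members),
            presence=tuple(g for g in genomes if g in set(presence)),
            category=category,
            is_signature=category == "signature",
            is_outgroup_only=category == "outgroup_only",
            go_terms=go,
        )

    # free-standing singleton genes
    si = 0
    for genome in ingroup:
        for _ in range(config.n_singletons_per_genome):
            counters[genome] += 1
            gid = f"{genome}|orf{counters[genome]:05d}"
            signalp = bool(rng.random() < config.signal_peptide_rate)
            pept = (
                str(rng.choice(PEPTIDASE_SUBFAMILIES))
                if rng.random() < config.peptidase_rate
                else None
            )
            tm = bool(rng.random() < config.tm_rate)
            go = tuple(
                rng.choice(shared_pool, size=config.go_terms_per_family, replace=False)
            ) if config.go_terms_per_family else ()
            proteomes[genome].append(
                ProteinRecord(gid, genome, singleton_ancestors[si], signalp, tm, pept, go)
            )
            gene_to_family[gid] = SINGLETON
            si += 1

    annotations = annotations_from_records(proteomes)
    truth = SyntheticTruth(
        families=families,
        gene_to_family=gene_to_family,
        lost_go_terms=tuple(lost_terms),
    )
    return proteomes, annotations, truth


def generate_skewed_genome(
    length: int,
    origin: int,
    terminus: int,
    skew_strength: float,
    gc_content: float,
    seed: int,
) -> str:
    """Random circular chromosome with a planted replichore structure.

    The leading replichore (origin → terminus, walking rightwards with
    wrap-around) is G-enriched and the lagging one C-enriched: among G/C
    positions, the leading strand carries G with probability
    ``(1 + skew_strength) / 2``.  Overall G+C fraction ≈ *gc_content*.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    if not (0 <= origin < length and 0 <= terminus < length):
        raise ValueError("origin and terminus must lie in [0, length)")
    if origin == terminus:
        raise ValueError("origin and terminus must differ")
    if not 0.0 < skew_strength <= 1.0:
        raise ValueError("skew_strength must lie in (0, 1]")
    if not 0.0 < gc_content < 1.0:
        raise ValueError("gc_content must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    pos = np.arange(length)
    if origin < terminus:
        leading = (pos >= origin) & (pos < terminus)
    else:
        leading = (pos >= origin) | (pos < terminus)
    is_gc = rng.random(length) < gc_content
    p_g = np.where(leading, (1.0 + skew_strength) / 2.0, (1.0 - skew_strength) / 2.0)
    g = rng.random(length) < p_g
    at = rng.random(length) < 0.5
    arr = np.empty(length, dtype=np.uint8)
    arr[is_gc & g] = ord("G")
    arr[is_gc & ~g] = ord("C")
    arr[~is_gc & at] = ord("A")
    arr[~is_gc & ~at] = ord("T")
    return arr.tobytes().decode()


def write_pangenome(
    proteomes: Mapping[str, list[ProteinRecord]],
    annotations: pd.DataFrame,
    truth: SyntheticTruth,
    outdir: str | Path,
) -> None:
    """Write per-genome FASTA, the annotation TSV and the truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for genome in sorted(proteomes):
        write_protein_fasta(proteomes[genome], outdir / f"{genome}.faa")
    write_annotations(annotations, outdir / "annotations.tsv")
    truth.to_json(outdir / "truth.json")
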