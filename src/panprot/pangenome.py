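"""Core / dispensable / unique partitioning and redundancy statistics.

Definitions (matching standard pan-genome usage):

* **core** — families with ≥1 member in *every* panel genome (presence,
  not single-copy, so duplicated core families remain core);
* **dispensable** — families present in ≥2 but not all genomes;
* **LSE** (lineage-specific expansion) — families of ≥2 genes all from
  one genome;
* **singleton** — families of exactly one gene.

LSE and singletons together form the "unique" compartment (present in
only one genome).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from ._util import round_half_up
from .mcl import OrthologFamily


@dataclass(frozen=True)
class PangenomePartition:
    """The core/dispensable/unique decomposition of a family set."""

    genome_ids: tuple[str, ...]
    core: tuple[str, ...]
    dispensable: tuple[str, ...]
    lse: tuple[str, ...]
    singletons: tuple[str, ...]
    per_genome_unique: Mapping[str, int]   # Venn petals: LSE + singletons per genome

    @property
    def unique(self) -> tuple[str, ...]:
        return tuple(sorted(self.lse + self.singletons))

    @property
    def n_families(self) -> int:
        return len(self.core) + len(self.dispensable) + len(self.lse) + len(self.singletons)

    def counts(self) -> dict[str, int]:
        return {
            "core": len(self.core),
            "dispensable": len(self.dispensable),
            "unique": len(self.unique),
            "lse": len(self.lse),
            "singletons": len(self.singletons),
            "total": self.n_families,
        }


@dataclass(frozen=True)
class RedundancyStats:
    """Per-genome paralog redundancy."""

    genome_id: str
    n_paralog_families: int      # families with >=2 members in this genome
    n_genes_in_paralogs: int     # genes of this genome inside such families


def partition_families(
    families: Sequence[OrthologFamily],
    genome_ids: Sequence[str],
) -> PangenomePartition:
    """Classify families over the given genome panel."""
    panel = tuple(sorted(genome_ids))
    panel_set = set(panel)
    core, disp, lse, single = [], [], [], []
    petals = {g: 0 for g in panel}
    for fam in families:
        unknown = fam.genomes - panel_set
        if unknown:
            raise ValueError(
                f"family {fam.family_id} has members from unknown genome(s): "
                f"{sorted(unknown)}"
            )
        present = fam.genomes
        if fam.size == 1:
            single.append(fam.family_id)
            petals[next(iter(present))] += 1
        elif len(present) == 1:
            lse.append(fam.family_id)
            petals[next(iter(present))] += 1
        elif present == panel_set:
            core.append(fam.family_id)
        else:
            disp.append(fam.family_id)
    return PangenomePartition(
        genome_ids=panel,
        core=tuple(sorted(core)),
        dispensable=tuple(sorted(disp)),
        lse=tuple(sorted(lse)),
        singletons=tuple(sorted(single)),
        per_genome_unique=petals,
    )


def core_duplication_fraction(
    partition: PangenomePartition,
    families: Sequence[OrthologFamily],
) -> tuple[int, float | None]:
    """Core families carrying ≥2 copies in at least one genome.

    Returns (count, percentage of the core rounded half-up to 2
    decimals); the percentage is None when the core is empty.
    """
    by_id = {f.family_id: f for f in families}
    dup = [
        fid for fid in partition.core
        if any(c >= 2 for c in by_id[fid].genome_counts.values())
    ]
    if not partition.core:
        return 0, None
    pct = round_half_up(100.0 * len(dup) / len(partition.core), 2)
    return len(dup), pct


def paralog_stats(
    families: Sequence[OrthologFamily],
    genome: str,
) -> RedundancyStats:
    """Families with ≥2 members in *genome*, and the genes they hold there."""
    if not any(genome in f.genome_counts for f in families):
        raise ValueError(f"unknown genome id: {genome!r}")
    nfam = 0
    ngenes = 0
    for f in families:
        c = f.genome_counts.get(genome, 0)
        if c >= 2:
            nfam += 1
            ngenes += c
    return RedundancyStats(genome, nfam, ngenes)


def category_count_table(
    annotations: pd.DataFrame,
    category_column: str,
    unassigned: str = "unassigned",
) -> pd.DataFrame:
    """Per-genome × per-category contingency counts.

    Empty/missing category cells fall into the *unassigned* bucket.
    Used for COG-style category comparisons between genome groups.
    """
    if category_column not in annotations.columns:
        raise ValueError(f"category column {category_column!r} not in table")
    df = annotations[["genome_id", category_column]].copy()
    cat = df[category_column].astype(str).str.strip()
    cat = cat.where(~cat.isin(["", "nan", "None"]), unassigned)
    df[category_column] = cat
    return (
        df.groupby(["genome_id", category_column])
        .size()
        .unstack(fill_value=0)
        .sort_index()
    )


def write_partition(
    partition: PangenomePartition,
    families: Sequence[OrthologFamily],
    path: str | Path,
) -> None:
    cat = {}
    for name in ("core", "dispensable", "lse", "singletons"):
        for fid in getattr(partition, name):
            cat[fid] = name
    rows = [
        {"family_id": f.family_id, "category": cat[f.family_id], "size": f.size,
         "n_genomes": len(f.genomes)}
        for f in sorted(families, key=lambda f: f.family_id)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_venn_counts(partition: PangenomePartition, path: str | Path) -> None:
    payload = dict(partition.counts())
    payload["per_genome_unique"] = dict(partition.per_genome_unique)
    Path(path).write_text(json.dumps(payload, indent=1))
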