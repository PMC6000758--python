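"""Genome-summary and secretory-peptidase statistics.

A *secretory peptidase* is a gene carrying both a peptidase subfamily
code (MEROPS-style annotation) and a positive signal-peptide flag
("SignalP-fused peptidase").  All percentages and densities are rounded
half-up to two decimals to match printed report precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from ._util import round_half_up


@dataclass(frozen=True)
class GenomeSummary:
    genome_id: str
    genome_size_bp: int
    orf_count: int
    orf_total_length_bp: int
    pct_orf_length: float | None
    signalp_count: int
    pct_signalp: float | None
    tm_count: int
    pct_tm: float | None


@dataclass(frozen=True)
class SecretomeSummary:
    genome_id: str
    genome_size_bp: int
    total_peptidases: int
    secretory_peptidases: int
    density_per_mb: float           # secretory peptidases per Mb of genome
    n_subfamilies_total: int
    n_subfamilies_secretory: int
    pct_secretory_of_orfs: float | None


def _one_genome(annotations: pd.DataFrame, genome_id: str) -> pd.DataFrame:
    sub = annotations[annotations["genome_id"] == genome_id]
    if sub.empty:
        raise ValueError(f"no annotation rows for genome {genome_id!r}")
    return sub


def genome_summary(
    genome_id: str,
    genome_size_bp: int,
    annotations: pd.DataFrame,
    orf_total_length_bp: int | None = None,
) -> GenomeSummary:
    """Table-1-style per-genome statistics.

    ``orf_total_length_bp`` defaults to 3·(length_aa + 1) summed over
    genes (codons plus stop); pass the measured value when known.
    """
    sub = _one_genome(annotations, genome_id)
    orf_count = len(sub)
    if orf_total_length_bp is None:
        orf_total_length_bp = int(3 * (sub["length_aa"].astype(int) + 1).sum())
    signalp = int(sub["signalp"].astype(int).sum())
    tm = int(sub["tm"].astype(int).sum())
    pct = lambda num, den: round_half_up(100.0 * num / den, 2) if den else None
    return GenomeSummary(
        genome_id=genome_id,
        genome_size_bp=genome_size_bp,
        orf_count=orf_count,
        orf_total_length_bp=orf_total_length_bp,
        pct_orf_length=pct(orf_total_length_bp, genome_size_bp),
        signalp_count=signalp,
        pct_signalp=pct(signalp, orf_count),
        tm_count=tm,
        pct_tm=pct(tm, orf_count),
    )


def secretory_density(secretory_count: int, genome_size_bp: int) -> float:
    """Secretory peptidases per megabase, rounded half-up to 2 decimals."""
    if genome_size_bp <= 0:
        raise ValueError("genome size must be positive")
    return round_half_up(secretory_count / (genome_size_bp / 1e6), 2)


def secretome_summary(
    genome_id: str,
    genome_size_bp: int,
    annotations: pd.DataFrame,
) -> SecretomeSummary:
    """Table-2-style peptidase statistics for one genome."""
    sub = _one_genome(annotations, genome_id)
    pept = sub[sub["peptidase_subfamily"].astype(str).str.strip() != ""]
    sec = pept[pept["signalp"].astype(int) == 1]
    orf_count = len(sub)
    return SecretomeSummary(
        genome_id=genome_id,
        genome_size_bp=genome_size_bp,
        total_peptidases=len(pept),
        secretory_peptidases=len(sec),
        density_per_mb=secretory_density(len(sec), genome_size_bp),
        n_subfamilies_total=pept["peptidase_subfamily"].nunique(),
        n_subfamilies_secretory=sec["peptidase_subfamily"].nunique(),
        pct_secretory_of_orfs=(
            round_half_up(100.0 * len(sec) / orf_count, 2) if orf_count else None
        ),
    )


def summaries_frame(summaries: Sequence[GenomeSummary | SecretomeSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def group_compare(
    summaries: pd.DataFrame,
    group_labels: pd.Series | dict[str, str],
    columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-group min/max/mean of each numeric statistic.

    No hypothesis test is performed — the output is descriptive ranges
    for between-group comparison (e.g. ingroup vs outgroup densities).
    """
    df = summaries.copy()
    if isinstance(group_labels, dict):
        df["group"] = df["genome_id"].map(group_labels)
        if df["group"].isna().any():
            missing = df.loc[df["group"].isna(), "genome_id"].tolist()
            raise ValueError(f"genomes without group label: {missing}")
    else:
        df["group"] = list(group_labels)
    if df.groupby("group").size().min() < 1:  # pragma: no cover - defensive
        raise ValueError("every group needs at least one genome")
    if columns is None:
        columns = [
            c for c in df.columns
            if c not in ("genome_id", "group") and pd.api.types.is_numeric_dtype(df[c])
        ]
    return df.groupby("group")[list(columns)].agg(["min", "max", "mean"])


def write_summary_table(
    summaries: Sequence[GenomeSummary | SecretomeSummary], path: str | Path
) -> None:
    summaries_frame(summaries).to_csv(path, sep="\t", index=False)
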