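"""Protein records, annotation tables and the FASTA/TSV conventions.

A gene is identified as ``genome|gene`` in FASTA headers.  Per-gene
annotations (signal peptide, transmembrane helix, peptidase subfamily,
GO terms) travel in a flat table with one row per gene; they are inputs
produced by external predictors (SignalP, TMHMM, MEROPS batch BLAST,
GO annotation), never predicted here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ANNOTATION_COLUMNS = [
    "gene_id",
    "genome_id",
    "length_aa",
    "signalp",
    "tm",
    "peptidase_subfamily",
    "go_terms",
]


@dataclass(frozen=True)
class ProteinRecord:
    """One protein-coding gene."""

    gene_id: str
    genome_id: str
    sequence: str
    signal_peptide: bool = False
    tm: bool = False
    peptidase_subfamily: str | None = None
    go_terms: tuple[str, ...] = field(default_factory=tuple)


Proteomes = Mapping[str, list[ProteinRecord]]


def iter_records(proteomes: Proteomes) -> Iterable[ProteinRecord]:
    for genome in sorted(proteomes):
        yield from proteomes[genome]


def read_protein_fasta(path: str | Path, genome_id: str | None = None) -> list[ProteinRecord]:
    """Read one per-genome protein FASTA.

    Record ids of the form ``genome|gene`` carry the genome id; otherwise
    the genome id must be given (conventionally the file stem).
    """
    path = Path(path)
    out: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if "|" in rid:
            genome, _, _gene = rid.partition("|")
        elif genome_id is not None:
            genome = genome_id
        else:
            raise ValueError(
                f"{path}: record id {rid!r} has no 'genome|gene' form and no "
                "genome_id was given"
            )
        out.append(ProteinRecord(gene_id=rid, genome_id=genome, sequence=str(rec.seq)))
    return out


def write_protein_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(r.sequence), id=r.gene_id, description="")
        for r in records
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_proteomes(paths: Iterable[str | Path]) -> dict[str, list[ProteinRecord]]:
    """Read several per-genome FASTA files into a genome→records mapping."""
    proteomes: dict[str, list[ProteinRecord]] = {}
    for p in paths:
        p = Path(p)
        recs = read_protein_fasta(p, genome_id=p.stem)
        for r in recs:
            proteomes.setdefault(r.genome_id, []).append(r)
    return proteomes


def annotations_from_records(proteomes: Proteomes) -> pd.DataFrame:
    """Build the annotation table from in-memory records."""
    rows = [
        {
            "gene_id": r.gene_id,
            "genome_id": r.genome_id,
            "length_aa": len(r.sequence),
            "signalp": int(r.signal_peptide),
            "tm": int(r.tm),
            "peptidase_subfamily": r.peptidase_subfamily or "",
            "go_terms": ";".join(r.go_terms),
        }
        for r in iter_records(proteomes)
    ]
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"peptidase_subfamily": str, "go_terms": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    df["peptidase_subfamily"] = df["peptidase_subfamily"].fillna("")
    df["go_terms"] = df["go_terms"].fillna("")
    return df


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def split_go_terms(cell: str) -> tuple[str, ...]:
    """Parse a semicolon-separated GO cell ('' → no terms)."""
    return tuple(t for t in str(cell).split(";") if t)
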