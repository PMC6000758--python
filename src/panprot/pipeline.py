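"""End-to-end runs: the pan-genome analysis and the panel comparison.

Every stage reads and writes plain files (FASTA/TSV/JSON) so stages are
independently inspectable and re-runnable; a run manifest records the
configuration, seed and package version.  Two entry points:

* :func:`run_pangenome` — ingroup-only: similarity graph → MCL families
  → core/dispensable/unique partition → redundancy stats (+ per-genome
  summary when genome sizes are known);
* :func:`run_comparison` — ingroup + outgroup: genus signatures,
  lineage-specific absences with GO-loss inference, per-strain
  gains/losses, secretome statistics and GC-skew profiles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from . import comparative, pangenome, secretome
from .graph import EdgeCutoffs, build_graph, write_edges
from .gcskew import windowed_skew, write_skew_report
from .mcl import MCLParams, cluster_families, write_families, write_mcl_text
from .records import read_annotations, read_proteomes
from .comparative import SignatureThresholds

log = logging.getLogger("panprot")


@dataclass
class PipelineConfig:
    """Declarative run configuration (YAML-loadable; CLI flags override)."""

    ingroup: list[str] = field(default_factory=list)      # protein FASTA paths
    outgroup: list[str] = field(default_factory=list)
    annotations: str | None = None                        # annotation TSV
    nucleotide: list[str] = field(default_factory=list)   # genome FASTA (skew/sizes)
    outdir: str = "panprot_out"
    cutoffs: EdgeCutoffs = field(default_factory=EdgeCutoffs)
    mcl_params: MCLParams = field(default_factory=MCLParams)
    signature: SignatureThresholds = field(default_factory=SignatureThresholds)
    skew_window: int | None = None
    skew_step: int | None = None
    prescreen_min_kmers: int | None = 2
    min_outgroup_prevalence: int | None = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, typ in (
            ("cutoffs", EdgeCutoffs),
            ("mcl_params", MCLParams),
            ("signature", SignatureThresholds),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = typ(**raw[key])
        return cls(**raw)

    def validate(self, need_outgroup: bool = False) -> None:
        if not self.ingroup:
            raise ValueError("config must list at least one ingroup genome")
        if need_outgroup and not self.outgroup:
            raise ValueError("this analysis requires a non-empty outgroup panel")
        for p in [*self.ingroup, *self.outgroup, *self.nucleotide]:
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
        if self.annotations and not Path(self.annotations).exists():
            raise FileNotFoundError(f"annotation table not found: {self.annotations}")

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        try:
            d["panprot_version"] = _pkg_version("panprot")
        except Exception:  # pragma: no cover - not installed
            d["panprot_version"] = "unknown"
        return d


def _genome_sizes(config: PipelineConfig) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for p in config.nucleotide:
        p = Path(p)
        total = sum(len(rec.seq) for rec in SeqIO.parse(str(p), "fasta"))
        sizes[p.stem] = total
    return sizes


def _write_manifest(config: PipelineConfig, outdir: Path, extra: dict) -> None:
    manifest = config.to_manifest()
    manifest.update(extra)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))


def run_pangenome(config: PipelineConfig) -> dict:
    """Ingroup pan-genome analysis; returns in-memory results + paths."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("edge cutoffs: %s", config.cutoffs)
    log.info("MCL params: %s", config.mcl_params)

    proteomes = read_proteomes(config.ingroup)
    genome_ids = sorted(proteomes)
    edges = build_graph(
        proteomes, config.cutoffs, prescreen_min_kmers=config.prescreen_min_kmers
    )
    write_edges(edges, outdir / "edges.tsv")
    families = cluster_families(
        proteomes, config.cutoffs, config.mcl_params,
        prescreen_min_kmers=config.prescreen_min_kmers,
    )
    gene_genomes = {
        r.gene_id: r.genome_id for recs in proteomes.values() for r in recs
    }
    write_families(families, outdir / "families.tsv", gene_genomes)
    write_mcl_text(families, outdir / "families.mcl.txt")

    partition = pangenome.partition_families(families, genome_ids)
    pangenome.write_partition(partition, families, outdir / "partition.tsv")
    pangenome.write_venn_counts(partition, outdir / "venn.json")
    n_dup, dup_pct = pangenome.core_duplication_fraction(partition, families)

    redundancy = [pangenome.paralog_stats(families, g) for g in genome_ids]
    pd.DataFrame([r.__dict__ for r in redundancy]).to_csv(
        outdir / "redundancy.tsv", sep="\t", index=False
    )

    summaries = []
    sizes = _genome_sizes(config)
    if config.annotations and sizes:
        ann = read_annotations(config.annotations)
        for g in genome_ids:
            if g in sizes:
                summaries.append(secretome.genome_summary(g, sizes[g], ann))
        if summaries:
            secretome.write_summary_table(summaries, outdir / "genome_summary.tsv")

    _write_manifest(config, outdir, {"stage": "pangenome"})
    return {
        "outdir": outdir,
        "families": families,
        "partition": partition,
        "core_duplicated": n_dup,
        "core_duplicated_pct": dup_pct,
        "redundancy": redundancy,
        "genome_summaries": summaries,
        "edges": edges,
    }


def run_comparison(config: PipelineConfig) -> dict:
    """Combined ingroup+outgroup comparison; extends :func:`run_pangenome`."""
    config.validate(need_outgroup=True)
    base = run_pangenome(config)
    outdir = Path(config.outdir)

    in_prot = read_proteomes(config.ingroup)
    out_prot = read_proteomes(config.outgroup)
    ingroup_ids = sorted(in_prot)
    panel_ids = ingroup_ids + sorted(out_prot)

    partition = base["partition"]
    families = base["families"]
    by_id = {f.family_id: f for f in families}
    core_fams = [by_id[fid] for fid in partition.core]
    log.info("signature thresholds: %s", config.signature)
    signatures = comparative.detect_signature_families(
        core_fams, in_prot, out_prot, config.signature,
        prescreen_min_kmers=config.prescreen_min_kmers,
    )
    pd.DataFrame({"family_id": signatures}).to_csv(
        outdir / "signature_families.tsv", sep="\t", index=False
    )

    combined = dict(in_prot)
    combined.update(out_prot)
    combined_families = cluster_families(
        combined, config.cutoffs, config.mcl_params,
        prescreen_min_kmers=config.prescreen_min_kmers, family_prefix="CF",
    )
    gene_genomes = {
        r.gene_id: r.genome_id for recs in combined.values() for r in recs
    }
    write_families(combined_families, outdir / "combined_families.tsv", gene_genomes)
    absences = comparative.lineage_specific_absences(
        combined_families, ingroup_ids, panel_ids,
        min_outgroup_prevalence=config.min_outgroup_prevalence,
    )
    lost_terms: tuple[str, ...] = ()
    ann = read_annotations(config.annotations) if config.annotations else None
    if ann is not None:
        lost_terms = comparative.infer_lost_go_terms(
            [a.family_id for a in absences], combined_families, ann, ingroup_ids
        )
    pd.DataFrame(
        [
            {
                "family_id": a.family_id,
                "outgroup_prevalence": a.outgroup_prevalence,
                "outgroup_genomes": ";".join(a.outgroup_genomes),
            }
            for a in absences
        ]
    ).to_csv(outdir / "absences.tsv", sep="\t", index=False)
    pd.DataFrame({"go_term": list(lost_terms)}).to_csv(
        outdir / "lost_go_terms.tsv", sep="\t", index=False
    )

    gains = {
        g: comparative.strain_gained_families(families, g, ingroup_ids)
        for g in ingroup_ids
    }
    losses = {
        g: comparative.strain_lost_families(families, g, ingroup_ids)
        for g in ingroup_ids
    }
    pd.DataFrame(
        [
            {"strain": g, "direction": d, "family_id": fid}
            for g in ingroup_ids
            for d, fams in (("gained", gains[g]), ("lost", losses[g]))
            for fid in fams
        ],
        columns=["strain", "direction", "family_id"],
    ).to_csv(outdir / "gains_losses.tsv", sep="\t", index=False)

    sizes = _genome_sizes(config)
    secretome_summaries = []
    if ann is not None and sizes:
        for g in panel_ids:
            if g in sizes and (ann["genome_id"] == g).any():
                secretome_summaries.append(secretome.secretome_summary(g, sizes[g], ann))
        if secretome_summaries:
            secretome.write_summary_table(
                secretome_summaries, outdir / "secretome.tsv"
            )

    skews = {}
    for p in config.nucleotide:
        p = Path(p)
        seq = "".join(str(rec.seq) for rec in SeqIO.parse(str(p), "fasta"))
        profile = windowed_skew(seq, config.skew_window, config.skew_step)
        write_skew_report(
            profile, outdir / f"{p.stem}.skew.tsv", outdir / f"{p.stem}.skew.json"
        )
        skews[p.stem] = profile

    _write_manifest(config, outdir, {"stage": "comparison"})
    return {
        **base,
        "signatures": signatures,
        "combined_families": combined_families,
        "absences": absences,
        "lost_go_terms": lost_terms,
        "gains": gains,
        "losses": losses,
        "secretome_summaries": secretome_summaries,
        "skews": skews,
    }
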