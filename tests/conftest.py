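import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from panprot import SynthConfig, generate_pangenome
from panprot.mcl import cluster_families
from panprot.pangenome import partition_families


@pytest.fixture(scope="session")
def default_panel():
    """The default synthetic study design (5 ingroup + 4 outgroup genomes)."""
    cfg = SynthConfig()
    proteomes, annotations, truth = generate_pangenome(cfg)
    return {
        "config": cfg,
        "proteomes": proteomes,
        "annotations": annotations,
        "truth": truth,
        "ingroup": {g: v for g, v in proteomes.items() if g in cfg.ingroup_ids},
        "outgroup": {g: v for g, v in proteomes.items() if g in cfg.outgroup_ids},
    }


@pytest.fixture(scope="session")
def default_clustering(default_panel):
    """Ingroup and combined clusterings of the default panel (computed once)."""
    ing = default_panel["ingroup"]
    ingroup_families = cluster_families(ing, prescreen_min_kmers=2)
    combined_families = cluster_families(
        default_panel["proteomes"], prescreen_min_kmers=2, family_prefix="CF"
    )
    partition = partition_families(ingroup_families, sorted(ing))
    return {
        "ingroup_families": ingroup_families,
        "combined_families": combined_families,
        "partition": partition,
    }


@pytest.fixture()
def tiny_panel():
    """A minimal, fast panel: 3 ingroup + 2 outgroup genomes, 20 families."""
    cfg = SynthConfig(
        n_ingroup_genomes=3,
        n_outgroup_genomes=2,
        n_core_families=10,
        n_dispensable_families=4,
        n_singletons_per_genome=1,
        n_lse_families=1,
        n_signature_families=2,
        n_outgroup_only_families=3,
        protein_length=80,
        seed=11,
    )
    proteomes, annotations, truth = generate_pangenome(cfg)
    return cfg, proteomes, annotations, truth
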