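"""Synthetic-data generator: determinism, planted patterns, mutation model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panprot import SynthConfig, generate_pangenome, generate_skewed_genome, mutate_protein
from panprot._util import AMINO_ACIDS
from panprot.simulate import SINGLETON

protein = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=200)


class TestMutateProtein:
    def test_zero_divergence_is_identity(self):
        rng = np.random.default_rng(0)
        assert mutate_protein("MKVLAWGHE", 0.0, rng) == "MKVLAWGHE"

    def test_rejects_bad_residues_and_divergence(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            mutate_protein("MKX1", 0.1, rng)
        with pytest.raises(ValueError):
            mutate_protein("MKV", 1.0, rng)
        with pytest.raises(ValueError):
            mutate_protein("", 0.1, rng)

    def test_substitution_fraction_matches_divergence(self):
        # binomial check: mean observed substitution fraction over replicates
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list(AMINO_ACIDS), 1000))
        fracs = [
            np.mean([a != b for a, b in zip(seq, mutate_protein(seq, 0.2, rng))])
            for _ in range(100)
        ]
        assert abs(np.mean(fracs) - 0.2) < 0.02

    def test_pairwise_identity_of_two_mutants_matches_closed_form(self):
        # two independent mutants at divergence d agree per site with
        # probability (1-d)^2 + d^2/19 (substitutions are uniform over
        # the 19 alternatives)
        d = 0.2
        expected = (1 - d) ** 2 + d ** 2 / 19
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list(AMINO_ACIDS), 2000))
        obs = []
        for _ in range(50):
            m1 = mutate_protein(seq, d, rng)
            m2 = mutate_protein(seq, d, rng)
            obs.append(np.mean([a == b for a, b in zip(m1, m2)]))
        assert abs(np.mean(obs) - expected) < 0.01

    @settings(deadline=None, max_examples=25)
    @given(seq=protein, d=st.floats(0, 0.99), seed=st.integers(0, 2**16))
    def test_length_and_alphabet_preserved(self, seq, d, seed):
        out = mutate_protein(seq, d, np.random.default_rng(seed))
        assert len(out) == len(seq)
        assert set(out) <= set(AMINO_ACIDS)


class TestGeneratePangenome:
    def test_deterministic_for_fixed_seed(self):
        cfg = SynthConfig(n_core_families=8, n_dispensable_families=3, seed=5,
                          n_outgroup_only_families=2, protein_length=50)
        p1, a1, t1 = generate_pangenome(cfg)
        p2, a2, t2 = generate_pangenome(cfg)
        assert {g: [r.sequence for r in v] for g, v in p1.items()} == {
            g: [r.sequence for r in v] for g, v in p2.items()
        }
        assert a1.equals(a2)
        assert t1.gene_to_family == t2.gene_to_family

    def test_zero_divergence_core_only(self):
        cfg = SynthConfig(
            n_ingroup_genomes=3, n_outgroup_genomes=0, n_core_families=5,
            n_dispensable_families=0, n_singletons_per_genome=0,
            n_lse_families=0, n_signature_families=0,
            n_outgroup_only_families=0, duplication_rate=0.0,
            within_family_divergence=0.0, protein_length=40, seed=1,
        )
        proteomes, _, truth = generate_pangenome(cfg)
        assert len(truth.families) == 5
        for fam in truth.families.values():
            assert fam.category == "core"
            seqs = {
                r.sequence
                for recs in proteomes.values()
                for r in recs
                if r.gene_id in fam.members
            }
            assert len(seqs) == 1  # identical in all three genomes

    def test_planted_presence_patterns_realized(self, tiny_panel):
        cfg, proteomes, _, truth = tiny_panel
        gene_genome = {
            r.gene_id: g for g, recs in proteomes.items() for r in recs
        }
        ingroup, outgroup = set(cfg.ingroup_ids), set(cfg.outgroup_ids)
        for fam in truth.families.values():
            present = {gene_genome[m] for m in fam.members}
            assert present == set(fam.presence)
            if fam.category == "core":
                assert ingroup <= present
            elif fam.category == "dispensable":
                assert 2 <= len(present & ingroup) < len(ingroup)
                assert not present & outgroup
            elif fam.category == "lse":
                assert len(present) == 1 and len(fam.members) >= 2
            elif fam.category == "signature":
                assert present == ingroup
            elif fam.category == "outgroup_only":
                assert present <= outgroup and present

    def test_every_gene_appears_exactly_once(self, tiny_panel):
        _, proteomes, annotations, truth = tiny_panel
        all_ids = [r.gene_id for recs in proteomes.values() for r in recs]
        assert len(all_ids) == len(set(all_ids))
        assert set(all_ids) == set(truth.gene_to_family)
        assert set(annotations["gene_id"]) == set(all_ids)
        in_families = [m for f in truth.families.values() for m in f.members]
        assert len(in_families) == len(set(in_families))
        singles = [g for g, f in truth.gene_to_family.items() if f == SINGLETON]
        assert len(in_families) + len(singles) == len(all_ids)

    def test_infeasible_design_rejected(self):
        # far more families than a length-10 protein can keep separated
        cfg = SynthConfig(
            n_core_families=4000, protein_length=10,
            cross_family_min_distance=0.95, within_family_divergence=0.0,
        )
        with pytest.raises(ValueError, match="infeasible"):
            generate_pangenome(cfg)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(n_core_families=-1).validate()
        with pytest.raises(ValueError):
            SynthConfig(signal_peptide_rate=1.5).validate()
        with pytest.raises(ValueError):
            SynthConfig(
                within_family_divergence=0.8, cross_family_min_distance=0.7
            ).validate()


class TestGenerateSkewedGenome:
    def test_extreme_skew_pure_g_and_c(self):
        g = generate_skewed_genome(1000, 0, 500, 1.0, 0.999999, seed=0)
        lead, lag = g[:500], g[500:]
        assert set(lead) == {"G"} and set(lag) == {"C"}

    def test_gc_content_approximate(self):
        g = generate_skewed_genome(200_000, 0, 100_000, 0.3, 0.44, seed=3)
        gc = (g.count("G") + g.count("C")) / len(g)
        assert abs(gc - 0.44) < 0.01

    def test_wraparound_replichore(self):
        g = generate_skewed_genome(10_000, 8000, 3000, 1.0, 0.999999, seed=1)
        # leading replichore wraps: [8000, 10000) + [0, 3000)
        assert set(g[8000:] + g[:3000]) == {"G"}
        assert set(g[3000:8000]) == {"C"}

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            generate_skewed_genome(100, 5, 5, 0.5, 0.5, 0)
        with pytest.raises(ValueError):
            generate_skewed_genome(100, 0, 50, 0.0, 0.5, 0)
        with pytest.raises(ValueError):
            generate_skewed_genome(100, 200, 50, 0.5, 0.5, 0)
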