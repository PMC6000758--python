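"""Signature, absence, GO-loss and gain/loss set logic vs brute force."""

import itertools

import pandas as pd
import pytest

from panprot import (
    OrthologFamily,
    SignatureThresholds,
    detect_signature_families,
    infer_lost_go_terms,
    lineage_specific_absences,
    strain_gained_families,
    strain_lost_families,
)
from panprot.records import ProteinRecord

from oracles import all_presence_patterns

PANEL = ["g1", "g2", "g3", "g4", "g5"]


def fam_with_pattern(fid, genomes):
    members = tuple(f"{g}|{fid}" for g in sorted(genomes))
    return OrthologFamily(fid, members, {g: 1 for g in genomes})


class TestSignatureThresholds:
    def test_invariant_enforced(self):
        with pytest.raises(ValueError):
            SignatureThresholds(
                ingroup_min_identity_pct=20, outgroup_max_identity_pct=30
            )

    def test_default_mode_hit_logic(self):
        t = SignatureThresholds()
        assert t.outgroup_hit_acceptable(35.0, 10.0, 1e-3)
        assert not t.outgroup_hit_acceptable(25.0, 90.0, 1e-3)   # identity too low
        assert not t.outgroup_hit_acceptable(35.0, 90.0, 0.5)    # E too high

    def test_alt_mode_requires_all_three(self):
        t = SignatureThresholds(alt_mode=True)
        assert t.outgroup_hit_acceptable(25.0, 60.0, 1e-3)
        assert not t.outgroup_hit_acceptable(25.0, 40.0, 1e-3)   # coverage too low
        assert not t.outgroup_hit_acceptable(15.0, 60.0, 1e-3)   # similarity too low


class TestDetectSignatures:
    def test_planted_signatures_recovered(self, tiny_panel):
        from panprot.mcl import cluster_families
        from panprot.pangenome import partition_families

        cfg, proteomes, _, truth = tiny_panel
        ing = {g: proteomes[g] for g in cfg.ingroup_ids}
        outg = {g: proteomes[g] for g in cfg.outgroup_ids}
        fams = cluster_families(ing, prescreen_min_kmers=2)
        part = partition_families(fams, sorted(ing))
        by_id = {f.family_id: f for f in fams}
        core = [by_id[fid] for fid in part.core]
        sigs = detect_signature_families(core, ing, outg)
        planted = {
            frozenset(f.members) for f in truth.families.values() if f.is_signature
        }
        assert {frozenset(by_id[s].members) for s in sigs} == planted

    def test_outgroup_hit_disqualifies(self):
        # long enough that the intra-family pair passes E <= 1e-30
        seq = "MKVLAWGHEDRRAGEMKVLAWGHEDRRAGE" * 3
        ing = {
            "a": [ProteinRecord("a|1", "a", seq)],
            "b": [ProteinRecord("b|1", "b", seq)],
        }
        outg = {"o": [ProteinRecord("o|1", "o", seq)]}  # identical outgroup hit
        fam = OrthologFamily("F1", ("a|1", "b|1"), {"a": 1, "b": 1})
        assert detect_signature_families([fam], ing, outg) == []

    def test_unrelated_intra_pair_disqualifies(self):
        a = "MKVLAWGHEDRRAGEMKVLAWGHEDRRAGE" * 3
        c = "QNDKESTRFYIPCHMGAVLQNDKESTRFYI" * 3  # unrelated to a
        ing = {
            "a": [ProteinRecord("a|1", "a", a)],
            "b": [ProteinRecord("b|1", "b", c)],
        }
        outg = {"o": [ProteinRecord("o|1", "o", "WWWWWWFFFF" * 3)]}
        fam = OrthologFamily("F1", ("a|1", "b|1"), {"a": 1, "b": 1})
        assert detect_signature_families([fam], ing, outg) == []

    def test_growing_outgroup_shrinks_signature_set(self, tiny_panel):
        from panprot.mcl import cluster_families
        from panprot.pangenome import partition_families

        cfg, proteomes, _, _ = tiny_panel
        ing = {g: proteomes[g] for g in cfg.ingroup_ids}
        fams = cluster_families(ing, prescreen_min_kmers=2)
        part = partition_families(fams, sorted(ing))
        by_id = {f.family_id: f for f in fams}
        core = [by_id[fid] for fid in part.core]
        out_small = {cfg.outgroup_ids[0]: proteomes[cfg.outgroup_ids[0]]}
        out_big = {g: proteomes[g] for g in cfg.outgroup_ids}
        # grow the outgroup with an ingroup genome's own sequences: every
        # conserved family now has an outgroup-acceptable hit
        out_bigger = dict(out_big)
        out_bigger["extra"] = [
            ProteinRecord(f"extra|{r.gene_id.split('|')[1]}", "extra", r.sequence)
            for r in proteomes[cfg.ingroup_ids[0]]
        ]
        s_small = set(detect_signature_families(core, ing, out_small))
        s_big = set(detect_signature_families(core, ing, out_big))
        s_bigger = set(detect_signature_families(core, ing, out_bigger))
        assert s_bigger <= s_big <= s_small
        assert s_bigger == set()

    def test_empty_outgroup_rejected(self):
        with pytest.raises(ValueError):
            detect_signature_families([], {"a": []}, {})


class TestAbsences:
    def test_full_prevalence_returned_and_partial_not(self):
        fams = [
            fam_with_pattern("A", ["g4", "g5"]),       # all outgroup
            fam_with_pattern("B", ["g5"]),             # one outgroup genome
            fam_with_pattern("C", ["g1", "g4", "g5"]), # has ingroup member
        ]
        calls = lineage_specific_absences(fams, ["g1", "g2", "g3"], PANEL)
        assert [c.family_id for c in calls] == ["A"]
        calls1 = lineage_specific_absences(
            fams, ["g1", "g2", "g3"], PANEL, min_outgroup_prevalence=1
        )
        assert [c.family_id for c in calls1] == ["A", "B"]

    def test_single_ingroup_member_never_returned(self):
        fams = [fam_with_pattern("C", ["g1", "g4", "g5"])]
        assert lineage_specific_absences(fams, ["g1", "g2", "g3"], PANEL) == []

    def test_ingroup_not_in_panel_rejected(self):
        with pytest.raises(ValueError):
            lineage_specific_absences([], ["zz"], PANEL)

    def test_planted_outgroup_only_families_recovered(self, tiny_panel):
        from panprot.mcl import cluster_families

        cfg, proteomes, _, truth = tiny_panel
        combined = cluster_families(proteomes, prescreen_min_kmers=2)
        by_id = {f.family_id: f for f in combined}
        calls = lineage_specific_absences(
            combined, list(cfg.ingroup_ids), sorted(proteomes),
            min_outgroup_prevalence=1,
        )
        got = {frozenset(by_id[c.family_id].members) for c in calls}
        planted = {
            frozenset(f.members)
            for f in truth.families.values()
            if f.is_outgroup_only
        }
        assert got == planted


class TestLostGoTerms:
    def _ann(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "genome_id", "go_terms"]
        )

    def test_term_only_on_absent_family_is_lost(self):
        fams = [fam_with_pattern("A", ["g4"])]
        ann = self._ann(
            [["g4|A", "g4", "GO:1;GO:2"], ["g1|x", "g1", "GO:2"]]
        )
        lost = infer_lost_go_terms(["A"], fams, ann, ["g1", "g2", "g3"])
        assert lost == ("GO:1",)  # GO:2 survives in the ingroup

    def test_randomized_set_difference_oracle(self):
        import numpy as np

        rng = np.random.default_rng(5)
        terms = [f"GO:{i}" for i in range(12)]
        fams, rows = [], []
        absent_terms, ingroup_terms = set(), set()
        for k in range(15):
            genome = "g4" if k % 2 else "g1"
            fid = f"F{k}"
            fams.append(fam_with_pattern(fid, [genome]))
            picked = list(rng.choice(terms, 3, replace=False))
            rows.append([f"{genome}|{fid}", genome, ";".join(picked)])
            if genome == "g1":
                ingroup_terms.update(picked)
            else:
                absent_terms.update(picked)
        ann = self._ann(rows)
        absent_ids = [f.family_id for f in fams if "g4" in f.genome_counts]
        lost = infer_lost_go_terms(absent_ids, fams, ann, ["g1", "g2", "g3"])
        assert set(lost) == absent_terms - ingroup_terms


class TestGainLoss:
    def test_singleton_gained_by_its_strain_only(self):
        fams = [fam_with_pattern("A", ["g1"]), fam_with_pattern("B", ["g1", "g2"])]
        assert strain_gained_families(fams, "g1", PANEL) == ["A"]
        assert strain_gained_families(fams, "g2", PANEL) == []

    def test_gained_sets_disjoint_across_strains(self, tiny_panel):
        from panprot.mcl import cluster_families

        cfg, proteomes, _, _ = tiny_panel
        ing = {g: proteomes[g] for g in cfg.ingroup_ids}
        fams = cluster_families(ing, prescreen_min_kmers=2)
        gained = [
            set(strain_gained_families(fams, g, cfg.ingroup_ids))
            for g in cfg.ingroup_ids
        ]
        for s1, s2 in itertools.combinations(gained, 2):
            assert not s1 & s2

    def test_exhaustive_presence_patterns(self):
        """All 2^5−1 patterns against the brute-force definitions."""
        fams = [
            fam_with_pattern(f"P{i}", sorted(pattern))
            for i, pattern in enumerate(all_presence_patterns(PANEL))
        ]
        for strain in PANEL:
            lost = set(strain_lost_families(fams, strain, PANEL))
            gained = set(strain_gained_families(fams, strain, PANEL))
            expected_lost = {
                f.family_id
                for f in fams
                if set(f.genome_counts) == set(PANEL) - {strain}
            }
            expected_gained = {
                f.family_id for f in fams if set(f.genome_counts) == {strain}
            }
            assert lost == expected_lost
            assert gained == expected_gained
            # lost families are dispensable by construction
            for fid in lost:
                f = next(x for x in fams if x.family_id == fid)
                assert 2 <= len(f.genome_counts) < len(PANEL)

    def test_core_family_lost_by_none(self):
        fams = [fam_with_pattern("A", PANEL)]
        for strain in PANEL:
            assert strain_lost_families(fams, strain, PANEL) == []

    def test_unknown_strain_rejected(self):
        with pytest.raises(ValueError):
            strain_gained_families([], "zz", PANEL)
        with pytest.raises(ValueError):
            strain_lost_families([], "zz", PANEL)
        with pytest.raises(ValueError):
            strain_lost_families([], "g1", ["g1"])
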