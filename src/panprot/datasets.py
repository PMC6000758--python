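"""Published reference tables for the *Kangiella* genus panel.

Machine-readable copies of the printed per-genome summary (Table-1
style) and peptidase comparison (Table-2 style) tables from the
*Kangiella* comparative-genomics study, plus its headline ortholog
counts.  They serve as arithmetic-replay inputs: the package's own
summary functions recompute the printed percentages and densities from
the printed integer inputs.

Note: the printed secretory-peptidase density for *K. profundi* FT102
(20.40/Mb) is not consistent with the printed inputs (54 secretory
peptidases on 2,653,010 bp gives 20.35); see the methods note.
"""

from __future__ import annotations

import pandas as pd

#: Per-genome features of the five Kangiella strains.
KANGIELLA_GENOME_TABLE = pd.DataFrame(
    [
        # strain, genome_size_bp, pct_gc, orf_count, orf_total_length_bp,
        # signalp_count, tm_count, n_paralog_families, n_genes_in_paralogs
        ("K_aquimarina_DSM16071", 2686123, 43.72, 2446, 2438865, 317, 606, 130, 344),
        ("K_geojedonensis_KCTC23420", 2495242, 43.78, 2208, 2244783, 298, 533, 121, 296),
        ("K_koreensis_DSM16069", 2852073, 43.69, 2632, 2594526, 339, 701, 150, 396),
        ("K_profundi_FT102", 2653010, 43.81, 2484, 2382009, 305, 610, 142, 370),
        ("K_sediminilitoris_KCTC23892", 2496140, 43.40, 2308, 2250390, 283, 581, 133, 332),
    ],
    columns=[
        "genome_id", "genome_size_bp", "pct_gc", "orf_count",
        "orf_total_length_bp", "signalp_count", "tm_count",
        "n_paralog_families", "n_genes_in_paralogs",
    ],
)

#: Printed percentage rows of the same table (for replay comparison).
KANGIELLA_PRINTED_PERCENTAGES = pd.DataFrame(
    [
        ("K_aquimarina_DSM16071", 90.79, 12.96, 24.78),
        ("K_geojedonensis_KCTC23420", 89.96, 13.50, 24.14),
        ("K_koreensis_DSM16069", 90.97, 12.88, 26.63),
        ("K_profundi_FT102", 89.79, 12.28, 24.56),
        ("K_sediminilitoris_KCTC23892", 90.15, 12.26, 25.17),
    ],
    columns=["genome_id", "pct_orf_length", "pct_signalp", "pct_tm"],
)

#: Peptidase comparison across the 23 Oceanospirillales genomes.
#: ``density_consistent`` flags rows whose printed density matches the
#: printed count/size inputs at 2 decimals (K. profundi's does not).
PEPTIDASE_TABLE = pd.DataFrame(
    [
        ("K_aquimarina_DSM16071", "Kangiella", 142, 56, 20.85, 2686123, True),
        ("K_geojedonensis_KCTC23420", "Kangiella", 140, 50, 20.04, 2495242, True),
        ("K_koreensis_DSM16069", "Kangiella", 156, 62, 21.74, 2852073, True),
        ("K_profundi_FT102", "Kangiella", 142, 54, 20.40, 2653010, False),
        ("K_sediminilitoris_KCTC23892", "Kangiella", 142, 43, 17.23, 2496140, True),
        ("Alcanivorax_borkumensis_SK2", "other", 108, 20, 6.41, None, False),
        ("Alcanivorax_dieselolei_B5", "other", 151, 21, 4.26, None, False),
        ("Alcanivorax_pacificus_W11-5", "other", 121, 20, 4.80, None, False),
        ("Alcanivorax_sp_NBRC101098", "other", 107, 21, 6.78, None, False),
        ("Chromohalobacter_salexigens_DSM3043", "other", 123, 15, 4.06, None, False),
        ("Gynuella_sunshinyii_YC6258", "other", 156, 29, 4.48, None, False),
        ("Halomonas_campaniensis", "other", 133, 25, 3.46, None, False),
        ("Hahella_chejuensis_KCTC2396", "other", 219, 54, 13.25, None, False),
        ("Halomonas_elongata_DSM2581", "other", 122, 12, 2.95, None, False),
        ("Halomonas_huangheensis", "other", 147, 23, 4.83, None, False),
        ("Halomonas_sp_KO116", "other", 132, 21, 4.06, None, False),
        ("Halomonas_sp_R57-5", "other", 141, 20, 3.97, None, False),
        ("Marinomonas_mediterranea_MMB-1", "other", 120, 15, 3.20, None, False),
        ("Marinomonas_posidonica_IVIA-Po-181", "other", 111, 15, 3.85, None, False),
        ("Marinomonas_sp_MWYL1", "other", 122, 11, 2.16, None, False),
        ("Oleispira_antarctica_RB-8", "other", 119, 15, 3.40, None, False),
        ("Thalassolituus_oleivorans_MIL-1", "other", 117, 20, 5.10, None, False),
        ("Thalassolituus_oleivorans_R6-15", "other", 115, 22, 5.84, None, False),
    ],
    columns=[
        "genome_id", "group", "total_peptidases", "secretory_peptidases",
        "printed_density_per_mb", "genome_size_bp", "density_consistent",
    ],
)

#: Headline ortholog-family counts reported for the 5-genome panel.
REPORTED_FAMILY_COUNTS = {
    "core": 1708,
    "dispensable": 802,
    "unique": 1034,
    "lse": 10,
    "singletons": 1024,
    "total": 3544,
    "core_duplicated": 21,
    "core_duplicated_pct": 1.23,
}

#: Counts from the combined 23-genome comparison.
REPORTED_COMPARISON_COUNTS = {
    "combined_families": 23058,
    "genus_specific_absences": 96,
    "lost_go_terms": 31,
    "signature_families": 4,
}
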