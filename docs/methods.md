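# Methods

This note documents the models, conventions and numerical choices
behind `panprot`, what the synthetic benchmark does and does not show,
and known limitations.

## Similarity graph

BLASTP is replaced by exact Smith–Waterman with affine gaps, computed
by biotite's `align_optimal`. Scoring is BLOSUM62 with gap open 11 /
extend 1 in the BLAST convention (a length-g gap costs 11 + g; biotite's
native convention is shifted accordingly inside `align_local`).
Statistical significance uses Karlin–Altschul normalisation with the
standard gapped-BLOSUM62 constants λ = 0.267, K = 0.041:
S′ = (λS − ln K)/ln 2 and E = m·n·2^(−S′). The search space n is the
total residue count of the full input, fixed before any filtering, so
edge retention is independent of processing order; m is the shorter
sequence's length (the lower-E direction of the pair).

Conventions the underlying literature leaves open, all config-exposed:

* identity denominator = alignment length including gap columns;
* coverage = aligned residues of the shorter sequence / its length;
* the "score ≥ 40" retention cutoff is a **bit**score by default
  (`score_type="raw"` selects raw score);
* gap penalties are not specified by the upstream protocol; BLASTP
  defaults (11/1) are used.

An edge is retained only when identity ≥ 30 %, coverage ≥ 50 %,
E ≤ 1e-5 and score ≥ 40 hold simultaneously.

`build_graph` is exact (every unordered pair aligned) by default. The
pipeline enables a shared-k-mer prescreen (`prescreen_min_kmers=2`,
k = 4): a pair is aligned only if the two sequences share ≥2 distinct
4-mers. This is a heuristic whose assumption — sequences from different
families sit far below the 30 % identity cutoff, while related pairs
share many 4-mers — holds by construction for the synthetic generator
(see below) and for typical ortholog data at these thresholds; pairs
near the retention boundary could in principle be missed. Tests compare
the prescreened graph against the exact one. For real data with
precomputed BLAST results, `edges_from_hit_table` ingests 12-column
tabular (outfmt-6) hits instead.

## Markov clustering

Edges are weighted w = −log₁₀ E, capped at 300 when E underflows to
zero. Each node receives a self-loop equal to its maximum incident
weight (standard MCL practice; a unit-loop policy is selectable). The
column-stochastic matrix is iterated — expansion (matrix power 2), then
inflation (entrywise power 1.5 with column renormalisation), then
pruning of entries < 1e-5 — until the maximum entry change is < 1e-6 or
200 iterations (non-convergence warns and returns the current state).
Defaults for prune/tolerance/iteration count are package conventions,
exposed in `MCLParams`.

Because MCL never merges nodes across zero-weight cuts, the iteration
runs independently per connected component (exact, and much faster than
one global matrix). Readout: attractors are rows with positive
diagonal mass; attractors holding mass on each other share a cluster;
every other node joins the cluster of the attractors attracting it. A
node attracted by several clusters (e.g. the bridge of a barbell graph)
goes to the largest cluster, ties broken toward the cluster whose
smallest member gene id sorts first — a deterministic convention.
Matrix construction uses lexicographic gene ordering, so clustering is
bit-reproducible. The inter-species edge-weight normalisation of the
full OrthoMCL schema is **not** reproduced (its details are not part of
the protocol this package follows); the weight function is pluggable.

## Pan-genome partition

*Core* requires presence (≥1 member) in every panel genome —
duplicated core families remain core. *Dispensable*: present in ≥2 but
not all. *LSE*: ≥2 members, all in one genome. *Singleton*: exactly
one member. These four classes are a disjoint cover; "unique" = LSE +
singletons, reported per genome as Venn petals. Percentages (core
duplication fraction, summary-table percentages, densities) are rounded
half-up to two decimals, matching printed-table precision.

## Signature and absence calls

The two-sided signature filter has two published variants and both are
implemented. The default (the one under which the reported four
*Kangiella* signature families were obtained) disqualifies a family
when any member has an outgroup hit with identity ≥ 30 % and E ≤ 0.1;
the alternative (`alt_mode`) reads the acceptability test as
similarity > 20 % **and** coverage > 50 % **and** E < 0.1. The original
outgroup was the nr database minus the genus; this package substitutes
a user-supplied outgroup panel — nr-scale search is out of scope, and E
thresholds are therefore relative to a much smaller search space. A
consequence visible in the synthetic benchmark: a chance local
alignment between unrelated sequences occasionally clears E ≤ 0.1 at
≥30 % identity and disqualifies a planted signature family, so signature
recovery is typically, not always, exact (observed ≥ 9/10 across seeds).

Lineage-specific absences default to requiring presence in **all**
outgroup genomes ("absent only in the ingroup", read strictly);
`min_outgroup_prevalence` relaxes this, since the published criterion
does not state the required outgroup prevalence. GO-loss inference
compares literal term sets (a term on an absent family and on zero
ingroup genes) with no ontology-ancestor propagation — the published
procedure does not state any.

Gains/losses are pure presence-pattern logic; "lost by strain X" means
present in exactly the other n−1 panel genomes, which makes lost
families dispensable by construction.

## Secretome statistics

A *secretory peptidase* is a gene with both a MEROPS-style subfamily
code and a positive signal-peptide flag. Both flags are **inputs**
(produced upstream by SignalP/MEROPS-like annotation); the package
never predicts them. Density = secretory peptidases / (genome size in
Mb), rounded half-up to 2 decimals. `group_compare` reports per-group
min/max/mean only — no hypothesis test is attached, because the
published comparison asserts significance without naming a test and
inventing one here would overstate the method.

Two printed-table inconsistencies are handled explicitly: the
*K. profundi* FT102 density row (20.40/Mb) cannot be reproduced from
the printed inputs (54 secretory peptidases on 2,653,010 bp → 20.35)
and is flagged `density_consistent=False` in
`panprot.datasets.PEPTIDASE_TABLE`, excluded from replay checks; and
the printed lower bound of the secretory-percentage range (1.68 %)
cannot be reconstructed from any printed numerator/denominator pair, so
no replay is attempted for it.

## GC skew

skew_i = (G_i − C_i)/(G_i + C_i) per window, defined 0 when a window
contains no G or C; N bases are excluded from numerator and
denominator. Windows wrap circularly; default window = sequence
length/1000 (minimum 100 bp) with step = window (non-overlapping) — a
declared convention, since the original web tool's auto-windowing is
undocumented. Coordinates are 0-based window midpoints. The cumulative
skew's argmin sits near the replication origin and argmax near the
terminus when the leading replichore is G-enriched; ties break to the
smallest index.

## Synthetic data generator

The generator emulates the study design: an ingroup genus panel
(default 5 genomes) against an outgroup panel (default 4), with planted
family categories exercising each analysis stage — 150 core (homologs
in every genome, so conserved families are not mistaken for
signatures), 10 signature (every ingroup, no outgroup genome), 60
dispensable (≥2 but not all ingroup genomes; ingroup-only, the minimal
design for partition and loss logic), 5 LSE, 25 singletons, 30
outgroup-only (in every outgroup genome — material for absence calls,
each carrying one private GO term that becomes a plantable "lost"
pathway). ~280 families and ~1.7k genes total.

Protein evolution is substitution-only (no indels): each family member
is an independent mutant of a random ancestor at divergence d/2 per
branch, giving expected pairwise identity (1−d/2)² + (d/2)²/19 ≈ 1−d
(≈90 % at the default d = 0.1). Family ancestors are drawn i.i.d. over
the 20-letter alphabet and re-drawn until every ancestor pair differs in
≥ `cross_family_min_distance` (default 0.7) of aligned positions; a
design that cannot be separated this way at the chosen protein length
(default 90 aa, ±20 %) is rejected as infeasible. This guarantees the
separability invariant: between-family identity ≪ 30 % cutoff ≪
within-family identity (~90 %).

Annotations (signal peptide, TM, peptidase subfamily, GO terms) are
drawn per family at the configured rates, mirroring the use of external
predictor output as input. Gene duplications are planted per
family-genome occurrence at `duplication_rate` (LSE families always get
2–3 copies). Nucleotide genomes plant a replichore structure: among
G/C positions the leading strand carries G with probability
(1+s)/2.

What passing tests show — and don't. Recovery of the planted structure
demonstrates that the graph–MCL–set-logic machinery implements its
definitions correctly and is well-conditioned at realistic divergence.
It does **not** demonstrate robustness to features real proteomes have
and the generator lacks: indels and length variation within families,
domain shuffling and promiscuous domains (the main cause of MCL
over-merging in practice), horizontal transfer, fragmented gene models,
or divergence gradients near the retention cutoffs. Headline counts of
the original study (1,708 core; 96 genus-specific absences; 4
signature families) depend on the real genomes and an nr-scale outgroup
and are not reproducible at this scale; the package instead replays the
printed tables' arithmetic exactly and validates the machinery on
planted truth.

## Problem sizes and determinism

Default benchmark sizes (≈1.7k genes, ≈280 families, 100 kb skew
genomes) were chosen so the full pipeline runs in seconds on one CPU
while keeping every category populated well above counting noise. All
randomness flows from a single seeded NumPy generator per run; fixed
seed ⇒ byte-identical FASTA, tables and reports (the run manifest
records config, seed and package version).

## Known limitations

* No BLAST-heuristic parity: scores are exact SW, so E-values differ
  from BLAST's (composition-based statistics are not implemented).
* The MCL implementation is dense per connected component — suitable
  for panels of tens of genomes, not thousands.
* GO terms are compared literally; no ontology graph closure.
* `group_compare` is descriptive only.
* Signature detection aligns family members against the full outgroup
  panel; with the default prescreen, outgroup hits sharing fewer than
  two 4-mers are not examined (negligible at the default thresholds,
  see above).
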