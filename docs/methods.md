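# Methods

This note documents the models and procedures behind each `ferroscan`
stage, the parameters that matter, what the synthetic-data generator does
and does not emulate, and the numerical choices made where the design was
genuinely open.

## Heme-motif census

A *c*-type cytochrome binds heme covalently at a CXXCH motif; the spaced
variants CX₃CH and CX₄CH occur in some multiheme proteins. The scanner
matches all three classes with literal C/C/H anchors; wildcard positions
accept any alphabetic character (ambiguity codes included) but never `*`,
so a motif cannot span an internal stop codon. Terminal `*` are stripped
at ingest; internal ones are kept precisely because they should break
motif matching.

**Overlap policy.** Nested and overlapping matches are collapsed by a
leftmost-start greedy rule with a shortest-span tie-break at equal start;
scanning resumes immediately after each accepted hit. Rationale: two heme
attachments cannot share a cysteine, so overlapping candidates describe at
most one heme. The policy is configurable (`overlap="allow"` reports every
match) because the behavior of heme-counting scripts in the literature is
not standardized. Correctness is anchored to an independent
enumerate-then-greedy oracle (regex lookahead enumeration + sorted sweep)
that the scanner must match exactly on large random samples.

Per-protein totals are binned with edges `(1, 2, 3, 4, 10)` giving
categories 1 / 2 / 3 / 4–9 / 10+; proteins with ≥ 3 total motifs are
counted as multiheme cytochromes (`min_mhc`, configurable). The
group-contrast statistic is the ratio of mean per-genome counts of
motif-bearing proteins between two genome sets.

## Homolog clustering

All motif-bearing proteins are compared all-vs-all with Smith–Waterman
local alignment (BLOSUM62, gap open 11 / extend 1, via
Bio.Align.PairwiseAligner). Identity is computed over aligned columns
(gap columns included in the denominator); coverage is the aligned span
divided by each sequence's full length. An edge requires coverage ≥ 0.8 on
**both** sequences and identity ≥ 30%. The identity floor is this
package's own guard against low-complexity edges; setting `min_id=0`
reproduces a pure-coverage mode.

Clustering is iterative greedy set cover: the unassigned node with the
most unassigned neighbors becomes a centroid and absorbs them; ties break
to the longer sequence, then the lexicographically smaller id, making the
partition deterministic. This replaces cascaded prefilter-based clustering
tools with an exact implementation of the same contract at desk scale
(thousands, not hundreds of thousands, of sequences).

Two pragmatic accelerations, both conservative and configurable: pairs
whose length ratio already forbids bidirectional coverage are skipped, and
pairs sharing fewer than 4 distinct amino-acid 4-mers are not aligned
(unrelated random proteins share ~0.4 on average; homologs at the identity
levels the thresholds accept share dozens). Sequences shorter than 40
residues are always aligned.

**Classification.** A cluster containing a catalog (isolate
representative) sequence inherits its role label. Otherwise each member is
searched against the catalog (identity ≥ 35%, coverage ≥ 0.7 both ways)
and the majority best-hit label wins (`consensus`); ties give
`ambiguous`, no qualifying hits `unclassified`. Pangenome bins follow the
prevalence rules: near-core (> 85% of genomes), strain-specific (exactly
one genome), accessory otherwise.

## Complex synteny calling

A complex definition lists subunit roles with optional heme-count ranges
(Cyc2 exactly 1; MtoA and MtrC exactly 10; PCC3 periplasmic ≥ 20,
extracellular 10–35; UetA 4, UetJ 11–12, UetD/E/G 3 each; Slit_1323 1,
Slit_1324 2). Porins and other non-cytochrome subunits are matched by
sequence similarity only — no transmembrane or localization prediction.
Role candidates must pass identity ≥ 30% / coverage ≥ 0.7 against a role
reference *and* the heme constraint.

The caller anchors on the first required heme-constrained role. A complex
is **complete** when, for some anchor candidate, every required role has a
candidate on the same contig within a window of 15 gene ranks; among
satisfying anchors the smallest span wins, then the lowest anchor rank. A
duplicated variant-flagged role (second PCC3 periplasmic cytochrome)
upgrades the call to **complete-variant**. If at least one required role
is present anywhere but colocalization fails, the verdict is **partial**;
with no required-role hits, **absent**. The 15-rank window is this
package's choice: the largest shipped operon (Uet, 9 genes) fits with
margin, and the value is configurable per complex. The UetC porin is
optional because it is absent from a substantial fraction of otherwise
complete Uet loci.

Strand is recorded but ignored — no strand rule is imposed on operon
membership. Definitions ship as editable YAML
(`src/ferroscan/data/complexes.yaml`).

## Marker profiling

Each marker is a set of subunit roles (operon tokens such as narGH,
nxrAB, lutABCP). Detection is reference-based homology (identity ≥ 30%,
coverage ≥ 0.7), replacing HMM engines so the package runs without
external databases; catalog entries may carry heme expectations (the cyc2
call additionally requires exactly one motif). A marker is present when
the fraction of subunits with ≥ 1 qualifying hit reaches the marker's
rule — default 1.0 (all subunits), with per-marker overrides (lutABCP at
0.75). Group percents are `100 × carriers / group size`. Derived flags
combine columns: either/both iron oxidase, and denitrification-to-N₂O
(a nitrate reductase AND a nitrite reductase AND nitric-oxide reductase);
full denitrification additionally requires nosZ.

## Genome similarity

- **AAI** = mean identity over reciprocal best protein hits (identity
  ≥ 30%, coverage ≥ 0.7 both ways). Pairs with < 10 reciprocal hits are
  flagged low-support. Zero reciprocal pairs yields an explicit
  "undefined" result, not an exception. The computation is run in a
  canonical genome order so the matrix is exactly symmetric.
- **ANI** (gene-based) = mean nucleotide identity over bidirectional best
  gene hits (identity ≥ 70%, length ratio ≥ 0.7), with identity =
  matches / alignment columns from edlib global alignment. rRNA/tRNA-
  tagged genes are excluded by default because their conservation inflates
  the estimate; the flag exists to demonstrate the effect.
- **16S identity** is computed only for near-full-length sequences
  (≥ 1,450 nt), under global alignment with terminal gaps excluded.

No genus/species thresholds are applied to any of these metrics.

## Phylogeny

Thirteen ribosomal proteins are extracted per genome as the best catalog
hit at identity ≥ 40% / coverage ≥ 0.7. Markers present in fewer than
~89.5% of genomes are dropped (logged); genomes missing a retained marker
are gap-padded after masking.

Per-marker alignment is progressive: 3-mer distance matrix → UPGMA guide
tree (scipy average linkage) → profile–profile global alignment with
affine gaps (open 11 / extend 1) on BLOSUM62 column-frequency scores.
Sequences are canonically sorted before the guide tree is built, so the
result is invariant to input order; traceback tie-breaks are fixed
(match > gap-in-second > gap-in-first). mafft is used in the test suite
as an independent cross-check of alignment quality, never as the
implementation.

Masking drops columns with gap fraction strictly greater than 0.70 (a
column at exactly 0.70 is retained), then an automated end trim peels
leading/trailing columns with gap fraction > 0.5 — an automation of the
manual end trimming common in concatenation workflows; both thresholds are
parameters. Masking is idempotent.

Distances ignore columns gapped in either row; the Poisson correction
d = −ln(1 − p) is applied by default (p-distance available). Saturated
pairs (p ≥ 1) and pairs with no shared columns are set to a documented cap
of 10 substitutions/site with a warning. Trees come from neighbor-joining
(scikit-bio), which is exact on additive matrices — the anchor for
correctness tests. Bootstrap supports come from column resampling with a
seeded generator; replicate bipartitions are matched to the full-data tree
(canonicalized splits), supports written as internal node labels. Trees
are emitted unrooted; an optional outgroup re-roots the output.
Maximum-likelihood inference is deliberately out of scope: the target
here is clade recovery on cohort-scale data, for which distance methods
with bootstrap are sufficient and orders of magnitude faster.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:

- **Four clades** — three FeOB-analog groups (Gallionella-, Sideroxydans-,
  Ferriphaselus-like) and one NOB analog (Nitrotoga-like) — on a fixed
  tree `(((G,S),F),N)` with internal branches shared, so clades are
  recoverable by tree reconstruction. Default branch lengths give
  root-to-tip divergence ≈ 0.17 substitutions/site (scalable); tips add
  0.03 within-group.
- **Gene families** evolve down the tree by per-site substitution, uniform
  over a 18-letter alphabet that excludes C and H; planted motif anchors
  (C…CH) are protected from mutation. Consequence: planted heme counts
  are *exact* truth — mutation can neither destroy nor create a motif —
  which makes motif-recovery tests exact rather than statistical. Planted
  motifs are spaced generously (≥ 6 residues apart) so that two unrelated
  multiheme families do not become spuriously similar through their shared
  periodic anchor scaffold.
- **Markers and complexes** are planted per-group by Bernoulli prevalence
  draws echoing the observed contrasts (cyc2 0.83 in FeOB groups and 0 in
  NOB; nxrAB 0.85 in NOB only; PCC3 biased to the Sideroxydans analog at
  0.59 vs 0.12; Uet exclusive to the Gallionella analog; nosZ 0
  everywhere). A planted complex draws its architecture from a verdict
  mixture (complete / partial with one required subunit dropped /
  two-periplasmic variant for PCC3, roughly 0.60/0.27/0.13; the UetC porin
  is included with probability 2/3 without affecting completeness) and is
  placed as an adjacent CDS run.
- **The FeOB:NOB ratio** of motif-bearing proteins per genome is a planted
  parameter (default 1.5). Complex placements already contribute motif
  genes, so the generator computes the expected complex-derived count per
  group analytically and draws the remaining filler MHC count from a
  Poisson with the complementary mean — the per-genome expectation is the
  target exactly (15 vs 10 at defaults). Filler families carry heme counts
  from the palette (1, 2, 3, 4, 10, 11, 21, 27, 35); the NOB pool is
  restricted to ≤ 4 hemes, so only FeOB-analog genomes carry 10+-heme
  proteins.
- **Nucleotide genes** are reverse-translated with a fixed codon table (so
  nucleotide divergence tracks protein divergence); each genome also gets
  an evolved 16S (at 10% of the protein rate) and a conserved tRNA, both
  type-tagged for the ANI exclusion. A separate divergence-ladder helper
  emits genomes at exact nucleotide/protein divergences (0–30%) for metric
  decay tests.
- The reference catalog is the set of ancestral (root) family sequences
  with role labels and heme expectations — the synthetic stand-in for an
  isolate-derived reference set.

Not emulated, hence untested on synthetic data: indels and alignment
ambiguity within families (planted families are colinear), recombination
and HGT, composition bias (no C/H outside motifs), contamination or
fragmented assemblies (completeness/contamination are metadata only), and
rate heterogeneity across sites. Passing tests therefore demonstrate the
pipeline's logic and thresholds, not robustness to assembly artifacts or
deep-time alignment error.

Determinism: every stochastic step flows from one integer-seeded
generator; identical configs produce byte-identical cohorts and the
pipeline reruns reproduce identical artifacts.

## Problem sizes used in validation

The shipped tests and the acceptance script run on cohorts of 8–80
genomes (2–20 per group) with ~60–110 genes per genome, 200-replicate
bootstraps, and 5,000–10,000 random sequences for the scanner/oracle
comparison — sizes chosen so the full suite completes in a few minutes on
one CPU while keeping every estimate's sampling error well inside its
test tolerance. The heme-ratio tolerance (±0.374 around the planted 1.5)
is 3 standard deviations of the estimator measured over 100 repeat
simulations at n = 20 genomes/group.

## Known limitations

- Reference-based detection cannot find families absent from the catalog;
  on real data the catalog must carry isolate-verified representatives
  per role (the synthetic catalog is generated, and labelled as such).
- Coverage thresholds use local-alignment span; heavily fragmented genes
  (split CDS) will under-cover and be missed.
- The greedy set-cover partition is contract-equivalent to, but not
  identical with, cascaded clustering tools; cluster granularity near the
  coverage threshold can differ.
- `partial` complex verdicts require only same-genome presence of ≥ 1
  required role; they do not distinguish "scattered but present" from
  "mostly missing".
- NJ + bootstrap recovers clades under the simulator's conditions; deep
  or rate-heterogeneous phylogenies warrant ML inference outside this
  package.
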