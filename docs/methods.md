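# Methods

This note documents the models, rules and numerical choices behind
`domarch`, and what the synthetic cohorts do and do not establish about
real genome surveys.

## Hit filtering and the two-pass design

The pipeline assumes the classical two-pass survey layout. A *search* pass
runs PDZ profile HMMs (Pfam families PDZ/PF00595, PDZ_1/PF13180,
PDZ_2/PF12812 and the Superfamily PDZ superfamily 50156) against whole
proteomes and selects candidate proteins; a *scan* pass annotates the
candidates against the complete domain databases. Inclusion is by two
inclusive E-value thresholds per pass: full-sequence ≤ 0.01 with per-hit
(independent) E-value ≤ 0.03 for search, and 0.01/0.01 for scan. Running
HMMER or Phobius themselves is out of scope — the package consumes their
tabular output formats. Superfamily assignment rows carry a single
E-value; it is stored in both threshold slots so one policy applies
uniformly.

Coordinates are 1-based inclusive throughout (the HMMER and PTT
convention). Domain extent is taken from the `domtblout` *envelope*
columns rather than the alignment columns: the envelope is HMMER's stated
region for the domain's location, and the wider extent makes overlap
resolution conservative. Parsing is total — every row yields either a
record or an error naming the file and line; there are no silent drops.

## Cross-database merging

Pfam is the reference classification and Superfamily the cross-check. A
Superfamily hit overlapping a Pfam hit by at least 50% of either extent is
absorbed as corroboration (the Pfam record is kept and flagged), so a
Superfamily PDZ nested inside a Pfam PDZ can never double-count a tandem
repeat. Superfamily hits with no Pfam counterpart survive as independent
domains — this is how the highly diverged PDZ domains of the Fe–S
oxidoreductase and GspC families, which only the structure-based model
detects, enter the architectures.

## Overlap resolution

Post-filter hits on one protein may still overlap (duplicate calls,
competing models). The resolver returns the subset of hits with maximum
total bit score subject to a pairwise constraint: two hits are compatible
when their overlap is at most 20% of the shorter hit's length. The small
tolerance keeps adjacent tandem PDZ repeats and split domains (e.g. a
protease domain interrupted by a Q-linker) while removing duplicate calls
on the same region; both the tolerance and the absorption threshold are
configurable.

For up to 16 hits the optimum is found exactly by a pruned depth-first
search over inclusion decisions in descending-score order (hit counts per
protein are far smaller in practice; 2^16 is the worst case and the bound
prunes most of it). Beyond 16 hits a greedy descending-score pass is used.
A plain greedy rule was considered and rejected: it is suboptimal whenever
one high-scoring hit blocks two disjoint medium-scoring hits whose sum
exceeds it, and such configurations occur readily in random instances.
Ties on total score prefer more retained domains, then the
lexicographically smallest coordinate tuple, making the result
deterministic. Unit and acceptance tests verify exact agreement with an
independent brute-force subset enumeration on instances of ≤ 8 hits.

## Family classification

Classification is architecture-first: each of the 12 family signatures
demands a PDZ domain plus family-specific non-PDZ domains, evaluated in a
fixed precedence order (HtrA, Ctp, RseP, APN, Lon, SpoIVB, AP, ZEP, GspC,
Fe–S oxidoreductase, Haem-binding uptake, ComP — the order in which the
families are usually presented). Precedence doubles as the tie-break for
architectures satisfying several signatures; a dedicated test enumerates
all 66 signature pairs. ComP requires both sensor-kinase domains
(HisKA_3 and HATPase_c); the Fe–S oxidoreductase signature additionally
requires the PDZ domain N-terminal to the radical SAM domain. SpoIVB is
recognized from Peptidase_S55 alone. Domain vocabulary is mediated by a
configurable synonym table because Pfam names and clan membership drift
across releases; signature definitions round-trip through an editable
YAML config.

Motifs corroborate: when a protein sequence is available, RseP must show
HExGH in the N-terminal half and NxxPxxxLDG in the C-terminal half, and
the Fe–S oxidoreductase must show CxxxCxxC; without a sequence, domain
evidence suffices and the assignment carries a "motif unchecked" note.
Motif matching is exact-residue with `x` as wildcard; overlapping matches
are all reported, and a region constraint requires the match to lie fully
within the stated half of the sequence. Manual curation steps of real
surveys (MSA construction and pruning of divergent sequences) are not
reproduced; architectures matching no signature remain Unclassified with
a note.

For signature matching, consecutive same-identifier segments separated by
fewer than 60 residues (split domains) count as one logical domain; this
does not affect PDZ tandem counting, which happens upstream.

## Neighborhood extraction

A gene is a neighbor of a PDZ-coding anchor when it is codirectional
(same replicon, same strand) and within `max_gap` nucleotides. The
intergenic distance convention is d = start(next) − end(prev) − 1, clamped
at zero, so overlapping or abutting genes — common in prokaryotes — count
as neighbors. The default gap is 50 nt with 300 nt available for E. coli-
style analyses. Extension is transitive (operon-style chains) because
conserved contexts are multi-gene runs; a pairwise-to-anchor-only mode is
available by flag. Replicons are treated as linear: the origin junction of
circular replicons is not joined (documented limitation). Cross-genome
neighbor identity is keyed on gene name with locus-tag fallback, and
unnamed genes aggregate under "unnamed".

## Rank-sum testing

The Wilcoxon–Mann–Whitney statistic is computed from midranks. For
tie-free samples with n₁+n₂ ≤ 12 the p-value is exact by enumeration of
rank assignments; otherwise the normal approximation is used with
tie-corrected variance and a 0.5 continuity correction. An independent
oracle (`exact_rank_sum_p`) enumerates all C(n₁+n₂, n₁) labelings of the
pooled sample, handling ties, up to n₁+n₂ ≤ 14; tests also cross-check the
asymptotic path against `scipy.stats.mannwhitneyu`. One-sided tests are
the default — group comparisons state the directional null "the right-
side (higher-complexity) group is higher" — with two-sided available by
flag. The measured worst one-sided deviation of the normal path from the
exact oracle over samples of 8–14 observations is ≈ 0.015; the two-sided
p doubles a tail and with it this deviation. No multiple-testing
correction is applied by default (raw Wilcoxon p-values are reported, per
survey practice); Benjamini–Hochberg adjustment is available off by
default. Genomes with NA phenotype are excluded per comparison, never
imputed; groups below two genomes are skipped with a warning.

Habitat categories are compared as adjacent pairs of the complexity
ordering SPECIALIZED < HOST_ASSOCIATED < MULTIPLE < AQUATIC < TERRESTRIAL
(all-pairs mode by flag); oxygen pools anaerobic + facultative against
aerobic; Gram-positive is compared against Gram-negative; and archaea and
fungi are each compared against eubacteria. Genome-size trends use
Spearman rank correlation (the trend claim is about monotone association,
not linearity) and require at least four genomes.

## Synthetic cohorts: what they emulate

The generator's defaults are the study conditions. Per-genome PDZ-gene
counts follow a negative binomial (dispersion k = 5; Poisson as the
k → ∞/None special case) whose mean is a product of planted factors:
oxygen requirement (aerobic 8, anaerobic 3, facultative 5), habitat
(terrestrial 1.4, aquatic 1.3, multiple 1.0, host-associated 0.7,
specialized 0.6), and — in eubacteria only — genome size relative to the
range midpoint; archaea and fungi draw flat low means (2.0 and 1.5).
The overdispersion mirrors the heavy right tail of real per-genome count
distributions (planctomycetes and myxobacteria carry > 10 copies).
Kingdom mix is 80% eubacteria, 12% archaea, 8% fungi. Family membership
is drawn from a mix derived from a real survey's phyletic table,
renormalised so protease families are 88% of classified proteins and 7%
of all proteins are unclassifiable; 27% of PDZ proteins carry a second
(tandem) PDZ hit, so domain hits outnumber proteins by the surveyed
ratio. Localization labels use 11.16% cytoplasmic among known categories
with a 3% no-information rate. The Ctp family carries the canonical Pfam
PDZ family; Fe–S oxidoreductase and GspC PDZ domains are emitted as
Superfamily-only hits; everything else is the noncanonical PDZ_2.

Decoy hits above the inclusion thresholds (failing either the sequence or
the per-hit threshold, in both search and scan tables) are planted from a
dedicated vocabulary that can never complete a family signature.
Codirectional clusters are planted next to RseP anchors (cdsA, uppS, dxr,
frr, rpsB), Fe–S oxidoreductase anchors (engA, gpsA) and Lon anchors
(coaD, rsmD) at fixed sub-threshold gaps; filler genes are separated by
≥ 99 nt so no accidental clusters form. Protein sequences are uniform
random residues with motif instances spliced at controlled offsets — no
attempt at realistic composition or evolution, and HMM scores are drawn,
not computed from alignments.

Consequently, passing tests establish that the pipeline's logic is exact
on data obeying its assumptions (correct threshold handling, architecture
assembly, signature recovery, neighborhood chains, calibrated tests);
they do not establish robustness to real-data phenomena such as
fragmented assemblies, mis-annotated gene models, HMM boundary noise, or
compositional biases.

## Problem sizes and calibration

The statistical checks run on the generator's counts-only fast path (the
same rate model without laying out hits and sequences): type-I error of
the one-sided oxygen comparison under a planted null (two Poisson(5)
groups of 30) over 1000 seeded replicates — 1000 rather than 200 because
the Monte-Carlo standard error of a 200-replicate estimate (~0.016) is
comparable to the width of any sensible acceptance band around 0.05,
whereas at 1000 it is ~0.007; power of the planted negative-binomial
8-vs-3 aerobic effect (30 genomes per group) over 100 replicates; and
genome-size trend detection (eubacteria positive, archaea flat) over 100
replicates of 80-genome cohorts. End-to-end recovery runs on a 60-genome
cohort (~270 PDZ proteins at the default rates). All randomness flows
from explicit seeds; fixed seeds reproduce cohorts byte-for-byte.

## Known limitations

- Circular replicons are linearized; neighborhoods spanning the origin are
  split.
- The canonical/noncanonical PDZ distinction is propagated from the Pfam
  family label only; no structural topology is determined.
- Superfamily hits carry no bit score in the assignment-table dialect, so
  in overlap resolution a Superfamily-only PDZ competes with score 0 and
  survives only when unopposed (which is the planted situation for the
  families it matters to).
- The phylum → "Other bacteria/Archaea" bucketing of summary tables is
  caller-supplied; the package does not guess bucket membership.
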