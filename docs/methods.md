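# Methods

This note records the models, parameter choices, and numerical conventions
behind kcrtools, and what the synthetic-data experiments do and do not
demonstrate about real data.

## Quantification model

Reporter-ion intensities are treated as log-normal: the two-sample
two-tailed t-test prescribed for the log2 values is exactly specified when
log2 intensities are Gaussian, which is also the model the generator
simulates. Per unique peptide, the fold change is the ratio of group means
over non-missing channels; a group contributes only when it has at least
`min_values_per_group` (default 2 of 3) non-missing values — with fewer,
the peptide (or site) is *unquantified* rather than imputed. The protein
ratio is the median over unique-peptide ratios, which is robust to a
single aberrant peptide; the protein-level test statistic instead uses the
per-channel sum of unique-peptide intensities, mimicking a summed
protein-abundance profile. The default test is Welch's (unequal
variances); a pooled-variance switch exists because the underlying method
description does not specify the variant. With 3 + 3 channels the test has
few degrees of freedom, so p-values are noisy for individual proteins —
the calibration guarantee is about the *rate* of false positives (5% at
α = 0.05), verified on 1000 simulated null proteins.

Classification: *up* iff ratio > `fc_threshold` (default 1.2) and
p < `alpha` (default 0.05); *down* symmetric with 1/1.2; otherwise
*unchanged*; *unquantified* when no ratio exists. `use_pvalue=False`
applies the ratio rule alone, since published site counts sometimes state
only the fold-change rule. Raising `fc_threshold` can only move calls
toward *unchanged* (monotonicity), a property the tests enforce.

## Normalization

Channels are mean-normalized: channel *c* is multiplied by
(grand mean of channel means)/(mean of *c*), computed over non-missing
cells, so all channel means coincide afterwards while within-row ratios of
co-measured channels are preserved. The centering reading is per-channel
multiplicative scaling of intensities; a row-centering alternative was
considered and rejected as it destroys absolute scale, but the estimator
of the factors is configurable in one place.

Normalization is a *peptide-level* operation. For PTM-site tables the
mostly-null assumption behind in-table centering fails — the rows are
exactly the regulated signal — so `mean_normalize(site_table, design,
reference=peptide_table)` estimates factors on the peptide table and
applies them to the site table; the pipeline does this by default. In-table
factors remain the behavior when no reference is passed (e.g., when a site
table arrives without its companion proteome run).

## Site normalization and crosstalk

The normalized site ratio is raw site ratio ÷ parent protein ratio; the
identity `norm_ratio × protein_ratio = raw_ratio` holds to floating-point
precision for every quantified site and is asserted at 1e-9 relative
error. Sites whose parent protein is unquantified are classified on the
raw ratio and flagged (`normalized = 0`). Sites with localization
probability ≤ 0.75 are removed before any quantification.

Crosstalk classifies each protein present in both result sets:
*consistent* when the protein and at least one site share a differential
direction with no site contradicting; *opposite* when the directions
disagree; *mixed* when sites disagree among themselves; *unchanged* when
neither side is differential. The quadrant convention for
(protein log2 ratio, mean site normalized log2 ratio) is 1 = (+,+),
2 = (−,+), 3 = (−,−), 4 = (+,−), so discordant points fall in quadrants 2
and 4.

## Motif discovery

The iterative procedure is the classic motif-x scheme. At each step every
free (offset, residue) cell is scored by the binomial upper tail
P(X ≥ k | n, p₀) with k = current-foreground matches, n = current
foreground windows observed (non-pad) at that offset, and p₀ = the
residue's frequency at that offset in the *current* background. The most
significant cell with p ≤ 1e-6 and at least 20 foreground matches is
fixed; both sets are reduced to matching windows. When no cell qualifies,
the motif is emitted with counts and fold increase measured against the
*original* input sets, its matches are removed from the global foreground,
and the background is restored. Defaults (1e-6, 20) follow the original
motif-x convention because the upstream description names the software
without parameters; both are flags.

Numerical conventions: pad characters (`_`, marking protein termini) are
non-observations and are excluded from numerator and denominator of every
positional frequency; p-value ties break deterministically by smaller
|offset|, then negative before positive offset, then alphabetical residue,
so window order never changes the output. Motif names render constraints
ascending with `Kcr` at the center (`FKcrE`; unconstrained interior
positions as `.`). The heatmap matrix is the positional log2 odds of
foreground vs background residue frequencies with a 0.5 pseudocount per
residue; cells with zero counts on both sides, and the center column, are
left undefined rather than zero.

## Conservation

BLASTP-style hit ranking is replaced by exact Smith–Waterman scoring
(BLOSUM62, gap open −11, extend −1; a gap of length L scores
open + (L−1)·extend). At the scale this package targets (hundreds of
proteins per species) the exact quadratic algorithm is fast,
deterministic, and has no E-value heuristics; a minimum-score floor
(default 50) suppresses spurious reciprocal pairs between short unrelated
sequences. Reciprocal best hits break score ties lexicographically by
sequence id (logged), which keeps `find_rbh(A,B)` and `find_rbh(B,A)`
symmetric.

Conservation is counted per ortholog pair on the global (Needleman–
Wunsch) alignment: each query lysine maps through the alignment and is
conserved iff the aligned subject column is lysine; a gap is never
conserved. Lysines are partitioned into crotonylated (the site list) and
control (all other K of the same proteins), accumulated per species, and
tested with the two-tailed Fisher's exact test. Pairwise alignment per
ortholog pair is used instead of a joint multiple alignment because counts
are defined between the query protein and one subject at a time; an
external MSA can be plugged in by supplying pre-aligned pairs to
`count_conservation`.

`fisher_two_tailed` sums hypergeometric point probabilities of all tables
with the observed margins whose probability does not exceed the observed
one, with 1e-7 relative slack against floating-point ties; totals within
1e-12 of 1 are snapped to 1. It is validated against an exact-rational
enumeration oracle and against an independent library implementation.

## Enrichment

Term enrichment builds, per term, the 2×2 table of differential vs
background membership and applies the same Fisher kernel, followed by
Benjamini–Hochberg correction across terms (Bonferroni by flag). The
background is the identified/quantified protein set of the run, and the
differential set must be its subset. Both raw p and corrected q are
reported since published practice on correcting before the 0.05 cutoff
varies. No ontology graph propagation is performed; the annotation map is
taken as given.

## Synthetic-data generator

The generator emulates the *structure* of a 6-plex TMT Kcr experiment, not
any particular instrument:

- **Proteome** — i.i.d. residues from a configurable frequency vector
  (uniform by default), lengths uniform in a range (default 100–600).
- **Digestion** — tryptic cleavage after K/R except before P, no missed
  cleavages, length filter 7–50 by default; peptides tile the protein
  exactly, and uniqueness is sequence-level across the database.
- **Sites and motifs** — each lysine becomes a Kcr site with probability
  `site_fraction`; a site carries a planted motif with the motif's
  prevalence, which stamps the constrained residues into the flanks (the
  returned proteome reflects the edits). The default pipeline motif is
  F at −1 with E at +1 at prevalence 0.3.
- **Intensities** — log2 intensity = base (20) + protein baseline
  N(0, 1.5) + peptide/site response offset N(0, 1) + treatment effect in T
  channels + N(0, noise_sd). The baseline spreads give a realistic
  multi-order-of-magnitude intensity range. Site rows add the site effect
  on top of the protein effect, so proteome normalization has exactly the
  protein component to remove. Cells go missing completely at random.
  Localization probabilities come from a two-component Beta mixture
  (85% Beta(40,2), 15% Beta(4,4)), so the > 0.75 filter removes a
  controllable minority.
- **Effects** — planted log2 effects are sparse and sign-balanced by
  default, the regime in which mean normalization is unbiased (real PTM
  surveys report near-equal up/down counts); an anticorrelated mode ties
  site effects against their protein's direction to exercise the
  crosstalk classifier.
- **Orthologs** — per species, residues substitute independently at
  `substitution_rate`, never into lysine; lysines are retained with
  probability `kcr_keep` (0.8 default) or `control_keep` (0.5 default) and
  otherwise substituted away. Because substitution can never create a K at
  any column, the recorded retention draws are exact conservation ground
  truth, and the conservation counter is required to reproduce them
  bit-for-bit. No indels are simulated, so ortholog alignment is trivially
  colinear — RBH and alignment correctness are instead tested against
  independent oracles.

What passing these tests does *not* show: robustness to interference and
ratio compression of isobaric labels, peptide-level missingness that
depends on abundance (the simulator's is completely at random), shared
peptides across homologous proteins (razor-peptide inference is out of
scope), search-engine-level FDR, or alignment quality under indels and
domain rearrangement.

## Problem sizes and determinism

The validation experiments use desk-scale sizes chosen to make the
statistics stable: 1000 proteins for null calibration of the t-test,
~600 proteins (≈ 500 sites, comparable to a real site table's order of
magnitude) for effect recovery, 500+ sites for motif recovery, 40 proteins
per species for RBH/conservation, 1000 random 2×2 tables for the Fisher
oracle, and 40-mers for the alignment reference. Every stochastic step
takes an explicit seed; a pipeline run's outputs are byte-identical across
repeats, and each written table carries the tool version and a hash of the
effective configuration in its header line.

## Known limitations

- Protein inference is by identifier: shared peptides are flagged
  non-unique and excluded from quantification, not apportioned.
- The t-test with 3 replicates per group has limited power; the package
  reports p-values but no moderated-variance shrinkage.
- RBH with exact all-vs-all alignment scales quadratically; for
  proteome-scale inputs a seeded heuristic search would be needed
  upstream.
- The localization filter is a hard cutoff, matching standard practice,
  rather than a probabilistic weighting.
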