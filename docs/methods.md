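# Methods

This note records the models behind each stage of the pipeline, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions a maintainer would need
to reason about results.

## Protein grouping

Sequences are clustered greedily, longest first (ties broken by accession)
against existing group representatives in group-creation order; a sequence
joins the first representative it matches at or above the identity
threshold (default 0.95), otherwise it founds a new group. Identity is
defined on a global alignment with match +1, mismatch −1, linear gap −1 as

    identity(a, b) = (identical aligned positions) / min(|a|, |b|)

The shorter-sequence denominator means a clean fragment scores 1.0 against
its full-length parent — the convention of greedy clustering tools in this
field. Because several alignments can attain the optimal score, "identical
aligned positions" is made well-defined by maximising the pair
(score, identities) lexicographically in the dynamic programme; this is
deterministic and symmetric, and the test suite checks it against an
independent full-matrix implementation. The optional shared-5-mer
prefilter skips alignments between sequences sharing no 5-mer. For
near-full-length pairs at a 95% threshold a shared 5-mer is guaranteed by
pigeonhole, but for a short fragment against a long sequence it is not, so
the screen is off by default and enabled only where its assumptions hold
(the analysis scripts, where all sequences are full-length).

## Quantification

- **Peptide→group assignment.** A peptide is assigned to the single group
  containing all of its parent accessions; if its accessions span more
  than one group, the peptide is flagged shared and contributes nothing.
  Group intensity per sample is the sum of its unshared peptide
  intensities; a group with no observed peptide in a sample is missing,
  and zero intensity is treated as missing (MS1 non-detection), never as
  a measured 0.
- **Match-between-runs.** For a peptide identified in at least one run but
  absent from an acceptor run, an unidentified acceptor feature is
  assigned that peptide when |Δm/z|/(m/z) ≤ 10 ppm and |Δrt| ≤ 15 min
  against the donor *medians*; the closest-ppm candidate wins, each
  feature takes at most one peptide, and existing identifications are
  never overwritten. Transfer happens before shared-peptide exclusion, so
  a transferred peptide inherits its donor's group assignment and shared
  flag; transferred rows are flagged in the output.
- **Missing-value filter.** A group is removed if (1) both cohorts are
  all-missing, (2) one cohort is all-missing and the other has fewer than
  4 non-missing values, or (3) both cohorts have fewer than 4 each.
  Reading rule (2) as "one condition contains *only* nulls" is the only
  reading under which the three rules are distinct; the rules then
  collapse to keep iff max(n₁, n₂) ≥ 4, and the implementation asserts
  this equivalence on every call.
- **Normalization.** Each sample is transformed by
  glog2((x − a)/b), glog2(y) = log2(y + √(y²+1)) − 1 (computed via
  arcsinh for stability), with (a, b) solved so the transformed
  non-missing values have median 0 and MAD 1. The transform is monotone,
  missing stays missing, and two samples differing by a multiplicative
  constant normalize to identical columns. Because the transform is
  monotone, the post-transform median depends only on the central order
  statistics, so a is solved exactly on those (glog2(0.75) = 0 gives the
  odd-count case in closed form) and b by bisection on the MAD, which is
  strictly decreasing in b. This deterministic calibration plays the role
  of variance-stabilizing normalization; the exact maximum-likelihood vsn
  fit is intentionally not reproduced — the moderated test downstream
  needs approximate variance stabilization, not a particular fit, and a
  closed, deterministic transform is testable. Applying the normalization
  to an already-normalized matrix is the identity. Constant samples
  (MAD 0) map to all-zero columns; samples with fewer than 3 non-missing
  values are an error.

## Moderated testing

Per testable group (≥2 non-missing values in each cohort): pooled variance
s² on d = n₁+n₂−2 degrees of freedom. The prior (d₀, s₀²) is fitted by
method of moments on z = log s²: with e = z − ψ(d/2) + log(d/2),
solve ψ′(d₀/2) = var(e) − mean(ψ′(d/2)) by Newton inversion of the
trigamma function, and s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)). When the
observed spread of z is no larger than sampling noise predicts, d₀ = ∞ and
s₀² is the geometric mean of the s² (exactly s² when all are equal, so the
moderated t then equals the ordinary t). The posterior variance is
s̃² = (d₀s₀² + d·s²)/(d₀+d) — always between s₀² and s² — and the
statistic t̃ = Δx̄/(s̃·√(1/n₁+1/n₂)) is referred to Student-t with d₀+d
degrees of freedom (normal when d₀ = ∞).

Groups that pass the missingness filter but are untestable (one cohort
with fewer than 2 values) are reported as presence/absence observations
with missing statistics; they are excluded from the prior fit and from m
in the q-value computation.

q-values: π₀ = min(1, #{p > λ}/((1−λ)m)) at fixed λ = 0.5 (no smoother —
deterministic and adequate at these scales; configurable), floored at 1/m
to avoid the degenerate all-zero case; q is the step-up minimum of
π₀·m·p⁽ʲ⁾/j, clipped at 1. With π₀ = 1 this is exactly
Benjamini–Hochberg.

Significance is the conjunction p ≤ 0.005 and q < 0.1; the |log2FC| > 1
flag is carried separately as a display attribute (volcano coloring), not
a gate — the two thresholds play different roles. The expected number of
false discoveries among n calls at threshold q is round(n·q).
Left-censored imputation is deliberately absent from the testing path:
only the mean-imputed summaries (PCA, distances) fill missing values, and
only per group, for display.

PCA is a column-centered SVD of the samples × groups matrix with signs
fixed by making each component's largest-magnitude loading positive;
distances are plain Euclidean. Both use per-group mean imputation for the
summary only.

## GO accounting

A group observed in a sample contributes fully to *each* of its terms (no
fractional splitting): one count in unweighted mode, its weight in
weighted mode. The weight is the **mean** intensity of the group's
observed unshared peptides in that sample — a deliberate length control: a
50-peptide protein and a 5-peptide protein with equal per-peptide signal
get equal weight. The regression suite documents that this rule is not
invariant to splitting one peptide row into two half-intensity rows (the
mean halves; a sum-based rule would not) — the mean-based accounting is
the intended behaviour, not an accident. Unannotated groups accrue to
"None"; terms below a 1% share in every sample may be collapsed into
"Other" (threshold configurable; both categories keep per-sample shares
summing to 1). Annotations are consumed as given — no propagation up the
GO graph.

Enrichment is the plain (non-conditional) one-sided hypergeometric test on
the 2×2 table (significant vs not) × (annotated vs not) over the
background significant ∪ universe, per term and namespace. Odds ratios
apply a Haldane 0.5 correction when a cell is zero. Terms with fewer than
2 annotated groups in the background are skipped. The reporting threshold
in the analysis scripts is p < 0.01, unadjusted, mirroring common
practice for exploratory term lists.

## Taxonomy

The tree is two NCBI-taxdump-style tables (taxid, parent, rank; taxid,
name) with a single root; construction validates parent chains and
rejects cycles. The LCA of a taxid set is the deepest node ancestral to
or equal to all of them. Profiling at a rank: a peptide's intensity
accrues to its LCA's ancestor at that rank when the LCA is at or below
the rank, else to "Unassigned/unknown" — this is what sends broadly
conserved (shared) peptides to the unassigned bin at finer ranks, and it
makes the unassigned share non-increasing as the rank coarsens. A lineage
missing the requested rank (e.g., a species with no named family) rolls
to the nearest named ancestor at or above it. 16S count tables roll up
through the same machinery with counts in place of intensities. Ratios
between two taxa are reported both raw and in "1:x" form with x the
rounded inverse.

## Dark peptidome

Database and de novo PSM tables are outer-joined on (sample, scan);
duplicate scan ids within a sample are an error, and unidentified feature
rows on the database side are ignored. Paired records get a similarity:
both sequences are stripped of modification tags, L is collapsed to I
(indistinguishable by mass to de novo sequencing), and the scaled score is

    100 · max(0, NW score) / max(|a|, |b|)

with the same +1/−1/−1 scheme as clustering; 100 iff the processed
sequences are identical, and any substitution or length difference drops
the raw score strictly below the longer length. The dark count per sample
is the number of records with de novo score ≥ cutoff (default 75; the
boundary convention is ≥, the boundary bin is negligible) and no database
peptide; database-only scans count toward totals but never toward
histograms. The summary reports the dark fraction (average dark count /
average total MS2 per sample) and the projected identification increase
(total dark / total identified), unrounded — rounding is presentation.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at
desk scale, from one seeded configuration:

- **Database.** Families of near-duplicate proteins over the 20-residue
  alphabet. One mutation-position set of size round(L·(1−identity)) is
  drawn per family and every non-founder member substitutes at those same
  positions, so the founder identity *and* every within-family pairwise
  identity are at least the configured value (independent per-member
  mutation would let pairwise identity fall to 1 − 2k/L, breaking the
  intended ≥95% structure at identity 0.97). A configuration whose
  mutation count rounds to zero while identity < 1 is rejected.
- **Digestion.** Tryptic: cleave after K/R except before P, 0..N missed
  cleavages, detectability window 6–50 residues (standard bottom-up
  practice).
- **Intensities.** log2 intensity = family baseline
  N(intensity_log_mean = 23, sd = 2) + cohort effect (±log2_effect_size
  on n_diff_groups planted families, sign randomized) + per-family ×
  sample biological replicate effect N(0, 0.5) + per-peptide offset
  N(0, 1) + per-observation noise N(0, 0.5). The biological term is
  essential: it is what keeps group-level variance realistic after
  peptide summation averages measurement noise away; without it the
  moderated test sees absurdly precise groups and any small systematic
  offset becomes significant.
- **Missingness** is left-censored: P(dropout) = expit(steepness ·
  (midpoint − log2 intensity)), defaults midpoint 19 (two baseline SDs
  below the mean) and steepness 1. midpoint = −∞ is the no-dropout limit
  regardless of steepness. A configurable fraction of dropped
  identifications still emit an unidentified MS1 feature row (empty
  peptide) — the material match-between-runs operates on.
- **m/z and retention time.** Precursor m/z from the monoisotopic peptide
  mass at charge 2 (the simplest realistic choice; MBR only needs
  consistent m/z); rt drawn once per peptide (uniform 5–115 min) with
  N(0, 0.2 min) per-sample jitter. No PTMs are simulated.
- **De novo run.** Every database-assigned scan gets a de novo call (true
  peptide with per-residue error 0.03) and a score from the identified
  Beta(8, 1) component — chosen so the mass above the 75 cutoff is
  1 − 0.75⁸ ≈ 0.90. Appended spectra per sample split between "dark"
  (random tryptic-like peptides absent from the database, identified-
  component score, counted in the ground truth) and noise (random
  sequence, Beta(1.5, 6) score).

Determinism: identical configurations (including seed) produce
byte-identical outputs; the quantification and de novo stages draw from
independent seed streams so adding one stage does not perturb the other.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: spectrum-level detail (no peak lists, no
search-engine score distributions, no FDR structure), correlated peptide
behaviour (ionisation competition, retention-time drift between runs),
heavy-tailed or batch-structured intensity noise, homology between
families (cross-family identity is whatever chance produces), and real
annotation or taxonomy databases. Calibration results (type-I error,
recovery rates) are statements about this generative model, not about any
particular instrument or cohort.

## Problem sizes

The analysis scripts and the calibration tests run at sizes chosen to
exercise every code path while completing in minutes on one CPU: 200
families × 3 members × 300 residues for the worked study; 2000 singleton
families × 80 residues for the null-calibration simulation; 20 seeds of
the planted simulation (30 true effects at log2FC = 2); 1000 planted
database-absent spectra for the dark-recovery check. These are the
package's own desk-scale study conditions; the statistical machinery is
size-agnostic.
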