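# Methods

This note records the models, conventions and numerical choices behind
`popscan`, and what the synthetic-data validation does and does not show.

## Genotype model and coordinates

Genotypes are codes {0, 1, 2} counting copies of `allele_b` with a
distinct missing sentinel (−1); every frequency denominator uses
non-missing counts only.  `allele_b` is the minor allele as observed in
the source file (ties broken lexicographically).  All coordinates are
1-based and inclusive at both ends; writers state this in headers.

## Quality control

QC is a fixed two-pass procedure: (1) markers with ≥ 5% missing calls are
discarded; (2) per-individual missingness is recomputed on the surviving
markers, individuals with ≤ 5% missingness are kept, and marker
missingness (≤ 5%) and MAF (≥ 5%) are then re-evaluated on the surviving
individuals.  The asymmetry (strict ≥ for the pass-1 drop, ≤ for the
pass-2 keep) is intentional and matched by the tests.  Applying QC twice
is a no-op (tested).  Every dropped marker or sample carries exactly one
reason in the `QCReport`.

When merging two cohorts, only markers passing QC in both are retained;
allele labels are harmonized by swap and/or reverse-complement.
Strand-ambiguous A/T and C/G markers are dropped by default because their
orientation is indeterminable without frequency heuristics; a
`keep_ambiguous` flag enables frequency-matching inference instead.

## Relatedness (π̂)

The estimator is the classical method of moments from IBS sharing:
observed counts of markers at which a pair shares 0/1/2 alleles are
equated with their expectations under IBD states 0/1/2 computed from
sample allele frequencies; state proportions are solved sequentially,
negative values clamped to 0 and renormalized; π̂ = P(IBD=1)/2 + P(IBD=2),
clamped to [0, 1].  No small-sample bias corrections are applied; at the
marker counts used here (≥ 20,000) the estimator recovers 1.0 / 0.5 / ~0
for duplicates, first-degree pairs and unrelated pairs within 0.05
(tested by gene-dropping simulation).  Pruning removes, for each pair
with π̂ > 0.25 visited in ascending index order, the member with the
larger index; pairs already broken by an earlier removal are skipped.

## IBS distance and its two conventions

With A and B the counts of one- and two-allele mismatches over M
mutually non-missing markers, the default "normalized" distance is
(0.5·A + B)/M, a scaled Hamming-type metric in [0, 1] (symmetric, zero
diagonal, triangle inequality — property-tested).  The raw count A + B/2
is retained as the `as_printed` convention for auditability of legacy
reports that quote it; note it down-weights two-allele mismatches below
one-allele mismatches and is not normalized per pair.  Missing data are
handled pairwise-complete.

MDS is classical Torgerson scaling — eigendecomposition of the doubly
centered squared-distance matrix, coordinates scaled by √max(λ, 0) —
with a deterministic sign convention (first nonzero loading of each axis
positive).  Axes beyond the non-negative spectrum are zero-padded and
flagged.  Plot orientation is otherwise arbitrary.

The cross-cohort permutation test shuffles cohort labels with group
sizes fixed and uses the add-one estimator p = (1 + #{perm ≥ obs}) /
(1 + n_perm), one-sided (separation inflates cross-group distance).  A
seed is mandatory.  **Calibration caveat:** with the *median* statistic
the permutation distribution is heavily tied — the median of hundreds of
quantized pair distances rarely moves under relabeling — so the test is
conservative (empirical type-I ≈ 0.01 at α = 0.05 in our null
simulations).  The *mean* statistic is calibrated (0.05 ± 0.02 over 500
null replicates, tested).  Both remain valid (super-uniform) tests.

## F_ST

Exactly the heterozygosity-proportion recipe: p₁, p₂, pooled p from
genotype counts (autosomal diploidy, no HWE correction); H_T = p(1−p);
H_S = (N₁p₁(1−p₁) + N₂p₂(1−p₂))/N; F_ST = 1 − H_S/H_T, undefined when
H_T = 0.  H omits the conventional factor 2; the ratio — hence F_ST — is
invariant to it (tested).  Concavity of p(1−p) guarantees F_ST ∈ [0, 1].
Windows are anchored at position 0 per chromosome with half-open
[s, s + width) membership, default 5 Mb width / 2.5 Mb step; windows with
fewer than 200 defined markers are suppressed (the smallest window in
comparable published scans holds ~400 SNPs; the threshold avoids
empty-window noise).  Undefined markers are excluded from window means,
not counted as zero.  Ratios divide by the genome-wide (autosomal, by
default) mean/median over the same marker set.

## Runs of homozygosity

A window of consecutive autosomal markers is valid when it has ≥ 100
SNPs, ≤ 1 heterozygote, ≤ 5 missing calls, no adjacent gap > 1,000 kb,
and segment-level density (end − start)/n_snps ≤ 50 kb/SNP.  The caller
emits maximal valid windows (no one-marker extension stays valid) and
resolves overlaps in favor of the larger SNP count, ties to the smaller
start.  The semantics are *defined* by an exhaustive window-enumeration
oracle; the production scan (event-position arithmetic for the
heterozygote/missing budgets, an affine transform test for density) is
proven equal to the oracle on thousands of randomized ≤200-SNP instances.

Parameter notes: the 1,000-kb gap default is the conventional array-data
limit (a 1-kb gap limit — occasionally quoted for this analysis — would
forbid any run at ~5.5 kb mean marker spacing; it remains reachable via
configuration).  The 5-missing allowance follows common tooling defaults.
Density is checked over the whole emitted segment, not per sub-window.

**Interval association.**  All distinct segment endpoints are sorted per
chromosome; each pair of adjacent endpoints bounds an elementary interval
within which carrier status is constant (a carrier's segment covers the
interval entirely).  Each interval with at least ⌊0.05·N⌋ carriers is
tested with Fisher's exact test (two-sided, minimum-likelihood rule);
the sample odds ratio is reported, with the Haldane–Anscombe +0.5 OR when
a cell is zero.  Note a conditional-MLE odds ratio, as printed by some
legacy tools, differs slightly from the sample OR (e.g. 5.06 vs 5.09 on
the 12/91/5/193 table); we report the sample OR.  Adjacent intervals
with identical carrier sets are not merged.  Raw p-values are reported
(matching the uncorrected convention of small exploratory scans); a
Benjamini–Hochberg column is emitted alongside for modern use.

**Age regression.**  Each ROH summary metric is fit by OLS on
intercept + AGE + SEX(male) + AGE×SEX(male).  Single-sex inputs drop the
sex terms with a flag; a constant outcome is reported with slope p = 1
and R² = 0.

## CNV burden

Calls are parsed from the text dialect of array CNV callers; copy number
2 is rejected (a call must be a variant), and malformed lines are
collected into an error report rather than dropped.  Size classification
uses the call record's printed length when present — honoring the source
tool's reporting, which can differ from the coordinate span — else the
span; thresholds are strict (> t kb).  Duplications are cn > 2 (cn = 4
counts as duplication), deletions cn < 2.  Burden is a per-sample carrier
indicator (a sample with several qualifying calls counts once) tested by
Fisher's exact test; group denominators are always supplied by the
caller, never inferred from the call list.  The bundled inventory of 32
large calls from a 103/197 case/control study reproduces its published
summary table cell-for-cell and the >2 Mb burden p = 0.019.

## Synthetic data: what it shows and what it does not

The generator uses the Balding–Nichols model: ancestral frequency
p ~ U(0.05, 0.5), cohort frequencies Beta(p(1−F)/F, (1−p)(1−F)/F),
genotypes Binomial(2, p_cohort), uniform missingness.  Defaults mirror a
small two-cohort array study: 103 + 203 subjects, F = 0.005 (the order
of differentiation between neighboring European populations), 5-kb
constant marker spacing (≈550K-array genome density, so ROH density/gap
constraints behave realistically), 1% missing calls.  All randomness
flows from one seed; identical configurations are byte-identical.

ROH tracts are planted by overwriting genotypes to the homozygote of the
allele the carrier already holds more copies of — simpler than simulating
autozygosity by descent and sufficient for validating the caller and the
scan.  For endpoint-recovery studies `plant_roh(..., het_flank=2)` forces
two heterozygous markers immediately outside each tract edge: without
such delimiters the caller's one-heterozygote budget legitimately extends
a called run several markers past the planted edge through a homozygous
flank, so "endpoint error ≤ one marker spacing" is only a meaningful
target on delimited tracts.  With delimiters the overrun is at most one
marker (the single allowed flank heterozygote), and the recovery tests
confirm exactly that bound.

No linkage disequilibrium is simulated — none of the statistics here
model LD — so passing tests say nothing about LD-induced artifacts in
real arrays (e.g. background ROH from common haplotypes: in HWE
simulation, chance 100-SNP homozygous runs are essentially impossible,
whereas real data show many; the interval scan is therefore exercised
with planted neutral tracts as competition).  Likewise intensity-level
artifacts (genomic waves, batch effects) and genotyping error are out of
scope: the CNV generator produces calls, not intensities.

## Problem sizes used in validation

Simulation-backed checks run at reduced but representative sizes chosen
as a deliberate design point: relatedness recovery at 20,000 markers;
planted-tract recovery on a 15-Mb chromosome with 30 samples;
interval-scan localization over 100 replicates of 100 + 100 samples on a
12-Mb chromosome; resampling-test calibration over 500 null replicates of
40 samples × 300 markers with 99 permutations each.  Replicate counts
match the validation design; per-replicate sizes are the smallest at
which the tested effects are unambiguous.
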