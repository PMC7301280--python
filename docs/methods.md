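# Methods

This note documents the models, numerical choices, and design decisions
behind `proteoage`, and what the synthetic-data generators do and do not
emulate.

## Statistical kernel

**Moderated t-test.** For a two-group contrast on a log2 matrix, the
per-feature statistic is the mean difference divided by a shrunken
standard error. The per-feature pooled residual variance s²_g (d = n_a +
n_b − 2 df) is shrunk toward a prior s₀² with prior weight d₀:
s̃²_g = (d₀·s₀² + d·s²_g)/(d₀ + d), and p-values come from a t
distribution with d + d₀ df. The prior is estimated by closed-form moment
matching on z_g = log s²_g: under the scaled-inverse-chi-square hierarchy,
E[z] and Var[z] are digamma/trigamma expressions in d/2 and d₀/2, so d₀
solves trigamma(d₀/2) = Var(z) − trigamma(d/2) (Newton inversion of the
trigamma), and s₀² follows from the mean. When the observed spread of log
variances does not exceed chi-square sampling noise, d₀ = ∞ and all
features share s₀². The implementation reproduces the reference R/limma
`eBayes` moderation to ~1e-13 relative on heteroscedastic fixtures (the
test suite runs that cross-check through Rscript); with d₀ forced to 0 it
is exactly the ordinary pooled-variance t-test. Constant features report
p = 1 with zero fold change.

**Multiple testing and combination.** Benjamini–Hochberg step-up
adjustment throughout (NaNs propagate and are excluded from the test
count). P-values across independent contrasts are combined by Fisher's
method, X = −2Σ ln p ~ χ²(2k); an input of exactly 0 is clipped to the
smallest positive float with a warning. Over-representation is the
hypergeometric upper tail; two-sided Fisher exact tests use the standard
conditional enumeration (scipy), verified against full table enumeration
for universes ≤ 30.

**Count data.** Transcript differential expression uses a single generic
route: library-size normalization followed by log2(+0.5) and the
moderated t-test. Library sizes are median-of-ratios size factors (per
sample, the median ratio of counts to the per-gene geometric mean) rather
than raw column totals: when a sizeable fraction of genes shifts
cumulatively with age, total-count normalization induces a composition
bias that contaminates every gene's fold change; median-of-ratios factors
are robust to it. Dispersion-based count models are deliberately out of
scope — downstream logic consumes only (log2 FC, adjusted p).

## TMT processing and iBAQ

PSMs are discarded if they map to reverse or contaminant entries, score
below 15, or have reporter intensities below 10³ in *all* channels (one
adequate channel suffices to keep the PSM). Reporter intensities of
retained PSMs are log2 transformed and median-centered per channel
("normalization" is unspecified in most processing descriptions;
per-channel median-centering is the scale-robust default). Protein groups
take the median over proteotypic (unique) peptide observations complete
in every channel and need ≥ 2 distinct unique peptides.

For iBAQ, each peptide's channel ratio is the median over its PSMs of
reporter_c/Σreporters, renormalized to sum to 1 so that splitting the
peptide's total precursor area conserves it exactly (tested at 1e-9
relative). After splitting, channel intensities are multiplied by the
per-channel median peptide ratio — a sampling-aberration correction that
rescales all channels by roughly 1/plex and cancels in the final
median normalization (each channel scaled so its median iBAQ is 1, which
makes the output invariant to rescaling any single sample). The iBAQ
denominator counts distinct fully tryptic peptides of length 8–25 with no
missed cleavage; trypsin cleaves C-terminal to K/R unless followed by P
(the canonical rule, hand-implemented because common digest libraries add
further exceptions such as WKP/MRP that this pipeline does not want);
unknown residues (X/B/Z/U) never cleave but peptides containing them
still count. Proteins with zero observable peptides cannot enter the
formula and are excluded.

## Decoupling

Per-sample correlation is Pearson on log₁₀ protein vs log₁₀ transcript
abundance over features positive in both layers for that sample (log
scale is the field standard for abundance correlation); samples with
< 100 shared features are flagged and excluded from the one-way ANOVA of
per-sample r across age groups.

Mechanism classification runs over proteins with adjusted p below the
threshold, in fixed decision order: (iii) transcript not detected;
(i) transcript significant with the same fold-change sign;
(ii) transcript same sign but not significant ("consistent" is
interpreted as same sign regardless of magnitude); (iv) protein
down-regulated and targeted by ≥ 1 miRNA that is up-regulated (log2
FC > 0, adjusted p < threshold) — the repressive-direction convention;
(v) all remainder, attributed to other post-transcriptional regulation.
Classes are exhaustive and mutually exclusive; per-contrast fractions sum
to 1.

## Complex stoichiometry

Member log2 abundances are normalized per sample by subtracting the
trimmed mean of all quantified members of the complex. The trim is 20%
total (10% per tail), with at least one value dropped per tail once ≥ 5
members are quantified — at the 5-member floor this keeps 3 values. The
floor of 5 quantified members applies everywhere. A protein in several
complexes contributes an independent complex-relative row per complex.

Member-level differential testing runs on the complex-relative values;
a complex is *affected* when ≥ 2 members pass adjusted p < 0.05 and
|log2 FC| > 0.5. Known property: an extreme shift of a *single* member
changes which values the trimmed mean drops and can leak an apparent
opposite shift (≈ shift/n_retained) into the other members; at realistic
shift magnitudes (~1.2 log2) the leak stays below the fold-change
threshold, but pathological single-member shifts can occasionally flag a
complex. This is inherent to trimmed-mean normalization, not a bug.

The IQR of member fold changes uses linear-interpolation (type-7)
quantiles so tests can be exact. IQR vectors across contrasts are
compared by the two-sided Wilcoxon rank-sum test: exact enumeration when
both sides have ≤ 12 values and no ties, otherwise the tie-corrected
normal approximation without continuity correction (so identical inputs
give exactly p = 1). Ranking by ΔIQR counts exact zeros as half an
increase.

## SEC co-elution

Profiles are normalized to unit row sum over the 39 fractions (all-zero
rows dropped); correlations use all fractions including zeros, which are
informative of absence. The random-complex null draws size-matched random
protein sets (default 1000, seeded; a draw never reproduces a real
complex's member set). The rank-sum comparison of real vs random
co-elution is computed on **per-complex median** pairwise correlations,
not on the pooled pairwise values: correlations within a set share
members, and pooling dependent values miscalibrates the test (measured on
null catalogs: 14% of seeds below p = 0.05 when pooling; uniform when
summarized per set). The pooled vectors are still reported for the
distribution view.

Consensus profiles are per-fraction medians over ≥ 5 quantified members,
scaled to maximum 1. Elution shifts between conditions are quantified by
the apex (ties to the earliest fraction, with a warning for flat
profiles) and the center of mass; the flag threshold is a configurable
|COM shift| ≥ 2 fractions (the shift metric itself is this package's
addition — the underlying observation is qualitative). Intensities below
5% of the profile maximum are excluded from the COM: a noise floor spread
over all fractions would otherwise pull the COM toward the axis midpoint
and attenuate real shifts. Positive shift means later elution (lower
apparent mass). Fractions are 0-based internally and 1-based in all
reports.

## Aggregates

Proteins must be quantified in ≥ 2 replicates per sample group; the
retained matrix is quantile normalized (columns forced onto the mean of
the per-column sorted values; ties averaged; missing values keep their
rank positions and are excluded from the reference) before the
pellet-vs-homogenate moderated differential. Enrichment uses raw
p < 0.05 with log2 FC > 0.5 (depletion symmetric), matching volcano-style
reporting. Features with missing values that pass the replicate filter
are currently excluded from the moderated test (complete-case); the
synthetic generator produces complete matrices, so tests do not exercise
partial missingness in the t-test itself.

Biophysical scores: the chaperone-requirement classifier output is folded
to a signed probability (−P, 0, +P for negative/indeterminate/positive,
P ∈ [0.5, 1]); disorder is the random-coil fraction n_c/N. Score
distributions of the top vs bottom 20% of proteins ranked by enrichment
are compared by the two-sample KS test. Set enrichment among aggregate
proteins uses the two-sided Fisher exact test (sidedness is a
documentation gap upstream; two-sided is the conservative default), and
complexes are ranked by the median member enrichment with ≥ 3 quantified
members.

## Survival

Δ_ij = log2((g_ij(t₂) + 0.5)/(g_ij(t₁) + 0.5)) on median-of-ratios
normalized counts; the pseudo-count keeps Δ finite and is configurable.
The per-gene Cox model h(t | Δ) = h₀(t)·exp(c·Δ) is fit by
Newton–Raphson on the single-covariate partial likelihood with Breslow
tie handling; the covariate is standardized internally for stable steps
and the coefficient mapped back. Risk sets honour left truncation at the
entry age (the analyzed cohort conditions on surviving to the second
sampling). Degenerate cases: a constant covariate reports c = 0, p = 1;
a monotone likelihood (runaway scaled coefficient or collapsing
curvature) sets the divergence flag instead of reporting a finite MLE.
Wald z and p come from the observed information at the optimum. The fit
matches a 1-D numeric maximization of the same partial likelihood to
1e-6 and the lifelines Cox implementation (with delayed entry) to ~1e-4.

Gene-wise fitting uses a vectorized joint Newton solver when the data
have the cohort's standard shape (all events, unique times, common
entry — risk sets are then nested and per-event denominators reduce to
reverse cumulative sums), and falls back to per-gene fits otherwise; the
two paths agree to 1e-6 and the fast path handles 1000 genes × 159 fish
in ~0.1 s.

The extreme-group comparison summarizes each fish by the mean Δ over the
gene set (median and first principal component are selectable), takes the
k most decreasing and k most increasing fish (ties at the k-th rank break
deterministically by fish id), and compares lifespans by the two-group
log-rank test (lifelines). With a common entry age, delayed entry does
not affect the two-group comparison.

Survival simulation inverts the model in closed form: with an exponential
baseline (default rate 0.07/week, giving a residual median lifespan of
~10 weeks past entry, in the range of short-lived killifish cohorts) and
linear predictor Σ c_i·Δ_ij, residual life after entry is exponential
with rate λ·exp(lp) by memorylessness.

## Synthetic cohort: what it emulates, and what it does not

The cohort generator emulates: a 3 × 5 age-group design; gene-level
log-normal abundance (log₁₀ mean 1.5, sd 1.0 by default); transcript
counts as a gamma-Poisson (negative binomial) mixture with gene-level
dispersion 0.1 — common RNA-seq structure; proteins as log-normal
intensities linked to the same gene means; per-gene mechanism classes in
configurable proportions; a miRNA layer in which every miRNA-candidate
gene is targeted by ≥ 1 up-regulated miRNA and decoy targets keep the map
uninformative by itself.

**Correlation steering.** When per-group correlation targets are given
(default 0.48/0.43/0.33, the declining-coupling structure of an aging
cohort), the generator decomposes protein deviations into a stable
per-gene post-transcriptional offset (shared by all groups, sized from
the most-concordant group's target — stable offsets do not create
between-group fold changes) plus per-group per-sample noise solved
analytically from the realized transcript statistics (covariance and
variance computed under the same positive-in-both-layers mask the
analysis applies). Impossible targets raise an error reporting the
achievable maximum. Achieved per-sample correlations land within ±0.05 of
target at ≥ 2000 genes (typically ±0.02). In this mode the
lower-correlation groups necessarily carry large per-sample protein
noise — that is what decoupling *is* — so differential power in those
groups is genuinely reduced.

**Class identifiability.** For post-transcriptional classes (miRNA and
other), the transcript fold change is drawn mildly *discordant*
(opposite sign, ~0.4 log2) rather than exactly flat: a strictly flat
transcript has a random noisy fold-change sign, which would send half of
these genes into the "same sign, not significant" class and make the
truth unrecoverable in principle. The transcript-consistent class draws
its transcript change as a fraction of the protein change sized to sit
between sign stability and the significance threshold; this window
depends on count precision, so the strong-effect recovery condition uses
low dispersion (0.01), well-expressed genes (log₁₀ mean 2.5), and a
consistent-fraction of 0.15, under which ≥ 95% of class labels are
recovered. The generators do not emulate: batch effects, missing values,
shared peptides/razor proteins, isotope impurity, realistic chromatogram
shapes, or miRNA target prediction (the target map is an input).

## Problem sizes and defaults

Benchmarks run at the sizes the analyses are designed for: correlation
recovery at 5000 genes; mechanism recovery at 3000 genes; stoichiometry
operating characteristics over 40 seeds of 40-complex experiments
(5 perturbed, 2 members shifted +1.2 log2, noise 0.2, n = 4/group); SEC
shift detection over 100 seeds (+3 fractions, noise 0.05); null
calibrations at ≥ 1000 replicates; SEC null uniformity over 200 seeds;
Cox recovery at n = 500; risk-set detection over 50 seeds of the 159-fish
cohort. The whole benchmark suite completes in about a minute.
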