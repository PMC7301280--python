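# proteoage

Loss of protein homeostasis is a hallmark of vertebrate brain aging. In the
short-lived killifish *Nothobranchius furzeri* — and in aging mouse brain —
this manifests as a cascade of linked molecular phenotypes: transcript and
protein abundances progressively **decouple** with age, protein complexes
lose their **stoichiometry**, assemblies shift on size-exclusion
chromatography, orphaned subunits become enriched in **SDS-insoluble
aggregates**, and early-adult changes in the expression of proteostasis
genes predict individual **lifespan**.

`proteoage` is a tested, reusable implementation of the full analysis chain
behind these observations, for computational biologists who want to run the
same statistics on their own multi-omics aging data or probe the pipeline's
operating characteristics on synthetic data with known ground truth:

* **TMT quantification** — PSM filtering (reverse/contaminant hits, search
  score < 15, reporter intensity < 10³ in all channels), per-channel log2
  median-centering, protein-group summarization by the median over complete
  proteotypic peptides (≥ 2 unique peptides), and iBAQ from TMT by splitting
  each peptide's precursor (MS1) area across channels in proportion to its
  reporter ratios and dividing by the count of observable tryptic peptides
  (fully tryptic, length 8–25, no missed cleavage).
* **Moderated differential statistics** — an empirical-Bayes moderated
  two-sample t-test (the per-feature residual variance *s²_g* is shrunk
  toward a prior *s₀²* with weight *d₀* estimated by closed-form moment
  matching on log *s²_g*; *t* has *d + d₀* degrees of freedom),
  Benjamini–Hochberg FDR, Fisher's p-value combination, hypergeometric
  over-representation, and a coefficient-based gene-set test.
* **Decoupling** — per-sample Pearson correlation of log₁₀ iBAQ vs log₁₀
  transcript abundance with a one-way ANOVA across age groups; fold-change
  concordance quadrants; and a five-class mechanism assignment for each
  age-affected protein (concordant-significant, transcript-consistent,
  no transcript detected, miRNA-candidate, other post-transcriptional).
* **Complex stoichiometry** — member abundances normalized to the trimmed
  mean of their complex per sample; a complex is *affected* when ≥ 2 members
  change significantly (adj. p < 0.05, |log2 FC| > 0.5) on the
  complex-relative scale; stoichiometry loss is quantified by the
  interquartile range (IQR) of member fold changes and compared across
  contrasts by the Wilcoxon rank-sum test.
* **SEC co-elution** — elution profiles normalized to unit row sum across
  39 fractions, within-complex pairwise correlations benchmarked against
  size-matched random complexes, median consensus profiles scaled to max 1,
  and an apex/center-of-mass detector for elution shifts between
  conditions.
* **Aggregates** — quantile-normalized pellet vs total-homogenate
  differential (enriched: p < 0.05, log2 FC > 0.5), signed
  chaperone-requirement classifier scores (−P / 0 / +P) and the random-coil
  disorder fraction n_c/N, top-vs-bottom 20% Kolmogorov–Smirnov
  comparisons, and Fisher-exact set enrichment.
* **Survival** — per-gene Cox proportional hazards on expression change,
  h(t | Δ) = h₀(t)·exp(c·Δ) with Δ = log2 of the expression ratio between
  two sampling ages; single-covariate Newton–Raphson on the Breslow partial
  likelihood with left truncation at the second sampling; extreme-group
  log-rank comparison of the k most decreasing vs k most increasing fish.
* **Synthetic data** — generators for every input (cohort matrices, PSM
  tables, SEC profiles, aggregate experiments, longitudinal survival) with
  injectable effects recorded in a ground-truth sidecar, so each stage's
  sensitivity, specificity, and calibration are measurable.

## Worked example

Generate a three-age-group cohort (n = 5/group) whose per-group
protein–transcript correlations are steered to 0.48 / 0.43 / 0.33, then
recover them:

```python
from proteoage.synthetic import CohortDesign, generate_omics_cohort
from proteoage.decoupling import per_sample_correlation

design = CohortDesign(seed=1, n_genes=5000)
transcripts, proteins, mirna_de, target_map, truth = generate_omics_cohort(design)
res = per_sample_correlation(proteins, transcripts)
print(res.group_means.round(3))
print(f"ANOVA across age groups: F = {res.anova_f:.1f}, p = {res.anova_p:.2e}")
```

```
group
young    0.479
adult    0.429
old      0.337
Name: r, dtype: float64
ANOVA across age groups: F = 719.2, p = 3.21e-13
```

The per-sample correlation declines from young to old exactly as injected,
and the ANOVA confirms the group effect — at n = 5 per group the decline in
transcript–protein coupling is highly resolvable.

Link early-adult expression changes to lifespan in a 159-fish longitudinal
cohort where a 50-gene risk set (per-gene hazard coefficient c = 0.1)
drives mortality:

```python
from proteoage.synthetic import generate_longitudinal_survival
from proteoage.survival import genewise_cox, extreme_group_logrank
from proteoage.differential import coefficient_set_test
from proteoage.containers import ComplexCatalog

genes = [f"G{i:05d}" for i in range(300)]
delta, surv, truth = generate_longitudinal_survival(
    n_fish=159, genes=genes,
    risk_sets={"proteasome": {"genes": genes[:50], "c": 0.1}}, seed=1,
)
fits = genewise_cox(delta, surv)
sets = coefficient_set_test(fits["coef"], ComplexCatalog({"proteasome": set(genes[:50])}))
print(sets.round(4).to_string())
lr = extreme_group_logrank(delta, surv, genes[:50], k=32)
print(f"log-rank chi2 = {lr['chi2']:.1f}, p = {lr['p']:.2e}")
print(f"median lifespan, bottom-32 vs top-32 fish: "
      f"{lr['median_low']:.1f} vs {lr['median_high']:.1f} weeks")
```

```
            n_members     t    p  direction  adj_p
set_id
proteasome         50  6.02  0.0          1    0.0
log-rank chi2 = 37.1, p = 1.11e-09
median lifespan, bottom-32 vs top-32 fish: 49.9 vs 23.5
```

The coefficient-based set test flags the injected risk set with positive
direction (larger expression increases → higher mortality), and the fish
with the strongest increases of the risk-set summary live less than half
as long as those with the strongest decreases.

The full synthetic pipeline (cohort → differential → decoupling →
stoichiometry → SEC → aggregates → survival) runs from the command line:

```bash
proteoage run --seed 1 --outdir run1          # all stages + manifest.json
proteoage simulate psm --n-proteins 50 --outdir sim   # PSM-level inputs
proteoage tmt process --psm sim/psms.tsv --fasta sim/proteins.fasta --outdir tmt
```

Every output directory contains a `manifest.json` (config, seed, package
versions) sufficient to reproduce the run byte-identically.

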