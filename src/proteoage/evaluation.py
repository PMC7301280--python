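"""Study-condition evaluations: calibration and recovery benchmarks.

Each function runs a pipeline stage on synthetic data generated under the
cohort's stated conditions and measures how well the stage recovers the
injected truth (or holds its nominal error rate under the null). They are
the package's own quality gates, shared by the test suite and the
reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ComplexCatalog, Contrast, FishSurvival, OmicsMatrix, SECMatrix
from .decoupling import classify_mechanism, per_sample_correlation
from .differential import count_differential, moderated_t_test
from .aggregates import aggregate_enrichment
from .sec_coelution import (
    complex_profile,
    detect_elution_shift,
    normalize_profiles,
    random_complex_null,
)
from .stoichiometry import call_affected, normalize_to_complex
from .survival import cox_fit_single, extreme_group_logrank, genewise_cox
from .synthetic import (
    CohortDesign,
    generate_aggregate_experiment,
    generate_longitudinal_survival,
    generate_omics_cohort,
    generate_sec_profiles,
    generate_stoichiometry_experiment,
)

#: generator settings for the strong-effect / low-noise mechanism
#: identifiability condition (well-expressed genes, precise counts)
STRONG_EFFECT_KWARGS = dict(
    protein_noise_sd=0.1,
    dispersion=0.01,
    gene_mean_log10=2.5,
    gene_sd_log10=0.8,
    consistent_transcript_ratio=0.15,
)


# --------------------------------------------------------------------------
# calibration (null) benchmarks


def moderated_t_null_fraction(seed: int, n_features: int = 1000, n_per_group: int = 4) -> float:
    """Fraction of null Gaussian features below p = 0.05 under the
    moderated t-test (nominal 0.05)."""
    rng = np.random.default_rng(seed)
    cols = [f"a{i}" for i in range(n_per_group)] + [f"b{i}" for i in range(n_per_group)]
    df = pd.DataFrame(
        rng.normal(0.0, 1.0, (n_features, 2 * n_per_group)),
        index=[f"F{i:05d}" for i in range(n_features)],
        columns=cols,
    )
    m = OmicsMatrix(df, kind="log2")
    contrast = Contrast(tuple(cols[:n_per_group]), tuple(cols[n_per_group:]))
    res = moderated_t_test(m, contrast)
    return float((res["p"] < 0.05).mean())


def cox_null_fraction(seed: int, n_genes: int = 1000, n_fish: int = 159) -> float:
    """Wald type-I error of the per-gene Cox fit on all-null data."""
    delta, surv, _ = generate_longitudinal_survival(n_fish, n_genes, {}, seed=seed)
    fits = genewise_cox(delta, surv)
    return float((fits["p"] < 0.05).mean())


def aggregate_null_fraction(seed: int, n_proteins: int = 1000) -> float:
    """Fraction of null proteins below p = 0.05 in the pellet-vs-TH
    differential (no enrichment injected)."""
    matrix, _, _ = generate_aggregate_experiment(
        n_proteins=n_proteins, enriched_set=set(), seed=seed
    )
    de, _, _ = aggregate_enrichment(matrix)
    return float((de["p"] < 0.05).mean())


def logrank_null_fraction(seed: int, n_reps: int = 1000, n_fish: int = 159) -> float:
    """Type-I error of the extreme-group log-rank split (k = n/2) when
    expression change carries no mortality signal."""
    hits = 0
    k = n_fish // 2
    for rep in range(n_reps):
        delta, surv, _ = generate_longitudinal_survival(
            n_fish, ["G0"], {}, seed=seed + rep
        )
        res = extreme_group_logrank(delta, surv, ["G0"], k=k)
        hits += res["p"] < 0.05
    return hits / n_reps


def sec_null_pvalues(
    seed: int,
    n_seeds: int = 200,
    n_proteins: int = 300,
    n_fractions: int = 39,
    n_sets: int = 8,
    n_draws: int = 50,
) -> np.ndarray:
    """Rank-sum p-values of the real-vs-random co-elution comparison when
    the 'real' catalog is itself randomly defined; uniform under a
    calibrated test."""
    ps = []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + s)
        x = np.arange(1, n_fractions + 1, dtype=float)
        apex = rng.uniform(1, n_fractions, n_proteins)
        width = rng.uniform(1.5, 3.0, n_proteins)
        rows = np.exp(-((x[None, :] - apex[:, None]) ** 2) / (2 * width[:, None] ** 2))
        profiles = normalize_profiles(
            SECMatrix(pd.DataFrame(rows, index=[f"P{i}" for i in range(n_proteins)], columns=x))
        )
        sets = {
            f"C{i}": set(
                rng.choice(profiles.data.index, size=int(rng.integers(5, 9)), replace=False)
            )
            for i in range(n_sets)
        }
        res = random_complex_null(
            profiles, ComplexCatalog(sets), n_draws=n_draws, seed=seed + s + 10_000
        )
        ps.append(res["p"])
    return np.asarray(ps)


# --------------------------------------------------------------------------
# recovery benchmarks


def correlation_recovery(
    seed: int,
    n_genes: int = 5000,
    targets: tuple = (0.48, 0.43, 0.33),
) -> dict:
    """Generate a cohort steered to the target per-group correlations and
    measure how closely the analysis recovers them (plus the ANOVA across
    groups)."""
    design = CohortDesign(seed=seed, n_genes=n_genes)
    transcripts, proteins, _, _, _ = generate_omics_cohort(design, decoupling_targets=targets)
    res = per_sample_correlation(proteins, transcripts)
    means = res.group_means.reindex(design.group_labels)
    errors = {g: float(means[g] - t) for g, t in zip(design.group_labels, targets)}
    return {
        "group_means": {g: float(v) for g, v in means.items()},
        "targets": dict(zip(design.group_labels, targets)),
        "errors": errors,
        "max_abs_error": max(abs(e) for e in errors.values()),
        "anova_p": res.anova_p,
    }


def mechanism_recovery(seed: int, n_genes: int = 3000) -> dict:
    """Fraction of truly affected genes assigned their true mechanism
    class under the strong-effect / low-noise condition, per contrast."""
    design = CohortDesign(seed=seed, n_genes=n_genes, **STRONG_EFFECT_KWARGS)
    transcripts, proteins, mirna_de, target_map, truth = generate_omics_cohort(
        design, decoupling_targets=None
    )
    plog = proteins.to_log2()
    detected = set(transcripts.features)
    out = {}
    for a, b in zip(design.group_labels[1:], design.group_labels[:-1]):
        contrast = Contrast.from_groups(plog, a, b)
        classes = classify_mechanism(
            moderated_t_test(plog, contrast),
            count_differential(transcripts, contrast),
            detected,
            mirna_de,
            target_map,
        )
        merged = pd.concat(
            [classes["mechanism_class"], truth.mechanism_class.rename("true")],
            axis=1,
            join="inner",
        ).dropna()
        merged = merged[merged["true"] != "null"]
        out[contrast.label] = float((merged["mechanism_class"] == merged["true"]).mean())
    out["min_recovery"] = min(out.values())
    return out


def stoichiometry_operating_characteristics(
    seed: int,
    n_seeds: int = 40,
    n_complexes: int = 40,
    n_perturbed: int = 5,
    shift: float = 1.2,
    noise_sd: float = 0.2,
) -> dict:
    """Sensitivity (perturbed complexes flagged) and specificity (null
    complexes flagged) of the affected-complex call across seeds."""
    hits = total = false = null_total = 0
    for s in range(n_seeds):
        matrix, catalog, truth = generate_stoichiometry_experiment(
            n_complexes=n_complexes,
            perturbed_complexes=n_perturbed,
            n_members_perturbed=2,
            shift=shift,
            noise_sd=noise_sd,
            seed=seed + s,
        )
        contrast = Contrast.from_groups(matrix, "old", "young")
        res = call_affected(normalize_to_complex(matrix, catalog), contrast)
        flagged = set(res.table.index[res.table["is_affected"]])
        perturbed = set(truth.perturbed_complexes)
        hits += len(flagged & perturbed)
        total += len(perturbed)
        false += len(flagged - perturbed)
        null_total += len(res.table) - len(perturbed)
    return {
        "sensitivity": hits / total,
        "false_positive_rate": false / null_total,
    }


def sec_shift_power(
    seed: int,
    n_seeds: int = 100,
    shift: float = 3.0,
    noise_sd: float = 0.05,
    min_shift: float = 2.0,
) -> float:
    """Fraction of seeds in which an injected elution shift of the old
    condition is flagged by the center-of-mass detector."""
    catalog = ComplexCatalog({f"C{i}": {f"M{i}_{j}" for j in range(6)} for i in range(5)})
    flagged = 0
    for s in range(n_seeds):
        young, old, _ = generate_sec_profiles(
            catalog, shifts={"C0": shift}, noise_sd=noise_sd, seed=seed + s
        )
        yn, on = normalize_profiles(young), normalize_profiles(old)
        pa = complex_profile(yn, catalog.members("C0"))
        pb = complex_profile(on, catalog.members("C0"))
        flagged += detect_elution_shift(pa, pb, min_shift=min_shift).flagged
    return flagged / n_seeds


def cox_coefficient_recovery(seed: int, n_fish: int = 500, true_c: float = 1.0) -> dict:
    """Single-gene Cox fit at large n: fitted coefficient vs truth."""
    delta, surv, _ = generate_longitudinal_survival(
        n_fish, ["G0"], {"risk": {"genes": ["G0"], "c": true_c}}, seed=seed
    )
    fit = cox_fit_single(delta.data.iloc[0].to_numpy(), surv)
    return {"c_hat": fit.coef, "true_c": true_c, "abs_error": abs(fit.coef - true_c)}


def risk_set_detection_rate(
    seed: int,
    n_seeds: int = 50,
    n_fish: int = 159,
    n_genes: int = 300,
    set_size: int = 50,
    c: float = 0.8,
) -> float:
    """Fraction of seeds in which the coefficient-based set test flags
    the injected risk-gene set (adj p < 0.05, positive direction)."""
    from .differential import coefficient_set_test

    genes = [f"G{i:05d}" for i in range(n_genes)]
    risk = {"risk": {"genes": genes[:set_size], "c": c}}
    catalog = ComplexCatalog({"risk": set(genes[:set_size])})
    detected = 0
    for s in range(n_seeds):
        delta, surv, _ = generate_longitudinal_survival(
            n_fish, genes, risk, seed=seed + s
        )
        fits = genewise_cox(delta, surv)
        res = coefficient_set_test(fits["coef"], catalog)
        detected += bool(
            len(res) and res.loc["risk", "adj_p"] < 0.05 and res.loc["risk", "direction"] > 0
        )
    return detected / n_seeds


def aggregate_detection_rate(
    seed: int,
    n_seeds: int = 40,
    n_proteins: int = 500,
    shift: float = 2.0,
    noise_sd: float = 0.2,
) -> float:
    """Fraction of injected aggregate-enriched proteins recovered
    (p < 0.05 and log2 fc > 0.5) across seeds."""
    hits = total = 0
    for s in range(n_seeds):
        enriched = {f"P{i + 1:05d}" for i in range(30)}
        matrix, _, truth = generate_aggregate_experiment(
            n_proteins=n_proteins, enriched_set=enriched,
            shift_mean=shift, noise_sd=noise_sd, seed=seed + s,
        )
        _, called, _ = aggregate_enrichment(matrix)
        hits += len(called & set(truth.enriched_proteins))
        total += len(truth.enriched_proteins)
    return hits / total
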