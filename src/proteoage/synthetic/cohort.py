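"""Matched transcript/protein cohort generator with controllable
transcript-protein concordance and per-gene regulatory-mechanism classes.

The design emulates a three-age-group cohort (young / adult / old,
n per group ~5). Transcripts are negative-binomial counts around
log-normal gene means; proteins are log-normal intensities linked to the
same gene means through class-specific rules. Per-sample log-log
correlation between the two layers is controlled per group either by an
explicit target (the generator solves for the protein noise that achieves
it) or left free with a configurable measurement noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..containers import ComplexCatalog, OmicsMatrix
from .truth import SyntheticTruth

log = logging.getLogger(__name__)

LOG10_2 = np.log10(2.0)

DEFAULT_MECHANISM_FRACTIONS = {
    "concordant-significant": 0.35,
    "transcript-consistent": 0.20,
    "no-transcript": 0.15,
    "miRNA-candidate": 0.10,
    "other-post-transcriptional": 0.20,
}

#: per-group per-sample protein-transcript correlation structure of an
#: aging brain cohort: concordance declines from young to old
DEFAULT_DECOUPLING_TARGETS = (0.48, 0.43, 0.33)


@dataclass
class CohortDesign:
    """Cohort layout and gene/complex universe sizes."""

    n_groups: int = 3
    group_labels: tuple = ("young", "adult", "old")
    n_per_group: int = 5
    n_genes: int = 5000
    n_complexes: int = 40
    complex_size_range: tuple = (5, 60)
    seed: int = 0
    # generation knobs
    affected_fraction: float = 0.2
    effect_size_mean: float = 1.2  # |log2 fc| of affected proteins
    effect_size_sd: float = 0.2
    dispersion: float = 0.1  # NB gene-level dispersion
    gene_mean_log10: float = 1.5
    gene_sd_log10: float = 1.0
    protein_noise_sd: float = 0.1  # log2, per-sample measurement noise
    consistent_transcript_ratio: float = 0.35  # transcript fc as fraction of protein fc, class ii
    discordant_shift_mean: float = 0.4  # |log2| opposite-sign transcript fc, classes iv/v
    discordant_shift_sd: float = 0.1
    n_mirna: int = 60

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if len(self.group_labels) != self.n_groups:
            raise ValueError("group_labels must match n_groups")
        if self.complex_size_range[0] < 5:
            raise ValueError("complex sizes must be >= 5")

    @property
    def sample_ids(self) -> list[str]:
        return [f"{g}_{i + 1}" for g in self.group_labels for i in range(self.n_per_group)]

    def metadata(self) -> pd.DataFrame:
        rows = [
            (f"{g}_{i + 1}", g, f"fish_{g}_{i + 1}")
            for g in self.group_labels
            for i in range(self.n_per_group)
        ]
        meta = pd.DataFrame(rows, columns=["sample_id", "group", "animal"]).set_index("sample_id")
        return meta


class UnreachableCorrelation(ValueError):
    """Raised when a target per-sample correlation exceeds what the
    generated structure can achieve; carries the achievable value."""

    def __init__(self, group: str, target: float, achievable: float):
        self.group, self.target, self.achievable = group, target, achievable
        super().__init__(
            f"group {group!r}: target correlation {target:.3f} unreachable; "
            f"achievable maximum ~{achievable:.3f}"
        )


def _assign_classes(rng, n_genes: int, fractions: dict, affected_fraction: float) -> np.ndarray:
    fr = dict(fractions)
    total = sum(fr.values())
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"mechanism fractions must sum to 1, got {total}")
    n_affected = int(round(affected_fraction * n_genes))
    counts = {k: int(np.floor(v * n_affected)) for k, v in fr.items()}
    remainder = n_affected - sum(counts.values())
    for k in list(fr)[:remainder]:
        counts[k] += 1
    labels = np.array(
        [k for k, c in counts.items() for _ in range(c)] + ["null"] * (n_genes - n_affected),
        dtype=object,
    )
    return rng.permutation(labels)


def _nb_counts(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson mixture: Var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def generate_omics_cohort(
    design: CohortDesign,
    decoupling_targets: tuple | None = DEFAULT_DECOUPLING_TARGETS,
    mechanism_fractions: dict | None = None,
) -> tuple[OmicsMatrix, OmicsMatrix, pd.DataFrame, dict, SyntheticTruth]:
    """Generate matched transcript counts and protein intensities.

    Returns ``(transcripts, proteins, mirna_de, target_map, truth)``.

    When ``decoupling_targets`` is given (one correlation per group, in
    (0, 1)), the per-sample log-log Pearson correlation of the two layers
    is steered to the target by decomposing protein deviations into a
    stable per-gene post-transcriptional offset (shared by all groups,
    sized for the highest target) plus per-group per-sample noise solved
    analytically from the realized transcript statistics. Impossible
    targets raise :class:`UnreachableCorrelation` reporting the achievable
    value. With ``decoupling_targets=None`` protein noise is just
    ``design.protein_noise_sd`` per sample.
    """
    if mechanism_fractions is None:
        mechanism_fractions = DEFAULT_MECHANISM_FRACTIONS
    if decoupling_targets is not None:
        if len(decoupling_targets) != design.n_groups:
            raise ValueError("need one correlation target per group")
        if not all(0 < t < 1 for t in decoupling_targets):
            raise ValueError("correlation targets must lie in (0, 1)")

    rng = np.random.default_rng(design.seed)
    genes = np.array([f"G{i:05d}" for i in range(design.n_genes)])
    meta = design.metadata()
    samples = list(meta.index)
    groups = meta["group"]

    classes = _assign_classes(rng, design.n_genes, mechanism_fractions, design.affected_fraction)
    gene_mean = rng.normal(design.gene_mean_log10, design.gene_sd_log10, design.n_genes)

    # per-gene group shifts (log2): progressive with age so both contrasts
    # (adult vs young, old vs adult) see the class-consistent pattern
    protein_shift = np.zeros((design.n_genes, design.n_groups))
    transcript_shift = np.zeros((design.n_genes, design.n_groups))
    affected = classes != "null"
    signs = rng.choice([-1.0, 1.0], design.n_genes)
    signs[classes == "miRNA-candidate"] = -1.0  # canonical repressive action
    steps = np.abs(rng.normal(design.effect_size_mean, design.effect_size_sd, design.n_genes))
    small = np.abs(rng.normal(design.discordant_shift_mean, design.discordant_shift_sd, design.n_genes))
    for idx in range(design.n_genes):
        if not affected[idx]:
            continue
        cls = classes[idx]
        # cumulative protein trajectory: 0, delta, 2*delta across groups
        delta_p = signs[idx] * steps[idx]
        protein_shift[idx] = delta_p * np.arange(design.n_groups)
        if cls == "concordant-significant":
            transcript_shift[idx] = protein_shift[idx]
        elif cls == "transcript-consistent":
            # same direction, sized to stay below the significance
            # threshold of a count-based test at n~5
            transcript_shift[idx] = design.consistent_transcript_ratio * protein_shift[idx]
        elif cls in ("miRNA-candidate", "other-post-transcriptional"):
            # mildly discordant transcript (opposite sign), matching the
            # workflow that pools discordant and unregulated transcripts
            transcript_shift[idx] = -np.sign(delta_p) * small[idx] * np.arange(design.n_groups)
        # "no-transcript": transcript layer never sees this gene

    no_transcript = classes == "no-transcript"
    t_genes = genes[~no_transcript]

    # transcripts: NB counts around log-normal means with group shifts
    group_of = groups.to_numpy()
    group_index = {g: i for i, g in enumerate(design.group_labels)}
    counts = np.zeros((design.n_genes, len(samples)), dtype=np.int64)
    lib_factor = rng.lognormal(mean=0.0, sigma=0.08, size=len(samples))
    for j, s in enumerate(samples):
        gi = group_index[group_of[j]]
        mu = 10.0 ** (gene_mean + transcript_shift[:, gi] * LOG10_2) * lib_factor[j]
        counts[:, j] = _nb_counts(rng, mu, design.dispersion)
    counts_df = pd.DataFrame(counts, index=genes, columns=samples).loc[t_genes]

    # proteins: log10 mean = gene mean + shift + stable per-gene offset
    protein_offset = 3.0  # intensity scale
    sd_floor = design.protein_noise_sd * LOG10_2
    u = rng.normal(0.0, 1.0, design.n_genes)  # stable post-transcriptional offset shape

    if decoupling_targets is None:
        sigma_pt = 0.0
        noise_sd = {g: sd_floor for g in design.group_labels}
        achieved = None
    else:
        sigma_pt, noise_sd, achieved = _solve_noise(
            design, decoupling_targets, counts_df, gene_mean, protein_shift,
            no_transcript, sd_floor, group_index, groups,
        )

    protein = np.zeros((design.n_genes, len(samples)))
    for j, s in enumerate(samples):
        gi = group_index[group_of[j]]
        mean_log10 = gene_mean + protein_shift[:, gi] * LOG10_2 + protein_offset + sigma_pt * u
        protein[:, j] = 10.0 ** (mean_log10 + rng.normal(0.0, noise_sd[group_of[j]], design.n_genes))
    protein_df = pd.DataFrame(protein, index=genes, columns=samples)

    mirna_de, target_map = _generate_mirna_layer(rng, design, genes, classes)

    truth = SyntheticTruth(
        seed=design.seed,
        mechanism_class=pd.Series(classes, index=genes, name="mechanism_class"),
        protein_shift=pd.DataFrame(protein_shift, index=genes, columns=design.group_labels),
        transcript_shift=pd.DataFrame(
            transcript_shift, index=genes, columns=design.group_labels
        ),
        target_correlations=(
            dict(zip(design.group_labels, map(float, decoupling_targets)))
            if decoupling_targets is not None
            else None
        ),
        solved_noise={g: float(v) for g, v in noise_sd.items()},
        mirna_targets={m: sorted(t) for m, t in target_map.items()},
    )
    transcripts = OmicsMatrix(counts_df, kind="counts", meta=meta)
    proteins = OmicsMatrix(protein_df, kind="intensity", meta=meta)
    return transcripts, proteins, mirna_de, target_map, truth


def _solve_noise(design, targets, counts_df, gene_mean, protein_shift, no_transcript,
                 sd_floor, group_index, groups):
    """Solve the per-group per-sample protein noise that achieves the
    requested log-log correlations, given the realized transcript layer.

    Writes the stable per-gene offset variance from the most-concordant
    group, then tops each group up with i.i.d. sample noise.
    """
    present = ~no_transcript
    required_extra = {}
    var_pm = {}
    for g, r in zip(design.group_labels, targets):
        gi = group_index[g]
        cols = [s for s in counts_df.columns if groups[s] == g]
        p_mean = gene_mean[present] + protein_shift[present, gi] * np.log10(2.0)
        covs, var_ts, vpms = [], [], []
        for s in cols:
            c = counts_df[s].to_numpy(dtype=float)
            mask = c > 0  # the correlation readout masks zero counts per sample
            t_log = np.log10(c[mask])
            pm = p_mean[mask]
            covs.append(np.cov(t_log, pm)[0, 1])
            var_ts.append(t_log.var(ddof=1))
            vpms.append(pm.var(ddof=1))
        cov = float(np.mean(covs))
        var_t = float(np.mean(var_ts))
        vpm = float(np.mean(vpms))
        needed_total = cov**2 / (r**2 * var_t)  # Var_protein needed
        achievable = cov / np.sqrt(var_t * (vpm + sd_floor**2))
        if needed_total < vpm + sd_floor**2 - 1e-12:
            raise UnreachableCorrelation(g, r, float(achievable))
        required_extra[g] = needed_total - vpm
        var_pm[g] = vpm
    # stable offset sized for the most-concordant group (smallest extra)
    sigma_pt2 = max(min(required_extra.values()) - sd_floor**2, 0.0)
    noise_sd = {}
    achieved = {}
    for g in design.group_labels:
        extra = max(required_extra[g] - sigma_pt2, sd_floor**2)
        noise_sd[g] = float(np.sqrt(extra))
        achieved[g] = None
    return float(np.sqrt(sigma_pt2)), noise_sd, achieved


def _generate_mirna_layer(rng, design, genes, classes):
    """miRNA differential table plus miRNA -> target-gene map.

    Every miRNA-candidate gene is the target of at least one miRNA that is
    up-regulated (log2 fc > 0, adj p < 0.05); decoy miRNAs (down or null)
    target random genes so the map is not informative by itself.
    """
    n_up = max(design.n_mirna // 3, 1)
    ids = np.array([f"mir-{i + 1}" for i in range(design.n_mirna)])
    up = ids[:n_up]
    fc = np.concatenate(
        [
            np.abs(rng.normal(1.0, 0.3, n_up)),
            -np.abs(rng.normal(1.0, 0.3, design.n_mirna - n_up)) * rng.choice(
                [0.0, 1.0], design.n_mirna - n_up
            ),
        ]
    )
    adj_p = np.where(fc != 0, rng.uniform(1e-6, 0.04, design.n_mirna), rng.uniform(0.2, 1.0, design.n_mirna))
    mirna_de = pd.DataFrame({"log2fc": fc, "adj_p": adj_p}, index=pd.Index(ids, name="mirna_id"))

    target_map: dict[str, set] = {m: set() for m in ids}
    candidates = genes[classes == "miRNA-candidate"]
    for gene in candidates:
        chosen = rng.choice(up, size=rng.integers(1, min(3, len(up)) + 1), replace=False)
        for m in chosen:
            target_map[m].add(gene)
    # decoy targets: random non-candidate genes (never down-regulated
    # proteins lacking transcript signal would confound class v; restrict
    # decoys to null and concordant genes)
    decoy_pool = genes[(classes == "null") | (classes == "concordant-significant")]
    for m in ids:
        extra = rng.choice(decoy_pool, size=min(20, len(decoy_pool)), replace=False)
        target_map[m].update(extra)
    return mirna_de, {m: t for m, t in target_map.items() if t}


def generate_complex_catalog(
    design: CohortDesign,
    feature_ids,
    rng: np.random.Generator | None = None,
) -> ComplexCatalog:
    """Random protein-complex catalog over ``feature_ids`` with sizes drawn
    uniformly from the design's size range (all >= 5). Members are drawn
    without replacement per complex; complexes may overlap."""
    if rng is None:
        rng = np.random.default_rng(design.seed + 1)
    feature_ids = np.asarray(list(feature_ids))
    lo, hi = design.complex_size_range
    sets = {}
    for i in range(design.n_complexes):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(feature_ids))
        members = rng.choice(feature_ids, size=size, replace=False)
        sets[f"CPX{i + 1:03d}"] = set(members.tolist())
    return ComplexCatalog(sets, {k: "synthetic complex" for k in sets})
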