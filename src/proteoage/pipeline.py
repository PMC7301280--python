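"""Configuration handling and the end-to-end synthetic pipeline driver.

``run_pipeline`` executes the requested stages in dependency order on a
synthetic cohort, writes every stage's tables under the output directory,
and emits a provenance manifest (config, seed, package versions) that
suffices to reproduce the run byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .containers import Contrast, OmicsMatrix
from .differential import coefficient_set_test, count_differential, moderated_t_test
from .decoupling import classify_mechanism, concordance_quadrants, per_sample_correlation
from .aggregates import (
    aggregate_enrichment,
    clever_score,
    compare_extremes,
    s2d_score,
    set_enrichment_in_aggregates,
)
from .sec_coelution import (
    complex_profile,
    detect_elution_shift,
    normalize_profiles,
    random_complex_null,
)
from .stoichiometry import call_affected, complex_iqr, normalize_to_complex, rank_iqr_difference
from .survival import extreme_group_logrank, genewise_cox
from .synthetic import (
    CohortDesign,
    generate_aggregate_experiment,
    generate_complex_catalog,
    generate_omics_cohort,
    generate_longitudinal_survival,
    generate_sec_profiles,
)

log = logging.getLogger(__name__)

ALL_STAGES = ("cohort", "differential", "decoupling", "stoichiometry", "sec", "aggregates", "survival")

#: stage -> stages it needs
_DEPENDS = {
    "differential": ("cohort",),
    "decoupling": ("cohort", "differential"),
    "stoichiometry": ("cohort", "differential"),
    "sec": ("cohort",),
    "aggregates": (),
    "survival": (),
}


@dataclass
class PipelineConfig:
    stages: tuple = ALL_STAGES
    seed: int = 0
    outdir: str = "proteoage_run"
    log_level: str = "INFO"
    cohort: dict = field(default_factory=dict)  # CohortDesign overrides
    decoupling_targets: tuple | None = (0.48, 0.43, 0.33)
    adj_p: float = 0.05
    sec: dict = field(default_factory=lambda: {"n_fractions": 39, "shift": 5.0, "n_shifted": 3, "n_draws": 200})
    aggregates: dict = field(default_factory=lambda: {"n_proteins": 2000, "n_enriched": 100})
    survival: dict = field(default_factory=lambda: {"n_fish": 159, "n_genes": 300, "risk_c": 0.1, "risk_size": 50, "k": 32})

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "decoupling_targets" in raw and raw["decoupling_targets"] is not None:
            raw["decoupling_targets"] = tuple(raw["decoupling_targets"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["stages"] = list(payload["stages"])
        if payload["decoupling_targets"] is not None:
            payload["decoupling_targets"] = list(payload["decoupling_targets"])
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the top-level seed."""
    return (seed * 1000003 + ALL_STAGES.index(stage) + 1) % (2**31)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the requested stages; returns a dict of in-memory results and
    writes all tables plus a provenance manifest under ``config.outdir``."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    requested = list(config.stages)
    for stage in requested:
        if stage not in ALL_STAGES:
            raise ValueError(f"unknown stage {stage!r}")
    # close over dependencies, keep canonical order
    needed = set(requested)
    for stage in requested:
        needed.update(_DEPENDS.get(stage, ()))
    stages = [s for s in ALL_STAGES if s in needed]

    results: dict = {}
    manifest = {
        "package_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "stages": stages,
        "config": dataclasses.asdict(config),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in stages},
    }

    try:
        for stage in stages:
            log.info("running stage %s", stage)
            _RUNNERS[stage](config, results, outdir)
    except Exception:
        manifest["status"] = "failed"
        _write_manifest(manifest, outdir)
        raise
    manifest["status"] = "complete"
    _write_manifest(manifest, outdir)
    return results


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)


def _run_cohort(config: PipelineConfig, results: dict, outdir: Path) -> None:
    design = CohortDesign(seed=stage_seed(config.seed, "cohort"), **config.cohort)
    transcripts, proteins, mirna_de, target_map, truth = generate_omics_cohort(
        design, decoupling_targets=config.decoupling_targets
    )
    catalog = generate_complex_catalog(design, proteins.features)
    results.update(
        design=design, transcripts=transcripts, proteins=proteins,
        mirna_de=mirna_de, target_map=target_map, cohort_truth=truth, catalog=catalog,
    )
    io.write_matrix(transcripts, outdir / "transcript_counts.tsv", stage="cohort")
    io.write_matrix(proteins, outdir / "protein_intensity.tsv", stage="cohort")
    io.write_sample_metadata(transcripts.meta, outdir / "sample_metadata.tsv")
    mirna_de.to_csv(outdir / "mirna_differential.tsv", sep="\t")
    io.write_gmt(catalog, outdir / "complexes.gmt")
    with open(outdir / "mirna_targets.tsv", "w") as fh:
        fh.write("mirna_id\tgene_id\n")
        for mirna, targets in target_map.items():
            for gene in sorted(targets):
                fh.write(f"{mirna}\t{gene}\n")
    truth.to_json(outdir / "cohort_truth.json")


def _contrasts(design) -> list[Contrast]:
    labels = design.group_labels
    meta = design.metadata()
    out = []
    for young, old in zip(labels[:-1], labels[1:]):
        a = [s for s in meta.index if meta.loc[s, "group"] == old]
        b = [s for s in meta.index if meta.loc[s, "group"] == young]
        out.append(Contrast(tuple(a), tuple(b), label=f"{old}vs{young}"))
    return out


def _run_differential(config: PipelineConfig, results: dict, outdir: Path) -> None:
    design = results["design"]
    protein_log2 = results["proteins"].to_log2()
    transcript_de, protein_de = {}, {}
    for contrast in _contrasts(design):
        transcript_de[contrast.label] = count_differential(results["transcripts"], contrast)
        protein_de[contrast.label] = moderated_t_test(protein_log2, contrast)
        transcript_de[contrast.label].to_csv(
            outdir / f"transcript_de_{contrast.label}.tsv", sep="\t"
        )
        protein_de[contrast.label].to_csv(outdir / f"protein_de_{contrast.label}.tsv", sep="\t")
    results.update(transcript_de=transcript_de, protein_de=protein_de, protein_log2=protein_log2)


def _run_decoupling(config: PipelineConfig, results: dict, outdir: Path) -> None:
    corr = per_sample_correlation(results["proteins"], results["transcripts"])
    corr.per_sample.to_csv(outdir / "per_sample_correlation.tsv", sep="\t")
    detected = set(results["transcripts"].features)
    summary_rows = []
    classifications = {}
    for label, p_de in results["protein_de"].items():
        t_de = results["transcript_de"][label]
        quad = concordance_quadrants(p_de, t_de, adj_p_threshold=config.adj_p)
        classes = classify_mechanism(
            p_de, t_de, detected, results["mirna_de"], results["target_map"], adj_p=config.adj_p
        )
        classes.to_csv(outdir / f"mechanism_classes_{label}.tsv", sep="\t")
        classifications[label] = classes
        summary_rows.append({"contrast": label, "r_joint": quad["r"], **quad["counts"]})
    pd.DataFrame(summary_rows).to_csv(outdir / "quadrant_summary.tsv", sep="\t", index=False)
    results.update(correlation=corr, mechanism=classifications)


def _run_stoichiometry(config: PipelineConfig, results: dict, outdir: Path) -> None:
    normalized = normalize_to_complex(results["protein_log2"], results["catalog"])
    calls, iqrs = {}, {}
    for contrast in _contrasts(results["design"]):
        res = call_affected(normalized, contrast, adj_p=config.adj_p)
        res.table.to_csv(outdir / f"stoichiometry_calls_{contrast.label}.tsv", sep="\t")
        calls[contrast.label] = res
        fcs = res.members["log2fc"].reset_index("complex_id", drop=True)
        iqrs[contrast.label] = complex_iqr(
            fcs.groupby(level=0).first(), results["catalog"]
        )
    labels = list(iqrs)
    if len(labels) >= 2:
        ranking, fraction = rank_iqr_difference(iqrs[labels[0]], iqrs[labels[1]])
        ranking.to_csv(outdir / "iqr_ranking.tsv", sep="\t")
        results["iqr_fraction_increased"] = fraction
    results.update(stoichiometry=calls, iqr=iqrs)


def _run_sec(config: PipelineConfig, results: dict, outdir: Path) -> None:
    params = dict(config.sec)
    catalog = results["catalog"]
    shifted = catalog.names()[: int(params.get("n_shifted", 3))]
    shifts = {name: float(params.get("shift", 5.0)) for name in shifted}
    young, old, truth = generate_sec_profiles(
        catalog,
        n_fractions=int(params.get("n_fractions", 39)),
        shifts=shifts,
        seed=stage_seed(config.seed, "sec"),
    )
    io.write_sec_matrix(young, outdir / "sec_young.tsv")
    io.write_sec_matrix(old, outdir / "sec_old.tsv")
    young_n, old_n = normalize_profiles(young), normalize_profiles(old)
    null = random_complex_null(
        young_n, catalog, n_draws=int(params.get("n_draws", 200)),
        seed=stage_seed(config.seed, "sec"),
    )
    rows = []
    for name in catalog.names():
        members = catalog.members(name)
        try:
            pa = complex_profile(young_n, members)
            pb = complex_profile(old_n, members)
        except ValueError:
            continue
        shift = detect_elution_shift(pa, pb)
        rows.append((name, shift.apex_shift, shift.com_shift, shift.flagged, name in shifts))
    table = pd.DataFrame(
        rows, columns=["complex_id", "apex_shift", "com_shift", "flagged", "injected"]
    ).set_index("complex_id")
    table.to_csv(outdir / "sec_shifts.tsv", sep="\t")
    results.update(sec_null=null, sec_shifts=table, sec_truth=truth)


def _run_aggregates(config: PipelineConfig, results: dict, outdir: Path) -> None:
    params = dict(config.aggregates)
    n_proteins = int(params.get("n_proteins", 2000))
    n_enriched = int(params.get("n_enriched", 100))
    rng = np.random.default_rng(stage_seed(config.seed, "aggregates"))
    proteins = [f"P{i + 1:05d}" for i in range(n_proteins)]
    enriched_truth = set(rng.choice(proteins, size=n_enriched, replace=False).tolist())
    matrix, scores, truth = generate_aggregate_experiment(
        n_proteins=n_proteins,
        enriched_set=enriched_truth,
        seed=stage_seed(config.seed, "aggregates"),
    )
    de, enriched, depleted = aggregate_enrichment(matrix)
    de.to_csv(outdir / "aggregate_enrichment.tsv", sep="\t")
    signed = scores.apply(
        lambda r: clever_score(r["clever_label"], r["clever_P"])
        if r["clever_label"] != "indeterminate"
        else 0.0,
        axis=1,
    )
    disorder = scores.apply(lambda r: s2d_score(r["n_coil"], r["n_residues"]), axis=1)
    ks_clever = compare_extremes(de["log2fc"], signed)
    ks_s2d = compare_extremes(de["log2fc"], disorder)
    results.update(
        aggregate_de=de, aggregate_enriched=enriched, aggregate_truth=truth,
        ks_clever=ks_clever, ks_s2d=ks_s2d,
    )


def _run_survival(config: PipelineConfig, results: dict, outdir: Path) -> None:
    params = dict(config.survival)
    n_genes = int(params.get("n_genes", 300))
    size = int(params.get("risk_size", 50))
    genes = [f"G{i:05d}" for i in range(n_genes)]
    risk = {"risk_set": {"genes": genes[:size], "c": float(params.get("risk_c", 0.8))}}
    delta, surv, truth = generate_longitudinal_survival(
        n_fish=int(params.get("n_fish", 159)),
        genes=genes,
        risk_sets=risk,
        seed=stage_seed(config.seed, "survival"),
    )
    io.write_matrix(delta, outdir / "delta_expression.tsv", stage="survival")
    io.write_survival(surv, outdir / "lifespans.tsv")
    fits = genewise_cox(delta, surv)
    fits.to_csv(outdir / "cox_fits.tsv", sep="\t")
    from .containers import ComplexCatalog

    catalog = ComplexCatalog({"risk_set": set(risk["risk_set"]["genes"])})
    set_test = coefficient_set_test(fits["coef"], catalog)
    logrank = extreme_group_logrank(delta, surv, risk["risk_set"]["genes"], k=int(params.get("k", 32)))
    results.update(
        cox_fits=fits, survival_truth=truth, risk_set_test=set_test, logrank=logrank,
        delta=delta, survival_data=surv,
    )


_RUNNERS = {
    "cohort": _run_cohort,
    "differential": _run_differential,
    "decoupling": _run_decoupling,
    "stoichiometry": _run_stoichiometry,
    "sec": _run_sec,
    "aggregates": _run_aggregates,
    "survival": _run_survival,
}
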