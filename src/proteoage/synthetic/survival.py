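"""Synthetic longitudinal expression-to-mortality data.

Lifespans are drawn from the proportional-hazards model
``h(t | delta) = h0(t) * exp(sum_i c_i * delta_ij)`` by inverse-transform
sampling on an exponential baseline, conditional on survival past the
second sampling time (all fish in the analysis set are alive at entry).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..containers import FishSurvival, OmicsMatrix
from .truth import SyntheticTruth


def generate_longitudinal_survival(
    n_fish: int = 159,
    genes: int | list = 1000,
    risk_sets: dict | None = None,
    baseline_rate: float = 0.07,
    entry_time: float = 20.0,
    delta_sd: float = 1.0,
    seed: int = 0,
) -> tuple[OmicsMatrix, FishSurvival, SyntheticTruth]:
    """Generate a per-fish expression-change matrix and lifespans.

    ``risk_sets`` maps set names to ``{"genes": [...], "c": coefficient}``;
    the per-fish log hazard ratio is the sum of c * delta over all risk
    genes. ``baseline_rate`` is the exponential hazard per week after
    entry. Returns (delta matrix genes x fish, survival records, truth).
    """
    rng = np.random.default_rng(seed)
    if isinstance(genes, int):
        gene_ids = [f"G{i:05d}" for i in range(genes)]
    else:
        gene_ids = list(genes)
    risk_sets = dict(risk_sets or {})
    coef = pd.Series(0.0, index=gene_ids)
    for name, spec in risk_sets.items():
        c = float(spec["c"])
        if not np.isfinite(c):
            raise ValueError(f"risk set {name!r}: non-finite coefficient")
        members = [g for g in spec["genes"] if g in coef.index]
        coef.loc[members] += c

    fish_ids = [f"fish_{i + 1:03d}" for i in range(n_fish)]
    delta = rng.normal(0.0, delta_sd, size=(len(gene_ids), n_fish))
    delta_df = pd.DataFrame(delta, index=gene_ids, columns=fish_ids)

    lp = coef.to_numpy() @ delta  # per-fish linear predictor
    # exponential baseline is memoryless: residual life after entry is
    # exponential with rate baseline_rate * exp(lp)
    u = rng.uniform(size=n_fish)
    lifespan = entry_time - np.log(u) / (baseline_rate * np.exp(lp))
    surv = FishSurvival(
        pd.DataFrame(
            {
                "lifespan": lifespan,
                "event": np.ones(n_fish, dtype=int),
                "entry_time": np.full(n_fish, entry_time),
            },
            index=pd.Index(fish_ids, name="fish_id"),
        )
    )
    meta = pd.DataFrame(
        {"group": ["fish"] * n_fish}, index=pd.Index(fish_ids, name="sample_id")
    )
    matrix = OmicsMatrix(delta_df, kind="log2", meta=meta)
    truth = SyntheticTruth(
        seed=seed,
        cox_coefficients=coef,
        baseline_rate=float(baseline_rate),
        risk_sets={
            name: {"genes": sorted(spec["genes"]), "c": float(spec["c"])}
            for name, spec in risk_sets.items()
        },
    )
    return matrix, surv, truth
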