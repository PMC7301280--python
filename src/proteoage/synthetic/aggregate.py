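"""Synthetic SDS-insoluble aggregate experiment: total-homogenate vs
pellet intensities with injectable enrichment, plus correlated (or
independent) biophysical-classifier outputs per protein.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..containers import OmicsMatrix
from .truth import SyntheticTruth


def generate_aggregate_experiment(
    n_proteins: int = 2000,
    enriched_set: set | None = None,
    score_link: str = "linked",
    n_replicates: int = 3,
    shift_mean: float = 1.0,
    shift_sd: float = 0.3,
    noise_sd: float = 0.3,
    seed: int = 0,
    shifts: dict | None = None,
) -> tuple[OmicsMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate a log2 protein x sample matrix (TH and Pellet replicates)
    and per-protein biophysical classifier outputs.

    Proteins in ``enriched_set`` receive a pellet-vs-homogenate log2 shift
    drawn around ``shift_mean`` (overridable per protein via ``shifts``).
    ``score_link='linked'`` makes the classifier outputs (chaperone-
    requirement label and probability; random-coil counts) increase with
    the injected enrichment; ``'none'`` renders them independent.
    """
    if score_link not in ("linked", "none"):
        raise ValueError("score_link must be 'linked' or 'none'")
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates per sample group")
    rng = np.random.default_rng(seed)
    proteins = np.array([f"P{i + 1:05d}" for i in range(n_proteins)])
    enriched_set = set(enriched_set or set())
    unknown = enriched_set - set(proteins)
    if unknown:
        raise ValueError(f"enriched_set contains unknown proteins: {sorted(unknown)[:5]}")

    baseline = rng.normal(25.0, 2.0, n_proteins)
    shift = np.zeros(n_proteins)
    is_enriched = np.isin(proteins, list(enriched_set))
    shift[is_enriched] = rng.normal(shift_mean, shift_sd, int(is_enriched.sum()))
    if shifts:
        for pid, value in shifts.items():
            shift[np.where(proteins == pid)[0][0]] = value

    columns, blocks = [], []
    for r in range(n_replicates):
        columns.append(f"TH_{r + 1}")
        blocks.append(baseline + rng.normal(0.0, noise_sd, n_proteins))
    for r in range(n_replicates):
        columns.append(f"Pellet_{r + 1}")
        blocks.append(baseline + shift + rng.normal(0.0, noise_sd, n_proteins))
    data = pd.DataFrame(np.column_stack(blocks), index=proteins, columns=columns)
    meta = pd.DataFrame(
        {
            "label": [c.split("_")[0] for c in columns],
            "replicate": [c.split("_")[1] for c in columns],
            "group": [c.split("_")[0] for c in columns],
        },
        index=pd.Index(columns, name="sample_id"),
    )
    matrix = OmicsMatrix(data, kind="log2", meta=meta)

    # biophysical classifier outputs
    if score_link == "linked":
        latent = shift + rng.normal(0.0, 0.5, n_proteins)
    else:
        latent = rng.normal(0.0, 1.0, n_proteins)
    prob = 0.5 + 0.5 / (1.0 + np.exp(-1.5 * np.abs(latent)))  # in (0.5, 1)
    label = np.where(latent > 0.2, "positive", np.where(latent < -0.2, "negative", "indeterminate"))
    n_residues = rng.integers(100, 1000, n_proteins)
    coil_frac = 1.0 / (1.0 + np.exp(-(latent - 1.0)))
    n_coil = np.minimum((coil_frac * n_residues).astype(int), n_residues)
    scores = pd.DataFrame(
        {
            "clever_label": label,
            "clever_P": np.where(label == "indeterminate", np.nan, prob),
            "n_coil": n_coil,
            "n_residues": n_residues,
        },
        index=pd.Index(proteins, name="protein_id"),
    )
    truth = SyntheticTruth(
        seed=seed,
        enriched_proteins={p: float(s) for p, s in zip(proteins, shift) if s != 0.0},
        score_link=score_link,
    )
    return matrix, scores, truth
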