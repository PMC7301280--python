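"""Synthetic protein-complex stoichiometry experiment.

Generates a log2 intensity matrix whose complex members co-vary around a
shared complex abundance, then perturbs the stoichiometry of selected
complexes by shifting a subset of members in one group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..containers import ComplexCatalog, OmicsMatrix
from .truth import SyntheticTruth


def generate_stoichiometry_experiment(
    n_complexes: int = 100,
    members_range: tuple = (5, 12),
    n_per_group: int = 4,
    group_labels: tuple = ("young", "old"),
    perturbed_complexes: int = 0,
    n_members_perturbed: int = 2,
    shift: float = 1.2,
    noise_sd: float = 0.2,
    complex_sd: float = 0.5,
    seed: int = 0,
) -> tuple[OmicsMatrix, ComplexCatalog, SyntheticTruth]:
    """Log2 protein matrix with complex-membership covariance and
    injectable stoichiometry perturbations.

    Every member's log2 abundance is (complex abundance) + (member
    offset) + noise; the complex abundance varies per sample (shared by
    all members, so it cancels under complex-relative normalization).
    The first ``perturbed_complexes`` complexes get
    ``n_members_perturbed`` members shifted by ``shift`` log2 units in
    the last group. Perturbed complexes always have >= 2 shifted members
    unless explicitly asked otherwise.
    """
    rng = np.random.default_rng(seed)
    samples = [f"{g}_{i + 1}" for g in group_labels for i in range(n_per_group)]
    meta = pd.DataFrame(
        {"group": [s.rsplit("_", 1)[0] for s in samples]},
        index=pd.Index(samples, name="sample_id"),
    )
    last_group = group_labels[-1]
    last_cols = [j for j, s in enumerate(samples) if meta.loc[s, "group"] == last_group]

    rows, index = [], []
    sets: dict[str, set] = {}
    perturbed: dict[str, dict] = {}
    pid = 0
    for ci in range(n_complexes):
        name = f"CPX{ci + 1:03d}"
        size = int(rng.integers(*members_range))
        members = [f"P{pid + k:05d}" for k in range(size)]
        pid += size
        sets[name] = set(members)
        complex_abundance = rng.normal(20.0, 1.0) + rng.normal(0.0, complex_sd, len(samples))
        member_offset = rng.normal(0.0, 1.0, size)
        block = complex_abundance[None, :] + member_offset[:, None] + rng.normal(
            0.0, noise_sd, (size, len(samples))
        )
        if ci < perturbed_complexes:
            chosen = list(rng.choice(size, size=n_members_perturbed, replace=False))
            for k in chosen:
                block[k, last_cols] += shift
            perturbed[name] = {members[k]: float(shift) for k in chosen}
        rows.append(block)
        index.extend(members)
    data = pd.DataFrame(np.vstack(rows), index=index, columns=samples)
    matrix = OmicsMatrix(data, kind="log2", meta=meta)
    catalog = ComplexCatalog(sets)
    truth = SyntheticTruth(seed=seed, perturbed_complexes=perturbed)
    return matrix, catalog, truth
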