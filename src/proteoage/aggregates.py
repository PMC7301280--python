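"""Protein-aggregate enrichment analysis and biophysical scoring.

The pellet-vs-total-homogenate contrast identifies proteins enriched in
SDS-insoluble aggregates (quantile-normalized log2 intensities, moderated
differential test, p < 0.05 and log2 fc > 0.5). Sequence-derived
biophysical scores — a signed chaperone-requirement classifier
probability and the random-coil residue fraction — are compared between
the most and least enriched proteins, and catalog sets are tested for
over-representation among the enriched.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ComplexCatalog, Contrast, OmicsMatrix
from .differential import bh_adjust, moderated_t_test


def quantile_normalize(matrix: OmicsMatrix) -> OmicsMatrix:
    """Force every sample column onto the common reference distribution
    (the mean of the per-column sorted values); ties receive the average
    of their reference values; missing values keep their position and are
    excluded from the reference. Idempotent."""
    values = matrix.data.to_numpy(dtype=float)
    n_rows, n_cols = values.shape
    counts = (~np.isnan(values)).sum(axis=0)
    if (counts == 0).any():
        raise ValueError("column with no observed values")

    # reference quantile function on a common grid of n_rows points;
    # per-column sorted vectors are linearly stretched onto the grid
    grid = np.arange(n_rows, dtype=float)
    stretched = np.empty((n_rows, n_cols))
    for j in range(n_cols):
        obs = np.sort(values[~np.isnan(values[:, j]), j])
        src = np.linspace(0, n_rows - 1, num=obs.size)
        stretched[:, j] = np.interp(grid, src, obs)
    reference = stretched.mean(axis=1)

    out = np.full_like(values, np.nan)
    for j in range(n_cols):
        mask = ~np.isnan(values[:, j])
        col = values[mask, j]
        ranks = stats.rankdata(col, method="average")  # 1..n_obs, ties averaged
        positions = (ranks - 1) * (n_rows - 1) / max(col.size - 1, 1)
        out[mask, j] = np.interp(positions, grid, reference)
    return OmicsMatrix(
        pd.DataFrame(out, index=matrix.features, columns=matrix.samples),
        kind="log2",
        meta=matrix.meta,
    )


def filter_min_replicates(matrix: OmicsMatrix, min_per_group: int = 2) -> OmicsMatrix:
    """Keep proteins quantified (non-missing) in at least
    ``min_per_group`` replicates of every sample group."""
    groups = matrix.groups()
    keep = pd.Series(True, index=matrix.features)
    for group in groups.unique():
        cols = matrix.samples_in_group(group)
        keep &= matrix.data[cols].notna().sum(axis=1) >= min_per_group
    return OmicsMatrix(matrix.data.loc[keep], kind=matrix.kind, meta=matrix.meta)


def aggregate_enrichment(
    exp: OmicsMatrix,
    p_threshold: float = 0.05,
    fc_threshold: float = 0.5,
    pellet_label: str = "Pellet",
    th_label: str = "TH",
) -> tuple[pd.DataFrame, set, set]:
    """Pellet vs total-homogenate moderated differential on the
    quantile-normalized log2 matrix. Enriched proteins pass p below
    ``p_threshold`` with log2 fc above ``fc_threshold`` (depleted is
    symmetric). Returns (differential table, enriched set, depleted set).
    """
    filtered = filter_min_replicates(exp)
    normalized = quantile_normalize(filtered)
    complete = normalized.data.notna().all(axis=1)
    tested = OmicsMatrix(normalized.data.loc[complete], kind="log2", meta=normalized.meta)
    contrast = Contrast.from_groups(tested, pellet_label, th_label, label="PelletvsTH")
    de = moderated_t_test(tested, contrast)
    enriched = set(de.index[(de["p"] < p_threshold) & (de["log2fc"] > fc_threshold)])
    depleted = set(de.index[(de["p"] < p_threshold) & (de["log2fc"] < -fc_threshold)])
    return de, enriched, depleted


def clever_score(label: str, P: float | None = None) -> float:
    """Signed classification probability: -P if negative, 0 if
    indeterminate, +P if positive (P in [0.5, 1])."""
    if label == "indeterminate":
        return 0.0
    if label not in ("positive", "negative"):
        raise ValueError(f"unknown label {label!r}")
    if P is None or not 0.5 <= P <= 1.0:
        raise ValueError(f"classification probability must lie in [0.5, 1], got {P}")
    return float(P) if label == "positive" else -float(P)


def s2d_score(n_coil: int, n_residues: int) -> float:
    """Disorder score: fraction of residues predicted in random-coil
    conformation, n_c / N."""
    if n_residues <= 0:
        raise ValueError("n_residues must be positive")
    if not 0 <= n_coil <= n_residues:
        raise ValueError("need 0 <= n_coil <= n_residues")
    return n_coil / n_residues


def compare_extremes(
    enrichment: pd.Series,
    scores: pd.Series,
    quantile: float = 0.2,
) -> dict:
    """Two-sample Kolmogorov-Smirnov comparison of score distributions in
    the top vs bottom ``quantile`` of proteins ranked by aggregate
    enrichment."""
    joined = pd.concat([enrichment.rename("fc"), scores.rename("score")], axis=1).dropna()
    n = len(joined)
    k = int(np.floor(n * quantile))
    if k < 10:
        raise ValueError(f"need >= 10 proteins per tail, have {k}")
    if 2 * k > n:
        raise ValueError("tails overlap: quantile too large for input size")
    ranked = joined.sort_values("fc")
    bottom = ranked["score"].iloc[:k].to_numpy()
    top = ranked["score"].iloc[-k:].to_numpy()
    stat, p = stats.ks_2samp(top, bottom)
    return {"statistic": float(stat), "p": float(p), "n_per_tail": k}


def set_enrichment_in_aggregates(
    enriched: set,
    universe: set,
    catalog: ComplexCatalog,
    member_fc: pd.Series | None = None,
    min_members_ranked: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-sided Fisher exact test per catalog set on the (in-set x
    enriched) 2x2 table, BH-adjusted; plus a ranking of complexes by the
    median aggregate enrichment (log2 fc) of their members, restricted to
    complexes with at least ``min_members_ranked`` quantified members."""
    enriched = set(enriched)
    universe = set(universe)
    if not enriched <= universe:
        raise ValueError("enriched set must be a subset of the universe")
    rows = []
    for name, members in catalog.items():
        in_set = members & universe
        if not in_set:
            continue
        a = len(in_set & enriched)
        b = len(in_set) - a
        c = len(enriched) - a
        d = len(universe) - len(in_set) - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((name, len(in_set), a, float(p)))
    fisher = pd.DataFrame(rows, columns=["set_id", "set_size", "hits", "p"]).set_index("set_id")
    if len(fisher):
        fisher["adj_p"] = bh_adjust(fisher["p"].to_numpy())
        fisher = fisher.sort_values("p")

    ranking = pd.DataFrame(columns=["n_members", "median_log2fc"])
    if member_fc is not None:
        fc = member_fc.dropna()
        rows = []
        for name, members in catalog.items():
            present = fc.index.intersection(members)
            if len(present) < min_members_ranked:
                continue
            rows.append((name, len(present), float(fc.loc[present].median())))
        ranking = (
            pd.DataFrame(rows, columns=["set_id", "n_members", "median_log2fc"])
            .set_index("set_id")
            .sort_values("median_log2fc", ascending=False)
        )
    return fisher, ranking


def two_sample_t(values_a, values_b) -> tuple[float, float]:
    """Plain unpaired two-sample t-test on supplied numeric vectors (used
    for e.g. gel-densitometry yield comparisons)."""
    t, p = stats.ttest_ind(np.asarray(values_a, float), np.asarray(values_b, float))
    return float(t), float(p)


def presence_filter(
    evidence: pd.DataFrame,
    min_unique_peptides: int = 2,
    min_replicates: int = 1,
) -> list:
    """Identification filter over a protein-evidence table with columns
    ``protein_id``, ``replicate``, ``n_unique_peptides``: keep proteins
    with at least ``min_unique_peptides`` in at least ``min_replicates``
    replicates."""
    ok = evidence[evidence["n_unique_peptides"] >= min_unique_peptides]
    counts = ok.groupby("protein_id")["replicate"].nunique()
    return sorted(counts.index[counts >= min_replicates])
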