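"""Protein-complex stoichiometry analysis.

Member abundances are expressed relative to their complex (subtracting
the trimmed-mean member log2 intensity per sample), member-level
differential testing on the complex-relative values calls affected
members and complexes, and the interquartile range of member fold
changes quantifies stoichiometry loss per complex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ComplexCatalog, Contrast, OmicsMatrix
from .differential import bh_adjust, moderated_t_test

log = logging.getLogger(__name__)


def trimmed_mean(values, trim: float = 0.2) -> float:
    """Symmetric trimmed mean dropping ``trim``/2 of the values in each
    tail, with at least one value dropped per tail once n >= 5."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        raise ValueError("trimmed mean of empty input")
    k = int(np.floor(n * trim / 2.0))
    if n >= 5:
        k = max(k, 1)
    if 2 * k >= n:
        raise ValueError(f"trim {trim} leaves no values at n={n}")
    return float(v[k : n - k].mean())


def normalize_to_complex(
    matrix: OmicsMatrix,
    catalog: ComplexCatalog,
    trim: float = 0.2,
    min_members: int = 5,
) -> OmicsMatrix:
    """Complex-relative log2 matrix: per sample and complex, subtract the
    trimmed mean of quantified member log2 intensities from each member.

    Output rows are (complex, member) pairs — a protein belonging to
    several complexes contributes one row per complex. Complexes with
    fewer than ``min_members`` quantified members are skipped (logged).
    """
    if matrix.kind != "log2":
        raise ValueError("normalize_to_complex expects a log2 matrix")
    blocks, keys = [], []
    features = set(matrix.features)
    for name in catalog.names():
        members = sorted(catalog.members(name) & features)
        if len(members) < min_members:
            log.info("complex %s: %d members quantified (<%d), skipped", name, len(members), min_members)
            continue
        sub = matrix.data.loc[members]
        centers = sub.apply(lambda col: trimmed_mean(col, trim), axis=0)
        blocks.append(sub - centers)
        keys.extend((name, m) for m in members)
    if not blocks:
        raise ValueError("no complex reached the member floor")
    out = pd.concat(blocks)
    out.index = pd.MultiIndex.from_tuples(keys, names=["complex_id", "feature_id"])
    return OmicsMatrix(out, kind="log2", meta=matrix.meta)


@dataclass
class ComplexStoichResult:
    table: pd.DataFrame  # per complex: n_quantified, n_affected, is_affected
    members: pd.DataFrame  # member-level differential on complex-relative values
    fraction_affected: float
    label: str = ""


def call_affected(
    normalized: OmicsMatrix,
    contrast: Contrast,
    adj_p: float = 0.05,
    min_abs_fc: float = 0.5,
    min_members_affected: int = 2,
) -> ComplexStoichResult:
    """Member-level moderated differential testing on complex-relative
    values; a complex is affected when at least ``min_members_affected``
    members change significantly (adj p and absolute log2 fc thresholds).
    """
    missing = set(contrast.group_a + contrast.group_b) - set(normalized.samples)
    if missing:
        raise ValueError(f"contrast samples not in matrix: {sorted(missing)[:5]}")
    de = moderated_t_test(normalized, contrast)
    de = de.assign(
        affected=(de["adj_p"] < adj_p) & (de["log2fc"].abs() > min_abs_fc)
    )
    grouped = de.groupby(level="complex_id")
    table = pd.DataFrame(
        {
            "n_quantified": grouped.size(),
            "n_affected": grouped["affected"].sum().astype(int),
        }
    )
    table["is_affected"] = table["n_affected"] >= min_members_affected
    fraction = float(table["is_affected"].mean()) if len(table) else np.nan
    return ComplexStoichResult(table, de, fraction, label=contrast.label)


def complex_iqr(
    member_fcs: pd.Series,
    catalog: ComplexCatalog,
    min_members: int = 5,
) -> pd.Series:
    """Interquartile range (Q3 - Q1, linear-interpolation quantiles) of
    member log2 fold changes per complex; complexes with fewer than
    ``min_members`` scored members are excluded."""
    member_fcs = member_fcs.dropna()
    index = pd.Index(member_fcs.index)
    out = {}
    for name in catalog.names():
        members = index.intersection(catalog.members(name))
        if len(members) < min_members:
            continue
        v = member_fcs.loc[members].to_numpy(dtype=float)
        q1, q3 = np.percentile(v, [25, 75])  # type-7 linear interpolation
        out[name] = float(q3 - q1)
    return pd.Series(out, name="iqr").rename_axis("complex_id")


def compare_iqr(iqr_a: pd.Series, iqr_b: pd.Series) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of two per-complex IQR
    vectors. Exact enumeration when both n <= 12 and no ties; otherwise
    the tie-corrected normal approximation."""
    a = np.asarray(iqr_a.dropna(), dtype=float)
    b = np.asarray(iqr_b.dropna(), dtype=float)
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(a) <= 12 and len(b) <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def rank_iqr_difference(iqr_a: pd.Series, iqr_b: pd.Series) -> tuple[pd.DataFrame, float]:
    """Rank complexes by the change in stoichiometry spread between two
    contrasts (IQR_b - IQR_a, descending) and report the fraction of
    complexes with increased IQR (exact zeros count half)."""
    shared = iqr_a.index.intersection(iqr_b.index)
    delta = (iqr_b.loc[shared] - iqr_a.loc[shared]).rename("delta_iqr")
    table = pd.DataFrame(
        {
            "iqr_a": iqr_a.loc[shared],
            "iqr_b": iqr_b.loc[shared],
            "delta_iqr": delta,
            "percent_increase": 100.0 * delta / iqr_a.loc[shared].replace(0, np.nan),
        }
    ).sort_values("delta_iqr", ascending=False)
    n = len(delta)
    fraction = float(((delta > 0).sum() + 0.5 * (delta == 0).sum()) / n) if n else np.nan
    return table, fraction
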