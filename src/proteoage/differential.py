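"""Moderated differential abundance and set-level statistics.

This is the statistical kernel used by every downstream stage:

* an empirical-Bayes moderated two-sample t-test for log2 abundance
  matrices, with the variance prior estimated by closed-form moment
  matching on the log sample variances;
* Benjamini-Hochberg FDR adjustment;
* Fisher's method for combining p-values across contrasts;
* hypergeometric over-representation of gene sets;
* a coefficient-based set test (member vs non-member scores).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import ComplexCatalog, Contrast, OmicsMatrix

#: fixed column order of differential result tables
RESULT_COLUMNS = ["log2fc", "t", "p", "adj_p", "mean_abundance"]


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on a log-convex scale)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_variance_prior(sample_vars: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-matching estimate of the scaled inverse-chi-square variance
    prior (d0, s0^2) from per-feature sample variances with ``df`` residual
    degrees of freedom each.

    Matches the mean and variance of log(s^2), whose sampling moments under
    the hierarchical model are digamma/trigamma expressions in d/2 and d0/2.
    Returns ``d0 = inf`` when the observed spread of log variances is no
    larger than pure chi-square sampling noise.
    """
    v = np.asarray(sample_vars, dtype=float)
    v = v[np.isfinite(v) & (v > 0)]
    if v.size < 2:
        raise ValueError("need >= 2 positive sample variances to estimate the prior")
    z = np.log(v)
    emean = z.mean()
    evar = z.var(ddof=1)
    resid = evar - special.polygamma(1, df / 2.0)
    if resid <= 0:
        d0 = np.inf
        log_s0 = emean - special.digamma(df / 2.0) + np.log(df / 2.0)
    else:
        d0 = 2.0 * _trigamma_inverse(resid)
        log_s0 = (
            emean
            - special.digamma(df / 2.0)
            + np.log(df / 2.0)
            + special.digamma(d0 / 2.0)
            - np.log(d0 / 2.0)
        )
    return float(d0), float(np.exp(log_s0))


def moderated_t_test(
    matrix: OmicsMatrix,
    contrast: Contrast,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated t-test of group_a vs group_b.

    Per feature: ``log2fc`` is the mean difference (a - b), the pooled
    residual variance is shrunk toward the prior s0^2 with prior weight d0,
    and p-values come from a t distribution with d + d0 degrees of freedom.

    ``d0_override = 0`` disables moderation (ordinary pooled-variance t);
    ``d0_override = inf`` forces the fully shared variance s0^2.
    Constant features (zero fold change and zero variance) get p = 1.
    """
    if matrix.kind != "log2":
        raise ValueError("moderated_t_test expects a log2 matrix")
    a = matrix.data.loc[:, list(contrast.group_a)].to_numpy(dtype=float)
    b = matrix.data.loc[:, list(contrast.group_b)].to_numpy(dtype=float)
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in contrast samples")
    na, nb = a.shape[1], b.shape[1]
    df = na + nb - 2
    if df < 1:
        raise ValueError("zero residual degrees of freedom")

    fc = a.mean(axis=1) - b.mean(axis=1)
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df
    constant = (s2 == 0) & (fc == 0)

    if d0_override is None:
        d0, s02 = estimate_variance_prior(s2, df)
    else:
        d0 = float(d0_override)
        _, s02 = estimate_variance_prior(s2, df) if s2[s2 > 0].size >= 2 else (np.inf, 1.0)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = df
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
        df_total = df + d0

    design = np.sqrt(1.0 / na + 1.0 / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = fc / (np.sqrt(s2_post) * design)
    p = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    tstat = np.where(constant, 0.0, tstat)
    p = np.where(constant, 1.0, p)
    # zero shrunken variance without zero fc: infinitely confident; p -> 0
    p = np.where(~constant & (s2_post == 0), 0.0, p)

    out = pd.DataFrame(
        {
            "log2fc": fc,
            "t": tstat,
            "p": p,
            "adj_p": bh_adjust(p),
            "mean_abundance": np.concatenate([a, b], axis=1).mean(axis=1),
        },
        index=matrix.features,
    )
    if out.index.nlevels == 1 and out.index.name is None:
        out.index.name = "feature_id"
    out.attrs["d0"] = d0
    out.attrs["s0_squared"] = s02
    out.attrs["label"] = contrast.label
    return out[RESULT_COLUMNS]


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Library-size factors robust to composition bias: per sample, the
    median ratio of its counts to the per-gene geometric mean, over genes
    positive in all samples."""
    values = counts.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if positive.sum() < 1:
        raise ValueError("no gene positive in all samples; cannot derive size factors")
    logs = np.log(values[positive])
    geo = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - geo, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def log_cpm(counts: OmicsMatrix, pseudo: float = 0.5, size_factors: str = "median-of-ratios") -> OmicsMatrix:
    """log2(CPM + pseudo) transform of a count matrix.

    Effective library sizes come from median-of-ratios size factors by
    default (robust to composition bias when many genes shift in one
    direction); ``size_factors='total'`` uses plain column totals.
    """
    if counts.kind != "counts":
        raise ValueError("log_cpm expects a count matrix")
    totals = counts.data.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("sample with zero total counts")
    if size_factors == "median-of-ratios":
        sf = median_of_ratios_size_factors(counts.data)
        lib = sf * (totals / sf).mean()  # constant scale across samples
    elif size_factors == "total":
        lib = totals
    else:
        raise ValueError(f"unknown size_factors {size_factors!r}")
    cpm = counts.data.div(lib, axis=1) * 1e6
    return OmicsMatrix(np.log2(cpm + pseudo), kind="log2", meta=counts.meta)


def count_differential(counts: OmicsMatrix, contrast: Contrast, pseudo: float = 0.5) -> pd.DataFrame:
    """Differential expression for count data: log2(CPM + pseudo)
    followed by the moderated t-test. A deliberately generic route — the
    downstream logic only needs (log2fc, adj_p) per feature."""
    return moderated_t_test(log_cpm(counts, pseudo), contrast)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs propagate and are
    excluded from the number of tests."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        if ((p[mask] < 0) | (p[mask] > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def fisher_combine(p_list) -> float:
    """Fisher's method: X = -2 sum(ln p) ~ chi-square with 2k df under H0."""
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if (p > 1).any() or (p < 0).any():
        raise ValueError("p-values must lie in [0, 1]")
    if (p == 0).any():
        warnings.warn("p = 0 clipped to the smallest positive float", RuntimeWarning)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    if p.size == 1:
        return float(p[0])
    x = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x, df=2 * p.size))


def ora_test(
    selected: set[str],
    universe: set[str],
    catalog: ComplexCatalog,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each catalog set in
    ``selected`` against ``universe``. Sets disjoint from the universe are
    excluded. Returns one row per set with upper-tail p, BH adj_p, and a
    significance flag at the given FDR."""
    selected = set(selected)
    universe = set(universe)
    if not selected <= universe:
        raise ValueError("selected features must be a subset of the universe")
    if not selected:
        return pd.DataFrame(
            columns=["set_size", "hits", "p", "adj_p", "significant"]
        ).rename_axis("set_id")
    rows = []
    m = len(universe)
    n_sel = len(selected)
    for name, members in catalog.items():
        in_universe = members & universe
        if not in_universe:
            continue
        hits = len(in_universe & selected)
        p = stats.hypergeom.sf(hits - 1, m, len(in_universe), n_sel)
        rows.append((name, len(in_universe), hits, float(p)))
    out = pd.DataFrame(rows, columns=["set_id", "set_size", "hits", "p"]).set_index("set_id")
    if len(out):
        out["adj_p"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["adj_p"] < fdr
        out = out.sort_values("p")
    return out


def coefficient_set_test(
    scores: pd.Series,
    catalog: ComplexCatalog,
    min_members: int = 5,
) -> pd.DataFrame:
    """Per-set two-sample t-test of member scores against non-member
    scores (two-sided), BH-adjusted across sets; ``direction`` is the sign
    of the member-minus-background mean difference.

    This is the set-level readout applied to per-gene Cox coefficients.
    """
    scores = scores.dropna()
    values = scores.to_numpy(dtype=float)
    index = pd.Index(scores.index)
    rows = []
    for name, members in catalog.items():
        mask = index.isin(members)
        if mask.sum() < min_members or (~mask).sum() < 2:
            continue
        inside, outside = values[mask], values[~mask]
        if inside.std(ddof=1) == 0 and outside.std(ddof=1) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(inside, outside, equal_var=False)
        diff = inside.mean() - outside.mean()
        rows.append((name, int(mask.sum()), float(t), float(p), int(np.sign(diff))))
    out = pd.DataFrame(
        rows, columns=["set_id", "n_members", "t", "p", "direction"]
    ).set_index("set_id")
    if len(out):
        out["adj_p"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values("p")
    return out
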