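"""Longitudinal expression-to-mortality analysis.

Per-gene Cox proportional-hazards fits relate each gene's expression
change between two sampling ages (delta = log2 of the later over the
earlier normalized expression) to subsequent mortality:
``h(t | delta) = h0(t) * exp(c * delta)``. The single-covariate partial
likelihood is maximized by Newton-Raphson with Breslow tie handling and
left truncation at the second sampling age. Extreme-group comparison
contrasts the lifespans of the fish with the strongest decreases vs
increases of a gene-set summary by the two-group log-rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy import stats

from .containers import FishSurvival, OmicsMatrix
from .differential import bh_adjust, median_of_ratios_size_factors

log = logging.getLogger(__name__)


def compute_delta(
    expr_t1: OmicsMatrix,
    expr_t2: OmicsMatrix,
    pseudo: float = 0.5,
    normalize: bool = True,
) -> OmicsMatrix:
    """Per-gene, per-fish expression change: log2 of (later + pseudo)
    over (earlier + pseudo) on library-size-normalized values
    (median-of-ratios factors across both time points). Fish missing at
    either time are dropped (logged)."""
    shared_fish = expr_t1.samples.intersection(expr_t2.samples)
    dropped = expr_t1.samples.symmetric_difference(expr_t2.samples)
    if len(dropped):
        log.info("dropped %d fish missing at one time point", len(dropped))
    if not len(shared_fish):
        raise ValueError("no fish present at both time points")
    shared_genes = expr_t1.features.intersection(expr_t2.features)
    g1 = expr_t1.data.loc[shared_genes, shared_fish]
    g2 = expr_t2.data.loc[shared_genes, shared_fish]
    if normalize:
        combined = pd.concat(
            [g1.add_suffix("_t1"), g2.add_suffix("_t2")], axis=1
        )
        sf = median_of_ratios_size_factors(combined)
        g1 = g1.div(sf[[f"{c}_t1" for c in shared_fish]].to_numpy(), axis=1)
        g2 = g2.div(sf[[f"{c}_t2" for c in shared_fish]].to_numpy(), axis=1)
    delta = np.log2((g2 + pseudo) / (g1 + pseudo))
    meta = pd.DataFrame(
        {"group": ["fish"] * len(shared_fish)}, index=pd.Index(shared_fish, name="sample_id")
    )
    return OmicsMatrix(delta, kind="log2", meta=meta)


@dataclass
class CoxFit:
    coef: float
    se: float
    z: float
    p: float
    converged: bool
    degenerate: bool = False
    diverged: bool = False
    loglik: float = np.nan
    loglik_null: float = np.nan


def partial_loglik(c: float, x: np.ndarray, time: np.ndarray, event: np.ndarray,
                   entry: np.ndarray) -> float:
    """Breslow partial log-likelihood of a single covariate with left
    truncation: risk sets are {k : entry_k < t <= T_k}."""
    ll = 0.0
    eta = c * x
    for t in np.unique(time[event == 1]):
        dead = (time == t) & (event == 1)
        risk = (entry < t) & (time >= t)
        ll += eta[dead].sum() - dead.sum() * np.log(np.exp(eta[risk]).sum())
    return float(ll)


def cox_fit_single(
    x,
    surv: FishSurvival,
    max_iter: int = 50,
    tol: float = 1e-10,
    max_coef: float = 50.0,
) -> CoxFit:
    """Newton-Raphson maximization of the single-covariate Breslow
    partial likelihood with delayed entry.

    A constant covariate gives a flat likelihood (degenerate, c = 0,
    p = 1). A monotone likelihood (perfect separation of event order by
    the covariate) is reported with the divergence flag once the scaled
    coefficient exceeds ``max_coef``.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("covariate contains non-finite values")
    time, event, entry = surv.lifespan, surv.event, surv.entry_time
    if x.size != time.size:
        raise ValueError("covariate length must match the number of fish")
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("no events in the survival data")
    if np.ptp(x) == 0:
        ll = partial_loglik(0.0, x, time, event, entry)
        return CoxFit(0.0, np.nan, 0.0, 1.0, True, degenerate=True,
                      loglik=ll, loglik_null=ll)

    sd = x.std()
    xs = (x - x.mean()) / sd  # scale for stable Newton steps
    event_times = np.unique(time[event == 1])
    dead_masks = [(time == t) & (event == 1) for t in event_times]
    risk_masks = [(entry < t) & (time >= t) for t in event_times]
    d_counts = np.array([m.sum() for m in dead_masks])
    s_sums = np.array([xs[m].sum() for m in dead_masks])

    def score_info(c):
        grad, info, ll = 0.0, 0.0, 0.0
        for s_t, d_t, risk in zip(s_sums, d_counts, risk_masks):
            xr = xs[risk]
            w = np.exp(c * xr)
            w_sum = w.sum()
            mean = (w * xr).sum() / w_sum
            var = (w * xr**2).sum() / w_sum - mean**2
            grad += s_t - d_t * mean
            info += d_t * var
            ll += c * s_t - d_t * np.log(w_sum)
        return grad, info, ll

    c = 0.0
    _, _, ll_null = score_info(0.0)
    ll_prev = ll_null
    converged = diverged = False
    for _ in range(max_iter):
        grad, info, ll = score_info(c)
        if info <= 0:
            diverged = True
            break
        step = grad / info
        # step-halving if the likelihood would decrease
        new_c = c + step
        for _ in range(20):
            _, _, ll_new = score_info(new_c)
            if ll_new >= ll - 1e-12:
                break
            new_c = c + (new_c - c) / 2.0
        c = new_c
        if abs(c) > max_coef:
            diverged = True
            break
        if abs(grad) < tol * max(1.0, abs(ll)):
            converged = True
            break
        ll_prev = ll

    grad, info, ll = score_info(c)
    # monotone partial likelihood: the gradient flattens while the scaled
    # coefficient runs away and the curvature collapses
    if abs(c) > 20.0 or info < 1e-6 * n_events:
        diverged = True
    if diverged or info <= 0:
        return CoxFit(np.sign(c) * np.inf if c != 0 else 0.0, np.nan, np.nan, np.nan,
                      False, diverged=True, loglik=ll, loglik_null=ll_null)
    se_s = 1.0 / np.sqrt(info)
    coef = c / sd
    se = se_s / sd
    z = coef / se
    p = 2.0 * stats.norm.sf(abs(z))
    return CoxFit(float(coef), float(se), float(z), float(p), converged,
                  loglik=float(ll), loglik_null=float(ll_null))


def _genewise_cox_fast(X: np.ndarray, time: np.ndarray, max_iter: int = 50,
                       tol: float = 1e-10, max_coef: float = 50.0):
    """Joint Newton-Raphson over all genes for the common special case of
    all-events data with unique event times and a shared entry time:
    risk sets are nested, so the per-event denominators reduce to reverse
    cumulative sums. Returns arrays (coef, se, converged, diverged) on
    the standardized-covariate scale already mapped back."""
    order = np.argsort(-time)  # descending: cumsum gives risk-set sums
    Xo = X[:, order]
    sd = Xo.std(axis=1)
    ok = sd > 0
    Xs = np.zeros_like(Xo)
    Xs[ok] = (Xo[ok] - Xo[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
    n_genes, n = Xs.shape
    c = np.zeros(n_genes)
    active = ok.copy()
    diverged = np.zeros(n_genes, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        xs = Xs[active]
        w = np.exp(c[active, None] * xs)
        cw = np.cumsum(w, axis=1)
        cwx = np.cumsum(w * xs, axis=1)
        cwx2 = np.cumsum(w * xs**2, axis=1)
        mean = cwx / cw
        var = cwx2 / cw - mean**2
        grad = (xs - mean).sum(axis=1)
        info = var.sum(axis=1)
        bad = info <= 0
        step = np.where(bad, 0.0, grad / np.maximum(info, 1e-300))
        step = np.clip(step, -2.0, 2.0)  # guard huge early steps
        c_active = c[active] + step
        c[active] = c_active
        idx = np.flatnonzero(active)
        div_now = bad | (np.abs(c_active) > max_coef)
        done = (np.abs(grad) < tol * n) & ~div_now
        diverged[idx[div_now]] = True
        active[idx[done | div_now]] = False
    # final information for standard errors
    w = np.exp(c[:, None] * Xs)
    cw = np.cumsum(w, axis=1)
    mean = np.cumsum(w * Xs, axis=1) / cw
    var = np.cumsum(w * Xs**2, axis=1) / cw - mean**2
    info = var.sum(axis=1)
    coef = np.full(n_genes, np.nan)
    se = np.full(n_genes, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        coef[ok] = c[ok] / sd[ok]
        se[ok] = 1.0 / (np.sqrt(np.maximum(info, 1e-300)) * sd)[ok]
    coef[~ok] = 0.0  # degenerate constant covariate
    converged = ok & ~diverged & ~active
    return coef, se, converged, diverged, ~ok


def genewise_cox(delta: OmicsMatrix, surv: FishSurvival) -> pd.DataFrame:
    """One Cox fit per gene with BH adjustment across genes; per-gene
    failures are recorded via flags, never fatal.

    Uses a vectorized joint Newton solver when the survival data have
    all-events, unique times and a common entry (the cohort's standard
    shape); otherwise falls back to per-gene fits.
    """
    fish = [f for f in delta.samples if f in surv.fish_ids]
    if len(fish) < len(delta.samples):
        log.info("restricting to %d fish present in the survival table", len(fish))
    sub = FishSurvival(surv.table.loc[fish].copy())
    time, event, entry = sub.lifespan, sub.event, sub.entry_time
    simple = (
        event.all()
        and len(np.unique(time)) == len(time)
        and len(np.unique(entry)) == 1
    )
    X = delta.data.loc[:, fish].to_numpy(dtype=float)
    if simple and np.isfinite(X).all():
        coef, se, converged, diverged, degenerate = _genewise_cox_fast(X, time)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = coef / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        p = np.where(degenerate, 1.0, p)
        z = np.where(degenerate, 0.0, z)
        out = pd.DataFrame(
            {
                "coef": coef,
                "se": se,
                "z": z,
                "p": p,
                "converged": converged | degenerate,
                "degenerate": degenerate,
                "diverged": diverged,
            },
            index=delta.features.rename("gene_id"),
        )
    else:
        rows = []
        for gene in delta.features:
            x = delta.data.loc[gene, fish].to_numpy(dtype=float)
            try:
                fit = cox_fit_single(x, sub)
            except ValueError as exc:
                log.warning("gene %s: %s", gene, exc)
                fit = CoxFit(np.nan, np.nan, np.nan, np.nan, False)
            rows.append(
                (gene, fit.coef, fit.se, fit.z, fit.p, fit.converged, fit.degenerate, fit.diverged)
            )
        out = pd.DataFrame(
            rows,
            columns=["gene_id", "coef", "se", "z", "p", "converged", "degenerate", "diverged"],
        ).set_index("gene_id")
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    return out


def extreme_group_logrank(
    delta: OmicsMatrix,
    surv: FishSurvival,
    gene_set,
    k: int = 32,
    summary: str = "mean",
) -> dict:
    """Compare lifespans of the ``k`` fish with the most pronounced
    decreases vs the ``k`` with the most pronounced increases of the
    gene-set summary (default: mean delta over the set) by the two-group
    log-rank test. Ties at the k-th rank break deterministically by fish
    id (logged)."""
    genes = delta.features.intersection(set(gene_set))
    if not len(genes):
        raise ValueError("gene set not represented in the delta matrix")
    fish = [f for f in delta.samples if f in surv.fish_ids]
    if 2 * k > len(fish):
        raise ValueError(f"2k = {2 * k} exceeds the {len(fish)} available fish")
    block = delta.data.loc[genes, fish]
    if summary == "mean":
        score = block.mean(axis=0)
    elif summary == "median":
        score = block.median(axis=0)
    elif summary == "first-pc":
        centered = block.sub(block.mean(axis=1), axis=0)
        _, _, vt = np.linalg.svd(centered.to_numpy(), full_matrices=False)
        score = pd.Series(vt[0], index=block.columns)
    else:
        raise ValueError(f"unknown summary {summary!r}")

    order = score.loc[sorted(score.index)].sort_values(kind="mergesort")  # ties by fish id
    if order.iloc[k - 1] == order.iloc[k] or order.iloc[-k] == order.iloc[-k - 1]:
        log.info("ties straddle the k-th rank; broken by fish id")
    low = list(order.index[:k])
    high = list(order.index[-k:])
    t_low = surv.table.loc[low, "lifespan"]
    t_high = surv.table.loc[high, "lifespan"]
    e_low = surv.table.loc[low, "event"]
    e_high = surv.table.loc[high, "event"]
    res = logrank_test(t_low, t_high, event_observed_A=e_low, event_observed_B=e_high)
    return {
        "low_group": low,
        "high_group": high,
        "chi2": float(res.test_statistic),
        "p": float(res.p_value),
        "median_low": float(t_low.median()),
        "median_high": float(t_high.median()),
    }
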