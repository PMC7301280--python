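"""SEC-MS co-fractionation analysis.

Elution profiles are normalized to unit row sum, within-complex pairwise
correlations are compared to size-matched random complexes, a median
consensus profile (scaled to max 1) summarizes each complex, and an
apex/center-of-mass metric detects elution shifts between conditions
(positive shift = later elution = lower apparent mass).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ComplexCatalog, SECMatrix

log = logging.getLogger(__name__)


def normalize_profiles(raw: SECMatrix) -> SECMatrix:
    """Divide each protein's intensities by its total across fractions so
    every retained row sums to 1; all-zero rows are dropped (logged).
    Idempotent."""
    totals = raw.data.sum(axis=1)
    zero = totals == 0
    if zero.any():
        log.info("dropped %d all-zero SEC rows", int(zero.sum()))
    data = raw.data.loc[~zero].div(totals[~zero], axis=0)
    return SECMatrix(data, condition=raw.condition, replicate=raw.replicate, normalized=True)


def within_complex_correlations(
    profiles: SECMatrix,
    catalog: ComplexCatalog,
    min_members: int = 5,
) -> dict[str, np.ndarray]:
    """All member-pair Pearson correlations across fractions, per complex
    with at least ``min_members`` quantified subunits."""
    out = {}
    features = set(profiles.proteins)
    for name in catalog.names():
        members = sorted(catalog.members(name) & features)
        if len(members) < min_members:
            log.info("complex %s below member floor, excluded", name)
            continue
        out[name] = _pairwise_correlations(profiles.data.loc[members].to_numpy())
    return out


def _pairwise_correlations(rows: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(rows)
    iu = np.triu_indices(len(rows), k=1)
    vals = corr[iu]
    return vals[np.isfinite(vals)]


def random_complex_null(
    profiles: SECMatrix,
    catalog: ComplexCatalog,
    n_draws: int = 1000,
    seed: int = 0,
    min_members: int = 5,
) -> dict:
    """Null distribution of pairwise correlations from randomly defined
    complexes matching the real complex size multiset, and a two-sided
    rank-sum test of real vs random co-elution.

    The pooled pairwise-correlation vectors are reported for both real
    and random complexes (the distribution view); the rank-sum test is
    computed on per-complex median correlations — pairwise correlations
    within a set share members and are not independent, so pooling them
    would miscalibrate the test. Random sets never reproduce a real
    complex's exact member set, and the draw is deterministic under
    ``seed``.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    real = within_complex_correlations(profiles, catalog, min_members)
    if not real:
        raise ValueError("no complex reached the member floor")
    sizes = [len(catalog.members(name) & set(profiles.proteins)) for name in real]
    universe = np.asarray(profiles.proteins)
    if len(universe) <= max(sizes):
        raise ValueError("profile universe smaller than the largest complex")
    member_sets = {frozenset(catalog.members(name)) for name in real}

    rng = np.random.default_rng(seed)
    null_corrs = []
    for i in range(n_draws):
        size = sizes[i % len(sizes)]
        while True:
            chosen = rng.choice(universe, size=size, replace=False)
            if frozenset(chosen) not in member_sets:
                break
        null_corrs.append(_pairwise_correlations(profiles.data.loc[chosen].to_numpy()))
    real_medians = np.array([np.median(v) for v in real.values()])
    null_medians = np.array([np.median(v) for v in null_corrs if v.size])
    stat, p = stats.mannwhitneyu(
        real_medians, null_medians, alternative="two-sided", method="auto"
    )
    real_vec = np.concatenate(list(real.values()))
    null_vec = np.concatenate(null_corrs)
    return {
        "real": real_vec,
        "null": null_vec,
        "real_medians": real_medians,
        "null_medians": null_medians,
        "statistic": float(stat),
        "p": float(p),
        "median_real": float(np.median(real_vec)),
        "median_null": float(np.median(null_vec)),
    }


def complex_profile(profiles: SECMatrix, members) -> np.ndarray:
    """Consensus complex profile: per-fraction median over quantified
    members, scaled so the maximum equals 1."""
    members = sorted(set(members) & set(profiles.proteins))
    if len(members) < 5:
        raise ValueError(f"need >= 5 quantified members, have {len(members)}")
    consensus = profiles.data.loc[members].median(axis=0).to_numpy()
    peak = consensus.max()
    if peak <= 0:
        raise ValueError("all-zero consensus profile")
    return consensus / peak


@dataclass
class ElutionShift:
    apex_shift: float
    com_shift: float
    flagged: bool


def detect_elution_shift(
    profile_a: np.ndarray,
    profile_b: np.ndarray,
    min_shift: float = 2.0,
    floor: float = 0.05,
) -> ElutionShift:
    """Apex and center-of-mass displacement of profile_b relative to
    profile_a on a shared fraction axis; flagged when the absolute
    center-of-mass shift reaches ``min_shift`` fractions. Positive values
    mean later elution. Apex ties break to the earliest fraction.

    Intensities below ``floor`` times the profile maximum are excluded
    from the center of mass: a baseline noise floor spread over all
    fractions would otherwise pull the COM toward the axis midpoint and
    attenuate real shifts.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must share the fraction axis")
    fractions = np.arange(1, a.size + 1, dtype=float)

    def apex(p):
        if np.allclose(p, p[0]):
            warnings.warn("flat profile: apex tie broken to earliest fraction", RuntimeWarning)
        return float(fractions[int(np.argmax(p))])

    def com(p):
        masked = np.where(p >= floor * p.max(), p, 0.0) if p.max() > 0 else p
        total = masked.sum()
        if total == 0:
            raise ValueError("cannot compute center of mass of an all-zero profile")
        return float((fractions * masked).sum() / total)

    apex_shift = apex(b) - apex(a)
    com_shift = com(b) - com(a)
    return ElutionShift(apex_shift, com_shift, bool(abs(com_shift) >= min_shift))
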