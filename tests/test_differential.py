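import itertools
import shutil
import subprocess
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from proteoage.containers import ComplexCatalog, Contrast, OmicsMatrix
from proteoage.differential import (
    bh_adjust,
    coefficient_set_test,
    count_differential,
    fisher_combine,
    log_cpm,
    moderated_t_test,
    ora_test,
)


def _null_matrix(n_features=200, n_per_group=3, seed=0, hetero=True):
    rng = np.random.default_rng(seed)
    if hetero:
        s2 = 0.04 * 8 / rng.chisquare(8, n_features)
    else:
        s2 = np.ones(n_features)
    data = rng.normal(0.0, np.sqrt(s2)[:, None], (n_features, 2 * n_per_group))
    cols = [f"a{i}" for i in range(n_per_group)] + [f"b{i}" for i in range(n_per_group)]
    df = pd.DataFrame(data, index=[f"F{i:04d}" for i in range(n_features)], columns=cols)
    m = OmicsMatrix(df, kind="log2")
    c = Contrast(tuple(cols[:n_per_group]), tuple(cols[n_per_group:]))
    return m, c


# --- moderated t -----------------------------------------------------------


def test_zero_prior_weight_equals_ordinary_t(log2_matrix_20x6, contrast_20x6):
    res = moderated_t_test(log2_matrix_20x6, contrast_20x6, d0_override=0)
    a = log2_matrix_20x6.data[list(contrast_20x6.group_a)].to_numpy()
    b = log2_matrix_20x6.data[list(contrast_20x6.group_b)].to_numpy()
    t_ref, p_ref = stats.ttest_ind(a, b, axis=1)
    np.testing.assert_allclose(res["t"], t_ref, atol=1e-9)
    np.testing.assert_allclose(res["p"], p_ref, atol=1e-9)


def test_infinite_prior_gives_shared_variance(log2_matrix_20x6, contrast_20x6):
    res = moderated_t_test(log2_matrix_20x6, contrast_20x6, d0_override=np.inf)
    # shared variance: t proportional to fold change everywhere
    ratio = res["t"] / res["log2fc"]
    np.testing.assert_allclose(ratio, ratio.iloc[0], rtol=1e-9)


def test_constant_feature_gets_p_one():
    df = pd.DataFrame(
        np.vstack([np.full(6, 5.0), np.random.default_rng(0).normal(size=(10, 6))]),
        index=[f"F{i}" for i in range(11)],
        columns=list("abcdef"),
    )
    m = OmicsMatrix(df, kind="log2")
    c = Contrast(("a", "b", "c"), ("d", "e", "f"))
    res = moderated_t_test(m, c)
    assert res.loc["F0", "p"] == 1.0
    assert res.loc["F0", "log2fc"] == 0.0


def test_moderated_t_shift_equivariance(log2_matrix_20x6, contrast_20x6):
    shifted = OmicsMatrix(log2_matrix_20x6.data + 3.0, kind="log2", meta=log2_matrix_20x6.meta)
    a = moderated_t_test(log2_matrix_20x6, contrast_20x6)
    b = moderated_t_test(shifted, contrast_20x6)
    np.testing.assert_allclose(a["log2fc"], b["log2fc"], atol=1e-9)
    np.testing.assert_allclose(a["p"], b["p"], atol=1e-9)


def test_moderated_t_matches_limma_reference():
    """Cross-check the empirical-Bayes moderation against the R limma
    implementation on a heteroscedastic fixture."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript not available for the limma cross-check")
    import tempfile
    from pathlib import Path

    m, c = _null_matrix(n_features=300, n_per_group=4, seed=3)
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        m.data.to_csv(tmp / "mat.tsv", sep="\t")
        script = tmp / "check.R"
        script.write_text(
            "suppressMessages(library(limma))\n"
            f"m <- as.matrix(read.delim('{tmp}/mat.tsv', row.names=1))\n"
            "design <- cbind(Intercept=1, A=c(rep(1,4), rep(0,4)))\n"
            "fit <- eBayes(lmFit(m, design))\n"
            "out <- data.frame(t=fit$t[,'A'], p=fit$p.value[,'A'])\n"
            f"write.table(out, '{tmp}/r.tsv', sep='\\t', quote=FALSE)\n"
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp / "r.tsv", sep="\t", index_col=0)
    res = moderated_t_test(m, c)
    np.testing.assert_allclose(res["t"], ref["t"], rtol=1e-6)
    np.testing.assert_allclose(res["p"], ref["p"], rtol=1e-5, atol=1e-12)


# --- BH --------------------------------------------------------------------


def test_bh_step_up_worked_example():
    np.testing.assert_allclose(
        bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )


@pytest.mark.parametrize("p,expected", [([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]), ([0.3], [0.3])])
def test_bh_trivial_cases(p, expected):
    np.testing.assert_allclose(bh_adjust(p), expected)


def test_bh_nan_propagates_and_excluded_from_m():
    out = bh_adjust([0.01, np.nan, 0.04])
    assert np.isnan(out[1])
    np.testing.assert_allclose(out[[0, 2]], bh_adjust([0.01, 0.04]))


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
@settings(max_examples=100, deadline=None)
def test_bh_never_decreases_and_permutation_invariant(p):
    p = np.asarray(p)
    adj = bh_adjust(p)
    assert (adj >= p - 1e-12).all()
    perm = np.random.default_rng(0).permutation(len(p))
    np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm], atol=1e-12)


# --- Fisher combination ----------------------------------------------------


def test_fisher_combine_worked_value():
    x = -2 * np.log(0.05) * 2
    assert np.isclose(x, 11.9829, atol=1e-3)
    assert np.isclose(fisher_combine([0.05, 0.05]), stats.chi2.sf(x, 4), rtol=1e-12)
    assert np.isclose(fisher_combine([0.05, 0.05]), 0.0175, atol=5e-4)


def test_fisher_combine_trivial_cases():
    assert fisher_combine([1.0, 1.0]) == 1.0
    assert fisher_combine([0.42]) == 0.42


def test_fisher_combine_monotone_in_k():
    values = [fisher_combine([0.2] * k) for k in range(2, 8)]
    assert all(a > b for a, b in zip(values, values[1:]))


def test_fisher_combine_zero_clipped_with_warning():
    with pytest.warns(RuntimeWarning):
        p = fisher_combine([0.0, 0.5])
    assert 0 <= p < 1e-10


# --- ORA -------------------------------------------------------------------


def brute_force_hypergeom_upper(hits, set_size, n_selected, universe_size):
    """Enumerate all selections of n_selected from the universe and count
    those with >= hits members inside the set."""
    favorable = sum(
        comb(set_size, k) * comb(universe_size - set_size, n_selected - k)
        for k in range(hits, min(set_size, n_selected) + 1)
    )
    return favorable / comb(universe_size, n_selected)


def test_ora_exact_small_universe():
    universe = {f"g{i}" for i in range(20)}
    selected = {f"g{i}" for i in range(5)}
    catalog = ComplexCatalog({"S": set(selected)})
    res = ora_test(selected, universe, catalog)
    assert np.isclose(res.loc["S", "p"], 1 / comb(20, 5), rtol=1e-12)


def test_ora_matches_enumeration():
    rng = np.random.default_rng(2)
    universe = [f"g{i}" for i in range(25)]
    for _ in range(20):
        set_size = int(rng.integers(3, 12))
        n_sel = int(rng.integers(3, 12))
        members = set(rng.choice(universe, size=set_size, replace=False))
        selected = set(rng.choice(universe, size=n_sel, replace=False))
        res = ora_test(selected, set(universe), ComplexCatalog({"S": members}))
        hits = len(members & selected)
        expected = brute_force_hypergeom_upper(hits, set_size, n_sel, 25)
        assert np.isclose(res.loc["S", "p"], expected, rtol=1e-9)


def test_ora_disjoint_set_excluded_and_full_selection_p_one():
    universe = {f"g{i}" for i in range(10)}
    catalog = ComplexCatalog({"inside": {"g0", "g1"}, "outside": {"x1", "x2"}})
    res = ora_test(universe, universe, catalog)
    assert "outside" not in res.index
    assert res.loc["inside", "p"] == 1.0


def test_ora_empty_selection_empty_table():
    res = ora_test(set(), {"g1", "g2"}, ComplexCatalog({"S": {"g1"}}))
    assert len(res) == 0


# --- coefficient set test --------------------------------------------------


def test_coefficient_set_test_null_and_symmetry(rng):
    scores = pd.Series(rng.normal(size=500), index=[f"g{i}" for i in range(500)])
    catalog = ComplexCatalog({"S": {f"g{i}" for i in range(50)}})
    res = coefficient_set_test(scores, catalog)
    neg = coefficient_set_test(-scores, catalog)
    assert np.isclose(res.loc["S", "p"], neg.loc["S", "p"], rtol=1e-12)
    assert res.loc["S", "direction"] == -neg.loc["S", "direction"]


def test_coefficient_set_test_identical_scores_p_one():
    scores = pd.Series(1.0, index=[f"g{i}" for i in range(100)])
    res = coefficient_set_test(scores, ComplexCatalog({"S": {f"g{i}" for i in range(10)}}))
    assert res.loc["S", "p"] == 1.0
    assert res.loc["S", "direction"] == 0


def test_coefficient_set_test_detects_shifted_set(rng):
    scores = pd.Series(rng.normal(size=2000), index=[f"g{i}" for i in range(2000)])
    scores.iloc[:50] += 1.0
    res = coefficient_set_test(scores, ComplexCatalog({"S": {f"g{i}" for i in range(50)}}))
    assert res.loc["S", "adj_p"] < 0.05
    assert res.loc["S", "direction"] == 1


# --- count route -----------------------------------------------------------


def test_log_cpm_requires_counts(log2_matrix_20x6):
    with pytest.raises(ValueError):
        log_cpm(log2_matrix_20x6)


def test_count_differential_detects_shift(rng):
    n = 300
    mu = 10 ** rng.normal(2.0, 0.5, n)
    counts = rng.poisson(np.tile(mu[:, None], (1, 8)).astype(float))
    counts[:20, 4:] = rng.poisson(mu[:20, None] * 4.0)  # 2 log2 units up
    df = pd.DataFrame(
        counts, index=[f"G{i}" for i in range(n)],
        columns=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)],
    )
    m = OmicsMatrix(df, kind="counts")
    c = Contrast(tuple(f"b{i}" for i in range(4)), tuple(f"a{i}" for i in range(4)))
    res = count_differential(m, c)
    assert (res["adj_p"].iloc[:20] < 0.05).mean() > 0.9
    assert res["log2fc"].iloc[:20].mean() == pytest.approx(2.0, abs=0.3)
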