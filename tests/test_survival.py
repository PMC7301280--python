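import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from proteoage.containers import FishSurvival, OmicsMatrix
from proteoage.survival import (
    compute_delta,
    cox_fit_single,
    extreme_group_logrank,
    genewise_cox,
    median_of_ratios_size_factors,
    partial_loglik,
)
from proteoage.synthetic import generate_longitudinal_survival


def _surv(lifespans, events=None, entry=0.0):
    n = len(lifespans)
    return FishSurvival(
        pd.DataFrame(
            {
                "lifespan": lifespans,
                "event": events if events is not None else [1] * n,
                "entry_time": [entry] * n,
            },
            index=pd.Index([f"fish_{i:03d}" for i in range(n)], name="fish_id"),
        )
    )


# --- delta -----------------------------------------------------------------


def _counts(values, fish):
    df = pd.DataFrame(values, index=[f"G{i}" for i in range(len(values))], columns=fish)
    return OmicsMatrix(df, kind="counts")


def test_delta_zero_for_unchanged_expression(rng):
    fish = [f"f{i}" for i in range(6)]
    counts = rng.poisson(200, (30, 6)).astype(float)
    m = _counts(counts, fish)
    delta = compute_delta(m, m)
    np.testing.assert_allclose(delta.data.to_numpy(), 0.0, atol=1e-12)


def test_delta_quadrupling_gives_two_without_normalization(rng):
    fish = [f"f{i}" for i in range(4)]
    counts = rng.poisson(5000, (20, 4)).astype(float)
    m1 = _counts(counts, fish)
    m2 = _counts(counts * 4.0, fish)
    delta = compute_delta(m1, m2, normalize=False)
    np.testing.assert_allclose(delta.data.to_numpy(), 2.0, atol=1e-3)


def test_delta_fish_order_and_missing_fish(rng):
    fish = [f"f{i}" for i in range(5)]
    c1 = rng.poisson(300, (10, 5)).astype(float)
    c2 = rng.poisson(300, (10, 5)).astype(float)
    m1 = _counts(c1, fish)
    m2 = _counts(c2, fish)
    base = compute_delta(m1, m2)
    m2_perm = _counts(c2[:, ::-1], fish[::-1])
    perm = compute_delta(m1, m2_perm)
    pd.testing.assert_frame_equal(base.data[fish], perm.data[fish], atol=1e-12, rtol=0)
    # a fish missing at t2 is dropped
    m2_short = _counts(c2[:, :4], fish[:4])
    short = compute_delta(m1, m2_short)
    assert list(short.samples) == fish[:4]


def test_size_factors_undo_library_scaling(rng):
    counts = pd.DataFrame(
        rng.poisson(400, (50, 4)).astype(float), columns=[f"s{i}" for i in range(4)]
    )
    scaled = counts * [1.0, 2.0, 0.5, 4.0]
    sf = median_of_ratios_size_factors(scaled)
    ratio = sf / sf.iloc[0]
    np.testing.assert_allclose(ratio, [1.0, 2.0, 0.5, 4.0], rtol=0.05)


# --- single Cox fit --------------------------------------------------------


def test_constant_covariate_degenerate():
    surv = _surv([5.0, 6.0, 7.0, 8.0])
    fit = cox_fit_single(np.ones(4), surv)
    assert fit.degenerate
    assert fit.coef == 0.0
    assert fit.p == 1.0


def test_two_fish_separable_diverges():
    surv = _surv([1.0, 2.0])
    fit = cox_fit_single(np.array([1.0, 0.0]), surv)
    assert fit.diverged
    assert not fit.converged


def test_fit_matches_numeric_maximizer():
    genes = ["G0"]
    delta, surv, _ = generate_longitudinal_survival(
        20, genes, {"rs": {"genes": genes, "c": 1.0}}, seed=9
    )
    x = delta.data.iloc[0].to_numpy()
    fit = cox_fit_single(x, surv)
    res = minimize_scalar(
        lambda c: -partial_loglik(c, x, surv.lifespan, surv.event, surv.entry_time),
        bounds=(-10, 10),
        method="bounded",
        options={"xatol": 1e-10},
    )
    assert fit.converged
    assert fit.coef == pytest.approx(res.x, abs=1e-6)
    assert fit.loglik >= fit.loglik_null - 1e-12


def test_fit_matches_lifelines_with_left_truncation():
    lifelines = pytest.importorskip("lifelines")
    genes = ["G0"]
    delta, surv, _ = generate_longitudinal_survival(
        60, genes, {"rs": {"genes": genes, "c": 0.7}}, seed=4
    )
    x = delta.data.iloc[0].to_numpy()
    fit = cox_fit_single(x, surv)
    df = pd.DataFrame(
        {"T": surv.lifespan, "E": surv.event, "entry": surv.entry_time, "x": x}
    )
    cph = lifelines.CoxPHFitter().fit(df, duration_col="T", event_col="E", entry_col="entry")
    assert fit.coef == pytest.approx(float(cph.params_.iloc[0]), abs=1e-4)
    assert fit.se == pytest.approx(float(cph.standard_errors_.iloc[0]), abs=1e-4)


def test_sign_flip_and_shift_invariance():
    genes = ["G0"]
    delta, surv, _ = generate_longitudinal_survival(
        50, genes, {"rs": {"genes": genes, "c": 0.5}}, seed=2
    )
    x = delta.data.iloc[0].to_numpy()
    base = cox_fit_single(x, surv)
    flipped = cox_fit_single(-x, surv)
    shifted = cox_fit_single(x + 100.0, surv)
    assert flipped.coef == pytest.approx(-base.coef, abs=1e-8)
    assert flipped.p == pytest.approx(base.p, abs=1e-10)
    assert shifted.coef == pytest.approx(base.coef, abs=1e-8)


def test_no_events_errors():
    surv = _surv([5.0, 6.0, 7.0], events=[0, 0, 0])
    with pytest.raises(ValueError, match="no events"):
        cox_fit_single(np.array([1.0, 2.0, 3.0]), surv)


# --- genewise --------------------------------------------------------------


def test_duplicated_gene_rows_get_identical_fits():
    delta, surv, _ = generate_longitudinal_survival(
        40, ["G0", "G1"], {"rs": {"genes": ["G0"], "c": 0.8}}, seed=5
    )
    dup = OmicsMatrix(
        pd.concat([delta.data, delta.data.loc[["G0"]].rename(index={"G0": "G0_copy"})]),
        kind="log2",
        meta=delta.meta,
    )
    fits = genewise_cox(dup, surv)
    assert fits.loc["G0", "coef"] == pytest.approx(fits.loc["G0_copy", "coef"], abs=1e-10)


def test_fast_path_matches_per_gene_solver():
    delta, surv, _ = generate_longitudinal_survival(
        50, 20, {"rs": {"genes": [f"G{i:05d}" for i in range(5)], "c": 1.0}}, seed=6
    )
    fast = genewise_cox(delta, surv)
    for gene in list(delta.features)[:8]:
        slow = cox_fit_single(delta.data.loc[gene].to_numpy(), surv)
        assert fast.loc[gene, "coef"] == pytest.approx(slow.coef, abs=1e-6)
        assert fast.loc[gene, "se"] == pytest.approx(slow.se, abs=1e-6)


def test_null_coefficients_center_on_zero():
    delta, surv, _ = generate_longitudinal_survival(150, 400, {}, seed=8)
    fits = genewise_cox(delta, surv)
    assert abs(fits["coef"].mean()) < 0.02
    assert fits["p"].between(0, 1).all()


# --- log-rank --------------------------------------------------------------


def test_identical_lifespan_multisets_give_null_logrank():
    lifespans = [5.0, 6.0, 7.0, 8.0, 9.0, 10.0] * 2
    surv = _surv(lifespans)
    score = [0.0] * 6 + [1.0] * 6  # groups split but same lifespans
    delta = OmicsMatrix(
        pd.DataFrame([score], index=["G0"], columns=surv.fish_ids),
        kind="log2",
    )
    res = extreme_group_logrank(delta, surv, ["G0"], k=6)
    assert res["chi2"] == pytest.approx(0.0, abs=1e-12)
    assert res["p"] == pytest.approx(1.0)


def test_logrank_monotone_time_transformation_invariant():
    delta, surv, _ = generate_longitudinal_survival(
        60, ["G0"], {"rs": {"genes": ["G0"], "c": 1.0}}, seed=12
    )
    res = extreme_group_logrank(delta, surv, ["G0"], k=15)
    transformed = FishSurvival(
        surv.table.assign(
            lifespan=np.log(surv.table["lifespan"]), entry_time=0.0
        )
    )
    res2 = extreme_group_logrank(delta, transformed, ["G0"], k=15)
    assert res["chi2"] == pytest.approx(res2["chi2"], rel=1e-9)


def test_logrank_detects_risk_gradient():
    delta, surv, _ = generate_longitudinal_survival(
        159, ["G0"], {"rs": {"genes": ["G0"], "c": 1.1}}, seed=13
    )
    res = extreme_group_logrank(delta, surv, ["G0"], k=32)
    assert res["p"] < 0.001
    assert res["median_low"] > res["median_high"]  # low delta = low hazard


def test_logrank_k_too_large_errors():
    delta, surv, _ = generate_longitudinal_survival(20, ["G0"], {}, seed=1)
    with pytest.raises(ValueError, match="exceeds"):
        extreme_group_logrank(delta, surv, ["G0"], k=11)


# --- generator contracts ---------------------------------------------------


def test_survival_generator_deterministic_and_entry_respected():
    a = generate_longitudinal_survival(50, 10, {}, seed=3)
    b = generate_longitudinal_survival(50, 10, {}, seed=3)
    pd.testing.assert_frame_equal(a[0].data, b[0].data)
    pd.testing.assert_frame_equal(a[1].table, b[1].table)
    assert (a[1].lifespan > a[1].entry_time).all()


def test_survival_generator_rejects_nonfinite_coefficient():
    with pytest.raises(ValueError, match="non-finite"):
        generate_longitudinal_survival(20, ["G0"], {"rs": {"genes": ["G0"], "c": np.inf}})
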