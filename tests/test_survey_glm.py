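"""Design-weighted logistic regression: ML/sandwich oracles, closed-form
weighted odds ratios, GVIF, and linearized prevalences."""

import logging

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import epistab as e
from epistab.survey import ModelSpec, compute_gvif, fit_survey_logistic

from conftest import make_table


def _srs_table(n=200, seed=5):
    """Equal weights, one stratum, each record its own PSU."""
    rng = np.random.default_rng(seed)
    x1 = rng.standard_normal(n)
    x2 = rng.choice(["a", "b", "c"], n)
    d = (rng.random(n) < 0.4).astype(int)
    eta = -0.5 + 0.8 * x1 + 0.5 * (x2 == "b") + 0.6 * d
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    df = pd.DataFrame({
        "y": y, "d": d, "x1": x1, "x2": x2,
        "stratum": ["s0"] * n,
        "psu": [f"p{i}" for i in range(n)],
        "weight": np.ones(n),
        "year": ["2016"] * n,
    })
    return make_table(df, {"y": "outcome"})


def test_srs_fit_matches_ml_and_record_level_sandwich():
    """Unit weights + singleton PSUs: coefficients equal ordinary ML
    logistic estimates and vcov equals the record-level sandwich with the
    single-stratum (n/(n-1)) finite factor, both to 1e-8."""
    tab = _srs_table()
    fit = fit_survey_logistic(tab, ModelSpec("y", "d", ("x1", "x2")))
    df = tab.df
    n = len(df)
    # independent oracle: statsmodels ML with the same parameterization
    X = pd.DataFrame({
        "const": 1.0,
        "d": df["d"].astype(float),
        "x1": df["x1"],
    })
    ref = df["x2"].iloc[0]  # our coding references the first observed level
    for lv in pd.unique(df["x2"]):
        if lv != ref:
            X[f"x2[{lv}]"] = (df["x2"] == lv).astype(float)
    res = sm.GLM(df["y"], X[ [c.replace("(intercept)", "const") for c in
        ["const"] + fit.column_names[1:]] ],
        family=sm.families.Binomial()).fit(tol=1e-12)
    np.testing.assert_allclose(fit.beta, res.params.values, atol=1e-8)
    Xv = X[["const"] + fit.column_names[1:]].to_numpy()
    mu = res.fittedvalues.to_numpy()
    u = (df["y"].to_numpy() - mu)[:, None] * Xv
    bread = np.linalg.inv(Xv.T @ (Xv * (mu * (1 - mu))[:, None]))
    meat = n / (n - 1) * u.T @ u
    np.testing.assert_allclose(fit.vcov, bread @ meat @ bread, atol=1e-8)
    assert fit.df_design == n - 1


def _weighted_2x2_table(w11, w10, w01, w00):
    df = pd.DataFrame({
        "d": [1, 1, 0, 0],
        "y": [1, 0, 1, 0],
        "weight": [w11, w10, w01, w00],
        "stratum": ["s0"] * 4,
        "psu": ["p0", "p1", "p2", "p3"],
        "year": ["2016"] * 4,
    })
    return make_table(df, {"y": "outcome"})


def test_saturated_weighted_2x2_gives_closed_form_or():
    tab = _weighted_2x2_table(20.0, 80.0, 10.0, 90.0)
    fit = fit_survey_logistic(tab, ModelSpec("y", "d"),
                              compute_diagnostics=False)
    assert np.exp(fit.coef("d")[0]) == pytest.approx(
        (20 * 90) / (80 * 10), rel=1e-6
    )


def test_printed_column_percentages_imply_crude_or_about_two():
    """Weights equal to the published weighted column percentages of any
    disability among current/never e-cigarette users give the crude
    weighted OR implied by those printed numbers."""
    w11, w10 = 20.8, 11.5   # any disability among current / never users
    w01, w00 = 78.4, 88.0   # no disability among current / never users
    tab = _weighted_2x2_table(w11, w01, w10, w00)
    fit = fit_survey_logistic(tab, ModelSpec("y", "d"),
                              compute_diagnostics=False)
    expected = (w11 / w01) / (w10 / w00)
    assert expected == pytest.approx(2.03, abs=0.005)
    assert np.exp(fit.coef("d")[0]) == pytest.approx(expected, rel=1e-6)


def test_weight_scale_invariance():
    rng = np.random.default_rng(0)
    tab = _srs_table(150, seed=2)
    tab.df["weight"] = rng.uniform(0.5, 5.0, 150)
    tab.df["stratum"] = rng.choice(["s0", "s1", "s2"], 150)
    tab.df["psu"] = tab.df["stratum"] + "_" + rng.choice(
        ["a", "b", "c", "d"], 150
    )
    spec = ModelSpec("y", "d", ("x1",))
    fit1 = fit_survey_logistic(tab, spec)
    tab.df["weight"] *= 37.5
    fit2 = fit_survey_logistic(tab, spec)
    np.testing.assert_allclose(fit1.beta, fit2.beta, atol=1e-9)
    np.testing.assert_allclose(fit1.vcov, fit2.vcov, atol=1e-9)


def test_linearization_agrees_with_psu_jackknife():
    """On a 3-stratum x 4-PSU design the linearized variance of the
    exposure log-odds is within 15% of the brute-force delete-one-PSU
    jackknife."""
    rng = np.random.default_rng(8)
    n = 1200
    strata = rng.choice(["s0", "s1", "s2"], n)
    psu = np.char.add(strata, rng.choice(["_a", "_b", "_c", "_d"], n))
    x1 = rng.standard_normal(n)
    d = (rng.random(n) < 0.4).astype(int)
    # a PSU-level random effect so clustering actually matters
    psu_eff = {u: rng.normal(0, 0.3) for u in np.unique(psu)}
    eta = -0.8 + 0.6 * d + 0.5 * x1 + np.array([psu_eff[u] for u in psu])
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    w = rng.uniform(0.5, 2.0, n)
    df = pd.DataFrame({"y": y, "d": d, "x1": x1, "stratum": strata,
                       "psu": psu, "weight": w, "year": ["2016"] * n})
    tab = make_table(df, {"y": "outcome"})
    spec = ModelSpec("y", "d", ("x1",))
    fit = fit_survey_logistic(tab, spec)
    var_lin = fit.vcov[1, 1]

    # jackknife: drop one PSU, reweight its stratum by n_h/(n_h - 1)
    var_jk = 0.0
    thetas = []
    for h in np.unique(strata):
        units = np.unique(psu[strata == h])
        n_h = len(units)
        th = []
        for u in units:
            keep = psu != u
            dfk = df.loc[keep].copy()
            infl = (dfk["stratum"] == h).to_numpy()
            dfk.loc[infl, "weight"] *= n_h / (n_h - 1)
            fk = fit_survey_logistic(make_table(dfk, {"y": "outcome"}),
                                     spec, compute_diagnostics=False)
            th.append(fk.beta[1])
        th = np.array(th)
        var_jk += (n_h - 1) / n_h * ((th - th.mean()) ** 2).sum()
        thetas.extend(th)
    assert var_lin == pytest.approx(var_jk, rel=0.15)


def test_lonely_psu_warns_and_still_fits(caplog):
    tab = _srs_table(100, seed=3)
    tab.df.loc[0, "stratum"] = "lonely"
    tab.df.loc[0, "psu"] = "lonely_p"
    with caplog.at_level(logging.WARNING, logger="epistab.survey"):
        fit = fit_survey_logistic(tab, ModelSpec("y", "d", ("x1",)))
    assert "lonely" in caplog.text.lower()
    assert np.isfinite(fit.vcov).all()


def test_separation_raises_naming_term():
    n = 80
    rng = np.random.default_rng(1)
    y = (rng.random(n) < 0.5).astype(int)
    df = pd.DataFrame({
        "y": y, "d": y.copy(), "stratum": ["s"] * n,
        "psu": [f"p{i}" for i in range(n)], "weight": np.ones(n),
        "year": ["2016"] * n,
    })
    with pytest.raises(e.SeparationError, match="d"):
        fit_survey_logistic(make_table(df, {"y": "outcome"}),
                            ModelSpec("y", "d"), compute_diagnostics=False)


# -- GVIF -------------------------------------------------------------------

def test_gvif_is_one_for_orthogonal_predictors():
    rng = np.random.default_rng(0)
    n = 500
    X = rng.standard_normal((n, 3))
    # orthogonalize exactly
    Q, _ = np.linalg.qr(X - X.mean(0))
    g = compute_gvif(Q, np.ones(n), [(f"x{j}", [j]) for j in range(3)],
                     [f"x{j}" for j in range(3)])
    np.testing.assert_allclose(g["gvif"], 1.0, atol=1e-8)
    assert not g["flagged"].any()


def test_gvif_closed_form_for_correlated_pair():
    """Sample correlation 0.8: VIF = 1/(1-0.64) = 2.778, flagged."""
    rng = np.random.default_rng(1)
    n = 4000
    a = rng.standard_normal(n)
    b = 0.8 * a + np.sqrt(1 - 0.64) * rng.standard_normal(n)
    # force the empirical correlation to exactly 0.8
    a = (a - a.mean()) / a.std()
    b = (b - b.mean()) / b.std()
    b = 0.8 * a + np.sqrt(1 - 0.64) * (
        (b - (a @ b / n) * a) / np.sqrt(1 - (a @ b / n) ** 2)
    )
    X = np.column_stack([a, b])
    g = compute_gvif(X, np.ones(n), [("a", [0]), ("b", [1])], ["a", "b"])
    assert g["gvif"].iloc[0] == pytest.approx(1 / (1 - 0.64), abs=1e-3)
    assert g["gvif_adj"].iloc[0] == pytest.approx(1.667, abs=2e-3)
    assert g["flagged"].all()


def test_gvif_invariant_to_recoding_other_terms():
    """Determinant-ratio property: applying an invertible linear map to
    another term's columns leaves a term's GVIF unchanged."""
    rng = np.random.default_rng(2)
    n = 800
    A = rng.standard_normal((n, 2))
    B = rng.standard_normal((n, 2)) + 0.4 * A
    X1 = np.column_stack([A, B])
    M = np.array([[2.0, 1.0], [0.5, 1.5]])  # invertible recode of B
    X2 = np.column_stack([A, B @ M])
    groups = [("A", [0, 1]), ("B", [2, 3])]
    g1 = compute_gvif(X1, np.ones(n), groups, list("abcd"))
    g2 = compute_gvif(X2, np.ones(n), groups, list("abcd"))
    assert g1["gvif"].iloc[0] == pytest.approx(g2["gvif"].iloc[0], rel=1e-10)


def test_gvif_singular_design_raises():
    rng = np.random.default_rng(3)
    a = rng.standard_normal(200)
    X = np.column_stack([a, 2 * a])
    with pytest.raises(e.DegenerateDataError):
        compute_gvif(X, np.ones(200), [("a", [0]), ("b", [1])], ["a", "b"])


# -- weighted prevalence ----------------------------------------------------

def test_prevalence_hand_summation():
    df = pd.DataFrame({
        "x": [1, 0, 1],
        "stratum": ["s"] * 3, "psu": ["a", "b", "c"],
        "weight": [1.0, 2.0, 3.0], "year": ["2016"] * 3,
    })
    out = e.weighted_prevalence(make_table(df), "x")
    assert out["estimate"].iloc[0] == pytest.approx(4 / 6)


def test_prevalence_srs_reduces_to_binomial_formula():
    rng = np.random.default_rng(4)
    n = 400
    x = (rng.random(n) < 0.3).astype(int)
    df = pd.DataFrame({
        "x": x, "stratum": ["s"] * n,
        "psu": [f"p{i}" for i in range(n)],
        "weight": np.ones(n), "year": ["2016"] * n,
    })
    out = e.weighted_prevalence(make_table(df), "x")
    p = x.mean()
    assert out["estimate"].iloc[0] == pytest.approx(p)
    assert out["se"].iloc[0] == pytest.approx(
        np.sqrt(p * (1 - p) / (n - 1)), rel=1e-10
    )
    assert 0.0 <= out["ci_low"].iloc[0] <= out["ci_high"].iloc[0] <= 1.0
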