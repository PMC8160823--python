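"""Penalized path: KKT bound, agreement with an independent convex solver,
cross-validated penalty choice, and the variable-selection rule."""

import warnings

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

import epistab as e
from epistab.lasso import (
    ColumnInfo,
    DesignCoding,
    lambda_grid,
    lambda_max,
    stratified_fold_ids,
)


def _random_problem(seed, n=300, p=5, signal=0.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    Xs, keep = e.standardize(X)
    eta = -0.5 + signal * Xs[:, 0]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return Xs, y


@pytest.mark.parametrize("seed", range(20))
def test_zero_solution_at_and_above_lambda_max(seed):
    """KKT: at any penalty >= max|x^T(y-ybar)|/n the path is exactly 0."""
    X, y = _random_problem(seed, signal=0.8)
    lmax = lambda_max(X, y)
    betas, b0s, _ = e.fit_lasso_path(
        X, y, np.array([lmax * 1.5, lmax])
    )
    assert np.all(betas == 0.0)
    ybar = y.mean()
    assert b0s[0] == pytest.approx(np.log(ybar / (1 - ybar)), abs=1e-8)
    # and strictly below lambda_max something enters
    betas2, _, _ = e.fit_lasso_path(
        X, y, np.array([lmax, lmax * 0.95])
    )
    assert np.any(betas2[1] != 0.0)


@pytest.mark.parametrize("frac", [0.5, 0.1, 0.01])
def test_path_matches_independent_convex_solver(frac):
    """Coefficients agree with sklearn's saga L1 solver (which minimizes
    the same objective with C = 1/(n*lambda)) at interior penalties."""
    X, y = _random_problem(0, n=500, signal=1.0)
    n = len(y)
    lmax = lambda_max(X, y)
    lams = lambda_grid(lmax, 40, 5e-3)
    betas, b0s, _ = e.fit_lasso_path(X, y, lams, tol=1e-9)
    lam = lmax * frac
    idx = int(np.argmin(np.abs(lams - lam)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf = LogisticRegression(
            C=1.0 / (n * lams[idx]), l1_ratio=1.0, solver="saga",
            max_iter=50_000, tol=1e-12,
        )
        clf.fit(X, y)
    np.testing.assert_allclose(betas[idx], clf.coef_[0], atol=2e-6)
    assert b0s[idx] == pytest.approx(clf.intercept_[0], abs=2e-6)


def test_constant_response_gives_zero_path_with_warning():
    X, _ = _random_problem(1)
    y = np.ones(X.shape[0])
    with pytest.warns(UserWarning, match="constant"):
        betas, _, _ = e.fit_lasso_path(X, y, np.array([0.1, 0.01]))
    assert np.all(betas == 0.0)


def test_dominant_predictor_leads_the_path():
    """A predictor identical to the response has the largest coefficient
    magnitude everywhere along the nonzero path."""
    rng = np.random.default_rng(7)
    n = 200
    y = (rng.random(n) < 0.5).astype(float)
    X = np.column_stack([y, rng.standard_normal((n, 3)).T.flatten()[:n],
                         rng.standard_normal(n), rng.standard_normal(n)])
    Xs, _ = e.standardize(X)
    lams = lambda_grid(lambda_max(Xs, y), 30, 1e-3)
    betas, _, ncomp = e.fit_lasso_path(Xs, y, lams)
    for il in range(1, ncomp):
        if np.any(betas[il] != 0):
            assert np.argmax(np.abs(betas[il])) == 0


def test_lambda_min_is_the_cv_argmin():
    X, y = _random_problem(2, n=400, signal=1.0)
    cv = e.select_lambda_min(X, y, rng=np.random.default_rng(0))
    assert cv.mean_cv_error[cv.lambda_min_index] == cv.mean_cv_error.min()
    assert cv.mean_cv_error[cv.lambda_min_index] <= cv.mean_cv_error[0]
    assert cv.lambda_min == cv.lambda_grid[cv.lambda_min_index]


def test_pure_noise_keeps_null_model_competitive():
    """On pure noise the CV minimum is within two CV standard errors of
    the null (lambda_max) deviance."""
    for seed in range(5):
        X, y = _random_problem(100 + seed, n=400, p=8, signal=0.0)
        cv = e.select_lambda_min(X, y, rng=np.random.default_rng(seed))
        gap = cv.mean_cv_error[0] - cv.mean_cv_error[cv.lambda_min_index]
        assert gap <= 2 * cv.cv_se[cv.lambda_min_index]


def test_strong_signal_is_kept_at_lambda_min():
    """log-OR 2 on n=1000: the signal coefficient is nonzero at the CV
    minimum in at least 19 of 20 seeds."""
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(200 + seed)
        X = rng.standard_normal((1000, 5))
        Xs, _ = e.standardize(X)
        y = (rng.random(1000) < 1 / (1 + np.exp(-(-0.5 + 2 * Xs[:, 0])))
             ).astype(float)
        cv = e.select_lambda_min(Xs, y, rng=rng)
        betas, _, ncomp = e.fit_lasso_path(
            Xs, y, cv.lambda_grid[: cv.lambda_min_index + 1]
        )
        if (
            cv.lambda_min_index > 0
            and betas[min(cv.lambda_min_index, ncomp - 1)][0] != 0
        ):
            hits += 1
    assert hits >= 19


def test_cv_requires_both_classes():
    X, _ = _random_problem(3)
    with pytest.raises(e.DegenerateDataError):
        e.select_lambda_min(X, np.zeros(X.shape[0]),
                            rng=np.random.default_rng(0))


def test_stratified_folds_cover_both_classes():
    y = np.array([1.0] * 15 + [0.0] * 85)
    folds = stratified_fold_ids(y, 10, np.random.default_rng(0))
    for k in range(10):
        assert set(y[folds == k]) == {0.0, 1.0}


# -- selection rule ---------------------------------------------------------

def _coding():
    return DesignCoding([
        ColumnInfo("x", "b", False),
        ColumnInfo("x", "MISSING", True),
        ColumnInfo("z", None, False),
        ColumnInfo("w", "2", False),
        ColumnInfo("w", "3", False),
    ])


def test_missing_only_coefficient_does_not_select():
    sel = e.variable_selected_at(np.array([0.0, 0.7, 0.0, 0.0, 0.0]),
                                 _coding())
    assert sel == {"x": False, "z": False, "w": False}


def test_all_zero_selects_nothing():
    sel = e.variable_selected_at(np.zeros(5), _coding())
    assert not any(sel.values())


def test_single_level_coefficient_selects_variable():
    sel = e.variable_selected_at(np.array([0.0, 0.0, 0.0, 0.4, 0.0]),
                                 _coding())
    assert sel == {"x": False, "z": False, "w": True}


def test_dropped_columns_count_as_zero():
    keep = np.array([True, False, True, True, True])
    # kept columns are x[b], z, w[2], w[3]; the dropped x[MISSING] is zero
    sel = e.variable_selected_at(np.array([0.1, 0.0, 0.2, 0.0]),
                                 _coding(), keep)
    assert sel == {"x": True, "z": False, "w": True}


def test_unmapped_coefficients_rejected():
    with pytest.raises(e.SchemaError):
        e.variable_selected_at(np.zeros(3), _coding())


def test_encoding_reference_and_missing_dummy():
    import pandas as pd

    df = pd.DataFrame({
        "c": ["b", "a", e.MISSING, "b"],
        "x": [1.0, 2.0, 3.0, 4.0],
    })
    X, coding = e.encode_candidates(df, ["c", "x"])
    names = [(ci.variable, ci.level) for ci in coding.columns]
    # reference is the first observed non-MISSING level ("b")
    assert ("c", "b") not in names
    assert ("c", "a") in names and ("c", e.MISSING) in names
    assert ("x", None) in names
    assert X.shape == (4, 3)
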