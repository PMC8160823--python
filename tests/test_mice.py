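"""Chained-equation imputation: invariants, frequency recovery,
convergence diagnostics."""

import numpy as np
import pandas as pd
import pytest

import epistab as e
from epistab.mice import ImputationSet, _fit_multinomial, _predict_proba
from epistab.preprocess import MISSING

from conftest import make_table


def _mcar_binary_table(n=2000, p_yes=0.3, p_miss=0.2, seed=0):
    rng = np.random.default_rng(seed)
    x = np.where(rng.random(n) < p_yes, "yes", "no").astype(object)
    mask = rng.random(n) < p_miss
    x[mask] = MISSING
    df = pd.DataFrame({
        "x": x,
        "y": (rng.random(n) < 0.2).astype(int),
        "d": (rng.random(n) < 0.3).astype(int),
    })
    return make_table(df, {"x": "candidate", "y": "outcome"}), mask


def test_complete_data_returns_identical_copies():
    tab, _ = _mcar_binary_table(p_miss=0.0)
    out = e.impute(tab, ["x"], "y", "d", e.ImputationConfig(m=3,
                   n_chain_iterations=2))
    assert out.m == 3
    for ds in out.datasets:
        pd.testing.assert_frame_equal(ds, tab.df)
    assert out.trace == {}
    assert e.convergence_diagnostics(out) == {}


def test_observed_cells_are_untouched_and_reproducible():
    tab, mask = _mcar_binary_table()
    cfg = e.ImputationConfig(m=4, n_chain_iterations=3, seed=7)
    out = e.impute(tab, ["x"], "y", "d", cfg)
    for ds in out.datasets:
        assert (ds.loc[~mask, "x"] == tab.df.loc[~mask, "x"]).all()
        assert not (ds["x"] == MISSING).any()
        pd.testing.assert_frame_equal(ds[["y", "d"]], tab.df[["y", "d"]])
    out2 = e.impute(tab, ["x"], "y", "d", cfg)
    for a, b in zip(out.datasets, out2.datasets):
        pd.testing.assert_frame_equal(a, b)


def test_mcar_imputed_frequency_recovers_truth():
    """Binary covariate, 20% MCAR, P(yes) = 0.3: the pooled imputed
    frequency sits within 3 Monte-Carlo SEs of 0.3."""
    tab, mask = _mcar_binary_table(n=2000, seed=3)
    out = e.impute(tab, ["x"], "y", "d",
                   e.ImputationConfig(m=10, n_chain_iterations=5, seed=1))
    fracs = [
        (ds.loc[mask, "x"] == "yes").mean() for ds in out.datasets
    ]
    pooled = float(np.mean(fracs))
    n_imputed = int(mask.sum())
    se = np.sqrt(0.3 * 0.7 / n_imputed)
    assert abs(pooled - 0.3) < 3 * se


def test_mar_imputation_tracks_the_driver_strata():
    """Three-level covariate whose missingness and distribution both depend
    on a fully observed binary driver: per-stratum imputed frequencies
    match per-stratum observed frequencies."""
    rng = np.random.default_rng(11)
    n = 4000
    z = rng.choice(["lo", "hi"], n)
    probs = {"lo": [0.6, 0.3, 0.1], "hi": [0.2, 0.3, 0.5]}
    x = np.array([
        rng.choice(["a", "b", "c"], p=probs[zi]) for zi in z
    ], dtype=object)
    p_miss = np.where(z == "hi", 0.3, 0.05)
    mask = rng.random(n) < p_miss
    x_obs = x.copy()
    x_obs[mask] = MISSING
    df = pd.DataFrame({
        "x": x_obs, "z": z,
        "y": (rng.random(n) < 0.2).astype(int),
        "d": (rng.random(n) < 0.3).astype(int),
    })
    tab = make_table(df, {"x": "candidate", "z": "candidate",
                          "y": "outcome"})
    out = e.impute(tab, ["x", "z"], "y", "d",
                   e.ImputationConfig(m=5, n_chain_iterations=5, seed=2))
    for stratum in ("lo", "hi"):
        sel = mask & (z == stratum)
        obs = (~mask) & (z == stratum)
        imputed_a = np.mean([
            (ds.loc[sel, "x"] == "a").mean() for ds in out.datasets
        ])
        observed_a = (df.loc[obs, "x"] == "a").mean()
        se = np.sqrt(observed_a * (1 - observed_a) / sel.sum())
        assert abs(imputed_a - observed_a) < 4 * se


def test_single_stream_single_sweep_is_stochastic_regression_imputation():
    tab, mask = _mcar_binary_table()
    out = e.impute(tab, ["x"], "y", "d",
                   e.ImputationConfig(m=1, n_chain_iterations=1, seed=5))
    assert out.m == 1
    assert out.trace["x"].shape == (1, 1, 2)
    assert not (out.datasets[0]["x"] == MISSING).any()


def test_degenerate_inputs_rejected():
    tab, _ = _mcar_binary_table()
    cfg = e.ImputationConfig(m=1, n_chain_iterations=1)
    all_missing = tab.copy()
    all_missing.df["x"] = MISSING
    with pytest.raises(e.DegenerateDataError):
        e.impute(all_missing, ["x"], "y", "d", cfg)
    cont = tab.copy()
    cont.df["x"] = np.where(np.arange(len(cont.df)) % 5 == 0, np.nan, 1.0)
    with pytest.raises(e.ConfigurationError):
        e.impute(cont, ["x"], "y", "d", cfg)
    bad_outcome = tab.copy()
    bad_outcome.df.loc[0, "y"] = np.nan
    with pytest.raises(e.ConfigurationError):
        e.impute(bad_outcome, ["x"], "y", "d", cfg)


def test_diagnostics_flag_growing_between_stream_spread():
    """Streams drifting apart over the last third of sweeps are flagged;
    well-mixed flat traces are not."""
    n_iter = 12
    grow = np.zeros((4, n_iter, 2))
    flat = np.zeros((4, n_iter, 2))
    rng = np.random.default_rng(0)
    for s in range(4):
        flat[s, :, 0] = 0.3 + 0.01 * rng.standard_normal(n_iter)
        # streams fan out linearly: spread grows with the sweep index
        grow[s, :, 0] = 0.3 + (s - 1.5) * 0.02 * np.arange(n_iter)
    grow[:, :, 1] = 1 - grow[:, :, 0]
    flat[:, :, 1] = 1 - flat[:, :, 0]
    cfg = e.ImputationConfig(m=4, n_chain_iterations=n_iter)
    imp_grow = ImputationSet([], {"v": grow}, {"v": ["a", "b"]}, cfg)
    imp_flat = ImputationSet([], {"v": flat}, {"v": ["a", "b"]}, cfg)
    assert e.convergence_diagnostics(imp_grow)["v"]["flagged"]
    assert not e.convergence_diagnostics(imp_flat)["v"]["flagged"]


def test_real_chain_is_not_flagged():
    tab, _ = _mcar_binary_table(seed=13)
    out = e.impute(tab, ["x"], "y", "d",
                   e.ImputationConfig(m=5, n_chain_iterations=9, seed=3))
    diag = e.convergence_diagnostics(out)
    assert not diag["x"]["flagged"]


def test_multinomial_fit_matches_sklearn():
    """The internal ridge-ML multinomial fit agrees with sklearn's
    multinomial logistic regression at matched regularization."""
    from sklearn.linear_model import LogisticRegression

    rng = np.random.default_rng(4)
    n = 1500
    X = np.column_stack([np.ones(n), rng.standard_normal((n, 2)).T[0],
                         rng.standard_normal(n)])
    eta1 = 0.5 + 0.8 * X[:, 1]
    eta2 = -0.3 + 0.5 * X[:, 2]
    denom = 1 + np.exp(eta1) + np.exp(eta2)
    u = rng.random(n)
    p1 = np.exp(eta1) / denom
    p2 = np.exp(eta2) / denom
    y = np.where(u < p1, 1, np.where(u < p1 + p2, 2, 0))
    B = _fit_multinomial(X, y, 3, ridge=1e-6)
    probs = _predict_proba(X, B)
    clf = LogisticRegression(C=1e6, max_iter=5000, tol=1e-10)
    clf.fit(X[:, 1:], y)
    sk_probs = clf.predict_proba(X[:, 1:])
    assert np.abs(probs - sk_probs).max() < 1e-3
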