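"""Numba kernels for the L1-penalized logistic path and its cross-validation.

The stability-selection stage performs on the order of 10^5 penalized path
fits per analysis, so the inner solver is a compiled glmnet-style coordinate
descent: an outer quadratic (IRLS) approximation around the current linear
predictor, an inner cyclic coordinate descent with soft-thresholding, warm
starts along a decreasing lambda grid, and early path termination once the
model is saturated and the deviance has stopped improving.

The objective minimized for each lambda is

    (1/n) * sum_i nll_i(beta0 + x_i beta) + lambda * sum_j |beta_j|

with an unpenalized intercept, where nll is the Bernoulli negative
log-likelihood.  Under this scaling the smallest lambda with an all-zero
solution is lambda_max = max_j |x_j^T (y - ybar)| / n for centered,
standardized columns; the soft threshold carries a 1e-10 relative slack so
the solution at lambda_max is exactly the zero vector rather than numerical
dust.

Design matrices are passed transposed (p, n), C-contiguous, so column sweeps
are cache-friendly.  Cross-validation path fits use a single quadratic
approximation per lambda step (the warm-started approximation error is far
below the fold-to-fold noise in the CV curve); final fits re-weight to full
convergence.
"""

import math

import numpy as np
from numba import njit

@njit(cache=True, inline="always")
def _fexp(x):
    """exp with the argument clamped to [-30, 30] (sigmoid saturation)."""
    if x > 30.0:
        x = 30.0
    elif x < -30.0:
        x = -30.0
    return math.exp(x)


@njit(cache=True, inline="always")
def _nll(eta, yi):
    """Bernoulli negative log-likelihood of one observation."""
    s = eta if yi > 0.5 else -eta
    # softplus(-s) = log(1 + exp(-s)), stable for either sign
    if s > 30.0:
        return 0.0
    if s < -30.0:
        return -s
    return math.log1p(_fexp(-s))


@njit(cache=True, fastmath=True)
def fit_logistic_path(XT, y, lams, tol, max_outer, dev_change_tol):
    """Fit the penalized path over a decreasing lambda grid with warm starts.

    Parameters
    ----------
    XT : (p, n) standardized predictors, transposed.
    y : (n,) 0/1 responses.
    lams : (nl,) strictly decreasing penalties.
    tol : coefficient-change convergence tolerance (columns have unit
        variance, so deltas are comparable across j).
    max_outer : cap on quadratic re-approximations per lambda; 1 gives the
        fast single-approximation mode used inside cross-validation.
    dev_change_tol : once every predictor is active, stop extending the path
        when the per-lambda training-deviance improvement falls below
        dev_change_tol * null_deviance; 0 disables early termination.

    Returns
    -------
    betas : (nl, p) coefficients (rows beyond n_computed repeat nothing and
        stay zero).
    b0s : (nl,) intercepts.
    n_computed : number of lambdas actually fitted (path may terminate
        early).
    """
    p, n = XT.shape
    nl = lams.shape[0]
    betas = np.zeros((nl, p))
    b0s = np.zeros(nl)

    ybar = 0.0
    for i in range(n):
        ybar += y[i]
    ybar /= n
    if ybar < 1e-12 or ybar > 1.0 - 1e-12:
        # degenerate response: zero path at every lambda
        return betas, b0s, nl

    beta = np.zeros(p)
    b0 = math.log(ybar / (1.0 - ybar))
    eta = np.full(n, b0)
    w = np.empty(n)
    r = np.empty(n)
    h = np.empty(p)
    dbeta = np.zeros(p)  # pending eta updates since last quadratic build

    dev_null = -(ybar * math.log(ybar) + (1.0 - ybar) * math.log(1.0 - ybar))
    dev_prev = dev_null
    n_computed = nl
    db0 = 0.0

    for il in range(nl):
        lam = lams[il]
        lam_slack = lam * (1.0 + 1e-10)
        for _outer in range(max_outer):
            # fold pending coefficient deltas into eta, then rebuild the
            # quadratic approximation in the same pass structure
            if db0 != 0.0:
                for i in range(n):
                    eta[i] += db0
                db0 = 0.0
            for j in range(p):
                if dbeta[j] != 0.0:
                    d = dbeta[j]
                    for i in range(n):
                        eta[i] += XT[j, i] * d
                    dbeta[j] = 0.0
            for i in range(n):
                pi = 1.0 / (1.0 + _fexp(-eta[i]))
                wi = pi * (1.0 - pi)
                if wi < 1e-6:
                    wi = 1e-6
                w[i] = wi
                r[i] = y[i] - pi
            for j in range(p):
                s = 0.0
                for i in range(n):
                    s += w[i] * XT[j, i] * XT[j, i]
                h[j] = s / n
            # coordinate descent on this quadratic: full KKT sweeps over all
            # predictors alternate with cheap refinement sweeps over the
            # current active set, glmnet-style
            first_pass_delta = -1.0
            for _kkt in range(50):
                maxdelta = 0.0
                for j in range(p):
                    g = 0.0
                    for i in range(n):
                        g += XT[j, i] * r[i]
                    g /= n
                    z = g + h[j] * beta[j]
                    if z > lam_slack:
                        bnew = (z - lam) / h[j]
                    elif z < -lam_slack:
                        bnew = (z + lam) / h[j]
                    else:
                        bnew = 0.0
                    d = bnew - beta[j]
                    if d != 0.0:
                        beta[j] = bnew
                        dbeta[j] += d
                        for i in range(n):
                            r[i] -= w[i] * XT[j, i] * d
                        ad = abs(d)
                        if ad > maxdelta:
                            maxdelta = ad
                # unpenalized intercept
                gs = 0.0
                hs = 0.0
                for i in range(n):
                    gs += r[i]
                    hs += w[i]
                d0 = gs / hs
                if d0 != 0.0:
                    b0 += d0
                    db0 += d0
                    for i in range(n):
                        r[i] -= w[i] * d0
                ad0 = abs(d0)
                if ad0 > maxdelta:
                    maxdelta = ad0
                if first_pass_delta < 0.0:
                    first_pass_delta = maxdelta
                if maxdelta < tol:
                    break
                # refine on the active set only until it stabilizes
                for _cycle in range(200):
                    adelta = 0.0
                    for j in range(p):
                        if beta[j] == 0.0:
                            continue
                        g = 0.0
                        for i in range(n):
                            g += XT[j, i] * r[i]
                        g /= n
                        z = g + h[j] * beta[j]
                        if z > lam_slack:
                            bnew = (z - lam) / h[j]
                        elif z < -lam_slack:
                            bnew = (z + lam) / h[j]
                        else:
                            bnew = 0.0
                        d = bnew - beta[j]
                        if d != 0.0:
                            beta[j] = bnew
                            dbeta[j] += d
                            for i in range(n):
                                r[i] -= w[i] * XT[j, i] * d
                            ad = abs(d)
                            if ad > adelta:
                                adelta = ad
                    gs = 0.0
                    for i in range(n):
                        gs += r[i]
                    d0 = gs / hs
                    if d0 != 0.0:
                        b0 += d0
                        db0 += d0
                        for i in range(n):
                            r[i] -= w[i] * d0
                    if abs(d0) > adelta:
                        adelta = abs(d0)
                    if adelta < tol:
                        break
            # the re-weighted solve moved nothing: stationary point reached
            if first_pass_delta < tol:
                break
        for j in range(p):
            betas[il, j] = beta[j]
        b0s[il] = b0

        # early termination: all predictors active and deviance saturated
        if dev_change_tol > 0.0:
            n_active = 0
            for j in range(p):
                if beta[j] != 0.0:
                    n_active += 1
            if n_active == p:
                dev = 0.0
                for i in range(n):
                    ei = eta[i] + db0
                    for j in range(p):
                        if dbeta[j] != 0.0:
                            ei += XT[j, i] * dbeta[j]
                    dev += _nll(ei, y[i])
                dev /= n
                if dev_prev - dev < dev_change_tol * dev_null and il >= 1:
                    n_computed = il + 1
                    break
                dev_prev = dev
    return betas, b0s, n_computed


@njit(cache=True, fastmath=True)
def _heldout_deviance(XT, y, idx, betas, b0s, n_computed):
    """Total held-out negative log-likelihood per lambda over rows idx."""
    nl = betas.shape[0]
    p = betas.shape[1]
    tot = np.zeros(nl)
    for il in range(nl):
        jl = il if il < n_computed else n_computed - 1
        s = 0.0
        for t in range(idx.shape[0]):
            i = idx[t]
            eta = b0s[jl]
            for j in range(p):
                eta += betas[jl, j] * XT[j, i]
            s += _nll(eta, y[i])
        tot[il] = s
    return tot


@njit(cache=True, fastmath=True)
def cv_deviance(XT, y, lams, fold_ids, n_folds, tol, max_outer,
                dev_change_tol):
    """Mean held-out deviance per lambda under pre-assigned CV folds.

    For each fold the path is refitted on the complement and evaluated on
    the fold; lambdas beyond a fold's early-termination point reuse that
    fold's last (saturated) fit.  Returns the per-fold total held-out
    deviance, (n_folds, nl), and the per-fold test counts.
    """
    p, n = XT.shape
    nl = lams.shape[0]
    tot = np.zeros((n_folds, nl))
    counts = np.zeros(n_folds)
    for k in range(n_folds):
        n_te = 0
        for i in range(n):
            if fold_ids[i] == k:
                n_te += 1
        n_tr = n - n_te
        XT_tr = np.empty((p, n_tr))
        y_tr = np.empty(n_tr)
        te_idx = np.empty(n_te, dtype=np.int64)
        a = 0
        b = 0
        for i in range(n):
            if fold_ids[i] == k:
                te_idx[b] = i
                b += 1
            else:
                for j in range(p):
                    XT_tr[j, a] = XT[j, i]
                y_tr[a] = y[i]
                a += 1
        betas, b0s, ncomp = fit_logistic_path(
            XT_tr, y_tr, lams, tol, max_outer, dev_change_tol)
        tot[k] = _heldout_deviance(XT, y, te_idx, betas, b0s, ncomp)
        counts[k] = n_te
    return tot, counts
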