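"""Full-information maximum likelihood (FIML) for incomplete data.

Rows are grouped by missingness pattern; each pattern contributes the
multivariate-normal log-likelihood of its observed sub-vector under the
pattern-marginalized implied mean and covariance.  The model chi-square is
2*(ll_saturated - ll_model), with the saturated mean/covariance obtained by
EM.  A saturated mean structure (one free mean per observed variable) is
estimated alongside the covariance-structure parameters, so model degrees of
freedom coincide with the complete-data ML fit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .fit import FitError, FittedModel, _smart_starts, implied_covariance
from .model import ModelSpec

__all__ = ["fiml_loglik", "fit_fiml", "mvn_em"]

_LOG2PI = np.log(2 * np.pi)


def _pattern_stats(Y: np.ndarray):
    """Sufficient statistics per missingness pattern.

    Returns a list of (obs_idx, n_g, mean_g, scatter_g) with scatter the
    ML (divisor n_g) covariance of the pattern's observed block.
    """
    mask = ~np.isnan(Y)
    if not mask.any(axis=1).all():
        raise FitError("a row has no observed variables")
    out = []
    keys, inv = np.unique(mask, axis=0, return_inverse=True)
    for g, key in enumerate(keys):
        rows = Y[inv == g][:, key]
        obs = np.flatnonzero(key)
        ng = rows.shape[0]
        m = rows.mean(axis=0)
        d = rows - m
        out.append((obs, ng, m, d.T @ d / ng))
    return out


def _ll_patterns(patterns, mu: np.ndarray, Sigma: np.ndarray) -> float:
    ll = 0.0
    for obs, ng, m, sc in patterns:
        sub = Sigma[np.ix_(obs, obs)]
        k = len(obs)
        try:
            c = linalg.cholesky(sub, lower=True)
        except linalg.LinAlgError as exc:
            raise FitError(
                f"implied sub-covariance singular for pattern {tuple(obs)}"
            ) from exc
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        inv = linalg.cho_solve((c, True), np.eye(k))
        dm = m - mu[obs]
        ll += -0.5 * ng * (k * _LOG2PI + logdet + np.sum(inv * sc)
                           + dm @ inv @ dm)
    return float(ll)


def fiml_loglik(spec: ModelSpec, params, data: pd.DataFrame,
                means=None) -> float:
    """FIML log-likelihood of incomplete data under the implied moments.

    ``means`` may be a dict or array over ``spec.observed``; when omitted,
    the observed per-column means are used (pure covariance-structure use).
    """
    Y = data[spec.observed].to_numpy(float)
    if means is None:
        mu = np.nanmean(Y, axis=0)
    elif isinstance(means, dict):
        mu = np.array([means[v] for v in spec.observed], float)
    else:
        mu = np.asarray(means, float)
    Sigma = implied_covariance(spec, params)
    return _ll_patterns(_pattern_stats(Y), mu, Sigma)


# --------------------------------------------------------------------------
def mvn_em(Y: np.ndarray, max_iter: int = 500,
           tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray, float]:
    """EM estimate of a saturated multivariate-normal mean and covariance.

    Returns (mu, Sigma, loglik) for data with NaN missingness.
    """
    Y = np.asarray(Y, float)
    n, p = Y.shape
    col_ok = ~np.all(np.isnan(Y), axis=0)
    if not col_ok.all():
        raise FitError(f"variable column(s) {np.flatnonzero(~col_ok)} "
                       "entirely missing; drop them explicitly")
    patterns = _pattern_stats(Y)
    mu = np.nanmean(Y, axis=0)
    d = np.where(np.isnan(Y), 0.0, Y - mu)
    Sigma = d.T @ d / n + np.eye(p) * 1e-3
    ll_old = -np.inf
    mask = ~np.isnan(Y)
    keys, inv_map = np.unique(mask, axis=0, return_inverse=True)
    groups = [np.flatnonzero(inv_map == g) for g in range(len(keys))]
    for _ in range(max_iter):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        for key, rows in zip(keys, groups):
            obs = np.flatnonzero(key)
            mis = np.flatnonzero(~key)
            Yo = Y[np.ix_(rows, obs)]
            ng = len(rows)
            if len(mis) == 0:
                sum_x += Yo.sum(axis=0)
                sum_xx += Yo.T @ Yo
                continue
            Soo = Sigma[np.ix_(obs, obs)]
            Smo = Sigma[np.ix_(mis, obs)]
            W = linalg.solve(Soo, Smo.T, assume_a="pos").T     # S_mo S_oo^-1
            cond_cov = Sigma[np.ix_(mis, mis)] - W @ Smo.T
            Em = mu[mis] + (Yo - mu[obs]) @ W.T
            X = np.zeros((ng, p))
            X[:, obs] = Yo
            X[:, mis] = Em
            sum_x += X.sum(axis=0)
            xx = X.T @ X
            xx[np.ix_(mis, mis)] += ng * cond_cov
            sum_xx += xx
        mu = sum_x / n
        Sigma = sum_xx / n - np.outer(mu, mu)
        Sigma = (Sigma + Sigma.T) / 2
        ll = _ll_patterns(patterns, mu, Sigma)
        if ll - ll_old < tol:
            break
        ll_old = ll
    return mu, Sigma, ll


# --------------------------------------------------------------------------
def fit_fiml(spec: ModelSpec, data: pd.DataFrame, *, max_restarts: int = 3,
             gtol: float = 1e-5, compute_se: bool = True,
             seed: int = 0) -> FittedModel:
    """Fit the covariance structure plus saturated means by FIML."""
    spec.check_identified()
    Y = data[spec.observed].to_numpy(float)
    n, p = Y.shape
    patterns = _pattern_stats(Y)
    mu_sat, S_sat, ll_sat = mvn_em(Y)

    labels = spec.free_labels()
    k = len(labels)
    mean_labels = [f"mean({v})" for v in spec.observed]

    def unpack(x):
        return x[:k], x[k:]

    def negll(x):
        th, mu = unpack(x)
        try:
            Sigma = implied_covariance(spec, th)
            return -_ll_patterns(patterns, mu, Sigma)
        except FitError:
            return 1e12

    x0 = np.concatenate([_smart_starts(spec, S_sat), mu_sat])
    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(max_restarts + 1):
        res = optimize.minimize(negll, x0, method="L-BFGS-B", jac="3-point",
                                options={"maxiter": 4000, "ftol": 5e-15})
        gnorm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
        if best is None or res.fun < best[0].fun:
            best = (res, gnorm)
        if gnorm < gtol * max(1.0, n / 100):
            break
        x0 = best[0].x * (1 + 0.1 * rng.standard_normal(len(x0)))
    res, gnorm = best
    # gradient tolerance scales with N because the objective is -sum ll
    converged = bool(res.fun < 1e11 and gnorm < gtol * max(1.0, n))

    th, mu = unpack(res.x)
    params = dict(zip(labels, map(float, th)))
    params.update(dict(zip(mean_labels, map(float, mu))))
    ll_model = -float(res.fun)
    chi2 = max(2.0 * (ll_sat - ll_model), 0.0)
    df = p * (p + 1) // 2 - k
    pval = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0

    warns = []
    for e in spec._covs:
        if e.free and e.row == e.col and params[e.label] < 0:
            warns.append(f"Heywood case: variance {e.label} < 0")

    se = {l: np.nan for l in params}
    if compute_se and converged:
        H = _num_hessian(negll, res.x)
        try:
            acov = linalg.inv(H)
            d = np.diag(acov).copy()
            d[d < 0] = np.nan
            se_vec = np.sqrt(d)
        except linalg.LinAlgError:
            se_vec = np.full(len(res.x), np.nan)
            warns.append("observed information singular")
        se = dict(zip(labels + mean_labels, map(float, se_vec)))

    return FittedModel(spec=spec, estimator="fiml", params=params, se=se,
                       n=n, chi2=chi2, df=df, p=pval, converged=converged,
                       grad_norm=gnorm, loglik=ll_model, warnings_=warns,
                       sample_cov=S_sat, sample_mean=mu_sat)


def _num_hessian(f, x, h_rel: float = 1e-4) -> np.ndarray:
    k = len(x)
    h = h_rel * np.maximum(1.0, np.abs(x))
    H = np.zeros((k, k))
    f0 = f(x)
    fp = np.zeros(k)
    for i in range(k):
        xp = x.copy(); xp[i] += h[i]
        fp[i] = f(xp)
    for i in range(k):
        for j in range(i, k):
            xpp = x.copy(); xpp[i] += h[i]; xpp[j] += h[j]
            H[i, j] = H[j, i] = (f(xpp) - fp[i] - fp[j] + f0) / (h[i] * h[j])
    return H
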