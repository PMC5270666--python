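"""Maximum-likelihood covariance-structure estimation.

Fits a :class:`~deltascreen.sem.model.ModelSpec` to a sample covariance
matrix by minimizing the normal-theory ML discrepancy

    F_ML(theta) = ln|Sigma(theta)| + tr(S Sigma^-1) - ln|S| - p,

with chi-square = (N - 1) * F_min (the Wishart-likelihood reporting
convention common in covariance-structure software; switchable to N).
The gradient of F_ML is analytic; standard errors come from the numerically
differentiated observed information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .model import ModelSpec, SpecError

__all__ = ["FittedModel", "FitError", "implied_covariance", "ml_discrepancy",
           "fit_ml", "fit_ml_cov", "independence_fit_cov", "sample_cov"]

_BIG = 1e12


class FitError(RuntimeError):
    pass


@dataclass
class FittedModel:
    """Estimation result: point estimates, SEs, fit statistics."""

    spec: ModelSpec
    estimator: str                     # "ml" | "fiml" | "ml-multigroup"
    params: dict[str, float]
    se: dict[str, float]
    n: int
    chi2: float
    df: int
    p: float
    converged: bool
    grad_norm: float
    fmin: float | None = None          # ML discrepancy at solution
    loglik: float | None = None        # FIML log-likelihood at solution
    warnings_: list[str] = field(default_factory=list)
    sample_cov: np.ndarray | None = None
    sample_mean: np.ndarray | None = None

    def theta(self) -> np.ndarray:
        return np.array([self.params[l] for l in self.spec.free_labels()])

    def z(self) -> dict[str, float]:
        return {l: self.params[l] / self.se[l] if self.se.get(l, 0) > 0
                else np.nan for l in self.params}

    def pvalues(self) -> dict[str, float]:
        return {l: 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
                for l, z in self.z().items()}

    def to_frame(self) -> pd.DataFrame:
        """Parameter table (parameter, estimate, SE, z, p)."""
        rows = []
        pv = self.pvalues()
        zz = self.z()
        for l in self.params:
            rows.append((l, self.params[l], self.se.get(l, np.nan),
                         zz.get(l, np.nan), pv.get(l, np.nan)))
        return pd.DataFrame(rows, columns=["parameter", "estimate", "se",
                                           "z", "p"])


# --------------------------------------------------------------------------
def implied_covariance(spec: ModelSpec, params) -> np.ndarray:
    """Model-implied covariance of the observed variables, F B S B' F'."""
    A, S = spec.matrices(params)
    nv = A.shape[0]
    B = linalg.solve(np.eye(nv) - A, np.eye(nv))
    C = B @ S @ B.T
    sigma = C[: spec.n_obs, : spec.n_obs]
    if not np.all(np.isfinite(sigma)):
        raise FitError("implied covariance has non-finite entries")
    return sigma


def ml_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    """Normal-theory discrepancy F_ML(S, Sigma); zero iff S == Sigma."""
    S = np.asarray(S, float)
    Sigma = np.asarray(Sigma, float)
    p = S.shape[0]
    if S.shape != Sigma.shape:
        raise ValueError("dimension mismatch")
    try:
        cS = linalg.cholesky(Sigma, lower=True)
    except linalg.LinAlgError as exc:
        raise FitError("singular model-implied covariance") from exc
    sign, logdet_s = np.linalg.slogdet(S)
    if sign <= 0:
        raise FitError("sample covariance not positive definite")
    logdet_sigma = 2.0 * np.sum(np.log(np.diag(cS)))
    trace = np.trace(linalg.cho_solve((cS, True), S))
    return float(logdet_sigma + trace - logdet_s - p)


def sample_cov(data: pd.DataFrame, columns: list[str]) -> tuple[np.ndarray, int]:
    """Complete-case sample covariance (ML divisor N, so complete-data ML
    and FIML maximize the same likelihood) and N."""
    sub = data[columns].dropna()
    n = len(sub)
    if n <= len(columns):
        raise FitError("too few complete cases for the observed registry")
    return np.cov(sub.to_numpy(float), rowvar=False, ddof=0), n


# --------------------------------------------------------------------------
def _objective_factory(spec: ModelSpec, S: np.ndarray):
    nv = len(spec.variables)
    p = spec.n_obs
    eye = np.eye(nv)
    path_ix, cov_ix = spec.entry_index_maps()
    k = spec.n_free
    sign, logdet_s = np.linalg.slogdet(S)
    if sign <= 0:
        raise FitError("sample covariance not positive definite")

    def fun_grad(theta):
        A, Sm = spec.matrices(theta)
        try:
            B = linalg.solve(eye - A, eye)
        except linalg.LinAlgError:
            return _BIG, np.zeros(k)
        C = B @ Sm @ B.T
        Sigma = C[:p, :p]
        try:
            cS = linalg.cholesky(Sigma, lower=True)
        except linalg.LinAlgError:
            return _BIG, np.zeros(k)
        logdet_sigma = 2.0 * np.sum(np.log(np.diag(cS)))
        Sigma_inv = linalg.cho_solve((cS, True), np.eye(p))
        f = logdet_sigma + float(np.sum(Sigma_inv * S)) - logdet_s - p
        E = Sigma_inv - Sigma_inv @ S @ Sigma_inv
        Ebar = np.zeros((nv, nv))
        Ebar[:p, :p] = E
        T1 = C @ Ebar @ B          # d/dA[i,j] = 2 * T1[j, i]
        T2 = B.T @ Ebar @ B        # d/dS[i,j]
        g = np.zeros(k)
        for lpos, i, j in path_ix:
            g[lpos] += 2.0 * T1[j, i]
        for lpos, i, j in cov_ix:
            g[lpos] += T2[i, i] if i == j else 2.0 * T2[i, j]
        return f, g

    return fun_grad


def _smart_starts(spec: ModelSpec, S: np.ndarray) -> np.ndarray:
    """Data-informed start values.

    Regressions among observed variables start at their OLS solution from S
    (exact ML for saturated recursive path models, so the optimizer only
    polishes); loadings start at 0.7 * sd; free (co)variances at their
    sample moments, residual variances at half the sample variance.
    """
    obs_ix = {v: i for i, v in enumerate(spec.observed)}
    starts = dict(zip(spec.free_labels(), spec.start_values()))

    parents: dict[str, list[str]] = {}
    for e in spec._paths:
        parents.setdefault(e.row, []).append(e.col)

    for dst, srcs in parents.items():
        if dst not in obs_ix:
            continue
        obs_srcs = [s for s in srcs if s in obs_ix]
        beta = {}
        if obs_srcs:
            ii = [obs_ix[s] for s in obs_srcs]
            d = obs_ix[dst]
            try:
                b = linalg.solve(S[np.ix_(ii, ii)], S[ii, d],
                                 assume_a="pos")
                beta = dict(zip(obs_srcs, b))
            except linalg.LinAlgError:
                pass
        for e in spec._paths:
            if e.free and e.row == dst and e.col in beta and e.label in starts:
                starts[e.label] = float(beta[e.col])

    for e in spec._paths:   # loadings latent -> observed
        if e.free and e.col not in obs_ix and e.row in obs_ix:
            # scale the declared start by the indicator's sd so spec-level
            # start structure (which fixes the factor-rotation basin) survives
            starts[e.label] = e.value * np.sqrt(S[obs_ix[e.row], obs_ix[e.row]])

    for e in spec._covs:
        if not e.free:
            continue
        if e.row in obs_ix and e.col in obs_ix:
            i, j = obs_ix[e.row], obs_ix[e.col]
            if i == j:
                has_parent = any(p.row == e.row for p in spec._paths)
                starts[e.label] = S[i, i] * (0.5 if has_parent else 1.0)
            else:
                starts[e.label] = S[i, j]
    return np.array([starts[l] for l in spec.free_labels()])


def fit_ml_cov(spec: ModelSpec, S: np.ndarray, n: int, *,
               chisq_divisor: str = "n-1", max_restarts: int = 5,
               gtol: float = 1e-5, compute_se: bool = True,
               seed: int = 0) -> FittedModel:
    """Fit by ML given a complete-case sample covariance ``S`` and size ``n``."""
    spec.check_identified()
    k = spec.n_free
    if n <= k:
        raise FitError(f"N={n} must exceed the {k} free parameters")
    fun_grad = _objective_factory(spec, S)
    x0 = _smart_starts(spec, S)
    rng = np.random.default_rng(seed)

    best = None
    for attempt in range(max_restarts + 1):
        res = optimize.minimize(fun_grad, x0, jac=True, method="L-BFGS-B",
                                options={"maxiter": 3000, "ftol": 1e-14,
                                         "gtol": 1e-10})
        gnorm = float(np.max(np.abs(res.jac)))
        if best is None or res.fun < best[0].fun:
            best = (res, gnorm)
        if gnorm < gtol and res.fun < _BIG / 2:
            break
        x0 = _smart_starts(spec, S) * (1 + 0.2 * rng.standard_normal(k)) \
            + 0.05 * rng.standard_normal(k)
    res, gnorm = best
    converged = bool(gnorm < gtol and res.fun < _BIG / 2)

    theta = res.x
    labels = spec.free_labels()
    params = dict(zip(labels, map(float, theta)))

    warns: list[str] = []
    _, Sm = spec.matrices(theta)
    for e in spec._covs:
        if e.free and e.row == e.col and params[e.label] < 0:
            warns.append(f"Heywood case: variance {e.label} = "
                         f"{params[e.label]:.4g} < 0")

    nfac = (n - 1) if chisq_divisor == "n-1" else n
    fmin = float(res.fun)
    chi2 = max(nfac * fmin, 0.0)
    p_obs = spec.n_obs
    df = p_obs * (p_obs + 1) // 2 - k
    pval = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0

    se = {l: np.nan for l in labels}
    if compute_se and converged:
        se_vec, hess_warn = _information_se(fun_grad, theta, nfac)
        se = dict(zip(labels, se_vec))
        if hess_warn:
            warns.append(hess_warn)

    return FittedModel(spec=spec, estimator="ml", params=params, se=se, n=n,
                       chi2=chi2, df=df, p=pval, converged=converged,
                       grad_norm=gnorm, fmin=fmin, warnings_=warns,
                       sample_cov=S)


def _information_se(fun_grad, theta, nfac) -> tuple[np.ndarray, str | None]:
    """SEs from the numerically differentiated analytic gradient of F_ML.

    acov(theta) = 2 / nfac * H^-1 with H the Hessian of F_ML.
    """
    k = len(theta)
    H = np.zeros((k, k))
    h = 1e-5 * np.maximum(1.0, np.abs(theta))
    for j in range(k):
        tp = theta.copy(); tp[j] += h[j]
        tm = theta.copy(); tm[j] -= h[j]
        _, gp = fun_grad(tp)
        _, gm = fun_grad(tm)
        H[:, j] = (gp - gm) / (2 * h[j])
    H = (H + H.T) / 2
    warn = None
    try:
        acov = 2.0 / nfac * linalg.inv(H)
    except linalg.LinAlgError:
        acov = 2.0 / nfac * linalg.pinv(H)
        warn = "information matrix singular; SEs from pseudo-inverse"
    d = np.diag(acov).copy()
    if np.any(d < 0):
        warn = "negative information diagonal; some SEs undefined"
        d[d < 0] = np.nan
    return np.sqrt(d), warn


def fit_ml(spec: ModelSpec, data: pd.DataFrame, **kwargs) -> FittedModel:
    """Complete-case ML fit from subject-level data."""
    S, n = sample_cov(data, spec.observed)
    fitted = fit_ml_cov(spec, S, n, **kwargs)
    fitted.sample_mean = data[spec.observed].dropna().mean().to_numpy()
    return fitted


# --------------------------------------------------------------------------
def independence_fit_cov(S: np.ndarray, n: int, *,
                         chisq_divisor: str = "n-1") -> FittedModel:
    """Closed-form independence (null) model: variances free, covariances 0."""
    p = S.shape[0]
    sign, logdet_s = np.linalg.slogdet(S)
    if sign <= 0:
        raise FitError("sample covariance not positive definite")
    f0 = float(np.sum(np.log(np.diag(S))) - logdet_s)
    nfac = (n - 1) if chisq_divisor == "n-1" else n
    chi2 = max(nfac * f0, 0.0)
    df = p * (p - 1) // 2
    names = [f"v{i}" for i in range(p)]
    spec = ModelSpec(observed=names)
    for i, nm in enumerate(names):
        spec.add_variance(nm, start=S[i, i])
    return FittedModel(spec=spec, estimator="ml",
                       params={f"{nm}~~{nm}": float(S[i, i])
                               for i, nm in enumerate(names)},
                       se={}, n=n, chi2=chi2, df=df,
                       p=float(stats.chi2.sf(chi2, df)) if df else 1.0,
                       converged=True, grad_norm=0.0, fmin=f0, sample_cov=S)
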