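"""Independent SEM oracles used only by the test suite.

These deliberately avoid the package's reticular-action assembly and
analytic-gradient optimizer:

* CFA models are assembled directly as Sigma = Lam Phi Lam' + Theta and fit
  with Nelder-Mead-free numeric BFGS from truth-informed starts.
* Recursive path models with a saturated exogenous block are solved in
  closed form: the normal-theory likelihood factorizes into conditional
  regressions, so equation-wise OLS from the sample moments IS the ML
  solution (no optimizer at all).
* The ML discrepancy has a second form via eigendecomposition.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg, optimize


def eig_ml_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    """F_ML recomputed through eigendecompositions only."""
    p = S.shape[0]
    w_sigma, V = linalg.eigh(Sigma)
    if np.any(w_sigma <= 0):
        raise ValueError("Sigma not positive definite")
    w_s = linalg.eigh(S, eigvals_only=True)
    if np.any(w_s <= 0):
        raise ValueError("S not positive definite")
    logdet_sigma = float(np.sum(np.log(w_sigma)))
    logdet_s = float(np.sum(np.log(w_s)))
    # tr(S Sigma^-1) = sum_ij (V' S V)_ij-diagonal weighted by 1/w
    trace = float(np.sum(np.diag(V.T @ S @ V) / w_sigma))
    return logdet_sigma + trace - logdet_s - p


# --------------------------------------------------------------------------
# CFA oracle: theta packs [loadings..., uniques..., factor covs...]
class CfaDescription:
    """factors: list of lists of indicator indices (per factor);
    free factor covariances for every factor pair; unit factor variances."""

    def __init__(self, p: int, factors: list[list[int]]):
        self.p = p
        self.factors = factors
        self.q = len(factors)
        self.n_load = sum(len(f) for f in factors)
        self.n_cov = self.q * (self.q - 1) // 2

    def sigma(self, theta: np.ndarray) -> np.ndarray:
        lam = np.zeros((self.p, self.q))
        k = 0
        for j, idxs in enumerate(self.factors):
            for i in idxs:
                lam[i, j] = theta[k]
                k += 1
        uniq = theta[k:k + self.p]
        k += self.p
        phi = np.eye(self.q)
        for a in range(self.q):
            for b in range(a + 1, self.q):
                phi[a, b] = phi[b, a] = theta[k]
                k += 1
        return lam @ phi @ lam.T + np.diag(uniq)

    def n_par(self) -> int:
        return self.n_load + self.p + self.n_cov


def fit_cfa_oracle(desc: CfaDescription, S: np.ndarray,
                   start: np.ndarray) -> np.ndarray:
    """Numeric-gradient BFGS on the directly assembled discrepancy."""
    sign, logdet_s = np.linalg.slogdet(S)
    p = S.shape[0]

    def f(theta):
        Sigma = desc.sigma(theta)
        try:
            c = linalg.cholesky(Sigma, lower=True)
        except linalg.LinAlgError:
            return 1e10
        logdet = 2 * np.sum(np.log(np.diag(c)))
        tr = np.trace(linalg.cho_solve((c, True), S))
        return logdet + tr - logdet_s - p

    res = optimize.minimize(f, start, method="BFGS",
                            options={"gtol": 1e-10, "maxiter": 5000})
    # polish with a second pass from the first solution
    res = optimize.minimize(f, res.x, method="BFGS",
                            options={"gtol": 1e-11, "maxiter": 5000})
    return res.x


# --------------------------------------------------------------------------
# Recursive path-model oracle: exact closed-form ML
def fit_path_oracle(order: list[str], parents: dict[str, list[str]],
                    S: np.ndarray, names: list[str]) -> dict[str, float]:
    """Closed-form ML for a recursive path model.

    ``order`` lists variables causally; exogenous variables (no parents)
    get their sample (co)variances; each endogenous variable's paths are
    the OLS solution on its parents and its residual variance the OLS
    residual variance.  Returns {label: value} with the package's label
    conventions (dst~src, v~~v, a~~b).
    """
    ix = {nm: i for i, nm in enumerate(names)}
    out: dict[str, float] = {}
    exog = [v for v in order if not parents.get(v)]
    for i, v in enumerate(exog):
        out[f"{v}~~{v}"] = S[ix[v], ix[v]]
        for w in exog[i + 1:]:
            out[f"{v}~~{w}"] = S[ix[v], ix[w]]
    for v in order:
        pa = parents.get(v)
        if not pa:
            continue
        pi = [ix[w] for w in pa]
        beta = linalg.solve(S[np.ix_(pi, pi)], S[pi, ix[v]], assume_a="pos")
        for w, bcoef in zip(pa, beta):
            out[f"{v}~{w}"] = float(bcoef)
        out[f"{v}~~{v}"] = float(S[ix[v], ix[v]] - S[pi, ix[v]] @ beta)
    return out


# --------------------------------------------------------------------------
def random_cfa(rng: np.random.Generator):
    """Random identified CFA; returns (package spec, oracle desc, truth
    theta, variable names)."""
    from deltascreen.sem import ModelSpec

    q = int(rng.integers(1, 3))
    sizes = [int(rng.integers(3, 5)) for _ in range(q)]
    p = sum(sizes)
    names = [f"y{i}" for i in range(p)]
    factors = []
    k = 0
    for sz in sizes:
        factors.append(list(range(k, k + sz)))
        k += sz
    desc = CfaDescription(p, factors)
    loads = rng.uniform(0.5, 0.9, desc.n_load)
    uniqs = rng.uniform(0.3, 0.6, p)
    covs = rng.uniform(0.2, 0.5, desc.n_cov)
    truth = np.concatenate([loads, uniqs, covs])

    spec = ModelSpec(observed=names, latent=[f"f{j}" for j in range(q)])
    for j in range(q):
        spec.add_variance(f"f{j}", free=False, value=1.0)
    for j, idxs in enumerate(factors):
        for i in idxs:
            spec.add_path(f"f{j}", names[i], start=0.7)
    for nm in names:
        spec.add_variance(nm, start=0.5)
    for a in range(q):
        for b in range(a + 1, q):
            spec.add_covariance(f"f{a}", f"f{b}", start=0.3)
    return spec, desc, truth, names


def cfa_oracle_params(desc: CfaDescription, theta: np.ndarray,
                      names: list[str]) -> dict[str, float]:
    """Map oracle theta to the package's label convention."""
    out = {}
    k = 0
    for j, idxs in enumerate(desc.factors):
        for i in idxs:
            out[f"{names[i]}~f{j}"] = theta[k]
            k += 1
    for i in range(desc.p):
        out[f"{names[i]}~~{names[i]}"] = theta[k]
        k += 1
    for a in range(desc.q):
        for b in range(a + 1, desc.q):
            out[f"f{a}~~f{b}"] = theta[k]
            k += 1
    return out


def random_path_model(rng: np.random.Generator):
    """Random recursive path model; returns (spec, order, parents, names,
    true coefficient matrix for simulation)."""
    from deltascreen.sem import ModelSpec

    p = int(rng.integers(4, 7))
    names = [f"v{i}" for i in range(p)]
    n_exog = int(rng.integers(1, 3))
    parents: dict[str, list[str]] = {}
    for i in range(n_exog, p):
        preds = names[:i]
        size = int(rng.integers(1, len(preds) + 1))
        chosen = sorted(rng.choice(len(preds), size=size, replace=False))
        parents[names[i]] = [preds[j] for j in chosen]

    spec = ModelSpec(observed=names)
    exog = names[:n_exog]
    for i, v in enumerate(exog):
        spec.add_variance(v)
        for w in exog[i + 1:]:
            spec.add_covariance(v, w)
    for v in names[n_exog:]:
        for w in parents[v]:
            spec.add_path(w, v)
        spec.add_variance(v)

    B = np.zeros((p, p))
    for v, pa in parents.items():
        for w in pa:
            B[names.index(v), names.index(w)] = rng.uniform(-0.8, 0.8)
    return spec, names, parents, B, n_exog


def simulate_path_data(names, B, n_exog, n, rng):
    p = len(names)
    X = np.empty((n, p))
    X[:, :n_exog] = rng.standard_normal((n, n_exog))
    if n_exog > 1:   # give exogenous block some correlation
        X[:, 1] = 0.4 * X[:, 0] + np.sqrt(1 - 0.16) * X[:, 1]
    for i in range(n_exog, p):
        X[:, i] = X @ B[i] + rng.standard_normal(n)
    return X
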