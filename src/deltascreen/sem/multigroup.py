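"""Simultaneous multi-group ML estimation.

Groups are fit jointly by minimizing sum_g (N_g - 1) * F_ML,g; the joint
likelihood is block-diagonal across groups, so parameters are independent
between groups except where two group specs share a free-parameter label,
which equates them.  Use :meth:`ModelSpec.relabel` to build group specs with
disjoint labels apart from a chosen shared set.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg, optimize, stats

from .fit import (FitError, FittedModel, _objective_factory, _smart_starts)
from .model import ModelSpec

__all__ = ["fit_ml_multigroup"]


def fit_ml_multigroup(specs: list[ModelSpec], S_list: list[np.ndarray],
                      n_list: list[int], *, chisq_divisor: str = "n-1",
                      max_restarts: int = 3, gtol: float = 1e-6,
                      compute_se: bool = True, seed: int = 0) -> FittedModel:
    if not (len(specs) == len(S_list) == len(n_list)):
        raise ValueError("specs, covariances and sizes must align")
    for sp in specs:
        sp.check_identified()

    # global parameter registry: union of group labels, in first-seen order
    global_labels: list[str] = []
    seen = set()
    for sp in specs:
        for l in sp.free_labels():
            if l not in seen:
                seen.add(l)
                global_labels.append(l)
    pos = {l: i for i, l in enumerate(global_labels)}
    k = len(global_labels)

    group_fun = []
    group_idx = []
    weights = []
    for sp, S, n in zip(specs, S_list, n_list):
        group_fun.append(_objective_factory(sp, S))
        group_idx.append(np.array([pos[l] for l in sp.free_labels()], int))
        weights.append((n - 1) if chisq_divisor == "n-1" else n)

    def fun_grad(theta):
        f = 0.0
        g = np.zeros(k)
        for fg, idx, w in zip(group_fun, group_idx, weights):
            fg_val, fg_grad = fg(theta[idx])
            f += w * fg_val
            np.add.at(g, idx, w * fg_grad)
        return f, g

    # starts: average the per-group data-informed starts for shared labels
    x0 = np.zeros(k)
    cnt = np.zeros(k)
    for sp, S, idx in zip(specs, S_list, group_idx):
        st = _smart_starts(sp, S)
        np.add.at(x0, idx, st)
        np.add.at(cnt, idx, 1.0)
    x0 /= np.maximum(cnt, 1.0)

    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(max_restarts + 1):
        res = optimize.minimize(fun_grad, x0, jac=True, method="L-BFGS-B",
                                options={"maxiter": 5000, "ftol": 1e-14,
                                         "gtol": 1e-10})
        gnorm = float(np.max(np.abs(res.jac)))
        if best is None or res.fun < best[0].fun:
            best = (res, gnorm)
        if gnorm < gtol * max(1.0, max(weights)):
            break
        x0 = best[0].x * (1 + 0.1 * rng.standard_normal(k))
    res, gnorm = best
    converged = bool(res.fun < 1e11 and gnorm < gtol * max(weights))

    params = dict(zip(global_labels, map(float, res.x)))
    chi2 = max(float(res.fun), 0.0)
    df = sum(sp.n_obs * (sp.n_obs + 1) // 2 for sp in specs) - k
    pval = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0

    se = {l: np.nan for l in global_labels}
    warns: list[str] = []
    if compute_se and converged:
        # -2 lnL ~ sum_g w_g F_g + const, so acov = 2 * H^-1
        H = np.zeros((k, k))
        h = 1e-5 * np.maximum(1.0, np.abs(res.x))
        for j in range(k):
            tp = res.x.copy(); tp[j] += h[j]
            tm = res.x.copy(); tm[j] -= h[j]
            H[:, j] = (fun_grad(tp)[1] - fun_grad(tm)[1]) / (2 * h[j])
        H = (H + H.T) / 2
        try:
            acov = 2.0 * linalg.inv(H)
            d = np.diag(acov).copy()
            d[d < 0] = np.nan
            se = dict(zip(global_labels, map(float, np.sqrt(d))))
        except linalg.LinAlgError:
            warns.append("joint information matrix singular")

    # carry the first spec for registry purposes; chi2/df describe the joint fit
    return FittedModel(spec=specs[0], estimator="ml-multigroup",
                       params=params, se=se, n=int(sum(n_list)), chi2=chi2,
                       df=df, p=pval, converged=converged, grad_norm=gnorm,
                       fmin=float(res.fun), warnings_=warns)
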