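"""The latent dementia phenotype (delta) and its cognitive residual (g').

delta is the fraction of general cognitive performance shared with
functional status: all five indicators (four cognitive tests plus summed
IADL) load on delta, the four cognitive indicators additionally load on the
orthogonal g', and IADL loads on delta only.  Both latent variances are
fixed to 1 so factor-score weights are scale-free.  Higher scores mean
better performance throughout; the delta composite is therefore expected to
correlate negatively with age and with CDR severity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.metrics import roc_auc_score

from .sem import (FitError, FittedModel, ModelSpec, fit_fiml, fit_indices,
                  fit_ml, independence_fit_cov)
from .synthetic import INDICATORS

__all__ = ["build_deq_spec", "factor_score_weights", "composite_scores",
           "factor_determinacy", "auc_roc", "validate_vs_severity",
           "DeltaFit", "fit_delta"]


def build_deq_spec(indicator_names: list[str] = INDICATORS) -> ModelSpec:
    """Bifactor specification: 5 indicators on delta, 4 cognitive on g'.

    Exactly five names are required and one of them must identify IADL
    (case-insensitive substring "iadl"); delta and g' are orthogonal with
    unit variance.  Free parameters: 5 + 4 loadings + 5 residual variances
    = 14, leaving 1 model degree of freedom.
    """
    if len(indicator_names) != 5:
        raise ValueError(f"expected exactly 5 indicators, got "
                         f"{len(indicator_names)}")
    iadl = [nm for nm in indicator_names if "iadl" in nm.lower()]
    if len(iadl) != 1:
        raise ValueError("exactly one indicator must identify IADL "
                         f"(got {iadl or 'none'})")
    spec = ModelSpec(observed=list(indicator_names),
                     latent=["delta", "gprime"])
    spec.add_variance("delta", free=False, value=1.0)
    spec.add_variance("gprime", free=False, value=1.0)
    spec.add_covariance("delta", "gprime", free=False, value=0.0)
    for nm in indicator_names:
        # starts encode the construct: IADL is the dominant delta marker,
        # the cognitive tests are dominated by g' with delta residual
        # content of unknown sign; this picks the intended rotation basin
        spec.add_path("delta", nm, start=0.85 if nm == iadl[0] else 0.0)
        if nm != iadl[0]:
            spec.add_path("gprime", nm, start=0.70)
        spec.add_variance(nm, start=0.15 if nm == iadl[0] else 0.40)
    spec.check_identified()
    return spec


def _lambda_phi_sigma(fitted: FittedModel):
    spec = fitted.spec
    A, S = spec.matrices(fitted.params)
    p = spec.n_obs
    lat = [spec.variables.index(v) for v in spec.latent]
    Lam = A[:p, lat]
    Phi = S[np.ix_(lat, lat)]
    Theta = S[:p, :p]
    Sigma = Lam @ Phi @ Lam.T + Theta
    return Lam, Phi, Sigma


def factor_score_weights(fitted: FittedModel) -> pd.DataFrame:
    """Regression-method weights W = Sigma^-1 Lambda Phi (indicators x
    factors), deterministic given the estimates."""
    Lam, Phi, Sigma = _lambda_phi_sigma(fitted)
    try:
        W = linalg.solve(Sigma, Lam @ Phi, assume_a="pos")
    except linalg.LinAlgError as exc:
        raise FitError("implied covariance singular; no factor-score "
                       "weights") from exc
    return pd.DataFrame(W, index=fitted.spec.observed,
                        columns=fitted.spec.latent)


def factor_determinacy(fitted: FittedModel) -> dict[str, float]:
    """Grice determinacy: correlation between the regression factor score
    and the factor it estimates, rho_j = (W'Lam Phi)_jj /
    sqrt((W'Sigma W)_jj Phi_jj)."""
    Lam, Phi, Sigma = _lambda_phi_sigma(fitted)
    W = factor_score_weights(fitted).to_numpy()
    num = np.diag(W.T @ Lam @ Phi)
    den = np.sqrt(np.diag(W.T @ Sigma @ W) * np.diag(Phi))
    rho = np.where(den > 0, num / den, np.nan)
    return dict(zip(fitted.spec.latent, np.clip(rho, 0.0, 1.0)))


def composite_scores(W: pd.DataFrame, observed: pd.DataFrame,
                     means: pd.Series, sds: pd.Series) -> pd.DataFrame:
    """Apply factor weights to standardized observed indicators.

    Indicators are standardized to the *fitting sample's* scale via
    ``means``/``sds``.  Rows with any missing indicator are scored missing
    (complete-case scoring, which keeps the composites deterministic).
    """
    missing = [c for c in W.index if c not in observed.columns]
    if missing:
        raise KeyError(f"observed table lacks indicator column(s) {missing}")
    Z = (observed[W.index] - means[W.index]) / sds[W.index]
    scores = Z.to_numpy(float) @ W.to_numpy(float)
    scores[Z.isna().any(axis=1).to_numpy()] = np.nan
    out = pd.DataFrame(scores, index=observed.index, columns=list(W.columns))
    return out.rename(columns={"delta": "deq"})


def auc_roc(scores, labels, positive: str = "AD",
            higher_scores_indicate_positive: bool = False):
    """AUC by the Mann-Whitney identity with a Hanley-McNeil 95% CI.

    By default lower composite scores indicate the positive (impaired)
    class, matching the delta sign convention.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    ok = ~np.isnan(s)
    s, y = s[ok], y[ok]
    pos = y == positive
    n1, n2 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError(f"need both classes non-empty "
                         f"(positive={positive!r}: {n1} vs {n2})")
    direction = 1.0 if higher_scores_indicate_positive else -1.0
    auc = float(roc_auc_score(pos.astype(int), direction * s))
    q1 = auc / (2 - auc)
    q2 = 2 * auc ** 2 / (1 + auc)
    se = np.sqrt((auc * (1 - auc) + (n1 - 1) * (q1 - auc ** 2)
                  + (n2 - 1) * (q2 - auc ** 2)) / (n1 * n2))
    lo, hi = np.clip([auc - 1.96 * se, auc + 1.96 * se], 0.0, 1.0)
    return auc, (float(lo), float(hi))


def validate_vs_severity(scores, cdr):
    """Pearson correlation of the delta composite with CDR sum of boxes.

    Higher delta composite = better performance, so the expected sign is
    negative.  Returns (r, p)."""
    s = np.asarray(scores, float)
    c = np.asarray(cdr, float)
    ok = ~(np.isnan(s) | np.isnan(c))
    if ok.sum() < 3:
        raise ValueError("need at least 3 paired non-missing values")
    r, p = stats.pearsonr(s[ok], c[ok])
    return float(r), float(p)


def _canonicalize_signs(fitted: FittedModel, indicators: list[str]) -> None:
    """Resolve the reflection indeterminacy of each factor.

    Factor loadings are only identified up to a column sign flip; fix the
    convention that IADL loads positively on delta and the cognitive
    loadings on g' are positive on average (higher score = better
    performance for both factors)."""
    iadl = next(nm for nm in indicators if "iadl" in nm.lower())
    if fitted.params.get(f"{iadl}~delta", 0.0) < 0:
        for nm in indicators:
            key = f"{nm}~delta"
            if key in fitted.params:
                fitted.params[key] = -fitted.params[key]
    gsum = sum(fitted.params.get(f"{nm}~gprime", 0.0) for nm in indicators)
    if gsum < 0:
        for nm in indicators:
            key = f"{nm}~gprime"
            if key in fitted.params:
                fitted.params[key] = -fitted.params[key]


# --------------------------------------------------------------------------
@dataclass
class DeltaFit:
    """Fitted bifactor model with everything needed to score new data."""

    fitted: FittedModel
    weights: pd.DataFrame
    means: pd.Series
    sds: pd.Series
    determinacy: dict[str, float]
    indices: dict

    def score(self, observed: pd.DataFrame) -> pd.DataFrame:
        return composite_scores(self.weights, observed, self.means, self.sds)


def fit_delta(cohort: pd.DataFrame, indicators: list[str] = INDICATORS,
              estimator: str = "ml", seed: int = 0) -> DeltaFit:
    """Standardize the indicators, fit the bifactor spec, derive weights,
    determinacy and fit indices."""
    spec = build_deq_spec(indicators)
    means = cohort[indicators].mean()
    sds = cohort[indicators].std(ddof=1)
    z = (cohort[indicators] - means) / sds
    if estimator == "fiml":
        fitted = fit_fiml(spec, z, seed=seed)
    else:
        fitted = fit_ml(spec, z, seed=seed)
    _canonicalize_signs(fitted, indicators)
    null = independence_fit_cov(fitted.sample_cov, fitted.n)
    idx = fit_indices(fitted, null).as_dict()
    return DeltaFit(fitted=fitted, weights=factor_score_weights(fitted),
                    means=means, sds=sds,
                    determinacy=factor_determinacy(fitted), indices=idx)
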