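"""Per-biomarker mediation screen of age's effect on the delta composite.

PATH-LABEL WARNING
------------------
This package retains the path labels used in the delta-biomarker
literature, which are REVERSED from the conventional mediation a/b/c'
notation:

    path a : age -> delta composite, adjusted DIRECT effect
             (the conventional c')
    path b : biomarker -> delta composite    (conventional b)
    path c : age -> biomarker                (the conventional a)

The indirect effect is c*b, the total age effect is a + c*b, and the
percent mediated is 100*|c*b| / (|c*b| + |a|), which is positive for both
attenuating mediators (indirect effect shares the direct effect's sign) and
accentuating ones (opposite sign, i.e. suppression).  MacKinnon's signed
proportion c*b/(c*b + a) is emitted as a diagnostic column.

Each biomarker enters one at a time; biomarker and composites are adjusted
for the covariate set, age is never adjusted.  Significance of paths b and
c is gated at the Bonferroni-corrected p < 0.001, giving the four-class
taxonomy: 1 = mediator (b and c pass), 2 = age-related only (c passes),
3 = delta-related only (b passes), 4 = neither.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sem import (FittedModel, ModelSpec, fit_indices, fit_ml_cov,
                  independence_fit_cov, sample_cov)
from .synthetic import COVARIATES

__all__ = ["build_base_model", "build_mediation_model", "mediation_effect",
           "bonferroni_gate", "classify_protein", "run_screen",
           "MediationResult", "BONFERRONI_ALPHA"]

BONFERRONI_ALPHA = 1e-3


def _exogenous_block(spec: ModelSpec, exog: list[str]) -> None:
    """Free variances and pairwise covariances among the exogenous set."""
    for i, v in enumerate(exog):
        spec.add_variance(v)
        for w in exog[i + 1:]:
            spec.add_covariance(v, w)


def build_base_model(covariate_names: list[str] = COVARIATES) -> ModelSpec:
    """Regression of the delta and g' composites on age plus covariates.

    Age is the only unadjusted exogenous variable; covariates freely
    intercorrelate (with each other and with age), and the two composite
    residuals covary.  This model is saturated, so its coefficients match
    the multiple-regression total effects.
    """
    obs = ["deq", "gprime", "age"] + list(covariate_names)
    spec = ModelSpec(observed=obs)
    _exogenous_block(spec, ["age"] + list(covariate_names))
    for dv in ("deq", "gprime"):
        spec.add_path("age", dv, label=f"{dv}~age")
        for cv in covariate_names:
            spec.add_path(cv, dv)
        spec.add_variance(dv)
    spec.add_covariance("deq", "gprime")
    return spec


def build_mediation_model(biomarker_name: str,
                          covariate_names: list[str] = COVARIATES
                          ) -> ModelSpec:
    """Three-path model adding one (preprocessed) biomarker.

    biomarker ~ age (path c) + covariates; deq ~ age (path a) +
    biomarker (path b) + covariates; gprime ~ age + covariates.  No
    biomarker -> g' path is freed, leaving one model degree of freedom.
    """
    obs = ["deq", "gprime", "age", biomarker_name] + list(covariate_names)
    spec = ModelSpec(observed=obs)
    _exogenous_block(spec, ["age"] + list(covariate_names))

    spec.add_path("age", biomarker_name, label="path_c")
    for cv in covariate_names:
        spec.add_path(cv, biomarker_name)
    spec.add_variance(biomarker_name)

    spec.add_path("age", "deq", label="path_a")
    spec.add_path(biomarker_name, "deq", label="path_b")
    for cv in covariate_names:
        spec.add_path(cv, "deq")
    spec.add_variance("deq")

    spec.add_path("age", "gprime", label="gprime~age")
    for cv in covariate_names:
        spec.add_path(cv, "gprime")
    spec.add_variance("gprime")
    spec.add_covariance("deq", "gprime")
    return spec


def mediation_effect(path_a: float, path_c: float, path_b: float,
                     se_c: float, se_b: float):
    """Indirect effect, Sobel z, percent mediated and direction.

    indirect = c*b; sobel_z = c*b / sqrt(b^2 se_c^2 + c^2 se_b^2);
    percent = 100*|c*b| / (|c*b| + |a|).  Raises when the percent is
    undefined (a = 0 and c*b = 0).
    """
    for nm, v in [("path_a", path_a), ("path_c", path_c),
                  ("path_b", path_b)]:
        if not np.isfinite(v):
            raise ValueError(f"{nm} not finite")
    if not (se_c > 0 and se_b > 0):
        raise ValueError("standard errors must be positive")
    indirect = path_c * path_b
    if indirect == 0.0:
        sobel_z = 0.0
    else:
        sobel_z = indirect / np.sqrt(path_b ** 2 * se_c ** 2
                                     + path_c ** 2 * se_b ** 2)
    if indirect == 0.0 and path_a == 0.0:
        raise ValueError("percent mediated undefined: both the direct and "
                         "indirect effects are zero")
    percent = 100.0 * abs(indirect) / (abs(indirect) + abs(path_a))
    if indirect == 0.0:
        direction = ""
    elif np.sign(indirect) == np.sign(path_a):
        direction = "attenuating"
    else:
        direction = "accentuating"
    return float(indirect), float(sobel_z), float(percent), direction


def bonferroni_gate(p_value: float, alpha: float = BONFERRONI_ALPHA) -> bool:
    """Strict Bonferroni gate: True iff p < alpha (default 0.001)."""
    if not 0 <= p_value <= 1:
        raise ValueError("p-value outside [0, 1]")
    return p_value < alpha


@dataclass
class MediationResult:
    biomarker: str
    path_a: float = np.nan
    se_a: float = np.nan
    p_a: float = np.nan
    path_b: float = np.nan
    se_b: float = np.nan
    p_b: float = np.nan
    path_c: float = np.nan
    se_c: float = np.nan
    p_c: float = np.nan
    indirect: float = np.nan
    sobel_z: float = np.nan
    p_indirect: float = np.nan
    percent_mediated: float = np.nan
    signed_proportion: float = np.nan   # MacKinnon c*b/(c*b+a), diagnostic
    direction: str = ""
    protein_class: int = 4
    chi2: float = np.nan
    df: int = 0
    cfi: float = np.nan
    rmsea: float = np.nan
    converged: bool = False
    failure: str = ""

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def classify_protein(p_c: float, p_b: float,
                     alpha: float = BONFERRONI_ALPHA) -> int:
    """Four-class taxonomy from the gated path p-values."""
    c_pass = bonferroni_gate(p_c, alpha)
    b_pass = bonferroni_gate(p_b, alpha)
    if c_pass and b_pass:
        return 1
    if c_pass:
        return 2
    if b_pass:
        return 3
    return 4


def fit_mediation(data: pd.DataFrame, biomarker: str,
                  covariate_names: list[str] = COVARIATES,
                  alpha: float = BONFERRONI_ALPHA,
                  seed: int = 0) -> MediationResult:
    """Fit one biomarker's three-path model and summarize it."""
    spec = build_mediation_model(biomarker, covariate_names)
    res = MediationResult(biomarker=biomarker)
    try:
        S, n = sample_cov(data, spec.observed)
        fitted = fit_ml_cov(spec, S, n, seed=seed)
    except Exception as exc:  # recorded, never silently dropped
        res.failure = f"{type(exc).__name__}: {exc}"
        return res
    pv = fitted.pvalues()
    res.path_a = fitted.params["path_a"]
    res.se_a = fitted.se.get("path_a", np.nan)
    res.p_a = pv.get("path_a", np.nan)
    res.path_b = fitted.params["path_b"]
    res.se_b = fitted.se.get("path_b", np.nan)
    res.p_b = pv.get("path_b", np.nan)
    res.path_c = fitted.params["path_c"]
    res.se_c = fitted.se.get("path_c", np.nan)
    res.p_c = pv.get("path_c", np.nan)
    res.converged = fitted.converged
    if not fitted.converged:
        res.failure = "non-convergence"
        return res
    try:
        ind, z, pct, direction = mediation_effect(
            res.path_a, res.path_c, res.path_b, res.se_c, res.se_b)
    except ValueError as exc:
        res.failure = str(exc)
        return res
    res.indirect, res.sobel_z, res.direction = ind, z, direction
    res.p_indirect = 2.0 * stats.norm.sf(abs(z))
    denom = ind + res.path_a
    res.signed_proportion = ind / denom if denom != 0 else np.nan
    res.protein_class = classify_protein(res.p_c, res.p_b, alpha)
    # percent mediated is only meaningful for class-1 (true mediator) calls
    res.percent_mediated = pct if res.protein_class == 1 else np.nan
    null = independence_fit_cov(S, n)
    idx = fit_indices(fitted, null)
    res.chi2, res.df, res.cfi, res.rmsea = (idx.chi2, idx.df, idx.cfi,
                                            idx.rmsea)
    return res


def run_screen(data: pd.DataFrame, biomarker_list: list[str],
               covariate_names: list[str] = COVARIATES,
               alpha: float = BONFERRONI_ALPHA,
               seed: int = 0) -> pd.DataFrame:
    """Screen every biomarker one-at-a-time against the delta composite.

    ``data`` must already hold the ``deq``/``gprime`` composites and
    preprocessed biomarker columns.  Results are sorted by class, then by
    |percent mediated| descending; deterministic given data and config.
    """
    results = [fit_mediation(data, bm, covariate_names, alpha, seed=seed)
               for bm in biomarker_list]
    frame = pd.DataFrame([r.as_dict() for r in results])
    if frame.empty:
        return frame
    key = frame["percent_mediated"].abs().fillna(-1.0)
    frame = (frame.assign(_k=key)
             .sort_values(["protein_class", "_k", "biomarker"],
                          ascending=[True, False, True])
             .drop(columns="_k").reset_index(drop=True))
    return frame


def write_class_tables(screen: pd.DataFrame, outdir) -> dict[int, str]:
    """Emit the four class membership tables plus the mediation-effects
    table (class 1 with paths, Sobel z and percent mediated)."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[int, str] = {}
    for cls in (1, 2, 3, 4):
        sub = screen[screen["protein_class"] == cls][["biomarker"]]
        p = outdir / f"class{cls}_proteins.csv"
        sub.to_csv(p, index=False)
        paths[cls] = str(p)
    effects = screen[screen["protein_class"] == 1][
        ["biomarker", "path_a", "sobel_z", "p_indirect",
         "percent_mediated", "direction"]]
    effects.to_csv(outdir / "mediation_effects.csv", index=False)
    screen.to_csv(outdir / "screen_full.csv", index=False)
    return paths
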