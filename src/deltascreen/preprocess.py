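"""Biomarker conditioning chain: outlier trimming, log-normalization,
standardization and batch adjustment.

The chain order is fixed: (1) delete values beyond 3 SD of the column mean
(single pass, raw scale); (2) natural-log transform columns whose sample
skewness exceeds a threshold, then z-standardize; (3) residualize on batch
dummies; (4) re-standardize.  No step mutates its input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["remove_outliers", "normalize_biomarker", "residualize",
           "preprocess_cohort", "PreprocessError"]


class PreprocessError(ValueError):
    pass


def remove_outliers(values, sd_limit: float = 3.0):
    """Set entries with single-pass |z| > sd_limit to missing.

    z-scores use the mean and sample SD (ddof=1) of the non-missing input;
    the pass is not iterated.  Returns (cleaned array, count removed).
    """
    v = np.asarray(values, float).copy()
    ok = ~np.isnan(v)
    if ok.sum() == 0:
        raise PreprocessError("all values missing")
    if ok.sum() < 3:
        return v, 0
    mu = v[ok].mean()
    sd = v[ok].std(ddof=1)
    if sd == 0:
        return v, 0
    out = ok & (np.abs(v - mu) / sd > sd_limit)
    v[out] = np.nan
    return v, int(out.sum())


def normalize_biomarker(values, skew_threshold: float = 1.0,
                        name: str = "biomarker"):
    """Log-transform when |skewness| exceeds the threshold, then
    z-standardize (ddof=1) the non-missing entries.

    Non-positive values under the log branch are shifted by (1 - min) first.
    Returns (normalized array, log_applied flag).
    """
    v = np.asarray(values, float).copy()
    ok = ~np.isnan(v)
    if ok.sum() < 3:
        raise PreprocessError(f"{name}: fewer than 3 non-missing values")
    if v[ok].std(ddof=1) == 0:
        raise PreprocessError(f"{name}: zero variance after transform")
    log_applied = False
    g1 = stats.skew(v[ok], bias=False)
    if np.isfinite(g1) and abs(g1) > skew_threshold:
        shift = 0.0
        mn = v[ok].min()
        if mn <= 0:
            shift = 1.0 - mn
        v[ok] = np.log(v[ok] + shift)
        log_applied = True
    sd = v[ok].std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise PreprocessError(f"{name}: zero variance after transform")
    v[ok] = (v[ok] - v[ok].mean()) / sd
    return v, log_applied


def residualize(target, regressors) -> np.ndarray:
    """OLS residuals of target on the regressor matrix (plus intercept).

    Computed on complete cases; rows with a missing target stay missing.
    With an empty regressor matrix the centered target is returned.
    """
    y = np.asarray(target, float).copy()
    X = np.asarray(regressors, float)
    if X.ndim == 1:
        X = X[:, None]
    ok = ~np.isnan(y)
    if X.size:
        ok &= ~np.isnan(X).any(axis=1)
    if ok.sum() < 3:
        raise PreprocessError("fewer than 3 complete cases")
    out = np.full_like(y, np.nan)
    if X.size == 0 or X.shape[1] == 0:
        out[ok] = y[ok] - y[ok].mean()
        return out
    Xc = sm.add_constant(X[ok], has_constant="add")
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        corr = np.corrcoef(Xc[:, 1:], rowvar=False)
        pairs = [(i, j) for i in range(corr.shape[0])
                 for j in range(i + 1, corr.shape[1])
                 if abs(corr[i, j]) > 1 - 1e-10] if Xc.shape[1] > 2 else []
        raise PreprocessError(
            f"regressor matrix rank deficient (rank {rank} < {Xc.shape[1]}); "
            f"collinear column pairs: {pairs or 'constant column'}")
    res = sm.OLS(y[ok], Xc).fit()
    out[ok] = res.resid
    return out


def _batch_dummies(batch: pd.Series) -> np.ndarray:
    levels = sorted(pd.unique(batch.dropna()))
    if len(levels) <= 1:
        return np.empty((len(batch), 0))
    # drop the first level; constant column would be collinear with intercept
    return np.column_stack([(batch == lv).to_numpy(float)
                            for lv in levels[1:]])


@dataclass
class PreprocessReport:
    table: pd.DataFrame  # column, n_outliers, log_applied, batch_r2

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def preprocess_cohort(cohort: pd.DataFrame, biomarker_cols: list[str],
                      batch_col: str | None = "batch", *,
                      sd_limit: float = 3.0, skew_threshold: float = 1.0
                      ) -> tuple[pd.DataFrame, PreprocessReport]:
    """Apply the full conditioning chain to every biomarker column.

    Returns a new cohort table plus a per-column report (outliers removed,
    whether the log branch fired, variance explained by batch).
    """
    out = cohort.copy()
    dummies = (_batch_dummies(cohort[batch_col])
               if batch_col and batch_col in cohort else
               np.empty((len(cohort), 0)))
    rows = []
    for col in biomarker_cols:
        v, n_out = remove_outliers(out[col].to_numpy(float), sd_limit)
        v, logged = normalize_biomarker(v, skew_threshold, name=col)
        var_before = np.nanvar(v, ddof=1)
        v = residualize(v, dummies)
        var_after = np.nanvar(v, ddof=1)
        batch_r2 = max(0.0, 1.0 - var_after / var_before) if var_before else 0.0
        ok = ~np.isnan(v)
        sd = v[ok].std(ddof=1)
        if sd == 0:
            raise PreprocessError(f"{col}: zero variance after batch "
                                  "adjustment")
        v[ok] = (v[ok] - v[ok].mean()) / sd
        out[col] = v
        rows.append((col, n_out, logged, batch_r2))
    report = PreprocessReport(pd.DataFrame(
        rows, columns=["column", "n_outliers", "log_applied", "batch_r2"]))
    return out, report
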