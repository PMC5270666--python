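"""Global fit indices and nested-model chi-square tests.

Conventions follow the common SEM reporting practice: CMIN/DF < 5 is read
as adequate, CFI >= 0.90 as non-misspecified, RMSEA <= 0.05 as close fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fit import FittedModel

__all__ = ["FitIndices", "fit_indices", "chi_square_difference"]


@dataclass
class FitIndices:
    chi2: float
    df: int
    p: float
    cmin_df: float
    cfi: float
    rmsea: float

    def as_dict(self) -> dict:
        return {"chi2": self.chi2, "df": self.df, "p": self.p,
                "cmin_df": self.cmin_df, "cfi": self.cfi,
                "rmsea": self.rmsea}


def fit_indices(model: FittedModel, null_model: FittedModel) -> FitIndices:
    """CMIN/DF, CFI and RMSEA from the model and independence-model fits.

    CFI = 1 - max(chi2_M - df_M, 0) / max(chi2_0 - df_0, chi2_M - df_M, 0),
    clipped to [0, 1].  RMSEA = sqrt(max(chi2_M - df_M, 0) / (df_M (N-1))).
    With df_M = 0 the RMSEA is undefined (NaN); the CFI max() guards still
    give 1.0 for a perfectly fitting saturated model.
    """
    cm, dm = model.chi2, model.df
    c0, d0 = null_model.chi2, null_model.df
    num = max(cm - dm, 0.0)
    den = max(c0 - d0, cm - dm, 0.0)
    cfi = 1.0 if den == 0.0 else float(np.clip(1.0 - num / den, 0.0, 1.0))
    if dm > 0:
        rmsea = float(np.sqrt(num / (dm * (model.n - 1))))
        cmin_df = cm / dm
        p = float(stats.chi2.sf(cm, dm))
    else:
        rmsea = float("nan")
        cmin_df = float("nan")
        p = 1.0
    return FitIndices(chi2=cm, df=dm, p=p, cmin_df=cmin_df, cfi=cfi,
                      rmsea=rmsea)


def chi_square_difference(constrained: FittedModel,
                          unconstrained: FittedModel,
                          tol: float = 1e-6):
    """Likelihood-ratio test of nested fits on the same data.

    Returns (delta_chi2, delta_df, p).  The constrained model must lose
    degrees of freedom relative to the unconstrained one.
    """
    ddf = constrained.df - unconstrained.df
    if ddf <= 0:
        raise ValueError("models are not nested (delta df <= 0)")
    dchi = constrained.chi2 - unconstrained.chi2
    if dchi < -tol * max(1.0, abs(unconstrained.chi2)):
        raise ValueError(
            f"constrained chi2 below unconstrained ({dchi:.3g}); "
            "one of the fits has not converged")
    dchi = max(dchi, 0.0)
    return dchi, ddf, float(stats.chi2.sf(dchi, ddf))
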