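"""Split-half generalizability of the mediation models.

The screen's models are fit in a random half of the cohort; each named
path is then constrained equal across the two halves in a simultaneous
two-group fit, and the fit degradation relative to the unconstrained
two-group fit is a chi-square difference test.  Retention of the equality
constraint (p above the gate) is the generalizability criterion;
mediation effects are recomputed from the constrained estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sem import (FittedModel, ModelSpec, chi_square_difference,
                  fit_ml_multigroup, sample_cov)

__all__ = ["random_split", "constrained_comparison", "SplitHalfResult"]


def random_split(cohort: pd.DataFrame, seed: int = 0
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive halves with |n_A - n_B| <= 1; reproducible."""
    n = len(cohort)
    if n < 4:
        raise ValueError("need at least 4 subjects to split")
    perm = np.random.default_rng(seed).permutation(n)
    half = (n + 1) // 2
    a = cohort.iloc[np.sort(perm[:half])]
    b = cohort.iloc[np.sort(perm[half:])]
    return a, b


@dataclass
class SplitHalfResult:
    delta_chi2: float
    delta_df: int
    p: float
    constrained: FittedModel
    unconstrained: FittedModel
    estimates_a: dict[str, float]
    estimates_b: dict[str, float]
    constrained_estimates: dict[str, float]

    def retained(self, alpha: float = 1e-3) -> bool:
        """Equality constraint retained (generalizes) iff p >= alpha."""
        return self.p >= alpha

    def report(self) -> pd.DataFrame:
        rows = []
        for path in self.constrained_estimates:
            rows.append((path, self.estimates_a.get(path, np.nan),
                         self.estimates_b.get(path, np.nan),
                         self.constrained_estimates[path],
                         self.delta_chi2, self.delta_df, self.p))
        return pd.DataFrame(rows, columns=[
            "path", "estimate_A", "estimate_B", "constrained_estimate",
            "delta_chi2", "delta_df", "p"])


def constrained_comparison(spec: ModelSpec, half_a: pd.DataFrame,
                           half_b: pd.DataFrame,
                           paths_to_constrain: list[str],
                           seed: int = 0) -> SplitHalfResult:
    """Two-group fit with the named free-parameter labels equated.

    All labels in ``paths_to_constrain`` must be free parameters of
    ``spec``; they stay common across the two group copies (jointly
    constrained), every other parameter is group-specific.
    """
    labels = set(spec.free_labels())
    bad = [p for p in paths_to_constrain if p not in labels]
    if bad:
        raise ValueError(f"cannot constrain unknown parameter(s) {bad}")
    shared = set(paths_to_constrain)

    S_a, n_a = sample_cov(half_a, spec.observed)
    S_b, n_b = sample_cov(half_b, spec.observed)

    spec_a_u = spec.relabel("A:")
    spec_b_u = spec.relabel("B:")
    unconstrained = fit_ml_multigroup([spec_a_u, spec_b_u], [S_a, S_b],
                                      [n_a, n_b], seed=seed)
    spec_a_c = spec.relabel("A:", shared=shared)
    spec_b_c = spec.relabel("B:", shared=shared)
    constrained = fit_ml_multigroup([spec_a_c, spec_b_c], [S_a, S_b],
                                    [n_a, n_b], seed=seed)
    if paths_to_constrain:
        dchi, ddf, p = chi_square_difference(constrained, unconstrained)
    else:
        dchi, ddf, p = 0.0, 0, 1.0

    est_a = {l: unconstrained.params[f"A:{l}"] for l in paths_to_constrain}
    est_b = {l: unconstrained.params[f"B:{l}"] for l in paths_to_constrain}
    est_c = {l: constrained.params[l] for l in paths_to_constrain}
    return SplitHalfResult(delta_chi2=dchi, delta_df=ddf, p=p,
                           constrained=constrained,
                           unconstrained=unconstrained,
                           estimates_a=est_a, estimates_b=est_b,
                           constrained_estimates=est_c)
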