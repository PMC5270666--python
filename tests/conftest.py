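import numpy as np
import pandas as pd
import pytest

from deltascreen.sem import ModelSpec
from deltascreen.synthetic import SynthConfig, generate_cohort


def one_factor_spec(names=("a", "b", "c", "d")) -> ModelSpec:
    spec = ModelSpec(observed=list(names), latent=["f"])
    spec.add_variance("f", free=False, value=1.0)
    for v in names:
        spec.add_path("f", v, start=0.7)
        spec.add_variance(v, start=0.5)
    return spec


def one_factor_data(lam, n, seed=0) -> pd.DataFrame:
    lam = np.asarray(lam, float)
    rng = np.random.default_rng(seed)
    f = rng.standard_normal(n)
    X = np.outer(f, lam) + rng.standard_normal((n, len(lam))) * np.sqrt(
        1 - lam ** 2)
    return pd.DataFrame(X, columns=list("abcd")[: len(lam)])


@pytest.fixture(scope="session")
def default_cohort():
    """One moderate default-condition cohort shared across tests."""
    cfg = SynthConfig(n_subjects=3000, seed=7)
    table, truth = generate_cohort(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def scored_cohort(default_cohort):
    """Default cohort preprocessed and scored, plus the delta fit."""
    from deltascreen.delta import fit_delta
    from deltascreen.preprocess import preprocess_cohort

    cfg, table, truth = default_cohort
    biom = [f"biomarker_{m:03d}" for m in range(cfg.n_biomarkers)]
    clean, _ = preprocess_cohort(table, biom)
    dfit = fit_delta(clean, seed=0)
    clean = clean.join(dfit.score(clean))
    return cfg, clean, truth, dfit
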