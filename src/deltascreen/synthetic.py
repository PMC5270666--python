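"""Synthetic cohort generator with known mediation ground truth.

Emulates the measurement and mediation structure the analysis pipeline
assumes: a latent dementia factor (delta) indicated by four cognitive tests
plus summed IADL, its orthogonal cognitive residual (g'), a panel of serum
biomarkers linked to age and/or delta, demographic/clinical covariates,
batch effects, lognormal skew, outliers and missingness.

The generating equations, on standardized scales (age_std = (age-71)/9.5):

    x_m    = c_m * age_std + e_m                      (latent biomarker level)
    delta  = a * age_std + sum_m b_m x_m + gamma' cov + zeta
    g'     = w * age_std + xi                          (w = 0 by default)
    z_i    = lam_delta_i * delta + lam_g_i * g' + u_i  (IADL: delta only)

with every variable scaled to unit variance.  The *observed* biomarker is a
corrupted transform of x_m: a batch shift is added and, for skew-flagged
markers, the result is exponentiated; the preprocessing chain (outlier
trimming, log, batch residualization, standardization) is the correct
inverse.  Diagnosis is a tertile cut of delta (worst third "AD", best "NC"),
and CDR sum-of-boxes is a noisy decreasing transform of delta floored at 0.

Because every structural equation is linear in an orthonormal basis of
disturbances, the population covariance of all model variables is available
in closed form (``population_covariance``); it is the path-tracing oracle
the sampling code is tested against.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SynthConfig", "SynthTruth", "ConfigurationError", "default_config",
    "generate_cohort", "inject_missingness", "population_covariance",
    "write_cohort", "INDICATORS", "COVARIATES",
]

INDICATORS = ["lm2", "vr1", "cowa", "digit_span", "iadl"]
COVARIATES = ["apoe4", "educ", "ethnicity", "gender", "gds", "hcy", "hgba1c"]

# Table-1-style marginals used to put covariates/indicators on survey scales
_COV_MARGINALS = {
    "apoe4": ("bernoulli", 0.39),
    "educ": ("normal", 13.24, 4.25),
    "ethnicity": ("bernoulli", 0.36),
    "gender": ("bernoulli", 0.39),
    "gds": ("halfnormal_like", 5.60, 5.25),
    "hcy": ("normal", 10.0, 3.0),
    "hgba1c": ("normal", 6.0, 1.0),
}
_IND_SCALE = {"lm2": (8.05, 4.30), "vr1": (7.88, 3.68), "cowa": (8.41, 3.49),
              "digit_span": (8.89, 3.01), "iadl": (10.48, 4.52)}


class ConfigurationError(ValueError):
    pass


@dataclass
class SynthConfig:
    n_subjects: int = 3000
    n_biomarkers: int = 100
    n_true_mediators: int | None = None   # default: 20% of the panel
    # delta's cognitive content is balanced around zero (memory tests carry
    # positive disability-specific residual variance, attention/fluency
    # slightly negative) with IADL the dominant delta indicator; with equal
    # g' loadings this makes sum(lam_delta * lam_g) = 0, so the regression
    # factor scores of the two orthogonal factors are themselves orthogonal
    loading_delta: np.ndarray = field(
        default_factory=lambda: np.array([0.25, -0.25, 0.25, -0.25, 0.88]))
    loading_gprime: np.ndarray = field(
        default_factory=lambda: np.array([0.70, 0.70, 0.70, 0.70]))
    path_a: float = -0.25
    path_c_vec: np.ndarray | None = None   # age -> biomarker, per marker
    path_b_vec: np.ndarray | None = None   # biomarker -> delta, per marker
    covariate_effects: dict[str, float] = field(default_factory=lambda: {
        "apoe4": -0.15, "educ": 0.15, "ethnicity": -0.05, "gender": -0.05,
        "gds": -0.10, "hcy": -0.05, "hgba1c": -0.05})
    path_age_gprime: float = 0.0
    batch_count: int = 5
    batch_sd: float = 0.3
    skew_flag: np.ndarray | None = None
    skew_sigma: float = 0.8
    missing_rate: float = 0.02
    missing_mechanism: str = "mcar"
    outlier_rate: float = 0.005
    age_mean: float = 71.0
    age_sd: float = 9.5
    dx_cuts: tuple[float, float] = (1 / 3, 2 / 3)
    cdr_mean: float = 2.42
    cdr_slope: float = 2.8
    cdr_noise: float = 1.2
    seed: int = 0

    def __post_init__(self):
        M = self.n_biomarkers
        if self.n_true_mediators is None:
            self.n_true_mediators = max(1, round(0.2 * M))
        if self.n_true_mediators > M:
            raise ConfigurationError("n_true_mediators exceeds n_biomarkers")
        if self.path_c_vec is None or self.path_b_vec is None:
            c, b = _default_panel(M, self.n_true_mediators)
            if self.path_c_vec is None:
                self.path_c_vec = c
            if self.path_b_vec is None:
                self.path_b_vec = b
        self.path_c_vec = np.asarray(self.path_c_vec, float)
        self.path_b_vec = np.asarray(self.path_b_vec, float)
        if self.skew_flag is None:
            self.skew_flag = np.arange(M) % 2 == 0
        self.skew_flag = np.asarray(self.skew_flag, bool)
        self.loading_delta = np.asarray(self.loading_delta, float)
        self.loading_gprime = np.asarray(self.loading_gprime, float)
        self.validate()

    def validate(self) -> None:
        M = self.n_biomarkers
        if self.n_true_mediators > M:
            raise ConfigurationError("n_true_mediators exceeds n_biomarkers")
        for name, vec, size in [("path_c_vec", self.path_c_vec, M),
                                ("path_b_vec", self.path_b_vec, M),
                                ("skew_flag", self.skew_flag, M),
                                ("loading_delta", self.loading_delta, 5),
                                ("loading_gprime", self.loading_gprime, 4)]:
            if len(vec) != size:
                raise ConfigurationError(f"{name} must have length {size}")
        if not np.all(np.isfinite(self.loading_delta)) or \
           not np.all(np.isfinite(self.loading_gprime)):
            raise ConfigurationError("loadings must be finite")
        for nm, r in [("missing_rate", self.missing_rate),
                      ("outlier_rate", self.outlier_rate)]:
            if not 0 <= r < 1:
                raise ConfigurationError(f"{nm} must lie in [0, 1)")
        if np.any(np.abs(self.path_c_vec) >= 1):
            raise ConfigurationError("biomarker: |path c| >= 1 implies "
                                     "non-positive noise variance")
        if self.zeta_variance() <= 0:
            raise ConfigurationError(
                "delta: implied disturbance variance is non-positive; "
                "reduce path_a / path_b_vec / covariate effects")
        uniq = self.unique_variances()
        bad = [ind for ind, u in zip(INDICATORS, uniq) if u <= 0]
        if bad:
            raise ConfigurationError(
                f"indicator(s) {bad}: loadings imply non-positive unique "
                "variance")
        if abs(self.path_age_gprime) >= 1:
            raise ConfigurationError("gprime: |age path| must be < 1")

    # ------------------------------------------------------------ structure
    def delta_coefficients(self):
        """(a, b_vec, gamma_vec) of delta's structural equation."""
        gamma = np.array([self.covariate_effects.get(c, 0.0)
                          for c in COVARIATES])
        return self.path_a, self.path_b_vec, gamma

    def zeta_variance(self) -> float:
        a, b, gamma = self.delta_coefficients()
        c = self.path_c_vec
        # var(a*age + b'x + gamma'cov); cov(x) = cc' + diag(1-c^2)
        var = a ** 2 + 2 * a * (b @ c) + (b @ c) ** 2 \
            + b @ ((1 - c ** 2) * b) + gamma @ gamma
        return 1.0 - float(var)

    def unique_variances(self) -> np.ndarray:
        lg = np.append(self.loading_gprime, 0.0)  # IADL loads delta only
        return 1.0 - self.loading_delta ** 2 - lg ** 2

    def total_age_effect(self) -> float:
        """Population age_std -> delta total effect (= corr, both unit var)."""
        return float(self.path_a + self.path_b_vec @ self.path_c_vec)

    def biomarker_truth(self) -> pd.DataFrame:
        a = self.path_a
        c, b = self.path_c_vec, self.path_b_vec
        ind = c * b
        denom = np.abs(ind) + abs(a)
        pct = np.where(ind == 0, 0.0,
                       np.where(denom == 0, np.nan,
                                100.0 * np.abs(ind) / denom))
        cls = np.full(len(c), 4)
        cls[(c != 0) & (b != 0)] = 1
        cls[(c != 0) & (b == 0)] = 2
        cls[(c == 0) & (b != 0)] = 3
        direction = np.where(ind == 0, "",
                             np.where(np.sign(ind) == np.sign(a),
                                      "attenuating", "accentuating"))
        return pd.DataFrame({
            "biomarker": [f"biomarker_{m:03d}" for m in range(len(c))],
            "true_c": c, "true_b": b, "true_indirect": ind,
            "true_percent_mediated": pct, "true_class": cls,
            "true_direction": direction, "skewed": self.skew_flag,
        })

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return d


def _default_panel(M: int, n_med: int, n_age_only: int | None = None,
                   n_delta_only: int | None = None):
    """Default panel composition: mediators first, then age-only and
    delta-only markers (15 each at the 100-marker default, scaled down
    proportionally otherwise), remainder null."""
    if n_age_only is None:
        n_age_only = min(15 * M // 100 if M >= 20 else max(M - n_med, 0) // 3,
                         M - n_med)
    if n_delta_only is None:
        n_delta_only = min(n_age_only, M - n_med - n_age_only)
    c = np.zeros(M)
    b = np.zeros(M)
    for m in range(n_med):
        c[m] = 0.3 if m % 2 == 0 else -0.3
        b[m] = -0.1
    for m in range(n_med, n_med + n_age_only):
        c[m] = 0.3 if m % 2 == 0 else -0.3
    for m in range(n_med + n_age_only, n_med + n_age_only + n_delta_only):
        b[m] = 0.1 if m % 2 == 0 else -0.1
    return c, b


def default_config(**overrides) -> SynthConfig:
    """The package's reference study conditions."""
    return SynthConfig(**overrides)


# --------------------------------------------------------------------------
@dataclass
class SynthTruth:
    """Generating parameters and per-subject latent scores."""

    path_a: float
    total_age_effect: float
    zeta_variance: float
    biomarkers: pd.DataFrame
    delta: np.ndarray
    gprime: np.ndarray
    seed: int
    config: dict

    def to_json(self) -> str:
        return json.dumps({
            "path_a": self.path_a,
            "total_age_effect": self.total_age_effect,
            "zeta_variance": self.zeta_variance,
            "biomarkers": self.biomarkers.to_dict(orient="list"),
            "delta": np.asarray(self.delta).tolist(),
            "gprime": np.asarray(self.gprime).tolist(),
            "seed": self.seed,
            "config": self.config,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SynthTruth":
        d = json.loads(text)
        return cls(path_a=d["path_a"],
                   total_age_effect=d["total_age_effect"],
                   zeta_variance=d["zeta_variance"],
                   biomarkers=pd.DataFrame(d["biomarkers"]),
                   delta=np.array(d["delta"]), gprime=np.array(d["gprime"]),
                   seed=d["seed"], config=d["config"])


# --------------------------------------------------------------------------
def _draw_covariates(rng: np.random.Generator, n: int):
    """Raw covariates and their standardized (theoretical-moment) versions."""
    raw = {}
    std = {}
    for name in COVARIATES:
        kind, *pars = _COV_MARGINALS[name]
        if kind == "bernoulli":
            p = pars[0]
            x = (rng.random(n) < p).astype(float)
            raw[name] = x
            std[name] = (x - p) / np.sqrt(p * (1 - p))
        else:
            mu, sd = pars
            z = rng.standard_normal(n)
            if kind == "halfnormal_like":
                x = np.maximum(mu + sd * z, 0.0)
            else:
                x = mu + sd * z
            raw[name] = x
            std[name] = z
    return raw, std


def generate_cohort(config: SynthConfig) -> tuple[pd.DataFrame, SynthTruth]:
    """Draw a cohort and return it with its generating ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, M = config.n_subjects, config.n_biomarkers
    a, b, gamma = config.delta_coefficients()
    c = config.path_c_vec

    age_std = rng.standard_normal(n)
    cov_raw, cov_std = _draw_covariates(rng, n)
    x = age_std[:, None] * c + rng.standard_normal((n, M)) * np.sqrt(1 - c ** 2)
    cov_mat = np.column_stack([cov_std[nm] for nm in COVARIATES])
    zeta_var = config.zeta_variance()
    delta = (a * age_std + x @ b + cov_mat @ gamma
             + np.sqrt(zeta_var) * rng.standard_normal(n))
    w = config.path_age_gprime
    gprime = w * age_std + np.sqrt(1 - w ** 2) * rng.standard_normal(n)

    uniq = config.unique_variances()
    lg = np.append(config.loading_gprime, 0.0)
    data = {"subject_id": [f"S{i:05d}" for i in range(n)],
            "age": config.age_mean + config.age_sd * age_std}
    for j, ind in enumerate(INDICATORS):
        z = (config.loading_delta[j] * delta + lg[j] * gprime
             + np.sqrt(uniq[j]) * rng.standard_normal(n))
        mu_i, sd_i = _IND_SCALE[ind]
        data[ind] = mu_i + sd_i * z
    for nm in COVARIATES:
        data[nm] = cov_raw[nm]

    batch = rng.integers(0, config.batch_count, size=n)
    data["batch"] = batch
    shift = rng.normal(0.0, config.batch_sd, size=(config.batch_count, M))
    raw_biom = x + shift[batch, :]
    obs_biom = np.where(config.skew_flag,
                        np.exp(config.skew_sigma * raw_biom), raw_biom)
    for m in range(M):
        data[f"biomarker_{m:03d}"] = obs_biom[:, m]

    # diagnosis: tertile-like cut of delta (worst -> AD, best -> NC)
    lo, hi = np.quantile(delta, config.dx_cuts)
    dx = np.where(delta <= lo, "AD", np.where(delta >= hi, "NC", "MCI"))
    data["dx"] = dx
    cdr = (config.cdr_mean - config.cdr_slope * delta
           + config.cdr_noise * rng.standard_normal(n))
    data["cdr"] = np.maximum(cdr, 0.0)

    table = pd.DataFrame(data)

    if config.outlier_rate > 0:
        biom_cols = [f"biomarker_{m:03d}" for m in range(M)]
        vals = table[biom_cols].to_numpy()
        mask = rng.random(vals.shape) < config.outlier_rate
        mu = vals.mean(axis=0)
        sd = vals.std(axis=0, ddof=1)
        mag = (4.0 + 2.0 * rng.random(vals.shape)) * sd
        sign = np.where(rng.random(vals.shape) < 0.5, -1.0, 1.0)
        table[biom_cols] = np.where(mask, mu + sign * mag, vals)

    if config.missing_rate > 0:
        table = inject_missingness(table, config.missing_rate,
                                   config.missing_mechanism,
                                   seed=int(rng.integers(2 ** 31 - 1)))

    truth = SynthTruth(path_a=a, total_age_effect=config.total_age_effect(),
                       zeta_variance=zeta_var,
                       biomarkers=config.biomarker_truth(),
                       delta=delta, gprime=gprime, seed=config.seed,
                       config=config.to_dict())
    return table, truth


def inject_missingness(table: pd.DataFrame, rate: float, mechanism: str = "mcar",
                       seed: int = 0, columns: list[str] | None = None
                       ) -> pd.DataFrame:
    """Mask cells at the given expected rate; age/dx/batch are never masked.

    mechanism "mcar": uniform Bernoulli.  "mar-age": above-median-age
    subjects are masked at 1.5x the rate, below-median at 0.5x, so the
    marginal rate is preserved while depending on the always-observed age.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    mechanism = mechanism.lower()
    if mechanism not in {"mcar", "mar-age", "mar_on_age"}:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    out = table.copy()
    if rate == 0:
        return out
    if columns is None:
        protected = {"subject_id", "age", "dx", "batch"}
        columns = [cl for cl in table.columns
                   if cl not in protected and
                   pd.api.types.is_numeric_dtype(table[cl])]
    rng = np.random.default_rng(seed)
    shape = (len(out), len(columns))
    if mechanism == "mcar":
        p = np.full(shape, rate)
    else:
        older = (out["age"] > out["age"].median()).to_numpy()
        p = np.where(older[:, None], 1.5 * rate, 0.5 * rate)
        p = np.clip(p, 0, 0.999)
    mask = rng.random(shape) < p
    block = out[columns].to_numpy(float)
    block[mask] = np.nan
    out[columns] = block
    return out


# --------------------------------------------------------------------------
def population_covariance(config: SynthConfig) -> pd.DataFrame:
    """Closed-form path-tracing covariance of the standardized model
    variables: age_std, latent biomarkers x_m, delta, gprime, and the
    standardized indicators."""
    M = config.n_biomarkers
    a, b, gamma = config.delta_coefficients()
    c = config.path_c_vec
    q = len(COVARIATES)
    # orthonormal disturbance basis:
    # [age, cov_1..q, e_1..M, zeta, xi, u_1..5]
    nb = 1 + q + M + 2 + 5
    names = (["age_std"] + [f"x_{m:03d}" for m in range(M)]
             + ["delta", "gprime"] + [f"z_{ind}" for ind in INDICATORS])
    L = np.zeros((len(names), nb))
    row = {nm: i for i, nm in enumerate(names)}
    L[row["age_std"], 0] = 1.0
    for m in range(M):
        L[row[f"x_{m:03d}"], 0] = c[m]
        L[row[f"x_{m:03d}"], 1 + q + m] = np.sqrt(1 - c[m] ** 2)
    dl = row["delta"]
    L[dl, 0] = a
    for j in range(q):
        L[dl, 1 + j] = gamma[j]
    for m in range(M):
        L[dl] += b[m] * L[row[f"x_{m:03d}"]]
    L[dl, 1 + q + M] = np.sqrt(config.zeta_variance())
    gp = row["gprime"]
    w = config.path_age_gprime
    L[gp, 0] = w
    L[gp, 1 + q + M + 1] = np.sqrt(1 - w ** 2)
    uniq = config.unique_variances()
    lg = np.append(config.loading_gprime, 0.0)
    for j, ind in enumerate(INDICATORS):
        r = row[f"z_{ind}"]
        L[r] = config.loading_delta[j] * L[dl] + lg[j] * L[gp]
        L[r, 1 + q + M + 2 + j] = np.sqrt(uniq[j])
    return pd.DataFrame(L @ L.T, index=names, columns=names)


def write_cohort(table: pd.DataFrame, truth: SynthTruth, cohort_path,
                 truth_path) -> None:
    table.to_csv(cohort_path, index=False)
    with open(truth_path, "w") as fh:
        fh.write(truth.to_json())
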