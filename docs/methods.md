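# Methods

## The model

All estimation reduces to linear structural equation models over observed
and latent variables. Internally a model is held in reticular-action form:
stack every variable into `v`, write `v = A v + u` with `Cov(u) = S`, and
the implied covariance of the observed block is
`Σ(θ) = F (I − A)⁻¹ S (I − A)⁻ᵀ Fᵀ`. Complete-case estimation minimizes
the normal-theory discrepancy

    F_ML(θ) = ln|Σ(θ)| + tr(S Σ(θ)⁻¹) − ln|S| − p,

with χ² = (N − 1)·F_min (switchable to N). The sample covariance uses the
ML divisor N, so the complete-data ML fit and the FIML fit maximize the
same likelihood and agree to optimizer precision; the (N − 1) factor in the
χ² is a reporting convention. Incomplete data are handled by
full-information maximum likelihood: rows are grouped by missingness
pattern and each pattern contributes the multivariate-normal log-likelihood
of its observed sub-vector under the marginalized implied moments. A
saturated mean structure (one free mean per observed variable) is estimated
alongside, leaving the covariance-structure degrees of freedom unchanged;
the FIML χ² is 2·(ll_saturated − ll_model) with the saturated moments
obtained by EM.

### The δ/g′ measurement model

δ is defined as the disability-related fraction of general cognitive
performance. The measurement model is a bifactor: all five indicators
(Logical Memory II, Visual Reproduction I, COWA, Digit Span, summed IADL)
load on δ; the four cognitive indicators additionally load on the
orthogonal g′; IADL loads on δ only. Both latent variances are fixed at 1
(rather than fixing marker loadings) so factor-score weights are
scale-free. Composites use the regression method, W = Σ̂⁻¹Λ̂Φ̂, applied to
indicators standardized to the fitting sample's scale; rows missing any
indicator are scored missing, which keeps scoring deterministic and makes
the ROC analyses complete-case by construction. Grice determinacy
ρ_j = (WᵀΛΦ)_jj / √((WᵀΣW)_jj Φ_jj) is reported per factor, with an
acceptance floor of 0.80 for δ (configurable).

Factor loadings are identified only up to a column sign flip; the package
fixes the convention that IADL loads positively on δ and g′'s loadings are
positive on average, so that higher scores always mean better performance
and the δ composite correlates negatively with age and with CDR severity.

### The mediation screen

Path labels follow the δ-biomarker literature and are **reversed** from the
conventional mediation notation: path *c* is age→biomarker, path *b* is
biomarker→δ-composite, and path *a* is the covariate-adjusted *direct*
age→δ effect (the conventional c′). Biomarkers enter one at a time. Each
biomarker's model regresses the biomarker on age and the covariates, the δ
composite on age, the biomarker and the covariates, and the g′ composite on
age and the covariates (no biomarker→g′ path, leaving one model degree of
freedom so the fit indices are informative); age is the only unadjusted
exogenous variable, and all exogenous variables covary freely. The base
model is the same without the biomarker; being a saturated regression, its
age coefficient is the total age effect, and the decomposition
a + c·b ≈ total is checked on synthetic data.

The indirect effect is c·b with the delta-method (Sobel) z,
z = c·b/√(b²·se_c² + c²·se_b²); a parametric bootstrap guards this
approximation in the tests. Percent mediated is 100·|c·b|/(|c·b| + |a|),
which is positive for attenuating mediators (indirect effect shares the
direct effect's sign) and accentuating ones (suppression); the signed
proportion c·b/(c·b + a) is emitted as a diagnostic. Paths b and c are
gated at the Bonferroni-corrected p < 0.001 (strict inequality), giving the
four classes: both pass → 1 (mediator), only c → 2 (age-related only),
only b → 3 (δ-related only), neither → 4. Percent mediated is reported
only for class-1 calls; path a's own significance never affects classing.

Split-half generalizability refits a mediation model in a random half,
equates the paths found significant there across the two halves in a
simultaneous two-group fit (block-diagonal joint likelihood, shared
parameters expressed by shared labels, constrained jointly per model), and
tests the fit degradation by χ² difference; retention (p ≥ 0.001) is the
generalizability criterion, and mediation effects are recomputed from the
constrained estimates.

## The synthetic-data generator

The generator draws cohorts with exactly the structure the analysis
assumes, on standardized scales (age_std = (age − 71)/9.5, matching
typical aging-cohort demographics):

    x_m   = c_m·age_std + e_m                      (latent biomarker level)
    δ     = a·age_std + Σ_m b_m·x_m + γᵀcov + ζ
    g′    = w·age_std + ξ                          (w = 0 by default)
    z_i   = λδ_i·δ + λg_i·g′ + u_i                 (IADL: δ only)

with every variable scaled to unit variance (the ζ variance is solved for;
a configuration whose implied variance is non-positive is rejected naming
the offending variable). The *observed* biomarker corrupts x_m with a
batch shift (uniform-random batch assignment, shifts N(0, 0.3) per
batch×marker) and, for half the panel, exponentiation (lognormal skew,
σ = 0.8); the preprocessing chain is the correct inverse. Outliers
(0.5% of cells at 4–6 SD) and missingness (2% MCAR by default; an
age-dependent variant masks older subjects at 1.5× the rate) are injected
last; age, diagnosis and batch are never masked. Diagnosis is a tertile
cut of δ (worst third "AD", best "NC") and CDR sum-of-boxes is a noisy
decreasing linear transform of δ floored at zero. Because the structural
equations are linear in an orthonormal disturbance basis, the population
covariance of every model variable is available in closed form
(`population_covariance`), which is the path-tracing oracle the sampler is
tested against.

Default effect sizes define the reference study conditions: direct age
effect a = −0.25 per SD of age; a 100-marker panel with 20 mediators
(c = ±0.3, b = −0.1, half attenuating and half accentuating so the total
age effect equals a), 15 age-only markers (c = ±0.3), 15 δ-only markers
(b = ±0.1), and 50 null markers. With these choices age explains ~6% of
δ's variance, per-biomarker true percent mediated is ≈10.7%, and the
p < 0.001 gate has ≈85–90% sensitivity at n = 3000 — a regime of many
weak-but-detectable partial mediators.

Measurement defaults required one genuinely open design choice. Regression
scores of two orthogonal factors are correlated in proportion to
Σ_i λδ_i λg_i/θ_i, so "δ and g′ composites are uncorrelated" and "δ
determinacy ≥ 0.8" jointly constrain the loading pattern: with uniformly
positive cognitive δ loadings the score correlation cannot fall below
≈0.1, and shrinking the loadings toward zero un-anchors the scale of the
IADL loading (a likelihood ridge producing wild negative-variance
estimates). The defaults therefore balance δ's cognitive content around
zero — memory tests +0.25, attention/fluency −0.25, IADL 0.88, g′
loadings 0.70 — which makes Σλδλg exactly zero (composites genuinely
orthogonal), keeps rotation and scale strongly identified, and yields δ
determinacy ≈0.92. Substantively this reads δ as expressed through
function: IADL is its dominant indicator, and the cognitive tests
contribute only small disability-specific residuals of either sign.

### What the generator does not emulate

Real cohorts feature consensus diagnoses with misclassification,
longitudinal visit structure beyond the implicit baseline-biomarker /
later-outcome ordering, non-Gaussian cognitive floors/ceilings,
ethnicity-specific measurement differences, correlated biomarker panels
(assay cross-reactivity), and informative (MNAR) missingness. Passing
tests therefore certify the *machinery* — estimation, arithmetic, gating,
calibration — under the model's assumptions, not robustness of the
scientific conclusions to their violation.

## Numerical choices

* **Optimization**: L-BFGS-B on F_ML with *analytic* gradients (assembled
  from (I−A)⁻¹-based trace identities and verified against finite
  differences in the tests); data-informed start values — OLS solutions
  from the sample moments for regressions among observed variables (exact
  for saturated recursive models, so the optimizer only polishes),
  sample moments for free (co)variances, construct-informed loading starts
  for the bifactor (IADL-dominant, which selects the intended rotation
  basin). Up to five jittered restarts on non-convergence; the
  convergence flag requires a gradient max-norm below 1e-5 and is never
  silently swallowed — screen failures are recorded per biomarker.
* **Standard errors**: inverse observed information, with the Hessian
  obtained by central differences of the analytic gradient;
  acov = 2/(N−1)·H⁻¹. Negative-variance (Heywood) estimates are reported
  with a recorded warning, not truncated.
* **FIML**: numeric 3-point gradients (the pattern-sum objective), EM for
  the saturated moments (tolerance 1e-8 on the log-likelihood).
* **Fit indices**: CMIN/DF, CFI = 1 − max(χ²_M−df_M,0)/max(χ²_0−df_0,
  χ²_M−df_M,0) clipped to [0,1], RMSEA = √(max(χ²_M−df_M,0)/(df_M(N−1))).
  At df = 0 the CFI's guards still give 1.0 for a perfect fit while RMSEA
  and CMIN/DF are reported as NaN.
* **Preprocessing order** is fixed: outliers → log/standardize → batch
  residualize → re-standardize. The outlier pass is single (not iterated)
  and evaluated on the raw scale with the sample SD; re-applying the full
  chain is an exact no-op whenever the second pass flags no cells (always
  true for bounded data, and checked as such), but on heavy-tailed data a
  handful of borderline cells can cross the 3 SD line after
  re-standardization — deletion is defined on the raw scale precisely to
  keep the rule single-shot. Non-positive values under the log branch are
  shifted by (1 − min) first. Skewness uses the bias-corrected sample
  coefficient with |γ₁| > 1.0 triggering the log (configurable).
* **Batch adjustment** is pre-residualization on batch dummies rather than
  in-model dummy regressors, so every per-biomarker model has an identical
  structure; for standardized variables the two are equivalent up to the
  residualization's variance rescaling.
* **Residual covariances** are admitted only when declared in a spec; no
  automated forward selection. The shipped δ specification frees none.
* **Determinism**: every stochastic step takes an explicit seed; identical
  seed and configuration reproduce byte-identical output tables.

## Problem sizes used by the shipped checks

The test suite and the acceptance script run at the reference conditions
(n = 3000, 100 biomarkers) for single analyses; replicated calibrations
use scaled designs that preserve the estimand — oracle cross-checks on 20
random specifications at n = 2000, percent-mediated recovery over 100
replicates per effect size at n = 3000 (single-mediator cohorts, so the
per-biomarker model matches the generating truth exactly), null
false-positive calibration over 500 screens of 4 null biomarkers at
n = 600, and χ²-difference calibration over 200 replicates at n = 300.

## Known limitations

* Estimation is normal-theory ML/FIML only; no robust (sandwich) errors,
  weighted least squares, or ordinal-indicator machinery.
* The per-biomarker models are fit to complete cases of the scored data;
  FIML is available for the measurement model but composite scoring itself
  is deliberately complete-case.
* Mediation is one biomarker at a time with no interactions or joint
  models; percent mediated inherits the usual caveats of
  proportion-of-effect measures when the direct effect is near zero.
* The split-half step constrains paths jointly per model (one-at-a-time
  constraint testing is available through the same interface but is not
  the default).
* Causal language for the mediation estimands rests on the temporal
  ordering and covariate set of the design; the package checks arithmetic
  and calibration, not identification assumptions.
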