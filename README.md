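# deltascreen

Construction and validation of a latent dementia phenotype (δ) from
cognitive and functional indicators, and a per-biomarker structural-equation
mediation screen asking which serum proteins carry age's effect on future
dementia severity.

## The problem

In aging cohorts, age is reliably but weakly associated with dementia
severity. δ ("dementia") operationalizes the *disabling* fraction of general
cognitive performance: it is the shared variance between cognitive tests and
instrumental activities of daily living (IADL). Its orthogonal complement,
g′, is the residual of Spearman's general intelligence factor after δ is
removed — cognitive variance that does not disable. A serum protein
measured at baseline may *mediate* age's effect on a later δ composite:
age → protein → δ. Screening a ~100-protein panel for such mediators, with
a severe multiple-comparison gate, yields a four-class taxonomy of the
panel — (1) mediators of age's δ effect, (2) age-related but δ-independent
proteins, (3) age-independent δ predictors, (4) proteins related to
neither.

`deltascreen` implements this analysis end to end as a reusable, tested
pipeline, together with a synthetic-cohort generator whose ground truth
makes every stage verifiable:

* **`deltascreen.synthetic`** — cohorts with the assumed latent structure:
  δ and g′ with five indicators (LM II, VR I, COWA, Digit Span, IADL),
  age→biomarker→δ mediation with configurable paths, covariates, batch
  effects, lognormal skew, outliers, missingness — plus the exact
  generating parameters and closed-form path-tracing moments.
* **`deltascreen.preprocess`** — the biomarker conditioning chain:
  single-pass ±3 SD outlier deletion, log-normalization of skewed columns,
  standardization, batch-dummy residualization.
* **`deltascreen.sem`** — a covariance-structure engine: model-implied
  covariance Σ(θ), the ML discrepancy F\_ML with analytic gradients,
  full-information maximum likelihood (FIML) for incomplete data,
  observed-information standard errors, CMIN/DF–CFI–RMSEA fit indices,
  nested χ²-difference tests, and simultaneous multi-group estimation with
  cross-group equality constraints.
* **`deltascreen.delta`** — the bifactor δ/g′ specification (IADL loads on
  δ only, factors orthogonal with unit variance), regression-method factor
  score weights W = Σ⁻¹ΛΦ, composite scoring, Grice factor determinacy,
  ROC/AUC validation against diagnosis and correlation with CDR severity.
* **`deltascreen.mediation`** — the screen: per-biomarker three-path model
  (path c: age→biomarker, path b: biomarker→δ, path a: the adjusted direct
  age→δ effect — note these labels are *reversed* from the conventional
  a/b/c′ notation), the product-of-coefficients indirect effect c·b with
  the delta-method Sobel z, percent mediated 100·|c·b|/(|c·b|+|a|), the
  Bonferroni p < 0.001 gate, and the four-class taxonomy.
* **`deltascreen.splithalf`** — split-half generalizability: random halves,
  significant paths equated across halves in a two-group fit, χ²-difference
  retention test.
* **`deltascreen.pipeline` / `deltascreen.cli`** — one-command orchestration
  with YAML configuration and a machine-readable run manifest.

## Worked example

```python
import numpy as np
from deltascreen import SynthConfig, generate_cohort, fit_delta, run_screen
from deltascreen.preprocess import preprocess_cohort
from deltascreen.delta import auc_roc

cfg = SynthConfig(n_subjects=3000, seed=1)     # 100 biomarkers, 20 true mediators
cohort, truth = generate_cohort(cfg)

biomarkers = [f"biomarker_{m:03d}" for m in range(cfg.n_biomarkers)]
cohort, report = preprocess_cohort(cohort, biomarkers)

dfit = fit_delta(cohort, seed=1)               # bifactor delta / g' model
cohort = cohort.join(dfit.score(cohort))
print(f"delta determinacy: {dfit.determinacy['delta']:.3f}")

ok = cohort["deq"].notna()
auc, ci = auc_roc(cohort.loc[ok, "deq"], cohort.loc[ok, "dx"], positive="AD")
print(f"AUC (AD vs NC):    {auc:.3f}  (95% CI {ci[0]:.3f}-{ci[1]:.3f})")

screen = run_screen(cohort, biomarkers, seed=1)
class1 = screen[screen.protein_class == 1]
print(f"class-1 mediators: {len(class1)} of {cfg.n_biomarkers}")
print(class1[["biomarker", "path_a", "sobel_z", "percent_mediated",
              "direction"]].head(3).round(3).to_string(index=False))
```

prints

```
delta determinacy: 0.919
AUC (AD vs NC):    0.938  (95% CI 0.927-0.949)
class-1 mediators: 18 of 100
    biomarker  path_a  sobel_z  percent_mediated   direction
biomarker_018  -0.018   -5.363            15.821 attenuating
biomarker_006  -0.018   -5.046            14.371 attenuating
biomarker_008  -0.018   -4.822            14.071 attenuating
```

Determinacy is the correlation between the δ composite and the latent
factor it estimates (0.92 here — the composite is a faithful proxy). The
AUC says the δ composite separates generated "AD" from "NC" subjects almost
perfectly, while the same statistic for g′ sits at chance (≈0.51): only the
disability-related fraction of cognition discriminates. Of the 100-protein
panel, 18 of the 20 built-in mediators pass both path gates at p < 0.001
with zero false calls; `path_a` is in raw units (δ-composite change per
year of age), `percent_mediated` is the share of age's total effect carried
through the protein, and `direction` says whether the indirect effect
absorbs (attenuates) or opposes (accentuates) the direct effect.

The same run is available from the shell:

```bash
deltascreen run-all --seed 1 --out runs/demo
```

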