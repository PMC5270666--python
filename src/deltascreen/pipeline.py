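"""End-to-end orchestration: cohort -> preprocessing -> delta model ->
base model -> mediation screen -> split-half confirmation -> reports.

Every stage writes its outputs under the run directory and communicates
with later stages only through those documented files plus the in-memory
frames it returns; a machine-readable manifest records the seed, the
configuration hash and each stage's fit statistics against the adequacy
thresholds (CMIN/DF < 5, CFI >= 0.90, RMSEA <= 0.05).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig, load_config
from .delta import auc_roc, fit_delta, validate_vs_severity
from .mediation import fit_mediation, run_screen, write_class_tables
from .preprocess import preprocess_cohort
from .sem import fit_ml, independence_fit_cov, fit_indices, sample_cov, fit_ml_cov
from .mediation import build_base_model, build_mediation_model, bonferroni_gate
from .splithalf import constrained_comparison, random_split
from .synthetic import (COVARIATES, INDICATORS, SynthConfig, SynthTruth,
                        generate_cohort, write_cohort)

__all__ = ["run_full_analysis", "PipelineError"]

log = logging.getLogger("deltascreen")


class PipelineError(RuntimeError):
    pass


def _required_columns(biomarkers: list[str]) -> list[str]:
    return INDICATORS + COVARIATES + ["age", "dx", "cdr", "batch"] + biomarkers


def _check_schema(cohort: pd.DataFrame) -> list[str]:
    biomarkers = sorted(c for c in cohort.columns
                        if c.startswith("biomarker_"))
    missing = [c for c in _required_columns(biomarkers)
               if c not in cohort.columns]
    if missing:
        raise PipelineError(
            "cohort schema mismatch; missing column(s): "
            + ", ".join(missing))
    if not biomarkers:
        raise PipelineError("cohort has no biomarker_* columns")
    return biomarkers


def _json_default(o):
    if isinstance(o, (np.floating, np.integer, np.bool_)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o).__name__)


def run_full_analysis(config: AnalysisConfig | str | Path,
                      out_dir) -> Path:
    """Execute the full analysis; returns the output directory."""
    if not isinstance(config, AnalysisConfig):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "deltascreen",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "stages": {},
    }

    # ---- stage 1: cohort -------------------------------------------------
    truth = None
    if config.cohort_csv:
        cohort = pd.read_csv(config.cohort_csv)
        if config.truth_json:
            truth = SynthTruth.from_json(Path(config.truth_json).read_text())
    else:
        synth = SynthConfig(seed=config.seed, **config.simulate)
        cohort, truth = generate_cohort(synth)
        write_cohort(cohort, truth, out / "cohort.csv", out / "truth.json")
    biomarkers = _check_schema(cohort)
    manifest["stages"]["cohort"] = {"n_subjects": len(cohort),
                                    "n_biomarkers": len(biomarkers)}
    log.info("cohort: %d subjects, %d biomarkers", len(cohort),
             len(biomarkers))

    # ---- stage 2: preprocessing -----------------------------------------
    cohort, report = preprocess_cohort(
        cohort, biomarkers, "batch",
        sd_limit=config.outlier_sd, skew_threshold=config.skew_threshold)
    report.to_csv(out / "preprocess_report.csv")
    manifest["stages"]["preprocess"] = {
        "n_outliers_total": int(report.table["n_outliers"].sum()),
        "n_log_applied": int(report.table["log_applied"].sum()),
    }

    # ---- stage 3: delta model and composites ----------------------------
    dfit = fit_delta(cohort, estimator=config.estimator, seed=config.seed)
    scores = dfit.score(cohort)
    cohort = cohort.join(scores)
    scores.assign(subject_id=cohort.get("subject_id")).to_csv(
        out / "composite_scores.csv", index=False)
    ok_cases = scores["deq"].notna()
    auc_deq, ci_deq = auc_roc(scores.loc[ok_cases, "deq"],
                              cohort.loc[ok_cases, "dx"], positive="AD")
    auc_g, ci_g = auc_roc(scores.loc[ok_cases, "gprime"],
                          cohort.loc[ok_cases, "dx"], positive="AD")
    r_cdr, p_cdr = validate_vs_severity(cohort["deq"], cohort["cdr"])
    delta_report = {
        "fit_indices": dfit.indices,
        "determinacy": dfit.determinacy,
        "determinacy_floor": config.determinacy_floor,
        "determinacy_ok": dfit.determinacy["delta"]
        >= config.determinacy_floor,
        "auc_deq_ad_vs_nc": auc_deq, "auc_deq_ci": ci_deq,
        "auc_gprime_ad_vs_nc": auc_g, "auc_gprime_ci": ci_g,
        "cdr_correlation": r_cdr, "cdr_p": p_cdr,
        "weights": dfit.weights.to_dict(),
    }
    (out / "delta_report.json").write_text(
        json.dumps(delta_report, indent=1, default=_json_default))
    manifest["stages"]["delta"] = _adequacy(dfit.indices)
    if not delta_report["determinacy_ok"]:
        log.warning("delta determinacy %.3f below floor %.2f",
                    dfit.determinacy["delta"], config.determinacy_floor)

    # ---- stage 4: base model --------------------------------------------
    base_spec = build_base_model(COVARIATES)
    base = fit_ml(base_spec, cohort, seed=config.seed,
                  chisq_divisor=config.chisq_divisor)
    base.to_frame().to_csv(out / "base_model.csv", index=False)
    base_idx = fit_indices(base, independence_fit_cov(
        base.sample_cov, base.n)).as_dict()
    manifest["stages"]["base_model"] = {
        **_adequacy(base_idx),
        "age_effect_deq": base.params["deq~age"],
        "age_effect_gprime": base.params["gprime~age"],
    }

    # ---- stage 5: mediation screen --------------------------------------
    screen = run_screen(cohort, biomarkers, COVARIATES,
                        alpha=config.gate_alpha, seed=config.seed)
    write_class_tables(screen, out)
    class_counts = screen["protein_class"].value_counts().to_dict()
    manifest["stages"]["screen"] = {
        "class_counts": {int(k): int(v) for k, v in class_counts.items()},
        "n_failures": int((screen["failure"] != "").sum()),
        "worst_cfi": float(np.nanmin(screen["cfi"]))
        if screen["cfi"].notna().any() else None,
    }
    log.info("screen: class counts %s", class_counts)

    # ---- stage 6: split-half generalizability ---------------------------
    if config.splithalf:
        rows = []
        class1 = screen[screen["protein_class"] == 1]["biomarker"]
        half_a, half_b = random_split(cohort, seed=config.seed)
        for bm in class1.head(config.splithalf_max):
            spec = build_mediation_model(bm, COVARIATES)
            fit_a = fit_ml(spec, half_a, seed=config.seed)
            pv = fit_a.pvalues()
            sig = [p for p in ("path_a", "path_b", "path_c")
                   if bonferroni_gate(pv.get(p, 1.0), config.gate_alpha)]
            if not sig:
                continue
            res = constrained_comparison(spec, half_a, half_b, sig,
                                         seed=config.seed)
            rep = res.report().assign(biomarker=bm,
                                      retained=res.retained(
                                          config.gate_alpha))
            rows.append(rep)
        sh = (pd.concat(rows, ignore_index=True) if rows
              else pd.DataFrame(columns=["biomarker", "path"]))
        sh.to_csv(out / "splithalf_report.csv", index=False)
        manifest["stages"]["splithalf"] = {
            "n_models": int(len(rows)),
            "n_retained": int(sh.groupby("biomarker")["retained"]
                              .first().sum()) if len(sh) else 0,
        }

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True,
                   default=_json_default))
    return out


def _adequacy(idx: dict) -> dict:
    """Fit statistics annotated against the conventional thresholds."""
    cmin = idx.get("cmin_df")
    cfi = idx.get("cfi")
    rmsea = idx.get("rmsea")
    return {
        **idx,
        "cmin_df_ok": bool(cmin < 5.0) if cmin == cmin else None,
        "cfi_ok": bool(cfi >= 0.90) if cfi == cfi else None,
        "rmsea_ok": bool(rmsea <= 0.05) if rmsea == rmsea else None,
    }
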