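"""End-to-end orchestration: simulate -> fit -> analyze -> report.

``run_pipeline`` executes the full study workflow on a synthetic cohort and
writes a bundle of machine-readable tables:

* ``cohort.csv`` — the generated patient table;
* ``descriptive.csv`` — two-group comparison (test choice, statistic, p);
* ``univariate.csv`` / ``multivariate.csv`` — logistic screen and joint
  model (ORs, Wald CIs, p-values);
* ``roc.csv`` — per-predictor and combined-model ROC summaries with
  DeLong comparisons against the combined model;
* ``validation.json`` — bootstrap internal validation and calibration
  slope/intercept;
* ``calibration.csv`` / ``decision_curve.csv`` — point tables;
* ``manifest.json`` — config hash, seed and package version.

Identical config + seed produces a byte-identical bundle.  Fractions are
reported on the x1e-2 scale and ADC in 1e-3 mm^2/s (model coefficients are
per those units); internal computation uses base units.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    bootstrap_validate,
    calibration_curve,
    decision_curve,
    delong_test,
    multivariate_fit,
    roc_analysis,
    univariate_screen,
)
from .exceptions import ConfigError, RsifitError, SeparationError
from .simulate import GroupDistributionSpec, default_cohort_spec, generate_cohort
from .stats import descriptive_table

logger = logging.getLogger("rsifit")

#: model-frame columns offered as candidate predictors by default
DEFAULT_CANDIDATES = (
    "age", "sex_male", "smoking", "diameter_cm",
    "f1_pct", "f2_pct", "f3_pct", "adc", "suvmax",
)


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    mode: str = "summary"
    n_scc: int = 30
    n_ac: int = 67
    spec_path: str | None = None
    candidates: tuple[str, ...] = DEFAULT_CANDIDATES
    elimination: str = "none"
    bootstrap_B: int = 1000
    log_level: str = "INFO"

    def __post_init__(self):
        if self.bootstrap_B < 1:
            raise ConfigError("bootstrap_B must be >= 1")
        if self.mode not in {"summary", "image"}:
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.spec_path is not None and not Path(self.spec_path).exists():
            raise ConfigError(f"spec file not found: {self.spec_path}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        d = json.loads(path.read_text())
        d["candidates"] = tuple(d.get("candidates", DEFAULT_CANDIDATES))
        return cls(**d)


def model_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """Report-unit predictor matrix: fractions x1e2, ADC in 1e-3 mm^2/s."""
    mf = cohort[["age", "sex_male", "smoking", "diameter_cm", "suvmax",
                 "adc"]].copy()
    for f in ("f1", "f2", "f3"):
        mf[f"{f}_pct"] = cohort[f] * 100.0
    return mf


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run the full workflow; returns the bundle as in-memory objects and
    writes it under ``out_dir``.  Any stage failure aborts with the stage
    name and leaves a partial-results manifest."""
    logging.basicConfig(level=config.log_level)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    manifest = {
        "config": {**asdict(config), "candidates": list(config.candidates)},
        "config_sha256": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": config.seed,
        "rsifit_version": __version__,
        "stages_completed": [],
    }
    stage = "configure"
    try:
        spec = (
            GroupDistributionSpec.from_json(config.spec_path)
            if config.spec_path
            else default_cohort_spec()
        )

        stage = "simulate"
        cohort = generate_cohort(
            spec, config.n_scc, config.n_ac, seed=config.seed,
            mode=config.mode,
        )
        logger.info("simulated cohort: %d SCC / %d AC (mode=%s)",
                    (cohort["group"] == "SCC").sum(),
                    (cohort["group"] == "AC").sum(), config.mode)
        cohort.to_csv(out / "cohort.csv", index=False)
        bundle["cohort"] = cohort
        manifest["stages_completed"].append(stage)

        stage = "descriptive"
        desc = descriptive_table(cohort)
        desc.to_csv(out / "descriptive.csv", index=False)
        bundle["descriptive"] = desc
        manifest["stages_completed"].append(stage)

        stage = "model"
        mf = model_frame(cohort)
        y = (cohort["group"] == "SCC").astype(int).to_numpy()
        uni = univariate_screen(mf, list(config.candidates), y)
        uni.round(6).to_csv(out / "univariate.csv", index=False)
        bundle["univariate"] = uni
        passed = [p for p in uni.loc[uni["passed"], "predictor"]]
        logger.info("univariate screen passed: %s", passed)
        # the fraction triple sums to 100 exactly: entering all three with
        # an intercept is rank deficient, so the weakest (largest p) of the
        # three is dropped before the joint fit
        fracs = [p for p in passed if p in {"f1_pct", "f2_pct", "f3_pct"}]
        if len(fracs) == 3:
            pvals = uni.set_index("predictor")["p_value"]
            weakest = max(fracs, key=lambda f: pvals[f])
            passed.remove(weakest)
            logger.info("dropped %s (simplex collinearity)", weakest)
        # with strongly separated groups the joint model can be completely
        # separated; drop the offending predictor and refit, as an analyst
        # reporting interpretable odds ratios would
        while True:
            try:
                model = multivariate_fit(mf, passed, y,
                                         elimination=config.elimination)
                break
            except SeparationError as exc:
                if exc.predictor not in passed or len(passed) == 1:
                    raise
                passed.remove(exc.predictor)
                logger.info("dropped %s (perfect separation)", exc.predictor)
        logger.info("multivariate model converged in %d iterations on %s",
                    model.n_iter_, model.feature_names_)
        multi = model.summary()
        multi.round(6).to_csv(out / "multivariate.csv", index=False)
        bundle["model"] = model
        bundle["multivariate"] = multi
        manifest["stages_completed"].append(stage)

        stage = "roc"
        prob = model.predict_proba(mf[model.feature_names_].to_numpy())[:, 1]
        combined = roc_analysis(prob, y)
        rows = []
        for name in config.candidates:
            s = mf[name].to_numpy(dtype=float)
            direction = 1
            if roc_analysis(s, y).auc < 0.5:
                direction = -1
            r = roc_analysis(direction * s, y)
            d = delong_test(prob, direction * s, y)
            rows.append(
                dict(
                    variable=name, auc=r.auc, ci_low=r.ci_low,
                    ci_high=r.ci_high, cutoff=direction * r.cutoff,
                    direction=direction,
                    sensitivity_pct=100 * r.sensitivity,
                    specificity_pct=100 * r.specificity,
                    delong_z_vs_combined=d.z, delong_p_vs_combined=d.p_value,
                )
            )
        rows.append(
            dict(
                variable="combined", auc=combined.auc,
                ci_low=combined.ci_low, ci_high=combined.ci_high,
                cutoff=combined.cutoff, direction=1,
                sensitivity_pct=100 * combined.sensitivity,
                specificity_pct=100 * combined.specificity,
                delong_z_vs_combined=0.0, delong_p_vs_combined=1.0,
            )
        )
        roc = pd.DataFrame(rows).round(6)
        roc.to_csv(out / "roc.csv", index=False)
        bundle["roc"] = roc
        manifest["stages_completed"].append(stage)

        stage = "validate"
        report = bootstrap_validate(
            mf, model.feature_names_, y, B=config.bootstrap_B,
            seed=config.seed,
        )
        calib = calibration_curve(prob, y)
        calib.curve.round(6).to_csv(out / "calibration.csv", index=False)
        dca = decision_curve(prob, y)
        dca.table.round(6).to_csv(out / "decision_curve.csv", index=False)
        validation = {
            **asdict(report),
            "calibration_slope": calib.slope,
            "calibration_intercept": calib.intercept,
        }
        _json_dump(validation, out / "validation.json")
        bundle["validation"] = report
        bundle["calibration"] = calib
        bundle["decision_curve"] = dca
        manifest["stages_completed"].append(stage)
    except RsifitError:
        manifest["failed_stage"] = stage
        _json_dump(manifest, out / "manifest.json")
        logger.error("pipeline aborted at stage %r", stage)
        raise

    _json_dump(manifest, out / "manifest.json")
    bundle["manifest"] = manifest
    return bundle
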