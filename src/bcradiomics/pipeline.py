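"""End-to-end workflow: extract -> (harmonize) -> retrain -> frozen validation.

The workflow mirrors a two-institution external-validation design: three
prediction models (clinical, radiomics, combined) are trained on cohort 1;
their coefficients, cut-offs and directions are then frozen and applied
unchanged to cohort 2.  Optional ComBat harmonization is fitted once — on
the pooled feature table, so every scanner batch that validation will see
is known at fit time — and frozen alongside the models.

Each run writes a JSON report that enumerates every analysis setting in
force (bins, connectivity, harmonization covariates, model list) next to
the metrics, plus a human-readable markdown summary.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .harmonize import CombatModel, apply_combat, fit_combat
from .modeling import (ThresholdModel, evaluate_model,
                       fit_logistic_combination, fit_single_feature_model,
                       roc_curve)
from .survival import hazard_ratio

__all__ = ["RunConfig", "RetrainResult", "run_retrain", "run_validate",
           "write_report", "file_checksum"]

_CLINICAL_PREDICTORS = ["n_risk_factors", "psa_postop"]
_REQUIRED_CLINICAL = ["patient_id", "follow_up_months", "bcr_event",
                      "n_risk_factors", "psa_postop"]
_REQUIRED_FEATURES = ["patient_id", "batch"]


@dataclass
class RunConfig:
    """Resolved settings for one retrain/validate run."""

    feature_col: str = "SZE"
    n_bins: int = 64
    connectivity: int = 26
    harmonize: bool = False
    preserve: tuple[str, ...] = ()  # covariates protected during ComBat
    models: tuple[str, ...] = ("clinical", "radiomics", "combined")
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        known = {"clinical", "radiomics", "combined"}
        bad = set(self.models) - known
        if bad:
            raise ValidationError(f"unknown model name(s): {sorted(bad)}")
        if self.connectivity not in (6, 18, 26):
            raise ValidationError("connectivity must be 6, 18 or 26")
        if self.n_bins < 1:
            raise ValidationError("n_bins must be positive")

    def settings_in_force(self) -> dict:
        return {
            "feature": self.feature_col,
            "discretization": {"method": "FBN", "n_bins": self.n_bins},
            "glszm_connectivity": self.connectivity,
            "harmonization": {"enabled": self.harmonize,
                              "preserved_covariates": list(self.preserve)},
            "cox_ties": "breslow",
            "icc_model": "two-way random effects, absolute agreement "
                         "(ICC(2,1) single / ICC(2,k) average)",
            "multiple_testing_correction": "none (raw p-values reported)",
            "models": list(self.models),
            "seed": self.seed,
        }


@dataclass
class RetrainResult:
    models: dict[str, ThresholdModel]
    report: dict
    combat: CombatModel | None = None


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {missing}")


def _merged(features: pd.DataFrame, clinical: pd.DataFrame,
            config: RunConfig) -> pd.DataFrame:
    _check_columns(features, _REQUIRED_FEATURES + [config.feature_col],
                   "features")
    _check_columns(clinical, _REQUIRED_CLINICAL, "clinical")
    df = features.merge(clinical, on="patient_id", how="inner",
                        suffixes=("", "_clin"))
    if len(df) == 0:
        raise ValidationError("no patients shared between features and "
                              "clinical tables")
    return df


def _model_block(model: ThresholdModel, table: pd.DataFrame,
                 labels: np.ndarray, times: np.ndarray,
                 events: np.ndarray) -> dict:
    """Metrics for one model on one cohort: BCR prediction + bRFS strata."""
    rep = evaluate_model(model, table, labels)
    scores = model.score(table)
    auc = roc_curve(scores, labels, model.direction).auc
    pred = model.predict(table).astype(int)
    block = {
        "auc": auc,
        "cutoff": model.cutoff,
        "direction": model.direction,
        "n": int(rep.n),
        "events": int(labels.sum()),
        **{k: v for k, v in rep.as_dict().items() if k != "CI95"},
        "ci95": rep.as_dict()["CI95"],
    }
    if pred.min() == pred.max():  # one-sided prediction: no strata to compare
        block["stratification"] = None
        return block
    strat = hazard_ratio(pred, times, events)
    block["stratification"] = {
        "HR": strat.hazard_ratio,
        "HR_ci95": list(strat.hr_ci95),
        "HR_oe": strat.hr_oe,
        "logrank_statistic": strat.logrank_statistic,
        "logrank_p": strat.logrank_p,
        "n_per_group": list(strat.n_per_group),
        "events_per_group": list(strat.events_per_group),
        "infinite_hr": strat.infinite_hr,
    }
    return block


def _harmonized_feature(config: RunConfig, features: pd.DataFrame,
                        extra_features: pd.DataFrame | None,
                        clinical: pd.DataFrame) -> tuple[pd.DataFrame, CombatModel]:
    """Fit ComBat on the pooled table so all validation batches are known."""
    cols = [config.feature_col]
    pooled = features if extra_features is None else pd.concat(
        [features, extra_features], ignore_index=True)
    dup = pooled["patient_id"].duplicated()
    if dup.any():
        raise ValidationError(
            "patient ids must be unique across the pooled cohorts; "
            f"duplicated: {sorted(pooled.loc[dup, 'patient_id'].unique())[:5]}")
    cov = None
    if config.preserve:
        merged = pooled.merge(clinical, on="patient_id", how="left")
        cov = merged[list(config.preserve)]
    model = fit_combat(pooled[cols], pooled["batch"], covariates=cov)
    return pooled, model


def run_retrain(config: RunConfig, features: pd.DataFrame,
                clinical: pd.DataFrame,
                validation_features: pd.DataFrame | None = None) -> RetrainResult:
    """Train the configured models on cohort 1.

    ``validation_features`` is only consulted when harmonization is on, so
    the frozen ComBat model already knows the validation scanners (their
    feature values never influence the predictive-model fits, which use
    cohort-1 rows exclusively).
    """
    config.validate()
    df = _merged(features, clinical, config)
    labels = df["bcr_event"].to_numpy(int)
    times = df["follow_up_months"].to_numpy(float)
    feat = config.feature_col

    combat = None
    if config.harmonize:
        pooled, combat = _harmonized_feature(config, features,
                                             validation_features, clinical)
        harm = apply_combat(combat, pooled[[feat]], pooled["batch"])
        harm_map = dict(zip(pooled["patient_id"], harm[feat]))
        df[feat] = df["patient_id"].map(harm_map)

    models: dict[str, ThresholdModel] = {}
    report: dict = {"settings": config.settings_in_force(), "training": {}}
    meta = {"cohort": "training", "harmonized": config.harmonize}
    if "radiomics" in config.models:
        models["radiomics"] = fit_single_feature_model(
            df[feat], labels, name=feat, direction="auto", metadata=meta)
    if "clinical" in config.models:
        models["clinical"] = fit_logistic_combination(
            df[_CLINICAL_PREDICTORS], labels, metadata=meta)
    if "combined" in config.models:
        models["combined"] = fit_logistic_combination(
            df[[feat] + _CLINICAL_PREDICTORS], labels, metadata=meta)

    events = labels
    for name, model in models.items():
        report["training"][name] = _model_block(model, df, labels, times,
                                                events)
    return RetrainResult(models=models, report=report, combat=combat)


def run_validate(config: RunConfig, models: dict[str, ThresholdModel],
                 features: pd.DataFrame, clinical: pd.DataFrame,
                 combat: CombatModel | None = None) -> dict:
    """Apply frozen models to cohort 2 and report their performance.

    Models are used exactly as stored — no coefficient, cut-off or
    direction is re-estimated here.
    """
    config.validate()
    df = _merged(features, clinical, config)
    labels = df["bcr_event"].to_numpy(int)
    times = df["follow_up_months"].to_numpy(float)
    feat = config.feature_col
    if config.harmonize:
        if combat is None:
            raise ValidationError("harmonized validation requires the frozen "
                                  "ComBat model from training")
        harm = apply_combat(combat, df[[feat]], df["batch"])
        df[feat] = harm[feat].to_numpy()
    report: dict = {"settings": config.settings_in_force(), "validation": {}}
    for name, model in models.items():
        report["validation"][name] = _model_block(model, df, labels, times,
                                                  labels)
    return report


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_report(report: dict, outdir, name: str = "report") -> Path:
    """Write a run report as JSON plus a markdown summary table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    jpath = outdir / f"{name}.json"
    jpath.write_text(json.dumps(report, indent=2, default=_jsonable))
    lines = [f"# {name}", ""]
    for section in ("training", "validation"):
        if section not in report:
            continue
        lines += [f"## {section}", "",
                  "| model | AUC | BAcc | Se | Sp | HR | log-rank p |",
                  "|---|---|---|---|---|---|---|"]
        for mname, blk in report[section].items():
            strat = blk.get("stratification") or {}
            hr = strat.get("HR")
            p = strat.get("logrank_p")
            lines.append(
                f"| {mname} | {blk['auc']:.3f} | {blk['BAcc']:.3f} | "
                f"{blk['Se']:.3f} | {blk['Sp']:.3f} | "
                f"{'-' if hr is None else format(hr, '.2f')} | "
                f"{'-' if p is None else format(p, '.2g')} |")
        lines.append("")
    (outdir / f"{name}.md").write_text("\n".join(lines))
    return jpath


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
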