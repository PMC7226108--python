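"""Threshold prediction models: ROC/AUC, Youden cut-offs, logistic scores.

Three model families mirror the study design: a single-feature *radiomics*
model (the score is the feature itself, dichotomized at a Youden-optimal
cut-off), a *clinical* model, and a *combined* model, the latter two
scoring patients with a maximum-likelihood logistic combination of their
predictors.  A fitted :class:`ThresholdModel` carries its cut-off and
direction explicitly and is applied frozen at validation: no re-fitting.

Confidence intervals on proportions are exact Clopper-Pearson.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn import metrics as skm
from statsmodels.stats.proportion import proportion_confint

from .errors import DegenerateLabelsError, SchemaError, ValidationError

__all__ = [
    "ROCResult",
    "ThresholdModel",
    "ClassificationReport",
    "roc_curve",
    "youden_cutoff",
    "fit_logistic_combination",
    "fit_single_feature_model",
    "evaluate_model",
]


@dataclass
class ROCResult:
    """Empirical ROC of a scalar score against binary labels.

    ``direction`` states the positivity rule: ">=" predicts the event when
    the score is at or above a threshold, "<=" when at or below.  The
    per-threshold arrays are aligned; thresholds are on the original score
    scale.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_threshold: float
    youden_sensitivity: float
    youden_specificity: float
    direction: str = ">="


def _validate_labels(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValidationError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("both outcome classes must be present")
    return y


def _midpoint_cutoff(chosen: float, oriented_scores: np.ndarray) -> float:
    """Report a cut-off halfway between adjacent distinct observed scores.

    ``chosen`` is an oriented score value t such that the rule is
    "positive iff oriented score >= t" (t may be +inf for the degenerate
    all-negative rule).
    """
    s = np.unique(oriented_scores)
    below = s[s < chosen]
    if not np.isfinite(chosen):  # all-negative rule: any value above max
        return float(s[-1] + 0.5)
    if len(below) == 0:  # all-positive rule: any value below min
        return float(s[0] - 0.5)
    return float((chosen + below[-1]) / 2.0)


def roc_curve(scores, labels, direction: str = ">=") -> ROCResult:
    """Empirical ROC over all distinct thresholds, AUC by trapezoid.

    The Youden-optimal threshold maximizes J = Se + Sp - 1; ties are broken
    toward higher specificity.  The reported threshold is the midpoint
    between the two adjacent distinct scores it separates.
    """
    y = _validate_labels(labels)
    s = np.asarray(scores, dtype=float)
    if direction not in (">=", "<="):
        raise ValidationError(f"direction must be '>=' or '<=', got {direction!r}")
    oriented = s if direction == ">=" else -s
    fpr, tpr, thr = skm.roc_curve(y, oriented, drop_intermediate=False)
    auc = float(skm.auc(fpr, tpr))
    j = tpr - fpr
    idx = int(np.argmax(j))  # thresholds decrease, so first max has highest Sp
    cut_oriented = _midpoint_cutoff(float(thr[idx]), oriented)
    cut = cut_oriented if direction == ">=" else -cut_oriented
    thr_orig = thr if direction == ">=" else -thr
    return ROCResult(
        thresholds=thr_orig, sensitivity=tpr, specificity=1.0 - fpr, auc=auc,
        youden_threshold=cut, youden_sensitivity=float(tpr[idx]),
        youden_specificity=float(1.0 - fpr[idx]), direction=direction,
    )


def youden_cutoff(roc: ROCResult) -> float:
    """Threshold maximizing J = Se + Sp - 1 on a fitted ROC.

    Recomputes the maximum from the stored per-threshold arrays (ties
    toward higher specificity) so it can be checked against an exhaustive
    search.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    tied = np.flatnonzero(j == np.max(j))
    # operating points are ordered by decreasing specificity, so the first
    # exact maximum is the higher-Sp tie-break the stored threshold used
    assert tied[np.argmax(roc.specificity[tied])] == tied[0]
    return roc.youden_threshold


@dataclass
class ThresholdModel:
    """A frozen classifier: a score plus an explicit cut-off and direction.

    ``coef`` maps intercept/predictor names to logistic coefficients; when
    None the model is the identity on its single predictor (pure
    single-feature threshold model).
    """

    predictors: list[str]
    cutoff: float
    direction: str  # "<=" or ">="
    coef: dict[str, float] | None = None
    metadata: dict = field(default_factory=dict)
    separation_flag: bool = False
    training_report: "ClassificationReport | None" = None

    def score(self, table: pd.DataFrame) -> np.ndarray:
        missing = [p for p in self.predictors if p not in table.columns]
        if missing:
            raise SchemaError(f"predictor column(s) missing: {missing}")
        x = table[self.predictors].to_numpy(float)
        if self.coef is None:
            if len(self.predictors) != 1:
                raise SchemaError("identity model requires exactly one predictor")
            return x[:, 0]
        eta = self.coef["intercept"] + x @ np.array(
            [self.coef[p] for p in self.predictors])
        return 1.0 / (1.0 + np.exp(-eta))

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        s = self.score(table)
        return s <= self.cutoff if self.direction == "<=" else s >= self.cutoff

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = {
            "predictors": self.predictors, "cutoff": self.cutoff,
            "direction": self.direction, "coef": self.coef,
            "metadata": self.metadata, "separation_flag": self.separation_flag,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path) -> "ThresholdModel":
        d = json.loads(Path(path).read_text())
        return cls(predictors=d["predictors"], cutoff=d["cutoff"],
                   direction=d["direction"], coef=d["coef"],
                   metadata=d.get("metadata", {}),
                   separation_flag=d.get("separation_flag", False))


@dataclass
class ClassificationReport:
    """Confusion-matrix metrics with exact binomial 95% CIs."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    ppv: float
    npv: float
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "Se": self.sensitivity, "Sp": self.specificity,
            "BAcc": self.balanced_accuracy, "PPV": self.ppv, "NPV": self.npv,
            "CI95": {k: list(v) for k, v in self.ci95.items()},
        }


def _report_from_counts(tp: int, fp: int, tn: int, fn: int) -> ClassificationReport:
    def _ratio(num, den):
        return num / den if den else float("nan")

    se = _ratio(tp, tp + fn)
    sp = _ratio(tn, tn + fp)
    ci = {}
    for name, (k, m) in {"Se": (tp, tp + fn), "Sp": (tn, tn + fp),
                         "PPV": (tp, tp + fp), "NPV": (tn, tn + fn)}.items():
        if m:
            ci[name] = tuple(proportion_confint(k, m, alpha=0.05, method="beta"))
    return ClassificationReport(
        tp=tp, fp=fp, tn=tn, fn=fn, sensitivity=se, specificity=sp,
        balanced_accuracy=(se + sp) / 2.0, ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn), ci95=ci,
    )


def fit_logistic_combination(predictors: pd.DataFrame, labels,
                             metadata: dict | None = None) -> ThresholdModel:
    """Maximum-likelihood logistic model with a Youden cut-off on its scores.

    Newton/IRLS fit at tolerance 1e-8.  Perfect separation is flagged (the
    coefficients from a quasi-Newton fallback are returned with a warning)
    and the cut-off is still taken from the training ROC.
    """
    x = pd.DataFrame(predictors).astype(float)
    y = _validate_labels(labels)
    if len(x) < 10 * x.shape[1]:
        warnings.warn(
            f"only {len(x)} samples for {x.shape[1]} predictors (< 10 per "
            "predictor)", UserWarning)
    const = [c for c in x.columns if x[c].nunique() <= 1]
    if const:
        raise ValidationError(f"constant predictor column(s): {const}")
    design = sm.add_constant(x.to_numpy(), has_constant="add")
    separation = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            fit = sm.Logit(y, design).fit(method="newton", tol=1e-8, disp=0)
        params = fit.params
    except Exception:
        separation = True
        warnings.warn("possible perfect separation; coefficients from a "
                      "quasi-Newton fallback", UserWarning)
        fit = sm.Logit(y, design).fit(method="bfgs", maxiter=500, disp=0)
        params = fit.params
    coef = {"intercept": float(params[0])}
    coef.update({name: float(v) for name, v in zip(x.columns, params[1:])})
    model = ThresholdModel(predictors=list(x.columns), cutoff=0.0,
                           direction=">=", coef=coef,
                           metadata=metadata or {}, separation_flag=separation)
    scores = model.score(x)
    roc = roc_curve(scores, y, direction=">=")
    model.cutoff = roc.youden_threshold
    model.training_report = evaluate_model(model, x, y)
    return model


def fit_single_feature_model(values, labels, name: str = "feature",
                             direction: str = "auto",
                             metadata: dict | None = None) -> ThresholdModel:
    """Dichotomize a single feature at its Youden-optimal cut-off.

    ``direction="auto"`` orients the rule from the data: the side on which
    events concentrate becomes the positive side (the orientation with the
    larger AUC).
    """
    v = np.asarray(values, dtype=float)
    y = _validate_labels(labels)
    if direction == "auto":
        auc_ge = roc_curve(v, y, ">=").auc
        direction = ">=" if auc_ge >= 0.5 else "<="
    roc = roc_curve(v, y, direction)
    model = ThresholdModel(predictors=[name], cutoff=roc.youden_threshold,
                           direction=roc.direction, coef=None,
                           metadata=metadata or {})
    model.training_report = evaluate_model(
        model, pd.DataFrame({name: v}), y)
    return model


def evaluate_model(model: ThresholdModel, predictors: pd.DataFrame,
                   labels) -> ClassificationReport:
    """Apply a frozen model and tabulate its confusion-matrix metrics.

    Never re-fits: the stored coefficients, cut-off and direction are used
    unchanged.
    """
    y = np.asarray(labels).astype(int)
    pred = model.predict(pd.DataFrame(predictors)).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    return _report_from_counts(tp, fp, tn, fn)
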