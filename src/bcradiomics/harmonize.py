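"""ComBat empirical-Bayes harmonization of feature tables across scanners.

Implements the parametric location/scale ComBat model: each feature is
standardized against a pooled mean and variance (optionally after removing
designated biological covariate effects), per-batch additive (gamma) and
multiplicative (delta) effects are estimated, shrunk towards their across-
feature priors by parametric empirical Bayes (normal prior on gamma,
inverse-gamma on delta), and removed.  The model is fitted once on a
training table and can then be applied, frozen, to any table whose batch
labels were present at fit time.

By default no covariates are protected (pure technical harmonization); a
``covariates`` argument preserves designated biological effects.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import UnseenBatchError, ValidationError

__all__ = ["CombatModel", "fit_combat", "apply_combat"]


@dataclass
class CombatModel:
    """Fitted ComBat parameters for a feature table.

    All arrays are indexed ``[batch, feature]`` or ``[feature]``; the
    feature and batch orderings are stored alongside.
    """

    features: list[str]
    batches: list[str]
    grand_mean: np.ndarray  # per feature
    pooled_var: np.ndarray  # per feature
    beta_cov: np.ndarray  # (n_cov, n_feat) covariate coefficients
    covariates: list[str]
    gamma_star: np.ndarray  # (n_batch, n_feat)
    delta_star: np.ndarray  # (n_batch, n_feat), all > 0
    passthrough: list[str] = field(default_factory=list)  # zero-variance feats
    noop: bool = False  # single-batch model
    train_harmonized: pd.DataFrame | None = None

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = {
            "features": self.features,
            "batches": self.batches,
            "grand_mean": self.grand_mean.tolist(),
            "pooled_var": self.pooled_var.tolist(),
            "beta_cov": self.beta_cov.tolist(),
            "covariates": self.covariates,
            "gamma_star": self.gamma_star.tolist(),
            "delta_star": self.delta_star.tolist(),
            "passthrough": self.passthrough,
            "noop": self.noop,
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path) -> "CombatModel":
        d = json.loads(Path(path).read_text())
        return cls(
            features=d["features"], batches=d["batches"],
            grand_mean=np.asarray(d["grand_mean"]),
            pooled_var=np.asarray(d["pooled_var"]),
            beta_cov=np.asarray(d["beta_cov"]).reshape(-1, len(d["features"])),
            covariates=d["covariates"],
            gamma_star=np.asarray(d["gamma_star"]),
            delta_star=np.asarray(d["delta_star"]),
            passthrough=d["passthrough"], noop=d["noop"],
        )


def _eb_iterate(z: np.ndarray, gamma_hat: np.ndarray, delta_hat_sq: np.ndarray,
                n_b: int, tol: float = 1e-8, max_iter: int = 500):
    """Empirical-Bayes shrinkage for one batch (vectors over features)."""
    gamma_bar = gamma_hat.mean()
    tau_sq = gamma_hat.var(ddof=1) if gamma_hat.size > 1 else 1.0
    if tau_sq <= 0:
        tau_sq = 1e-12
    m = delta_hat_sq.mean()
    s2 = delta_hat_sq.var(ddof=1) if delta_hat_sq.size > 1 else 0.0
    if s2 <= 0:
        # degenerate prior: no shrinkage signal for delta
        a_prior, b_prior = 2.0 + 1e-8, m * (1.0 + 1e-8)
    else:
        a_prior = (2 * s2 + m**2) / s2
        b_prior = (m * s2 + m**3) / s2

    g_new = gamma_hat.copy()
    d_new = delta_hat_sq.copy()
    for _ in range(max_iter):
        g_old, d_old = g_new, d_new
        g_new = (n_b * tau_sq * gamma_hat + d_old * gamma_bar) / (
            n_b * tau_sq + d_old)
        sse = ((z - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * sse + b_prior) / (n_b / 2.0 + a_prior - 1.0)
        if (np.max(np.abs(g_new - g_old)) < tol
                and np.max(np.abs(d_new - d_old)) < tol):
            break
    return g_new, d_new


def fit_combat(table: pd.DataFrame, batch: pd.Series,
               covariates: pd.DataFrame | None = None,
               parametric: bool = True) -> CombatModel:
    """Fit parametric ComBat on a patients x features table.

    Parameters
    ----------
    table : DataFrame
        Numeric feature values, one row per patient.
    batch : Series
        Scanner/batch label per patient, aligned with ``table``.
    covariates : DataFrame, optional
        Biological covariates whose effects are preserved (removed before
        standardization and added back after adjustment).

    Notes
    -----
    A single-batch table yields a no-op model with a warning.  Features
    with zero pooled variance are flagged and passed through unharmonized.
    """
    if not parametric:
        raise NotImplementedError("only parametric empirical Bayes is provided")
    table = table.astype(float)
    if table.isna().any().any():
        raise ValidationError("feature table contains missing values")
    batch = pd.Series(batch).astype(str).reset_index(drop=True)
    x = table.to_numpy()  # (n, p)
    n, p = x.shape
    if len(batch) != n:
        raise ValidationError("batch labels must align with table rows")
    levels = sorted(batch.unique())
    counts = batch.value_counts()
    if any(counts[b] < 2 for b in levels) and len(levels) > 1:
        raise ValidationError("each batch needs >= 2 patients to fit")

    cov_names: list[str] = []
    c = np.zeros((n, 0))
    if covariates is not None:
        cov_df = pd.DataFrame(covariates).reset_index(drop=True).astype(float)
        cov_names = list(cov_df.columns)
        c = cov_df.to_numpy()

    if len(levels) < 2:
        warnings.warn("only one batch present; ComBat is a no-op", UserWarning)
        model = CombatModel(
            features=list(table.columns), batches=levels,
            grand_mean=x.mean(axis=0), pooled_var=x.var(axis=0),
            beta_cov=np.zeros((len(cov_names), p)), covariates=cov_names,
            gamma_star=np.zeros((1, p)), delta_star=np.ones((1, p)),
            noop=True,
        )
        model.train_harmonized = table.copy()
        return model

    # Design: batch one-hot + covariates; solve by least squares.
    b_onehot = np.column_stack([(batch == b).to_numpy(float) for b in levels])
    design = np.hstack([b_onehot, c])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    batch_means = coef[:len(levels)]  # (n_batch, p)
    beta_cov = coef[len(levels):]  # (n_cov, p)

    w = np.array([counts[b] / n for b in levels])
    grand_mean = w @ batch_means  # per feature

    fitted = design @ coef
    resid = x - fitted
    pooled_var = (resid**2).mean(axis=0)

    # a feature is unharmonizable when it carries (numerically) no variance
    zero_var = x.var(axis=0) <= 1e-12 * (np.abs(x.mean(axis=0)) ** 2 + 1.0)
    ok = ~zero_var & (pooled_var > 0)
    pooled_var = np.where(ok, pooled_var, 0.0)
    passthrough = [table.columns[k] for k in range(p) if not ok[k]]
    if passthrough:
        warnings.warn(
            f"zero-variance features passed through unharmonized: {passthrough}",
            UserWarning)
    sd = np.sqrt(np.where(ok, pooled_var, 1.0))

    stand_mean = grand_mean[None, :] + c @ beta_cov
    z = (x - stand_mean) / sd[None, :]

    gamma_star = np.zeros((len(levels), p))
    delta_star = np.ones((len(levels), p))
    for bi, b in enumerate(levels):
        idx = (batch == b).to_numpy()
        zb = z[idx]
        gamma_hat = zb.mean(axis=0)
        delta_hat_sq = zb.var(axis=0, ddof=1)
        delta_hat_sq = np.clip(delta_hat_sq, 1e-12, None)
        g_star, d_star_sq = _eb_iterate(zb, gamma_hat, delta_hat_sq, idx.sum())
        gamma_star[bi] = g_star
        delta_star[bi] = np.sqrt(np.clip(d_star_sq, 1e-12, None))
    # passthrough features: identity adjustment
    gamma_star[:, ~ok] = 0.0
    delta_star[:, ~ok] = 1.0

    model = CombatModel(
        features=list(table.columns), batches=levels, grand_mean=grand_mean,
        pooled_var=pooled_var, beta_cov=beta_cov, covariates=cov_names,
        gamma_star=gamma_star, delta_star=delta_star, passthrough=passthrough,
    )
    model.train_harmonized = apply_combat(model, table, batch, covariates)
    return model


def apply_combat(model: CombatModel, table: pd.DataFrame, batch: pd.Series,
                 covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Apply a frozen ComBat model to a feature table.

    Raises
    ------
    UnseenBatchError
        If the table contains a batch label absent from the fitted model;
        there is no silent pass-through.
    """
    table = table.astype(float)
    if list(table.columns) != model.features:
        raise ValidationError(
            f"feature columns {list(table.columns)} do not match the model's "
            f"{model.features}")
    batch = pd.Series(batch).astype(str).reset_index(drop=True)
    unseen = sorted(set(batch) - set(model.batches))
    if unseen:
        raise UnseenBatchError(
            f"batch label(s) {unseen} were not present when the model was fitted")
    if model.noop:
        return table.copy()
    x = table.to_numpy()
    n, p = x.shape
    c = np.zeros((n, 0))
    if model.covariates:
        if covariates is None:
            raise ValidationError(
                f"model was fitted with covariates {model.covariates}; "
                "covariate values are required to apply it")
        cov_df = pd.DataFrame(covariates).reset_index(drop=True).astype(float)
        c = cov_df[model.covariates].to_numpy()

    ok = model.pooled_var > 0
    sd = np.sqrt(np.where(ok, model.pooled_var, 1.0))
    stand_mean = model.grand_mean[None, :] + c @ model.beta_cov
    z = (x - stand_mean) / sd[None, :]
    bidx = np.array([model.batches.index(b) for b in batch])
    z_adj = (z - model.gamma_star[bidx]) / model.delta_star[bidx]
    out = z_adj * sd[None, :] + stand_mean
    out[:, ~ok] = x[:, ~ok]
    return pd.DataFrame(out, columns=model.features, index=table.index)
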