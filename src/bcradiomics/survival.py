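"""Recurrence-free survival analysis: Kaplan-Meier, log-rank, Cox HRs.

Estimation is delegated to lifelines (product-limit estimator, log-rank
test, Cox partial likelihood with Breslow tie handling); this module wraps
it behind the pipeline's fixed result types, adds Greenwood variances and
the median-survival convention (first time at which S(t) <= 0.5), and
reports the O/E-based hazard ratio from the log-rank table alongside the
Cox estimate.

Times are in months; all p-values are two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import SchemaError, ValidationError

__all__ = [
    "SurvivalCurve",
    "StratificationResult",
    "km_estimate",
    "logrank_test",
    "hazard_ratio",
    "cox_multivariate",
]


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate with Greenwood variance."""

    times: np.ndarray  # event-time grid (unique observed times)
    survival: np.ndarray  # S(t) just after each time
    variance: np.ndarray  # Greenwood variance of S(t)
    at_risk: np.ndarray  # number at risk just before each time
    median: float | None  # first t with S(t) <= 0.5, None if never reached

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival,
                             "greenwood_var": self.variance,
                             "at_risk": self.at_risk})


@dataclass
class StratificationResult:
    """Two-group separation of recurrence-free survival."""

    hazard_ratio: float
    hr_ci95: tuple[float, float]
    logrank_statistic: float
    logrank_p: float
    n_per_group: tuple[int, int]
    events_per_group: tuple[int, int]
    hr_oe: float | None = None  # O/E ratio from the log-rank table
    infinite_hr: bool = False


def _as_arrays(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(int)
    if len(t) == 0:
        raise ValidationError("empty survival input")
    if len(t) != len(e):
        raise ValidationError("times and events must align")
    if np.any(t <= 0):
        raise ValidationError("times must be positive")
    return t, e


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate.

    Censored subjects leave the risk set after their time; S drops only at
    event times.  The reported grid is the set of unique observed times
    (events and censorings), starting from the earliest.
    """
    t, e = _as_arrays(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 \
        else kmf.event_table
    grid = table.index.to_numpy(dtype=float)
    at_risk = table["at_risk"].to_numpy(dtype=int)
    d = table["observed"].to_numpy(dtype=float)
    n = at_risk.astype(float)
    s = np.cumprod(1.0 - np.divide(d, n, out=np.zeros_like(d), where=n > 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = np.divide(d, n * (n - d), out=np.zeros_like(d),
                             where=(n - d) > 0)
        gw_terms[(n - d) <= 0] = 0.0
    var = s**2 * np.cumsum(gw_terms)
    below = np.flatnonzero(s <= 0.5)
    median = float(grid[below[0]]) if len(below) else None
    return SurvivalCurve(times=grid, survival=s, variance=var,
                         at_risk=at_risk, median=median)


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its two-sided p-value."""
    ta, ea = _as_arrays(times_a, events_a)
    tb, eb = _as_arrays(times_b, events_b)
    if ea.sum() + eb.sum() == 0:
        warnings.warn("no events in either group; log-rank undefined, "
                      "returning statistic 0, p = 1", UserWarning)
        return 0.0, 1.0
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def _oe_hazard_ratio(ta, ea, tb, eb) -> float | None:
    """Hazard-ratio approximation (O_A/E_A)/(O_B/E_B) from the log-rank table."""
    all_t = np.concatenate([ta, tb])
    all_e = np.concatenate([ea, eb])
    grp = np.concatenate([np.zeros(len(ta)), np.ones(len(tb))])
    ea_tot = 0.0
    eb_tot = 0.0
    for t in np.unique(all_t[all_e == 1]):
        at_risk = all_t >= t
        d = float(np.sum(all_e[(all_t == t)] == 1))
        n = float(at_risk.sum())
        na = float(np.sum(at_risk & (grp == 0)))
        ea_tot += d * na / n
        eb_tot += d * (n - na) / n
    oa, ob = float(ea.sum()), float(eb.sum())
    if ea_tot <= 0 or eb_tot <= 0 or ob == 0 or oa == 0:
        return None
    # oriented as group B vs group A, matching the Cox coefficient
    return (ob / eb_tot) / (oa / ea_tot)


def hazard_ratio(group, times, events) -> StratificationResult:
    """Cox hazard ratio of group B (indicator 1) relative to group A.

    Partial-likelihood fit with Breslow tie handling and a Wald 95% CI.
    When one group has no events the HR estimate diverges; the result is
    flagged ``infinite_hr`` instead of reporting a number.
    """
    g = np.asarray(group).astype(int)
    t, e = _as_arrays(times, events)
    if set(np.unique(g)) - {0, 1}:
        raise ValidationError("group indicator must be binary 0/1")
    na, nb = int(np.sum(g == 0)), int(np.sum(g == 1))
    ev_a = int(e[g == 0].sum())
    ev_b = int(e[g == 1].sum())
    ta, ea = t[g == 0], e[g == 0]
    tb, eb = t[g == 1], e[g == 1]
    stat, p = logrank_test(ta, ea, tb, eb)
    if ev_a == 0 or ev_b == 0:
        # HR of B vs A diverges to +inf when A has no events, to 0 when B has none
        hr_limit = float("inf") if ev_a == 0 and ev_b > 0 else (
            0.0 if ev_b == 0 and ev_a > 0 else float("nan"))
        return StratificationResult(
            hazard_ratio=hr_limit,
            hr_ci95=(float("nan"), float("nan")), logrank_statistic=stat,
            logrank_p=p, n_per_group=(na, nb),
            events_per_group=(ev_a, ev_b), infinite_hr=True)
    df = pd.DataFrame({"time": t, "event": e, "group": g})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    beta = float(cph.params_["group"])
    se = float(cph.standard_errors_["group"])
    return StratificationResult(
        hazard_ratio=float(np.exp(beta)),
        hr_ci95=(float(np.exp(beta - 1.959963984540054 * se)),
                 float(np.exp(beta + 1.959963984540054 * se))),
        logrank_statistic=stat, logrank_p=p, n_per_group=(na, nb),
        events_per_group=(ev_a, ev_b),
        hr_oe=_oe_hazard_ratio(ta, ea, tb, eb))


def cox_multivariate(covariates: pd.DataFrame, times, events) -> pd.DataFrame:
    """Joint Cox fit; per-covariate HR, Wald 95% CI and p-value.

    Raises a rank-deficiency error naming the offending columns when the
    covariate matrix is collinear, and warns when the number of events is
    below 5 per covariate.
    """
    x = pd.DataFrame(covariates).astype(float)
    t, e = _as_arrays(times, events)
    p = x.shape[1]
    xm = x.to_numpy() - x.to_numpy().mean(axis=0)
    if np.linalg.matrix_rank(xm) < p:
        # identify columns involved in the deficiency
        bad = []
        for i in range(p):
            others = np.delete(xm, i, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(xm):
                bad.append(x.columns[i])
        raise SchemaError(f"collinear covariate column(s): {bad or list(x.columns)}")
    if e.sum() < 5 * p:
        warnings.warn(f"only {int(e.sum())} events for {p} covariates "
                      "(< 5 per covariate)", UserWarning)
    df = x.copy()
    df["time"] = t
    df["event"] = e
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    summ = cph.summary
    out = pd.DataFrame({
        "HR": np.exp(summ["coef"]),
        "HR_lo95": np.exp(summ["coef"] - 1.959963984540054 * summ["se(coef)"]),
        "HR_hi95": np.exp(summ["coef"] + 1.959963984540054 * summ["se(coef)"]),
        "p": summ["p"],
    })
    out.index = list(x.columns)
    return out
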