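"""Clinical covariate derivation for post-prostatectomy risk modelling.

Covers the three derived quantities the models consume — the high-risk
pathological factor count, the Roach estimate of lymph-node involvement
risk, and the CAPRA-S post-surgical score — plus the biochemical-recurrence
(BCR) event rule: a PSA rise above 0.2 ng/mL confirmed by two successive
samples.

The CAPRA-S point table is vendored as a versioned CSV
(``data/capra_s_points.csv``) rather than hard-coded in logic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .errors import MissingDataError, ValidationError

__all__ = [
    "CohortRecord",
    "count_risk_factors",
    "roach_risk",
    "capra_s",
    "classify_bcr",
    "load_capra_s_table",
]

_STAGE_ORDER = ["pT1", "pT1a", "pT1b", "pT1c", "pT2", "pT2a", "pT2b", "pT2c",
                "pT3", "pT3a", "pT3b", "pT4"]


def _stage_rank(stage: str) -> int:
    s = stage.strip()
    if not re.fullmatch(r"pT[1-4][abc]?", s):
        raise ValidationError(f"unrecognized pT stage {stage!r}")
    try:
        return _STAGE_ORDER.index(s)
    except ValueError:
        return _STAGE_ORDER.index(s[:3])


def _stage_ge_pt3a(stage: str) -> bool:
    return _stage_rank(stage) >= _STAGE_ORDER.index("pT3")


def _stage_ge_pt3b(stage: str) -> bool:
    return _stage_rank(stage) >= _STAGE_ORDER.index("pT3b")


@dataclass
class CohortRecord:
    """One patient's clinical covariates and follow-up.

    ``gleason_primary`` is the primary Gleason pattern, needed to split a
    total score of 7 into 3+4 vs 4+3 for CAPRA-S; when absent, 3+4 is
    assumed.  ``pn_positive`` is the pathological nodal status after
    lymphadenectomy (None when no lymphadenectomy was done).
    """

    patient_id: str
    age: float  # years at surgery
    psa_preop: float  # ng/mL
    psa_postop: float  # ng/mL
    stage: str  # pT1..pT4 with a/b/c subcodes
    gleason: int  # total score 6..10
    margins: str  # "R0" or "R1"
    follow_up_months: float
    bcr_event: bool
    time_to_event_months: float | None = None
    gleason_primary: int | None = None
    lymphadenectomy: bool = False
    pn_positive: bool | None = None
    batch: str = ""

    def __post_init__(self) -> None:
        if self.psa_preop < 0 or self.psa_postop < 0:
            raise ValidationError("PSA must be non-negative")
        if not 6 <= self.gleason <= 10:
            raise ValidationError(f"Gleason score {self.gleason} outside 6..10")
        if self.follow_up_months <= 0:
            raise ValidationError("follow-up must be positive")
        if self.margins not in ("R0", "R1"):
            raise ValidationError(f"margins must be R0 or R1, got {self.margins!r}")
        _stage_rank(self.stage)  # validates
        if self.bcr_event:
            t = self.time_to_event_months
            if t is not None and t > self.follow_up_months + 1e-9:
                raise ValidationError("event time exceeds follow-up")


def count_risk_factors(record: CohortRecord) -> int:
    """Count high-risk pathological features, 0..3.

    The three factors are extraprostatic stage (>= pT3a), positive margins
    (R1), and Gleason score 8-10.
    """
    for name in ("stage", "margins", "gleason"):
        if getattr(record, name) is None:
            raise MissingDataError(f"record {record.patient_id}: missing {name}")
    return (int(_stage_ge_pt3a(record.stage))
            + int(record.margins == "R1")
            + int(record.gleason >= 8))


def roach_risk(psa: float, gleason: int) -> tuple[float, bool]:
    """Roach estimate of lymph-node involvement risk, in percent.

    risk (%) = PSA * 2/3 + (Gleason - 6) * 10, clamped to [0, 100].
    Returns ``(risk, high_risk)`` where ``high_risk`` means risk strictly
    above 15%.
    """
    if psa < 0:
        raise ValidationError("PSA must be non-negative")
    if gleason < 2:
        raise ValidationError("Gleason score must be >= 2")
    value = psa * 2.0 / 3.0 + (gleason - 6) * 10.0
    value = min(100.0, max(0.0, value))
    return value, value > 15.0


def load_capra_s_table() -> pd.DataFrame:
    with resources.files("bcradiomics.data").joinpath(
            "capra_s_points.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


_CAPRA_CACHE: dict[tuple[str, str], int] | None = None


def _capra_points(component: str, category: str) -> int:
    global _CAPRA_CACHE
    if _CAPRA_CACHE is None:
        tbl = load_capra_s_table()
        _CAPRA_CACHE = {(r.component, r.category): int(r.points)
                        for r in tbl.itertuples()}
    return _CAPRA_CACHE[(component, category)]


def capra_s(record: CohortRecord) -> tuple[int, bool]:
    """CAPRA-S post-surgical score and its high-risk flag (score > 3).

    Sums the published category points for preoperative PSA, pathological
    Gleason pattern, surgical margins, extracapsular extension, seminal
    vesicle invasion and lymph-node invasion.  ECE and SVI are derived from
    the pT stage (>= pT3a and >= pT3b respectively); nodal invasion from
    ``pn_positive`` when lymphadenectomy was performed.
    """
    for name in ("psa_preop", "gleason", "margins", "stage"):
        if getattr(record, name) is None:
            raise MissingDataError(f"record {record.patient_id}: missing {name}")

    psa = record.psa_preop
    if psa <= 6:
        psa_cat = "<=6"
    elif psa <= 10:
        psa_cat = "6.01-10"
    elif psa <= 20:
        psa_cat = "10.01-20"
    else:
        psa_cat = ">20"

    g = record.gleason
    if g <= 6:
        g_cat = "no_pattern_4_or_5"
    elif g >= 8:
        g_cat = "8-10"
    else:  # score 7: split on the primary pattern; assume 3+4 if unknown
        primary = record.gleason_primary if record.gleason_primary else 3
        g_cat = "primary_4_or_5" if primary >= 4 else "secondary_4_or_5"

    lni = bool(record.pn_positive) if record.pn_positive is not None else False

    score = (
        _capra_points("psa", psa_cat)
        + _capra_points("gleason", g_cat)
        + _capra_points("margins",
                        "positive" if record.margins == "R1" else "negative")
        + _capra_points("ece",
                        "present" if _stage_ge_pt3a(record.stage) else "absent")
        + _capra_points("svi",
                        "present" if _stage_ge_pt3b(record.stage) else "absent")
        + _capra_points("lni", "present" if lni else "absent")
    )
    return score, score > 3


def classify_bcr(psa_series: list[tuple[float, float]],
                 threshold: float = 0.2) -> tuple[bool, float | None]:
    """Apply the BCR rule to a time-ordered series of (time, PSA) samples.

    A recurrence is declared when two successive samples both exceed the
    threshold; the event time is the time of the first of the two
    confirmatory samples.  Returns ``(event, event_time)`` with
    ``event_time`` None when no event occurred.
    """
    if len(psa_series) == 0:
        raise MissingDataError("empty PSA series")
    times = [t for t, _ in psa_series]
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        raise ValidationError("PSA series must be time-ordered")
    for (t1, p1), (_, p2) in zip(psa_series, psa_series[1:]):
        if p1 > threshold and p2 > threshold:
            return True, t1
    return False, None
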