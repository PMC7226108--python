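"""Synthetic phantoms and cohorts for exercising the whole pipeline.

No patient imaging is distributed with this package; instead, two
generators provide data with the statistical structure the analysis
assumes:

* :func:`generate_phantom` builds an ellipsoidal tumour ROI whose interior
  is tiled into contiguous grey-level zones by seeded region growth.  The
  mean target zone volume ``theta`` (voxels) controls the zone-size
  distribution and therefore the small-zone-emphasis (SZE) feature:
  ``theta = 1`` gives all-singleton zones (SZE = 1), large ``theta`` gives
  few large zones (low SZE).  Grey levels are assigned by greedy graph
  colouring so that 26-adjacent zones receive different levels whenever
  the palette allows, which keeps the grown regions identical to the
  connected-component zones the GLSZM sees.

* :func:`generate_cohort` draws per-patient zone-size parameters (hence
  SZE values), injects per-scanner additive/multiplicative batch effects
  at the feature level, and draws biochemical-recurrence times from an
  exponential hazard linked to the feature, with uniform censoring and a
  24-month minimum follow-up.  An image-level mode generates an actual
  phantom per patient and runs the texture extractor on it.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clinical import CohortRecord, count_risk_factors, capra_s
from .errors import SpecError
from .image_io import ROIMask, Volume3D, extract_roi
from .texture import ExtractionConfig, build_glszm, discretize_fbn, \
    small_zone_emphasis

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "BatchSpec",
    "Cohort",
    "generate_phantom",
    "generate_cohort",
    "two_institution_specs",
]

_NEIGH6 = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                    [0, -1, 0], [0, 0, 1], [0, 0, -1]])


@dataclass
class PhantomSpec:
    """Recipe for one textured ellipsoidal phantom."""

    shape: tuple[int, int, int] = (24, 24, 24)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    semi_axes_mm: tuple[float, float, float] = (9.0, 8.0, 7.0)
    theta: float = 4.0  # mean target zone volume, voxels
    n_levels: int = 32
    noise_sd: float = 0.0  # in grey-level units
    seed: int = 0

    def validate(self) -> None:
        if self.theta < 1:
            raise SpecError(f"theta must be >= 1, got {self.theta}")
        for ax, (half_mm, n, s) in enumerate(
                zip(self.semi_axes_mm, self.shape, self.spacing)):
            if 2 * half_mm > n * s:
                raise SpecError(
                    f"semi-axis {half_mm} mm does not fit grid axis {ax} "
                    f"({n} voxels x {s} mm)")
        if self.n_levels < 1:
            raise SpecError("need at least one grey level")


@dataclass
class BatchSpec:
    """One scanner batch: sampling probability and feature-level effects."""

    label: str
    prob: float
    gamma: float = 0.0  # additive shift on the feature
    delta: float = 1.0  # multiplicative scale on the feature


@dataclass
class CohortSpec:
    """Recipe for a synthetic patient cohort.

    The hazard for biochemical recurrence is exponential with rate
    ``lambda0 * exp(beta * z + beta_clinical * c)`` where ``z`` encodes the
    SZE feature through ``hazard_link``:

    * ``"threshold"`` (default): z = 1 when the true SZE is at or below
      ``sze_threshold`` — a step-risk cohort with a well-defined generative
      cut-off;
    * ``"linear"``: z = (mean - SZE)/sd, the within-cohort standardized
      feature oriented so beta > 0 raises the hazard of low-SZE
      (heterogeneous) tumours, interpretable as a log-HR per SD.

    ``c`` is the centred high-risk-factor count, giving the clinical
    covariates a deliberately weaker association with recurrence than the
    imaging feature.
    """

    n: int = 107
    batches: tuple[BatchSpec, ...] = (
        BatchSpec("siemens_1.5T", 0.7, 0.0, 1.0),
        BatchSpec("philips_3T", 0.3, 0.05, 1.1),
    )
    theta_median: float = 1.35
    theta_log_sd: float = 0.25
    # image mode has its own zone-size scale: phantom-extracted SZE(theta)
    # differs from the 1/theta^2 feature link, and this median centres the
    # extracted feature distribution on the clinical cut-off scale (~0.53)
    image_theta_median: float = 2.0
    image_theta_log_sd: float = 0.4
    feature_noise_sd: float = 0.05  # multiplicative log-normal jitter on SZE
    lambda0: float = 0.002  # baseline monthly hazard
    beta: float = float(np.log(5.5))  # feature log-HR
    beta_clinical: float = float(np.log(1.3))  # per extra risk factor
    hazard_link: str = "threshold"
    sze_threshold: float = 0.53
    min_follow_up_months: float = 24.0
    censor_window_months: float = 84.0
    seed: int = 0
    id_prefix: str = "P"  # keeps patient ids unique across pooled cohorts
    mode: str = "feature"  # or "image"
    phantom_shape: tuple[int, int, int] = (16, 16, 16)
    image_batch_offset: bool = False  # per-batch additive intensity shift

    def validate(self) -> None:
        if self.lambda0 <= 0:
            raise SpecError("lambda0 must be positive")
        if self.censor_window_months <= self.min_follow_up_months:
            raise SpecError("censoring window must extend past the minimum "
                            "follow-up")
        if abs(sum(b.prob for b in self.batches) - 1.0) > 1e-9:
            raise SpecError("batch probabilities must sum to 1")
        if self.hazard_link not in ("threshold", "linear"):
            raise SpecError(f"unknown hazard link {self.hazard_link!r}")
        if self.mode not in ("feature", "image"):
            raise SpecError(f"unknown mode {self.mode!r}")


@dataclass
class Cohort:
    """A generated cohort: tidy feature table, clinical table, records."""

    features: pd.DataFrame  # patient_id, SZE, SZE_true, theta, batch
    clinical: pd.DataFrame
    records: list[CohortRecord]


def _ellipsoid_mask(spec: PhantomSpec) -> np.ndarray:
    idx = np.indices(spec.shape, dtype=float)
    centre = [(n - 1) / 2.0 for n in spec.shape]
    q = np.zeros(spec.shape)
    for ax in range(3):
        q += ((idx[ax] - centre[ax]) * spec.spacing[ax]
              / spec.semi_axes_mm[ax]) ** 2
    return q <= 1.0


def _grow_zones(mask: np.ndarray, theta: float,
                rng: np.random.Generator) -> np.ndarray:
    """Tile the mask into contiguous regions with mean size ~theta.

    Multi-source 6-connected breadth-first growth from round(Nv/theta)
    random seed voxels: every region stays contiguous and sizes
    concentrate around theta without leaving singleton fragments between
    large regions.  theta = 1 seeds every voxel (all singletons); theta =
    Nv seeds one region covering the whole ROI.
    """
    zone_id = np.zeros(mask.shape, dtype=np.int64)
    coords = np.argwhere(mask)
    n_fg = len(coords)
    n_zones = max(1, int(round(n_fg / theta)))
    seed_rows = rng.choice(n_fg, size=n_zones, replace=False)
    frontier = deque()
    for zid, row in enumerate(rng.permutation(seed_rows), start=1):
        pos = tuple(coords[row])
        zone_id[pos] = zid
        frontier.append(pos)
    shape = mask.shape
    while frontier:
        base = frontier.popleft()
        zid = zone_id[base]
        nbrs = _NEIGH6 + np.asarray(base)
        rng.shuffle(nbrs)
        for nb in nbrs:
            if np.any(nb < 0) or np.any(nb >= shape):
                continue
            t = tuple(nb)
            if mask[t] and not zone_id[t]:
                zone_id[t] = zid
                frontier.append(t)
    return zone_id


def _colour_zones(zone_id: np.ndarray, n_levels: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Greedy zone colouring avoiding equal levels on 26-adjacent zones."""
    n_zones = int(zone_id.max())
    if n_zones == 0:
        return np.zeros(0, dtype=np.int64)
    # adjacency via 26-neighbour shifts
    adj: list[set[int]] = [set() for _ in range(n_zones + 1)]
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                a = zone_id[max(dx, 0) or None: min(dx, 0) or None,
                            max(dy, 0) or None: min(dy, 0) or None,
                            max(dz, 0) or None: min(dz, 0) or None]
                b = zone_id[max(-dx, 0) or None: min(-dx, 0) or None,
                            max(-dy, 0) or None: min(-dy, 0) or None,
                            max(-dz, 0) or None: min(-dz, 0) or None]
                both = (a > 0) & (b > 0) & (a != b)
                for za, zb in zip(a[both].ravel(), b[both].ravel()):
                    adj[za].add(int(zb))
                    adj[zb].add(int(za))
    colours = np.zeros(n_zones + 1, dtype=np.int64)
    for z in rng.permutation(np.arange(1, n_zones + 1)):
        used = {colours[nb] for nb in adj[z] if colours[nb]}
        free = [c for c in range(1, n_levels + 1) if c not in used]
        pool = free if free else list(range(1, n_levels + 1))
        colours[z] = int(rng.choice(pool))
    return colours


def generate_phantom(spec: PhantomSpec) -> tuple[Volume3D, ROIMask]:
    """Build a textured ellipsoidal phantom; deterministic per seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    fg = _ellipsoid_mask(spec)
    n_fg = int(fg.sum())
    if n_fg == 0:
        raise SpecError("semi-axes produce an empty ellipsoid on this grid")
    if spec.theta > n_fg:
        raise SpecError(
            f"theta {spec.theta} exceeds ROI volume {n_fg} voxels")
    zone_id = _grow_zones(fg, spec.theta, rng)
    colours = _colour_zones(zone_id, spec.n_levels, rng)
    vox = np.zeros(spec.shape, dtype=float)
    inside = zone_id > 0
    vox[inside] = colours[zone_id[inside]].astype(float)
    if spec.noise_sd > 0:
        vox[inside] += rng.normal(0.0, spec.noise_sd, size=int(inside.sum()))
    vol = Volume3D(vox, spacing=spec.spacing)
    mask = ROIMask(fg.astype(np.uint8), spacing=spec.spacing)
    return vol, mask


def _phantom_sze(spec: PhantomSpec, connectivity: int = 26) -> float:
    vol, mask = generate_phantom(spec)
    roi = extract_roi(vol, mask)
    disc = discretize_fbn(roi, spec.n_levels)
    return small_zone_emphasis(build_glszm(disc, connectivity))


_STAGES = ("pT2c", "pT3a", "pT3b", "pT4")
_STAGE_P = (0.38, 0.33, 0.24, 0.05)
_GLEASON = (6, 7, 8, 9, 10)
_GLEASON_P = (0.15, 0.70, 0.08, 0.05, 0.02)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a full synthetic cohort; bit-identical for a fixed seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    t_med = spec.image_theta_median if spec.mode == "image" \
        else spec.theta_median
    t_sd = spec.image_theta_log_sd if spec.mode == "image" \
        else spec.theta_log_sd
    theta = t_med * np.exp(rng.normal(0.0, t_sd, size=n))
    theta = np.clip(theta, 1.0, None)
    if spec.mode == "image":
        sze_true = np.empty(n)
        for i in range(n):
            pspec = PhantomSpec(shape=spec.phantom_shape,
                                semi_axes_mm=tuple(
                                    0.4 * d for d in spec.phantom_shape),
                                theta=float(theta[i]),
                                seed=int(rng.integers(2**31 - 1)))
            sze_true[i] = _phantom_sze(pspec)
    else:
        sze_true = 1.0 / theta**2 * np.exp(
            rng.normal(0.0, spec.feature_noise_sd, size=n))
        sze_true = np.clip(sze_true, 1e-3, 1.0)

    probs = [b.prob for b in spec.batches]
    batch_idx = rng.choice(len(spec.batches), size=n, p=probs)
    gammas = np.array([b.gamma for b in spec.batches])[batch_idx]
    deltas = np.array([b.delta for b in spec.batches])[batch_idx]
    sze_obs = sze_true * deltas + gammas
    batch_labels = np.array([spec.batches[i].label for i in batch_idx])

    age = rng.normal(65.5, 7.0, size=n)
    psa_preop = np.exp(rng.normal(np.log(8.5), 0.5, size=n))
    gleason = rng.choice(_GLEASON, size=n, p=_GLEASON_P)
    stage = rng.choice(_STAGES, size=n, p=_STAGE_P)
    margins = np.where(rng.random(n) < 0.65, "R1", "R0")
    psa_postop = rng.uniform(0.0, 0.04, size=n)

    rf = np.array([
        int(stage[i] != "pT2c") + int(margins[i] == "R1")
        + int(gleason[i] >= 8) for i in range(n)])

    if spec.hazard_link == "threshold":
        z = (sze_true <= spec.sze_threshold).astype(float)
    else:
        sd = sze_true.std()
        z = (sze_true.mean() - sze_true) / (sd if sd > 0 else 1.0)
    c_clin = rf - rf.mean()
    rate = spec.lambda0 * np.exp(spec.beta * z + spec.beta_clinical * c_clin)
    t_event = rng.exponential(1.0 / rate)
    censor = rng.uniform(spec.min_follow_up_months,
                         spec.censor_window_months, size=n)
    event = t_event <= censor
    time = np.where(event, t_event, censor)

    records: list[CohortRecord] = []
    rows = []
    for i in range(n):
        pid = f"{spec.id_prefix}{i:04d}"
        rec = CohortRecord(
            patient_id=pid, age=float(age[i]),
            psa_preop=float(psa_preop[i]), psa_postop=float(psa_postop[i]),
            stage=str(stage[i]), gleason=int(gleason[i]),
            margins=str(margins[i]),
            follow_up_months=float(time[i]), bcr_event=bool(event[i]),
            time_to_event_months=float(time[i]) if event[i] else None,
            batch=str(batch_labels[i]),
        )
        records.append(rec)
        rows.append({
            "patient_id": pid, "age": rec.age,
            "psa_preop": rec.psa_preop, "psa_postop": rec.psa_postop,
            "stage": rec.stage, "gleason": rec.gleason,
            "margins": rec.margins,
            "n_risk_factors": count_risk_factors(rec),
            "capra_s": capra_s(rec)[0],
            "follow_up_months": rec.follow_up_months,
            "bcr_event": int(rec.bcr_event), "batch": rec.batch,
        })
    features = pd.DataFrame({
        "patient_id": [r.patient_id for r in records],
        "SZE": sze_obs, "SZE_true": sze_true, "theta": theta,
        "batch": batch_labels,
    })
    return Cohort(features=features, clinical=pd.DataFrame(rows),
                  records=records)


def two_institution_specs(seed: int = 0, beta: float | None = None,
                          mode: str = "feature") -> tuple[CohortSpec, CohortSpec]:
    """Cohort specs mirroring the two-institution study design.

    Institution 1 (training, n = 107): a 1.5T and a 3T scanner in a 70/30
    split.  Institution 2 (validation, n = 88): two 1.5T scanners in a
    roughly 56/44 split, with its own feature shifts.
    """
    kwargs = {} if beta is None else {"beta": beta}
    train = CohortSpec(
        n=107,
        batches=(BatchSpec("siemens_1.5T_inst1", 0.7, 0.0, 1.0),
                 BatchSpec("philips_3T_inst1", 0.3, 0.05, 1.1)),
        seed=seed, id_prefix="I1-", mode=mode, **kwargs)
    test = CohortSpec(
        n=88,
        batches=(BatchSpec("philips_1.5T_inst2", 0.557, -0.03, 0.95),
                 BatchSpec("siemens_1.5T_inst2", 0.443, 0.02, 1.05)),
        seed=seed + 1, id_prefix="I2-", mode=mode, **kwargs)
    return train, test
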