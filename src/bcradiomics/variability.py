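"""Inter-reader delineation agreement and its effect on classification.

Pairwise mask overlap is measured by the DICE coefficient and by the
average Hausdorff distance (AHD): the mean of the two directed mean
surface-to-surface distances, where a surface voxel is a foreground voxel
with at least one 6-connected background neighbour, and distances are in
physical millimetres via the voxel spacing.

Agreement of per-reader feature values uses two-way random-effects,
absolute-agreement intraclass correlation: ICC(2,1) for single measures
and ICC(2,k) for average measures, with F-based confidence intervals
(delegated to pingouin).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import GridMismatchError, UndefinedFeatureError, ValidationError
from .image_io import ROIMask
from .modeling import ThresholdModel

__all__ = [
    "SegmentationComparison",
    "dice",
    "avg_hausdorff",
    "icc",
    "classification_stability",
    "compare_readers",
]


@dataclass
class SegmentationComparison:
    """Agreement summary across readers for one patient set."""

    readers: list[str]
    pairwise_dice: dict[tuple[str, str], float]
    pairwise_ahd_mm: dict[tuple[str, str], float]
    icc_single: float | None = None
    icc_average: float | None = None
    icc_single_ci95: tuple[float, float] | None = None
    icc_average_ci95: tuple[float, float] | None = None
    classification_changes: int | None = None


def _check_same_grid(a: ROIMask, b: ROIMask) -> None:
    if a.shape != b.shape:
        raise GridMismatchError(f"mask shapes differ: {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing, atol=1e-9):
        raise GridMismatchError(
            f"mask spacings differ: {a.spacing} vs {b.spacing}")


def dice(a: ROIMask, b: ROIMask) -> float:
    """DICE overlap 2|A n B| / (|A| + |B|)."""
    _check_same_grid(a, b)
    na, nb = a.n_foreground, b.n_foreground
    if na + nb == 0:
        raise UndefinedFeatureError("DICE undefined for two empty masks")
    inter = int(np.logical_and(a.voxels > 0, b.voxels > 0).sum())
    return 2.0 * inter / (na + nb)


def _boundary_coords_mm(mask: ROIMask) -> np.ndarray:
    """Physical coordinates of boundary voxels (6-connectivity erosion diff)."""
    fg = mask.voxels > 0
    eroded = ndimage.binary_erosion(
        fg, structure=ndimage.generate_binary_structure(3, 1),
        border_value=0)
    boundary = fg & ~eroded
    coords = np.argwhere(boundary).astype(float)
    return coords * np.asarray(mask.spacing)[None, :]


def avg_hausdorff(a: ROIMask, b: ROIMask) -> float:
    """Average Hausdorff distance between mask boundaries, in mm.

    Mean of the two directed mean nearest-surface distances d(A->B) and
    d(B->A).
    """
    _check_same_grid(a, b)
    if a.n_foreground == 0 or b.n_foreground == 0:
        raise UndefinedFeatureError("average Hausdorff needs two non-empty masks")
    pa = _boundary_coords_mm(a)
    pb = _boundary_coords_mm(b)
    d_ab = cKDTree(pb).query(pa)[0].mean()
    d_ba = cKDTree(pa).query(pb)[0].mean()
    return float((d_ab + d_ba) / 2.0)


def icc(values: np.ndarray) -> dict:
    """Two-way random-effects absolute-agreement ICC of a readers x subjects
    matrix.

    Returns ICC(2,1) (single measures) and ICC(2,k) (average measures) with
    F-based 95% CIs.  Requires >= 2 readers, >= 3 subjects, no missing
    cells and non-zero between-subject variance.
    """
    import pingouin as pg

    m = np.asarray(values, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 3:
        raise ValidationError(
            "ICC needs a readers x subjects matrix with >= 2 readers and "
            ">= 3 subjects")
    if not np.isfinite(m).all():
        raise ValidationError("ICC matrix contains missing cells")
    if np.allclose(m.var(axis=0).sum() + m.mean(axis=0).var(), 0.0):
        raise UndefinedFeatureError(
            "zero between-subject variance; ICC undefined")
    k, n = m.shape
    long = pd.DataFrame({
        "subject": np.tile(np.arange(n), k),
        "reader": np.repeat(np.arange(k), n),
        "rating": m.ravel(),
    })
    res = pg.intraclass_corr(data=long, targets="subject", raters="reader",
                             ratings="rating").set_index("Type")
    # absolute-agreement two-way random: labelled ICC2/ICC2k or ICC(A,*)
    single = res.loc["ICC(A,1)"] if "ICC(A,1)" in res.index else res.loc["ICC2"]
    average = res.loc["ICC(A,k)"] if "ICC(A,k)" in res.index else res.loc["ICC2k"]
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    return {
        "single": float(single["ICC"]),
        "average": float(average["ICC"]),
        "single_ci95": tuple(float(v) for v in single[ci_col]),
        "average_ci95": tuple(float(v) for v in average[ci_col]),
    }


def classification_stability(model: ThresholdModel,
                             per_reader_features: dict[str, np.ndarray]) -> int:
    """Number of patients whose predicted class differs between any readers.

    ``per_reader_features`` maps reader id to the feature values of the
    same patients in the same order.
    """
    preds = {}
    name = model.predictors[0]
    lengths = {len(v) for v in per_reader_features.values()}
    if len(lengths) > 1:
        raise ValidationError("readers must cover the same patients")
    for reader, vals in per_reader_features.items():
        preds[reader] = model.predict(pd.DataFrame({name: np.asarray(vals)}))
    stacked = np.vstack([preds[r] for r in sorted(preds)])
    return int(np.sum(stacked.min(axis=0) != stacked.max(axis=0)))


def compare_readers(masks_by_reader: dict[str, list[ROIMask]],
                    features_by_reader: dict[str, np.ndarray] | None = None,
                    model: ThresholdModel | None = None) -> SegmentationComparison:
    """Full agreement report: pairwise DICE/AHD, feature ICC, stability."""
    readers = sorted(masks_by_reader)
    n_cases = {len(v) for v in masks_by_reader.values()}
    if len(n_cases) > 1:
        raise ValidationError("readers must segment the same patients")
    pair_dice = {}
    pair_ahd = {}
    for ra, rb in combinations(readers, 2):
        d_vals = [dice(a, b) for a, b in
                  zip(masks_by_reader[ra], masks_by_reader[rb])]
        h_vals = [avg_hausdorff(a, b) for a, b in
                  zip(masks_by_reader[ra], masks_by_reader[rb])]
        pair_dice[(ra, rb)] = float(np.mean(d_vals))
        pair_ahd[(ra, rb)] = float(np.mean(h_vals))
    comp = SegmentationComparison(readers=readers, pairwise_dice=pair_dice,
                                  pairwise_ahd_mm=pair_ahd)
    if features_by_reader is not None:
        mat = np.vstack([features_by_reader[r] for r in readers])
        r = icc(mat)
        comp.icc_single = r["single"]
        comp.icc_average = r["average"]
        comp.icc_single_ci95 = r["single_ci95"]
        comp.icc_average_ci95 = r["average_ci95"]
        if model is not None:
            comp.classification_changes = classification_stability(
                model, {r_: features_by_reader[r_] for r_ in readers})
    return comp
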