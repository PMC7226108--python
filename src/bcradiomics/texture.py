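"""GLSZM texture analysis of a delineated region.

The grey-level size-zone matrix (GLSZM) counts P(i, j): the number of
*zones* — maximal 3-D connected components of voxels sharing the same
discretized grey level i — of size j voxels inside the ROI.  From it the
small-zone-emphasis feature

    SZE = (1 / Nz) * sum_{i,j} P(i, j) / j**2

weights small zones; SZE lies in (0, 1] and equals 1 exactly when every
zone is a single voxel.  Intensities are discretized with a fixed bin
number (FBN) over the ROI-interior intensity range before zoning, in line
with IBSI conventions.

Zones are computed strictly within the mask: background voxels never join
a zone.  Connectivity is 26 (faces + edges + corners) by default and
configurable to 18 or 6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigError, EmptyROIError, UndefinedFeatureError
from .filters import SUBBAND_LABELS, wavelet_bank
from .image_io import ROIMask, ROIVoxelSet, Volume3D, extract_roi

__all__ = [
    "DiscretizedROI",
    "GLSZMatrix",
    "FeatureRecord",
    "ExtractionConfig",
    "discretize_fbn",
    "build_glszm",
    "small_zone_emphasis",
    "large_zone_emphasis",
    "zone_percentage",
    "extract_features",
]


@dataclass
class DiscretizedROI:
    """ROI voxels mapped to integer grey levels 1..n_levels."""

    levels: np.ndarray  # int, one per ROI voxel
    coordinates: np.ndarray  # (n, 3) int
    n_levels: int
    method: str = "FBN"
    n_bins: int = 64

    def __len__(self) -> int:
        return len(self.levels)


@dataclass
class GLSZMatrix:
    """Zone counts P(i, j) with the marginal totals used by features.

    ``counts[i-1, j-1]`` holds the number of zones of grey level i and
    size j.  ``n_zones`` is the total zone count Nz and ``n_voxels`` the
    ROI voxel count Nv; the identities  sum(P) == Nz  and
    sum(j * P) == Nv  hold by construction.
    """

    counts: np.ndarray  # (Ng, Jmax) int
    n_zones: int
    n_voxels: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)


@dataclass
class FeatureRecord:
    """One scalar radiomics measurement for one patient image."""

    patient_id: str
    sequence: str  # "ADC" or "T2"
    source: str  # "original" or a wavelet sub-band label
    feature: str
    value: float
    batch: str = ""


@dataclass
class ExtractionConfig:
    """Settings for :func:`extract_features`.

    sources: image sources to analyse — "original" and/or sub-band labels,
    or the shorthand "all" for original + the 8 sub-bands.
    """

    sources: tuple[str, ...] = ("original",)
    n_bins: int = 64
    connectivity: int = 26
    features: tuple[str, ...] = ("SZE",)
    wavelet: str = "coif1"
    sequence: str = "ADC"

    def resolved_sources(self) -> tuple[str, ...]:
        if self.sources == ("all",):
            return ("original",) + SUBBAND_LABELS
        return self.sources


def discretize_fbn(roi: ROIVoxelSet, n_bins: int) -> DiscretizedROI:
    """Fixed-bin-number discretization over the ROI intensity range.

    Each intensity x maps to  g = min(n_bins, 1 + floor(n_bins * (x - min)
    / (max - min))).  A constant ROI maps entirely to level 1.
    """
    if n_bins < 1:
        raise ConfigError(f"n_bins must be >= 1, got {n_bins}")
    if len(roi) == 0:
        raise EmptyROIError("cannot discretize an empty ROI")
    x = roi.values
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        levels = np.ones(len(x), dtype=np.int64)
        n_levels = 1
    else:
        levels = 1 + np.floor(n_bins * (x - lo) / (hi - lo)).astype(np.int64)
        np.minimum(levels, n_bins, out=levels)
        n_levels = n_bins
    return DiscretizedROI(levels=levels, coordinates=roi.coordinates,
                          n_levels=n_levels, n_bins=n_bins)


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def build_glszm(disc: DiscretizedROI, connectivity: int = 26) -> GLSZMatrix:
    """Build the GLSZM by connected-component labelling per grey level.

    Zones are maximal connected components of equal-level voxels under the
    chosen 3-D connectivity, computed within the ROI only.
    """
    if connectivity not in _STRUCTURES:
        raise ConfigError(
            f"connectivity must be one of 6, 18, 26; got {connectivity}"
        )
    if len(disc) == 0:
        raise EmptyROIError("cannot build a GLSZM from an empty ROI")
    structure = _STRUCTURES[connectivity]

    coords = disc.coordinates
    mins = coords.min(axis=0)
    shape = coords.max(axis=0) - mins + 1
    grid = np.zeros(shape, dtype=np.int64)  # 0 = outside ROI
    local = coords - mins
    grid[local[:, 0], local[:, 1], local[:, 2]] = disc.levels

    n_levels = int(disc.n_levels)
    zone_sizes_by_level: dict[int, np.ndarray] = {}
    jmax = 1
    for level in np.unique(disc.levels):
        labeled, n_comp = ndimage.label(grid == level, structure=structure)
        if n_comp == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        zone_sizes_by_level[int(level)] = sizes
        jmax = max(jmax, int(sizes.max()))

    counts = np.zeros((n_levels, jmax), dtype=np.int64)
    for level, sizes in zone_sizes_by_level.items():
        for j, c in zip(*np.unique(sizes, return_counts=True)):
            counts[level - 1, int(j) - 1] = int(c)
    return GLSZMatrix(counts=counts, n_zones=int(counts.sum()),
                      n_voxels=len(disc))


def _check_nonempty(m: GLSZMatrix) -> None:
    if m.n_zones < 1:
        raise UndefinedFeatureError("GLSZM has no zones; feature undefined")


def small_zone_emphasis(m: GLSZMatrix) -> float:
    """SZE = (1/Nz) * sum_{i,j} P(i,j) / j^2, in (0, 1]."""
    _check_nonempty(m)
    j = np.arange(1, m.counts.shape[1] + 1, dtype=float)
    return float((m.counts / j**2).sum() / m.n_zones)


def large_zone_emphasis(m: GLSZMatrix) -> float:
    """LZE = (1/Nz) * sum_{i,j} j^2 * P(i,j)."""
    _check_nonempty(m)
    j = np.arange(1, m.counts.shape[1] + 1, dtype=float)
    return float((m.counts * j**2).sum() / m.n_zones)


def zone_percentage(m: GLSZMatrix) -> float:
    """ZP = Nz / Nv: fraction of voxels that start their own zone."""
    _check_nonempty(m)
    return float(m.n_zones / m.n_voxels)


_FEATURE_FUNCS = {
    "SZE": small_zone_emphasis,
    "LZE": large_zone_emphasis,
    "ZP": zone_percentage,
}


def extract_features(vol: Volume3D, mask: ROIMask,
                     config: ExtractionConfig | None = None,
                     patient_id: str = "", batch: str = "") -> list[FeatureRecord]:
    """Discretize, zone and measure each requested image source.

    For every source (the original image and/or wavelet sub-bands) the ROI
    is re-discretized on that source's intensities, the GLSZM is built and
    the configured features are emitted.  Fully deterministic.
    """
    config = config or ExtractionConfig()
    sources = config.resolved_sources()
    images: dict[str, Volume3D] = {}
    if "original" in sources:
        images["original"] = vol
    subband_sources = [s for s in sources if s != "original"]
    if subband_sources:
        for band in wavelet_bank(vol, config.wavelet):
            if band.label in subband_sources:
                images[band.label] = band.as_volume()
    unknown = [s for s in sources if s not in images]
    if unknown:
        raise ConfigError(f"unknown image source(s): {unknown}")

    records: list[FeatureRecord] = []
    for source in sources:
        roi = extract_roi(images[source], mask)
        disc = discretize_fbn(roi, config.n_bins)
        glszm = build_glszm(disc, config.connectivity)
        for feat in config.features:
            if feat not in _FEATURE_FUNCS:
                raise ConfigError(f"unknown feature {feat!r}")
            records.append(FeatureRecord(
                patient_id=patient_id, sequence=config.sequence, source=source,
                feature=feat, value=_FEATURE_FUNCS[feat](glszm), batch=batch,
            ))
    return records
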