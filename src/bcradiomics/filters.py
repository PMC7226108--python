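"""Single-level undecimated 3-D wavelet filter bank.

The bank applies the low-pass (L) and high-pass (H) decomposition filters of
an orthonormal wavelet (coiflet-1 by default) separably along each axis,
producing the eight sub-band images LLL ... HHH.  The transform is
undecimated (stationary), so every sub-band keeps the shape of the input and
can be indexed by the original tumour mask.  Boundaries are mirror-padded.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pywt
from scipy.ndimage import convolve1d

from .errors import ValidationError
from .image_io import Volume3D

__all__ = ["SUBBAND_LABELS", "FilteredVolume", "wavelet_bank"]

#: The eight L/H axis combinations; label position k filters axis k.
SUBBAND_LABELS: tuple[str, ...] = tuple(
    "".join(c) for c in product("LH", repeat=3)
)


@dataclass
class FilteredVolume:
    """One wavelet sub-band of a parent volume."""

    voxels: np.ndarray
    label: str  # e.g. "HHL": H along x, H along y, L along z
    wavelet: str
    spacing: tuple[float, float, float]

    def as_volume(self) -> Volume3D:
        return Volume3D(self.voxels, spacing=self.spacing)


def wavelet_bank(vol: Volume3D, wavelet_name: str = "coif1") -> list[FilteredVolume]:
    """Compute the 8 single-level undecimated wavelet sub-bands of a volume.

    Each sub-band is obtained by convolving the image with the wavelet's
    1-D decomposition low- or high-pass filter along each of the three axes
    (separable filtering, mirror boundary).  Filter taps follow the standard
    orthonormal coefficients shipped with PyWavelets.

    Returns the sub-bands in the fixed order ``LLL, LLH, ..., HHH``.

    Raises
    ------
    ValidationError
        If any volume dimension is shorter than the filter support.
    """
    w = pywt.Wavelet(wavelet_name)
    lo = np.asarray(w.dec_lo, dtype=np.float64)
    hi = np.asarray(w.dec_hi, dtype=np.float64)
    flen = len(lo)
    for axis, n in enumerate(vol.shape):
        if n < flen:
            raise ValidationError(
                f"axis {axis} has length {n} < filter support {flen} "
                f"for wavelet {wavelet_name!r}"
            )
    data = np.asarray(vol.voxels, dtype=np.float64)
    bands: list[FilteredVolume] = []
    for label in SUBBAND_LABELS:
        out = data
        for axis, ch in enumerate(label):
            taps = lo if ch == "L" else hi
            out = convolve1d(out, taps, axis=axis, mode="mirror")
        bands.append(
            FilteredVolume(voxels=out, label=label, wavelet=wavelet_name,
                           spacing=vol.spacing)
        )
    return bands
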