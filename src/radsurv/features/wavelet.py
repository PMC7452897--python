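"""Single-level 3D undecimated (stationary) wavelet decomposition.

Each sub-band applies the 1D low- (L) or high-pass (H) decomposition
filter of the chosen basis along each array axis, without
downsampling, so every sub-band shares the grid of the input volume
and the original ROI mask applies unchanged.  Boundary handling is
periodic.  With the Haar basis all detail sub-bands of a constant
volume vanish identically.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy.ndimage import correlate1d

from ..catalog import WAVELET_SUBBANDS
from ..io import VolumetricImage

__all__ = ["wavelet_decompose"]


def wavelet_decompose(
    image: VolumetricImage, wavelet: str = "haar"
) -> dict[str, VolumetricImage]:
    """Return the 8 sub-bands labeled LLL..HHH (letter k = filter on axis k)."""
    w = pywt.Wavelet(wavelet)
    lo = np.asarray(w.dec_lo, dtype=float)
    hi = np.asarray(w.dec_hi, dtype=float)
    data = image.voxels
    if min(data.shape) < len(lo):
        raise ValueError(
            f"volume dims {data.shape} smaller than filter length {len(lo)}"
        )
    filters = {"L": lo, "H": hi}
    out: dict[str, VolumetricImage] = {}
    for label in WAVELET_SUBBANDS:
        band = data
        for axis, letter in enumerate(label):
            band = correlate1d(band, filters[letter], axis=axis, mode="wrap")
        out[label] = VolumetricImage(band, image.spacing_mm, image.modality)
    return out
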