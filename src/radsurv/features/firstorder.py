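"""First-order intensity statistics of the ROI.

Fifteen statistics of the raw ROI intensities; entropy and uniformity
are computed on the equal-width discretized histogram (same binning as
the texture matrices) so they are well defined for continuous,
z-scored intensities.  Skewness and kurtosis of a constant ROI are
defined as 0 (with a warning) rather than NaN.
"""

from __future__ import annotations

import warnings

import numpy as np

from ..io import ROIMask, VolumetricImage, discretize

__all__ = ["extract_first_order"]


def extract_first_order(
    image: VolumetricImage, mask: ROIMask, n_bins: int = 32
) -> dict[str, float]:
    mask.check_aligned(image)
    x = image.voxels[mask.voxels]
    if x.size == 0:
        raise ValueError("empty mask")
    mean = x.mean()
    var = x.var()  # population variance
    sd = np.sqrt(var)
    if var > 0:
        skew = np.mean((x - mean) ** 3) / sd**3
        kurt = np.mean((x - mean) ** 4) / var**2 - 3.0  # excess kurtosis
    else:
        warnings.warn("constant ROI: skewness/kurtosis defined as 0", stacklevel=2)
        skew = kurt = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-ROI discretize warns once already
        labels = discretize(image, mask, n_bins)
    counts = np.bincount(labels[mask.voxels], minlength=n_bins + 1)[1:]
    p = counts[counts > 0] / x.size
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())
    return {
        "mean": float(mean),
        "median": float(np.median(x)),
        "minimum": float(x.min()),
        "maximum": float(x.max()),
        "range": float(x.max() - x.min()),
        "variance": float(var),
        "standard_deviation": float(sd),
        "mean_absolute_deviation": float(np.abs(x - mean).mean()),
        "root_mean_square": float(np.sqrt(np.mean(x**2))),
        "energy": float(np.sum(x**2)),
        "entropy": entropy,
        "uniformity": uniformity,
        "skewness": float(skew),
        "kurtosis": float(kurt),
        "percentile_90": float(np.percentile(x, 90)),
    }
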