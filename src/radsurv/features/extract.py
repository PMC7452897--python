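"""Per-sequence and per-patient feature extraction.

A sequence contributes 620 features: shape (8), first-order (15) and
texture (53) on the original z-scored image, plus first-order +
texture (68) on each of the 8 undecimated wavelet sub-bands (544).  A
two-sequence patient (T2W + ADC) contributes 1240 sequence-qualified
features.  Cardinalities are asserted on every call.
"""

from __future__ import annotations

import numpy as np

from ..catalog import FeatureCatalog
from ..io import ROIMask, VolumetricImage
from .firstorder import extract_first_order
from .shape import extract_shape
from .texture import extract_texture
from .wavelet import wavelet_decompose

__all__ = ["extract_sequence", "extract_patient"]


def extract_sequence(
    image: VolumetricImage,
    mask: ROIMask,
    sequence: str,
    catalog: FeatureCatalog | None = None,
) -> dict[str, float]:
    """All 620 features of one MR sequence, keyed by qualified name."""
    catalog = catalog or FeatureCatalog()
    mask.check_aligned(image)
    out: dict[str, float] = {}
    for name, value in extract_shape(mask).items():
        out[f"{sequence}|shape|orig|{name}"] = value
    for name, value in extract_first_order(image, mask, catalog.n_bins).items():
        out[f"{sequence}|first_order|orig|{name}"] = value
    for name, value in extract_texture(image, mask, catalog.n_bins).items():
        out[f"{sequence}|texture|orig|{name}"] = value
    for label, band in wavelet_decompose(image, catalog.wavelet).items():
        for name, value in extract_first_order(band, mask, catalog.n_bins).items():
            out[f"{sequence}|wavelet|{label}|{name}"] = value
        for name, value in extract_texture(band, mask, catalog.n_bins).items():
            out[f"{sequence}|wavelet|{label}|{name}"] = value
    expected = catalog.sequence_names(sequence)
    assert list(out) == expected, "feature names deviate from catalog order"
    assert len(out) == 620
    bad = [k for k, v in out.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite features: {bad[:5]}")
    return out


def extract_patient(
    t2w: VolumetricImage,
    adc: VolumetricImage,
    mask_t2w: ROIMask,
    mask_adc: ROIMask,
    catalog: FeatureCatalog | None = None,
) -> dict[str, float]:
    """The 1240-feature vector of a two-sequence (T2W + ADC) patient."""
    if t2w is None or adc is None:
        raise ValueError("both T2W and ADC sequences are required (no imputation)")
    catalog = catalog or FeatureCatalog()
    out = extract_sequence(t2w, mask_t2w, "T2W", catalog)
    out.update(extract_sequence(adc, mask_adc, "ADC", catalog))
    assert len(out) == 1240
    return out
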