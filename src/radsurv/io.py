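"""Volume/mask I/O, intensity preprocessing and feature-table persistence.

Images are plain 3D intensity grids with voxel spacing in millimetres,
stored as NIfTI.  Masks must share the exact grid of their paired image;
no resampling is performed (synthetic data are generated aligned, and
real-data resampling is out of scope).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumetricImage",
    "ROIMask",
    "load_volume",
    "load_mask",
    "save_volume",
    "save_mask",
    "adc_from_dwi",
    "znormalize",
    "discretize",
    "write_feature_table",
    "read_feature_table",
]

#: modality labels accepted on a VolumetricImage
MODALITIES = ("T2W", "ADC", "DWI_b0", "DWI_b1000", "unknown")


@dataclass
class VolumetricImage:
    """A 3D intensity grid with physical voxel spacing.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Intensities in arbitrary units (ADC maps use 1e-3 mm^2/s).
    spacing_mm : tuple of 3 floats
        Voxel edge lengths along each axis, millimetres.
    modality : str
        One of ``T2W``, ``ADC``, ``DWI_b0``, ``DWI_b1000`` or ``unknown``.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    modality: str = "unknown"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.voxels.ndim}D")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite intensities")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing_mm}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class ROIMask:
    """A binary tumor mask aligned voxel-for-voxel with its image."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got {arr.ndim}D")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask is not binary; found values {uniq[:10]}")
        self.voxels = arr.astype(bool)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def check_aligned(self, image: VolumetricImage) -> None:
        if self.shape != image.shape:
            raise ValueError(f"mask grid {self.shape} != image grid {image.shape}")
        if not np.allclose(self.spacing_mm, image.spacing_mm):
            raise ValueError(
                f"mask spacing {self.spacing_mm} != image spacing {image.spacing_mm}"
            )


def _nifti_spacing(img: nib.Nifti1Image) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def load_volume(path: str | Path, modality: str = "unknown") -> VolumetricImage:
    """Load a 3D NIfTI volume; raises on non-3D data."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D data, got {data.ndim}D")
    return VolumetricImage(data, _nifti_spacing(img), modality)


def load_mask(path: str | Path) -> ROIMask:
    """Load a binary ROI mask from NIfTI, binarizing at > 0.5.

    Values other than {0, 1} (after thresholding non-integral data) are
    rejected: a labelled multi-structure mask is not a tumor ROI.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D mask, got {data.ndim}D")
    uniq = np.unique(data)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValueError(f"{path}: mask is not binary; values found: {uniq[:10]}")
    return ROIMask(data > 0.5, _nifti_spacing(img))


def _to_nifti(voxels: np.ndarray, spacing: tuple[float, float, float]) -> nib.Nifti1Image:
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(voxels), affine)
    img.header.set_zooms(spacing)
    return img


def save_volume(image: VolumetricImage, path: str | Path) -> None:
    nib.save(_to_nifti(image.voxels.astype(np.float64), image.spacing_mm), str(path))


def save_mask(mask: ROIMask, path: str | Path) -> None:
    nib.save(_to_nifti(mask.voxels.astype(np.uint8), mask.spacing_mm), str(path))


def adc_from_dwi(b0: VolumetricImage, b1000: VolumetricImage) -> VolumetricImage:
    """Apparent diffusion coefficient from a two-point DWI acquisition.

    Assumes monoexponential signal decay S(b) = S(0) exp(-b * ADC), so with
    b-values 0 and 1000 s/mm^2 the per-voxel map is

        ADC = ln(S_b0 / S_b1000) / 1000        [mm^2/s]

    reported in the conventional 1e-3 mm^2/s units.  Voxels where either
    signal is non-positive carry no valid decay information and are set to
    0 with a counted warning (typical of background/air).
    """
    if b0.shape != b1000.shape:
        raise ValueError(f"grid mismatch: b0 {b0.shape} vs b1000 {b1000.shape}")
    if not np.allclose(b0.spacing_mm, b1000.spacing_mm):
        raise ValueError("spacing mismatch between b0 and b1000 volumes")
    s0, s1 = b0.voxels, b1000.voxels
    valid = (s0 > 0) & (s1 > 0)
    adc = np.zeros_like(s0)
    # ln ratio / (b1 - b0) with b in s/mm^2, then * 1e3 => units of 1e-3 mm^2/s
    adc[valid] = np.log(s0[valid] / s1[valid]) / 1000.0 * 1e3
    n_bad = int((~valid).sum())
    if n_bad:
        warnings.warn(
            f"adc_from_dwi: {n_bad} voxel(s) with non-positive signal set to ADC=0",
            stacklevel=2,
        )
    return VolumetricImage(adc, b0.spacing_mm, "ADC")


def znormalize(image: VolumetricImage) -> VolumetricImage:
    """Z-score the whole volume to zero mean and unit standard deviation.

    Applied per patient and per sequence so that intensities from
    different scanners share a standard-normal scale.  A constant volume
    has no scale and is an error.
    """
    v = image.voxels
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot z-normalize a constant volume (zero variance)")
    return VolumetricImage((v - v.mean()) / sd, image.spacing_mm, image.modality)


def discretize(
    image: VolumetricImage, mask: ROIMask, n_bins: int = 32
) -> np.ndarray:
    """Equal-width gray-level discretization of ROI intensities.

    Returns an integer array on the full grid: 0 outside the ROI and a
    bin label in 1..n_bins inside, with bins spanning [min, max] of the
    ROI intensities and the maximum mapping to ``n_bins``.  A constant
    ROI collapses to bin 1 with a warning.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    mask.check_aligned(image)
    if mask.n_voxels == 0:
        raise ValueError("empty mask")
    roi = image.voxels[mask.voxels]
    lo, hi = roi.min(), roi.max()
    labels = np.zeros(image.shape, dtype=np.int32)
    if hi == lo:
        warnings.warn("constant ROI: all voxels assigned to bin 1", stacklevel=2)
        labels[mask.voxels] = 1
        return labels
    binned = np.floor((roi - lo) / (hi - lo) * n_bins).astype(np.int32) + 1
    binned[binned > n_bins] = n_bins  # the ROI maximum lands here
    labels[mask.voxels] = binned
    return labels


# ---------------------------------------------------------------------------
# feature tables

def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Persist a per-patient feature table as CSV.

    The table must be indexed by unique ``patient_id``; columns are fully
    qualified feature names (``sequence|group|subband|name``).
    """
    if table.index.name != "patient_id":
        raise ValueError("feature table must be indexed by 'patient_id'")
    if table.index.duplicated().any():
        dup = table.index[table.index.duplicated()][:5].tolist()
        raise ValueError(f"duplicate patient_id values: {dup}")
    table.to_csv(path, index=True)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="patient_id")
    if df.index.duplicated().any():
        raise ValueError("duplicate patient_id values in feature table")
    return df
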