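"""The canonical radiomic feature catalog.

The feature set mirrors the four-group layout used in multiparametric
rectal-MRI radiomics signatures: 8 shape/size features, 15 first-order
intensity statistics, 53 texture statistics (24 GLCM + 16 GLRLM +
13 GLSZM), and the first-order + texture set (68) recomputed on each of
the 8 sub-bands of a single-level 3D undecimated wavelet transform
(544), i.e. 620 features per MR sequence and 1240 per patient for a
T2W + ADC pair.  Base definitions follow the IBSI nomenclature; the
exact composition is a documented reconstruction constrained to those
printed group cardinalities and is configuration-swappable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "FeatureCatalog",
    "SHAPE_FEATURES",
    "FIRST_ORDER_FEATURES",
    "GLCM_FEATURES",
    "GLRLM_FEATURES",
    "GLSZM_FEATURES",
    "TEXTURE_FEATURES",
    "WAVELET_SUBBANDS",
]

SHAPE_FEATURES: tuple[str, ...] = (
    "volume",
    "surface_area",
    "surface_to_volume_ratio",
    "sphericity",
    "compactness_1",
    "compactness_2",
    "spherical_disproportion",
    "max_3d_diameter",
)

FIRST_ORDER_FEATURES: tuple[str, ...] = (
    "mean",
    "median",
    "minimum",
    "maximum",
    "range",
    "variance",
    "standard_deviation",
    "mean_absolute_deviation",
    "root_mean_square",
    "energy",
    "entropy",
    "uniformity",
    "skewness",
    "kurtosis",
    "percentile_90",
)

GLCM_FEATURES: tuple[str, ...] = tuple(
    "glcm_" + n
    for n in (
        "joint_energy",
        "joint_entropy",
        "contrast",
        "dissimilarity",
        "inverse_difference",
        "inverse_difference_moment",
        "inverse_difference_normalized",
        "inverse_difference_moment_normalized",
        "inverse_variance",
        "maximum_probability",
        "joint_average",
        "joint_variance",
        "correlation",
        "autocorrelation",
        "cluster_tendency",
        "cluster_shade",
        "cluster_prominence",
        "sum_average",
        "sum_entropy",
        "difference_average",
        "difference_entropy",
        "difference_variance",
        "imc1",
        "imc2",
    )
)

GLRLM_FEATURES: tuple[str, ...] = tuple(
    "glrlm_" + n
    for n in (
        "short_run_emphasis",
        "long_run_emphasis",
        "gray_level_nonuniformity",
        "gray_level_nonuniformity_normalized",
        "run_length_nonuniformity",
        "run_length_nonuniformity_normalized",
        "run_percentage",
        "gray_level_variance",
        "run_variance",
        "run_entropy",
        "low_gray_level_run_emphasis",
        "high_gray_level_run_emphasis",
        "short_run_low_gray_level_emphasis",
        "short_run_high_gray_level_emphasis",
        "long_run_low_gray_level_emphasis",
        "long_run_high_gray_level_emphasis",
    )
)

GLSZM_FEATURES: tuple[str, ...] = tuple(
    "glszm_" + n
    for n in (
        "small_area_emphasis",
        "large_area_emphasis",
        "gray_level_nonuniformity",
        "gray_level_nonuniformity_normalized",
        "size_zone_nonuniformity",
        "size_zone_nonuniformity_normalized",
        "zone_percentage",
        "gray_level_variance",
        "zone_variance",
        "zone_entropy",
        "low_gray_level_zone_emphasis",
        "high_gray_level_zone_emphasis",
        "small_area_low_gray_level_emphasis",
    )
)

TEXTURE_FEATURES: tuple[str, ...] = GLCM_FEATURES + GLRLM_FEATURES + GLSZM_FEATURES

#: wavelet sub-band labels; letter k is the filter (L=low/H=high pass)
#: applied along array axis k
WAVELET_SUBBANDS: tuple[str, ...] = (
    "LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH",
)


@dataclass(frozen=True)
class FeatureCatalog:
    """Ordered feature definitions plus extraction parameters.

    Parameters
    ----------
    n_bins : int
        Gray levels for ROI discretization before texture matrices.
    wavelet : str
        PyWavelets basis name for the undecimated decomposition.
    """

    n_bins: int = 32
    wavelet: str = "haar"
    shape_features: tuple[str, ...] = SHAPE_FEATURES
    first_order_features: tuple[str, ...] = FIRST_ORDER_FEATURES
    texture_features: tuple[str, ...] = TEXTURE_FEATURES
    subbands: tuple[str, ...] = WAVELET_SUBBANDS

    def __post_init__(self) -> None:
        if len(self.shape_features) != 8:
            raise ValueError("catalog must define exactly 8 shape features")
        if len(self.first_order_features) != 15:
            raise ValueError("catalog must define exactly 15 first-order features")
        if len(self.texture_features) != 53:
            raise ValueError("catalog must define exactly 53 texture features")
        if len(self.subbands) != 8:
            raise ValueError("catalog must define exactly 8 wavelet sub-bands")

    @property
    def n_per_sequence(self) -> int:
        """8 + 15 + 53 + 8 * (15 + 53) = 620."""
        base = len(self.first_order_features) + len(self.texture_features)
        return len(self.shape_features) + base + len(self.subbands) * base

    def sequence_names(self, sequence: str) -> list[str]:
        """The 620 qualified names ``sequence|group|subband|feature``."""
        names = [f"{sequence}|shape|orig|{f}" for f in self.shape_features]
        names += [f"{sequence}|first_order|orig|{f}" for f in self.first_order_features]
        names += [f"{sequence}|texture|orig|{f}" for f in self.texture_features]
        for sb in self.subbands:
            names += [f"{sequence}|wavelet|{sb}|{f}" for f in self.first_order_features]
            names += [f"{sequence}|wavelet|{sb}|{f}" for f in self.texture_features]
        assert len(names) == self.n_per_sequence == 620
        return names

    def patient_names(self, sequences: tuple[str, str] = ("T2W", "ADC")) -> list[str]:
        """The 1240 qualified names for a two-sequence patient."""
        return self.sequence_names(sequences[0]) + self.sequence_names(sequences[1])
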