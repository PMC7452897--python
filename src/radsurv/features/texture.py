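"""3D texture features from gray-level co-occurrence, run-length and
size-zone matrices.

All matrices are built on the equal-width discretized ROI (labels
1..n_bins, 0 outside the ROI).  GLCM uses the 13 unique distance-1
direction offsets, symmetric pairs, pooled (averaged) over directions;
GLRLM pools run counts over the same 13 directions; GLSZM uses
26-connected zones.  The split 24 GLCM + 16 GLRLM + 13 GLSZM gives the
catalog's 53 texture statistics.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..catalog import GLCM_FEATURES, GLRLM_FEATURES, GLSZM_FEATURES
from ..io import ROIMask, VolumetricImage, discretize

__all__ = [
    "OFFSETS_13",
    "glcm_matrix",
    "glrlm_matrix",
    "glszm_matrix",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "extract_texture",
]

#: the 13 unique direction offsets at Chebyshev distance 1 in 3D
#: (one representative per +/- pair)
OFFSETS_13: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

_EPS = np.finfo(float).eps


def _crop_to_roi(labels: np.ndarray) -> np.ndarray:
    """Tight bounding box around the nonzero labels (speed only)."""
    nz = np.nonzero(labels)
    slices = tuple(slice(int(a.min()), int(a.max()) + 1) for a in nz)
    return labels[slices]


def _shift_slices(offset: tuple[int, int, int]):
    src, dst = [], []
    for d in offset:
        if d == 0:
            src.append(slice(None))
            dst.append(slice(None))
        elif d > 0:
            src.append(slice(None, -d))
            dst.append(slice(d, None))
        else:
            src.append(slice(-d, None))
            dst.append(slice(None, d))
    return tuple(src), tuple(dst)


def glcm_matrix(
    labels: np.ndarray,
    n_levels: int,
    offsets: tuple[tuple[int, int, int], ...] = OFFSETS_13,
) -> np.ndarray:
    """Symmetric gray-level co-occurrence probabilities, pooled over
    directions.

    Each per-direction count matrix is normalized and the normalized
    matrices are averaged (directions with no valid pairs are skipped),
    so the result is invariant to the enumeration order of offsets.
    """
    lab = _crop_to_roi(np.asarray(labels))
    pooled = np.zeros((n_levels, n_levels))
    n_used = 0
    for off in offsets:
        src, dst = _shift_slices(off)
        a = lab[src].ravel()
        b = lab[dst].ravel()
        ok = (a > 0) & (b > 0)
        if not ok.any():
            continue
        idx = (a[ok] - 1) * n_levels + (b[ok] - 1)
        counts = np.bincount(idx, minlength=n_levels * n_levels).reshape(
            n_levels, n_levels
        ).astype(float)
        counts = counts + counts.T  # symmetric pairs
        pooled += counts / counts.sum()
        n_used += 1
    if n_used == 0:
        raise ValueError("ROI has no voxel pairs for any direction (too small)")
    return pooled / n_used


def glcm_features(P: np.ndarray) -> dict[str, float]:
    L = P.shape[0]
    i = np.arange(1, L + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    p = P
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sd_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))
    diff = np.abs(I - J)
    # p_{x+y}(k), k = 2..2L ; p_{x-y}(k), k = 0..L-1
    k_sum = np.arange(2, 2 * L + 1)
    p_sum = np.array([p[(I + J) == k].sum() for k in k_sum])
    k_diff = np.arange(0, L)
    p_diff = np.array([p[diff == k].sum() for k in k_diff])

    def _ent(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    hxy = _ent(p)
    hx = _ent(px)
    hy = _ent(py)
    pxy_prod = np.outer(px, py)
    nz = pxy_prod > 0
    hxy1 = float(-(p[nz] * np.log2(pxy_prod[nz])).sum())
    hxy2 = float(-(pxy_prod[nz] * np.log2(pxy_prod[nz])).sum())
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))) if hxy2 >= hxy else 0.0
    if sd_x * sd_y > 0:
        correlation = float(((I - mu_x) * (J - mu_y) * p).sum() / (sd_x * sd_y))
    else:
        correlation = 1.0  # single gray level: perfectly correlated
    da = float((k_diff * p_diff).sum())
    off_diag = diff > 0
    return {
        "glcm_joint_energy": float((p**2).sum()),
        "glcm_joint_entropy": hxy,
        "glcm_contrast": float((diff**2 * p).sum()),
        "glcm_dissimilarity": float((diff * p).sum()),
        "glcm_inverse_difference": float((p / (1.0 + diff)).sum()),
        "glcm_inverse_difference_moment": float((p / (1.0 + diff**2)).sum()),
        "glcm_inverse_difference_normalized": float((p / (1.0 + diff / L)).sum()),
        "glcm_inverse_difference_moment_normalized": float(
            (p / (1.0 + (diff / L) ** 2)).sum()
        ),
        "glcm_inverse_variance": float((p[off_diag] / diff[off_diag] ** 2).sum()),
        "glcm_maximum_probability": float(p.max()),
        "glcm_joint_average": mu_x,
        "glcm_joint_variance": float(((I - mu_x) ** 2 * p).sum()),
        "glcm_correlation": correlation,
        "glcm_autocorrelation": float((I * J * p).sum()),
        "glcm_cluster_tendency": float(((I + J - mu_x - mu_y) ** 2 * p).sum()),
        "glcm_cluster_shade": float(((I + J - mu_x - mu_y) ** 3 * p).sum()),
        "glcm_cluster_prominence": float(((I + J - mu_x - mu_y) ** 4 * p).sum()),
        "glcm_sum_average": float((k_sum * p_sum).sum()),
        "glcm_sum_entropy": _ent(p_sum),
        "glcm_difference_average": da,
        "glcm_difference_entropy": _ent(p_diff),
        "glcm_difference_variance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "glcm_imc1": float(imc1),
        "glcm_imc2": float(imc2),
    }


def glrlm_matrix(
    labels: np.ndarray,
    n_levels: int,
    offsets: tuple[tuple[int, int, int], ...] = OFFSETS_13,
) -> np.ndarray:
    """Gray-level run-length counts R[g-1, l-1], pooled over directions.

    A run is a maximal set of consecutive equal-gray-level ROI voxels
    along one direction; background (label 0) breaks runs and
    contributes none.
    """
    lab = _crop_to_roi(np.asarray(labels))
    shape = lab.shape
    max_run = int(np.ceil(np.sqrt(sum(s**2 for s in shape)))) + 1
    R = np.zeros((n_levels, max_run))
    X, Y, Z = np.indices(shape)
    flat = lab.ravel()
    for dx, dy, dz in offsets:
        # unit-step line parameter: the first nonzero component moves by
        # +/-1 each step, so its signed coordinate indexes positions
        # along the line and projecting it out identifies the line
        axes = (dx, dy, dz)
        a = next(i for i, c in enumerate(axes) if c != 0)
        tpos = (X, Y, Z)[a] * axes[a]
        t = tpos.ravel()
        u = (X - tpos * dx).ravel()
        v = (Y - tpos * dy).ravel()
        w = (Z - tpos * dz).ravel()
        order = np.lexsort((t, w, v, u))
        vals = flat[order]
        line = (u[order], v[order], w[order])
        # a new run starts at a new line or at a gray-level change
        start = np.empty(len(vals), dtype=bool)
        start[0] = True
        start[1:] = (vals[1:] != vals[:-1])
        for c in line:
            start[1:] |= c[1:] != c[:-1]
        run_id = np.cumsum(start) - 1
        run_val = vals[start]
        run_len = np.bincount(run_id)
        keep = run_val > 0
        if keep.any():
            np.add.at(R, (run_val[keep] - 1, run_len[keep] - 1), 1.0)
    # trim trailing all-zero run lengths
    used = np.nonzero(R.sum(axis=0))[0]
    return R[:, : used.max() + 1] if used.size else R[:, :1]


def glrlm_features(R: np.ndarray, n_voxels: int, n_directions: int = 13) -> dict[str, float]:
    n_runs = R.sum()
    if n_runs == 0:
        raise ValueError("empty run-length matrix")
    P = R / n_runs
    g = np.arange(1, R.shape[0] + 1)
    l = np.arange(1, R.shape[1] + 1)
    G, Lm = np.meshgrid(g, l, indexing="ij")
    pg = P.sum(axis=1)
    pl = P.sum(axis=0)
    mu_l = float((l * pl).sum())
    mu_g = float((g * pg).sum())
    pz = P[P > 0]
    return {
        "glrlm_short_run_emphasis": float((P / Lm**2).sum()),
        "glrlm_long_run_emphasis": float((P * Lm**2).sum()),
        "glrlm_gray_level_nonuniformity": float((R.sum(axis=1) ** 2).sum() / n_runs),
        "glrlm_gray_level_nonuniformity_normalized": float((pg**2).sum()),
        "glrlm_run_length_nonuniformity": float((R.sum(axis=0) ** 2).sum() / n_runs),
        "glrlm_run_length_nonuniformity_normalized": float((pl**2).sum()),
        "glrlm_run_percentage": float(n_runs / (n_voxels * n_directions)),
        "glrlm_gray_level_variance": float(((G - mu_g) ** 2 * P).sum()),
        "glrlm_run_variance": float(((Lm - mu_l) ** 2 * P).sum()),
        "glrlm_run_entropy": float(-(pz * np.log2(pz)).sum()),
        "glrlm_low_gray_level_run_emphasis": float((P / G**2).sum()),
        "glrlm_high_gray_level_run_emphasis": float((P * G**2).sum()),
        "glrlm_short_run_low_gray_level_emphasis": float((P / (G**2 * Lm**2)).sum()),
        "glrlm_short_run_high_gray_level_emphasis": float((P * G**2 / Lm**2).sum()),
        "glrlm_long_run_low_gray_level_emphasis": float((P * Lm**2 / G**2).sum()),
        "glrlm_long_run_high_gray_level_emphasis": float((P * G**2 * Lm**2).sum()),
    }


_STRUCT_26 = np.ones((3, 3, 3), dtype=int)


def glszm_matrix(labels: np.ndarray, n_levels: int) -> np.ndarray:
    """Gray-level size-zone counts Z[g-1, s-1] with 26-connected zones."""
    lab = _crop_to_roi(np.asarray(labels))
    sizes_by_level: list[tuple[int, np.ndarray]] = []
    max_size = 1
    for level in range(1, n_levels + 1):
        comp, n_comp = ndimage.label(lab == level, structure=_STRUCT_26)
        if n_comp == 0:
            continue
        sizes = np.bincount(comp.ravel())[1:]
        sizes_by_level.append((level, sizes))
        max_size = max(max_size, int(sizes.max()))
    Z = np.zeros((n_levels, max_size))
    for level, sizes in sizes_by_level:
        np.add.at(Z, (level - 1, sizes - 1), 1.0)
    return Z


def glszm_features(Z: np.ndarray, n_voxels: int) -> dict[str, float]:
    n_zones = Z.sum()
    if n_zones == 0:
        raise ValueError("empty size-zone matrix")
    P = Z / n_zones
    g = np.arange(1, Z.shape[0] + 1)
    s = np.arange(1, Z.shape[1] + 1)
    G, S = np.meshgrid(g, s, indexing="ij")
    pg = P.sum(axis=1)
    mu_g = float((g * pg).sum())
    mu_s = float((s * P.sum(axis=0)).sum())
    pz = P[P > 0]
    return {
        "glszm_small_area_emphasis": float((P / S**2).sum()),
        "glszm_large_area_emphasis": float((P * S**2).sum()),
        "glszm_gray_level_nonuniformity": float((Z.sum(axis=1) ** 2).sum() / n_zones),
        "glszm_gray_level_nonuniformity_normalized": float((pg**2).sum()),
        "glszm_size_zone_nonuniformity": float((Z.sum(axis=0) ** 2).sum() / n_zones),
        "glszm_size_zone_nonuniformity_normalized": float((P.sum(axis=0) ** 2).sum()),
        "glszm_zone_percentage": float(n_zones / n_voxels),
        "glszm_gray_level_variance": float(((G - mu_g) ** 2 * P).sum()),
        "glszm_zone_variance": float(((S - mu_s) ** 2 * P).sum()),
        "glszm_zone_entropy": float(-(pz * np.log2(pz)).sum()),
        "glszm_low_gray_level_zone_emphasis": float((P / G**2).sum()),
        "glszm_high_gray_level_zone_emphasis": float((P * G**2).sum()),
        "glszm_small_area_low_gray_level_emphasis": float((P / (G**2 * S**2)).sum()),
    }


def extract_texture(
    image: VolumetricImage, mask: ROIMask, n_bins: int = 32
) -> dict[str, float]:
    """The catalog's 53 texture statistics of the discretized ROI."""
    if mask.n_voxels < 2:
        raise ValueError("texture features need an ROI of at least 2 voxels")
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")  # constant-ROI discretize warning handled upstream
        labels = discretize(image, mask, n_bins)
    out: dict[str, float] = {}
    out.update(glcm_features(glcm_matrix(labels, n_bins)))
    out.update(glrlm_features(glrlm_matrix(labels, n_bins), mask.n_voxels))
    out.update(glszm_features(glszm_matrix(labels, n_bins), mask.n_voxels))
    ordered = {k: out[k] for k in GLCM_FEATURES + GLRLM_FEATURES + GLSZM_FEATURES}
    assert len(ordered) == 53
    return ordered
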