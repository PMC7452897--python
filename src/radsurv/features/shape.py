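"""Shape and size features of a binary tumor mask, in physical units.

Surface area uses the exposed-voxel-face convention: every face of a
foreground voxel not shared with another foreground voxel contributes
its physical face area.  This makes a 20 mm cube have exactly
A = 6 a^2 and hence sphericity (pi/6)^(1/3), and keeps single-voxel
masks well defined.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from ..io import ROIMask

__all__ = ["extract_shape"]


def _surface_area(vox: np.ndarray, spacing: tuple[float, float, float]) -> float:
    sx, sy, sz = spacing
    face_area = (sy * sz, sx * sz, sx * sy)
    total = 0.0
    for axis, fa in enumerate(face_area):
        m = vox.astype(np.int8)
        d = np.diff(m, axis=axis)
        exposed = int(np.abs(d).sum())
        # outer boundary faces at the two ends of the grid along this axis
        first = np.take(m, 0, axis=axis).sum()
        last = np.take(m, -1, axis=axis).sum()
        total += fa * (exposed + first + last)
    return float(total)


def _max_3d_diameter(vox: np.ndarray, spacing: tuple[float, float, float]) -> float:
    coords = np.argwhere(vox) * np.asarray(spacing)
    if len(coords) == 1:
        return 0.0
    if len(coords) > 4:
        try:
            hull = ConvexHull(coords)
            coords = coords[hull.vertices]
        except Exception:  # degenerate (coplanar/collinear) point sets
            pass
    return float(pdist(coords).max())


def extract_shape(mask: ROIMask) -> dict[str, float]:
    """Eight shape/size descriptors of the ROI.

    Sphericity = pi^(1/3) (6V)^(2/3) / A; compactness_1 = V / (sqrt(pi)
    A^(3/2)); compactness_2 = 36 pi V^2 / A^3; spherical disproportion
    is the reciprocal of sphericity.  Distances in mm, volume in mm^3.
    """
    vox = mask.voxels
    n = int(vox.sum())
    if n == 0:
        raise ValueError("empty mask")
    sx, sy, sz = mask.spacing_mm
    volume = n * sx * sy * sz
    area = _surface_area(vox, mask.spacing_mm)
    sphericity = np.pi ** (1 / 3) * (6.0 * volume) ** (2 / 3) / area
    return {
        "volume": volume,
        "surface_area": area,
        "surface_to_volume_ratio": area / volume,
        "sphericity": float(sphericity),
        "compactness_1": float(volume / (np.sqrt(np.pi) * area ** 1.5)),
        "compactness_2": float(36.0 * np.pi * volume**2 / area**3),
        "spherical_disproportion": float(1.0 / sphericity),
        "max_3d_diameter": _max_3d_diameter(vox, mask.spacing_mm),
    }
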