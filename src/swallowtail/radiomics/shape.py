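"""3D shape features of a binary ROI mask, IBSI definitions.

The 4-slice SNpc ROI is treated as a single 3D object.  Mesh-based
quantities (volume, surface area, sphericity, diameters) use a
marching-cubes triangulation of the mask; axis-based quantities use the
principal components of the physical voxel-center coordinates.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

__all__ = ["shape_features", "SHAPE_NAMES"]

SHAPE_NAMES = (
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Maximum3DDiameter", "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow",
    "MajorAxisLength", "MinorAxisLength", "LeastAxisLength",
    "Elongation", "Flatness",
)


def _max_diameter(points: np.ndarray) -> float:
    """Largest pairwise distance; convex hull prunes the candidate set."""
    if points.shape[0] < 2:
        return 0.0
    unique = np.unique(points, axis=0)
    if unique.shape[0] < 2:
        return 0.0
    if unique.shape[0] > 10 and unique.shape[1] <= 3:
        try:
            unique = unique[ConvexHull(unique, qhull_options="QJ").vertices]
        except Exception:
            pass
    return float(pdist(unique).max())


def shape_features(mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> dict[str, float]:
    """The 14 IBSI 3D shape features of a nonempty binary mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    spacing = np.asarray(spacing, dtype=float)
    voxel_volume = float(np.prod(spacing))
    n_voxels = int(mask.sum())

    padded = np.pad(mask, 1).astype(float)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    surface_area = float(measure.mesh_surface_area(verts, faces))
    tri = verts[faces]
    mesh_volume = float(abs(np.einsum("ij,ij->i", tri[:, 0],
                                      np.cross(tri[:, 1], tri[:, 2])).sum()) / 6.0)

    coords = np.argwhere(mask) * spacing
    if coords.shape[0] > 3:
        cov = np.cov(coords, rowvar=False)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1].clip(min=0.0)
    else:
        eigvals = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(eigvals)).tolist()
    elongation = float(np.sqrt(eigvals[1] / eigvals[0])) if eigvals[0] > 0 else 0.0
    flatness = float(np.sqrt(eigvals[2] / eigvals[0])) if eigvals[0] > 0 else 0.0

    sphericity = (
        (36.0 * np.pi * mesh_volume**2) ** (1.0 / 3.0) / surface_area
        if surface_area > 0 and mesh_volume > 0
        else 0.0
    )
    return {
        "MeshVolume": mesh_volume,
        "VoxelVolume": voxel_volume * n_voxels,
        "SurfaceArea": surface_area,
        "SurfaceVolumeRatio": surface_area / mesh_volume if mesh_volume > 0 else 0.0,
        "Sphericity": float(sphericity),
        "Maximum3DDiameter": _max_diameter(verts),
        "Maximum2DDiameterSlice": _max_diameter(verts[:, :2]),
        "Maximum2DDiameterColumn": _max_diameter(verts[:, [0, 2]]),
        "Maximum2DDiameterRow": _max_diameter(verts[:, [1, 2]]),
        "MajorAxisLength": float(major),
        "MinorAxisLength": float(minor),
        "LeastAxisLength": float(least),
        "Elongation": elongation,
        "Flatness": flatness,
    }
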