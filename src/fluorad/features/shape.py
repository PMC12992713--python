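"""3D shape descriptors of a binary segment, 14 values.

Mesh quantities come from a marching-cubes isosurface of the binary mask
honoring the anisotropic voxel spacing: surface area from the triangle
mesh, mesh volume via the divergence theorem over signed tetrahedra.
Axis lengths derive from the inertia spectrum of the physical voxel-center
coordinates (axis length = 4·√λ); a single-voxel segment falls back to the
voxel's own physical extent for its principal axes.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

__all__ = ["SHAPE_NAMES", "shape_features"]

SHAPE_NAMES = (
    "MeshVolume",
    "VoxelVolume",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "Sphericity",
    "Maximum3DDiameter",
    "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "MajorAxisLength",
    "MinorAxisLength",
    "LeastAxisLength",
    "Elongation",
    "Flatness",
)


_REFINE = 4  # subvoxel refinement factor for the isosurface


def _mesh(mask: np.ndarray, spacing) -> tuple[float, float]:
    """(mesh volume, surface area) from a marching-cubes isosurface.

    The surface is the zero level set of the signed Euclidean distance
    field of the mask, refined 4× by tricubic interpolation before meshing.
    Marching cubes directly on the binary mask chamfers sharp voxel edges,
    biasing the area of box-like segments low by ~3%; the refined distance
    field keeps faces in place, tightens the chamfer, and leaves smooth
    boundaries essentially unchanged.  The distance transform uses the
    physical (anisotropic) spacing.
    """
    from scipy import ndimage

    padded = np.pad(mask.astype(float), 2)
    sdf = ndimage.distance_transform_edt(padded, sampling=spacing) - ndimage.distance_transform_edt(
        1.0 - padded, sampling=spacing
    )
    fine = ndimage.zoom(sdf, _REFINE, order=3, grid_mode=True, mode="nearest")
    fine_spacing = tuple(s / _REFINE for s in spacing)
    verts, faces, _, _ = measure.marching_cubes(fine, level=0.0, spacing=fine_spacing)
    area = float(measure.mesh_surface_area(verts, faces))
    tri = verts[faces]
    vol = float(np.abs(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0))
    return vol, area


def _max_diameter(points: np.ndarray) -> float:
    """Largest pairwise Euclidean distance; hull vertices prune the set."""
    if len(points) == 1:
        return 0.0
    pts = np.unique(points, axis=0)
    if len(pts) > 10 and pts.shape[1] == 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # coplanar/collinear point sets
            pass
    if len(pts) > 2000:  # cap quadratic cost; hull normally keeps this tiny
        pts = pts[:: len(pts) // 2000 + 1]
    return float(pdist(pts).max()) if len(pts) > 1 else 0.0


def shape_features(mask: np.ndarray, spacing) -> dict[str, float]:
    mask = np.asarray(mask, bool)
    nvox = int(mask.sum())
    if nvox == 0:
        raise ValueError("shape features need a nonempty segment")
    spacing = np.asarray(spacing, float)
    voxel_volume = float(np.prod(spacing))

    mesh_volume, surface_area = _mesh(mask, spacing)
    idx = np.argwhere(mask)
    coords = (idx + 0.5) * spacing  # physical voxel centers

    # surface voxels suffice for diameters
    surf = coords
    if nvox > 1:
        from scipy import ndimage

        eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3, 3)))
        boundary = mask & ~eroded
        surf = (np.argwhere(boundary) + 0.5) * spacing

    max3d = _max_diameter(surf)
    # in-plane (slice) = x/y plane; column = x/z; row = y/z
    max2d_slice = _max_diameter(surf[:, [0, 1]])
    max2d_col = _max_diameter(surf[:, [0, 2]])
    max2d_row = _max_diameter(surf[:, [1, 2]])

    if nvox == 1:
        lam = np.sort(spacing**2 / 16.0)[::-1]  # axis length = voxel extent
    else:
        cov = np.cov(coords, rowvar=False, bias=True)
        lam = np.sort(np.clip(np.linalg.eigvalsh(cov), 0, None))[::-1]
    major, minor, least = (4.0 * np.sqrt(lam)).tolist()

    sphericity = (36.0 * np.pi * mesh_volume**2) ** (1.0 / 3.0) / surface_area
    return {
        "MeshVolume": mesh_volume,
        "VoxelVolume": nvox * voxel_volume,
        "SurfaceArea": surface_area,
        "SurfaceVolumeRatio": surface_area / mesh_volume,
        "Sphericity": float(sphericity),
        "Maximum3DDiameter": max3d,
        "Maximum2DDiameterSlice": max2d_slice,
        "Maximum2DDiameterColumn": max2d_col,
        "Maximum2DDiameterRow": max2d_row,
        "MajorAxisLength": float(major),
        "MinorAxisLength": float(minor),
        "LeastAxisLength": float(least),
        "Elongation": float(np.sqrt(lam[1] / lam[0])) if lam[0] > 0 else 0.0,
        "Flatness": float(np.sqrt(lam[2] / lam[0])) if lam[0] > 0 else 0.0,
    }
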