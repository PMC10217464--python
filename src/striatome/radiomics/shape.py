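"""Morphological (shape) features of a 3D ROI.

Mesh quantities come from a marching-cubes triangulation of the binary
mask; axis lengths from principal-component analysis of the voxel point
cloud; bounding constructs (axis-aligned box, oriented box, enclosing
ellipsoid, convex hull) from the hull of the voxel centres.  The oriented
bounding box uses the PCA-aligned box and the enclosing ellipsoid the
Khachiyan minimum-volume ellipsoid, both standard approximations.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

SHAPE_FEATURES = [
    "volume_mesh", "volume_voxel", "surface_area", "surface_to_volume",
    "compactness_1", "compactness_2", "spherical_disproportion", "sphericity",
    "asphericity", "centre_of_mass_shift", "max_3d_diameter",
    "major_axis_length", "minor_axis_length", "least_axis_length",
    "elongation", "flatness",
    "volume_density_aabb", "area_density_aabb",
    "volume_density_ombb", "area_density_ombb",
    "volume_density_aee", "area_density_aee",
    "volume_density_mvee", "area_density_mvee",
    "volume_density_convex_hull", "area_density_convex_hull",
    "integrated_intensity", "morans_i", "gearys_c",
]


def _mesh(mask: np.ndarray, spacing) -> tuple[float, float]:
    """(volume, surface area) of the half-voxel isosurface mesh."""
    padded = np.pad(mask.astype(float), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    area = float(measure.mesh_surface_area(verts, faces))
    tri = verts[faces]
    vol = float(abs(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum()) / 6.0)
    return vol, area


def _mvee(points: np.ndarray, tol: float = 1e-3, max_iter: int = 500):
    """Khachiyan minimum-volume enclosing ellipsoid; returns semi-axes."""
    n, d = points.shape
    Q = np.vstack([points.T, np.ones(n)])
    u = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        X = Q @ np.diag(u) @ Q.T
        M = np.einsum("ij,ji->i", Q.T, np.linalg.solve(X, Q))
        j = int(np.argmax(M))
        step = (M[j] - d - 1.0) / ((d + 1) * (M[j] - 1.0))
        new_u = (1 - step) * u
        new_u[j] += step
        if np.linalg.norm(new_u - u) < tol:
            u = new_u
            break
        u = new_u
    c = points.T @ u
    A = np.linalg.inv(
        points.T @ np.diag(u) @ points - np.outer(c, c)
    ) / d
    eigval = np.linalg.eigvalsh(A)
    return 1.0 / np.sqrt(np.maximum(eigval, 1e-12))  # semi-axes, ascending radii? (descending eigval)


def _ellipsoid_area(a: float, b: float, c: float) -> float:
    """Thomsen approximation of the ellipsoid surface area (error < 1.1%)."""
    p = 1.6075
    return float(4 * np.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3) ** (1 / p))


def _spatial_autocorrelation(coords: np.ndarray, vals: np.ndarray, cap: int = 1500):
    """Moran's I and Geary's C with inverse-distance weights.

    Pairwise; ROIs above ``cap`` voxels are deterministically thinned by
    striding to keep the quadratic cost bounded.
    """
    n = len(vals)
    if n > cap:
        step = int(np.ceil(n / cap))
        coords, vals = coords[::step], vals[::step]
        n = len(vals)
    if n < 2 or np.ptp(vals) == 0:
        return float("nan"), float("nan")
    d = pdist(coords)
    w = 1.0 / np.maximum(d, 1e-12)
    mu = vals.mean()
    dev = vals - mu
    ii, jj = np.triu_indices(n, k=1)
    s2 = float((dev**2).sum())
    wsum = float(w.sum())
    cross = float((w * dev[ii] * dev[jj]).sum())
    sqdiff = float((w * (vals[ii] - vals[jj]) ** 2).sum())
    morans = (n / (2 * wsum)) * (2 * cross) / s2
    gearys = ((n - 1) / (2 * (2 * wsum))) * (2 * sqdiff) / s2
    return morans, gearys


def shape_features(data: np.ndarray, mask: np.ndarray, spacing) -> dict[str, float]:
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("shape_features requires a non-empty mask")
    spacing = tuple(float(s) for s in spacing)
    nvox = int(mask.sum())
    voxvol = float(np.prod(spacing))
    v_voxel = nvox * voxvol

    coords = np.argwhere(mask) * np.asarray(spacing)
    vals = np.asarray(data, float)[mask]

    if nvox >= 2:
        v_mesh, area = _mesh(mask, spacing)
    else:  # single voxel: use the voxel box itself
        v_mesh, area = v_voxel, 2 * (
            spacing[0] * spacing[1] + spacing[0] * spacing[2] + spacing[1] * spacing[2]
        )

    f: dict[str, float] = {}
    f["volume_mesh"] = v_mesh
    f["volume_voxel"] = v_voxel
    f["surface_area"] = area
    f["surface_to_volume"] = area / v_mesh
    f["compactness_1"] = v_mesh / (np.sqrt(np.pi) * area**1.5)
    f["compactness_2"] = 36 * np.pi * v_mesh**2 / area**3
    f["spherical_disproportion"] = area / (36 * np.pi * v_mesh**2) ** (1 / 3)
    f["sphericity"] = (36 * np.pi * v_mesh**2) ** (1 / 3) / area
    f["asphericity"] = (area**3 / (36 * np.pi * v_mesh**2)) ** (1 / 3) - 1

    com_geom = coords.mean(axis=0)
    wsum = vals.sum()
    com_int = (coords * vals[:, None]).sum(axis=0) / wsum if wsum != 0 else com_geom
    f["centre_of_mass_shift"] = float(np.linalg.norm(com_int - com_geom))

    # hull of the voxel centres (degenerate point clouds fall back to extents)
    try:
        hull = ConvexHull(coords)
        hull_pts = coords[hull.vertices]
        v_hull, a_hull = float(hull.volume), float(hull.area)
    except Exception:
        hull_pts = coords
        v_hull, a_hull = v_voxel, area
    dmax = float(pdist(hull_pts).max()) if len(hull_pts) > 1 else float(max(spacing))
    f["max_3d_diameter"] = dmax

    centred = coords - com_geom
    cov = np.cov(centred.T) if nvox > 1 else np.zeros((3, 3))
    eig = np.sort(np.maximum(np.linalg.eigvalsh(np.atleast_2d(cov)), 0.0))[::-1]
    axis_len = 4.0 * np.sqrt(eig)  # full axis lengths, descending
    f["major_axis_length"], f["minor_axis_length"], f["least_axis_length"] = axis_len
    f["elongation"] = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else float("nan")
    f["flatness"] = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else float("nan")

    # axis-aligned bounding box (of voxel extents, +1 voxel per axis)
    spans = coords.max(axis=0) - coords.min(axis=0) + np.asarray(spacing)
    v_aabb = float(np.prod(spans))
    a_aabb = float(2 * (spans[0] * spans[1] + spans[0] * spans[2] + spans[1] * spans[2]))
    f["volume_density_aabb"] = v_mesh / v_aabb
    f["area_density_aabb"] = area / a_aabb

    # oriented (PCA-aligned) bounding box
    if eig[0] > 0:
        vecs = np.linalg.eigh(np.atleast_2d(cov))[1][:, ::-1]
        proj = centred @ vecs
        ospans = proj.max(axis=0) - proj.min(axis=0) + float(np.mean(spacing))
    else:
        ospans = spans
    v_ombb = float(np.prod(ospans))
    a_ombb = float(2 * (ospans[0] * ospans[1] + ospans[0] * ospans[2] + ospans[1] * ospans[2]))
    f["volume_density_ombb"] = v_mesh / v_ombb
    f["area_density_ombb"] = area / a_ombb

    # approximate enclosing ellipsoid from PCA semi-axes
    semi = np.maximum(axis_len / 2.0, np.min(spacing) / 2.0)
    v_aee = float(4 * np.pi / 3 * np.prod(semi))
    a_aee = _ellipsoid_area(*semi)
    f["volume_density_aee"] = v_mesh / v_aee
    f["area_density_aee"] = area / a_aee

    # minimum-volume enclosing ellipsoid of the hull points
    try:
        semi_mvee = np.sort(_mvee(hull_pts))[::-1]
        semi_mvee = np.maximum(semi_mvee, np.min(spacing) / 4.0)
        v_mvee = float(4 * np.pi / 3 * np.prod(semi_mvee))
        a_mvee = _ellipsoid_area(*semi_mvee)
    except Exception:
        v_mvee, a_mvee = v_aee, a_aee
    f["volume_density_mvee"] = v_mesh / v_mvee
    f["area_density_mvee"] = area / a_mvee

    f["volume_density_convex_hull"] = v_mesh / v_hull if v_hull > 0 else float("nan")
    f["area_density_convex_hull"] = area / a_hull if a_hull > 0 else float("nan")

    f["integrated_intensity"] = float(vals.mean()) * v_mesh
    f["morans_i"], f["gearys_c"] = _spatial_autocorrelation(coords, vals)
    return {k: float(v) for k, v in f.items()}
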