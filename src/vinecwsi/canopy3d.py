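"""Point-cloud branch of the canopy extraction.

Progressive-TIN ground classification (per-cell lowest points seed a Delaunay
terrain that is densified under distance/angle thresholds), statistical-outlier
noise filtering, rule-based understory removal, bottom trimming for reference
clouds and per-cell top segmentation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import Delaunay, cKDTree

from vinecwsi.errors import ContractError, DegenerateGeometryError
from vinecwsi.geodata import AttributedPointCloud

__all__ = [
    "GroundClassifierParams",
    "NoiseFilterParams",
    "TerrainSurface",
    "classify_ground",
    "filter_noise",
    "remove_understory",
    "trim_bottom",
    "segment_top",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroundClassifierParams:
    """Progressive-TIN densification thresholds.

    Defaults (1 m cells, 15 deg, 0.15 m, 3 iterations) suit ~3 m row spacing;
    all are exposed on the CLI.
    """

    cell_size: float = 1.0
    max_angle: float = 15.0
    max_distance: float = 0.15
    n_iterations: int = 3

    def __post_init__(self):
        if self.cell_size <= 0 or self.max_distance <= 0 or self.n_iterations <= 0:
            raise ContractError("classifier parameters must be positive")
        if not 0 < self.max_angle < 90:
            raise ContractError("max_angle must be in (0, 90) degrees")


@dataclass(frozen=True)
class NoiseFilterParams:
    """Statistical outlier removal: k nearest neighbors, sigma multiplier."""

    k_neighbors: int = 8
    sigma_multiplier: float = 2.0

    def __post_init__(self):
        if self.k_neighbors < 1:
            raise ContractError("k_neighbors must be >= 1")
        if self.sigma_multiplier <= 0:
            raise ContractError("sigma_multiplier must be positive")


class TerrainSurface:
    """Linear interpolation of terrain height on the final ground TIN.

    Undefined (NaN) outside the convex hull of the ground points.
    """

    def __init__(self, ground_xyz: np.ndarray):
        ground_xyz = np.asarray(ground_xyz, dtype=float)
        if len(ground_xyz) < 3:
            raise DegenerateGeometryError("terrain surface needs >= 3 ground points",
                                          n_points=len(ground_xyz))
        try:
            self._interp = LinearNDInterpolator(ground_xyz[:, :2], ground_xyz[:, 2])
            # force triangulation now so degenerate input fails loudly here
            self._interp(ground_xyz[0, 0], ground_xyz[0, 1])
        except Exception as exc:  # qhull raises its own error types
            raise DegenerateGeometryError(f"cannot triangulate ground points: {exc}",
                                          n_points=len(ground_xyz)) from exc

    @classmethod
    def from_ground(cls, cloud: AttributedPointCloud) -> "TerrainSurface":
        if cloud.class_label is None:
            raise ContractError("cloud has no class labels; run classify_ground first")
        ground = cloud.coords[cloud.class_label == "ground"]
        return cls(ground)

    def elevation(self, x, y) -> np.ndarray:
        return self._interp(np.asarray(x, dtype=float), np.asarray(y, dtype=float))

    def height_above(self, coords: np.ndarray) -> np.ndarray:
        """Height of each point above the interpolated terrain; NaN outside hull."""
        coords = np.asarray(coords, dtype=float)
        return coords[:, 2] - self.elevation(coords[:, 0], coords[:, 1])


def _lowest_per_cell(coords: np.ndarray, cell_size: float) -> np.ndarray:
    """Indices of the lowest point in each occupied planimetric cell."""
    ij = np.floor(coords[:, :2] / cell_size).astype(np.int64)
    # lexicographic cell key; stable argsort keeps deterministic ties
    order = np.lexsort((coords[:, 2], ij[:, 1], ij[:, 0]))
    ij_sorted = ij[order]
    first = np.ones(len(order), dtype=bool)
    first[1:] = np.any(ij_sorted[1:] != ij_sorted[:-1], axis=1)
    return order[first]


def classify_ground(cloud: AttributedPointCloud,
                    params: GroundClassifierParams = GroundClassifierParams()
                    ) -> AttributedPointCloud:
    """Label every point ground or canopy by progressive TIN densification.

    The lowest point of each ``cell_size`` cell seeds an initial terrain
    triangulation; a point joins the ground set when its vertical distance to
    the containing triangle is at most ``max_distance`` and the largest angle
    it subtends to the triangle's vertices is at most ``max_angle``.  The
    triangulation is rebuilt ``n_iterations`` times; whatever remains is
    canopy.  The output cloud keeps point order and all attributes.
    """
    n = len(cloud)
    if n < 3:
        raise DegenerateGeometryError(f"cannot triangulate {n} points", n_points=n)
    coords = cloud.coords
    xy = coords[:, :2] - coords[:, :2].mean(axis=0)
    if np.linalg.matrix_rank(xy, tol=1e-9) < 2:
        raise DegenerateGeometryError("all points collinear in plan view", n_points=n)
    is_ground = np.zeros(n, dtype=bool)
    is_ground[_lowest_per_cell(coords, params.cell_size)] = True
    tan_max = np.tan(np.radians(params.max_angle))
    # virtual corner vertices (z of the nearest seed) make the TIN cover the
    # full extent, so boundary points are not left outside the hull
    pad = params.cell_size
    lo = coords[:, :2].min(axis=0) - pad
    hi = coords[:, :2].max(axis=0) + pad
    corners_xy = np.array([[lo[0], lo[1]], [hi[0], lo[1]], [hi[0], hi[1]], [lo[0], hi[1]]])
    for _ in range(params.n_iterations):
        real_xy = coords[is_ground][:, :2]
        real_z = coords[is_ground][:, 2]
        nearest = cKDTree(real_xy).query(corners_xy)[1]
        ground_xy = np.vstack([real_xy, corners_xy])
        ground_z = np.concatenate([real_z, real_z[nearest]])
        try:
            tri = Delaunay(ground_xy)
        except Exception as exc:
            raise DegenerateGeometryError(f"degenerate seed geometry: {exc}",
                                          n_points=int(is_ground.sum())) from exc
        cand = np.flatnonzero(~is_ground)
        if len(cand) == 0:
            break
        simplex = tri.find_simplex(coords[cand][:, :2])
        inside = simplex >= 0
        cand = cand[inside]
        simplex = simplex[inside]
        if len(cand) == 0:
            continue
        # barycentric interpolation of the triangle plane at each candidate xy
        trans = tri.transform[simplex]
        delta = coords[cand][:, :2] - trans[:, 2]
        bary2 = np.einsum("ijk,ik->ij", trans[:, :2], delta)
        bary = np.column_stack([bary2, 1.0 - bary2.sum(axis=1)])
        z_plane = np.einsum("ij,ij->i", bary, ground_z[tri.simplices[simplex]])
        d = np.abs(coords[cand][:, 2] - z_plane)
        verts_xy = ground_xy[tri.simplices[simplex]]           # (m, 3, 2)
        dxy = np.linalg.norm(verts_xy - coords[cand][:, None, :2], axis=2)
        max_tan = (d[:, None] / np.maximum(dxy, 1e-12)).max(axis=1)
        accept = (d <= params.max_distance) & (max_tan <= tan_max)
        if not accept.any():
            break
        is_ground[cand[accept]] = True
    labels = np.where(is_ground, "ground", "canopy").astype("U10")
    return cloud.with_class(labels)


def filter_noise(cloud: AttributedPointCloud,
                 params: NoiseFilterParams = NoiseFilterParams(),
                 return_removed: bool = False):
    """Statistical outlier removal.

    A point is noise when its mean distance to its ``k_neighbors`` nearest
    neighbors exceeds the global mean of that quantity by more than
    ``sigma_multiplier`` standard deviations.  Retained points keep their
    order; with ``return_removed=True`` the removed points come back as a
    second cloud labeled ``noise``.
    """
    n = len(cloud)
    if n <= params.k_neighbors:
        raise ContractError(f"need more than k_neighbors={params.k_neighbors} points, got {n}")
    tree = cKDTree(cloud.coords)
    dists, _ = tree.query(cloud.coords, k=params.k_neighbors + 1)
    mean_dist = dists[:, 1:].mean(axis=1)  # drop self-distance column
    cutoff = mean_dist.mean() + params.sigma_multiplier * mean_dist.std(ddof=1)
    keep = mean_dist <= cutoff
    retained = cloud.subset(keep)
    if return_removed:
        removed = cloud.subset(~keep)
        removed = removed.with_class(np.full(len(removed), "noise", dtype="U10"))
        return retained, removed
    return retained


def remove_understory(canopy: AttributedPointCloud, ground_surface: TerrainSurface,
                      min_height: float = 0.5) -> AttributedPointCloud:
    """Drop points closer than ``min_height`` to the terrain (soil returns, trunks).

    Mirrors the 0.5 m raster threshold on the 3D side.  Points outside the
    terrain hull have undefined height and are dropped; the count is logged.
    """
    if min_height < 0:
        raise ContractError("min_height must be non-negative")
    h = ground_surface.height_above(canopy.coords)
    outside = np.isnan(h)
    if outside.any():
        log.info("remove_understory: dropped %d points outside terrain hull", int(outside.sum()))
    keep = ~outside & (h >= min_height)
    return canopy.subset(keep)


def trim_bottom(cloud: AttributedPointCloud, ground_surface: TerrainSurface,
                trim_m: float = 0.20) -> AttributedPointCloud:
    """Remove the bottom ``trim_m`` of the canopy relative to its lowest point.

    Points with height-above-terrain below ``min(height) + trim_m`` are
    dropped; used to align reference (LiDAR-like) clouds whose canopy extends
    lower than the photogrammetric ones.
    """
    if trim_m < 0:
        raise ContractError("trim must be non-negative")
    if len(cloud) == 0 or trim_m == 0:
        return cloud.subset(slice(None))
    h = ground_surface.height_above(cloud.coords)
    finite = np.isfinite(h)
    if not finite.any():
        warnings.warn("trim_bottom: no points have defined height; returning empty cloud")
        return cloud.subset(np.zeros(len(cloud), dtype=bool))
    cut = float(np.nanmin(h)) + trim_m
    keep = finite & (h >= cut)
    if not keep.any():
        warnings.warn("trim_bottom: trim exceeds canopy depth; result is empty")
    return cloud.subset(keep)


def segment_top(cloud: AttributedPointCloud, cell_size: float = 0.25,
                depth_m: float = 0.20) -> AttributedPointCloud:
    """Keep, per planimetric cell, only points within ``depth_m`` of the cell's top.

    Approximates the part of the canopy a nadir orthomosaic sees.
    """
    if cell_size <= 0 or depth_m <= 0:
        raise ContractError("cell_size and depth_m must be positive")
    n = len(cloud)
    if n == 0:
        return cloud.subset(slice(None))
    ij = np.floor(cloud.coords[:, :2] / cell_size).astype(np.int64)
    _, cell_id = np.unique(ij, axis=0, return_inverse=True)
    top = np.full(cell_id.max() + 1, -np.inf)
    np.maximum.at(top, cell_id, cloud.z)
    keep = cloud.z >= top[cell_id] - depth_m
    return cloud.subset(keep)
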