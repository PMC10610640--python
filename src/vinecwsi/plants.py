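"""Per-plant extraction: an equal-cell grid over the ROI, raster/cloud clipping,
per-plant mean CWSI and convex-hull canopy volumes.

The grid splits the ROI's minimum rotated rectangle (aligned to the row
azimuth) into ``n_along x n_across`` equal cells.  Membership is decided in
the rotated frame with a half-open rule, so every sample belongs to exactly
one cell and per-cell counts conserve the total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from vinecwsi.errors import ContractError, DegenerateGeometryError
from vinecwsi.geodata import AttributedPointCloud, RasterGrid, RoiPolygon, require_same_crs

__all__ = [
    "PlantGrid",
    "GridCell",
    "PlantRecord",
    "build_plant_grid",
    "clip_to_cell",
    "per_plant_cwsi",
    "per_plant_volumes",
    "convex_hull_volume",
]


@dataclass(frozen=True)
class GridCell:
    """One rotated-rectangle cell of a :class:`PlantGrid`."""

    cell_id: int
    vertices: np.ndarray  # 4 x 2, projected coordinates

    def to_shapely(self):
        from shapely.geometry import Polygon

        return Polygon(self.vertices)


@dataclass(frozen=True)
class PlantRecord:
    """Per-plant aggregate from one dataset (orthomosaic or cloud, one flight)."""

    plant_id: int
    n_samples: int
    mean_cwsi: float | None = None
    hull_volume: float | None = None
    source: str = ""

    def __post_init__(self):
        if self.n_samples < 0:
            raise ContractError("n_samples must be >= 0")
        if self.hull_volume is not None and self.hull_volume < 0:
            raise ContractError("hull_volume must be >= 0")


class PlantGrid:
    """Equal-cell partition of the ROI rectangle, aligned to the row azimuth.

    Cells are ordered along rows first, then across (along-row index fastest).
    """

    def __init__(self, origin: np.ndarray, e_along: np.ndarray, e_across: np.ndarray,
                 du: float, dv: float, n_along: int, n_across: int,
                 row_azimuth: float, crs_label: str = ""):
        self.origin = np.asarray(origin, dtype=float)
        self.e_along = np.asarray(e_along, dtype=float)
        self.e_across = np.asarray(e_across, dtype=float)
        self.du = float(du)
        self.dv = float(dv)
        self.n_along = int(n_along)
        self.n_across = int(n_across)
        self.row_azimuth = float(row_azimuth)
        self.crs_label = crs_label

    def __len__(self) -> int:
        return self.n_along * self.n_across

    @property
    def cell_dims(self) -> tuple[float, float]:
        return self.du, self.dv

    @property
    def cell_area(self) -> float:
        return self.du * self.dv

    def to_uv(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        dx = np.asarray(x, dtype=float) - self.origin[0]
        dy = np.asarray(y, dtype=float) - self.origin[1]
        u = dx * self.e_along[0] + dy * self.e_along[1]
        v = dx * self.e_across[0] + dy * self.e_across[1]
        return u, v

    def assign(self, x, y) -> np.ndarray:
        """Cell id per point; -1 when outside the gridded rectangle.

        Half-open rule: a point on a shared edge belongs to the cell with the
        larger index, and the rectangle's far edges are excluded.
        """
        u, v = self.to_uv(x, y)
        iu = np.floor(u / self.du).astype(int)
        iv = np.floor(v / self.dv).astype(int)
        ids = iv * self.n_along + iu
        inside = (iu >= 0) & (iu < self.n_along) & (iv >= 0) & (iv < self.n_across)
        return np.where(inside, ids, -1)

    def cell(self, cell_id: int) -> GridCell:
        if not 0 <= cell_id < len(self):
            raise ContractError(f"cell_id {cell_id} outside grid of {len(self)} cells")
        iv, iu = divmod(cell_id, self.n_along)
        corners_uv = [
            (iu * self.du, iv * self.dv),
            ((iu + 1) * self.du, iv * self.dv),
            ((iu + 1) * self.du, (iv + 1) * self.dv),
            (iu * self.du, (iv + 1) * self.dv),
        ]
        verts = np.array([self.origin + u * self.e_along + v * self.e_across
                          for u, v in corners_uv])
        return GridCell(cell_id=cell_id, vertices=verts)

    def cells(self) -> list[GridCell]:
        return [self.cell(i) for i in range(len(self))]

    def to_wkt(self) -> str:
        """All cells as a WKT polygon list, one per line, prefixed by id."""
        lines = [f"{c.cell_id}\t{c.to_shapely().wkt}" for c in self.cells()]
        return "\n".join(lines) + "\n"


def build_plant_grid(roi: RoiPolygon, n_along: int, n_across: int,
                     row_azimuth: float) -> PlantGrid:
    """Split the ROI's azimuth-aligned minimum rotated rectangle into equal cells."""
    if n_along < 1 or n_across < 1:
        raise ContractError("grid dimensions must be >= 1")
    az = np.radians(row_azimuth)
    e_along = np.array([np.sin(az), np.cos(az)])
    e_across = np.array([np.cos(az), -np.sin(az)])
    verts = roi.vertices
    u = verts @ e_along
    v = verts @ e_across
    u0, u1 = float(u.min()), float(u.max())
    v0, v1 = float(v.min()), float(v.max())
    if u1 <= u0 or v1 <= v0:
        raise ContractError("degenerate ROI: zero extent along or across rows")
    origin = u0 * e_along + v0 * e_across
    return PlantGrid(origin=origin, e_along=e_along, e_across=e_across,
                     du=(u1 - u0) / n_along, dv=(v1 - v0) / n_across,
                     n_along=n_along, n_across=n_across,
                     row_azimuth=row_azimuth, crs_label=roi.crs_label)


def clip_to_cell(data, grid: PlantGrid, cell_id: int):
    """Subset a raster or cloud to one grid cell.

    Raster cells are assigned by their center point; cloud points by the grid's
    half-open rule.  A cell outside the data extent yields an empty subset.
    """
    if isinstance(data, RasterGrid):
        require_same_crs(data.crs_label, grid.crs_label)
        cx, cy = data.cell_centers()
        member = grid.assign(cx.ravel(), cy.ravel()).reshape(data.shape) == cell_id
        out = np.where(member, data.values, np.nan)
        return data.with_values(out, nodata=float("nan"))
    if isinstance(data, AttributedPointCloud):
        require_same_crs(data.crs_label, grid.crs_label)
        ids = grid.assign(data.x, data.y)
        return data.subset(ids == cell_id)
    raise ContractError(f"unsupported data type {type(data).__name__}")


def _records_from_samples(grid: PlantGrid, ids: np.ndarray, values: np.ndarray,
                          source: str) -> list[PlantRecord]:
    records = []
    for cell_id in range(len(grid)):
        sel = ids == cell_id
        n = int(sel.sum())
        mean = float(values[sel].mean()) if n else None
        records.append(PlantRecord(plant_id=cell_id, n_samples=n, mean_cwsi=mean, source=source))
    return records


def per_plant_cwsi(grid: PlantGrid, data, scalar_name: str = "cwsi",
                   source: str = "") -> list[PlantRecord]:
    """Arithmetic mean of CWSI samples per grid cell.

    ``data`` is either a CWSI raster (valid cells only) or a cloud carrying a
    ``cwsi`` scalar.  Empty cells come back with ``n_samples=0`` and a missing
    mean, to be dropped by downstream regressions.
    """
    if isinstance(data, RasterGrid):
        require_same_crs(data.crs_label, grid.crs_label)
        valid = data.valid_mask
        cx, cy = data.cell_centers()
        ids = grid.assign(cx[valid], cy[valid])
        return _records_from_samples(grid, ids, data.values[valid], source)
    if isinstance(data, AttributedPointCloud):
        require_same_crs(data.crs_label, grid.crs_label)
        if scalar_name not in data.scalars:
            raise ContractError(f"cloud has no {scalar_name!r} scalar; compute the index first")
        ids = grid.assign(data.x, data.y)
        return _records_from_samples(grid, ids, data.scalars[scalar_name], source)
    raise ContractError(f"unsupported data type {type(data).__name__}")


def convex_hull_volume(points: np.ndarray) -> float:
    """Volume of the 3D convex hull of a point set.

    Raises :class:`DegenerateGeometryError` for fewer than 4 points or
    (near-)coplanar input.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ContractError("points must be N x 3")
    n = len(pts)
    if n < 4:
        raise DegenerateGeometryError(f"convex hull volume needs >= 4 points, got {n}",
                                      n_points=n)
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate (coplanar?) point set of {n} points: {exc}",
                                      n_points=n) from exc
    return float(hull.volume)


def per_plant_volumes(grid: PlantGrid, cloud: AttributedPointCloud,
                      source: str = "") -> list[PlantRecord]:
    """Convex-hull volume of the canopy points inside each grid cell.

    Cells whose point set is too degenerate for a 3D hull get no volume
    (``hull_volume=None``) and are excluded from downstream regressions.
    """
    require_same_crs(cloud.crs_label, grid.crs_label)
    ids = grid.assign(cloud.x, cloud.y)
    records = []
    for cell_id in range(len(grid)):
        pts = cloud.coords[ids == cell_id]
        try:
            vol = convex_hull_volume(pts)
        except DegenerateGeometryError:
            vol = None
        records.append(PlantRecord(plant_id=cell_id, n_samples=len(pts),
                                   hull_volume=vol, source=source))
    return records
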