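"""Synthetic vineyard scenes with closed-form ground truth.

Plants are half-ellipsoid canopies (truncated at ``canopy_base`` above the
terrain) on a regular row grid rotated to ``row_azimuth``, over a gently
inclined terrain plane.  Soil is warmer than canopy by default, and the canopy
carries a vertical temperature gradient (warmer toward the base), so the
qualitative pattern of lower stress values at the canopy top is reproduced by
construction.  Scene generation is a pure function of the configuration,
including the seed: all randomness comes from one generator in a documented
order (missing-plant draws, then per-plant surface points and temperature
noise in plant-id order, then ground points, soil temperatures and raster
noise).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from vinecwsi.errors import ContractError
from vinecwsi.geodata import (
    AttributedPointCloud,
    GridTransform,
    RasterGrid,
    RoiPolygon,
    write_cloud,
    write_raster,
)

__all__ = [
    "SceneConfig",
    "PlantTruth",
    "VineyardScene",
    "generate_scene",
    "scene_to_disk",
    "half_ellipsoid_volume",
    "ellipsoid_segment_volume",
    "half_ellipsoid_surface_area",
    "sample_half_ellipsoid_surface",
]

SYNTH_CRS = "LOCAL/metric (synthetic)"


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic vineyard scene.

    Spacings default to the VSP layout of 2.5 m between plants and 3 m between
    rows with a NE-SW (45 degree) row azimuth.  ``canopy_height`` is the
    vertical extent of the half-ellipsoid canopy above ``canopy_base``;
    ``vertical_temp_gradient`` is degrees C per metre of depth below the canopy
    top (positive = warmer toward the base).
    """

    n_rows: int = 3
    plants_per_row: int = 5
    row_spacing: float = 3.0
    plant_spacing: float = 2.5
    row_azimuth: float = 45.0
    canopy_height: float = 1.8
    canopy_base: float = 0.5
    canopy_radii: tuple[float, float] = (1.1, 0.5)
    soil_temp_mean: float = 45.0
    soil_temp_sd: float = 1.5
    canopy_top_temp_mean: float = 32.0
    vertical_temp_gradient: float = 2.0
    temp_noise_sd: float = 0.3
    missing_plant_prob: float = 0.0
    point_density: float = 250.0
    ground_point_density: float = 30.0
    cell_size: float = 0.25
    terrain_slope: tuple[float, float] = (0.02, 0.01)
    terrain_z0: float = 100.0
    margin: float = 2.0
    temperature_unit: str = "celsius"
    seed: int = 0

    def __post_init__(self):
        positive = {
            "n_rows": self.n_rows, "plants_per_row": self.plants_per_row,
            "row_spacing": self.row_spacing, "plant_spacing": self.plant_spacing,
            "canopy_height": self.canopy_height,
            "point_density": self.point_density,
            "ground_point_density": self.ground_point_density,
            "cell_size": self.cell_size,
        }
        for name, val in positive.items():
            if val <= 0:
                raise ContractError(f"{name} must be positive, got {val}")
        if min(self.canopy_radii) <= 0:
            raise ContractError("canopy radii must be positive")
        if not 0 <= self.missing_plant_prob <= 1:
            raise ContractError("missing_plant_prob must be in [0, 1]")
        if self.canopy_base < 0:
            raise ContractError("canopy_base must be non-negative")
        if self.temp_noise_sd < 0 or self.soil_temp_sd < 0:
            raise ContractError("noise standard deviations must be non-negative")
        if self.temperature_unit not in ("celsius", "kelvin"):
            raise ContractError("temperature_unit must be 'celsius' or 'kelvin'")

    @property
    def canopy_top(self) -> float:
        return self.canopy_base + self.canopy_height

    @property
    def n_plants(self) -> int:
        return self.n_rows * self.plants_per_row

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class PlantTruth:
    plant_id: int
    center_x: float
    center_y: float
    present: bool
    true_volume: float


@dataclass
class VineyardScene:
    """Synthetic bundle: rasters, truth-labeled cloud, ROI and per-plant truth."""

    config: SceneConfig
    dsm: RasterGrid
    dtm: RasterGrid
    thermal: RasterGrid
    cloud: AttributedPointCloud
    roi: RoiPolygon
    plant_truth: list[PlantTruth] = field(default_factory=list)


# --- closed-form canopy geometry -------------------------------------------


def half_ellipsoid_volume(a: float, b: float, c: float) -> float:
    """Volume of an upper half-ellipsoid with semi-axes a, b (planimetric) and c (vertical)."""
    return 2.0 / 3.0 * np.pi * a * b * c


def ellipsoid_segment_volume(a: float, b: float, c: float, z_cut: float) -> float:
    """Volume of the part of a full ellipsoid above the plane z = z_cut (center at 0).

    ``z_cut`` in [-c, c]; ``z_cut = 0`` gives the half-ellipsoid.
    """
    if not -c <= z_cut <= c:
        raise ContractError(f"z_cut must lie within [-c, c], got {z_cut}")
    t = z_cut / c
    return np.pi * a * b * c * (2.0 / 3.0 - t + t**3 / 3.0)


def half_ellipsoid_surface_area(a: float, b: float, c: float) -> float:
    """Approximate curved-surface area of the upper half-ellipsoid (Thomsen formula)."""
    p = 1.6075
    full = 4.0 * np.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0) ** (1.0 / p)
    return full / 2.0


def sample_half_ellipsoid_surface(rng: np.random.Generator, a: float, b: float,
                                  c: float, n: int) -> np.ndarray:
    """Uniform sample of n points on the curved upper surface of a half-ellipsoid.

    Rejection sampling: directions uniform on the upper unit hemisphere,
    accepted with probability proportional to the local area-scaling factor of
    the sphere-to-ellipsoid map.
    """
    g_max = max(a * b, a * c, b * c)
    out = np.zeros((0, 3))
    while len(out) < n:
        m = max(2 * (n - len(out)), 128)
        u = rng.normal(size=(m, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        u[:, 2] = np.abs(u[:, 2])
        g = np.sqrt((b * c * u[:, 0]) ** 2 + (a * c * u[:, 1]) ** 2 + (a * b * u[:, 2]) ** 2)
        accept = rng.uniform(size=m) * g_max <= g
        pts = u[accept] * (a, b, c)
        out = np.vstack([out, pts])
    return out[:n]


# --- scene assembly ---------------------------------------------------------


def _row_frame(azimuth_deg: float):
    """Unit vectors (east, north) along and across the rows."""
    az = np.radians(azimuth_deg)
    e_along = np.array([np.sin(az), np.cos(az)])
    e_across = np.array([np.cos(az), -np.sin(az)])
    return e_along, e_across


def _terrain(cfg: SceneConfig, x, y):
    sx, sy = cfg.terrain_slope
    return cfg.terrain_z0 + sx * np.asarray(x) + sy * np.asarray(y)


def generate_scene(config: SceneConfig) -> VineyardScene:
    """Build a full synthetic scene (rasters + truth-labeled cloud + ROI + truth table)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    a, b = cfg.canopy_radii
    c = cfg.canopy_height
    e_along, e_across = _row_frame(cfg.row_azimuth)

    # plant centers in the row frame; id ordering: along-row index fastest
    along = np.arange(cfg.plants_per_row) * cfg.plant_spacing
    across = np.arange(cfg.n_rows) * cfg.row_spacing
    uu, vv = np.meshgrid(along, across)          # shape (n_rows, plants_per_row)
    u_flat, v_flat = uu.ravel(), vv.ravel()
    centers = np.outer(u_flat, e_along) + np.outer(v_flat, e_across)

    # ROI rectangle of equal plant cells in the row frame
    u_lo, u_hi = -cfg.plant_spacing / 2, (cfg.plants_per_row - 0.5) * cfg.plant_spacing
    v_lo, v_hi = -cfg.row_spacing / 2, (cfg.n_rows - 0.5) * cfg.row_spacing
    corners_uv = [(u_lo, v_lo), (u_hi, v_lo), (u_hi, v_hi), (u_lo, v_hi)]
    roi_xy = np.array([u * e_along + v * e_across for u, v in corners_uv])

    # translate everything into the positive quadrant with a margin
    pad = max(a, b) + cfg.margin
    all_xy = np.vstack([centers, roi_xy])
    shift = pad - all_xy.min(axis=0)
    centers = centers + shift
    roi_xy = roi_xy + shift
    extent = all_xy.max(axis=0) + shift + pad

    # (1) missing plants
    missing = rng.uniform(size=cfg.n_plants) < cfg.missing_plant_prob
    truth = []
    for pid in range(cfg.n_plants):
        truth.append(PlantTruth(
            plant_id=pid, center_x=float(centers[pid, 0]), center_y=float(centers[pid, 1]),
            present=not missing[pid],
            true_volume=0.0 if missing[pid] else float(half_ellipsoid_volume(a, b, c)),
        ))

    # (2) canopy surface points + temperature noise, in plant-id order
    area = half_ellipsoid_surface_area(a, b, c)
    n_per_plant = int(round(cfg.point_density * area))
    coords_parts, temp_parts, label_parts = [], [], []
    rot = np.column_stack([e_along, e_across])   # local (u, v) -> (x, y)
    for pid in range(cfg.n_plants):
        if missing[pid]:
            continue
        local = sample_half_ellipsoid_surface(rng, a, b, c, n_per_plant)
        xy = centers[pid] + local[:, :2] @ rot.T
        base_z = _terrain(cfg, centers[pid, 0], centers[pid, 1]) + cfg.canopy_base
        z = base_z + local[:, 2]
        depth = (base_z + c) - z
        temp = cfg.canopy_top_temp_mean + cfg.vertical_temp_gradient * depth
        temp = temp + rng.normal(0.0, cfg.temp_noise_sd, size=len(z)) if cfg.temp_noise_sd > 0 else temp
        coords_parts.append(np.column_stack([xy, z]))
        temp_parts.append(temp)
        label_parts.append(np.full(len(z), "canopy", dtype="U10"))

    # (3) ground points, (4) soil temperatures, (5) ground sensor noise
    n_ground = int(round(cfg.ground_point_density * extent[0] * extent[1]))
    gxy = rng.uniform((0.0, 0.0), extent, size=(n_ground, 2))
    gz = _terrain(cfg, gxy[:, 0], gxy[:, 1])
    gtemp = cfg.soil_temp_mean + (rng.normal(0.0, cfg.soil_temp_sd, n_ground)
                                  if cfg.soil_temp_sd > 0 else 0.0)
    if cfg.temp_noise_sd > 0:
        gtemp = gtemp + rng.normal(0.0, cfg.temp_noise_sd, n_ground)
    coords_parts.append(np.column_stack([gxy, gz]))
    temp_parts.append(np.broadcast_to(gtemp, (n_ground,)).astype(float))
    label_parts.append(np.full(n_ground, "ground", dtype="U10"))

    coords = np.vstack(coords_parts)
    temps = np.concatenate(temp_parts)
    labels = np.concatenate(label_parts)
    if cfg.temperature_unit == "kelvin":
        temps = temps + 273.15
    cloud = AttributedPointCloud(coords=coords, temperature=temps,
                                 temperature_unit=cfg.temperature_unit,
                                 class_label=labels, crs_label=SYNTH_CRS)

    # rasters on the full extent
    ncols = int(np.ceil(extent[0] / cfg.cell_size))
    nrows = int(np.ceil(extent[1] / cfg.cell_size))
    transform = GridTransform(x0=0.0, y0=nrows * cfg.cell_size, dx=cfg.cell_size, dy=cfg.cell_size)
    rows, cols = np.indices((nrows, ncols))
    cx, cy = transform.cell_center(rows, cols)
    dtm_vals = _terrain(cfg, cx, cy)

    # canopy top surface per cell: max over present plants
    top_height = np.zeros((nrows, ncols))        # height above plant-base plane; 0 = no canopy
    canopy_depth = np.full((nrows, ncols), np.nan)
    canopy_z = np.full((nrows, ncols), -np.inf)
    for pid in range(cfg.n_plants):
        if missing[pid]:
            continue
        du = (cx - centers[pid, 0]) * e_along[0] + (cy - centers[pid, 1]) * e_along[1]
        dv = (cx - centers[pid, 0]) * e_across[0] + (cy - centers[pid, 1]) * e_across[1]
        r2 = (du / a) ** 2 + (dv / b) ** 2
        inside = r2 < 1.0
        base_z = _terrain(cfg, centers[pid, 0], centers[pid, 1]) + cfg.canopy_base
        z_top = np.where(inside, base_z + c * np.sqrt(np.clip(1.0 - r2, 0.0, None)), -np.inf)
        better = z_top > canopy_z
        canopy_z = np.where(better, z_top, canopy_z)
        canopy_depth = np.where(better, (base_z + c) - z_top, canopy_depth)

    has_canopy = np.isfinite(canopy_z) & (canopy_z > dtm_vals)
    dsm_vals = np.where(has_canopy, canopy_z, dtm_vals)

    # (6) thermal raster: temperature of the highest surface per cell + noise
    soil_t = cfg.soil_temp_mean + (rng.normal(0.0, cfg.soil_temp_sd, (nrows, ncols))
                                   if cfg.soil_temp_sd > 0 else 0.0)
    canopy_t = cfg.canopy_top_temp_mean + cfg.vertical_temp_gradient * np.nan_to_num(canopy_depth)
    thermal_vals = np.where(has_canopy, canopy_t, soil_t)
    if cfg.temp_noise_sd > 0:
        thermal_vals = thermal_vals + rng.normal(0.0, cfg.temp_noise_sd, (nrows, ncols))
    if cfg.temperature_unit == "kelvin":
        thermal_vals = thermal_vals + 273.15

    dtm = RasterGrid(values=dtm_vals, transform=transform, crs_label=SYNTH_CRS)
    dsm = RasterGrid(values=dsm_vals, transform=transform, crs_label=SYNTH_CRS)
    thermal = RasterGrid(values=thermal_vals, transform=transform, crs_label=SYNTH_CRS)
    roi = RoiPolygon(vertices=roi_xy, crs_label=SYNTH_CRS)
    return VineyardScene(config=cfg, dsm=dsm, dtm=dtm, thermal=thermal, cloud=cloud,
                         roi=roi, plant_truth=truth)


def scene_to_disk(scene: VineyardScene, outdir: str | os.PathLike) -> dict:
    """Write all scene artifacts plus a manifest; returns the manifest dict."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "dsm": os.path.join(outdir, "dsm.tif"),
        "dtm": os.path.join(outdir, "dtm.tif"),
        "thermal": os.path.join(outdir, "thermal.tif"),
        "cloud_txt": os.path.join(outdir, "cloud.txt"),
        "cloud_las": os.path.join(outdir, "cloud.las"),
        "roi": os.path.join(outdir, "roi.wkt"),
        "plant_truth": os.path.join(outdir, "plant_truth.csv"),
        "config": os.path.join(outdir, "scene_config.yaml"),
    }
    write_raster(scene.dsm, paths["dsm"])
    write_raster(scene.dtm, paths["dtm"])
    write_raster(scene.thermal, paths["thermal"])
    write_cloud(scene.cloud, paths["cloud_txt"], format="xyz-text")
    write_cloud(scene.cloud, paths["cloud_las"], format="las", drop_unsupported=True)
    with open(paths["roi"], "w") as fh:
        fh.write(scene.roi.to_shapely().wkt + "\n")
    with open(paths["plant_truth"], "w") as fh:
        fh.write("plant_id,center_x,center_y,present,true_volume\n")
        for t in scene.plant_truth:
            fh.write(f"{t.plant_id},{t.center_x:.6f},{t.center_y:.6f},"
                     f"{int(t.present)},{t.true_volume:.8f}\n")
    cfg_dict = asdict(scene.config)
    with open(paths["config"], "w") as fh:
        for key in sorted(cfg_dict):
            fh.write(f"{key}: {cfg_dict[key]}\n")
    manifest = {
        "seed": scene.config.seed,
        "config_hash": scene.config.config_hash(),
        "files": {k: os.path.basename(v) for k, v in paths.items()},
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def load_plant_truth(path: str | os.PathLike) -> list[PlantTruth]:
    """Read the plant-truth table written by :func:`scene_to_disk`."""
    out = []
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("plant_id")
        for line in fh:
            pid, cx, cy, present, vol = line.strip().split(",")
            out.append(PlantTruth(int(pid), float(cx), float(cy), bool(int(present)), float(vol)))
    return out
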