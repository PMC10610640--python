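"""Spatial data model and I/O for rasters (GeoTIFF) and attributed point clouds.

All coordinates are planar metric (projected CRS).  No reprojection is
implemented: operations that combine two inputs require identical CRS labels
and raise :class:`~vinecwsi.errors.CrsMismatchError` otherwise.

Raster convention
-----------------
North-up affine, origin at the top-left corner, row-major storage.  Cell
``(row, col)`` covers the half-open box ``[x, x + dx) x (y - dy, y]`` where
``(x, y)`` is the cell's top-left corner, so every point maps to exactly one
cell.

File formats
------------
GeoTIFF is read and written through :mod:`tifffile` using the standard GeoTIFF
tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory/GeoAsciiParams and the
GDAL nodata tag).  Point clouds support whitespace/comma-delimited text with a
self-describing header comment, LAS 1.2 (point format 0, classification codes
2=ground, 5=high vegetation, 7=noise) and PLY (ascii or binary little-endian).
The LAS and PLY codecs are intentionally minimal, self-contained
implementations of the parts of those formats this pipeline uses.
"""

from __future__ import annotations

import math
import os
import struct
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

from vinecwsi.errors import ContractError, MissingMetadataError

__all__ = [
    "GridTransform",
    "RasterGrid",
    "AttributedPointCloud",
    "RoiPolygon",
    "read_raster",
    "write_raster",
    "read_cloud",
    "write_cloud",
    "CLASS_LABELS",
    "LAS_CLASS_CODES",
]

# canonical class vocabulary and its LAS code mapping
CLASS_LABELS = ("ground", "canopy", "noise", "unassigned")
LAS_CLASS_CODES = {"unassigned": 1, "ground": 2, "canopy": 5, "noise": 7}
_LAS_CODE_TO_LABEL = {v: k for k, v in LAS_CLASS_CODES.items()}

# GeoTIFF / GDAL tag ids
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GEO_ASCII_PARAMS = 34737
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class GridTransform:
    """North-up affine map between cell indices and projected coordinates.

    ``x0, y0`` is the projected coordinate of the raster's top-left corner;
    ``dx, dy`` are strictly positive cell sizes in metres.
    """

    x0: float
    y0: float
    dx: float
    dy: float

    def __post_init__(self):
        if not (self.dx > 0 and self.dy > 0):
            raise ContractError(f"cell sizes must be strictly positive, got dx={self.dx}, dy={self.dy}")

    def cell_center(self, row, col):
        """Projected (x, y) of the center of cell(s) ``(row, col)``."""
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        return self.x0 + (col + 0.5) * self.dx, self.y0 - (row + 0.5) * self.dy

    def index_of(self, x, y):
        """Map projected coordinates to ``(row, col)`` under the half-open cell rule.

        Cell ``(r, c)`` owns ``[x0 + c*dx, x0 + (c+1)*dx)`` horizontally and
        ``(y0 - (r+1)*dy, y0 - r*dy]`` vertically (top edge inclusive).
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.dx).astype(int)
        # floor of (y0 - y)/dy puts a point lying exactly on a cell's top edge
        # into that cell and one on the bottom edge into the cell below
        row = np.floor((self.y0 - y) / self.dy).astype(int)
        return row, col

    def almost_equals(self, other: "GridTransform", tol: float = 1e-9) -> bool:
        return (
            abs(self.x0 - other.x0) <= tol
            and abs(self.y0 - other.y0) <= tol
            and abs(self.dx - other.dx) <= tol
            and abs(self.dy - other.dy) <= tol
        )


@dataclass
class RasterGrid:
    """A 2D cell array with affine georeferencing and no-data semantics."""

    values: np.ndarray
    transform: GridTransform
    crs_label: str
    nodata: float = float("nan")

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ContractError(f"raster values must be 2D, got shape {self.values.shape}")
        if not self.crs_label:
            raise MissingMetadataError("raster requires a CRS label")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells that carry data (finite and != nodata)."""
        mask = np.isfinite(self.values)
        if not math.isnan(self.nodata):
            mask &= self.values != self.nodata
        return mask

    def valid_values(self) -> np.ndarray:
        """1D array of data cells; no-data cells are excluded from every statistic."""
        return self.values[self.valid_mask]

    def filled(self, fill=np.nan) -> np.ndarray:
        """Values with no-data cells replaced by ``fill``."""
        return np.where(self.valid_mask, self.values, fill)

    def with_values(self, values: np.ndarray, nodata: float | None = None) -> "RasterGrid":
        """Same georeferencing, new cell values (and optionally a new sentinel)."""
        return RasterGrid(
            values=np.asarray(values, dtype=float),
            transform=self.transform,
            crs_label=self.crs_label,
            nodata=self.nodata if nodata is None else nodata,
        )

    def cell_centers(self):
        """(x, y) arrays (each of raster shape) of all cell centers."""
        rows, cols = np.indices(self.shape)
        return self.transform.cell_center(rows, cols)


@dataclass
class RoiPolygon:
    """Region-of-interest ring in projected metres."""

    vertices: np.ndarray
    crs_label: str = ""

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
            raise ContractError("ROI needs >= 3 planar vertices")
        poly = self.to_shapely()
        if not poly.is_valid:
            raise ContractError("ROI ring must be simple (non-self-intersecting)")
        if poly.area <= 0:
            raise ContractError("ROI must have positive area")

    def to_shapely(self):
        from shapely.geometry import Polygon

        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        return self.to_shapely().area


@dataclass
class AttributedPointCloud:
    """N 3D points with optional per-point temperature, color, class label and scalars.

    ``class_label`` uses the vocabulary ``{ground, canopy, noise, unassigned}``;
    ``temperature_unit`` is explicit metadata ("kelvin" or "celsius"), never
    inferred from magnitude.
    """

    coords: np.ndarray
    temperature: np.ndarray | None = None
    temperature_unit: str | None = None
    color: np.ndarray | None = None
    class_label: np.ndarray | None = None
    scalars: dict[str, np.ndarray] = field(default_factory=dict)
    crs_label: str = ""

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.size == 0:
            self.coords = self.coords.reshape(0, 3)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ContractError(f"coords must be N x 3, got shape {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ContractError("coordinates must be finite")
        n = len(self.coords)
        if self.temperature is not None:
            self.temperature = np.asarray(self.temperature, dtype=float).reshape(-1)
            if len(self.temperature) != n:
                raise ContractError("temperature length != N")
            if not np.all(np.isfinite(self.temperature)):
                raise ContractError("temperature must be finite where present")
            if self.temperature_unit not in ("kelvin", "celsius"):
                raise ContractError("temperature requires a declared unit: 'kelvin' or 'celsius'")
        if self.color is not None:
            self.color = np.asarray(self.color, dtype=np.int64).reshape(-1, 3)
            if len(self.color) != n:
                raise ContractError("color length != N")
            if self.color.min(initial=0) < 0 or self.color.max(initial=0) > 255:
                raise ContractError("color components must be 0-255")
        if self.class_label is not None:
            self.class_label = np.asarray(self.class_label, dtype="U10").reshape(-1)
            if len(self.class_label) != n:
                raise ContractError("class_label length != N")
            bad = set(np.unique(self.class_label)) - set(CLASS_LABELS)
            if bad:
                raise ContractError(f"unknown class labels: {sorted(bad)}")
        clean = {}
        for name, vec in self.scalars.items():
            vec = np.asarray(vec, dtype=float).reshape(-1)
            if len(vec) != n:
                raise ContractError(f"scalar field {name!r} length != N")
            clean[name] = vec
        self.scalars = clean

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def x(self):
        return self.coords[:, 0]

    @property
    def y(self):
        return self.coords[:, 1]

    @property
    def z(self):
        return self.coords[:, 2]

    def subset(self, index) -> "AttributedPointCloud":
        """Row-subset preserving order of the retained points and all attributes."""
        return AttributedPointCloud(
            coords=self.coords[index],
            temperature=None if self.temperature is None else self.temperature[index],
            temperature_unit=self.temperature_unit,
            color=None if self.color is None else self.color[index],
            class_label=None if self.class_label is None else self.class_label[index],
            scalars={k: v[index] for k, v in self.scalars.items()},
            crs_label=self.crs_label,
        )

    def with_scalar(self, name: str, values: np.ndarray) -> "AttributedPointCloud":
        scalars = dict(self.scalars)
        scalars[name] = np.asarray(values, dtype=float).reshape(-1)
        return replace(self, scalars=scalars)

    def with_class(self, labels: np.ndarray) -> "AttributedPointCloud":
        return replace(self, class_label=np.asarray(labels, dtype="U10"))

    def temperature_celsius(self) -> np.ndarray:
        """Temperature converted to Celsius regardless of stored unit."""
        if self.temperature is None:
            raise ContractError("cloud has no temperature attribute")
        if self.temperature_unit == "kelvin":
            from vinecwsi.cwsi_core import kelvin_to_celsius

            return kelvin_to_celsius(self.temperature)
        return self.temperature.copy()


# ---------------------------------------------------------------------------
# GeoTIFF raster I/O
# ---------------------------------------------------------------------------


def write_raster(grid: RasterGrid, path: str | os.PathLike, dtype=np.float32) -> str:
    """Write a :class:`RasterGrid` as a single-band GeoTIFF.

    Values are stored as ``dtype`` (float32 by default) with GeoTIFF geotags
    and a GDAL-style nodata tag.  Values are never clipped on write.
    """
    path = os.fspath(path)
    nodata_str = "nan" if math.isnan(grid.nodata) else repr(float(grid.nodata))
    ascii_params = grid.crs_label + "|"
    # GeoKeyDirectory: version 1.1.0, 3 keys (model type, raster type, citation)
    key_dir = (
        1, 1, 0, 3,
        1024, 0, 1, 1,  # GTModelTypeGeoKey = projected
        1025, 0, 1, 1,  # GTRasterTypeGeoKey = PixelIsArea
        1026, _TAG_GEO_ASCII_PARAMS, len(ascii_params), 0,  # citation -> ascii params
    )
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (grid.transform.dx, grid.transform.dy, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.transform.x0, grid.transform.y0, 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(key_dir), key_dir),
        (_TAG_GEO_ASCII_PARAMS, "s", len(ascii_params), ascii_params),
        (_TAG_GDAL_NODATA, "s", len(nodata_str), nodata_str),
    ]
    tifffile.imwrite(path, grid.values.astype(dtype), extratags=extratags)
    return path


def read_raster(path: str | os.PathLike, band: int = 0) -> RasterGrid:
    """Read a single- or multi-band GeoTIFF into a :class:`RasterGrid`.

    Raises :class:`MissingMetadataError` if the file lacks georeferencing tags
    or a CRS citation.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        tags = {t.code: t.value for t in page.tags.values()}
        values = tif.asarray()
    if values.ndim == 3:
        # band-interleaved (bands first or last); pick the requested band
        if values.shape[0] < values.shape[2]:
            values = values[band]
        else:
            values = values[..., band]
    elif band != 0:
        raise ContractError(f"band {band} requested from single-band raster")
    if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
        raise MissingMetadataError(f"{path}: missing georeferencing (ModelPixelScale/ModelTiepoint tags)")
    scale = tags[_TAG_MODEL_PIXEL_SCALE]
    tie = tags[_TAG_MODEL_TIEPOINT]
    # tiepoint maps raster (i, j) -> model (x, y); we require the top-left anchor
    x0 = float(tie[3]) - float(tie[0]) * float(scale[0])
    y0 = float(tie[4]) + float(tie[1]) * float(scale[1])
    transform = GridTransform(x0=x0, y0=y0, dx=float(scale[0]), dy=float(scale[1]))
    crs = tags.get(_TAG_GEO_ASCII_PARAMS)
    if not crs:
        raise MissingMetadataError(f"{path}: missing CRS metadata (GeoAsciiParams tag)")
    crs_label = str(crs).rstrip("|\x00 ")
    nodata = float("nan")
    if _TAG_GDAL_NODATA in tags:
        txt = str(tags[_TAG_GDAL_NODATA]).strip("\x00 ")
        nodata = float(txt)
    return RasterGrid(values=np.asarray(values, dtype=float), transform=transform,
                      crs_label=crs_label, nodata=nodata)


# ---------------------------------------------------------------------------
# Point cloud I/O
# ---------------------------------------------------------------------------

_TEXT_FLOAT_FMT = "%.10g"


def _cloud_columns(cloud: AttributedPointCloud):
    """Ordered (name, vector) column list for text export."""
    cols = [("x", cloud.x), ("y", cloud.y), ("z", cloud.z)]
    if cloud.temperature is not None:
        cols.append(("temperature", cloud.temperature))
    if cloud.color is not None:
        cols += [("red", cloud.color[:, 0]), ("green", cloud.color[:, 1]), ("blue", cloud.color[:, 2])]
    if cloud.class_label is not None:
        codes = np.array([LAS_CLASS_CODES[lbl] for lbl in cloud.class_label], dtype=float)
        cols.append(("classification", codes))
    for name in sorted(cloud.scalars):
        cols.append((name, cloud.scalars[name]))
    return cols


def _write_cloud_text(cloud: AttributedPointCloud, path: str) -> None:
    cols = _cloud_columns(cloud)
    with open(path, "w") as fh:
        fh.write("# columns: " + " ".join(name for name, _ in cols) + "\n")
        if cloud.temperature is not None:
            fh.write(f"# temperature_unit: {cloud.temperature_unit}\n")
        if cloud.crs_label:
            fh.write(f"# crs: {cloud.crs_label}\n")
        if len(cloud):
            data = np.column_stack([vec for _, vec in cols])
            np.savetxt(fh, data, fmt=_TEXT_FLOAT_FMT)


def _read_cloud_text(path: str, column_map: dict[str, int] | None,
                     temperature_unit: str | None) -> AttributedPointCloud:
    header_cols: list[str] | None = None
    header_unit = None
    header_crs = ""
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if body.startswith("columns:"):
                header_cols = body.split(":", 1)[1].split()
            elif body.startswith("temperature_unit:"):
                header_unit = body.split(":", 1)[1].strip()
            elif body.startswith("crs:"):
                header_crs = body.split(":", 1)[1].strip()
    if column_map is None:
        if header_cols is None:
            raise ContractError(f"{path}: no column_map given and no '# columns:' header found")
        column_map = {name: i for i, name in enumerate(header_cols)}
    try:
        data = np.loadtxt(path, comments="#", ndmin=2, dtype=float,
                          delimiter="," if _looks_csv(path) else None)
    except ValueError as exc:
        raise ContractError(f"{path}: malformed point rows ({exc})") from exc
    if data.size == 0:
        data = np.zeros((0, max(column_map.values()) + 1 if column_map else 3))
    for name, idx in column_map.items():
        if idx >= data.shape[1] and len(data):
            raise ContractError(f"{path}: declared column {name!r} at index {idx} but rows have {data.shape[1]} fields")
    for req in ("x", "y", "z"):
        if req not in column_map:
            raise ContractError(f"column_map must include {req!r}")
    coords = data[:, [column_map["x"], column_map["y"], column_map["z"]]]
    temperature = None
    unit = temperature_unit or header_unit
    if "temperature" in column_map:
        temperature = data[:, column_map["temperature"]]
        if unit is None:
            raise ContractError("temperature column present but no unit declared")
    color = None
    if all(c in column_map for c in ("red", "green", "blue")):
        color = data[:, [column_map["red"], column_map["green"], column_map["blue"]]].astype(int)
    class_label = None
    if "classification" in column_map:
        codes = data[:, column_map["classification"]].astype(int)
        class_label = np.array([_LAS_CODE_TO_LABEL.get(c, "unassigned") for c in codes], dtype="U10")
    handled = {"x", "y", "z", "temperature", "red", "green", "blue", "classification"}
    scalars = {name: data[:, idx] for name, idx in column_map.items() if name not in handled}
    return AttributedPointCloud(coords=coords, temperature=temperature,
                                temperature_unit=unit if temperature is not None else None,
                                color=color, class_label=class_label, scalars=scalars,
                                crs_label=header_crs)


def _looks_csv(path: str) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return "," in line
    return False


# --- LAS 1.2, point record format 0 ----------------------------------------

_LAS_HEADER_SIZE = 227
_LAS_POINT0 = np.dtype([
    ("X", "<i4"), ("Y", "<i4"), ("Z", "<i4"),
    ("intensity", "<u2"), ("flags", "u1"), ("classification", "u1"),
    ("scan_angle", "i1"), ("user_data", "u1"), ("point_source", "<u2"),
])


def _write_cloud_las(cloud: AttributedPointCloud, path: str) -> None:
    n = len(cloud)
    if n:
        mins = cloud.coords.min(axis=0)
        maxs = cloud.coords.max(axis=0)
    else:
        mins = maxs = np.zeros(3)
    extent = float((maxs - mins).max(initial=0.0))
    # scale chosen so quantization error stays <= 1e-6 m for desk-scale scenes
    scale = max(1e-6, extent / (2**31 - 2))
    offset = mins
    records = np.zeros(n, dtype=_LAS_POINT0)
    if n:
        q = np.round((cloud.coords - offset) / scale).astype(np.int64)
        records["X"], records["Y"], records["Z"] = q[:, 0], q[:, 1], q[:, 2]
        if cloud.class_label is not None:
            records["classification"] = [LAS_CLASS_CODES[lbl] for lbl in cloud.class_label]
        else:
            records["classification"] = LAS_CLASS_CODES["unassigned"]
    header = bytearray(_LAS_HEADER_SIZE)
    header[0:4] = b"LASF"
    header[24] = 1  # version major
    header[25] = 2  # version minor
    struct.pack_into("<H", header, 94, _LAS_HEADER_SIZE)
    struct.pack_into("<I", header, 96, _LAS_HEADER_SIZE)  # offset to point data
    struct.pack_into("<I", header, 100, 0)  # no VLRs
    header[104] = 0  # point data format 0
    struct.pack_into("<H", header, 105, _LAS_POINT0.itemsize)
    struct.pack_into("<I", header, 107, n)
    struct.pack_into("<I", header, 111, n)  # returns: all first-return
    struct.pack_into("<3d", header, 131, scale, scale, scale)
    struct.pack_into("<3d", header, 155, *offset)
    struct.pack_into("<6d", header, 179, maxs[0], mins[0], maxs[1], mins[1], maxs[2], mins[2])
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(records.tobytes())


def _read_cloud_las(path: str) -> AttributedPointCloud:
    with open(path, "rb") as fh:
        raw = fh.read()
    if raw[0:4] != b"LASF":
        raise ContractError(f"{path}: not a LAS file")
    point_offset = struct.unpack_from("<I", raw, 96)[0]
    point_format = raw[104]
    record_len = struct.unpack_from("<H", raw, 105)[0]
    n = struct.unpack_from("<I", raw, 107)[0]
    sx, sy, sz = struct.unpack_from("<3d", raw, 131)
    ox, oy, oz = struct.unpack_from("<3d", raw, 155)
    if point_format not in (0, 1):
        raise ContractError(f"{path}: unsupported LAS point format {point_format}")
    body = raw[point_offset:point_offset + n * record_len]
    base = np.frombuffer(body, dtype=np.uint8).reshape(n, record_len) if n else np.zeros((0, record_len), np.uint8)
    records = base[:, : _LAS_POINT0.itemsize].copy().view(_LAS_POINT0).reshape(n)
    coords = np.column_stack([
        records["X"] * sx + ox,
        records["Y"] * sy + oy,
        records["Z"] * sz + oz,
    ]) if n else np.zeros((0, 3))
    codes = records["classification"] & 0x1F
    class_label = np.array([_LAS_CODE_TO_LABEL.get(int(c), "unassigned") for c in codes], dtype="U10")
    return AttributedPointCloud(coords=coords, class_label=class_label if n else None)


# --- PLY (ascii / binary little-endian) -------------------------------------

_PLY_TYPES = {
    "char": "i1", "uchar": "u1", "short": "i2", "ushort": "u2",
    "int": "i4", "uint": "u4", "float": "f4", "double": "f8",
    "int8": "i1", "uint8": "u1", "int16": "i2", "uint16": "u2",
    "int32": "i4", "uint32": "u4", "float32": "f4", "float64": "f8",
}


def _write_cloud_ply(cloud: AttributedPointCloud, path: str, binary: bool = False) -> None:
    props: list[tuple[str, str, np.ndarray]] = [
        ("x", "double", cloud.x), ("y", "double", cloud.y), ("z", "double", cloud.z)]
    if cloud.temperature is not None:
        props.append(("temperature", "double", cloud.temperature))
    if cloud.color is not None:
        props += [("red", "uchar", cloud.color[:, 0]),
                  ("green", "uchar", cloud.color[:, 1]),
                  ("blue", "uchar", cloud.color[:, 2])]
    if cloud.class_label is not None:
        codes = np.array([LAS_CLASS_CODES[lbl] for lbl in cloud.class_label])
        props.append(("classification", "uchar", codes))
    for name in sorted(cloud.scalars):
        props.append((name, "double", cloud.scalars[name]))
    header = ["ply", "format binary_little_endian 1.0" if binary else "format ascii 1.0"]
    if cloud.temperature is not None:
        header.append(f"comment temperature_unit {cloud.temperature_unit}")
    if cloud.crs_label:
        header.append(f"comment crs {cloud.crs_label}")
    header.append(f"element vertex {len(cloud)}")
    header += [f"property {typ} {name}" for name, typ, _ in props]
    header.append("end_header")
    dtype = np.dtype([(name, "<" + _PLY_TYPES[typ]) for name, typ, _ in props])
    table = np.zeros(len(cloud), dtype=dtype)
    for name, _, vec in props:
        table[name] = vec
    if binary:
        with open(path, "wb") as fh:
            fh.write(("\n".join(header) + "\n").encode())
            fh.write(table.tobytes())
    else:
        with open(path, "w") as fh:
            fh.write("\n".join(header) + "\n")
            for rec in table:
                fh.write(" ".join(_TEXT_FLOAT_FMT % v for v in rec) + "\n")


def _read_cloud_ply(path: str, temperature_unit: str | None = None) -> AttributedPointCloud:
    with open(path, "rb") as fh:
        raw = fh.read()
    end = raw.find(b"end_header")
    if raw[:3] != b"ply" or end < 0:
        raise ContractError(f"{path}: not a PLY file")
    end = raw.find(b"\n", end) + 1
    header_lines = raw[:end].decode("ascii", errors="replace").splitlines()
    fmt = None
    n = 0
    props: list[tuple[str, str]] = []
    unit = temperature_unit
    crs = ""
    in_vertex = False
    for line in header_lines:
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "format":
            fmt = parts[1]
        elif parts[0] == "comment" and len(parts) >= 3 and parts[1] == "temperature_unit":
            unit = unit or parts[2]
        elif parts[0] == "comment" and len(parts) >= 3 and parts[1] == "crs":
            crs = " ".join(parts[2:])
        elif parts[0] == "element":
            in_vertex = parts[1] == "vertex"
            if in_vertex:
                n = int(parts[2])
        elif parts[0] == "property" and in_vertex:
            if parts[1] == "list":
                raise ContractError(f"{path}: list properties not supported")
            props.append((parts[2], parts[1]))
    if fmt not in ("ascii", "binary_little_endian"):
        raise ContractError(f"{path}: unsupported PLY format {fmt!r}")
    dtype = np.dtype([(name, "<" + _PLY_TYPES[typ]) for name, typ in props])
    if fmt == "ascii":
        body = raw[end:].decode()
        rows = [ln.split() for ln in body.splitlines() if ln.strip()]
        table = np.zeros(n, dtype=dtype)
        for i, row in enumerate(rows[:n]):
            for (name, _), val in zip(props, row):
                table[name][i] = float(val)
    else:
        table = np.frombuffer(raw[end:end + n * dtype.itemsize], dtype=dtype)
    names = [name for name, _ in props]
    for req in ("x", "y", "z"):
        if req not in names:
            raise ContractError(f"{path}: PLY vertex element lacks {req!r}")
    coords = np.column_stack([table["x"], table["y"], table["z"]]).astype(float) if n else np.zeros((0, 3))
    temperature = table["temperature"].astype(float) if "temperature" in names and n else None
    if "temperature" in names and unit is None:
        raise ContractError("temperature property present but no unit declared")
    color = None
    if all(c in names for c in ("red", "green", "blue")) and n:
        color = np.column_stack([table["red"], table["green"], table["blue"]]).astype(int)
    class_label = None
    if "classification" in names and n:
        class_label = np.array([_LAS_CODE_TO_LABEL.get(int(c), "unassigned")
                                for c in table["classification"]], dtype="U10")
    handled = {"x", "y", "z", "temperature", "red", "green", "blue", "classification"}
    scalars = {name: table[name].astype(float) for name in names if name not in handled and n}
    return AttributedPointCloud(coords=coords, temperature=temperature,
                                temperature_unit=unit if temperature is not None else None,
                                color=color, class_label=class_label, scalars=scalars,
                                crs_label=crs)


def read_cloud(path: str | os.PathLike, format: str = "xyz-text",
               column_map: dict[str, int] | None = None,
               temperature_unit: str | None = None) -> AttributedPointCloud:
    """Read a point cloud.

    Parameters
    ----------
    format:
        ``"xyz-text"`` (whitespace- or comma-delimited, ``#`` comments skipped),
        ``"las"`` or ``"ply"``.
    column_map:
        For text input: attribute name -> 0-based column index.  Must include
        ``x``, ``y``, ``z``; recognised extras are ``temperature``,
        ``red/green/blue``, ``classification`` (LAS codes); any other name
        becomes a scalar field.  If omitted, the self-describing
        ``# columns:`` header written by :func:`write_cloud` is used.
    temperature_unit:
        Declared unit of a mapped temperature column (``"kelvin"`` or
        ``"celsius"``).  Required when the file itself does not record one.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "xyz-text":
        return _read_cloud_text(path, column_map, temperature_unit)
    if format == "las":
        return _read_cloud_las(path)
    if format == "ply":
        return _read_cloud_ply(path, temperature_unit)
    raise ContractError(f"unknown cloud format {format!r}")


def write_cloud(cloud: AttributedPointCloud, path: str | os.PathLike,
                format: str = "xyz-text", drop_unsupported: bool = False,
                binary: bool = False) -> str:
    """Write a point cloud; scalar fields become extra columns/properties.

    LAS (point format 0) can carry coordinates and class labels only; writing a
    cloud with temperature, color or scalar fields raises unless
    ``drop_unsupported=True``, in which case those attributes are omitted.
    """
    path = os.fspath(path)
    if format == "xyz-text":
        _write_cloud_text(cloud, path)
    elif format == "las":
        unsupported = []
        if cloud.temperature is not None:
            unsupported.append("temperature")
        if cloud.color is not None:
            unsupported.append("color")
        unsupported += sorted(cloud.scalars)
        if unsupported and not drop_unsupported:
            raise ContractError(
                f"LAS point format 0 cannot store attributes {unsupported}; "
                "pass drop_unsupported=True to write coordinates and classes only")
        stripped = AttributedPointCloud(coords=cloud.coords, class_label=cloud.class_label,
                                        crs_label=cloud.crs_label)
        _write_cloud_las(stripped, path)
    elif format == "ply":
        _write_cloud_ply(cloud, path, binary=binary)
    else:
        raise ContractError(f"unknown cloud format {format!r}")
    return path


def require_same_crs(*labels: str) -> None:
    """Raise :class:`CrsMismatchError` unless all non-empty labels agree."""
    from vinecwsi.errors import CrsMismatchError

    known = [lbl for lbl in labels if lbl]
    if known and any(lbl != known[0] for lbl in known[1:]):
        raise CrsMismatchError(f"CRS labels differ: {sorted(set(known))}")
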