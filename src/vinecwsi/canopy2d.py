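"""Raster branch of the canopy extraction: CHM construction, binary masking and
masked thermal extraction.

The canopy height model is the cellwise difference DSM - DTM.  The binary mask
keeps cells whose height strictly exceeds the threshold (0.5 m by default);
applying it to a thermal layer retains canopy-cell temperatures and sets
everything else to no-data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from vinecwsi.errors import ContractError
from vinecwsi.geodata import RasterGrid, require_same_crs

__all__ = ["CanopyMask", "compute_chm", "threshold_mask", "apply_mask"]

DEFAULT_HEIGHT_THRESHOLD_M = 0.5


@dataclass
class CanopyMask:
    """Binary canopy raster (1 = canopy, 0 = everything else) plus its threshold."""

    grid: RasterGrid
    threshold_m: float

    def __post_init__(self):
        vals = self.grid.values
        if not np.all(np.isin(vals[np.isfinite(vals)], (0.0, 1.0))):
            raise ContractError("mask values must be binary")

    @property
    def as_bool(self) -> np.ndarray:
        return self.grid.values == 1.0


def _check_aligned(a: RasterGrid, b: RasterGrid, what: str) -> None:
    if a.shape != b.shape:
        raise ContractError(f"{what}: shape mismatch {a.shape} vs {b.shape}")
    if not a.transform.almost_equals(b.transform):
        raise ContractError(f"{what}: affine transforms differ")
    require_same_crs(a.crs_label, b.crs_label)


def compute_chm(dsm: RasterGrid, dtm: RasterGrid) -> RasterGrid:
    """Canopy height model: cellwise ``dsm - dtm``.

    No-data in either input propagates to the output cell.
    """
    _check_aligned(dsm, dtm, "compute_chm")
    valid = dsm.valid_mask & dtm.valid_mask
    out = np.full(dsm.shape, np.nan)
    out[valid] = dsm.values[valid] - dtm.values[valid]
    return RasterGrid(values=out, transform=dsm.transform, crs_label=dsm.crs_label,
                      nodata=float("nan"))


def threshold_mask(chm: RasterGrid, threshold_m: float = DEFAULT_HEIGHT_THRESHOLD_M) -> CanopyMask:
    """Binary mask of cells whose height strictly exceeds ``threshold_m``.

    Cells exactly at the threshold and no-data cells get 0.
    """
    if threshold_m < 0:
        raise ContractError(f"threshold must be non-negative, got {threshold_m}")
    out = np.zeros(chm.shape, dtype=float)
    valid = chm.valid_mask
    out[valid] = (chm.values[valid] > threshold_m).astype(float)
    grid = RasterGrid(values=out, transform=chm.transform, crs_label=chm.crs_label,
                      nodata=float("nan"))
    return CanopyMask(grid=grid, threshold_m=threshold_m)


def apply_mask(thermal: RasterGrid, mask: CanopyMask) -> RasterGrid:
    """Retain thermal values where the mask is 1; everything else becomes no-data."""
    _check_aligned(thermal, mask.grid, "apply_mask")
    keep = mask.as_bool & thermal.valid_mask
    out = np.full(thermal.shape, np.nan)
    out[keep] = thermal.values[keep]
    return RasterGrid(values=out, transform=thermal.transform, crs_label=thermal.crs_label,
                      nodata=float("nan"))
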