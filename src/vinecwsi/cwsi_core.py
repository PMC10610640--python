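"""Simplified crop water stress index: reference temperatures, the index itself,
unit conversion and summary statistics.

The wet and dry anchors are estimated from the canopy temperature distribution
itself: the wet reference is the mean of the coolest ``tail_fraction`` of the
values and the dry reference the mean of the warmest ``tail_fraction``
(0.5% by default).  CWSI is then the affine map
``(T - t_wet) / (t_dry - t_wet)``, applied elementwise to rasters or clouds.
Values outside [0, 1] are retained and flagged, never clipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from vinecwsi.errors import ContractError
from vinecwsi.geodata import AttributedPointCloud, RasterGrid

__all__ = [
    "ReferenceTemps",
    "ThermalSummary",
    "kelvin_to_celsius",
    "reference_temps",
    "cwsi",
    "cwsi_raster",
    "cwsi_cloud",
    "outlier_fraction",
    "summarize",
]

ABSOLUTE_ZERO_C = -273.15


@dataclass(frozen=True)
class ReferenceTemps:
    """Wet/dry reference anchors (degrees Celsius) and their provenance."""

    t_wet: float
    t_dry: float
    tail_fraction: float = 0.005
    n_tail: int = 1

    def __post_init__(self):
        if not self.t_dry > self.t_wet:
            raise ContractError(f"t_dry ({self.t_dry}) must exceed t_wet ({self.t_wet})")
        if not 0 < self.tail_fraction < 0.5:
            raise ContractError("tail_fraction must lie in (0, 0.5)")
        if self.n_tail < 1:
            raise ContractError("n_tail must be >= 1")

    @property
    def interval(self) -> float:
        """Width of the reference interval, t_dry - t_wet."""
        return self.t_dry - self.t_wet


def kelvin_to_celsius(t):
    """Convert temperatures from Kelvin to Celsius (t - 273.15).

    Rejects negative Kelvin; accepts scalars or arrays.
    """
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0):
        raise ContractError("temperature below 0 K")
    out = arr + ABSOLUTE_ZERO_C
    return float(out) if np.isscalar(t) or arr.ndim == 0 else out


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def reference_temps(values, tail_fraction: float = 0.005) -> ReferenceTemps:
    """Estimate the wet/dry anchors from a temperature sample (Celsius).

    ``t_wet`` is the mean of the ``n_tail`` smallest values and ``t_dry`` the
    mean of the ``n_tail`` largest, where
    ``n_tail = max(1, round(tail_fraction * N))`` (half away from zero).
    No-data must be excluded by the caller; NaN input is rejected.
    """
    vals = np.asarray(values, dtype=float).reshape(-1)
    if len(vals) < 2:
        raise ContractError("need at least 2 values for reference temperatures")
    if not np.all(np.isfinite(vals)):
        raise ContractError("reference sample contains non-finite values; exclude no-data first")
    if not 0 < tail_fraction < 0.5:
        raise ContractError("tail_fraction must lie in (0, 0.5)")
    n_tail = max(1, _round_half_away(tail_fraction * len(vals)))
    ordered = np.sort(vals, kind="stable")
    t_wet = float(ordered[:n_tail].mean())
    t_dry = float(ordered[-n_tail:].mean())
    if t_dry <= t_wet:
        raise ContractError("degenerate reference interval: t_wet == t_dry "
                            "(all sampled temperatures identical?)")
    return ReferenceTemps(t_wet=t_wet, t_dry=t_dry, tail_fraction=tail_fraction, n_tail=n_tail)


def cwsi(t_canopy, refs: ReferenceTemps):
    """CWSI = (T_canopy - t_wet) / (t_dry - t_wet); exact affine map, not clipped."""
    arr = np.asarray(t_canopy, dtype=float)
    out = (arr - refs.t_wet) / refs.interval
    return float(out) if arr.ndim == 0 else out


def cwsi_raster(thermal: RasterGrid, refs: ReferenceTemps) -> RasterGrid:
    """Apply the index to every data cell of a (masked) thermal raster in Celsius."""
    out = np.full(thermal.shape, np.nan)
    valid = thermal.valid_mask
    out[valid] = cwsi(thermal.values[valid], refs)
    return thermal.with_values(out, nodata=float("nan"))


def cwsi_cloud(cloud: AttributedPointCloud, refs: ReferenceTemps,
               scalar_name: str = "cwsi") -> AttributedPointCloud:
    """Attach a per-point CWSI scalar computed from the cloud's temperature."""
    temps = cloud.temperature_celsius()
    return cloud.with_scalar(scalar_name, cwsi(temps, refs))


def outlier_fraction(cwsi_values) -> float:
    """Fraction of index values falling outside [0, 1]."""
    vals = np.asarray(cwsi_values, dtype=float).reshape(-1)
    if len(vals) == 0:
        return 0.0
    return float(np.mean((vals < 0) | (vals > 1)))


@dataclass(frozen=True)
class ThermalSummary:
    """Per-dataset summary of temperatures and CWSI, one table row per dataset."""

    min_temp: float
    max_temp: float
    mean_temp: float
    sd_temp: float
    min_cwsi: float
    max_cwsi: float
    mean_cwsi: float
    sd_cwsi: float
    t_wet: float
    t_dry: float
    n_samples: int
    sample_spacing_cm: float | None = None

    def __post_init__(self):
        if self.n_samples < 1:
            raise ContractError("summary needs at least one sample")
        if not (self.min_temp <= self.mean_temp <= self.max_temp):
            raise ContractError("temperature min <= mean <= max violated")
        if not (self.min_cwsi <= self.mean_cwsi <= self.max_cwsi):
            raise ContractError("cwsi min <= mean <= max violated")


def _sd(vals: np.ndarray) -> float:
    return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0


def summarize(values, cwsi_values, refs: ReferenceTemps,
              spacing_cm: float | None = None) -> ThermalSummary:
    """Summary statistics (sd with n-1 denominator) for paired temperature/CWSI samples.

    Asserts the affine identities linking the two channels: the CWSI mean and
    extrema are the affine images of the temperature statistics and the CWSI sd
    is the temperature sd divided by the reference interval.
    """
    temps = np.asarray(values, dtype=float).reshape(-1)
    idx = np.asarray(cwsi_values, dtype=float).reshape(-1)
    if len(temps) != len(idx):
        raise ContractError("temperature and cwsi vectors differ in length")
    if len(temps) == 0:
        raise ContractError("empty input")
    summary = ThermalSummary(
        min_temp=float(temps.min()), max_temp=float(temps.max()),
        mean_temp=float(temps.mean()), sd_temp=_sd(temps),
        min_cwsi=float(idx.min()), max_cwsi=float(idx.max()),
        mean_cwsi=float(idx.mean()), sd_cwsi=_sd(idx),
        t_wet=refs.t_wet, t_dry=refs.t_dry,
        n_samples=len(temps), sample_spacing_cm=spacing_cm,
    )
    # affine consistency between the channels (tolerance scaled to magnitude)
    span = refs.interval
    for got, want in (
        (summary.mean_cwsi, (summary.mean_temp - refs.t_wet) / span),
        (summary.min_cwsi, (summary.min_temp - refs.t_wet) / span),
        (summary.max_cwsi, (summary.max_temp - refs.t_wet) / span),
        (summary.sd_cwsi, summary.sd_temp / span),
    ):
        if not math.isclose(got, want, rel_tol=1e-9, abs_tol=1e-9):
            raise ContractError(
                f"cwsi channel is not the affine image of the temperature channel "
                f"({got} vs {want}); were the two computed from different references?")
    return summary
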