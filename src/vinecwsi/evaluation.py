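"""Paired linear regressions between datasets (data models, flights, reference
volumes) and report generation.

Pairing across datasets is always by grid plant id; plants missing a value in
either member of a pair are dropped and counted.  Ordinary least squares with
a fitted intercept; R^2 = 1 - SSE/SST.  The p-value from the standard
F-statistic is included for information only.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from vinecwsi.errors import ContractError
from vinecwsi.plants import PlantRecord

__all__ = ["RegressionFit", "ComparisonReport", "fit_linear", "compare_datasets"]


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    n: int
    pairs_dropped: int = 0
    p_value: float | None = None

    def __post_init__(self):
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ContractError(f"r_squared out of range: {self.r_squared}")
        if self.n < 2:
            raise ContractError("regression needs n >= 2")


@dataclass
class ComparisonReport:
    """Matrix of fits keyed by (x-dataset, y-dataset) plus the paired samples."""

    fits: dict[tuple[str, str], RegressionFit] = field(default_factory=dict)
    pair_tables: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    value_field: str = "mean_cwsi"

    def to_table(self) -> str:
        """Delimited text rendering of the fit matrix."""
        lines = ["x_dataset\ty_dataset\tslope\tintercept\tr_squared\tn\tpairs_dropped\tp_value"]
        for (xn, yn), f in self.fits.items():
            p = "" if f.p_value is None else f"{f.p_value:.4g}"
            lines.append(f"{xn}\t{yn}\t{f.slope:.6g}\t{f.intercept:.6g}\t"
                         f"{f.r_squared:.6g}\t{f.n}\t{f.pairs_dropped}\t{p}")
        return "\n".join(lines) + "\n"


def fit_linear(x, y) -> RegressionFit:
    """Ordinary least squares of y on x with fitted intercept.

    Pairs with a missing (None/NaN) member are dropped and counted.  Zero
    variance in x is an error; zero variance in y yields R^2 = 0 with a
    warning.
    """
    x = np.array([np.nan if v is None else v for v in np.asarray(x, dtype=object)], dtype=float)
    y = np.array([np.nan if v is None else v for v in np.asarray(y, dtype=object)], dtype=float)
    if len(x) != len(y):
        raise ContractError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    dropped = int(len(x) - ok.sum())
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 2:
        raise ContractError(f"need >= 2 complete pairs, have {n} ({dropped} dropped)")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ContractError("zero variance in x; regression undefined")
    syy = float(np.sum((y - y.mean()) ** 2))
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    if syy == 0:
        warnings.warn("zero variance in y; defining R^2 = 0")
        return RegressionFit(slope=slope, intercept=intercept, r_squared=0.0,
                             n=n, pairs_dropped=dropped, p_value=None)
    resid = y - (slope * x + intercept)
    sse = float(np.sum(resid**2))
    r2 = 1.0 - sse / syy
    r2 = min(max(r2, 0.0), 1.0)
    p_value = None
    if n > 2 and sse > 0:
        f_stat = (syy - sse) / (sse / (n - 2))
        p_value = float(stats.f.sf(f_stat, 1, n - 2))
    return RegressionFit(slope=slope, intercept=intercept, r_squared=r2,
                         n=n, pairs_dropped=dropped, p_value=p_value)


def _values_by_id(records: list[PlantRecord], value_field: str) -> dict[int, float]:
    out = {}
    for rec in records:
        val = getattr(rec, value_field)
        if val is not None and np.isfinite(val):
            out[rec.plant_id] = float(val)
    return out


def compare_datasets(records: dict[str, list[PlantRecord]],
                     value_field: str = "mean_cwsi",
                     pairs: list[tuple[str, str]] | None = None) -> ComparisonReport:
    """Fit regressions for every requested (x, y) dataset pair.

    ``records`` maps dataset labels (e.g. "nadir_ortho", "nadir_cloud",
    "lidar") to per-plant records; ``value_field`` selects ``mean_cwsi`` or
    ``hull_volume``.  By default all unordered pairs are compared.
    """
    if len(records) < 2:
        raise ContractError("need at least 2 datasets to compare")
    if pairs is None:
        pairs = list(itertools.combinations(sorted(records), 2))
    report = ComparisonReport(value_field=value_field)
    for xn, yn in pairs:
        xs = _values_by_id(records[xn], value_field)
        ys = _values_by_id(records[yn], value_field)
        shared = sorted(set(xs) & set(ys))
        if not shared:
            raise ContractError(f"datasets {xn!r} and {yn!r} share no plant ids with data")
        all_ids = sorted(set(xs) | set(ys))
        x = [xs.get(i) for i in all_ids]
        y = [ys.get(i) for i in all_ids]
        fit = fit_linear(x, y)
        report.fits[(xn, yn)] = fit
        table = np.array([[i, xs[i], ys[i]] for i in shared])
        report.pair_tables[(xn, yn)] = table
        assert fit.n == len(table)
    return report
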