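"""Temporal and spatial consistency analysis of paired ECV stacks.

Two complementary applications of the change-agreement framework:

* **temporal (map) approach** — for each consecutive time step, all pixels
  of a region/stratum are pooled into one contingency table, giving a
  time series of agreement metrics;
* **spatial (pixel) approach** — for each pixel, all consecutive steps of
  the record are pooled, giving maps of agreement metrics.

Short-term temporal consistency is summarised by monthly climatologies of
the metric series; long-term consistency by the Seasonal Mann-Kendall
monotonic-trend test (per-month Kendall S statistics summed, tie-corrected
normal approximation, no inter-season covariance term).  Spatial
consistency between two products is tested per stratum with the Welch
unequal-variance t test on metric means and the two-sample
Kolmogorov-Smirnov test on metric distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .change import ClassificationConfig, classify_arrays, confidence_level_arrays
from .metrics import METRIC_NAMES, ContingencyTable, metrics_from_counts
from .stack import GriddedStack, RegionSpec

__all__ = [
    "classify_stacks",
    "temporal_agreement",
    "temporal_tables",
    "spatial_agreement",
    "monthly_climatology",
    "seasonal_mann_kendall",
    "SeasonalMKResult",
    "compare_products",
    "ProductComparison",
    "zonal_mean",
]


def classify_stacks(
    lai: GriddedStack,
    fapar: GriddedStack,
    config: ClassificationConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Classify every consecutive change of both stacks simultaneously.

    Returns two int8 code cubes of shape (T-1, ny, nx) with 1=decrease,
    2=non-significant, 3=increase and 0 where the step is masked.  A step
    is kept only when both ECVs are valid at both of its end points
    (pairwise-complete masking).
    """
    cfg = config or ClassificationConfig()
    lai.check_aligned(fapar)

    dl, cl = confidence_level_arrays(lai.masked_values(), lai.masked_uncertainties())
    df_, cf = confidence_level_arrays(fapar.masked_values(), fapar.masked_uncertainties())
    step_valid = (lai.mask[:-1] & lai.mask[1:] & fapar.mask[:-1] & fapar.mask[1:])

    lai_codes = classify_arrays(dl, cl, threshold=cfg.lai)
    fapar_codes = classify_arrays(df_, cf, threshold=cfg.fapar)
    both = step_valid & (lai_codes > 0) & (fapar_codes > 0)
    lai_codes[~both] = 0
    fapar_codes[~both] = 0
    return lai_codes, fapar_codes


def _step_counts(lai_codes: np.ndarray, fapar_codes: np.ndarray,
                 member: np.ndarray) -> np.ndarray:
    """Per-step 3x3 counts over a pixel membership mask -> (S, 3, 3)."""
    li = lai_codes[:, member]
    fi = fapar_codes[:, member]
    keep = (li > 0) & (fi > 0)
    cell = np.where(keep, (li - 1) * 3 + (fi - 1), 9)
    counts = np.apply_along_axis(np.bincount, 1, cell, minlength=10)[:, :9]
    return counts.reshape(-1, 3, 3)


def temporal_tables(
    lai: GriddedStack,
    fapar: GriddedStack,
    region: RegionSpec,
    config: ClassificationConfig | None = None,
) -> np.ndarray:
    """Per-time-step contingency counts over a region, shape (T-1, 3, 3)."""
    lai_codes, fapar_codes = classify_stacks(lai, fapar, config)
    return _step_counts(lai_codes, fapar_codes, region.membership)


def temporal_agreement(
    lai: GriddedStack,
    fapar: GriddedStack,
    region: RegionSpec,
    config: ClassificationConfig | None = None,
) -> pd.DataFrame:
    """Time series of agreement metrics pooled over a region (map approach).

    One contingency table per consecutive step, built from all region
    pixels valid at both step ends in both ECVs.  The series is indexed by
    the composite start date of the later composite of each step.
    ``processed_fraction`` relates the table total N to the region's pixel
    count; steps with N = 0 carry NaN metrics.
    """
    counts = temporal_tables(lai, fapar, region, config)
    processed = np.full(counts.shape[0], region.n_pixels, dtype=float)
    res = metrics_from_counts(counts, processed=processed)
    df = pd.DataFrame({k: res[k] for k in (*METRIC_NAMES, "n", "processed_fraction")},
                      index=lai.times[1:])
    df.index.name = "time"
    return df


def spatial_agreement(
    lai: GriddedStack,
    fapar: GriddedStack,
    config: ClassificationConfig | None = None,
) -> xr.Dataset:
    """Maps of agreement metrics pooled over time (pixel approach).

    For each pixel the full record of simultaneous change classes forms
    one contingency table; the result is an ``xarray.Dataset`` with one
    2-D variable per metric plus the case count ``n`` and
    ``processed_fraction`` (cases per available step).
    """
    lai_codes, fapar_codes = classify_stacks(lai, fapar, config)
    s, ny, nx = lai_codes.shape
    keep = (lai_codes > 0) & (fapar_codes > 0)
    cell = np.where(keep, (lai_codes - 1) * 3 + (fapar_codes - 1), 9)
    counts = np.zeros((9, ny, nx), dtype=np.int64)
    for c in range(9):
        counts[c] = (cell == c).sum(axis=0)
    counts = np.moveaxis(counts, 0, -1).reshape(ny, nx, 3, 3)
    res = metrics_from_counts(counts, processed=np.full((ny, nx), float(s)))
    data = {k: (("lat", "lon"), res[k])
            for k in (*METRIC_NAMES, "n", "processed_fraction")}
    return xr.Dataset(data, coords={"lat": lai.lat, "lon": lai.lon},
                      attrs={"cell_size": lai.cell_size, "crs": lai.crs})


def monthly_climatology(series: pd.DataFrame | pd.Series) -> pd.DataFrame:
    """Monthly climatological mean and standard deviation of metric series.

    Requires at least one full year of data.  Months are keyed by the
    composite start date of the series index.  Returns a frame indexed by
    calendar month (1-12) with MultiIndex columns (metric, mean|std);
    months with no data are missing, single-year months have zero spread.
    """
    df = series.to_frame() if isinstance(series, pd.Series) else series
    if not isinstance(df.index, pd.DatetimeIndex):
        raise TypeError("series must be indexed by composite dates")
    span = df.index.max() - df.index.min()
    if span < pd.Timedelta(days=360):
        raise ValueError("climatology needs at least one full year of data")
    # average within each (year, month) first, then take the climatological
    # mean and inter-annual spread across years
    yearly = df.groupby([df.index.year, df.index.month]).mean()
    yearly.index.names = ["year", "month"]
    grouped = yearly.groupby(level="month")
    mean = grouped.mean()
    std = grouped.std(ddof=0)
    out = pd.concat({"mean": mean, "std": std}, axis=1)
    out = out.swaplevel(axis=1).sort_index(axis=1)
    out.index.name = "month"
    return out


@dataclass(frozen=True)
class SeasonalMKResult:
    """Seasonal Mann-Kendall test result."""

    score: float         # summed Kendall S over seasons
    var_s: float         # tie-corrected variance of the score
    z: float
    p_value: float       # two-sided, normal approximation
    trend_sign: int      # -1, 0, +1 at the chosen alpha
    n_seasons_used: int


def _kendall_s(x: np.ndarray) -> tuple[float, float]:
    """Kendall S statistic and its tie-corrected variance for one season."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 2:
        return 0.0, 0.0
    diff = np.sign(x[None, :] - x[:, None])
    s = float(np.triu(diff, 1).sum())
    _, tie_counts = np.unique(x, return_counts=True)
    var = (n * (n - 1) * (2 * n + 5)
           - np.sum(tie_counts * (tie_counts - 1) * (2 * tie_counts + 5))) / 18.0
    return s, float(var)


def seasonal_mann_kendall(
    series: pd.Series,
    n_seasons: int = 12,
    alpha: float = 0.05,
) -> SeasonalMKResult:
    """Seasonal Mann-Kendall monotonic-trend test on a dated metric series.

    Observations are grouped into seasons by calendar month (``n_seasons``
    = 12) or by position within the year for coarser groupings; the
    Kendall S statistic and its tie-corrected variance are computed within
    each season and summed.  No inter-season covariance correction is
    applied.  Significance uses the continuity-corrected normal
    approximation, two-sided.

    Raises
    ------
    ValueError
        If the record spans fewer than two annual cycles.
    """
    if not isinstance(series.index, pd.DatetimeIndex):
        raise TypeError("series must be indexed by composite dates")
    span = series.index.max() - series.index.min()
    if span < pd.Timedelta(days=540):
        raise ValueError("seasonal Mann-Kendall needs at least two annual cycles")
    month = series.index.month
    if n_seasons == 12:
        season = month
    else:
        season = ((month - 1) * n_seasons // 12) + 1

    total_s = 0.0
    total_var = 0.0
    used = 0
    for g in np.unique(season):
        sub = series[season == g].sort_index()
        s, var = _kendall_s(sub.values)
        if var > 0:
            total_s += s
            total_var += var
            used += 1
    if total_var <= 0:
        # perfectly tied record in every season: no evidence of trend
        return SeasonalMKResult(0.0, 0.0, 0.0, 1.0, 0, used)
    if total_s > 0:
        z = (total_s - 1.0) / np.sqrt(total_var)
    elif total_s < 0:
        z = (total_s + 1.0) / np.sqrt(total_var)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    sign = 0
    if p < alpha:
        sign = 1 if total_s > 0 else -1
    return SeasonalMKResult(total_s, total_var, float(z), float(p), sign, used)


@dataclass(frozen=True)
class ProductComparison:
    """Welch and Kolmogorov-Smirnov two-sample comparison of metric maps."""

    welch_t: float
    welch_p: float
    ks_d: float
    ks_p: float
    n_a: int
    n_b: int


def compare_products(
    map_a: xr.Dataset,
    map_b: xr.Dataset,
    stratum: RegionSpec,
    metric: str = "OA",
) -> ProductComparison:
    """Test a metric's mean (Welch t) and distribution (KS) between products.

    Both metric maps are sampled at the stratum's pixels; NaN pixels are
    dropped independently per product.
    """
    a = np.asarray(map_a[metric].values)[stratum.membership]
    b = np.asarray(map_b[metric].values)[stratum.membership]
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two valid pixels per product")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        # identical degenerate samples: no difference by construction
        t, tp = 0.0, 1.0
    else:
        t, tp = stats.ttest_ind(a, b, equal_var=False)
    ks = stats.ks_2samp(a, b)
    return ProductComparison(float(t), float(tp), float(ks.statistic),
                             float(ks.pvalue), len(a), len(b))


def zonal_mean(
    field: xr.DataArray | np.ndarray,
    lat: np.ndarray | None = None,
    band_width: float = 1.0,
) -> pd.Series:
    """Area-unweighted latitude-band means of a 2-D metric field.

    Bands are half-open ``[edge, edge + band_width)`` anchored at integer
    multiples of the band width; bands with no valid pixel are missing.
    Returns a series indexed by the band's lower edge.
    """
    if isinstance(field, xr.DataArray):
        values = field.values
        lat = field["lat"].values if lat is None else lat
    else:
        values = np.asarray(field)
        if lat is None:
            raise ValueError("lat coordinates required for a plain array")
    if values.ndim != 2 or values.shape[0] != len(lat):
        raise ValueError("field must be 2-D with leading latitude axis")
    edges = np.floor(np.asarray(lat) / band_width) * band_width
    out: dict[float, float] = {}
    for e in np.unique(edges):
        rows = values[edges == e]
        valid = rows[np.isfinite(rows)]
        out[float(e)] = float(valid.mean()) if valid.size else np.nan
    s = pd.Series(out).sort_index()
    s.index.name = "lat_band"
    return s
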