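"""Raster time-series container for one ECV: values + uncertainties on a grid."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

__all__ = ["GriddedStack", "RegionSpec"]


@dataclass
class GriddedStack:
    """A (time, y, x) cube of ECV values with per-observation uncertainties.

    Attributes
    ----------
    values, uncertainties : ndarray, shape (T, ny, nx)
        ECV magnitudes and one-sigma half-widths; NaN where missing.
    mask : ndarray of bool, shape (T, ny, nx)
        True where the observation is valid.
    times : pandas.DatetimeIndex, length T
        Composite start dates, strictly increasing.
    lat, lon : ndarray, shape (ny,), (nx,)
        Cell-centre coordinates in degrees.
    cell_size : float
        Grid spacing in degrees (square cells assumed).
    variable : str
        ECV name, e.g. ``"lai"`` or ``"fapar"``.
    crs : str
        Coordinate reference tag (plain-text, e.g. ``"EPSG:4326"``).
    """

    values: np.ndarray
    uncertainties: np.ndarray
    times: pd.DatetimeIndex
    lat: np.ndarray
    lon: np.ndarray
    cell_size: float
    variable: str = "ecv"
    crs: str = "EPSG:4326"
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.uncertainties = np.asarray(self.uncertainties, dtype=float)
        self.times = pd.DatetimeIndex(self.times)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        if self.values.shape != self.uncertainties.shape:
            raise ValueError("values and uncertainties shapes differ")
        if self.values.ndim != 3:
            raise ValueError("expected a (time, y, x) cube")
        t, ny, nx = self.values.shape
        if len(self.times) != t or len(self.lat) != ny or len(self.lon) != nx:
            raise ValueError("coordinate lengths do not match cube shape")
        if len(self.times) > 1 and not self.times.is_monotonic_increasing:
            raise ValueError("timestamps must be strictly increasing")
        if self.mask is None:
            self.mask = np.isfinite(self.values) & np.isfinite(self.uncertainties)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape differs from values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def masked_values(self) -> np.ndarray:
        """Values with invalid observations replaced by NaN."""
        return np.where(self.mask, self.values, np.nan)

    def masked_uncertainties(self) -> np.ndarray:
        return np.where(self.mask, self.uncertainties, np.nan)

    def time_slice(self, start=None, stop=None) -> "GriddedStack":
        """Subset the record to composite dates in [start, stop]."""
        sel = np.ones(len(self.times), dtype=bool)
        if start is not None:
            sel &= self.times >= pd.Timestamp(start)
        if stop is not None:
            sel &= self.times <= pd.Timestamp(stop)
        return GriddedStack(values=self.values[sel],
                            uncertainties=self.uncertainties[sel],
                            times=self.times[sel], lat=self.lat, lon=self.lon,
                            cell_size=self.cell_size, variable=self.variable,
                            crs=self.crs, mask=self.mask[sel])

    def check_aligned(self, other: "GriddedStack") -> None:
        """Raise unless two stacks share grid and time axis."""
        if self.shape != other.shape:
            raise ValueError(f"grid mismatch: {self.shape} vs {other.shape}")
        if not np.allclose(self.lat, other.lat) or not np.allclose(self.lon, other.lon):
            raise ValueError("grid coordinates differ between stacks")
        if not self.times.equals(other.times):
            raise ValueError("time axes differ between stacks")

    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {
                "value": (("time", "lat", "lon"), self.values),
                "uncertainty": (("time", "lat", "lon"), self.uncertainties),
                "valid": (("time", "lat", "lon"), self.mask.astype(np.int8)),
            },
            coords={"time": self.times, "lat": self.lat, "lon": self.lon},
            attrs={"variable": self.variable, "cell_size": self.cell_size,
                   "crs": self.crs},
        )

    @classmethod
    def from_dataset(cls, ds: xr.Dataset, variable: str | None = None) -> "GriddedStack":
        if "uncertainty" not in ds:
            raise ValueError(
                "dataset lacks an 'uncertainty' variable; the framework "
                "cannot operate without per-observation uncertainties")
        lat = ds["lat"].values
        lon = ds["lon"].values
        cell = float(ds.attrs.get("cell_size",
                                  abs(lat[1] - lat[0]) if len(lat) > 1 else 1.0))
        mask = None
        if "valid" in ds:
            mask = ds["valid"].values.astype(bool)
        return cls(
            values=ds["value"].values,
            uncertainties=ds["uncertainty"].values,
            times=pd.DatetimeIndex(ds["time"].values),
            lat=lat, lon=lon, cell_size=cell,
            variable=variable or ds.attrs.get("variable", "ecv"),
            crs=ds.attrs.get("crs", "EPSG:4326"),
            mask=mask,
        )


@dataclass(frozen=True)
class RegionSpec:
    """A labelled pixel stratum, e.g. one land-cover class in one region."""

    label: str
    membership: np.ndarray  # bool (ny, nx)

    def __post_init__(self) -> None:
        m = np.asarray(self.membership, dtype=bool)
        if m.ndim != 2:
            raise ValueError("membership must be a 2-D pixel mask")
        if not m.any():
            raise ValueError(f"region {self.label!r} has empty membership")
        object.__setattr__(self, "membership", m)

    @property
    def n_pixels(self) -> int:
        return int(self.membership.sum())
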