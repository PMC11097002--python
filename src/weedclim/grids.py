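"""Regular lon/lat grids of monthly (or static) environmental variables.

A :class:`MonthlyGrid` holds one variable — land-surface temperature in
degrees Celsius, root-zone soil-moisture percentile, elevation in metres,
or a harvested-area layer — on a regular longitude/latitude grid with an
optional contiguous monthly time axis.  Missing values are ``NaN``.
Point lookups use nearest-cell sampling (ties broken toward the lower
index) and never extrapolate outside the grid's bounding box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

from .errors import ConfigError, DataError

__all__ = ["MonthlyGrid", "month_index", "index_to_month"]

#: Recognized variable kinds (informational; not enforced beyond RZSM range).
VARIABLES = ("LST_C", "LST_K_SCALED", "RZSM_PCT", "ELEV_M", "CROP_AREA")


def month_index(year: int, month: int) -> int:
    """Months since year 0, a convenient integer time coordinate."""
    return int(year) * 12 + (int(month) - 1)


def index_to_month(idx: int) -> tuple[int, int]:
    return idx // 12, idx % 12 + 1


def _check_axis(axis: np.ndarray, name: str) -> None:
    if axis.ndim != 1 or axis.size < 1:
        raise ConfigError(f"{name} axis must be 1-D and non-empty")
    if axis.size > 1:
        steps = np.diff(axis)
        if steps[0] <= 0 or np.any(np.abs(steps - steps[0]) > 1e-9):
            raise ConfigError(f"{name} axis must be strictly increasing and regular")


@dataclass
class MonthlyGrid:
    """One gridded variable, optionally resolved monthly.

    Parameters
    ----------
    variable : str
        Variable kind, e.g. ``"LST_C"`` or ``"ELEV_M"``.
    lon, lat : ndarray
        Regular, strictly increasing cell-centre axes in degrees.
    values : ndarray
        Shape ``(n_times, n_lat, n_lon)`` for monthly variables or
        ``(n_lat, n_lon)`` for static ones; NaN marks missing cells.
    start : (year, month) or None
        First month of the time axis; ``None`` for static grids.
    scale, offset : float
        Linear digital-number decoding, used only for ``LST_K_SCALED``.
    """

    variable: str
    lon: np.ndarray
    lat: np.ndarray
    values: np.ndarray
    start: tuple[int, int] | None = None
    scale: float = 1.0
    offset: float = 0.0
    attrs: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        _check_axis(self.lon, "lon")
        _check_axis(self.lat, "lat")
        if self.static:
            if self.values.shape != (self.lat.size, self.lon.size):
                raise ConfigError(
                    f"static grid shape {self.values.shape} does not match axes "
                    f"({self.lat.size}, {self.lon.size})"
                )
        else:
            if self.values.ndim != 3 or self.values.shape[1:] != (self.lat.size, self.lon.size):
                raise ConfigError(
                    f"monthly grid shape {self.values.shape} does not match axes"
                )
            y, m = self.start
            if not 1 <= m <= 12:
                raise ConfigError(f"start month {m} not in 1..12")
        if self.variable == "RZSM_PCT":
            vals = self.values[np.isfinite(self.values)]
            if vals.size and (vals.min() < 0 or vals.max() > 100):
                raise DataError("RZSM_PCT values must lie in [0, 100]")

    # ------------------------------------------------------------------
    @property
    def static(self) -> bool:
        return self.start is None

    @property
    def n_times(self) -> int:
        return 0 if self.static else self.values.shape[0]

    def times(self) -> list[tuple[int, int]]:
        """The (year, month) sequence covered by the time axis."""
        if self.static:
            return []
        i0 = month_index(*self.start)
        return [index_to_month(i0 + k) for k in range(self.n_times)]

    def time_slot(self, year: int, month: int) -> int | None:
        """Index into the time axis, or None if outside coverage."""
        if self.static:
            return None
        k = month_index(year, month) - month_index(*self.start)
        return k if 0 <= k < self.n_times else None

    # ------------------------------------------------------------------
    @staticmethod
    def _nearest(axis: np.ndarray, x) -> np.ndarray:
        """Nearest index on a regular axis; ties go to the lower index.

        Returns -1 for points outside [first - d/2, last + d/2].
        """
        x = np.asarray(x, dtype=float)
        d = axis[1] - axis[0] if axis.size > 1 else 1.0
        f = (x - axis[0]) / d
        idx = np.ceil(f - 0.5).astype(int)  # exact half-way -> lower cell
        bad = ~np.isfinite(x) | (f < -0.5) | (f > axis.size - 0.5)
        return np.where(bad, -1, np.clip(idx, 0, axis.size - 1))

    def cell_index(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """(iy, ix) nearest-cell indices; -1 where out of bounds/missing."""
        return self._nearest(self.lat, lat), self._nearest(self.lon, lon)

    def sample(self, lon: float, lat: float, year: int | None = None,
               month: int | None = None) -> float:
        """Nearest-cell value at a point, NaN when unresolvable.

        A time passed to a static grid is ignored; a monthly grid queried
        outside its time coverage or bounding box yields NaN.
        """
        iy, ix = self.cell_index(lon, lat)
        iy, ix = int(iy), int(ix)
        if iy < 0 or ix < 0:
            return float("nan")
        if self.static:
            return float(self.values[iy, ix])
        if year is None or month is None:
            raise DataError(f"monthly grid {self.variable!r} requires year and month")
        t = self.time_slot(year, month)
        if t is None:
            return float("nan")
        return float(self.values[t, iy, ix])

    # ------------------------------------------------------------------
    def to_dataset(self) -> xr.Dataset:
        if self.static:
            da = xr.DataArray(self.values, dims=("lat", "lon"),
                              coords={"lat": self.lat, "lon": self.lon})
        else:
            t0 = month_index(*self.start)
            da = xr.DataArray(
                self.values, dims=("time", "lat", "lon"),
                coords={"time": np.arange(t0, t0 + self.n_times),
                        "lat": self.lat, "lon": self.lon},
            )
            da.attrs["time_units"] = "months since year 0 (year*12 + month-1)"
        da.attrs.update(variable=self.variable, scale=self.scale, offset=self.offset)
        return da.to_dataset(name=self.variable.lower())

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "MonthlyGrid":
        name = list(ds.data_vars)[0]
        da = ds[name]
        start = None
        if "time" in da.dims:
            start = index_to_month(int(da.time.values[0]))
            t = np.asarray(da.time.values, dtype=int)
            if np.any(np.diff(t) != 1):
                raise DataError("time axis must be contiguous monthly")
        return cls(
            variable=str(da.attrs.get("variable", name.upper())),
            lon=da.lon.values, lat=da.lat.values, values=da.values, start=start,
            scale=float(da.attrs.get("scale", 1.0)),
            offset=float(da.attrs.get("offset", 0.0)),
        )

    @classmethod
    def from_netcdf(cls, path) -> "MonthlyGrid":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())
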