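"""Gridded ocean-current container for larval drift simulation.

A :class:`FlowField` holds horizontal (and optionally vertical) velocities on
a regular lon/lat/depth/time grid with a land mask, mirroring what a daily-mean
hindcast archive provides once regridded to z-levels. Velocities are
interpolated trilinearly in space and linearly in time between daily means.

IO is CF-style netCDF through xarray (NETCDF3 via the scipy backend), so
fields round-trip with standard tooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from scipy.interpolate import RegularGridInterpolator

__all__ = ["FlowField"]

EARTH_RADIUS_M = 6_371_000.0


def _check_axis(name: str, ax: np.ndarray) -> None:
    if ax.ndim != 1 or ax.size == 0:
        raise ValueError(f"{name} axis must be 1-D and nonempty")
    if ax.size > 1 and not np.all(np.diff(ax) > 0):
        raise ValueError(f"{name} axis must be strictly increasing")


def _pad_axis(ax: np.ndarray) -> np.ndarray:
    """Duplicate a length-1 axis so linear interpolation is well defined."""
    if ax.size > 1:
        return ax
    return np.array([ax[0], ax[0] + 1.0])


def _pad_data(a: np.ndarray) -> np.ndarray:
    for dim in range(a.ndim):
        if a.shape[dim] == 1:
            a = np.concatenate([a, a], axis=dim)
    return a


@dataclass
class FlowField:
    """Regular-grid velocity field (time, depth, lat, lon) with a land mask.

    Parameters
    ----------
    lon, lat
        Regular axes, degrees east / north, strictly increasing.
    depth
        Metres, positive down, strictly increasing.
    time
        Calendar timestamps of the (daily-mean) fields.
    u, v
        Eastward / northward velocity, m s^-1, shaped
        ``(time, depth, lat, lon)``.
    w
        Optional vertical velocity (kept for completeness of the data model;
        larval vertical motion is behavioral and never uses it).
    land_mask
        Boolean ``(lat, lon)``; True marks land. Masked cells must carry zero
        velocity.
    max_speed
        Speed cap in m s^-1 (default 1.0, the maximum observed for the
        Norwegian Coastal Current); construction fails if exceeded.
    """

    lon: np.ndarray
    lat: np.ndarray
    depth: np.ndarray
    time: np.ndarray
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray | None = None
    land_mask: np.ndarray | None = None
    max_speed: float = 1.0
    _interp_u: RegularGridInterpolator = field(init=False, repr=False, default=None)
    _interp_v: RegularGridInterpolator = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        self.time = pd.DatetimeIndex(pd.to_datetime(self.time))
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.w is not None:
            self.w = np.asarray(self.w, dtype=float)

        _check_axis("lon", self.lon)
        _check_axis("lat", self.lat)
        _check_axis("depth", self.depth)
        if len(self.time) > 1 and not self.time.is_monotonic_increasing:
            raise ValueError("time axis must be increasing")

        shape = (len(self.time), self.depth.size, self.lat.size, self.lon.size)
        for name, arr in (("u", self.u), ("v", self.v)):
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")

        speed = np.hypot(self.u, self.v)
        if speed.max(initial=0.0) > self.max_speed + 1e-12:
            raise ValueError(
                f"speed {speed.max():.3f} m/s exceeds max_speed {self.max_speed}"
            )

        if self.land_mask is None:
            self.land_mask = np.zeros((self.lat.size, self.lon.size), dtype=bool)
        else:
            self.land_mask = np.asarray(self.land_mask, dtype=bool)
            if self.land_mask.shape != (self.lat.size, self.lon.size):
                raise ValueError("land_mask must be shaped (lat, lon)")
            if np.any(speed[:, :, self.land_mask] != 0.0):
                raise ValueError("masked (land) cells must have zero velocity")

        self._build_interpolators()

    # ------------------------------------------------------------------ #

    @property
    def time_seconds(self) -> np.ndarray:
        """Time axis as seconds since the first field."""
        return (self.time.asi8 - self.time.asi8[0]) / 1e9

    def seconds_since_start(self, t) -> float:
        return (pd.Timestamp(t).value - self.time.asi8[0]) / 1e9

    def _build_interpolators(self) -> None:
        axes = (
            _pad_axis(self.time_seconds),
            _pad_axis(self.depth),
            _pad_axis(self.lat),
            _pad_axis(self.lon),
        )
        self._interp_u = RegularGridInterpolator(
            axes, _pad_data(self.u), method="linear", bounds_error=False, fill_value=np.nan
        )
        self._interp_v = RegularGridInterpolator(
            axes, _pad_data(self.v), method="linear", bounds_error=False, fill_value=np.nan
        )

    def velocity(self, t_seconds, lon, lat, depth):
        """Interpolate (u, v) in m s^-1 at scattered points.

        Time and depth queries are clamped to the grid span (daily means are
        held constant beyond the ends of the day axis); horizontal queries
        outside the grid return NaN, which the stepper treats as domain exit.
        """
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        depth = np.broadcast_to(np.asarray(depth, dtype=float), lon.shape)
        ts = self.time_seconds
        t = np.clip(np.broadcast_to(np.asarray(t_seconds, dtype=float), lon.shape),
                    ts[0], ts[-1])
        z = np.clip(depth, self.depth[0], self.depth[-1])
        pts = np.column_stack([t, z, lat, lon])
        return self._interp_u(pts), self._interp_v(pts)

    def in_domain(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.lon[0]) & (lon <= self.lon[-1])
            & (lat >= self.lat[0]) & (lat <= self.lat[-1])
        )

    def is_land(self, lon, lat):
        """Nearest-cell land test (out-of-domain points are not land)."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        ix = np.clip(np.rint(np.interp(lon, self.lon, np.arange(self.lon.size))).astype(int), 0, self.lon.size - 1)
        iy = np.clip(np.rint(np.interp(lat, self.lat, np.arange(self.lat.size))).astype(int), 0, self.lat.size - 1)
        out = self.land_mask[iy, ix] & self.in_domain(lon, lat)
        return out

    # ------------------------------- IO -------------------------------- #

    def to_dataset(self) -> xr.Dataset:
        data = {
            "u": (("time", "depth", "lat", "lon"), self.u),
            "v": (("time", "depth", "lat", "lon"), self.v),
            "land_mask": (("lat", "lon"), self.land_mask.astype(np.int8)),
        }
        if self.w is not None:
            data["w"] = (("time", "depth", "lat", "lon"), self.w)
        ds = xr.Dataset(
            data,
            coords={"time": self.time, "depth": self.depth,
                    "lat": self.lat, "lon": self.lon},
            attrs={"max_speed": self.max_speed},
        )
        ds["u"].attrs.update(units="m s-1", long_name="eastward velocity")
        ds["v"].attrs.update(units="m s-1", long_name="northward velocity")
        ds["depth"].attrs.update(units="m", positive="down")
        return ds

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "FlowField":
        return cls(
            lon=ds["lon"].values,
            lat=ds["lat"].values,
            depth=ds["depth"].values,
            time=ds["time"].values,
            u=ds["u"].values,
            v=ds["v"].values,
            w=ds["w"].values if "w" in ds else None,
            land_mask=ds["land_mask"].values.astype(bool) if "land_mask" in ds else None,
            max_speed=float(ds.attrs.get("max_speed", 1.0)),
        )

    @classmethod
    def from_netcdf(cls, path) -> "FlowField":
        with xr.open_dataset(Path(path), engine="scipy") as ds:
            return cls.from_dataset(ds.load())
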