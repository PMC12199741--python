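"""Gridded surface-velocity fields.

A :class:`VelocityField` holds eastward/northward surface currents ``u``/``v``
(m/s) on a regular lon–lat grid with daily (or other) time snapshots, plus a
boolean land mask.  Longitudes are normalised to the [0, 360) convention
everywhere inside the package because the study domain spans the antimeridian;
interpolation wraps across the 0/360 seam.

Sampling is bilinear in space and linear in time.  Masked (land) nodes
contribute zero velocity to the interpolation so that coastal queries never
propagate NaN; what a particle does near a coast is the transport module's
decision, not the field's.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import xarray as xr

from .errors import FieldFormatError, OutOfRangeError, ValidationError

#: metres per degree of latitude on the sphere used throughout the package
M_PER_DEG = 111_195.0

#: sphere radius for great-circle distances, km
EARTH_RADIUS_KM = 6371.0

_DEFAULT_VARS = {"u": "water_u", "v": "water_v", "lon": "lon", "lat": "lat", "time": "time"}


def wrap_lon(lon):
    """Map longitudes into [0, 360)."""
    return np.asarray(lon, dtype=float) % 360.0


def to_seconds(t):
    """Convert timestamps (datetime64, ISO strings, datetimes) to float POSIX seconds."""
    arr = np.asarray(t)
    if arr.dtype.kind in "fiu":
        return arr.astype(float)
    return arr.astype("datetime64[s]").astype("int64").astype(float)


def seconds_to_datetime(sec):
    """Inverse of :func:`to_seconds` (to the whole second)."""
    return np.asarray(np.round(np.asarray(sec)), dtype="int64").astype("datetime64[s]")


@dataclass
class VelocityField:
    """Surface currents on a lon(0–360)/lat/time grid.

    Parameters
    ----------
    lon, lat : 1-D arrays, degrees; strictly ascending (lon after wrap
        normalisation).
    time : 1-D array of datetime64, ascending.
    u, v : arrays shaped (time, lat, lon), m/s.  May hold NaN on land.
    land_mask : boolean (lat, lon); True = land.
    """

    lon: np.ndarray
    lat: np.ndarray
    time: np.ndarray
    u: np.ndarray
    v: np.ndarray
    land_mask: np.ndarray = None
    _tsec: np.ndarray = dc_field(init=False, repr=False)
    _u0: np.ndarray = dc_field(init=False, repr=False)
    _v0: np.ndarray = dc_field(init=False, repr=False)

    def __post_init__(self):
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.time = np.asarray(self.time, dtype="datetime64[s]")
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.land_mask is None:
            self.land_mask = np.zeros((self.lat.size, self.lon.size), dtype=bool)
        self.land_mask = np.asarray(self.land_mask, dtype=bool)

        if np.any(self.lon < 0) or np.any(self.lon >= 360):
            raise ValidationError("longitudes must lie in [0, 360)")
        for name, ax in (("lon", self.lon), ("lat", self.lat)):
            if ax.ndim != 1 or ax.size < 2 or np.any(np.diff(ax) <= 0):
                raise ValidationError(f"{name} axis must be 1-D and strictly ascending")
        if self.time.ndim != 1 or (self.time.size > 1 and np.any(np.diff(self.time) <= np.timedelta64(0, "s"))):
            raise ValidationError("time axis must be strictly ascending")
        shape = (self.time.size, self.lat.size, self.lon.size)
        if self.u.shape != shape or self.v.shape != shape:
            raise ValidationError(f"u/v must have shape {shape} (time, lat, lon)")
        if self.land_mask.shape != (self.lat.size, self.lon.size):
            raise ValidationError("land_mask must have shape (lat, lon)")
        sea = ~self.land_mask
        if not (np.all(np.isfinite(self.u[:, sea])) and np.all(np.isfinite(self.v[:, sea]))):
            raise ValidationError("u and v must be finite at all sea nodes")

        self._tsec = to_seconds(self.time)
        mask3 = np.broadcast_to(self.land_mask, shape)
        self._u0 = np.where(mask3, 0.0, self.u)
        self._v0 = np.where(mask3, 0.0, self.v)

    # ------------------------------------------------------------------
    @property
    def time_range(self):
        """(start, end) of the time axis as datetime64[s]."""
        return self.time[0], self.time[-1]

    @property
    def is_global_lon(self) -> bool:
        """True when the longitude axis covers the full circle (wraps)."""
        n = self.lon.size
        span = self.lon[-1] - self.lon[0]
        return bool(span + span / max(n - 1, 1) >= 360.0 - 1e-9)

    def lon_in_domain(self, lon) -> np.ndarray:
        """Whether longitudes fall inside the grid's zonal extent (always True
        for global grids)."""
        lon = np.asarray(lon, dtype=float)
        if self.is_global_lon:
            return np.ones(lon.shape, dtype=bool)
        q = wrap_lon(lon)
        return (q >= self.lon[0]) & (q <= self.lon[-1])

    def _lon_bracket(self, lon):
        """Wrap-aware bracketing node indices and fraction for longitude."""
        q = wrap_lon(lon)
        n = self.lon.size
        j = np.searchsorted(self.lon, q, side="right")
        j0 = (j - 1) % n
        j1 = j % n
        lon0 = self.lon[j0]
        span = (self.lon[j1] - lon0) % 360.0
        span = np.where(span == 0.0, 360.0, span)
        frac = ((q - lon0) % 360.0) / span
        return j0, j1, frac

    def _lat_bracket(self, lat):
        lat = np.asarray(lat, dtype=float)
        if np.any(lat < self.lat[0]) or np.any(lat > self.lat[-1]):
            raise OutOfRangeError("latitude outside grid range")
        i = np.clip(np.searchsorted(self.lat, lat, side="right"), 1, self.lat.size - 1)
        i0, i1 = i - 1, i
        frac = (lat - self.lat[i0]) / (self.lat[i1] - self.lat[i0])
        return i0, i1, frac

    def _time_bracket(self, tsec):
        tsec = np.asarray(tsec, dtype=float)
        if np.any(tsec < self._tsec[0]) or np.any(tsec > self._tsec[-1]):
            raise OutOfRangeError("time outside field range")
        if self._tsec.size == 1:
            z = np.zeros_like(tsec, dtype=int)
            return z, z, np.zeros_like(tsec)
        k = np.clip(np.searchsorted(self._tsec, tsec, side="right"), 1, self._tsec.size - 1)
        k0, k1 = k - 1, k
        frac = (tsec - self._tsec[k0]) / (self._tsec[k1] - self._tsec[k0])
        return k0, k1, frac

    def sample(self, lon, lat, t):
        """Interpolated (u, v) in m/s at the given positions and time(s).

        Bilinear in lon/lat (wrapping across the 0/360 seam), linear in time.
        Land nodes contribute (0, 0).  Raises :class:`OutOfRangeError` for
        times or latitudes outside the grid.
        """
        j0, j1, fx = self._lon_bracket(lon)
        i0, i1, fy = self._lat_bracket(lat)
        k0, k1, ft = self._time_bracket(to_seconds(t))

        def interp(arr):
            out = 0.0
            for kk, wt in ((k0, 1.0 - ft), (k1, ft)):
                plane = (
                    arr[kk, i0, j0] * (1 - fx) * (1 - fy)
                    + arr[kk, i0, j1] * fx * (1 - fy)
                    + arr[kk, i1, j0] * (1 - fx) * fy
                    + arr[kk, i1, j1] * fx * fy
                )
                out = out + wt * plane
            return out

        return interp(self._u0), interp(self._v0)

    def is_land(self, lon, lat):
        """Nearest-node land-mask lookup, wrap-aware in longitude.

        A query equidistant between nodes counts as land if *any* of the
        tied nearest nodes is land.
        """
        j0, j1, fx = self._lon_bracket(lon)
        i0, i1, fy = self._lat_bracket(lat)
        out = np.zeros(np.broadcast(np.asarray(lon), np.asarray(lat)).shape, dtype=bool)
        for jj, wj in ((j0, fx <= 0.5), (j1, fx >= 0.5)):
            for ii, wi in ((i0, fy <= 0.5), (i1, fy >= 0.5)):
                out |= wj & wi & self.land_mask[ii, jj]
        if out.ndim == 0:
            return bool(out)
        return out


# ----------------------------------------------------------------------
# NetCDF I/O (CF-style axes; NetCDF3 dialect via xarray's scipy engine)


def write_velocity_field(field: VelocityField, path, variables=None):
    """Write a field to NetCDF with land encoded as NaN.

    Emits the same dialect :func:`read_velocity_field` consumes, so synthetic
    and externally supplied forcing are interchangeable.
    """
    names = dict(_DEFAULT_VARS, **(variables or {}))
    mask3 = np.broadcast_to(field.land_mask, field.u.shape)
    ds = xr.Dataset(
        {
            names["u"]: ((names["time"], names["lat"], names["lon"]), np.where(mask3, np.nan, field.u)),
            names["v"]: ((names["time"], names["lat"], names["lon"]), np.where(mask3, np.nan, field.v)),
        },
        coords={
            names["lon"]: field.lon,
            names["lat"]: field.lat,
            names["time"]: field.time.astype("datetime64[ns]"),
        },
    )
    ds[names["lon"]].attrs.update(units="degrees_east", standard_name="longitude")
    ds[names["lat"]].attrs.update(units="degrees_north", standard_name="latitude")
    ds[names["u"]].attrs.update(units="m s-1")
    ds[names["v"]].attrs.update(units="m s-1")
    ds.to_netcdf(path, engine="scipy")


def read_velocity_field(path, variables=None, lon_convention="0_360") -> VelocityField:
    """Read a CF-style NetCDF surface-current file.

    Parameters
    ----------
    variables : mapping, optional
        Overrides for variable/axis names; defaults are ``water_u``/``water_v``
        with ``lon``/``lat``/``time`` axes.
    lon_convention : {"0_360", "signed_180"}
        Convention of the file's longitudes.  ``signed_180`` input is remapped
        into [0, 360) with the data columns reordered to keep axes ascending.
    """
    if lon_convention not in ("0_360", "signed_180"):
        raise ValidationError(f"unknown longitude convention {lon_convention!r}")
    names = dict(_DEFAULT_VARS, **(variables or {}))
    with xr.open_dataset(path, engine="scipy") as ds:
        for key in ("u", "v", "lon", "lat", "time"):
            if names[key] not in ds.variables:
                raise FieldFormatError(f"variable {names[key]!r} not found in {path}")
        lon = np.asarray(ds[names["lon"]].values, dtype=float)
        lat = np.asarray(ds[names["lat"]].values, dtype=float)
        time = np.asarray(ds[names["time"]].values)
        u = np.asarray(ds[names["u"]].values, dtype=float)
        v = np.asarray(ds[names["v"]].values, dtype=float)

    lon = wrap_lon(lon)
    order = np.argsort(lon, kind="stable")
    lon = lon[order]
    if np.any(np.diff(lon) <= 0):
        raise ValidationError("longitude axis not strictly monotone after wrap normalisation")
    u = u[:, :, order]
    v = v[:, :, order]

    if np.any(np.diff(lat) < 0):  # some products store lat descending
        lat = lat[::-1]
        u = u[:, ::-1, :]
        v = v[:, ::-1, :]
    if np.any(np.diff(lat) <= 0):
        raise ValidationError("latitude axis not strictly monotone")

    land = ~np.isfinite(u).all(axis=0) | ~np.isfinite(v).all(axis=0)
    u = np.where(np.broadcast_to(land, u.shape), np.nan, u)
    v = np.where(np.broadcast_to(land, v.shape), np.nan, v)
    return VelocityField(lon=lon, lat=lat, time=time, u=u, v=v, land_mask=land)
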