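"""Gridded meteorology in the terrain-following z* coordinate.

The vertical coordinate used throughout the package is

    z* = (z - z_g) * z_t / (z_t - z_g)

where ``z`` is geometric height, ``z_g`` the local terrain height and ``z_t``
the model-top height. z* equals 0 at the ground and ``z_t`` at the model top
everywhere, which lets a single set of vertical levels follow the terrain.

A :class:`MetSeries` holds hourly gridded horizontal wind (u, v), vertical
velocity in the z* coordinate (w*), air temperature (degC) and the vertical
diffusion coefficient Kz* (m2/s), all on one (time, level, lat, lon) grid.
Interpolation is linear in time and trilinear in space, which is exact at the
grid nodes and bounded by the surrounding node values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import xarray as xr
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "GridSpec",
    "MetSeries",
    "MetSample",
    "MetFormatError",
    "MetValidationError",
    "OutOfDomainError",
    "zstar_of",
    "z_of",
    "load_met",
    "save_met",
    "interp",
    "kz_gradient",
]

HOUR_S = 3600.0


class MetFormatError(ValueError):
    """A met file does not follow the documented convention."""


class MetValidationError(ValueError):
    """Field values or coordinates violate a MetSeries invariant."""


class OutOfDomainError(Exception):
    """A query point lies outside the gridded domain (space or time)."""


def zstar_of(z, z_g, z_t):
    """Terrain-following height z* of geometric height ``z``.

    Parameters are in metres; ``z`` must lie in [z_g, z_t] and z_g < z_t.
    """
    z = np.asarray(z, dtype=float)
    z_g = np.asarray(z_g, dtype=float)
    z_t = np.asarray(z_t, dtype=float)
    if np.any(z_g >= z_t):
        raise ValueError("terrain height z_g must be below the model top z_t")
    if np.any(z < z_g) or np.any(z > z_t):
        raise ValueError("z outside [z_g, z_t]")
    out = (z - z_g) * z_t / (z_t - z_g)
    return float(out) if out.ndim == 0 else out


def z_of(zstar, z_g, z_t):
    """Geometric height of terrain-following height ``zstar`` (inverse of zstar_of)."""
    zstar = np.asarray(zstar, dtype=float)
    z_g = np.asarray(z_g, dtype=float)
    z_t = np.asarray(z_t, dtype=float)
    if np.any(z_g >= z_t):
        raise ValueError("terrain height z_g must be below the model top z_t")
    if np.any(zstar < 0) or np.any(zstar > z_t):
        raise ValueError("z* outside [0, z_t]")
    out = z_g + zstar * (z_t - z_g) / z_t
    return float(out) if out.ndim == 0 else out


def _strictly_increasing(a: np.ndarray) -> bool:
    return a.ndim == 1 and a.size >= 1 and bool(np.all(np.diff(a) > 0))


@dataclass(frozen=True)
class GridSpec:
    """Horizontal/vertical grid geometry shared by all met variables.

    lats/lons are degrees north/east, strictly increasing. ``levels`` are z*
    heights in metres, strictly increasing, within [0, z_top]. ``terrain`` is
    the ground height z_g (m) per (lat, lon) cell.
    """

    lats: np.ndarray
    lons: np.ndarray
    levels: np.ndarray
    z_top: float
    terrain: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lats", np.asarray(self.lats, dtype=float))
        object.__setattr__(self, "lons", np.asarray(self.lons, dtype=float))
        object.__setattr__(self, "levels", np.asarray(self.levels, dtype=float))
        object.__setattr__(self, "terrain", np.asarray(self.terrain, dtype=float))
        for name in ("lats", "lons", "levels"):
            if not _strictly_increasing(getattr(self, name)):
                raise MetValidationError(f"{name} must be 1-D and strictly increasing")
        if self.levels[0] < 0 or self.levels[-1] > self.z_top:
            raise MetValidationError("levels must lie within [0, z_top]")
        if self.terrain.shape != (self.lats.size, self.lons.size):
            raise MetValidationError("terrain must have shape (nlat, nlon)")
        if not np.all(np.isfinite(self.terrain)):
            raise MetValidationError("terrain must be finite")
        if np.any(self.terrain < 0) or np.any(self.terrain >= self.z_top):
            raise MetValidationError("terrain must satisfy 0 <= z_g < z_top")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.levels.size, self.lats.size, self.lons.size)

    def contains(self, lat, lon) -> np.ndarray:
        """Vectorised horizontal bounding-box test (edges inclusive)."""
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        return (
            (lat >= self.lats[0])
            & (lat <= self.lats[-1])
            & (lon >= self.lons[0])
            & (lon <= self.lons[-1])
        )


class MetSample(NamedTuple):
    u: float
    v: float
    w_star: float
    temp: float
    kz: float


_VARS = ("u", "v", "w_star", "temp", "kz")


@dataclass
class MetSeries:
    """Hourly gridded meteorology on a fixed grid.

    All five variables share the shape (ntime, nlevel, nlat, nlon). Times are
    UTC instants at exactly 1 h spacing (the cadence the forecast chain
    produces; other cadences are rejected rather than resampled).
    """

    grid: GridSpec
    times: np.ndarray  # datetime64[ns], uniform 1 h spacing
    u: np.ndarray
    v: np.ndarray
    w_star: np.ndarray
    temp: np.ndarray
    kz: np.ndarray
    _samplers: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        for name in _VARS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    def validate(self) -> None:
        if self.times.size < 2:
            raise MetValidationError("a MetSeries needs at least 2 time instants")
        steps = np.diff(self.times).astype("timedelta64[s]").astype(float)
        if not np.all(steps == HOUR_S):
            raise MetValidationError(
                "time step must be exactly 1 h (got steps "
                f"{sorted(set(steps))} s)"
            )
        expected = (self.times.size,) + self.grid.shape
        for name in _VARS:
            arr = getattr(self, name)
            if arr.shape != expected:
                raise MetValidationError(
                    f"variable {name!r} has shape {arr.shape}, expected {expected}"
                )
        if np.any(self.kz < 0):
            raise MetValidationError("kz must be non-negative everywhere")

    # -- interpolation ----------------------------------------------------

    def _seconds(self, t) -> np.ndarray:
        t = np.asarray(t, dtype="datetime64[ns]")
        return (t - self.times[0]) / np.timedelta64(1, "s")

    def _sampler(self, name: str) -> RegularGridInterpolator:
        """Linear space-time interpolator for one variable (cached).

        Out-of-domain queries return NaN, which callers treat as the
        out-of-domain signal.
        """
        if name not in self._samplers:
            if name == "dkz":
                values = np.gradient(self.kz, self.grid.levels, axis=1)
            else:
                values = getattr(self, name)
            tsec = self._seconds(self.times)
            self._samplers[name] = RegularGridInterpolator(
                (tsec, self.grid.levels, self.grid.lats, self.grid.lons),
                values,
                method="linear",
                bounds_error=False,
                fill_value=np.nan,
            )
        return self._samplers[name]

    def sample(self, t, lat, lon, zstar, names=_VARS) -> dict[str, np.ndarray]:
        """Vectorised interpolation at scattered points; NaN means out of domain."""
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        zstar = np.atleast_1d(np.asarray(zstar, dtype=float))
        tsec = np.broadcast_to(np.atleast_1d(self._seconds(t)), lat.shape)
        pts = np.column_stack([tsec, zstar, lat, lon])
        return {name: self._sampler(name)(pts) for name in names}


def interp(met: MetSeries, t, lat: float, lon: float, zstar: float) -> MetSample:
    """All five met variables at one (t, lat, lon, z*) point.

    Raises :class:`OutOfDomainError` when the point falls outside the grid
    bounding box, the level range or the time span.
    """
    out = met.sample(t, lat, lon, zstar)
    vals = [float(out[name][0]) for name in _VARS]
    if any(np.isnan(v) for v in vals):
        raise OutOfDomainError(
            f"point (t={t}, lat={lat}, lon={lon}, z*={zstar}) outside the met domain"
        )
    return MetSample(*vals)


def kz_gradient(met: MetSeries, t, lat: float, lon: float, zstar: float) -> float:
    """dKz*/dz* at a point: centred differences at interior levels, one-sided
    at the first/last level, linearly interpolated to the query point."""
    out = met.sample(t, lat, lon, zstar, names=("dkz",))
    val = float(out["dkz"][0])
    if np.isnan(val):
        raise OutOfDomainError(
            f"point (t={t}, lat={lat}, lon={lon}, z*={zstar}) outside the met domain"
        )
    return val


# -- file I/O --------------------------------------------------------------

_REQUIRED_DIMS = ("time", "level", "lat", "lon")
_FILE_VARS = {"u": "u", "v": "v", "w": "w_star", "temp": "temp", "kz": "kz"}


def save_met(met: MetSeries, path) -> None:
    """Write a MetSeries as a NetCDF file (classic format via the scipy engine).

    Convention: dims (time, level, lat, lon); variables u, v, w, temp, kz plus
    terrain(lat, lon); global attribute z_top in metres; temp in degC.
    """
    met.validate()
    ds = xr.Dataset(
        {
            "u": (_REQUIRED_DIMS, met.u, {"units": "m s-1"}),
            "v": (_REQUIRED_DIMS, met.v, {"units": "m s-1"}),
            "w": (_REQUIRED_DIMS, met.w_star, {"units": "m s-1", "comment": "z* coordinate"}),
            "temp": (_REQUIRED_DIMS, met.temp, {"units": "degC"}),
            "kz": (_REQUIRED_DIMS, met.kz, {"units": "m2 s-1"}),
            "terrain": (("lat", "lon"), met.grid.terrain, {"units": "m"}),
        },
        coords={
            "time": met.times,
            "level": ("level", met.grid.levels, {"units": "m", "long_name": "z* height"}),
            "lat": ("lat", met.grid.lats, {"units": "degrees_north"}),
            "lon": ("lon", met.grid.lons, {"units": "degrees_east"}),
        },
        attrs={"z_top": float(met.grid.z_top)},
    )
    ds.to_netcdf(path, engine="scipy")


def load_met(path) -> MetSeries:
    """Read a met file written in the package convention and validate it.

    Temperature stored in kelvin (units attribute ``K``) is converted to degC.
    """
    try:
        ds = xr.open_dataset(path, engine="scipy")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed container
        raise MetFormatError(f"cannot read met file {path}: {exc}") from exc
    with ds:
        ds = ds.load()
    for dim in _REQUIRED_DIMS:
        if dim not in ds.dims:
            raise MetFormatError(f"missing dimension {dim!r}")
    for var in list(_FILE_VARS) + ["terrain"]:
        if var not in ds.variables:
            raise MetFormatError(f"missing variable {var!r}")
    if "z_top" not in ds.attrs:
        raise MetFormatError("missing global attribute 'z_top'")

    temp = ds["temp"].values.astype(float)
    if str(ds["temp"].attrs.get("units", "degC")).strip() in ("K", "kelvin", "Kelvin"):
        temp = temp - 273.15

    grid = GridSpec(
        lats=ds["lat"].values,
        lons=ds["lon"].values,
        levels=ds["level"].values,
        z_top=float(ds.attrs["z_top"]),
        terrain=ds["terrain"].values,
    )
    return MetSeries(
        grid=grid,
        times=ds["time"].values,
        u=ds["u"].values,
        v=ds["v"].values,
        w_star=ds["w"].values,
        temp=temp,
        kz=ds["kz"].values,
    )
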