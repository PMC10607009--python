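"""Analytic weather scenarios for testing the migration simulator.

Real predictions are driven by mesoscale forecast output; these generators
build :class:`~mothflight.met.MetSeries` objects with the vertical structure
the migration model cares about — a uniform flow, or a low-level jet with a
speed maximum near 1000-1500 m whose direction turns with height (an
Ekman-like spiral), a linear temperature profile that can cross the 13 degC
flight ceiling at a prescribed height, and constant/linear/parabolic vertical
diffusivity profiles.

Scenarios are horizontally homogeneous and time-constant by default so that
every downstream expectation stays closed-form; an optional linear time ramp
on the winds exercises temporal interpolation.

Direction convention (meteorological): ``direction`` is where the wind blows
FROM, degrees clockwise from north, so

    u = -speed * sin(direction),   v = -speed * cos(direction).

A 225 degree (southwesterly) wind blows toward the northeast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .met import GridSpec, MetSeries

__all__ = [
    "WindSpec",
    "TempSpec",
    "KzSpec",
    "ScenarioParams",
    "uniform_flow",
    "jet_scenario",
    "scenario_from_config",
    "temperature_profile",
    "ceiling_crossing_height",
    "lapse_for_ceiling",
    "wind_components",
]

DEFAULT_LEVELS = (
    0.0, 100.0, 250.0, 500.0, 750.0, 1000.0, 1250.0,
    1500.0, 1750.0, 2000.0, 2500.0, 3000.0,
)


def wind_components(speed, direction_deg):
    """(u, v) of a wind of ``speed`` m/s blowing from ``direction_deg``."""
    rad = np.deg2rad(direction_deg)
    return -speed * np.sin(rad), -speed * np.cos(rad)


@dataclass(frozen=True)
class WindSpec:
    """Wind profile: ``kind`` is ``uniform`` (u0, v0 everywhere) or ``jet``.

    The jet has a Gaussian speed profile
    ``speed(z*) = peak_speed * exp(-((z* - peak_height_m)/width_m)**2)``
    — a single maximum at the peak height — and its direction turns linearly
    with height at ``turning_deg_per_km`` (positive = clockwise with height).
    """

    kind: str = "uniform"
    u0: float = 0.0
    v0: float = 0.0
    peak_speed: float = 15.0
    peak_height_m: float = 1250.0
    direction_deg: float = 225.0
    turning_deg_per_km: float = 10.0
    width_m: float = 800.0

    def __post_init__(self):
        if self.kind not in ("uniform", "jet"):
            raise ValueError(f"unknown wind kind {self.kind!r}")
        if self.kind == "jet" and self.peak_speed < 0:
            raise ValueError("peak_speed must be >= 0")
        if self.kind == "jet" and self.width_m <= 0:
            raise ValueError("width_m must be > 0")


@dataclass(frozen=True)
class TempSpec:
    """Linear temperature profile: ``surface_c`` degC minus ``lapse_c_per_km``
    per kilometre of z* height."""

    surface_c: float = 25.0
    lapse_c_per_km: float = 6.5


@dataclass(frozen=True)
class KzSpec:
    """Vertical diffusivity profile (m2/s), one of:

    - ``constant``: Kz = k0
    - ``linear``:   Kz = k0 + slope * z*
    - ``parabolic``: Kz = 4 * kmax * s * (1 - s), s = z*/column_top_m — the
      classic boundary-layer shape, zero at the surface and column top.

    Values are clipped at 0 so the profile is always a valid diffusivity.
    """

    kind: str = "constant"
    k0: float = 10.0
    slope: float = 0.0
    kmax: float = 20.0
    column_top_m: float = 2000.0

    def __post_init__(self):
        if self.kind not in ("constant", "linear", "parabolic"):
            raise ValueError(f"unknown kz kind {self.kind!r}")

    def profile(self, levels: np.ndarray) -> np.ndarray:
        z = np.asarray(levels, dtype=float)
        if self.kind == "constant":
            k = np.full_like(z, self.k0)
        elif self.kind == "linear":
            k = self.k0 + self.slope * z
        else:
            s = z / self.column_top_m
            k = 4.0 * self.kmax * s * (1.0 - s)
        return np.clip(k, 0.0, None)


@dataclass(frozen=True)
class ScenarioParams:
    """Domain geometry, duration and profile specs for a synthetic scenario.

    ``duration_h`` is the simulated span in whole hours; the generated series
    has ``duration_h + 1`` hourly instants starting at ``start``.
    ``wind_time_ramp`` linearly scales the winds from a factor of 1 at the
    first instant to ``1 + wind_time_ramp`` at the last (0 = steady).
    """

    lat_min: float = 20.0
    lat_max: float = 45.0
    lon_min: float = 105.0
    lon_max: float = 145.0
    dlat: float = 1.0
    dlon: float = 1.0
    levels: tuple = DEFAULT_LEVELS
    z_top: float = 20000.0
    start: str = "2021-04-30T10:00"
    duration_h: int = 48
    wind: WindSpec = field(default_factory=WindSpec)
    temp: TempSpec = field(default_factory=TempSpec)
    kz: KzSpec = field(default_factory=KzSpec)
    wind_time_ramp: float = 0.0

    def __post_init__(self):
        if self.duration_h < 2:
            raise ValueError("duration_h must be >= 2")
        if self.lat_max <= self.lat_min or self.lon_max <= self.lon_min:
            raise ValueError("empty horizontal domain")

    def grid(self) -> GridSpec:
        lats = np.arange(self.lat_min, self.lat_max + 1e-9, self.dlat)
        lons = np.arange(self.lon_min, self.lon_max + 1e-9, self.dlon)
        return GridSpec(
            lats=lats,
            lons=lons,
            levels=np.asarray(self.levels, dtype=float),
            z_top=self.z_top,
            terrain=np.zeros((lats.size, lons.size)),
        )


def temperature_profile(levels, temp: TempSpec) -> np.ndarray:
    """Temperature (degC) at the given z* heights under a linear lapse."""
    z_km = np.asarray(levels, dtype=float) / 1000.0
    return temp.surface_c - temp.lapse_c_per_km * z_km


def ceiling_crossing_height(temp: TempSpec, ceiling_c: float = 13.0) -> float:
    """Height (m) at which the profile reaches ``ceiling_c``; inf if never."""
    if temp.surface_c <= ceiling_c:
        return 0.0
    if temp.lapse_c_per_km <= 0:
        return float("inf")
    return 1000.0 * (temp.surface_c - ceiling_c) / temp.lapse_c_per_km


def lapse_for_ceiling(surface_c: float, crossing_m: float, ceiling_c: float = 13.0) -> float:
    """Lapse rate (degC/km) that puts the ``ceiling_c`` crossing at ``crossing_m``."""
    if crossing_m <= 0:
        raise ValueError("crossing height must be positive")
    return 1000.0 * (surface_c - ceiling_c) / crossing_m


def _wind_profiles(spec: WindSpec, levels: np.ndarray):
    if spec.kind == "uniform":
        u = np.full_like(levels, spec.u0, dtype=float)
        v = np.full_like(levels, spec.v0, dtype=float)
        return u, v
    speed = spec.peak_speed * np.exp(-(((levels - spec.peak_height_m) / spec.width_m) ** 2))
    direction = spec.direction_deg + spec.turning_deg_per_km * (levels - spec.peak_height_m) / 1000.0
    return wind_components(speed, direction)


def _assemble(params: ScenarioParams) -> MetSeries:
    grid = params.grid()
    levels = grid.levels
    nt = params.duration_h + 1
    times = np.datetime64(params.start, "ns") + np.arange(nt) * np.timedelta64(3600, "s")

    u_prof, v_prof = _wind_profiles(params.wind, levels)
    t_prof = temperature_profile(levels, params.temp)
    k_prof = params.kz.profile(levels)

    shape = (nt,) + grid.shape
    ramp = 1.0 + params.wind_time_ramp * np.linspace(0.0, 1.0, nt)

    def tile(profile, factors=None):
        col = profile[None, :, None, None]
        arr = np.broadcast_to(col, shape).copy()
        if factors is not None:
            arr *= factors[:, None, None, None]
        return arr

    return MetSeries(
        grid=grid,
        times=times,
        u=tile(u_prof, ramp),
        v=tile(v_prof, ramp),
        w_star=np.zeros(shape),
        temp=tile(t_prof),
        kz=tile(k_prof),
    )


def uniform_flow(params: ScenarioParams) -> MetSeries:
    """Horizontally and vertically uniform wind; flat terrain; w* = 0."""
    if params.wind.kind != "uniform":
        raise ValueError("uniform_flow requires a wind spec of kind 'uniform'")
    return _assemble(params)


def jet_scenario(params: ScenarioParams) -> MetSeries:
    """Low-level jet with direction turning with height; flat terrain; w* = 0."""
    if params.wind.kind != "jet":
        raise ValueError("jet_scenario requires a wind spec of kind 'jet'")
    levels = np.asarray(params.levels, dtype=float)
    if not (levels[0] <= params.wind.peak_height_m <= levels[-1]):
        raise ValueError("jet peak height lies outside the level range")
    return _assemble(params)


def scenario_from_config(cfg: dict) -> MetSeries:
    """Build a scenario from a plain dict (the CLI's YAML/JSON spec)."""
    cfg = dict(cfg)
    wind = WindSpec(**cfg.pop("wind", {}))
    temp = TempSpec(**cfg.pop("temp", {}))
    kz = KzSpec(**cfg.pop("kz", {}))
    if "levels" in cfg:
        cfg["levels"] = tuple(float(x) for x in cfg["levels"])
    params = ScenarioParams(wind=wind, temp=temp, kz=kz, **cfg)
    if wind.kind == "jet":
        return jet_scenario(params)
    return uniform_flow(params)
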