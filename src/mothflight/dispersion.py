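"""Lagrangian equation of motion for windborne migrating moths.

Each moth is a particle advected by the wind plus its own airspeed, with
vertical turbulent diffusion in the terrain-following z* coordinate:

    x_{t+1}  = x_t  + (u + s_x) dt
    y_{t+1}  = y_t  + (v + s_y) dt
    z*_{t+1} = z*_t + w* dt + (dKz*/dz*) dt + sqrt(24 Kz* dt) R + w_c* dt

with R uniform on [-0.5, 0.5]. Since Var(R) = 1/12, the sqrt(24 Kz* dt)
coefficient makes the random-walk step variance exactly 2 Kz* dt, the
standard Lagrangian diffusion rate; the dKz*/dz* drift term keeps a
well-mixed vertical distribution well mixed under inhomogeneous diffusivity.

(s_x, s_y) is the moth's self-propulsion: a fixed airspeed (default 3 m/s)
aligned leeward, i.e. with the local wind vector; in calm air the heading is
undefined and self-propulsion vanishes. w_c* is the dusk ascent climb rate
(default 0.75 m/s, the radar-anchored 1350 m in 1800 s), applied from the
release start until one hour later regardless of individual take-off time.

Boundaries: a vertical step that would carry a moth into air at or below the
temperature ceiling (default 13.0 degC, the wing-beat limit) is cancelled
while the horizontal move is kept — moths stay below the cold layer and keep
flying. The ground is reflective (no landing is modelled) and so is the top
met level; a moth leaving the horizontal domain is deactivated at its last
valid position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .met import MetSeries
from .release import ReleasePlan

__all__ = [
    "SimConfig",
    "ParticleEnsemble",
    "TrajectorySet",
    "leeward_velocity",
    "vertical_increment",
    "apply_boundaries",
    "advance",
    "run_simulation",
]

# Metres per degree on the local tangent plane (fixed constants; arrival
# distances use the haversine, so this approximation only affects the
# per-step displacement conversion).
M_PER_DEG_LAT = 110_540.0
M_PER_DEG_LON_EQUATOR = 111_320.0


@dataclass(frozen=True)
class SimConfig:
    """Integrator settings and flight parameters.

    dt_s must divide one hour so snapshots align with the hourly met cadence.
    ``ascent_end_s`` is measured from the run start (a 10:00 UTC release with
    the default 3600 s means climbing ends at 11:00 UTC for every moth, so
    later take-offs ascend for less time).
    """

    dt_s: float = 120.0
    flight_speed: float = 3.0      # m/s, leeward self-propulsion
    ascent_speed: float = 0.75     # m/s, dusk climb rate w_c*
    ascent_end_s: float = 3600.0   # s after run start
    temp_min_c: float = 13.0       # flight ceiling temperature
    horizon_h: float = 48.0        # forecast horizon
    seed: int = 0

    def __post_init__(self):
        if self.dt_s <= 0 or 3600.0 % self.dt_s != 0:
            raise ValueError("dt_s must be positive and divide 3600 s")
        if self.horizon_h <= 0:
            raise ValueError("horizon_h must be positive")
        if self.flight_speed < 0 or self.ascent_end_s < 0:
            raise ValueError("flight_speed and ascent_end_s must be >= 0")


@dataclass
class ParticleEnsemble:
    """Mutable particle state arrays (one entry per moth)."""

    ids: np.ndarray
    sources: np.ndarray
    takeoff: np.ndarray      # datetime64[ns]
    lat: np.ndarray
    lon: np.ndarray
    zstar: np.ndarray
    active: np.ndarray       # bool; inactive particles never move again
    start: np.datetime64     # run/release start (anchors the ascent window)

    @classmethod
    def from_release(cls, plan: ReleasePlan) -> "ParticleEnsemble":
        return cls(
            ids=plan.ids.copy(),
            sources=plan.sources.copy(),
            takeoff=plan.takeoff.copy(),
            lat=plan.lat.copy(),
            lon=plan.lon.copy(),
            zstar=plan.zstar.copy(),
            active=np.ones(plan.n, dtype=bool),
            start=plan.start,
        )

    @property
    def n(self) -> int:
        return self.ids.size


@dataclass(frozen=True)
class TrajectorySet:
    """Particle positions recorded at every integration step.

    ``times`` has floor(horizon/dt) + 1 entries; arrays are (ntime, nparticle).
    ``hourly`` flags the snapshots that coincide with whole hours.
    """

    times: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    zstar: np.ndarray
    active: np.ndarray
    ids: np.ndarray
    sources: np.ndarray

    @property
    def hourly(self) -> np.ndarray:
        sec = (self.times - self.times[0]) / np.timedelta64(1, "s")
        return sec % 3600.0 == 0.0

    @property
    def start(self) -> np.datetime64:
        return self.times[0]

    def to_dataframe(self):
        """Long-form table (time_utc, particle_id, source, lat, lon, zstar_m, active)."""
        import pandas as pd

        nt, n = self.lat.shape
        return pd.DataFrame(
            {
                "time_utc": np.repeat(self.times, n),
                "particle_id": np.tile(self.ids, nt),
                "source": np.tile(self.sources, nt),
                "lat": self.lat.ravel(),
                "lon": self.lon.ravel(),
                "zstar_m": self.zstar.ravel(),
                "active": self.active.ravel(),
            }
        )


def leeward_velocity(u, v, flight_speed: float):
    """Self-propulsion vector: ``flight_speed`` along the local wind.

    Vectorised; returns (0, 0) where the wind is calm (heading undefined).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    speed = np.hypot(u, v)
    with np.errstate(invalid="ignore", divide="ignore"):
        sx = np.where(speed > 0, flight_speed * u / speed, 0.0)
        sy = np.where(speed > 0, flight_speed * v / speed, 0.0)
    if sx.ndim == 0:
        return float(sx), float(sy)
    return sx, sy


def vertical_increment(w_star, kz, dkz_dz, cfg: SimConfig, ascending: bool, R):
    """Candidate vertical displacement for one step (vectorised).

    ``R`` is uniform on [-0.5, 0.5]; the sqrt(24 Kz dt) coefficient gives the
    random-walk step a variance of 2 Kz dt. ``ascending`` states whether the
    run clock is still inside the dusk-ascent window.
    """
    dt = cfg.dt_s
    dz = (
        np.asarray(w_star, dtype=float) * dt
        + np.asarray(dkz_dz, dtype=float) * dt
        + np.sqrt(24.0 * np.clip(kz, 0.0, None) * dt) * np.asarray(R, dtype=float)
    )
    if ascending:
        dz = dz + cfg.ascent_speed * dt
    return dz


def apply_boundaries(
    z_old, z_cand, temp_at_cand, met: MetSeries, cfg: SimConfig
):
    """Vertical boundary rules for candidate heights (vectorised).

    1. reflect below ground: z* < 0 -> -z*
    2. reflect above the top met level
    3. temperature ceiling: where the candidate sits in air at or below
       ``temp_min_c``, the vertical move is cancelled (height reverts to
       ``z_old``; the horizontal move is kept by the caller)

    ``temp_at_cand`` must be sampled at the already-reflected candidate; pass
    the callable sampling step's output. Returns accepted heights.
    """
    top = met.grid.levels[-1]
    z = np.where(z_cand < 0, -z_cand, z_cand)
    z = np.where(z > top, 2.0 * top - z, z)
    z = np.clip(z, 0.0, top)  # guard pathological double crossings
    cold = np.asarray(temp_at_cand, dtype=float) <= cfg.temp_min_c
    return np.where(cold, z_old, z)


def _reflect(z, top):
    z = np.where(z < 0, -z, z)
    z = np.where(z > top, 2.0 * top - z, z)
    return np.clip(z, 0.0, top)


def advance(
    ens: ParticleEnsemble,
    met: MetSeries,
    cfg: SimConfig,
    t: np.datetime64,
    rng: np.random.Generator,
) -> ParticleEnsemble:
    """One integration step from t to t + dt, in place.

    Particles whose take-off time is still in the future stay at the source;
    inactive particles never move.
    """
    moving = ens.active & (ens.takeoff <= t)
    if not np.any(moving):
        return ens

    lat = ens.lat[moving]
    lon = ens.lon[moving]
    z = ens.zstar[moving]
    lev = met.grid.levels
    zq = np.clip(z, lev[0], lev[-1])  # sample at nearest level below the lowest

    fields = met.sample(t, lat, lon, zq, names=("u", "v", "w_star", "kz", "dkz"))
    bad = np.isnan(fields["u"])
    u = np.nan_to_num(fields["u"])
    v = np.nan_to_num(fields["v"])

    sx, sy = leeward_velocity(u, v, cfg.flight_speed)
    dx = (u + sx) * cfg.dt_s
    dy = (v + sy) * cfg.dt_s
    new_lon = lon + dx / (M_PER_DEG_LON_EQUATOR * np.cos(np.deg2rad(lat)))
    new_lat = lat + dy / M_PER_DEG_LAT

    # horizontal exit -> deactivate at the last valid position
    inside = met.grid.contains(new_lat, new_lon) & ~bad
    elapsed_s = (t - ens.start) / np.timedelta64(1, "s")
    ascending = elapsed_s < cfg.ascent_end_s
    R = rng.uniform(-0.5, 0.5, size=z.size)
    dz = vertical_increment(
        fields["w_star"], fields["kz"], fields["dkz"], cfg, ascending, R
    )
    z_cand = _reflect(z + np.nan_to_num(dz), lev[-1])

    temp = met.sample(t, new_lat, new_lon, np.clip(z_cand, lev[0], lev[-1]),
                      names=("temp",))["temp"]
    cold = np.nan_to_num(temp, nan=-np.inf) <= cfg.temp_min_c
    z_new = np.where(cold, z, z_cand)

    idx = np.flatnonzero(moving)
    ok = inside
    ens.lat[idx[ok]] = new_lat[ok]
    ens.lon[idx[ok]] = new_lon[ok]
    ens.zstar[idx[ok]] = z_new[ok]
    ens.active[idx[~ok]] = False
    return ens


def run_simulation(
    release: ReleasePlan, met: MetSeries, cfg: SimConfig
) -> TrajectorySet:
    """Integrate all particles from the release start over the forecast
    horizon, recording a snapshot at every step (deterministic per seed)."""
    start = release.start
    n_steps = int(round(cfg.horizon_h * 3600.0 / cfg.dt_s))
    end = start + np.timedelta64(int(cfg.horizon_h * 3600.0), "s")
    if start < met.times[0] or end > met.times[-1]:
        raise ValueError(
            f"met coverage [{met.times[0]}, {met.times[-1]}] does not span "
            f"the run [{start}, {end}]"
        )

    rng = np.random.default_rng(cfg.seed)
    ens = ParticleEnsemble.from_release(release)
    n = ens.n

    times = start + (np.arange(n_steps + 1) * cfg.dt_s * 1e9).astype("timedelta64[ns]")
    lat = np.empty((n_steps + 1, n))
    lon = np.empty((n_steps + 1, n))
    zst = np.empty((n_steps + 1, n))
    act = np.empty((n_steps + 1, n), dtype=bool)

    for k in range(n_steps + 1):
        lat[k] = ens.lat
        lon[k] = ens.lon
        zst[k] = ens.zstar
        act[k] = ens.active
        if k < n_steps:
            advance(ens, met, cfg, times[k], rng)

    return TrajectorySet(
        times=times, lat=lat, lon=lon, zstar=zst, active=act,
        ids=ens.ids, sources=ens.sources,
    )
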