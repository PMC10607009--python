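"""Trap-level arrival prediction from simulated trajectories.

A migration "arrives" at a pheromone-trap site when any simulated moth passes
within the detection radius (default 18 km) of the trap within the forecast
horizon (default 48 h). The passage test runs at every integration step, not
only at hourly snapshots: a moth moving at 13 m/s covers 47 km per hour and
could skip an 18 km disc between hourly frames. Flight time (FT) is the whole
number of hours, rounded to nearest, from the release start to the first
passage.

Daily runs are labelled with the JST calendar date following the take-off
evening: a release at 10:00 UTC (19:00 JST) on day d is the prediction row
for day d+1, the night the moths are in the air over Japan.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dispersion import TrajectorySet

__all__ = [
    "TrapSite",
    "ArrivalRecord",
    "DailyPrediction",
    "haversine",
    "load_traps",
    "detect_arrivals",
    "make_daily_predictions",
    "predictions_to_frame",
    "render_map",
]

EARTH_RADIUS_KM = 6371.0
DETECTION_RADIUS_KM = 18.0
MAP_CIRCLE_DIAMETER_KM = 18.0  # drawn circles: 18 km diameter (9 km radius)
JST_OFFSET = np.timedelta64(9, "h")


@dataclass(frozen=True)
class TrapSite:
    name: str
    lat: float
    lon: float

    def __post_init__(self):
        if not (-90.0 <= self.lat <= 90.0 and -180.0 <= self.lon <= 180.0):
            raise ValueError(f"trap {self.name!r}: coordinates out of range")


@dataclass(frozen=True)
class ArrivalRecord:
    """Earliest passage of any moth from one source within a trap's radius."""

    trap: str
    source: str
    first_pass_utc: np.datetime64
    flight_time_h: int
    min_distance_km: float


@dataclass(frozen=True)
class DailyPrediction:
    """One trap's row in the daily prediction table."""

    trap: str
    date_jst: object           # datetime.date
    predicted: bool
    source: str | None = None  # earliest-arriving source when predicted
    ft_h: int | None = None


def haversine(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in km (Earth radius 6371.0 km); vectorised."""
    lat1, lon1, lat2, lon2 = (np.deg2rad(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    a = (
        np.sin((lat2 - lat1) / 2.0) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2.0) ** 2
    )
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if np.ndim(d) == 0 else d


def load_traps(path) -> list[TrapSite]:
    """Trap catalog CSV with columns name, lat, lon ('#' lines are comments)."""
    df = pd.read_csv(path, comment="#")
    missing = {"name", "lat", "lon"} - set(df.columns)
    if missing:
        raise ValueError(f"trap catalog missing columns: {sorted(missing)}")
    return [TrapSite(r["name"], float(r["lat"]), float(r["lon"])) for _, r in df.iterrows()]


def detect_arrivals(
    traj: TrajectorySet,
    traps: list[TrapSite],
    radius_km: float = DETECTION_RADIUS_KM,
    horizon_h: float | None = None,
) -> list[ArrivalRecord]:
    """First passage per (trap, source) within ``radius_km``, checked at every
    recorded step; a distance exactly equal to the radius counts as arrival."""
    times = traj.times
    keep = slice(None)
    if horizon_h is not None:
        end = times[0] + np.timedelta64(int(horizon_h * 3600.0), "s")
        keep = times <= end
    t_sel = times[keep]
    lat = traj.lat[keep]
    lon = traj.lon[keep]
    act = traj.active[keep]

    records = []
    source_labels = np.asarray(traj.sources)
    for trap in traps:
        dist = haversine(lat, lon, trap.lat, trap.lon)
        within = (dist <= radius_km) & act
        for src in pd.unique(source_labels):
            cols = source_labels == src
            hit_any = within[:, cols].any(axis=1)
            if not hit_any.any():
                continue
            k = int(np.argmax(hit_any))
            first = t_sel[k]
            seconds = (first - times[0]) / np.timedelta64(1, "s")
            ft = int(math.floor(seconds / 3600.0 + 0.5))  # nearest hour, half up
            records.append(
                ArrivalRecord(
                    trap=trap.name,
                    source=str(src),
                    first_pass_utc=first,
                    flight_time_h=ft,
                    min_distance_km=float(dist[:, cols][act[:, cols]].min()),
                )
            )
    return records


def run_label_jst(run_start_utc) -> object:
    """JST date label for a run: the calendar date after the take-off evening."""
    start = np.datetime64(run_start_utc, "ns")
    jst = pd.Timestamp(start + JST_OFFSET)
    return (jst + pd.Timedelta(days=1)).date()


def make_daily_predictions(
    arrivals: list[ArrivalRecord],
    traps: list[TrapSite],
    run_start_utc,
) -> list[DailyPrediction]:
    """One yes/no row per trap; a 'yes' carries the earliest arrival's source
    and flight time (minimum FT across sources)."""
    label = run_label_jst(run_start_utc)
    by_trap: dict[str, list[ArrivalRecord]] = {}
    for rec in arrivals:
        by_trap.setdefault(rec.trap, []).append(rec)
    preds = []
    for trap in traps:
        recs = by_trap.get(trap.name)
        if recs:
            best = min(recs, key=lambda r: (r.flight_time_h, r.first_pass_utc))
            preds.append(
                DailyPrediction(trap.name, label, True, best.source, best.flight_time_h)
            )
        else:
            preds.append(DailyPrediction(trap.name, label, False))
    return preds


def predictions_to_frame(preds: list[DailyPrediction]) -> pd.DataFrame:
    """Prediction table: site, run_date_jst, predicted (Y/N), source, ft_h."""
    return pd.DataFrame(
        {
            "site": [p.trap for p in preds],
            "run_date_jst": [p.date_jst.isoformat() for p in preds],
            "predicted": ["Y" if p.predicted else "N" for p in preds],
            "source": [p.source or "" for p in preds],
            "ft_h": [p.ft_h if p.ft_h is not None else "" for p in preds],
        }
    )


def _circle_ring(lat: float, lon: float, radius_km: float, npts: int = 36):
    """Lon/lat ring approximating a geodesic circle (plate-carrée)."""
    ang = np.linspace(0.0, 2.0 * np.pi, npts, endpoint=False)
    deg_per_km_lat = 360.0 / (2.0 * np.pi * EARTH_RADIUS_KM)
    dlat = radius_km * deg_per_km_lat * np.cos(ang)
    dlon = radius_km * deg_per_km_lat * np.sin(ang) / np.cos(np.deg2rad(lat))
    ring = [[float(lon + dx), float(lat + dy)] for dx, dy in zip(dlon, dlat)]
    ring.append(ring[0])
    return ring


def render_map(
    traj: TrajectorySet,
    time,
    traps: list[TrapSite],
    path=None,
    extent=(105.0, 150.0, 15.0, 50.0),
):
    """Plot the ensemble at one snapshot time as open circles (18 km diameter,
    coloured by source, any flight height) plus trap markers, on plate-carrée
    axes; returns (figure, geojson_dict). Writes PNG/GeoJSON if ``path`` has
    suffixes .png/.geojson respectively (a bare stem writes both).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    time = np.datetime64(time, "ns")
    matches = np.flatnonzero(traj.times == time)
    if matches.size == 0:
        raise ValueError(f"no snapshot recorded at {time}")
    k = int(matches[0])

    act = traj.active[k]
    lats = traj.lat[k][act]
    lons = traj.lon[k][act]
    srcs = np.asarray(traj.sources)[act]

    fig, ax = plt.subplots(figsize=(8, 7))
    ax.set_xlim(extent[0], extent[1])
    ax.set_ylim(extent[2], extent[3])
    ax.set_xlabel("longitude (deg E)")
    ax.set_ylabel("latitude (deg N)")
    ax.set_title(f"simulated moths at {np.datetime_as_string(time, unit='m')} UTC")
    ax.set_aspect(1.0 / np.cos(np.deg2rad(np.mean(extent[2:]))))

    cmap = plt.get_cmap("tab10")
    order = list(dict.fromkeys(traj.sources))
    colors = {s: cmap(i % 10) for i, s in enumerate(order)}
    radius = MAP_CIRCLE_DIAMETER_KM / 2.0

    features = []
    for la, lo, s in zip(lats, lons, srcs):
        ring = _circle_ring(la, lo, radius)
        features.append(
            {
                "type": "Feature",
                "properties": {"source": str(s)},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    for s in order:
        sel = srcs == s
        if sel.any():
            ax.scatter(
                lons[sel], lats[sel], s=18, facecolors="none",
                edgecolors=[colors[s]], label=str(s),
            )
    for trap in traps:
        ax.plot(trap.lon, trap.lat, marker="^", color="k", ms=7)
        ax.annotate(trap.name, (trap.lon, trap.lat), fontsize=7,
                    xytext=(3, 3), textcoords="offset points")
        features.append(
            {
                "type": "Feature",
                "properties": {"trap": trap.name},
                "geometry": {"type": "Point", "coordinates": [trap.lon, trap.lat]},
            }
        )
    if len(order) > 0 and act.any():
        ax.legend(loc="lower right", fontsize=8, title="source")

    geojson = {"type": "FeatureCollection", "features": features}
    if path is not None:
        path = str(path)
        if path.endswith(".png"):
            fig.savefig(path, dpi=120)
        elif path.endswith(".geojson"):
            with open(path, "w") as fh:
                json.dump(geojson, fh)
        else:
            fig.savefig(path + ".png", dpi=120)
            with open(path + ".geojson", "w") as fh:
                json.dump(geojson, fh)
    return fig, geojson
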