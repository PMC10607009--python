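"""Emigration source areas and the per-particle take-off schedule.

Moths emigrate from source provinces on the Chinese mainland (Zhejiang,
Fujian, Guangdong, Jiangxi) and the island of Taiwan. Each simulated night,
every source releases a fixed number of moths (default 500) over a one-hour
window starting at dusk (default 10:00 UTC), at a constant temporal rate and
at horizontal positions drawn uniformly over the source polygon. Take-off is
from the ground (initial z* = 0); at the ~27 km grid scale of the driving
meteorology, canopy height is indistinguishable from the surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon, shape

__all__ = [
    "SourceArea",
    "ReleasePlan",
    "GeometryError",
    "load_sources",
    "sample_positions",
    "build_release",
]


class GeometryError(ValueError):
    """A source-area geometry is invalid or unusable."""


@dataclass(frozen=True)
class SourceArea:
    """A named emigration source polygon (lon/lat ring, WGS84)."""

    name: str
    polygon: Polygon

    def __post_init__(self):
        if not self.name:
            raise GeometryError("source area must have a non-empty name")
        if not isinstance(self.polygon, Polygon):
            raise GeometryError(f"source {self.name!r}: geometry must be a polygon")
        if not self.polygon.is_valid:
            raise GeometryError(f"source {self.name!r}: invalid geometry (self-intersection?)")
        if self.polygon.area <= 0:
            raise GeometryError(f"source {self.name!r}: polygon has zero area")


@dataclass(frozen=True)
class ReleasePlan:
    """Per-particle take-off schedule.

    Arrays are aligned by particle: ``takeoff`` UTC instants within
    [start, start + window_s), positions inside the labelled source polygon,
    initial height z* = 0.
    """

    ids: np.ndarray        # int
    sources: np.ndarray    # str labels
    takeoff: np.ndarray    # datetime64[ns]
    lat: np.ndarray
    lon: np.ndarray
    zstar: np.ndarray
    start: np.datetime64
    window_s: float

    @property
    def n(self) -> int:
        return self.ids.size


def load_sources(path) -> list[SourceArea]:
    """Read a GeoJSON FeatureCollection of named source polygons."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise GeometryError("source file must be a GeoJSON FeatureCollection")
    areas = []
    for i, feat in enumerate(gj.get("features", [])):
        name = (feat.get("properties") or {}).get("name")
        if not name:
            raise GeometryError(f"feature #{i} has no 'name' property")
        try:
            geom = shape(feat["geometry"])
        except Exception as exc:
            raise GeometryError(f"feature {name!r}: unreadable geometry: {exc}") from exc
        areas.append(SourceArea(name=name, polygon=geom))
    if not areas:
        raise GeometryError("source file contains no features")
    return areas


def sample_positions(area: SourceArea, n: int, rng: np.random.Generator):
    """Draw ``n`` points uniform over the source polygon.

    Rejection sampling from the bounding box; returns (lat, lon) arrays.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    lon_min, lat_min, lon_max, lat_max = area.polygon.bounds
    lats = np.empty(n)
    lons = np.empty(n)
    filled = 0
    while filled < n:
        m = max(4 * (n - filled), 16)
        x = rng.uniform(lon_min, lon_max, m)
        y = rng.uniform(lat_min, lat_max, m)
        inside = shapely.contains_xy(area.polygon, x, y)
        k = min(int(inside.sum()), n - filled)
        lons[filled : filled + k] = x[inside][:k]
        lats[filled : filled + k] = y[inside][:k]
        filled += k
    return lats, lons


def build_release(
    sources: list[SourceArea],
    start_utc,
    n_per_source: int = 500,
    window_s: float = 3600.0,
    rng: np.random.Generator | None = None,
) -> ReleasePlan:
    """Build the take-off schedule: per source, ``n_per_source`` moths take
    off evenly spaced over the release window (constant temporal rate), at
    uniform random positions inside the polygon, from the ground.
    """
    if not sources:
        raise ValueError("need at least one source area")
    if n_per_source < 1:
        raise ValueError("n_per_source must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    start = np.datetime64(start_utc, "ns")

    ids, labels, takeoffs, lats, lons = [], [], [], [], []
    pid = 0
    # i-th take-off at start + i * (window_s / n): all within [start, start+window)
    offsets_s = np.arange(n_per_source) * (window_s / n_per_source)
    for area in sources:
        la, lo = sample_positions(area, n_per_source, rng)
        for i in range(n_per_source):
            ids.append(pid)
            labels.append(area.name)
            pid += 1
        takeoffs.append(start + (offsets_s * 1e9).astype("timedelta64[ns]"))
        lats.append(la)
        lons.append(lo)

    return ReleasePlan(
        ids=np.asarray(ids, dtype=int),
        sources=np.asarray(labels, dtype=object),
        takeoff=np.concatenate(takeoffs),
        lat=np.concatenate(lats),
        lon=np.concatenate(lons),
        zstar=np.zeros(pid),
        start=start,
        window_s=float(window_s),
    )
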