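"""Packaged reference fixtures: trap catalog, simplified source polygons, and
the May-2021 worked example (Koshi and Isahaya predictions, catches, and
published per-day marks) plus the published per-site hitting-ratio matrix.

The source polygons are coarse simplifications (about ten vertices each) of
the emigration provinces; users with precise administrative boundaries should
supply their own GeoJSON.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "data_path",
    "load_trap_catalog",
    "load_source_areas",
    "load_example_predictions",
    "load_example_catches",
    "load_example_marks",
    "load_reference_ratios",
]


def data_path(name: str):
    """Filesystem path of a packaged data file."""
    return resources.files(__package__) / name


def load_trap_catalog(year: int | None = None):
    """Trap sites as a list of TrapSite (optionally one survey year)."""
    from ..arrival import TrapSite

    df = pd.read_csv(data_path("traps.csv"), comment="#")
    if year is not None:
        df = df[df["year"] == int(year)]
    return [TrapSite(r["name"], float(r["lat"]), float(r["lon"])) for _, r in df.iterrows()]


def load_source_areas():
    """The five packaged emigration source polygons."""
    from ..release import load_sources

    return load_sources(data_path("sources_east_asia.geojson"))


def _site_file(site: str, kind: str) -> str:
    site = site.lower().replace("-", "_")
    if site not in ("koshi", "isahaya"):
        raise ValueError("packaged example data exists for 'koshi' and 'isahaya' only")
    return f"{site}_2021_{kind}.csv"


def load_example_predictions(site: str = "koshi") -> pd.DataFrame:
    """May-2021 daily prediction rows for a packaged example site."""
    return pd.read_csv(data_path(_site_file(site, "predictions")), comment="#")


def load_example_catches(site: str = "koshi") -> pd.DataFrame:
    """May-2021 trap-catch records for a packaged example site."""
    return pd.read_csv(data_path(_site_file(site, "catches")), comment="#")


def load_example_marks(site: str = "koshi") -> pd.DataFrame:
    """Published per-day H/F/- marks for a packaged example site."""
    return pd.read_csv(data_path(_site_file(site, "marks")), comment="#")


def load_reference_ratios() -> pd.DataFrame:
    """Published per-site hitting ratios (year, site, ratio_3day, ratio_5day)."""
    return pd.read_csv(data_path("site_ratios.csv"), comment="#")
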