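"""Ensemble-level classification and summaries of the fitted parameters.

Monitoring stations are labelled by predominant emission source (traffic,
industrial, background) and surrounding area (urban, suburban, rural); the
nine combinations collapse into seven environment categories because the
suburban and rural variants of traffic and industrial sites are merged.
Sites can alternatively be grouped by mean wind speed into the four lowest
Beaufort classes.  Per group we summarise the distribution of the fitted
width parameter lambda by its median, interquartile range and central 95%
interval, and rank groups by median lambda from lowest (most polluted) to
highest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_BEAUFORT_BOUNDS
from .errors import DataError
from .tailfit import SiteFit

__all__ = [
    "ENVIRONMENT_CATEGORIES",
    "WIND_LABELS",
    "WindClass",
    "GroupSummary",
    "classify_site",
    "beaufort_class",
    "match_weather_station",
    "group_lambda_summary",
    "scatter_table",
]

STATION_TYPES = ("traffic", "industrial", "background")
AREA_TYPES = ("urban", "suburban", "rural")

# (station_type, area_type) -> combined environment category; suburban and
# rural are merged for traffic and industrial stations, giving 7 categories
# over the 9 combinations
_CATEGORY_MAP = {
    ("traffic", "urban"): "urban traffic",
    ("traffic", "suburban"): "suburban/rural traffic",
    ("traffic", "rural"): "suburban/rural traffic",
    ("background", "urban"): "urban background",
    ("background", "suburban"): "suburban background",
    ("background", "rural"): "rural background",
    ("industrial", "urban"): "urban industrial",
    ("industrial", "suburban"): "suburban/rural industrial",
    ("industrial", "rural"): "suburban/rural industrial",
}

ENVIRONMENT_CATEGORIES = tuple(dict.fromkeys(_CATEGORY_MAP.values()))

WIND_LABELS = ("calm & light air", "light breeze", "gentle breeze", "moderate breeze")
OUT_OF_RANGE = "above moderate breeze"


@dataclass(frozen=True)
class WindClass:
    """Beaufort classification of a site's mean wind speed."""

    mean_ws: float
    label: str
    in_scale: bool  # False when the speed exceeds the four classes used here


@dataclass(frozen=True)
class GroupSummary:
    """Distribution summary of lambda within one group of sites."""

    label: str
    n_sites: int
    median_lambda: float
    iqr: tuple[float, float]        # (q25, q75)
    interval95: tuple[float, float]  # central 95% percentile interval

    def __post_init__(self) -> None:
        q25, q75 = self.iqr
        lo, hi = self.interval95
        if not (q25 <= self.median_lambda <= q75):
            raise DataError("median must lie inside the interquartile range")
        if not (lo <= q25 and q75 <= hi):
            raise DataError("95% interval must contain the interquartile range")


def classify_site(station_type: str, area_type: str) -> str:
    """Combined environment category for a (station, area) type pair.

    Case-insensitive; exactly seven distinct categories exist.
    """
    key = (str(station_type).strip().lower(), str(area_type).strip().lower())
    try:
        return _CATEGORY_MAP[key]
    except KeyError:
        raise DataError(
            f"unknown station/area types {station_type!r}/{area_type!r}; "
            f"expected {STATION_TYPES} x {AREA_TYPES}") from None


def beaufort_class(mean_ws: float,
                   bounds: Sequence[float] = DEFAULT_BEAUFORT_BOUNDS) -> WindClass:
    """Classify a mean wind speed (m/s) into the four lowest Beaufort classes.

    Boundaries (upper bounds, inclusive) default to 1.5 / 3.3 / 5.4 / 7.9 m/s
    for calm & light air, light breeze, gentle breeze and moderate breeze.
    Speeds above the last bound are flagged as out of scale rather than
    given a fifth label.
    """
    ws = float(mean_ws)
    if not np.isfinite(ws) or ws < 0.0:
        raise DataError(f"mean wind speed must be a finite non-negative number; got {ws}")
    for label, upper in zip(WIND_LABELS, bounds):
        if ws <= upper:
            return WindClass(ws, label, True)
    return WindClass(ws, OUT_OF_RANGE, False)


def match_weather_station(site: tuple[float, float],
                          stations: Sequence[tuple[float, float]],
                          radius_deg: float = 0.1) -> int | None:
    """Index of the nearest weather station, or None.

    Distance is Chebyshev — max(|dlat|, |dlon|) in degrees — and a station
    qualifies only if strictly closer than ``radius_deg`` (a station at
    exactly the radius is rejected).
    """
    if len(stations) == 0:
        return None
    lat, lon = site
    arr = np.asarray(stations, dtype=float).reshape(-1, 2)
    dist = np.maximum(np.abs(arr[:, 0] - lat), np.abs(arr[:, 1] - lon))
    idx = int(np.argmin(dist))
    return idx if dist[idx] < radius_deg else None


def _lambda_of(fit) -> float:
    return fit.lam if isinstance(fit, SiteFit) else float(fit[1])


def group_lambda_summary(site_fits: Sequence[SiteFit],
                         groups: Mapping[str, str]) -> list[GroupSummary]:
    """Per-group lambda summaries, ranked by median lambda ascending.

    ``groups`` maps site codes to a group label (environment category or
    wind class); fits whose site is absent from the mapping are skipped.
    Quantiles use linear interpolation between order statistics.
    """
    if len(site_fits) == 0:
        raise DataError("no site fits to summarise")
    by_group: dict[str, list[float]] = {}
    for fit in site_fits:
        label = groups.get(fit.site_code)
        if label is None:
            continue
        by_group.setdefault(label, []).append(fit.lam)
    if not by_group:
        raise DataError("no site fit matched any group label")
    summaries = []
    for label, lams in by_group.items():
        arr = np.asarray(lams, dtype=float)
        q2_5, q25, q50, q75, q97_5 = np.percentile(arr, [2.5, 25, 50, 75, 97.5])
        summaries.append(GroupSummary(
            label=label, n_sites=arr.size, median_lambda=float(q50),
            iqr=(float(q25), float(q75)), interval95=(float(q2_5), float(q97_5))))
    summaries.sort(key=lambda s: s.median_lambda)
    return summaries


def scatter_table(site_fits: Sequence[SiteFit],
                  groups: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Table of (q, log10 lambda, category) tuples behind the parameter-plane
    scatter plot.  Rows with non-positive lambda are dropped with a warning.
    """
    rows = []
    n_dropped = 0
    for fit in site_fits:
        if fit.lam <= 0:
            n_dropped += 1
            continue
        rows.append({
            "site": fit.site_code,
            "pollutant": fit.pollutant,
            "q": fit.q,
            "log10_lambda": float(np.log10(fit.lam)),
            "category": groups.get(fit.site_code) if groups else None,
        })
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} fits with non-positive lambda",
                      stacklevel=2)
    return pd.DataFrame(rows, columns=["site", "pollutant", "q", "log10_lambda",
                                       "category"])
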