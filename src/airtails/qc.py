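"""Quality control of monitoring-site time series.

Three filters decide whether a site enters the analysis:

* length — at least ``min_points`` (default 8760 = 365 d x 24 h) valid
  hourly measurements, so a single season is never analysed alone;
* below-detection-limit fraction — strictly more than 15% of values below
  the detection limit rejects the site (such clean-air sites are not the
  analysis target, and heavier censoring makes the LOD/2 substitution
  unreliable);
* repeated values — a single value accounting for at least 15% of the
  measurements indicates a stuck sensor or corrupted archive.

Values below the detection limit (including negative readings) are replaced
by LOD/2, the standard convention for censored environmental data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import DataError, ParameterError

__all__ = [
    "SiteSeries",
    "QCReport",
    "substitute_lod",
    "filter_length",
    "filter_lod_fraction",
    "filter_repeats",
    "run_qc",
]

_DEFAULTS = PipelineConfig()

POLLUTANTS = ("no", "no2", "pm2.5", "pm10")


@dataclass(frozen=True)
class SiteSeries:
    """One site's hourly concentration series with station metadata.

    ``timestamps`` must be strictly increasing and hourly-aligned (gaps are
    allowed as missing rows); ``values`` are concentrations in µg/m³ and may
    contain NaN for missing measurements.
    """

    site_code: str
    pollutant: str
    timestamps: pd.DatetimeIndex
    values: np.ndarray
    lod: float | None = None
    station_type: str | None = None
    area_type: str | None = None
    latitude: float | None = None
    longitude: float | None = None
    n_substituted: int = 0  # values replaced by LOD/2, set by substitute_lod

    def __post_init__(self) -> None:
        if self.pollutant not in POLLUTANTS:
            raise DataError(f"pollutant must be one of {POLLUTANTS}; got {self.pollutant!r}")
        ts = pd.DatetimeIndex(self.timestamps)
        vals = np.asarray(self.values, dtype=float)
        if len(ts) != len(vals):
            raise DataError("timestamps and values must have equal length")
        if len(ts) > 1:
            diffs = np.diff(ts.asi8)
            hour_ns = 3_600_000_000_000
            if np.any(diffs <= 0):
                raise DataError("timestamps must be strictly increasing")
            if np.any(diffs % hour_ns != 0):
                raise DataError("timestamps must be hourly-aligned (whole-hour gaps)")
        if np.any(np.isinf(vals)):
            raise DataError("values must be finite where present")
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "values", vals)

    @property
    def valid_values(self) -> np.ndarray:
        """Non-missing measurements."""
        return self.values[~np.isnan(self.values)]

    @property
    def n_points(self) -> int:
        return int(np.sum(~np.isnan(self.values)))


@dataclass(frozen=True)
class QCReport:
    """Outcome of the three QC filters for one series."""

    site_code: str
    pollutant: str
    n_points: int
    frac_below_lod: float  # NaN when no detection limit was available
    max_value_frac: float
    passed: bool
    reasons: tuple[str, ...] = ()
    skipped: tuple[str, ...] = ()  # filters not applicable (e.g. no LOD)

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise DataError("passed must be equivalent to an empty reasons list")


def substitute_lod(series: SiteSeries) -> SiteSeries:
    """Replace every value below the detection limit (negatives included)
    by LOD/2 and record how many were substituted.  Idempotent."""
    if series.lod is None:
        raise ParameterError("series has no detection limit; cannot substitute")
    if series.lod <= 0:
        raise ParameterError(f"detection limit must be positive; got {series.lod}")
    below = series.values < series.lod  # NaN compares False
    n_below = int(np.sum(below))
    if n_below == 0:
        return series
    vals = series.values.copy()
    vals[below] = series.lod / 2.0
    return replace(series, values=vals, n_substituted=series.n_substituted + n_below)


def _frac_below_lod(series: SiteSeries) -> float:
    """Share of valid values below the LOD.

    Counting strictly-below works both before and after substitution: the
    LOD/2 substitutes themselves sit below the limit.
    """
    n = series.n_points
    if n == 0:
        return 0.0
    return float(np.sum(series.values < series.lod)) / n


def _max_value_frac(series: SiteSeries) -> float:
    """Largest share of any single repeated value among valid measurements."""
    vals = series.valid_values
    if vals.size == 0:
        return 0.0
    _, counts = np.unique(vals, return_counts=True)
    return float(counts.max()) / vals.size


def filter_length(series: SiteSeries, min_points: int = _DEFAULTS.min_points) -> bool:
    """Pass iff the series has at least ``min_points`` valid measurements."""
    return series.n_points >= min_points


def filter_lod_fraction(series: SiteSeries, lod_frac: float = _DEFAULTS.lod_frac) -> bool:
    """Pass iff at most ``lod_frac`` of values lie below the detection limit
    (strictly more fails; the boundary passes)."""
    if series.lod is None:
        raise ParameterError("series has no detection limit; filter not applicable")
    return _frac_below_lod(series) <= lod_frac


def filter_repeats(series: SiteSeries, repeat_frac: float = _DEFAULTS.repeat_frac) -> bool:
    """Pass iff no single value accounts for ``repeat_frac`` or more of the
    valid measurements (the boundary fails)."""
    return _max_value_frac(series) < repeat_frac


def run_qc(series: SiteSeries, *,
           min_points: int = _DEFAULTS.min_points,
           lod_frac: float = _DEFAULTS.lod_frac,
           repeat_frac: float = _DEFAULTS.repeat_frac) -> tuple[SiteSeries, QCReport]:
    """Apply LOD/2 substitution then all three filters.

    Returns the (possibly substituted) series together with a report that
    lists every failed filter, not just the first.  When the series carries
    no detection limit the LOD filter is skipped and noted in the report.
    """
    skipped: list[str] = []
    if series.lod is not None:
        series = substitute_lod(series)
        frac_lod = _frac_below_lod(series)
        lod_ok = frac_lod <= lod_frac
    else:
        frac_lod = float("nan")
        lod_ok = True
        skipped.append("lod_fraction")

    reasons = []
    if not filter_length(series, min_points):
        reasons.append("length")
    if not lod_ok:
        reasons.append("lod_fraction")
    if not filter_repeats(series, repeat_frac):
        reasons.append("repeats")

    report = QCReport(
        site_code=series.site_code,
        pollutant=series.pollutant,
        n_points=series.n_points,
        frac_below_lod=frac_lod,
        max_value_frac=_max_value_frac(series),
        passed=not reasons,
        reasons=tuple(reasons),
        skipped=tuple(skipped),
    )
    return series, report
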