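"""File formats and the end-to-end pipeline.

Three flat CSVs feed the analysis (comma-separated, UTF-8, header row,
ISO-8601 UTC hour-start dates):

* ``observations.csv`` — date, site, variable, value (µg/m³);
* ``sites.csv`` — site, site_type, site_area, latitude, longitude;
* ``wind.csv`` — station, date, ws (m/s), latitude, longitude.

:func:`run_pipeline` composes QC, per-site tail fitting, model selection
and the ensemble summaries, writing results and summary CSVs to the output
directory.  Per-site failures are recorded and the run continues.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .ensemble import beaufort_class, classify_site, group_lambda_summary, \
    match_weather_station, scatter_table
from .errors import AirTailsError, FormatError
from .qc import POLLUTANTS, SiteSeries, run_qc
from .tailfit import SiteFit, fit_site

__all__ = ["read_observations", "read_sites", "read_wind", "run_pipeline",
           "setup_logging"]

log = logging.getLogger("airtails")

_OBS_COLUMNS = ("date", "site", "variable", "value")
_SITE_COLUMNS = ("site", "site_type", "site_area", "latitude", "longitude")
_WIND_COLUMNS = ("station", "date", "ws")


def setup_logging(level: int = logging.INFO) -> None:
    """Timestamped logging to standard error."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(level)


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory columns {missing}")


def read_observations(path: str | Path, *, lod: float | None = None,
                      sites_meta: pd.DataFrame | None = None) -> list[SiteSeries]:
    """Read the observations CSV into one :class:`SiteSeries` per
    (site, variable) pair.

    Rows with an unknown pollutant or an unparseable date/value are counted
    and logged, never fatal.  Duplicated (site, variable, date) rows keep
    the last occurrence, with a warning.  Optional station metadata
    (``sites_meta``, the sites.csv table) and a detection limit are attached
    to every series.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, _OBS_COLUMNS, path)
    n_raw = len(df)
    df["date"] = pd.to_datetime(df["date"], errors="coerce", utc=True)
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    bad = df["date"].isna()
    if bad.any():
        log.warning("%s: dropped %d rows with unparseable dates", path, int(bad.sum()))
        df = df[~bad]
    known = df["variable"].isin(POLLUTANTS)
    if (~known).any():
        log.info("%s: ignored %d rows with out-of-scope variables %s", path,
                 int((~known).sum()), sorted(df.loc[~known, "variable"].unique()))
        df = df[known]
    dup = df.duplicated(subset=["site", "variable", "date"], keep="last")
    if dup.any():
        log.warning("%s: %d duplicated (site, variable, date) rows; keeping last",
                    path, int(dup.sum()))
        df = df[~dup]
    log.info("%s: %d of %d rows retained", path, len(df), n_raw)

    meta = {}
    if sites_meta is not None:
        meta = sites_meta.set_index("site").to_dict("index")

    series_list = []
    for (site, variable), grp in df.groupby(["site", "variable"], sort=True):
        grp = grp.sort_values("date")
        m = meta.get(site, {})
        series_list.append(SiteSeries(
            site_code=site, pollutant=variable,
            timestamps=pd.DatetimeIndex(grp["date"]),
            values=grp["value"].to_numpy(),
            lod=lod,
            station_type=m.get("site_type"), area_type=m.get("site_area"),
            latitude=m.get("latitude"), longitude=m.get("longitude")))
    return series_list


def read_sites(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, _SITE_COLUMNS, path)
    return df


def read_wind(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, _WIND_COLUMNS, path)
    df["ws"] = pd.to_numeric(df["ws"], errors="coerce")
    return df


def _results_frame(fits: list[SiteFit]) -> pd.DataFrame:
    short = {"exponential": "exp", "gamma": "gamma", "weibull": "weibull",
             "lognormal": "lognormal", "qexponential": "qexp"}
    rows = []
    for f in fits:
        row = {"site": f.site_code, "pollutant": f.pollutant,
               "x_peak": f.tailcut.x_peak, "n_tail": f.tailcut.n_tail,
               "q": f.q, "lambda": f.lam}
        for fam, s in short.items():
            row[f"loglik_{s}"] = f.fits[fam].loglik
        row.update(best_family=f.best_family, mean=f.mean, sd=f.sd)
        rows.append(row)
    return pd.DataFrame(rows)


def _wind_site_means(sites_df: pd.DataFrame, wind_df: pd.DataFrame,
                     radius_deg: float) -> dict[str, float]:
    """Mean wind speed per site from its nearest station strictly within
    the Chebyshev matching radius; unmatched sites are absent."""
    if "latitude" not in wind_df.columns or "longitude" not in wind_df.columns:
        raise FormatError("wind table needs latitude/longitude columns for matching")
    stations = wind_df.groupby("station").agg(
        latitude=("latitude", "first"), longitude=("longitude", "first"),
        mean_ws=("ws", "mean"))
    coords = stations[["latitude", "longitude"]].to_numpy()
    out = {}
    for _, row in sites_df.iterrows():
        idx = match_weather_station((row["latitude"], row["longitude"]),
                                    coords, radius_deg)
        if idx is not None:
            out[row["site"]] = float(stations["mean_ws"].iloc[idx])
    return out


def _summary_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame([{
        "group": s.label, "n_sites": s.n_sites, "median_lambda": s.median_lambda,
        "q25": s.iqr[0], "q75": s.iqr[1],
        "q2.5": s.interval95[0], "q97.5": s.interval95[1]} for s in summaries])


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """QC -> per-site tail fits -> ensemble summaries, with CSV outputs.

    Returns the tables also written to ``config.outdir``: ``qc`` (one row
    per series, with failure reasons), ``results`` (one row per fitted
    site), ``family_mean_loglik`` (model selection across the ensemble),
    ``scatter`` (the parameter-plane table), ``category_summary`` and — when
    wind data are available — ``wind_summary``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sites_df = read_sites(config.sites)
    series_list = read_observations(config.observations, lod=config.lod,
                                    sites_meta=sites_df)

    qc_rows, fits, failures = [], [], []
    for series in series_list:
        series, report = run_qc(series, min_points=config.min_points,
                                lod_frac=config.lod_frac,
                                repeat_frac=config.repeat_frac)
        qc_rows.append({
            "site": report.site_code, "pollutant": report.pollutant,
            "n_points": report.n_points, "frac_below_lod": report.frac_below_lod,
            "max_value_frac": report.max_value_frac, "passed": report.passed,
            "reasons": ";".join(report.reasons), "skipped": ";".join(report.skipped)})
        if not report.passed:
            continue
        try:
            fits.append(fit_site(series, qc_report=report, config=config))
        except AirTailsError as exc:
            failures.append({"site": series.site_code, "pollutant": series.pollutant,
                             "error": str(exc)})
            log.warning("fit failed for %s/%s: %s", series.site_code,
                        series.pollutant, exc)

    qc_df = pd.DataFrame(qc_rows)
    results = _results_frame(fits)
    tables: dict[str, pd.DataFrame] = {"qc": qc_df, "results": results}

    if fits:
        # ensemble model selection: the family whose mean log-likelihood
        # across sites is highest
        loglik_cols = [c for c in results.columns if c.startswith("loglik_")]
        mean_ll = results[loglik_cols].mean().rename_axis("family").reset_index(name="mean_loglik")
        mean_ll["family"] = mean_ll["family"].str.removeprefix("loglik_")
        tables["family_mean_loglik"] = mean_ll.sort_values(
            "mean_loglik", ascending=False, ignore_index=True)

        categories = {row["site"]: classify_site(row["site_type"], row["site_area"])
                      for _, row in sites_df.iterrows()}
        tables["scatter"] = scatter_table(fits, categories)
        tables["category_summary"] = _summary_frame(
            group_lambda_summary(fits, categories))

        wind_path = Path(config.wind)
        if wind_path.exists():
            wind_df = read_wind(wind_path)
            means = _wind_site_means(sites_df, wind_df, config.match_radius_deg)
            wind_groups = {site: beaufort_class(ws, config.beaufort_bounds).label
                           for site, ws in means.items()}
            fits_with_wind = [f for f in fits if f.site_code in wind_groups]
            if fits_with_wind:
                tables["wind_summary"] = _summary_frame(
                    group_lambda_summary(fits_with_wind, wind_groups))

    if failures:
        tables["failures"] = pd.DataFrame(failures)
        log.warning("%d site fits failed; see failures.csv", len(failures))

    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    log.info("pipeline done: %d series, %d passed QC, %d fitted",
             len(series_list), int(qc_df["passed"].sum()) if len(qc_df) else 0,
             len(fits))
    return tables
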