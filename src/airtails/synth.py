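"""Synthetic superstatistical concentration ensembles.

The generator emulates the statistical structure of hourly air-quality
monitoring data: concentrations are locally exponential with a rate
``lambda`` that fluctuates on a much longer time scale.  The rate is drawn
from a Gamma(a, theta) distribution once per window of ``window_hours`` and
held constant within the window, which makes the long-run marginal an exact
q-exponential with

    q = (a + 2)/(a + 1),      lambda_q = theta * (a + 1).

Note the distinct superstatistical convention ``q = <lam^2>/<lam>^2``
applied to the same Gamma rate gives ``1 + 1/a``; both are exposed (see
:func:`marginal_qexp` and :func:`airtails.qexp.superstat_q`) and the
marginal exponent is the one an MLE on the series estimates.

On top of the stationary mixture the generator adds the blemishes of real
monitoring data: a multiplicative seasonal cycle of the mean concentration,
below-detection-limit substitution at LOD/2, and stuck-sensor runs of a
constant value.  :func:`gen_site_ensemble` assembles a whole network of
sites with environment categories, coordinates and co-located wind-speed
series, with planted category ordering and planted QC defects, all
reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError
from .qc import POLLUTANTS, SiteSeries, substitute_lod
from .qexp import QExpParams

__all__ = [
    "SuperstatConfig",
    "SyntheticEnsemble",
    "DEFAULT_CATEGORY_PARAMS",
    "gen_lambda_process",
    "gen_concentration_series",
    "marginal_qexp",
    "gen_site_ensemble",
]

_START = "2017-01-01 00:00"

# Planted per-category Gamma parameters (a, theta).  theta increases from
# the most polluted environment (urban traffic, small lambda_q = theta*(a+1),
# high mean concentration) to the cleanest (rural background), mirroring the
# typical ranking of European monitoring networks.  With a = 2 every
# category has marginal q = 4/3.
DEFAULT_CATEGORY_PARAMS: dict[str, tuple[float, float]] = {
    "urban traffic": (2.0, 0.02),
    "suburban/rural traffic": (2.0, 0.04),
    "urban industrial": (2.0, 0.07),
    "urban background": (2.0, 0.10),
    "suburban background": (2.0, 0.15),
    "suburban/rural industrial": (2.0, 0.22),
    "rural background": (2.0, 0.30),
}

# one representative (station_type, area_type) pair per category
_CATEGORY_TYPES = {
    "urban traffic": ("traffic", "urban"),
    "suburban/rural traffic": ("traffic", "rural"),
    "urban industrial": ("industrial", "urban"),
    "urban background": ("background", "urban"),
    "suburban background": ("background", "suburban"),
    "rural background": ("background", "rural"),
    "suburban/rural industrial": ("industrial", "suburban"),
}

# per-site mean wind speeds (m/s) cycled across sites so all four Beaufort
# classes are populated
_WIND_MEANS = (0.8, 2.5, 4.5, 6.5)


@dataclass(frozen=True)
class SuperstatConfig:
    """Parameters of one synthetic site's superstatistical series.

    ``a`` and ``theta`` are the Gamma shape and scale of the fluctuating
    rate (units of ``theta``: 1/(µg/m³)); ``window_hours`` is the slow time
    scale over which the rate is held constant.  ``seasonal_amp`` modulates
    the mean concentration 1/lambda multiplicatively with period
    ``period_hours`` (one year by default).  ``lod`` enables detection-limit
    censoring at LOD/2; ``stuck_frac`` > 0 plants a contiguous run of
    ``stuck_value`` covering that fraction of the series.
    """

    a: float = 2.0
    theta: float = 0.1
    window_hours: int = 168
    n_hours: int = 43800
    seasonal_amp: float = 0.0
    period_hours: float = 8760.0
    lod: float | None = None
    stuck_frac: float = 0.0
    stuck_value: float = 7.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.theta <= 0:
            raise ParameterError("Gamma shape and scale must be positive")
        if self.window_hours < 1 or self.n_hours < 1:
            raise ParameterError("window_hours and n_hours must be >= 1")
        if not (0.0 <= self.seasonal_amp < 1.0):
            raise ParameterError("seasonal_amp must lie in [0, 1)")
        if not (0.0 <= self.stuck_frac < 1.0):
            raise ParameterError("stuck_frac must lie in [0, 1)")


@dataclass(frozen=True)
class SyntheticEnsemble:
    """Observation, site-metadata and wind tables for a synthetic network.

    ``manifest`` records the planted truth per site: environment category,
    Gamma parameters, marginal (q, lambda_q), mean wind speed and which QC
    defect (if any) was planted.
    """

    observations: pd.DataFrame
    sites: pd.DataFrame
    wind: pd.DataFrame
    manifest: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the three pipeline CSVs (plus the manifest) to ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [("observations", self.observations), ("sites", self.sites),
                         ("wind", self.wind), ("manifest", self.manifest)]:
            path = outdir / f"{name}.csv"
            df.to_csv(path, index=False)
            paths[name] = path
        return paths


def gen_lambda_process(config: SuperstatConfig) -> np.ndarray:
    """Hourly piecewise-constant rate process lambda(t).

    One independent Gamma(a, theta) draw per window of ``window_hours``,
    held constant within the window.  Seasonality multiplies the mean
    concentration 1/lambda by ``1 + seasonal_amp*sin(2*pi*t/period_hours)``,
    i.e. divides lambda by that factor.
    """
    rng = np.random.default_rng([config.seed, 0])
    n_windows = -(-config.n_hours // config.window_hours)  # ceil
    draws = rng.gamma(shape=config.a, scale=config.theta, size=n_windows)
    lam = np.repeat(draws, config.window_hours)[: config.n_hours]
    if config.seasonal_amp > 0.0:
        t = np.arange(config.n_hours, dtype=float)
        lam = lam / (1.0 + config.seasonal_amp * np.sin(2.0 * np.pi * t / config.period_hours))
    return lam


def gen_concentration_series(config: SuperstatConfig, *,
                             site_code: str = "syn0001",
                             pollutant: str = "no2",
                             station_type: str | None = None,
                             area_type: str | None = None,
                             latitude: float | None = None,
                             longitude: float | None = None) -> SiteSeries:
    """One site's hourly concentration series.

    Each hour's concentration is an independent Exponential(rate lambda(t))
    draw; stuck-sensor corruption and LOD/2 substitution are then applied if
    configured.  Fully reproducible from ``config.seed``.
    """
    if pollutant not in POLLUTANTS:
        raise DataError(f"pollutant must be one of {POLLUTANTS}")
    lam = gen_lambda_process(config)
    rng = np.random.default_rng([config.seed, 1])
    values = rng.exponential(scale=1.0 / lam)
    if config.stuck_frac > 0.0:
        run = int(round(config.stuck_frac * config.n_hours))
        start = int(rng.integers(0, config.n_hours - run + 1))
        values[start:start + run] = config.stuck_value
    timestamps = pd.date_range(_START, periods=config.n_hours, freq="h", tz="UTC")
    series = SiteSeries(
        site_code=site_code, pollutant=pollutant, timestamps=timestamps,
        values=values, lod=config.lod, station_type=station_type,
        area_type=area_type, latitude=latitude, longitude=longitude)
    if config.lod is not None:
        series = substitute_lod(series)
    return series


def marginal_qexp(a: float, theta: float) -> QExpParams:
    """Closed-form marginal of the Gamma(a, theta) mixture of exponentials.

    Integrating ``lam * exp(-lam*x)`` over a Gamma(a, theta) rate gives
    ``a*theta*(1 + theta*x)**-(a+1)``, which is exactly the q-exponential
    with ``q = (a+2)/(a+1)`` and ``lambda_q = theta*(a+1)``.
    """
    if a <= 0 or theta <= 0:
        raise ParameterError("Gamma shape and scale must be positive")
    return QExpParams(q=(a + 2.0) / (a + 1.0), lam=theta * (a + 1.0))


def _site_coords(i: int) -> tuple[float, float]:
    # >= 1 degree spacing so each site's own weather station is its nearest
    return 40.0 + (i // 20) * 1.0, -10.0 + (i % 20) * 1.5


def gen_site_ensemble(n_sites: int,
                      category_params: dict[str, tuple[float, float]] | None = None,
                      *,
                      seed: int = 0,
                      n_hours: int = 17520,
                      window_hours: int = 168,
                      seasonal_amp: float = 0.3,
                      lod: float = 0.1,
                      wind_frac: float = 0.8,
                      n_short: int = 0,
                      n_stuck: int = 0,
                      n_below_lod: int = 0) -> SyntheticEnsemble:
    """Generate a whole synthetic monitoring network.

    Sites are assigned environment categories round-robin (deterministic
    proportions) with per-category Gamma parameters so the category medians
    of lambda follow the planted ordering of ``category_params``.  The last
    ``n_short + n_stuck + n_below_lod`` sites carry planted QC defects,
    each constructed to clear its filter threshold with a wide margin:
    short series (half a year), a stuck run covering 30% of the series, or
    concentrations almost entirely below the detection limit.  A fraction
    ``wind_frac`` of sites gets a co-located weather station strictly
    within 0.1 degrees; the rest get one at 0.2 degrees, too far to match.
    """
    if n_sites < 1:
        raise DataError("n_sites must be >= 1")
    n_defect = n_short + n_stuck + n_below_lod
    if n_defect > n_sites:
        raise DataError("more planted defects than sites")
    params = category_params or DEFAULT_CATEGORY_PARAMS
    categories = list(params)
    site_seeds = np.random.SeedSequence(seed).generate_state(2 * n_sites) % (2**31)

    obs_frames, site_rows, wind_frames, manifest_rows = [], [], [], []
    n_wind = int(round(wind_frac * n_sites))
    for i in range(n_sites):
        code = f"syn{i:04d}"
        category = categories[i % len(categories)]
        a, theta = params[category]
        station_type, area_type = _CATEGORY_TYPES[category]
        lat, lon = _site_coords(i)
        pollutant = POLLUTANTS[i % len(POLLUTANTS)]

        defect = "none"
        cfg = SuperstatConfig(a=a, theta=theta, window_hours=window_hours,
                              n_hours=n_hours, seasonal_amp=seasonal_amp,
                              lod=lod, seed=int(site_seeds[i]))
        k = i - (n_sites - n_defect)  # index among defective sites, if any
        if 0 <= k < n_short:
            defect = "short"
            cfg = replace(cfg, n_hours=4380)
        elif n_short <= k < n_short + n_stuck:
            defect = "stuck"
            cfg = replace(cfg, stuck_frac=0.30, stuck_value=50.0 / (theta * 10))
        elif k >= n_short + n_stuck and k >= 0:
            defect = "below_lod"
            cfg = replace(cfg, a=2.0, theta=20.0)

        series = gen_concentration_series(
            cfg, site_code=code, pollutant=pollutant, station_type=station_type,
            area_type=area_type, latitude=lat, longitude=lon)
        obs_frames.append(pd.DataFrame({
            "date": series.timestamps.strftime("%Y-%m-%d %H:%M:%S"),
            "site": code, "variable": pollutant, "value": series.values}))
        site_rows.append({"site": code, "site_type": station_type,
                          "site_area": area_type, "latitude": lat, "longitude": lon})

        # wind station: co-located within the matching radius for the first
        # n_wind sites, deliberately too far for the rest
        ws_mean = _WIND_MEANS[i % len(_WIND_MEANS)]
        d = 0.05 if i < n_wind else 0.2
        wrng = np.random.default_rng([int(site_seeds[n_sites + i]), 2])
        ws = wrng.gamma(shape=4.0, scale=ws_mean / 4.0, size=series.timestamps.size)
        wind_frames.append(pd.DataFrame({
            "station": f"wx{i:04d}",
            "date": series.timestamps.strftime("%Y-%m-%d %H:%M:%S"),
            "ws": ws, "latitude": lat + d, "longitude": lon - d * 0.6}))

        marg = marginal_qexp(cfg.a, cfg.theta)
        manifest_rows.append({
            "site": code, "variable": pollutant, "category": category,
            "a": cfg.a, "theta": cfg.theta, "q_marginal": marg.q,
            "lambda_marginal": marg.lam, "mean_ws": ws_mean,
            "wind_matched": i < n_wind, "defect": defect})

    return SyntheticEnsemble(
        observations=pd.concat(obs_frames, ignore_index=True),
        sites=pd.DataFrame(site_rows),
        wind=pd.concat(wind_frames, ignore_index=True),
        manifest=pd.DataFrame(manifest_rows))
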