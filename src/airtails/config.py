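"""Pipeline configuration: the single source of truth for every threshold.

All QC thresholds, the station-matching radius, KDE settings, MLE settings
and the Beaufort class boundaries live here and nowhere else; the stage
functions take them as keyword arguments that default to these values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import FormatError

__all__ = ["PipelineConfig", "DEFAULT_BEAUFORT_BOUNDS"]

# upper bounds (m/s, inclusive) of the four lowest Beaufort classes, with
# Beaufort 0 and 1 merged into "calm & light air"
DEFAULT_BEAUFORT_BOUNDS = (1.5, 3.3, 5.4, 7.9)


@dataclass
class PipelineConfig:
    """Everything needed to run the pipeline end to end.

    Thresholds: a series needs ``min_points`` = 8760 valid hourly values
    (one full year) to be analysed; a site is rejected if strictly more than
    ``lod_frac`` = 15% of its values fall below the detection limit, or if a
    single repeated value accounts for at least ``repeat_frac`` = 15% of the
    measurements.  A pollution site is paired with a weather station only if
    the Chebyshev distance max(|dlat|, |dlon|) is strictly below
    ``match_radius_deg`` = 0.1 degrees.
    """

    # input/output paths
    observations: str = "observations.csv"
    sites: str = "sites.csv"
    wind: str = "wind.csv"
    outdir: str = "out"

    # QC thresholds
    min_points: int = 8760
    lod_frac: float = 0.15
    repeat_frac: float = 0.15
    lod: float | None = None  # detection limit in ug/m3; None skips the LOD filter

    # KDE peak detection
    kde_grid_size: int = 512
    kde_bw_method: str = "scott"

    # MLE settings
    mle_tol: float = 1e-8
    mle_max_iter: int = 500

    # weather-station matching and wind classes
    match_radius_deg: float = 0.1
    beaufort_bounds: tuple[float, ...] = DEFAULT_BEAUFORT_BOUNDS

    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_points <= 0 or self.lod_frac <= 0 or self.repeat_frac <= 0:
            raise FormatError("QC thresholds must be positive")
        if self.match_radius_deg <= 0:
            raise FormatError("match radius must be positive")
        self.beaufort_bounds = tuple(float(b) for b in self.beaufort_bounds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load from a flat YAML mapping; unknown keys are rejected."""
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            return cls()
        if not isinstance(raw, dict):
            raise FormatError(f"config file {path} must contain a flat mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data["beaufort_bounds"] = list(self.beaufort_bounds)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
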