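"""Seeded synthetic data with the statistical structure the pipeline assumes.

The generator emulates the three kinds of input the analysis consumes:

* **Point tables** — field points scattered over the plateau extent with
  elevations in a high-mountain band, temperature tied to elevation through a
  standard environmental lapse rate, LAI decreasing with elevation and
  increasing eastward, and oxygen concentration generated from the
  composite-index model itself (index built with the default contribution
  weights, line with the published slope/intercept) plus Gaussian noise whose
  default standard deviation (0.0952%) matches the held-out RMSE scale of the
  fitted model.
* **Raster stacks** — small co-registered elevation/temperature/LAI grids on
  the plateau bounding box with stylized east-low/west-high topography, a
  nodata margin, and seasonal variants (July warmer and leafier than January,
  cell by cell, by construction).
* **Calibration sessions** — simultaneous readings of instrument groups A-D
  around a latent true concentration, each group offset by its own linear
  response (group B the identity by default).

Everything is driven by an explicit seed; there is no hidden global
randomness.  The gradients are stylized — no attempt is made to reproduce the
real plateau's basins and ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Mapping, Optional, Sequence

import numpy as np

from .calibration import CalibrationSession
from .estimation import (
    ContributionWeights,
    LinearModel,
    NormalizationBounds,
    PLATEAU_MODEL,
    PLATEAU_WEIGHTS,
    composite_index,
    fit_minmax_bounds,
    normalize,
    predict_oxygen,
)
from .measurements import (
    MeasurementRecord,
    MeasurementTable,
    PLATEAU_EAST,
    PLATEAU_NORTH,
    PLATEAU_SOUTH,
    PLATEAU_WEST,
)
from .rasters import DEFAULT_NODATA, GeoTransform, RasterGrid, RasterStack

__all__ = [
    "SyntheticConfig",
    "PointTruth",
    "generate_points",
    "generate_rasters",
    "generate_calibration_sessions",
]

#: Default seasonal adjustments (degC added to temperature; factor on LAI).
_SEASON_TEMP_OFFSET = {"annual": 0.0, "january": -10.0, "july": 5.0}
_SEASON_LAI_FACTOR = {"annual": 0.6, "january": 0.15, "july": 1.0}


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; defaults are the study-scale conditions."""

    n_points: int = 422
    elevation_range: tuple[float, float] = (2000.0, 5500.0)
    #: Environmental lapse rate, degC per meter (negative: cooling aloft).
    lapse_rate: float = -6.0 / 1000.0
    sea_level_temperature: float = 25.0
    temperature_noise_sd: float = 1.5
    lai_max: float = 4.0
    lai_noise_sd: float = 0.3
    oc_model: LinearModel = PLATEAU_MODEL
    weights: ContributionWeights = PLATEAU_WEIGHTS
    noise_sd: float = 0.0952
    raster_shape: tuple[int, int] = (40, 60)
    extent: tuple[float, float, float, float] = (
        PLATEAU_WEST,
        PLATEAU_SOUTH,
        PLATEAU_EAST,
        PLATEAU_NORTH,
    )
    nodata_margin: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 4:
            raise ValueError("n_points must be at least 4")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if min(self.raster_shape) < 2:
            raise ValueError("raster dimensions must be at least 2x2")


@dataclass(frozen=True)
class PointTruth:
    """Generating parameters of a synthetic point table."""

    model: LinearModel
    weights: ContributionWeights
    bounds: NormalizationBounds
    noise_sd: float
    tmp: np.ndarray = field(repr=False, default=None)


def _point_environment(cfg: SyntheticConfig, rng: np.random.Generator, n: int):
    """Sample positions and the three drivers for n points."""
    west, south, east, north = cfg.extent
    lon = rng.uniform(west, east, n)
    lat = rng.uniform(south, north, n)
    lo, hi = cfg.elevation_range
    elev = rng.uniform(lo, hi, n)
    temp = (
        cfg.sea_level_temperature
        + cfg.lapse_rate * elev
        + rng.normal(0.0, cfg.temperature_noise_sd, n)
    )
    z = (elev - lo) / (hi - lo)
    east_frac = (lon - west) / (east - west)
    lai = np.clip(
        cfg.lai_max * (0.7 * (1.0 - z) + 0.3 * east_frac)
        + rng.normal(0.0, cfg.lai_noise_sd, n),
        0.0,
        None,
    )
    return lon, lat, elev, temp, lai


def generate_points(
    cfg: SyntheticConfig = SyntheticConfig(),
) -> tuple[MeasurementTable, np.ndarray, PointTruth]:
    """Generate a point measurement table plus per-record LAI and the truth.

    Oxygen concentration is built from the configured model: Min-Max bounds
    are taken over the generated sample, the composite index is formed with
    the configured weights, and OC = slope*Tmp + intercept + N(0, noise_sd).
    Reproducible given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_points
    lon, lat, elev, temp, lai = _point_environment(cfg, rng, n)
    bounds = fit_minmax_bounds(elev, temp, lai)
    tmp = composite_index(
        normalize(elev, bounds.elevation),
        normalize(temp, bounds.temperature),
        normalize(lai, bounds.lai),
        cfg.weights,
    )
    oc = predict_oxygen(tmp, cfg.oc_model) + rng.normal(0.0, cfg.noise_sd, n)

    # Timestamps in the late-July/early-August field window, cycling 2018-2020
    # (the group-B instrument years).
    records = []
    for i in range(n):
        year = 2018 + i % 3
        ts = datetime(year, 7, 25, 9, 0) + timedelta(
            days=int(rng.integers(0, 12)), minutes=int(rng.integers(0, 540))
        )
        pressure = 1013.25 * float(np.exp(-elev[i] / 8434.0))
        records.append(
            MeasurementRecord(
                tid=f"SYN-{i:04d}",
                fid=f"PT-{i:04d}",
                timestamp=ts,
                longitude=float(lon[i]),
                latitude=float(lat[i]),
                elevation=float(elev[i]),
                temperature=float(temp[i]),
                relative_humidity=float(rng.uniform(10.0, 90.0)),
                pressure=pressure,
                oxygen_concentration=float(oc[i]),
            )
        )
    table = MeasurementTable(records=records, source="synthetic")
    truth = PointTruth(
        model=cfg.oc_model, weights=cfg.weights, bounds=bounds, noise_sd=cfg.noise_sd, tmp=tmp
    )
    return table, lai, truth


def generate_rasters(cfg: SyntheticConfig = SyntheticConfig(), month: str = "annual") -> RasterStack:
    """Co-registered elevation/temperature/LAI stack for one season.

    ``month`` is "annual", "january" or "july".  July grids are warmer and
    leafier than January grids cell by cell (same seeded noise field, only the
    seasonal offset/factor differs).  A nodata margin rings the grid.
    """
    if month not in _SEASON_TEMP_OFFSET:
        raise ValueError(f"month must be one of {sorted(_SEASON_TEMP_OFFSET)}, got {month!r}")
    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.raster_shape
    west, south, east, north = cfg.extent
    transform = GeoTransform(
        west=west, north=north, dx=(east - west) / cols, dy=(north - south) / rows
    )
    xfrac = (np.arange(cols) + 0.5) / cols
    yfrac = (np.arange(rows) + 0.5) / rows
    xg, yg = np.meshgrid(xfrac, yfrac)

    lo, hi = cfg.elevation_range
    # Stylized topography: high in the west, descending eastward, with
    # east-west trending ridges and a little seeded roughness.
    relief = 0.75 * (1.0 - xg) + 0.15 * (0.5 + 0.5 * np.sin(4.0 * np.pi * yg))
    elev = lo + (hi - lo) * np.clip(relief + rng.normal(0.0, 0.02, (rows, cols)), 0.0, 1.0)
    temp = (
        cfg.sea_level_temperature
        + cfg.lapse_rate * elev
        + _SEASON_TEMP_OFFSET[month]
        + rng.normal(0.0, 0.3, (rows, cols))
    )
    z = (elev - lo) / (hi - lo)
    lai_base = np.clip(
        cfg.lai_max * (0.7 * (1.0 - z) + 0.3 * xg) + rng.normal(0.0, cfg.lai_noise_sd, (rows, cols)),
        0.0,
        None,
    )
    lai = lai_base * _SEASON_LAI_FACTOR[month]

    m = cfg.nodata_margin
    grids = []
    for arr in (elev, temp, lai):
        a = arr.copy()
        if m > 0:
            a[:m, :] = DEFAULT_NODATA
            a[-m:, :] = DEFAULT_NODATA
            a[:, :m] = DEFAULT_NODATA
            a[:, -m:] = DEFAULT_NODATA
        grids.append(RasterGrid(values=a, transform=transform, nodata=DEFAULT_NODATA))
    return RasterStack(elevation=grids[0], temperature=grids[1], lai=grids[2])


def generate_calibration_sessions(
    cfg: SyntheticConfig = SyntheticConfig(),
    group_offsets: Optional[Mapping[str, tuple[float, float]]] = None,
    n_sessions: int = 30,
    noise_sd: float = 0.01,
    groups: Sequence[str] = ("A", "B", "C", "D"),
) -> list[CalibrationSession]:
    """Simultaneous multi-group readings around latent true concentrations.

    Each group's reading is ``slope*truth + intercept + N(0, noise_sd)`` with
    per-group (slope, intercept) from ``group_offsets``.  Defaults give group
    B the identity response, the older CY-12C group (A) a visibly different
    response, and the other TD400 groups near-identity responses — matching
    the observed near-perfect agreement among same-model meters.
    """
    if n_sessions < 3:
        raise ValueError("n_sessions must be at least 3")
    offsets = {
        "A": (0.96, 0.70),
        "B": (1.0, 0.0),
        "C": (1.001, -0.02),
        "D": (0.999, 0.015),
    }
    if group_offsets:
        offsets.update(group_offsets)
    rng = np.random.default_rng(cfg.seed)
    sessions = []
    for i in range(n_sessions):
        truth = rng.uniform(19.6, 20.9)
        readings = {}
        for g in groups:
            slope, intercept = offsets[g]
            readings[g] = float(slope * truth + intercept + rng.normal(0.0, noise_sd))
        sessions.append(CalibrationSession(point_id=f"CAL-{i:03d}", readings=readings))
    return sessions
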