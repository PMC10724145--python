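"""Georeferenced grids and grid-by-grid oxygen-concentration mapping.

Rasters are single-band grids in geographic WGS-84 coordinates with a north-up
affine georeference (pixel-is-area, origin at the north-west corner, row-major
from the top) and a nodata sentinel (default -9999).  I/O is a lightweight
GeoTIFF reader/writer built on tifffile: values are stored as 32-bit floats
with the ModelPixelScale, ModelTiepoint, GeoKeyDirectory and GDAL_NODATA tags.

The mapping operations apply the fitted composite-index model cell by cell to
a co-registered elevation/temperature/LAI stack, difference two maps (July
minus January by convention), and measure ensemble spread (per-cell standard
deviation of predictions across a collection of fitted lines) as an
uncertainty layer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import tifffile

from .errors import CoregistrationError, ParameterError, RasterFormatError
from .estimation import (
    ContributionWeights,
    LinearModel,
    NormalizationBounds,
    PLATEAU_WEIGHTS,
    composite_index,
    normalize,
    predict_oxygen,
)

__all__ = [
    "GeoTransform",
    "RasterGrid",
    "RasterStack",
    "read_raster",
    "write_raster",
    "crop",
    "estimate_map",
    "difference_map",
    "uncertainty_map",
]

DEFAULT_NODATA = -9999.0
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class GeoTransform:
    """North-up affine georeference: NW-corner origin and pixel sizes.

    ``dx`` and ``dy`` are positive pixel widths/heights in degrees; rows run
    south from ``north``, columns east from ``west``.
    """

    west: float
    north: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("pixel sizes must be positive")

    def approx_equal(self, other: "GeoTransform", tol: float = 1e-9) -> bool:
        return (
            abs(self.west - other.west) <= tol
            and abs(self.north - other.north) <= tol
            and abs(self.dx - other.dx) <= tol
            and abs(self.dy - other.dy) <= tol
        )


@dataclass
class RasterGrid:
    """A single-band georeferenced grid with a nodata sentinel."""

    values: np.ndarray
    transform: GeoTransform
    crs: str = "EPSG:4326"
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("values must be a 2-D grid with at least one cell")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        """True where the cell holds a real value (finite and not nodata)."""
        return np.isfinite(self.values) & (self.values != self.nodata)

    def with_values(self, values: np.ndarray) -> "RasterGrid":
        return RasterGrid(values=values, transform=self.transform, crs=self.crs, nodata=self.nodata)


@dataclass(frozen=True)
class RasterStack:
    """Co-registered elevation, temperature and LAI layers."""

    elevation: RasterGrid
    temperature: RasterGrid
    lai: RasterGrid

    def __post_init__(self) -> None:
        _check_coregistered(self.elevation, self.temperature, self.lai)

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape


def _check_coregistered(*grids: RasterGrid) -> None:
    ref = grids[0]
    for g in grids[1:]:
        if g.shape != ref.shape:
            raise CoregistrationError(f"shape mismatch: {g.shape} vs {ref.shape}")
        if not g.transform.approx_equal(ref.transform):
            raise CoregistrationError("transform mismatch between layers")
        if g.crs != ref.crs:
            raise CoregistrationError(f"CRS mismatch: {g.crs!r} vs {ref.crs!r}")


def write_raster(grid: RasterGrid, path):
    """Write a grid to single-band float32 GeoTIFF with georeference tags."""
    t = grid.transform
    values = grid.values.astype(np.float32)
    # Geographic CRS keys: model type 2 (geographic), raster type 1
    # (pixel-is-area), EPSG geographic CS code (4326 for WGS-84).
    epsg = 4326 if grid.crs.upper() in ("EPSG:4326", "WGS84", "WGS-84") else 32767
    geokeys = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, epsg)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (t.dx, t.dy, 0.0), True),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.west, t.north, 0.0), True),
        (_TAG_GEO_KEYS, "H", len(geokeys), geokeys, True),
        (_TAG_GDAL_NODATA, "s", 0, repr(float(grid.nodata)), True),
    ]
    tifffile.imwrite(path, values, extratags=extratags)
    return path


def read_raster(path) -> RasterGrid:
    """Read a single-band georeferenced GeoTIFF written by :func:`write_raster`
    (or any north-up pixel-scale + tiepoint GeoTIFF)."""
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise RasterFormatError(f"expected a single-band raster, got {len(tif.pages)} pages")
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise RasterFormatError(
                f"expected a single-band raster, got {page.samplesperpixel} samples per pixel"
            )
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise RasterFormatError("missing georeference (pixel scale / tiepoint) tags")
        sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
        tie = tags[_TAG_TIEPOINT].value
        # Tiepoint maps raster (i, j) to model (x, y); require the NW corner.
        west = tie[3] - tie[0] * sx
        north = tie[4] + tie[1] * sy
        crs = "EPSG:4326"
        if _TAG_GEO_KEYS in tags:
            keys = tags[_TAG_GEO_KEYS].value
            for k in range(4, len(keys) - 3, 4):
                if keys[k] == 2048 and keys[k + 3] != 4326:
                    crs = f"EPSG:{keys[k + 3]}"
        nodata = DEFAULT_NODATA
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00"))
        values = tif.asarray().astype(float)
    return RasterGrid(
        values=values,
        transform=GeoTransform(west=float(west), north=float(north), dx=float(sx), dy=float(sy)),
        crs=crs,
        nodata=nodata,
    )


def crop(grid: RasterGrid, row0: int, row1: int, col0: int, col1: int) -> RasterGrid:
    """Sub-grid [row0:row1, col0:col1] with the origin shifted accordingly."""
    rows, cols = grid.shape
    if not (0 <= row0 < row1 <= rows and 0 <= col0 < col1 <= cols):
        raise ParameterError("crop window outside grid")
    t = grid.transform
    new_t = replace(t, west=t.west + col0 * t.dx, north=t.north - row0 * t.dy)
    return RasterGrid(
        values=grid.values[row0:row1, col0:col1].copy(),
        transform=new_t,
        crs=grid.crs,
        nodata=grid.nodata,
    )


def estimate_map(
    stack: RasterStack,
    weights: ContributionWeights = PLATEAU_WEIGHTS,
    bounds: NormalizationBounds = None,
    model: LinearModel = None,
    clamp: bool = True,
) -> RasterGrid:
    """Oxygen-concentration map: normalize each layer, form the composite
    index, and apply the linear model, cell by cell.

    A cell is nodata in the output wherever any input layer is nodata.  The
    output inherits the stack's transform and CRS.
    """
    if bounds is None:
        raise ParameterError("normalization bounds are required")
    model = model if model is not None else LinearModel()
    valid = (
        stack.elevation.valid_mask() & stack.temperature.valid_mask() & stack.lai.valid_mask()
    )
    ne = normalize(stack.elevation.values, bounds.elevation, clamp=clamp)
    nt = normalize(stack.temperature.values, bounds.temperature, clamp=clamp)
    nl = normalize(stack.lai.values, bounds.lai, clamp=clamp)
    oc = predict_oxygen(composite_index(ne, nt, nl, weights), model)
    out = stack.elevation.with_values(np.where(valid, oc, stack.elevation.nodata))
    return out


def difference_map(july: RasterGrid, january: RasterGrid) -> RasterGrid:
    """Seasonal contrast map: July minus January, cell by cell.

    Positive values mean the July oxygen concentration exceeds January's (the
    expected direction: warmer air and active vegetation in July).  Nodata in
    either input propagates.
    """
    _check_coregistered(july, january)
    valid = july.valid_mask() & january.valid_mask()
    diff = july.values - january.values
    return july.with_values(np.where(valid, diff, july.nodata))


def uncertainty_map(
    stack: RasterStack,
    weights: ContributionWeights = PLATEAU_WEIGHTS,
    bounds: NormalizationBounds = None,
    models: Sequence[LinearModel] = (),
    clamp: bool = True,
) -> RasterGrid:
    """Ensemble spread: per-cell standard deviation of predicted OC across models.

    The ensemble is the collection of averaged lines produced by the
    cross-validation configurations.  Population standard deviation; order of
    models is irrelevant; nodata propagates.
    """
    if bounds is None:
        raise ParameterError("normalization bounds are required")
    if len(models) < 2:
        raise ParameterError("uncertainty map needs an ensemble of at least 2 models")
    valid = (
        stack.elevation.valid_mask() & stack.temperature.valid_mask() & stack.lai.valid_mask()
    )
    ne = normalize(stack.elevation.values, bounds.elevation, clamp=clamp)
    nt = normalize(stack.temperature.values, bounds.temperature, clamp=clamp)
    nl = normalize(stack.lai.values, bounds.lai, clamp=clamp)
    tmp = composite_index(ne, nt, nl, weights)
    preds = np.stack([predict_oxygen(tmp, m) for m in models])
    # Sorting along the ensemble axis makes the reduction exactly invariant
    # to the order the models are supplied in.
    preds.sort(axis=0)
    std = preds.std(axis=0)  # population formula across the ensemble
    return stack.elevation.with_values(np.where(valid, std, stack.elevation.nodata))
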