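import numpy as np
import pytest

import oxymap as ox


@pytest.fixture(scope="session")
def reference_table() -> ox.MeasurementTable:
    """The bundled 13-point Qinghai Lake route sample."""
    return ox.load_reference_points()


@pytest.fixture(scope="session")
def synthetic_points():
    """Default-scale synthetic point table (n=422) with LAI and truth."""
    cfg = ox.SyntheticConfig(seed=1)
    return ox.generate_points(cfg)


@pytest.fixture()
def small_stack() -> ox.RasterStack:
    """Small synthetic annual raster stack with a nodata margin."""
    cfg = ox.SyntheticConfig(raster_shape=(12, 18), seed=7)
    return ox.generate_rasters(cfg, month="annual")


@pytest.fixture()
def stack_bounds(small_stack) -> ox.NormalizationBounds:
    """Min-Max bounds computed from the valid cells of the small stack."""
    valid = (
        small_stack.elevation.valid_mask()
        & small_stack.temperature.valid_mask()
        & small_stack.lai.valid_mask()
    )
    return ox.fit_minmax_bounds(
        small_stack.elevation.values[valid],
        small_stack.temperature.values[valid],
        small_stack.lai.values[valid],
    )


def design_matrix(table, lai):
    """(n, 3) driver matrix [elevation, temperature, lai] from a table."""
    return np.column_stack(
        [[r.elevation for r in table], [r.temperature for r in table], np.asarray(lai)]
    ).astype(float)
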