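"""Shared fixtures: small layouts and rasters built programmatically."""

import numpy as np
import pandas as pd
import pytest

from orthopheno import (
    CameraPose,
    GeoRaster,
    attach_plot_map,
    build_plot_grid,
)

UNIT_CORNERS = [(0.0, 1.0), (1.0, 1.0), (1.0, 0.0), (0.0, 0.0)]


@pytest.fixture
def unit_layout():
    """2x2 grid of 0.4x0.4 plots inside the unit square, fully labelled."""
    grid = build_plot_grid(UNIT_CORNERS, 2, 2, 0.4, 0.4, crs_tag="local-metric")
    plot_map = pd.DataFrame(
        {
            "plot_id": ["p11", "p12", "p21", "p22"],
            "entry": ["E1", "E2", "E2", "E1"],
            "block": [1, 1, 2, 2],
            "row": [1, 1, 2, 2],
            "col": [1, 2, 1, 2],
        }
    )
    return attach_plot_map(grid, plot_map)


def make_thermal_raster(
    dn: np.ndarray,
    origin=(0.0, 1.0),
    gsd=0.01,
    pose: CameraPose | None = None,
    image_id="IMG0000",
) -> GeoRaster:
    """Wrap a DN array as a north-up thermal GeoRaster (nodata DN = 0)."""
    return GeoRaster(
        bands={"thermal_ir": np.asarray(dn, dtype=np.uint16)},
        transform=(origin[0], gsd, 0.0, origin[1], 0.0, -gsd),
        nodata=0.0,
        crs_tag="local-metric",
        pose=pose,
        image_id=image_id,
    )


@pytest.fixture
def thermal_field_raster(unit_layout):
    """100x100 thermal raster covering the unit layout, one DN per plot."""
    dn = np.full((100, 100), 7000, dtype=np.uint16)
    # paint each plot with a distinct DN on the 0.01 m grid
    for k, plot in enumerate(unit_layout.plots):
        xmin, ymin, xmax, ymax = plot.polygon.bounds
        c0, c1 = round(xmin / 0.01), round(xmax / 0.01)
        r0, r1 = round((1 - ymax) / 0.01), round((1 - ymin) / 0.01)
        dn[r0:r1, c0:c1] = 7400 + 25 * k
    return make_thermal_raster(dn)
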