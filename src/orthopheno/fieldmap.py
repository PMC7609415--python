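"""Georeferenced plot grids ("field maps") for breeding trials.

A field experiment is a regular grid of small rectangular plots.  Surveying
all plot corners is impractical; instead the four corners of the whole
experiment are surveyed and every plot polygon is interpolated from them,
given the grid dimensions and the sown plot size.  Each grid cell spans the
full row/column pitch (plot plus alley); the plot polygon is the cell shrunk
about its centre to the stated plot length and width.

Conventions
-----------
* Field corners are given in the fixed order NW, NE, SE, SW.
* ``row`` increases from the NW corner toward SW; ``col`` from NW toward NE.
* ``plot_width_m`` runs along the column (NW->NE) direction and
  ``plot_length_m`` along the row (NW->SW) direction.
* Coordinates are (x, y) = (easting or longitude, northing or latitude);
  polygon rings are counter-clockwise.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, shape, mapping
from shapely.geometry.polygon import orient

from ._geo import ground_distance, is_geographic

logger = logging.getLogger(__name__)

__all__ = [
    "PlotRecord",
    "FieldLayout",
    "build_plot_grid",
    "attach_plot_map",
    "read_layout",
    "write_layout",
]


@dataclass(frozen=True)
class PlotRecord:
    """One plot: its polygon and experimental-design labels.

    ``entry`` is the genetic line sown in the plot; ``block`` the complete
    replicate; ``row``/``col`` the plot's grid position (nested within block
    when fitting row/column effects).  Unlabelled grid cells (alleys, fill)
    carry ``entry=None`` until a plot map is attached.
    """

    plot_id: str
    row: int
    col: int
    polygon: Polygon
    entry: str | None = None
    block: int | None = None

    def __post_init__(self) -> None:
        if not self.polygon.is_valid or len(self.polygon.exterior.coords) < 5:
            raise ValueError(f"plot {self.plot_id}: polygon must be a simple closed ring of >= 4 vertices")

    @property
    def center(self) -> tuple[float, float]:
        c = self.polygon.centroid
        return (c.x, c.y)


@dataclass
class FieldLayout:
    """Grid of plot polygons with design labels and grid metadata."""

    plots: list[PlotRecord]
    crs_tag: str
    n_rows: int
    n_cols: int
    plot_length_m: float
    plot_width_m: float
    corners: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.plots) > self.n_rows * self.n_cols:
            raise ValueError("more plots than grid cells")
        ids = [p.plot_id for p in self.plots]
        if len(set(ids)) != len(ids):
            raise ValueError("plot_id values are not unique")
        labelled = [(p.block, p.row, p.col) for p in self.plots if p.block is not None]
        if len(set(labelled)) != len(labelled):
            raise ValueError("(block, row, col) triples are not unique")

    @property
    def is_labelled(self) -> bool:
        return bool(self.plots) and all(p.entry is not None for p in self.plots)

    @property
    def geographic(self) -> bool:
        return is_geographic(self.crs_tag)

    def get(self, plot_id: str) -> PlotRecord:
        for p in self.plots:
            if p.plot_id == plot_id:
                return p
        raise KeyError(plot_id)

    def design_frame(self) -> pd.DataFrame:
        """Design labels as a DataFrame (plot_id, entry, block, row, col)."""
        return pd.DataFrame(
            {
                "plot_id": [p.plot_id for p in self.plots],
                "entry": [p.entry for p in self.plots],
                "block": [p.block for p in self.plots],
                "row": [p.row for p in self.plots],
                "col": [p.col for p in self.plots],
            }
        )


def _bilinear(corners: np.ndarray, s: float, t: float) -> np.ndarray:
    """Map unit-square parameters (s, t) into the corner quadrilateral.

    s runs NW->NE (columns), t runs NW->SW (rows).
    """
    nw, ne, se, sw = corners
    return (1 - t) * ((1 - s) * nw + s * ne) + t * ((1 - s) * sw + s * se)


def _check_convex(corners: np.ndarray) -> None:
    crosses = []
    for i in range(4):
        a, b, c = corners[i], corners[(i + 1) % 4], corners[(i + 2) % 4]
        v1, v2 = b - a, c - b
        crosses.append(v1[0] * v2[1] - v1[1] * v2[0])
    crosses = np.asarray(crosses)
    if np.any(crosses == 0) or not (np.all(crosses > 0) or np.all(crosses < 0)):
        raise ValueError("field corners must form a convex quadrilateral (order NW, NE, SE, SW)")


def build_plot_grid(
    corners,
    n_rows: int,
    n_cols: int,
    plot_length_m: float,
    plot_width_m: float,
    crs_tag: str = "local-metric",
) -> FieldLayout:
    """Interpolate an ``n_rows x n_cols`` grid of plot polygons from four field corners.

    Parameters
    ----------
    corners
        Four (x, y) pairs in the order NW, NE, SE, SW.
    n_rows, n_cols
        Grid dimensions; row index increases NW->SW, column index NW->NE.
    plot_length_m, plot_width_m
        Sown plot size in metres.  Each grid cell covers the full pitch of
        the grid; the plot polygon is the cell shrunk about its centre to
        this size.  Either dimension exceeding the cell pitch is an error.
    crs_tag
        Coordinate frame of the corners; geographic frames (WGS84 lon/lat)
        are supported, cell sizes then being measured on the ground.
    """
    corners = np.asarray([tuple(c) for c in corners], dtype=float)
    if corners.shape != (4, 2):
        raise ValueError("corners must be four (x, y) pairs ordered NW, NE, SE, SW")
    if n_rows < 1 or n_cols < 1:
        raise ValueError("n_rows and n_cols must be >= 1")
    _check_convex(corners)
    geographic = is_geographic(crs_tag)

    plots: list[PlotRecord] = []
    id_width = len(str(max(n_rows, n_cols)))
    for i in range(n_rows):
        t0, t1 = i / n_rows, (i + 1) / n_rows
        tc = 0.5 * (t0 + t1)
        for j in range(n_cols):
            s0, s1 = j / n_cols, (j + 1) / n_cols
            sc = 0.5 * (s0 + s1)
            left = _bilinear(corners, s0, tc)
            right = _bilinear(corners, s1, tc)
            top = _bilinear(corners, sc, t0)
            bottom = _bilinear(corners, sc, t1)
            cell_w = ground_distance(*left, *right, geographic)
            cell_l = ground_distance(*top, *bottom, geographic)
            if plot_width_m > cell_w * (1 + 1e-9):
                raise ValueError(
                    f"plot_width_m={plot_width_m} exceeds the cell pitch {cell_w:.6g} m along columns"
                )
            if plot_length_m > cell_l * (1 + 1e-9):
                raise ValueError(
                    f"plot_length_m={plot_length_m} exceeds the cell pitch {cell_l:.6g} m along rows"
                )
            hs = 0.5 * (plot_width_m / cell_w) * (s1 - s0)
            ht = 0.5 * (plot_length_m / cell_l) * (t1 - t0)
            ring = [
                _bilinear(corners, sc - hs, tc - ht),
                _bilinear(corners, sc + hs, tc - ht),
                _bilinear(corners, sc + hs, tc + ht),
                _bilinear(corners, sc - hs, tc + ht),
            ]
            poly = orient(Polygon([tuple(p) for p in ring]), sign=1.0)
            plot_id = f"r{i + 1:0{id_width}d}c{j + 1:0{id_width}d}"
            plots.append(PlotRecord(plot_id=plot_id, row=i + 1, col=j + 1, polygon=poly))

    layout = FieldLayout(
        plots=plots,
        crs_tag=crs_tag,
        n_rows=n_rows,
        n_cols=n_cols,
        plot_length_m=plot_length_m,
        plot_width_m=plot_width_m,
        corners=[tuple(c) for c in corners],
    )
    quad = Polygon([tuple(c) for c in corners]).buffer(1e-9)
    for p in layout.plots:
        if not quad.contains(p.polygon):
            raise ValueError(f"plot {p.plot_id} escapes the corner quadrilateral")
    return layout


_REQUIRED_MAP_COLS = ("plot_id", "entry", "block", "row", "col")


def attach_plot_map(
    layout: FieldLayout, plot_map: pd.DataFrame, warn_dropped: bool = True
) -> FieldLayout:
    """Join design labels onto the grid; unlabelled cells are dropped.

    ``plot_map`` needs columns plot_id, entry, block, row, col, with row/col
    referring to grid positions of ``layout``.  Grid cells not referenced by
    the map (alleys, fill plots) are removed with a logged warning.
    """
    missing = [c for c in _REQUIRED_MAP_COLS if c not in plot_map.columns]
    if missing:
        raise ValueError(f"plot map lacks columns: {missing}")
    pm = plot_map.copy()
    for c in ("block", "row", "col"):
        pm[c] = pm[c].astype(int)
    pm["plot_id"] = pm["plot_id"].astype(str)
    pm["entry"] = pm["entry"].astype(str)
    if (pm["entry"].str.len() == 0).any():
        raise ValueError("plot map contains empty entry labels")
    if pm.duplicated(subset=["block", "row", "col"]).any():
        raise ValueError("duplicate (block, row, col) in plot map")
    if pm["plot_id"].duplicated().any():
        raise ValueError("plot_id collision in plot map")

    by_pos = {(p.row, p.col): p for p in layout.plots}
    labelled: list[PlotRecord] = []
    for rec in pm.itertuples(index=False):
        key = (rec.row, rec.col)
        if key not in by_pos:
            raise ValueError(f"plot map references grid cell (row={rec.row}, col={rec.col}) outside the grid")
        cell = by_pos[key]
        labelled.append(
            replace(cell, plot_id=rec.plot_id, entry=rec.entry, block=rec.block)
        )
    n_dropped = len(layout.plots) - len(labelled)
    if n_dropped and warn_dropped:
        logger.warning("attach_plot_map: dropped %d unlabelled grid cells", n_dropped)
    return FieldLayout(
        plots=labelled,
        crs_tag=layout.crs_tag,
        n_rows=layout.n_rows,
        n_cols=layout.n_cols,
        plot_length_m=layout.plot_length_m,
        plot_width_m=layout.plot_width_m,
        corners=layout.corners,
    )


# GeoJSON property aliases: tolerate the attribute spellings shapefile-born
# layers commonly carry (10-char truncation, legacy names).
_ALIASES = {
    "plot_id": ("plot_id", "plot", "id", "plotid"),
    "entry": ("entry", "entry_id", "geno", "genotype"),
    "block": ("block", "rep", "replicate"),
    "row": ("row", "plot_row"),
    "col": ("col", "column", "plot_col", "range"),
}


def _lookup(props: dict, key: str, required: bool = False):
    lowered = {str(k).lower(): v for k, v in props.items()}
    for alias in _ALIASES[key]:
        if alias in lowered:
            return lowered[alias]
    if required:
        raise ValueError(f"feature lacks a '{key}' attribute (aliases tried: {_ALIASES[key]})")
    return None


def write_layout(layout: FieldLayout, path) -> str:
    """Write a layout as a GeoJSON FeatureCollection (the preferred format)."""
    path = str(path)
    if path.lower().endswith(".shp"):
        raise ValueError("ESRI Shapefile output is not supported; write GeoJSON (.geojson)")
    features = []
    for p in layout.plots:
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "plot_id": p.plot_id,
                    "entry": p.entry,
                    "block": p.block,
                    "row": p.row,
                    "col": p.col,
                },
                "geometry": mapping(p.polygon),
            }
        )
    doc = {
        "type": "FeatureCollection",
        "crs_tag": layout.crs_tag,
        "grid": {
            "n_rows": layout.n_rows,
            "n_cols": layout.n_cols,
            "plot_length_m": layout.plot_length_m,
            "plot_width_m": layout.plot_width_m,
            "corners": [list(c) for c in layout.corners],
        },
        "features": features,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
    return path


def read_layout(path) -> FieldLayout:
    """Read a layout written by :func:`write_layout` (or compatible GeoJSON)."""
    path = str(path)
    if path.lower().endswith(".shp"):
        raise ValueError("ESRI Shapefile input is not supported; convert to GeoJSON first")
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError("layout file is not a GeoJSON FeatureCollection")
    crs_tag = doc.get("crs_tag")
    if crs_tag is None:
        warnings.warn("layout file lacks a CRS tag; assuming 'unknown'", stacklevel=2)
        crs_tag = "unknown"
    plots = []
    for feat in doc["features"]:
        props = feat.get("properties", {})
        plot_id = _lookup(props, "plot_id", required=True)
        entry = _lookup(props, "entry")
        block = _lookup(props, "block")
        row = _lookup(props, "row")
        col = _lookup(props, "col")
        poly = shape(feat["geometry"])
        plots.append(
            PlotRecord(
                plot_id=str(plot_id),
                entry=None if entry is None else str(entry),
                block=None if block is None else int(block),
                row=int(row) if row is not None else 0,
                col=int(col) if col is not None else 0,
                polygon=orient(poly, sign=1.0),
            )
        )
    grid = doc.get("grid", {})
    return FieldLayout(
        plots=plots,
        crs_tag=crs_tag,
        n_rows=int(grid.get("n_rows", max((p.row for p in plots), default=1))),
        n_cols=int(grid.get("n_cols", max((p.col for p in plots), default=1))),
        plot_length_m=float(grid.get("plot_length_m", 0.0)),
        plot_width_m=float(grid.get("plot_width_m", 0.0)),
        corners=[tuple(c) for c in grid.get("corners", [])],
    )
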