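"""Georeferenced raster I/O and plot cropping.

A :class:`GeoRaster` holds named bands (by spectral role), an affine
geotransform, a nodata value and — for orthorectified single captures —
the camera pose at exposure.  Files are plain GeoTIFFs carrying the
standard georeferencing tags (ModelPixelScale, ModelTiepoint, GDAL_NODATA)
plus a JSON ImageDescription with band roles, image id, CRS tag and pose;
a ``<path>.pose.json`` sidecar is also honoured for the pose.

The geotransform follows the GDAL convention: world coordinates of the
*corner* of pixel (col=0, row=0) with north-up axis-aligned scaling
``x = x0 + col*dx``, ``y = y0 + row*dy`` (dy < 0).  Pixel values are
referenced at pixel centres (col + 0.5, row + 0.5).  Pixel indices are
0-based and windows half-open.
"""

from __future__ import annotations

import json
import logging
import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
import tifffile
from shapely.geometry import Polygon

logger = logging.getLogger(__name__)

__all__ = [
    "CameraPose",
    "GeoRaster",
    "read_geo_raster",
    "write_geo_raster",
    "crop_contained_plots",
]

#: recognised band roles
ROLES = ("thermal_ir", "blue", "green", "red", "nir", "rededge", "binary")

#: default role guesses by band count (MicaSense order for 5 bands)
_DEFAULT_ROLES = {
    1: ("thermal_ir",),
    3: ("red", "green", "blue"),
    5: ("blue", "green", "red", "nir", "rededge"),
}


@dataclass(frozen=True)
class CameraPose:
    """Camera ground position at exposure, from image metadata."""

    lon: float
    lat: float
    alt: float | None = None
    capture_index: int = 0

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon <= 180.0) and abs(self.lon) > 1e7:
            raise ValueError(f"lon out of range: {self.lon}")
        if not (-90.0 <= self.lat <= 90.0) and abs(self.lat) > 1e7:
            raise ValueError(f"lat out of range: {self.lat}")

    def to_dict(self) -> dict:
        return {
            "lon": self.lon,
            "lat": self.lat,
            "alt": self.alt,
            "capture_index": self.capture_index,
        }


@dataclass
class GeoRaster:
    """Multi-band raster with affine georeferencing and optional camera pose.

    All bands share shape, dtype, geotransform and nodata mask.
    """

    bands: dict[str, np.ndarray]
    transform: tuple[float, float, float, float, float, float]
    nodata: float
    crs_tag: str = "local-metric"
    pose: CameraPose | None = None
    image_id: str = ""

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("raster needs at least one band")
        shapes = {b.shape for b in self.bands.values()}
        if len(shapes) != 1:
            raise ValueError("all bands must share one shape")
        x0, dx, rx, y0, ry, dy = self.transform
        if rx != 0.0 or ry != 0.0:
            raise ValueError("rotated geotransforms are not supported")
        masks = [self._band_mask(b) for b in self.bands.values()]
        for m in masks[1:]:
            if not np.array_equal(masks[0], m):
                raise ValueError("nodata mask differs across bands")

    # -- geometry -----------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.bands.values())).shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster footprint."""
        h, w = self.shape
        x0, dx, _, y0, _, dy = self.transform
        xs = sorted((x0, x0 + w * dx))
        ys = sorted((y0, y0 + h * dy))
        return (xs[0], ys[0], xs[1], ys[1])

    def world_to_pixel(self, x, y):
        """Fractional (col, row) pixel coordinates of world points."""
        x0, dx, _, y0, _, dy = self.transform
        return (np.asarray(x) - x0) / dx, (np.asarray(y) - y0) / dy

    def pixel_centers(self, cols, rows):
        """World (x, y) of pixel centres for integer col/row arrays."""
        x0, dx, _, y0, _, dy = self.transform
        return x0 + (np.asarray(cols) + 0.5) * dx, y0 + (np.asarray(rows) + 0.5) * dy

    # -- data ---------------------------------------------------------

    def _band_mask(self, band: np.ndarray) -> np.ndarray:
        if np.issubdtype(band.dtype, np.floating) and np.isnan(self.nodata):
            return np.isnan(band)
        return band == np.asarray(self.nodata, dtype=band.dtype)

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where pixels are nodata."""
        return self._band_mask(next(iter(self.bands.values())))

    def band(self, role: str) -> np.ndarray:
        try:
            return self.bands[role]
        except KeyError:
            raise KeyError(
                f"band role '{role}' not present; available: {sorted(self.bands)}"
            ) from None

    def values(self, role: str) -> np.ndarray:
        """Band as float with nodata replaced by NaN."""
        arr = self.band(role).astype(float)
        arr[self.mask] = np.nan
        return arr

    def copy(self) -> "GeoRaster":
        return replace(self, bands={k: v.copy() for k, v in self.bands.items()})


# ----------------------------------------------------------------------
# GeoTIFF read/write (tifffile + standard GeoTIFF tags)
# ----------------------------------------------------------------------

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def write_geo_raster(raster: GeoRaster, path) -> str:
    """Write a GeoRaster to a GeoTIFF; float bands are stored at full width.

    Round-trips are bit-exact for integer bands and exact to float32/float64
    representation for float bands.
    """
    path = str(path)
    arrs = list(raster.bands.values())
    dtype = arrs[0].dtype
    for a in arrs[1:]:
        if a.dtype != dtype:
            raise ValueError("all bands of one file must share a dtype")
    data = np.stack(arrs, axis=0)
    x0, dx, _, y0, _, dy = raster.transform
    if dy >= 0:
        raise ValueError("north-up rasters require dy < 0 in the geotransform")
    desc = json.dumps(
        {
            "image_id": raster.image_id,
            "band_roles": list(raster.bands.keys()),
            "crs_tag": raster.crs_tag,
            "pose": raster.pose.to_dict() if raster.pose else None,
        }
    )
    nodata_str = "nan" if np.isnan(raster.nodata) else repr(float(raster.nodata))
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (abs(dx), abs(dy), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, nodata_str),
    ]
    kwargs = {}
    if data.shape[0] > 1:
        kwargs["planarconfig"] = "separate"
    else:
        data = data[0]
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        description=desc,
        metadata=None,
        extratags=extratags,
        **kwargs,
    )
    return path


def _read_sidecar_pose(path: str) -> CameraPose | None:
    sidecar = path + ".pose.json"
    if not os.path.exists(sidecar):
        return None
    with open(sidecar) as fh:
        d = json.load(fh)
    return CameraPose(
        lon=float(d["lon"]),
        lat=float(d["lat"]),
        alt=None if d.get("alt") is None else float(d["alt"]),
        capture_index=int(d.get("capture_index", 0)),
    )


def read_geo_raster(path, band_roles: list[str] | None = None) -> GeoRaster:
    """Read a GeoTIFF into a GeoRaster.

    Band roles come from (in priority order) the ``band_roles`` argument,
    the JSON ImageDescription, or a band-count heuristic (1 band = thermal,
    3 = RGB, 5 = MicaSense blue/green/red/nir/rededge).  The camera pose is
    taken from the ImageDescription or a ``.pose.json`` sidecar.
    """
    path = str(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = tif.asarray()
        tags = page.tags
        scale = tags.get(_TAG_PIXEL_SCALE)
        tie = tags.get(_TAG_TIEPOINT)
        if scale is None or tie is None:
            raise ValueError(f"{path}: missing GeoTIFF geotransform tags")
        sx, sy = float(scale.value[0]), float(scale.value[1])
        tx, ty = float(tie.value[3]), float(tie.value[4])
        transform = (tx, sx, 0.0, ty, 0.0, -sy)
        nodata_tag = tags.get(_TAG_GDAL_NODATA)
        desc = {}
        if page.description:
            try:
                desc = json.loads(page.description)
            except (json.JSONDecodeError, TypeError):
                desc = {}

    if data.ndim == 2:
        data = data[None, :, :]
    n_bands = data.shape[0]
    roles = band_roles or desc.get("band_roles")
    if roles is None:
        roles = _DEFAULT_ROLES.get(n_bands)
    if roles is None or len(roles) != n_bands:
        raise ValueError(
            f"{path}: cannot resolve roles for {n_bands} bands; "
            f"pass band_roles= (recognised roles: {ROLES})"
        )
    if nodata_tag is not None:
        raw = nodata_tag.value
        if isinstance(raw, bytes):
            raw = raw.decode()
        raw = str(raw).strip().strip("\x00")
        nodata = float("nan") if raw.lower() == "nan" else float(raw)
    else:
        warnings.warn(f"{path}: no nodata tag; assuming all pixels valid", stacklevel=2)
        nodata = float("nan") if np.issubdtype(data.dtype, np.floating) else np.iinfo(data.dtype).max

    pose = None
    if desc.get("pose"):
        d = desc["pose"]
        pose = CameraPose(
            lon=float(d["lon"]),
            lat=float(d["lat"]),
            alt=None if d.get("alt") is None else float(d["alt"]),
            capture_index=int(d.get("capture_index", 0)),
        )
    sidecar = _read_sidecar_pose(path)
    if sidecar is not None:
        pose = sidecar

    return GeoRaster(
        bands={role: data[i] for i, role in enumerate(roles)},
        transform=transform,
        nodata=nodata,
        crs_tag=desc.get("crs_tag", "unknown"),
        pose=pose,
        image_id=desc.get("image_id") or os.path.splitext(os.path.basename(path))[0],
    )


# ----------------------------------------------------------------------
# Plot cropping
# ----------------------------------------------------------------------


def polygon_pixel_mask(raster: GeoRaster, polygon: Polygon) -> tuple[slice, slice, np.ndarray]:
    """Window slices covering the polygon bbox and the pixel-centre-in-polygon mask."""
    h, w = raster.shape
    xs, ys = polygon.exterior.coords.xy
    cols, rows = raster.world_to_pixel(np.asarray(xs), np.asarray(ys))
    c0 = max(int(np.floor(cols.min())), 0)
    c1 = min(int(np.ceil(cols.max())), w)
    r0 = max(int(np.floor(rows.min())), 0)
    r1 = min(int(np.ceil(rows.max())), h)
    if c1 <= c0 or r1 <= r0:
        return slice(0, 0), slice(0, 0), np.zeros((0, 0), dtype=bool)
    cc, rr = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    px, py = raster.pixel_centers(cc, rr)
    inside = shapely.contains_xy(polygon, px.ravel(), py.ravel()).reshape(cc.shape)
    return slice(r0, r1), slice(c0, c1), inside


def crop_contained_plots(
    raster: GeoRaster,
    layout,
    max_nodata_frac: float = 0.0,
) -> list[tuple[str, GeoRaster]]:
    """Crop every plot *completely included* in the raster.

    A plot qualifies when (i) all polygon vertices fall inside the raster
    extent and (ii) the fraction of nodata pixels among pixels whose centre
    lies in the polygon does not exceed ``max_nodata_frac`` (default 0:
    fully strict, excluding plots touching orthorectification fringes).
    Returned windows are masked to the polygon (outside pixels set to
    nodata).  An empty result is not an error.
    """
    xmin, ymin, xmax, ymax = raster.extent
    invalid = raster.mask
    out: list[tuple[str, GeoRaster]] = []
    for plot in layout.plots:
        xs, ys = plot.polygon.exterior.coords.xy
        xs, ys = np.asarray(xs), np.asarray(ys)
        tol = 1e-9 * max(1.0, abs(xmax - xmin))
        if (
            xs.min() < xmin - tol
            or xs.max() > xmax + tol
            or ys.min() < ymin - tol
            or ys.max() > ymax + tol
        ):
            continue
        rsl, csl, inside = polygon_pixel_mask(raster, plot.polygon)
        n_inside = int(inside.sum())
        if n_inside == 0:
            continue
        n_bad = int((invalid[rsl, csl] & inside).sum())
        if n_bad > max_nodata_frac * n_inside:
            continue
        x0, dx, _, y0, _, dy = raster.transform
        win_transform = (x0 + csl.start * dx, dx, 0.0, y0 + rsl.start * dy, 0.0, dy)
        bands = {}
        for role, arr in raster.bands.items():
            win = arr[rsl, csl].copy()
            fill = (
                np.nan
                if (np.issubdtype(win.dtype, np.floating) and np.isnan(raster.nodata))
                else np.asarray(raster.nodata, dtype=win.dtype)
            )
            win[~inside] = fill
            bands[role] = win
        out.append(
            (
                plot.plot_id,
                GeoRaster(
                    bands=bands,
                    transform=win_transform,
                    nodata=raster.nodata,
                    crs_tag=raster.crs_tag,
                    pose=raster.pose,
                    image_id=raster.image_id,
                ),
            )
        )
    if not out:
        logger.warning("crop_contained_plots: no plot fully contained in %s", raster.image_id)
    return out
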