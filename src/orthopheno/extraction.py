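"""Plot-level trait extraction from orthomosaic and orthorectified rasters.

Three traits are supported:

* **CT** — canopy temperature.  Radiometric thermal pixels are digital
  numbers in centikelvin; Celsius temperature is the linear map
  ``T = K * DN + T0`` with defaults K = 0.04 °C/DN and T0 = −273.15 °C
  (so DN = 0 is absolute zero).  The per-plot value is the mode of the
  non-zero DNs inside the plot polygon, converted to °C.
* **NDVI** — (NIR − Red) / (NIR + Red) per pixel; per-plot value is the
  mode of non-zero NDVI pixels on a fixed-width histogram (default bin
  0.01, value reported at the bin midpoint).
* **GC** — early-stage ground cover: an HSV threshold on the rendered RGB
  image marks canopy pixels, and the plot value is the fraction of marked
  pixels among valid pixels in the polygon.

Each orthorectified observation also carries the camera azimuth: the angle
from true east (0°), counter-clockwise, of the vector from the plot centre
to the camera ground position.  The mosaic has no camera, hence no azimuth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.color import rgb2hsv

from ._geo import local_metric_displacement
from .fieldmap import FieldLayout
from .ortho_io import CameraPose, GeoRaster, crop_contained_plots

logger = logging.getLogger(__name__)

__all__ = [
    "ConversionConstants",
    "thermal_to_celsius",
    "ndvi_raster",
    "gc_binary",
    "plot_mode_nonzero",
    "ground_cover_fraction",
    "camera_azimuth",
    "extract_trait_table",
    "MOSAIC_SOURCE",
]

#: source_id used for the single whole-field mosaic observation of a plot
MOSAIC_SOURCE = "MOSAIC"

TRAITS = ("CT", "NDVI", "GC")


@dataclass(frozen=True)
class ConversionConstants:
    """Constants of the raster-to-trait conversions.

    ``kelvin_per_dn`` (K) and ``t0_celsius`` (T0) define the thermal DN to
    Celsius map T = K*DN + T0.  ``hue_window`` (degrees), ``sat_min`` and
    ``val_min`` delimit canopy pixels in HSV space; the hue window default
    [60°, 180°] spans green vegetation and is meant to be tuned once on a
    reference date and then frozen for subsequent dates.
    """

    kelvin_per_dn: float = 0.04
    t0_celsius: float = -273.15
    ndvi_bin_width: float = 0.01
    hue_window: tuple[float, float] = (60.0, 180.0)
    sat_min: float = 0.15
    val_min: float = 0.10

    def __post_init__(self) -> None:
        if self.kelvin_per_dn <= 0:
            raise ValueError("kelvin_per_dn must be > 0")
        lo, hi = self.hue_window
        if not (0 <= lo < hi <= 360):
            raise ValueError("hue_window must satisfy 0 <= lo < hi <= 360")
        if self.ndvi_bin_width <= 0:
            raise ValueError("ndvi_bin_width must be > 0")


DEFAULT_CONSTANTS = ConversionConstants()


# ----------------------------------------------------------------------
# Raster calculations
# ----------------------------------------------------------------------


def thermal_to_celsius(dn, constants: ConversionConstants = DEFAULT_CONSTANTS):
    """Convert thermal digital numbers to °C: ``T = K*DN + T0``.

    Accepts a plain array (NaN = nodata, propagated) or a GeoRaster with a
    ``thermal_ir`` band, returning the matching type.
    """
    K, T0 = constants.kelvin_per_dn, constants.t0_celsius
    if isinstance(dn, GeoRaster):
        vals = dn.values("thermal_ir")
        out = K * vals + T0
        return GeoRaster(
            bands={"thermal_ir": out},
            transform=dn.transform,
            nodata=float("nan"),
            crs_tag=dn.crs_tag,
            pose=dn.pose,
            image_id=dn.image_id,
        )
    arr = np.asarray(dn, dtype=float)
    return K * arr + T0


def ndvi_raster(nir, red):
    """Normalized difference vegetation index (NIR − Red)/(NIR + Red).

    Pixels where NIR + Red == 0 (and nodata pixels) become NaN.
    """
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    if nir.shape != red.shape:
        raise ValueError(f"band shape mismatch: {nir.shape} vs {red.shape}")
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom != 0, (nir - red) / np.where(denom == 0, 1.0, denom), np.nan)
    out[np.isnan(denom)] = np.nan
    return out


def gc_binary(rgb, constants: ConversionConstants = DEFAULT_CONSTANTS):
    """Binary canopy mask from an RGB image via HSV thresholds.

    A pixel is canopy (1) iff hue lies in ``hue_window`` degrees AND
    saturation >= sat_min AND value >= val_min.  ``rgb`` is an (H, W, 3)
    float array in [0, 1] or a GeoRaster with red/green/blue bands; NaN
    pixels yield 0 with their nodata status left to the caller's mask.
    """
    if isinstance(rgb, GeoRaster):
        arr = np.stack([rgb.values(r) for r in ("red", "green", "blue")], axis=-1)
    else:
        arr = np.asarray(rgb, dtype=float)
        if arr.ndim != 3 or arr.shape[-1] != 3:
            raise ValueError("rgb must be an (H, W, 3) array")
    nanmask = np.isnan(arr).any(axis=-1)
    safe = np.where(np.isnan(arr), 0.0, arr)
    hsv = rgb2hsv(np.clip(safe, 0.0, 1.0))
    hue = hsv[..., 0] * 360.0
    sat = hsv[..., 1]
    val = hsv[..., 2]
    lo, hi = constants.hue_window
    binary = (
        (hue >= lo) & (hue <= hi) & (sat >= constants.sat_min) & (val >= constants.val_min)
    ).astype(np.uint8)
    binary[nanmask] = 0
    return binary


# ----------------------------------------------------------------------
# Plot summaries
# ----------------------------------------------------------------------


def plot_mode_nonzero(values, bin_width: float | None = None):
    """Mode of the non-zero, non-nodata values of a plot window.

    Exact zeros are treated as the background/nodata sentinel and excluded.
    Integer input: exact-value mode.  Float input: mode of a fixed-width
    histogram whose bins are aligned at multiples of ``bin_width``; the bin
    midpoint is returned.  Ties break toward the smaller value / bin.

    Returns None when no valid non-zero pixel remains (empty plot).
    """
    arr = np.asarray(values)
    if np.issubdtype(arr.dtype, np.floating):
        flat = arr[np.isfinite(arr) & (arr != 0)]
        if flat.size == 0:
            return None
        if bin_width is None:
            bin_width = DEFAULT_CONSTANTS.ndvi_bin_width
        k = np.floor(flat / bin_width).astype(np.int64)
        uk, counts = np.unique(k, return_counts=True)
        best = uk[counts == counts.max()].min()
        return float((best + 0.5) * bin_width)
    flat = arr[arr != 0]
    if flat.size == 0:
        return None
    uv, counts = np.unique(flat, return_counts=True)
    return uv[counts == counts.max()].min()


def ground_cover_fraction(binary, valid=None):
    """Fraction of canopy pixels among valid pixels of a binary plot window.

    ``valid`` masks the pixels belonging to the plot polygon (True = count
    in the denominator); by default all pixels count.  Returns None when no
    valid pixel exists.
    """
    arr = np.asarray(binary)
    if valid is None:
        valid = np.ones(arr.shape, dtype=bool)
    n_valid = int(valid.sum())
    if n_valid == 0:
        return None
    return float((arr[valid] != 0).sum()) / n_valid


# ----------------------------------------------------------------------
# Camera azimuth
# ----------------------------------------------------------------------


def camera_azimuth(
    plot_center: tuple[float, float], pose: CameraPose, geographic: bool = True
) -> float:
    """Azimuth (degrees) of the camera as seen from the plot centre.

    Measured counter-clockwise from true east (east = 0°, north = 90°),
    in [0, 360).  Only the planar position is used; altitude is ignored.
    """
    east, north = local_metric_displacement(
        plot_center[0], plot_center[1], pose.lon, pose.lat, geographic
    )
    if east == 0.0 and north == 0.0:
        raise ValueError("camera coincides with the plot centre; azimuth undefined")
    return math.degrees(math.atan2(north, east)) % 360.0


# ----------------------------------------------------------------------
# Trait table
# ----------------------------------------------------------------------


def _required_roles(trait: str) -> tuple[str, ...]:
    return {
        "CT": ("thermal_ir",),
        "NDVI": ("nir", "red"),
        "GC": ("red", "green", "blue"),
    }[trait]


def _plot_value(trait: str, crop: GeoRaster, constants: ConversionConstants):
    """(value, n_pixels) summary of one plot crop, or (None, 0) if empty."""
    if trait == "CT":
        dn = crop.band("thermal_ir")
        valid = ~crop.mask
        dn = np.where(valid, dn, 0)
        mode_dn = plot_mode_nonzero(dn)
        if mode_dn is None:
            return None, 0
        n = int(((dn != 0) & valid).sum())
        return float(constants.kelvin_per_dn * mode_dn + constants.t0_celsius), n
    if trait == "NDVI":
        ndvi = ndvi_raster(crop.values("nir"), crop.values("red"))
        val = plot_mode_nonzero(ndvi, bin_width=constants.ndvi_bin_width)
        if val is None:
            return None, 0
        n = int((np.isfinite(ndvi) & (ndvi != 0)).sum())
        return float(val), n
    if trait == "GC":
        binary = gc_binary(crop, constants)
        valid = ~crop.mask
        frac = ground_cover_fraction(binary, valid)
        if frac is None:
            return None, 0
        return frac, int(valid.sum())
    raise ValueError(f"unknown trait {trait!r}; expected one of {TRAITS}")


def extract_trait_table(
    images,
    layout: FieldLayout,
    trait: str,
    constants: ConversionConstants = DEFAULT_CONSTANTS,
    mosaic: GeoRaster | None = None,
    date: str = "",
    max_nodata_frac: float = 0.0,
) -> pd.DataFrame:
    """Extract the long-format plot-level trait table from a set of rasters.

    Every orthorectified image contributes one observation per plot fully
    contained in it; the mosaic (if given) contributes exactly one
    observation per plot with ``source_id == "MOSAIC"`` and no azimuth.

    Returns a DataFrame with columns
    ``date, trait, plot_id, source_id, value, n_pixels, azimuth_deg``.
    """
    trait = trait.upper()
    roles = _required_roles(trait)
    sources = list(images)
    if mosaic is not None:
        sources = [mosaic] + sources
    for src in sources:
        missing = [r for r in roles if r not in src.bands]
        if missing:
            raise ValueError(
                f"image {src.image_id!r} lacks bands {missing} required for trait {trait}"
            )
    geographic = layout.geographic
    rows = []
    for src in sources:
        is_mosaic = mosaic is not None and src is mosaic
        for plot_id, crop in crop_contained_plots(src, layout, max_nodata_frac):
            value, n_pixels = _plot_value(trait, crop, constants)
            if value is None:
                logger.warning("empty plot %s in %s; record skipped", plot_id, src.image_id)
                continue
            azimuth = np.nan
            if not is_mosaic and src.pose is not None:
                try:
                    azimuth = camera_azimuth(layout.get(plot_id).center, src.pose, geographic)
                except ValueError:
                    logger.warning(
                        "camera over plot centre %s in %s; azimuth record skipped",
                        plot_id,
                        src.image_id,
                    )
                    continue
            rows.append(
                {
                    "date": date,
                    "trait": trait,
                    "plot_id": plot_id,
                    "source_id": MOSAIC_SOURCE if is_mosaic else src.image_id,
                    "value": value,
                    "n_pixels": n_pixels,
                    "azimuth_deg": azimuth,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["date", "trait", "plot_id", "source_id", "value", "n_pixels", "azimuth_deg"],
    )
    if table.duplicated(subset=["plot_id", "source_id"]).any():
        raise ValueError("duplicate (plot_id, source_id) observations")
    return table
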