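"""Pre-photogrammetry steps: capture checks, calibration, GCP matching.

Multispectral cameras write one file per spectral band per trigger; a
*capture* is the set of five band images from one trigger.  Before any
photogrammetry the pipeline (1) groups files into captures and drops
incomplete ones, (2) splits captures into ground and air groups by the
altitude recorded at exposure, (3) detects the radiometric calibration
panel in ground captures and converts digital numbers to reflectance, and
(4) detects white square ground-control-point (GCP) markers in air
captures and matches each to the nearest surveyed GCP.

The radiometric model is the simple linear one: per band, the factor
``F_b = rho_b / M_b`` maps the panel's mean digital number ``M_b`` to its
known reflectance ``rho_b``; applying ``F_b`` to a whole image converts it
to reflectance.  Vignetting and exposure compensation are not modelled.

Panel and GCP markers are both bright near-square regions; one detector
serves both: global Otsu threshold, connected components, then uniformity
(CV < 5%), aspect (0.8-1.25) and size filters, tie-broken by area then by
centroid position.  Thermal imagery is refused for GCP detection — the
low-resolution thermal stream does not render marker patterns reliably,
and those GCPs are picked manually downstream.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import erosion

from ._geo import ground_distance
from .ortho_io import GeoRaster, read_geo_raster

logger = logging.getLogger(__name__)

__all__ = [
    "CaptureSet",
    "SurveyedGCP",
    "CalibrationFactors",
    "GCPMatch",
    "group_and_filter_captures",
    "split_ground_air",
    "detect_panel",
    "calibration_factors",
    "apply_calibration",
    "detect_and_match_gcps",
    "read_gcps",
]

EXPECTED_ROLES = ("blue", "green", "red", "nir", "rededge")

#: MicaSense-style band suffix -> spectral role
_BAND_SUFFIX_ROLE = {1: "blue", 2: "green", 3: "red", 4: "nir", 5: "rededge"}


@dataclass
class CaptureSet:
    """All band rasters from one camera trigger."""

    capture_id: str
    band_rasters: dict[str, GeoRaster]
    altitude: float | None = None
    is_air: bool | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.band_rasters) <= 5:
            raise ValueError("a capture holds between 1 and 5 bands")
        if self.altitude is None:
            alts = [
                r.pose.alt
                for r in self.band_rasters.values()
                if r.pose is not None and r.pose.alt is not None
            ]
            if alts:
                self.altitude = float(np.mean(alts))

    @property
    def is_complete(self) -> bool:
        return set(self.band_rasters) == set(EXPECTED_ROLES)


@dataclass(frozen=True)
class SurveyedGCP:
    """One surveyed ground-control point (cm-accuracy lon/lat)."""

    gcp_id: str
    lon: float
    lat: float


@dataclass(frozen=True)
class CalibrationFactors:
    """Per-band factors F_b = rho_b / M_b and the panel reflectances rho_b."""

    factors: dict[str, float]
    panel_reflectance: dict[str, float]

    def __post_init__(self) -> None:
        for b, f in self.factors.items():
            if not f > 0:
                raise ValueError(f"calibration factor for {b} must be > 0")
        for b, r in self.panel_reflectance.items():
            if not 0 < r < 1:
                raise ValueError(f"panel reflectance for {b} must be in (0, 1)")


@dataclass(frozen=True)
class GCPMatch:
    """A detected marker centroid matched to a surveyed GCP."""

    image_id: str
    centroid_col: float
    centroid_row: float
    gcp_id: str
    distance_m: float


# ----------------------------------------------------------------------
# Capture grouping and altitude split
# ----------------------------------------------------------------------

_CAPTURE_RE = re.compile(r"^(?P<capture>.+?)[_-](?P<band>\d)$")


def _parse_capture(name: str) -> tuple[str, str] | None:
    """Split 'IMG_0012_3' into ('IMG_0012', 'red'); None if unparseable."""
    m = _CAPTURE_RE.match(name)
    if not m:
        return None
    band = int(m.group("band"))
    role = _BAND_SUFFIX_ROLE.get(band)
    if role is None:
        return None
    return m.group("capture"), role


def group_and_filter_captures(files) -> list[CaptureSet]:
    """Group band files into captures, dropping incomplete (<5 band) ones.

    ``files`` are GeoTIFF paths whose stem encodes capture and band as
    ``<capture>_<band 1..5>`` (the multispectral camera convention).
    Duplicate roles within a capture are an error; zero complete captures
    is an error.
    """
    import os

    grouped: dict[str, dict[str, GeoRaster]] = {}
    for path in files:
        stem = os.path.splitext(os.path.basename(str(path)))[0]
        parsed = _parse_capture(stem)
        if parsed is None:
            logger.warning("unrecognised capture filename %s; skipped", path)
            continue
        cap_id, role = parsed
        raster = read_geo_raster(path, band_roles=[role])
        bands = grouped.setdefault(cap_id, {})
        if role in bands:
            raise ValueError(f"capture {cap_id}: duplicate band role {role!r}")
        bands[role] = raster
    captures = []
    n_dropped = 0
    for cap_id in sorted(grouped):
        cap = CaptureSet(capture_id=cap_id, band_rasters=grouped[cap_id])
        if cap.is_complete:
            captures.append(cap)
        else:
            n_dropped += 1
            logger.warning(
                "capture %s dropped: %d/5 bands", cap_id, len(cap.band_rasters)
            )
    if not captures:
        raise ValueError("no complete 5-band capture found")
    if n_dropped:
        logger.warning("group_and_filter_captures: dropped %d incomplete captures", n_dropped)
    return captures


def split_ground_air(
    captures: list[CaptureSet], alt_threshold: float | str = "auto"
) -> tuple[list[CaptureSet], list[CaptureSet]]:
    """Partition captures into (ground, air) by exposure altitude.

    ``"auto"`` sets the threshold at the midpoint of the altitude range
    (min + range/2); a constant altitude makes that meaningless and raises,
    demanding an explicit threshold.
    """
    alts = [c.altitude for c in captures]
    if any(a is None for a in alts):
        raise ValueError("all captures need an altitude to split ground/air")
    if alt_threshold == "auto":
        lo, hi = min(alts), max(alts)
        if hi == lo:
            raise ValueError(
                "constant altitude: cannot derive an automatic threshold; pass one explicitly"
            )
        alt_threshold = lo + 0.5 * (hi - lo)
    thr = float(alt_threshold)
    ground, air = [], []
    for c in captures:
        (air if c.altitude >= thr else ground).append(c)
        c.is_air = c.altitude >= thr
    if not ground or not air:
        logger.warning(
            "split_ground_air: one-sided split (%d ground, %d air) at threshold %.2f",
            len(ground),
            len(air),
            thr,
        )
    return ground, air


# ----------------------------------------------------------------------
# Bright-square detector (calibration panel / GCP marker)
# ----------------------------------------------------------------------


def _detect_bright_square(
    gray: np.ndarray,
    size_fraction: tuple[float, float],
    cv_max: float = 0.05,
    aspect_range: tuple[float, float] = (0.8, 1.25),
):
    """Largest connected, near-uniform, near-square bright region.

    Returns (mask, region) or None.  Deterministic tie-break: largest area,
    then smallest (row, col) centroid.
    """
    finite = np.isfinite(gray)
    if not finite.any() or np.nanstd(gray) == 0:
        return None
    work = np.where(finite, gray, np.nanmin(gray))
    thr = threshold_otsu(work)
    bright = work > thr
    labels = label(bright)
    n_pix = gray.size
    lo, hi = size_fraction
    candidates = []
    for region in regionprops(labels):
        frac = region.area / n_pix
        if not lo <= frac <= hi:
            continue
        h = region.bbox[2] - region.bbox[0]
        w = region.bbox[3] - region.bbox[1]
        aspect = w / h
        if not aspect_range[0] <= aspect <= aspect_range[1]:
            continue
        vals = gray[labels == region.label]
        mean = float(np.mean(vals))
        if mean <= 0:
            continue
        cv = float(np.std(vals)) / mean
        if cv >= cv_max:
            continue
        candidates.append(region)
    if not candidates:
        return None
    candidates.sort(key=lambda r: (-r.area, r.centroid[0], r.centroid[1]))
    best = candidates[0]
    return labels == best.label, best


def _inner_mean(gray_bands: dict[str, np.ndarray], mask: np.ndarray, region) -> dict[str, float]:
    """Mean DN per band over the region eroded by 20% of its linear size."""
    h = region.bbox[2] - region.bbox[0]
    w = region.bbox[3] - region.bbox[1]
    k = max(1, int(round(0.2 * min(h, w))))
    inner = erosion(mask, np.ones((2 * k + 1, 2 * k + 1), dtype=bool))
    if not inner.any():
        inner = mask
    return {b: float(np.mean(arr[inner])) for b, arr in gray_bands.items()}


def detect_panel(
    capture: CaptureSet | GeoRaster,
    expected_panel_fraction: tuple[float, float] = (0.005, 0.25),
):
    """Find the radiometric calibration panel in a ground capture.

    Returns ``(mask, mean_dn)`` where ``mask`` marks the panel pixels and
    ``mean_dn`` maps band role -> mean digital number over the panel's
    inner region (the detected square eroded by 20% to avoid edge mixing).
    Raises ``ValueError("panel not found")`` when no region passes the
    uniformity/aspect/size filters.
    """
    if isinstance(capture, GeoRaster):
        bands = {role: capture.values(role) for role in capture.bands}
    else:
        bands = {role: r.values(role) for role, r in capture.band_rasters.items()}
    gray = np.nanmean(np.stack(list(bands.values())), axis=0)
    found = _detect_bright_square(gray, expected_panel_fraction)
    if found is None:
        raise ValueError("panel not found")
    mask, region = found
    return mask, _inner_mean(bands, mask, region)


def calibration_factors(
    mean_dn: dict[str, float], panel_reflectance: dict[str, float]
) -> CalibrationFactors:
    """Per-band reflectance calibration factors F_b = rho_b / M_b."""
    factors = {}
    for band, rho in panel_reflectance.items():
        if band not in mean_dn:
            raise ValueError(f"no panel mean DN for band {band!r}")
        M = mean_dn[band]
        if M <= 0:
            raise ValueError(f"panel mean DN for band {band!r} must be > 0 (got {M})")
        factors[band] = rho / M
    return CalibrationFactors(factors=factors, panel_reflectance=dict(panel_reflectance))


def apply_calibration(raster: GeoRaster, cal: CalibrationFactors) -> GeoRaster:
    """Convert a DN raster to reflectance: per band, reflectance = DN * F_b.

    Linear, hence it commutes with cropping and spatial subsetting.
    """
    bands = {}
    for role, arr in raster.bands.items():
        if role not in cal.factors:
            raise ValueError(f"no calibration factor for band {role!r}")
        out = arr.astype(float) * cal.factors[role]
        out[raster.mask] = np.nan
        bands[role] = out
    return GeoRaster(
        bands=bands,
        transform=raster.transform,
        nodata=float("nan"),
        crs_tag=raster.crs_tag,
        pose=raster.pose,
        image_id=raster.image_id,
    )


# ----------------------------------------------------------------------
# GCP detection and matching
# ----------------------------------------------------------------------


def read_gcps(path, min_spacing_m: float = 20.0) -> list[SurveyedGCP]:
    """Read surveyed GCPs from CSV (gcp_id, lon, lat) and check spacing.

    Markers closer together than ``min_spacing_m`` defeat pose-based
    matching and raise an error (relax the spacing to 0 to skip the check).
    """
    df = pd.read_csv(path)
    required = {"gcp_id", "lon", "lat"}
    if not required.issubset(df.columns):
        raise ValueError(f"GCP file needs columns {sorted(required)}")
    gcps = [
        SurveyedGCP(gcp_id=str(r.gcp_id), lon=float(r.lon), lat=float(r.lat))
        for r in df.itertuples(index=False)
    ]
    for i, a in enumerate(gcps):
        for b in gcps[i + 1 :]:
            d = ground_distance(a.lon, a.lat, b.lon, b.lat, geographic=True)
            if d <= min_spacing_m:
                raise ValueError(
                    f"GCPs {a.gcp_id} and {b.gcp_id} are {d:.1f} m apart "
                    f"(< required spacing {min_spacing_m} m)"
                )
    return gcps


def detect_and_match_gcps(
    air_captures,
    surveyed: list[SurveyedGCP],
    matching_radius_m: float = 20.0,
    marker_fraction: tuple[float, float] = (1e-5, 0.05),
    geographic: bool = True,
) -> list[GCPMatch]:
    """Detect white square markers in air images and match to surveyed GCPs.

    Matching uses only the camera pose: the surveyed GCP nearest the image
    position wins, and a match is recorded only when that distance is below
    ``matching_radius_m``.  Two surveyed GCPs both within the radius make
    the image ambiguous: it is skipped and logged.  Thermal rasters are
    refused — their markers are not detectable automatically.
    """
    matches: list[GCPMatch] = []
    for cap in air_captures:
        if isinstance(cap, GeoRaster):
            rasters = {"__single__": cap}
            image_id = cap.image_id
            pose = cap.pose
        else:
            rasters = cap.band_rasters
            image_id = cap.capture_id
            pose = next(
                (r.pose for r in cap.band_rasters.values() if r.pose is not None), None
            )
        if any("thermal_ir" in r.bands for r in rasters.values()):
            raise ValueError(
                "thermal imagery is refused for automatic GCP detection; "
                "pick thermal GCPs manually"
            )
        if pose is None:
            logger.warning("image %s has no pose; skipped", image_id)
            continue
        in_radius = [
            (g, ground_distance(pose.lon, pose.lat, g.lon, g.lat, geographic))
            for g in surveyed
        ]
        in_radius = [(g, d) for g, d in in_radius if d < matching_radius_m]
        if len(in_radius) > 1:
            logger.warning(
                "image %s: %d surveyed GCPs within %.0f m; ambiguous, skipped",
                image_id,
                len(in_radius),
                matching_radius_m,
            )
            continue
        if not in_radius:
            continue
        gray = np.nanmean(
            np.stack([r.values(role) for r in rasters.values() for role in r.bands]),
            axis=0,
        )
        found = _detect_bright_square(gray, marker_fraction)
        if found is None:
            continue
        _, region = found
        gcp, dist = in_radius[0]
        matches.append(
            GCPMatch(
                image_id=image_id,
                centroid_col=float(region.centroid[1]),
                centroid_row=float(region.centroid[0]),
                gcp_id=gcp.gcp_id,
                distance_m=float(dist),
            )
        )
    return matches
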