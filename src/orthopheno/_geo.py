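"""Local planar frames for field-scale geometry.

Breeding fields are well under a kilometre across, so geographic
coordinates are handled in a local equirectangular metric frame anchored
at a reference latitude: east = dlon * cos(lat_ref) * R, north = dlat * R
with R the mean Earth radius.  The approximation error at field scale is
below a centimetre, far under the GSD of any UAS sensor used here.
"""

from __future__ import annotations

import math

EARTH_RADIUS_M = 6371008.8

#: crs tags treated as already-metric planar frames (x east, y north, metres)
METRIC_TAGS = ("local", "metric", "utm", "epsg:326", "epsg:327")


def is_geographic(crs_tag: str) -> bool:
    """True when coordinates under ``crs_tag`` are lon/lat degrees."""
    tag = (crs_tag or "unknown").lower()
    if any(m in tag for m in METRIC_TAGS):
        return False
    return True  # WGS84 / unknown default to geographic-style handling


def local_metric_displacement(
    x_from: float, y_from: float, x_to: float, y_to: float, geographic: bool
) -> tuple[float, float]:
    """(east, north) displacement in metres from point ``from`` to ``to``.

    For metric frames this is a plain difference; for geographic frames the
    equirectangular approximation at the mean latitude is used.
    """
    if not geographic:
        return x_to - x_from, y_to - y_from
    lat_ref = math.radians(0.5 * (y_from + y_to))
    east = math.radians(x_to - x_from) * math.cos(lat_ref) * EARTH_RADIUS_M
    north = math.radians(y_to - y_from) * EARTH_RADIUS_M
    return east, north


def ground_distance(
    x1: float, y1: float, x2: float, y2: float, geographic: bool = True
) -> float:
    """Planar ground distance in metres between two points."""
    e, n = local_metric_displacement(x1, y1, x2, y2, geographic)
    return math.hypot(e, n)
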