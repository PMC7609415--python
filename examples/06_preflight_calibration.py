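"""Preflight steps: panel radiometric calibration and GCP matching.

Before photogrammetry, ground captures of the reflectance panel yield
per-band calibration factors (F_b = rho_b / M_b), and white square
ground-control markers detected in air images are matched to their
surveyed positions via the camera pose.
"""

import numpy as np

from orthopheno import (
    CameraPose,
    GeoRaster,
    SurveyedGCP,
    apply_calibration,
    calibration_factors,
    detect_and_match_gcps,
    detect_panel,
)
from orthopheno.preflight import CaptureSet

# --- ground capture with a calibration panel (DN units) ---------------
bands = {}
for i, role in enumerate(("blue", "green", "red", "nir", "rededge")):
    arr = np.full((200, 200), 0.12 + 0.01 * i)
    arr[80:120, 60:100] = 0.68  # the bright, uniform panel
    bands[role] = GeoRaster(
        bands={role: arr}, transform=(0, 0.01, 0, 2, 0, -0.01),
        nodata=float("nan"), crs_tag="local-metric",
    )
ground = CaptureSet(capture_id="GROUND_001", band_rasters=bands)

mask, mean_dn = detect_panel(ground)
rho = {role: 0.49 for role in mean_dn}  # vendor-certified panel reflectance
cal = calibration_factors(mean_dn, rho)
print("panel found:", int(mask.sum()), "px; per-band calibration factors:")
for role, f in cal.factors.items():
    print(f"  {role:8s} F = {f:.4f}")
refl = apply_calibration(ground.band_rasters["red"], cal)
print(f"panel mean after calibration: {np.nanmean(refl.band('red')[mask]):.4f} "
      f"(target reflectance {rho['red']})")

# --- air image with a GCP marker --------------------------------------
pose = CameraPose(lon=4.0, lat=1.0, alt=20.0)
air_arr = np.full((100, 100), 0.10)
air_arr[48:53, 48:53] = 0.95  # white square marker
air = GeoRaster(
    bands={"blue": air_arr}, transform=(pose.lon - 5, 0.1, 0, pose.lat + 5, 0, -0.1),
    nodata=float("nan"), crs_tag="local-metric", pose=pose, image_id="AIR_042",
)
surveyed = [SurveyedGCP("G1", 0.0, 0.0), SurveyedGCP("G2", 30.0, 0.0)]
matches = detect_and_match_gcps([air], surveyed, geographic=False)
m = matches[0]
print(f"\nGCP match: image {m.image_id} centroid ({m.centroid_col:.1f}, {m.centroid_row:.1f}) px")
print(f"  -> surveyed {m.gcp_id}, camera {m.distance_m:.1f} m from the marker")
print("Matching uses only the camera pose: markers are spaced > 20 m so the")
print("nearest surveyed point within the radius is unambiguous.")
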