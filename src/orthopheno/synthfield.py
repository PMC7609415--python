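"""Synthetic fields, flights and mosaics with known ground truth.

The generator emulates the structure of a UAS phenotyping campaign over a
replicated field trial so that the whole extraction + mixed-model pipeline
can be exercised at desk scale:

* plot truth follows the experimental-design decomposition
  ``value = mu + entry + block + row(block) + col(block) + plot``,
  each effect iid normal with its own variance;
* a serpentine flight with configurable footprint and overlap renders one
  orthorectified raster per camera trigger: a window of the field plus an
  image-level additive offset (emulating thermal flat-field-correction
  steps and ambient drift: an iid N(0, sigma2_image) term plus a linear
  drift per capture), optional per-plot azimuth dependence and iid pixel
  noise;
* an orthomosaic is blended from those images (mean or first-wins).

All randomness descends from one root seed through named child streams, so
regenerating any stage is reproducible bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .extraction import camera_azimuth
from .fieldmap import FieldLayout, attach_plot_map, build_plot_grid
from .ortho_io import CameraPose, GeoRaster

__all__ = [
    "SimParams",
    "SimTruth",
    "FlightPlan",
    "synthetic_layout",
    "simulate_field",
    "render_orthorectified",
    "render_mosaic",
    "simulate_trait_table",
]


@dataclass(frozen=True)
class SimParams:
    """Ground-truth parameters of a simulated trait surface.

    Variances follow the design decomposition of the trait; defaults are
    sized for midday canopy temperature in °C: entry-to-entry genetic
    differences of ~0.7 °C sd against image-level offsets of ~1.4 °C sd —
    uncooled thermal cores recalibrate in flight (flat-field correction)
    and ambient conditions move over a 15-minute window, so image offsets
    dominate the genetic signal.  ``drift_per_image`` is the systematic
    shift added per capture in flight order on top of the iid offsets,
    sized so a typical desk-scale flight of 100-200 captures accumulates
    the 2-3 °C of ambient drift seen over a midday measurement window;
    ``beta_azimuth`` is the per-degree view-angle slope exercising the
    azimuth covariate.
    """

    mu: float = 30.0
    sigma2_entry: float = 0.5
    sigma2_block: float = 0.2
    sigma2_row: float = 0.1
    sigma2_col: float = 0.1
    sigma2_plot: float = 0.5
    sigma2_image: float = 2.0
    sigma2_pixel: float = 0.04
    beta_azimuth: float = 0.0
    drift_per_image: float = 0.015

    def __post_init__(self) -> None:
        for name in (
            "sigma2_entry",
            "sigma2_block",
            "sigma2_row",
            "sigma2_col",
            "sigma2_plot",
            "sigma2_image",
            "sigma2_pixel",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SimTruth:
    """Realised effects behind one simulated field/flight."""

    params: SimParams
    seed: int
    entry_effects: dict[str, float] = field(default_factory=dict)
    block_effects: dict[int, float] = field(default_factory=dict)
    row_effects: dict[tuple[int, int], float] = field(default_factory=dict)
    col_effects: dict[tuple[int, int], float] = field(default_factory=dict)
    plot_effects: dict[str, float] = field(default_factory=dict)
    image_effects: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class FlightPlan:
    """Serpentine flight geometry over the field."""

    footprint_m: tuple[float, float] = (8.0, 9.0)
    overlap_frac: float = 0.80
    gsd_m: float = 0.25
    altitude_agl: float = 20.0
    serpentine: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_frac <= 0.95:
            raise ValueError("overlap_frac must lie in [0, 0.95]")
        if self.gsd_m <= 0 or min(self.footprint_m) <= 0:
            raise ValueError("gsd_m and footprint_m must be positive")


def _streams(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# ----------------------------------------------------------------------
# Layout and field truth
# ----------------------------------------------------------------------


def synthetic_layout(
    n_entries: int,
    n_blocks: int = 2,
    n_rows: int = 6,
    pitch_col_m: float = 2.0,
    pitch_row_m: float = 3.0,
    plot_width_m: float = 1.5,
    plot_length_m: float = 2.4,
    seed: int = 0,
) -> FieldLayout:
    """A labelled trial layout in a local metric frame.

    Blocks sit side by side along the column direction; within each block
    the entries are randomly assigned to plots (randomised complete block).
    """
    n_cols_per_block = math.ceil(n_entries / n_rows)
    n_cols = n_cols_per_block * n_blocks
    width, height = n_cols * pitch_col_m, n_rows * pitch_row_m
    corners = [(0.0, height), (width, height), (width, 0.0), (0.0, 0.0)]
    grid = build_plot_grid(
        corners, n_rows, n_cols, plot_length_m, plot_width_m, crs_tag="local-metric"
    )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    entries = [f"E{i + 1:04d}" for i in range(n_entries)]
    rows = []
    for b in range(1, n_blocks + 1):
        order = rng.permutation(n_entries)
        cells = [
            (r + 1, (b - 1) * n_cols_per_block + c + 1)
            for c in range(n_cols_per_block)
            for r in range(n_rows)
        ]
        for k, idx in enumerate(order):
            row, col = cells[k]
            rows.append(
                {
                    "plot_id": f"B{b}R{row:02d}C{col:02d}",
                    "entry": entries[idx],
                    "block": b,
                    "row": row,
                    "col": col,
                }
            )
    # fill cells beyond n_entries*n_blocks are dropped by design: no warning
    return attach_plot_map(grid, pd.DataFrame(rows), warn_dropped=False)


def simulate_field(
    layout: FieldLayout, params: SimParams = SimParams(), seed: int = 0
) -> tuple[pd.Series, SimTruth]:
    """Draw per-plot true trait values from the design decomposition.

    Returns a Series indexed by plot_id and the realised :class:`SimTruth`.
    Identical seeds give bitwise-identical output.
    """
    if not layout.is_labelled:
        raise ValueError("layout must carry entry/block labels (attach_plot_map first)")
    rngs = _streams(seed, ("entry", "block", "row", "col", "plot"))
    p = params
    entries = sorted({pl.entry for pl in layout.plots})
    blocks = sorted({pl.block for pl in layout.plots})
    row_keys = sorted({(pl.block, pl.row) for pl in layout.plots})
    col_keys = sorted({(pl.block, pl.col) for pl in layout.plots})
    truth = SimTruth(params=p, seed=seed)
    truth.entry_effects = dict(
        zip(entries, math.sqrt(p.sigma2_entry) * rngs["entry"].standard_normal(len(entries)))
    )
    truth.block_effects = dict(
        zip(blocks, math.sqrt(p.sigma2_block) * rngs["block"].standard_normal(len(blocks)))
    )
    truth.row_effects = dict(
        zip(row_keys, math.sqrt(p.sigma2_row) * rngs["row"].standard_normal(len(row_keys)))
    )
    truth.col_effects = dict(
        zip(col_keys, math.sqrt(p.sigma2_col) * rngs["col"].standard_normal(len(col_keys)))
    )
    plot_ids = [pl.plot_id for pl in layout.plots]
    truth.plot_effects = dict(
        zip(plot_ids, math.sqrt(p.sigma2_plot) * rngs["plot"].standard_normal(len(plot_ids)))
    )
    values = {
        pl.plot_id: p.mu
        + truth.entry_effects[pl.entry]
        + truth.block_effects[pl.block]
        + truth.row_effects[(pl.block, pl.row)]
        + truth.col_effects[(pl.block, pl.col)]
        + truth.plot_effects[pl.plot_id]
        for pl in layout.plots
    }
    return pd.Series(values, name="true_value"), truth


# ----------------------------------------------------------------------
# Rasterisation
# ----------------------------------------------------------------------


def _field_arrays(layout: FieldLayout, plot_values: pd.Series, gsd: float):
    """Paint the field onto a grid: (value array, plot-label array, transform).

    Background pixels are 0 in both arrays (labels are 1-based indices into
    ``layout.plots``).
    """
    xs, ys = [], []
    for pl in layout.plots:
        bx = pl.polygon.bounds
        xs += [bx[0], bx[2]]
        ys += [bx[1], bx[3]]
    xmin, xmax = min(xs) - gsd, max(xs) + gsd
    ymin, ymax = min(ys) - gsd, max(ys) + gsd
    w = int(np.ceil((xmax - xmin) / gsd))
    h = int(np.ceil((ymax - ymin) / gsd))
    transform = (xmin, gsd, 0.0, ymax, 0.0, -gsd)
    values = np.zeros((h, w))
    labels = np.zeros((h, w), dtype=np.int32)
    cc, rr = np.meshgrid(np.arange(w), np.arange(h))
    px = xmin + (cc + 0.5) * gsd
    py = ymax - (rr + 0.5) * gsd
    for k, pl in enumerate(layout.plots, start=1):
        b = pl.polygon.bounds
        sel = (px >= b[0] - gsd) & (px <= b[2] + gsd) & (py >= b[1] - gsd) & (py <= b[3] + gsd)
        inside = np.zeros_like(sel)
        inside[sel] = shapely.contains_xy(pl.polygon, px[sel], py[sel])
        values[inside] = plot_values[pl.plot_id]
        labels[inside] = k
    return values, labels, transform


def _serpentine_centers(extent, plan: FlightPlan):
    xmin, ymin, xmax, ymax = extent
    fw, fh = plan.footprint_m
    step_x = max(fw * (1.0 - plan.overlap_frac), plan.gsd_m)
    step_y = max(fh * (1.0 - plan.overlap_frac), plan.gsd_m)

    def _axis(lo, hi, half, step):
        # one pass beyond each edge, as real missions overfly the margins
        if hi - lo <= 2 * half:
            return [0.5 * (lo + hi) - step, 0.5 * (lo + hi), 0.5 * (lo + hi) + step]
        pts = list(np.arange(lo + half - step, hi - half + step + 1e-9, step))
        if pts[-1] < hi - half + step - 1e-9:
            pts.append(hi - half + step)
        return pts

    xs = _axis(xmin, xmax, fw / 2, step_x)
    ys = _axis(ymin, ymax, fh / 2, step_y)
    centers = []
    for i, y in enumerate(ys):
        row = xs if (not plan.serpentine or i % 2 == 0) else xs[::-1]
        centers.extend((x, y) for x in row)
    return centers


def _to_thermal_dn(celsius: np.ndarray, background: np.ndarray, k_per_dn=0.04):
    dn = np.rint((celsius + 273.15) / k_per_dn)
    dn = np.clip(dn, 1, np.iinfo(np.uint16).max).astype(np.uint16)
    dn[background] = 0
    return dn


def _ndvi_bands(ndvi: np.ndarray, background: np.ndarray, red_level=0.2):
    ndvi = np.clip(ndvi, -0.99, 0.99)
    red = np.full_like(ndvi, red_level)
    nir = red_level * (1.0 + ndvi) / (1.0 - ndvi)
    bands = {
        "blue": np.full_like(ndvi, 0.05),
        "green": np.full_like(ndvi, 0.08),
        "red": red,
        "nir": nir,
        "rededge": np.full_like(ndvi, 0.15),
    }
    for arr in bands.values():
        arr[background] = 0.0
    return {k: v.astype(np.float64) for k, v in bands.items()}


_GREEN = (0.2, 0.8, 0.2)
_SOIL = (0.45, 0.33, 0.18)


def _gc_bands(labels: np.ndarray, layout: FieldLayout, fractions: pd.Series, rng):
    """RGB field where a deterministic fraction of each plot's pixels is canopy."""
    h, w = labels.shape
    rgb = np.empty((3, h, w))
    for i, c in enumerate(_SOIL):
        rgb[i].fill(c)
    for k, pl in enumerate(layout.plots, start=1):
        idx = np.flatnonzero(labels == k)
        n = idx.size
        if n == 0:
            continue
        n_green = int(round(float(np.clip(fractions[pl.plot_id], 0, 1)) * n))
        chosen = idx[:n_green]  # deterministic: row-major order
        for i, c in enumerate(_GREEN):
            rgb[i].flat[chosen] = c
    return {"red": rgb[0], "green": rgb[1], "blue": rgb[2]}


def render_orthorectified(
    layout: FieldLayout,
    plot_values: pd.Series,
    plan: FlightPlan = FlightPlan(),
    params: SimParams = SimParams(),
    seed: int = 0,
    kind: str = "thermal",
    truth: SimTruth | None = None,
    fringe_frac: float = 0.0,
) -> tuple[list[GeoRaster], SimTruth]:
    """Render one orthorectified raster per serpentine camera trigger.

    Each image is a footprint-sized window of the field with its own
    additive offset ``I_n + drift * n`` (thermal/NDVI kinds), optional
    per-plot azimuth shift ``beta * theta(plot, camera)`` and iid pixel
    noise.  ``fringe_frac > 0`` stamps a nodata wedge in one corner,
    emulating the non-effective pixels of real orthorectification.
    ``kind`` selects the sensor: ``thermal`` (uint16 DN), ``multispectral``
    (5 reflectance bands encoding the value as NDVI) or ``rgb`` (ground
    cover; values are per-plot canopy fractions and no offsets are added).
    Returns the images and the SimTruth updated with image effects.
    """
    if kind not in ("thermal", "multispectral", "rgb"):
        raise ValueError("kind must be thermal, multispectral or rgb")
    values, labels, transform = _field_arrays(layout, plot_values, plan.gsd_m)
    xmin, _, _, ymax = transform[0], None, None, transform[3]
    h, w = values.shape
    extent = (xmin, ymax + h * transform[5], xmin + w * transform[1], ymax)
    fw, fh = plan.footprint_m
    win_w, win_h = int(round(fw / plan.gsd_m)), int(round(fh / plan.gsd_m))
    for pl in layout.plots:
        b = pl.polygon.bounds
        if b[2] - b[0] > fw or b[3] - b[1] > fh:
            raise ValueError("image footprint smaller than one plot")
    centers = _serpentine_centers(extent, plan)
    rngs = _streams(seed, ("image", "pixel"))
    if truth is None:
        truth = SimTruth(params=params, seed=seed)
    effects = math.sqrt(params.sigma2_image) * rngs["image"].standard_normal(len(centers))
    truth.image_effects = list(effects)
    plot_centers = {pl.plot_id: pl.center for pl in layout.plots}
    gsd = plan.gsd_m
    images: list[GeoRaster] = []
    for n, (cx, cy) in enumerate(centers):
        c0 = int(round((cx - fw / 2 - xmin) / gsd))
        r0 = int(round((ymax - (cy + fh / 2)) / gsd))
        c0, r0 = max(c0, 0), max(r0, 0)
        c1, r1 = min(c0 + win_w, w), min(r0 + win_h, h)
        win_vals = values[r0:r1, c0:c1].copy()
        win_labels = labels[r0:r1, c0:c1]
        background = win_labels == 0
        pose = CameraPose(lon=cx, lat=cy, alt=plan.altitude_agl, capture_index=n)
        if kind != "rgb":
            win_vals[~background] += effects[n] + params.drift_per_image * n
            if params.beta_azimuth != 0.0:
                for k in np.unique(win_labels[win_labels > 0]):
                    pl = layout.plots[k - 1]
                    theta = camera_azimuth(plot_centers[pl.plot_id], pose, geographic=False)
                    win_vals[win_labels == k] += params.beta_azimuth * theta
            if params.sigma2_pixel > 0:
                noise = math.sqrt(params.sigma2_pixel) * rngs["pixel"].standard_normal(
                    win_vals.shape
                )
                win_vals[~background] += noise[~background]
        win_transform = (
            xmin + c0 * gsd,
            gsd,
            0.0,
            ymax - r0 * gsd,
            0.0,
            -gsd,
        )
        if kind == "thermal":
            bands = {"thermal_ir": _to_thermal_dn(win_vals, background)}
            nodata = 0.0
        elif kind == "multispectral":
            bands = _ndvi_bands(win_vals, background)
            nodata = float("nan")
        else:
            bands = _gc_bands(win_labels, layout, plot_values, rngs["pixel"])
            nodata = float("nan")
        if fringe_frac > 0:
            hh, ww = next(iter(bands.values())).shape
            k = int(round(fringe_frac * min(hh, ww)))
            tri = np.add.outer(np.arange(hh), np.arange(ww)) < k
            for arr in bands.values():
                if np.issubdtype(arr.dtype, np.floating) and math.isnan(nodata):
                    arr[tri] = np.nan
                else:
                    arr[tri] = arr.dtype.type(nodata)
        images.append(
            GeoRaster(
                bands=bands,
                transform=win_transform,
                nodata=nodata,
                crs_tag=layout.crs_tag,
                pose=pose,
                image_id=f"IMG{n:04d}",
            )
        )
    return images, truth


def render_mosaic(images: list[GeoRaster], blend: str = "mean") -> GeoRaster:
    """Blend orthorectified images into one mosaic (no camera pose).

    ``mean`` averages valid overlapping pixels — the blend that carries
    every image's offset into the mosaic; ``first`` keeps the earliest
    capture's pixel.
    """
    if not images:
        raise ValueError("render_mosaic needs at least one image")
    if blend not in ("mean", "first"):
        raise ValueError("blend must be 'mean' or 'first'")
    gsd = images[0].transform[1]
    roles = list(images[0].bands)
    xmin = min(img.extent[0] for img in images)
    ymax = max(img.extent[3] for img in images)
    xmax = max(img.extent[2] for img in images)
    ymin = min(img.extent[1] for img in images)
    w = int(round((xmax - xmin) / gsd))
    h = int(round((ymax - ymin) / gsd))
    acc = {r: np.zeros((h, w)) for r in roles}
    cnt = np.zeros((h, w), dtype=np.int64)
    order = sorted(
        images, key=lambda im: im.pose.capture_index if im.pose else 0
    )
    for img in order:
        c0 = int(round((img.transform[0] - xmin) / gsd))
        r0 = int(round((ymax - img.transform[3]) / gsd))
        ih, iw = img.shape
        valid = ~img.mask
        sl = (slice(r0, r0 + ih), slice(c0, c0 + iw))
        if blend == "mean":
            for r in roles:
                acc[r][sl][valid] += img.band(r).astype(float)[valid]
            cnt[sl][valid] += 1
        else:
            fresh = valid & (cnt[sl] == 0)
            for r in roles:
                acc[r][sl][fresh] = img.band(r).astype(float)[fresh]
            cnt[sl][fresh] = 1
    nodata = images[0].nodata
    out_bands = {}
    dtype = next(iter(images[0].bands.values())).dtype
    for r in roles:
        arr = acc[r]
        if blend == "mean":
            with np.errstate(invalid="ignore"):
                arr = np.where(cnt > 0, arr / np.maximum(cnt, 1), np.nan)
        else:
            arr = np.where(cnt > 0, arr, np.nan)
        if np.issubdtype(dtype, np.integer):
            filled = np.where(np.isnan(arr), nodata, np.rint(arr))
            out_bands[r] = filled.astype(dtype)
        else:
            if not math.isnan(nodata):
                arr = np.where(np.isnan(arr), nodata, arr)
            out_bands[r] = arr
    return GeoRaster(
        bands=out_bands,
        transform=(xmin, gsd, 0.0, ymax, 0.0, -gsd),
        nodata=nodata,
        crs_tag=images[0].crs_tag,
        pose=None,
        image_id="MOSAIC",
    )


# ----------------------------------------------------------------------
# Table-level simulation (no rasters)
# ----------------------------------------------------------------------


def simulate_trait_table(
    n_entries: int = 200,
    n_blocks: int = 2,
    sigma2_entry: float = 1.0,
    sigma2_block: float = 0.2,
    sigma2_plot: float = 0.5,
    sigma2_resid: float = 1.0,
    subsamples=(4, 8),
    mu: float = 30.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a long table of subsampled plot observations directly.

    Skips the raster stage: observations follow
    ``y = mu + entry + block + plot + resid`` with the plot term unique to
    each entry x block combination and a variable number of subsamples per
    plot (uniform over the ``subsamples`` range, or exactly ``subsamples``
    if an int).  Returns the table (columns entry, block, plot, value) and
    a dict with the true components and the true entry-mean heritability
    implied by the realised subsample counts.
    """
    rngs = _streams(seed, ("entry", "block", "plot", "resid", "counts"))
    entries = [f"E{i + 1:04d}" for i in range(n_entries)]
    blocks = list(range(1, n_blocks + 1))
    g = dict(zip(entries, math.sqrt(sigma2_entry) * rngs["entry"].standard_normal(n_entries)))
    b = dict(zip(blocks, math.sqrt(sigma2_block) * rngs["block"].standard_normal(n_blocks)))
    rows = []
    counts = []
    plot_effs = math.sqrt(sigma2_plot) * rngs["plot"].standard_normal(n_entries * n_blocks)
    k = 0
    for e in entries:
        for bl in blocks:
            plot_id = f"{e}:B{bl}"
            pe = plot_effs[k]
            k += 1
            if isinstance(subsamples, int):
                m = subsamples
            else:
                m = int(rngs["counts"].integers(subsamples[0], subsamples[1] + 1))
            counts.append(m)
            eps = math.sqrt(sigma2_resid) * rngs["resid"].standard_normal(m)
            for j in range(m):
                rows.append(
                    {
                        "entry": e,
                        "block": bl,
                        "plot": plot_id,
                        "value": mu + g[e] + b[bl] + pe + eps[j],
                    }
                )
    table = pd.DataFrame(rows)
    n_h = len(counts) / sum(1.0 / c for c in counts)
    h2_true = sigma2_entry / (
        sigma2_entry + sigma2_plot / n_blocks + sigma2_resid / (n_blocks * n_h)
    )
    truth = {
        "sigma2_entry": sigma2_entry,
        "sigma2_block": sigma2_block,
        "sigma2_plot": sigma2_plot,
        "sigma2_resid": sigma2_resid,
        "mu": mu,
        "n_harmonic": n_h,
        "h2_true": h2_true,
    }
    return table, truth
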