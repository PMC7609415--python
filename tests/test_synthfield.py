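"""Simulator ground truth, flight geometry, blending and determinism."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from orthopheno import (
    FlightPlan,
    SimParams,
    extract_trait_table,
    fit_trait_model,
    ground_cover_fraction,
    gc_binary,
    render_mosaic,
    render_orthorectified,
    simulate_field,
    simulate_trait_table,
    synthetic_layout,
    thermal_to_celsius,
)


class TestSimulateField:
    def test_all_zero_variance_gives_mu(self):
        layout = synthetic_layout(10, 2, n_rows=5, seed=0)
        params = SimParams(
            mu=27.0, sigma2_entry=0, sigma2_block=0, sigma2_row=0, sigma2_col=0, sigma2_plot=0
        )
        values, _ = simulate_field(layout, params, seed=0)
        assert np.allclose(values, 27.0)

    def test_entry_only_variance_scale(self):
        """With only genetic variance, plot-value variance is ~ sigma2_entry."""
        layout = synthetic_layout(500, 1, n_rows=20, seed=1)
        params = SimParams(
            sigma2_entry=1.0, sigma2_block=0, sigma2_row=0, sigma2_col=0, sigma2_plot=0
        )
        values, _ = simulate_field(layout, params, seed=1)
        # chi-square bounds at n = 500
        assert 0.8 <= np.var(values, ddof=1) <= 1.2

    def test_same_seed_bitwise_identical(self):
        layout = synthetic_layout(20, 2, seed=4)
        v1, t1 = simulate_field(layout, SimParams(), seed=99)
        v2, t2 = simulate_field(layout, SimParams(), seed=99)
        assert v1.equals(v2)
        assert t1.entry_effects == t2.entry_effects

    def test_unlabelled_layout_rejected(self):
        from orthopheno import build_plot_grid

        grid = build_plot_grid([(0, 10), (10, 10), (10, 0), (0, 0)], 2, 2, 3.0, 3.0)
        with pytest.raises(ValueError, match="label"):
            simulate_field(grid, SimParams(), seed=0)


class TestRenderOrthorectified:
    def test_every_plot_covered_at_80pct_overlap(self):
        """Geometric oracle: with >= 80% overlap each plot polygon fits fully
        inside at least 3 image footprints, and extraction agrees."""
        layout = synthetic_layout(24, 2, n_rows=4, seed=2)
        values, truth = simulate_field(layout, SimParams(), seed=2)
        images, _ = render_orthorectified(layout, values, params=SimParams(), seed=2, truth=truth)
        # independent polygon-in-rectangle containment count
        for plot in layout.plots:
            n_contained = sum(
                box(*img.extent).contains(plot.polygon) for img in images
            )
            assert n_contained >= 3
        table = extract_trait_table(images, layout, "CT", date="d")
        counts = table.groupby("plot_id").size()
        assert set(counts.index) == {p.plot_id for p in layout.plots}
        assert (counts >= 3).all()

    def test_containment_counts_match_geometry_oracle(self):
        """Per-plot record counts equal the polygon-in-rectangle counts."""
        layout = synthetic_layout(24, 2, n_rows=4, seed=8)
        values, truth = simulate_field(layout, SimParams(), seed=8)
        images, _ = render_orthorectified(layout, values, params=SimParams(), seed=8, truth=truth)
        table = extract_trait_table(images, layout, "CT", date="d")
        counts = table.groupby("plot_id").size()
        for plot in layout.plots:
            oracle = sum(box(*img.extent).contains(plot.polygon) for img in images)
            assert counts[plot.plot_id] == oracle

    def test_noise_free_images_agree_on_overlap(self):
        layout = synthetic_layout(12, 2, n_rows=4, seed=3)
        params = SimParams(sigma2_image=0.0, drift_per_image=0.0, sigma2_pixel=0.0)
        values, truth = simulate_field(layout, params, seed=3)
        images, _ = render_orthorectified(layout, values, params=params, seed=3, truth=truth)
        a, b = images[0], images[1]
        # overlap region in world coordinates
        inter = box(*a.extent).intersection(box(*b.extent))
        assert inter.area > 0
        for img in (a, b):
            pass
        xmin, ymin, xmax, ymax = inter.bounds

        def window(img):
            c0 = round((xmin - img.transform[0]) / img.transform[1])
            c1 = round((xmax - img.transform[0]) / img.transform[1])
            r0 = round((img.transform[3] - ymax) / -img.transform[5])
            r1 = round((img.transform[3] - ymin) / -img.transform[5])
            return img.band("thermal_ir")[r0:r1, c0:c1]

        assert np.array_equal(window(a), window(b))

    def test_thermal_round_trip_within_quantization(self):
        layout = synthetic_layout(12, 2, n_rows=4, seed=5)
        params = SimParams(sigma2_image=0.0, drift_per_image=0.0, sigma2_pixel=0.0)
        values, truth = simulate_field(layout, params, seed=5)
        images, _ = render_orthorectified(layout, values, params=params, seed=5, truth=truth)
        table = extract_trait_table(images, layout, "CT", date="d")
        merged = table.merge(values.rename("truth"), left_on="plot_id", right_index=True)
        assert (merged.value - merged.truth).abs().max() <= 0.04 / 2 + 1e-9

    def test_footprint_smaller_than_plot_rejected(self):
        layout = synthetic_layout(12, 2, n_rows=4, seed=5)
        values, truth = simulate_field(layout, SimParams(), seed=5)
        with pytest.raises(ValueError, match="footprint"):
            render_orthorectified(
                layout, values, plan=FlightPlan(footprint_m=(1.0, 1.0)), seed=5, truth=truth
            )

    def test_fringe_stamps_nodata(self):
        layout = synthetic_layout(12, 2, n_rows=4, seed=6)
        values, truth = simulate_field(layout, SimParams(), seed=6)
        images, _ = render_orthorectified(
            layout, values, params=SimParams(), seed=6, truth=truth, fringe_frac=0.3
        )
        assert images[0].mask.any()


class TestRenderMosaic:
    def _two_constant_images(self, a=10.0, b=20.0):
        from orthopheno import GeoRaster, CameraPose

        def img(val, x0, idx):
            return GeoRaster(
                bands={"nir": np.full((4, 6), val)},
                transform=(x0, 1.0, 0, 4.0, 0, -1.0),
                nodata=float("nan"),
                crs_tag="local-metric",
                pose=CameraPose(lon=x0 + 3, lat=2, capture_index=idx),
                image_id=f"I{idx}",
            )

        return img(a, 0.0, 0), img(b, 3.0, 1)

    def test_mean_blend_averages_overlap(self):
        a, b = self._two_constant_images()
        mosaic = render_mosaic([a, b], blend="mean")
        # overlap columns 3..5 hold (10+20)/2
        assert np.allclose(mosaic.band("nir")[:, 3:6], 15.0)
        assert np.allclose(mosaic.band("nir")[:, :3], 10.0)
        assert np.allclose(mosaic.band("nir")[:, 6:], 20.0)

    def test_first_wins_keeps_earliest(self):
        a, b = self._two_constant_images()
        mosaic = render_mosaic([a, b], blend="first")
        assert np.allclose(mosaic.band("nir")[:, 3:6], 10.0)

    def test_single_image_identity(self):
        a, _ = self._two_constant_images()
        mosaic = render_mosaic([a], blend="mean")
        assert np.allclose(mosaic.band("nir"), a.band("nir"))
        assert mosaic.pose is None

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            render_mosaic([])


class TestGroundCoverRendering:
    def test_painted_fraction_recovered_exactly(self):
        """Painting fraction f of plot pixels green yields GC = f exactly
        under the default HSV thresholds (when f maps to a whole pixel count)."""
        layout = synthetic_layout(12, 2, n_rows=4, seed=7)
        # choose fractions with exact pixel counts: multiples of 1/n_pixels
        values, _ = simulate_field(layout, SimParams(), seed=7)
        fractions = pd.Series(0.25, index=values.index)
        images, _ = render_orthorectified(
            layout, fractions, params=SimParams(), seed=7, kind="rgb"
        )
        table = extract_trait_table(images, layout, "GC", date="d")
        # every plot window has n_pixels divisible by 4 in this geometry
        exact = table[table.n_pixels % 4 == 0]
        assert not exact.empty
        assert np.allclose(exact.value, 0.25)

    def test_soil_pixels_not_canopy(self):
        rgb = np.array([[[0.45, 0.33, 0.18]]])
        assert gc_binary(rgb)[0, 0] == 0


class TestEndToEndDeterminism:
    def test_fit_results_identical_across_runs(self):
        def run(seed):
            layout = synthetic_layout(16, 2, n_rows=4, seed=seed)
            params = SimParams()
            values, truth = simulate_field(layout, params, seed=seed)
            images, truth = render_orthorectified(
                layout, values, params=params, seed=seed, truth=truth
            )
            mosaic = render_mosaic(images, blend="mean")
            table = extract_trait_table(images, layout, "CT", mosaic=mosaic, date="d")
            fit, h2 = fit_trait_model(table, layout.design_frame(), "III")
            return fit, h2

        f1, h1 = run(17)
        f2, h2 = run(17)
        assert f1.variance_components == f2.variance_components
        assert f1.restricted_loglik == f2.restricted_loglik
        assert h1 == h2

    def test_image_offsets_inflate_within_plot_variance(self):
        """Paired simulation: sigma2_image > 0 raises the between-record
        spread within plots relative to sigma2_image = 0."""
        spreads = {0.0: [], 2.0: []}
        for seed in range(6):
            for s2i in spreads:
                layout = synthetic_layout(12, 2, n_rows=4, seed=seed)
                params = SimParams(sigma2_image=s2i, drift_per_image=0.0)
                values, truth = simulate_field(layout, params, seed=seed)
                images, _ = render_orthorectified(
                    layout, values, params=params, seed=seed, truth=truth
                )
                table = extract_trait_table(images, layout, "CT", date="d")
                spread = table.groupby("plot_id").value.var().mean()
                spreads[s2i].append(spread)
        assert np.mean(spreads[2.0]) > np.mean(spreads[0.0])


class TestSimulateTraitTable:
    def test_truth_bookkeeping(self):
        table, truth = simulate_trait_table(50, 2, subsamples=6, seed=1)
        assert len(table) == 50 * 2 * 6
        assert truth["n_harmonic"] == pytest.approx(6.0)
        expected_h2 = 1.0 / (1.0 + 0.5 / 2 + 1.0 / (2 * 6))
        assert truth["h2_true"] == pytest.approx(expected_h2)

    def test_deterministic(self):
        t1, _ = simulate_trait_table(20, 2, seed=5)
        t2, _ = simulate_trait_table(20, 2, seed=5)
        pd.testing.assert_frame_equal(t1, t2)
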