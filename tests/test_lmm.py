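"""REML engine correctness, heritability/BIC formulas, model orchestration."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from orthopheno import (
    HeritabilityInputs,
    ModelSpec,
    bic,
    compare_models,
    fit_trait_model,
    harmonic_mean,
    heritability,
    reml_fit,
    simulate_trait_table,
)

BALANCED_ONEWAY = pd.DataFrame(
    {"value": [1, 2, 3, 5, 7, 9], "group": ["a", "a", "b", "b", "c", "c"]}
)


class TestRemlFit:
    def test_balanced_oneway_equals_anova(self):
        """REML equals the closed-form ANOVA solution on a balanced design.

        Oracle: MSB = 21.5, MSW = 1.5 -> sigma2_group = (MSB-MSW)/2 = 10.
        """
        fit = reml_fit(BALANCED_ONEWAY, ModelSpec(random_terms=("group",)))
        assert fit.variance_components["group"] == pytest.approx(10.0, rel=1e-6)
        assert fit.variance_components["residual"] == pytest.approx(1.5, rel=1e-6)
        assert fit.converged and not fit.boundary_terms

    def test_anova_oracle_random_balanced_designs(self):
        """On random balanced one-way data with interior solutions, REML
        matches the method-of-moments ANOVA estimator."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            k, m = 8, 4
            g = rng.normal(0, 2, k)
            y = (g[:, None] + rng.normal(0, 1, (k, m))).ravel()
            df = pd.DataFrame({"value": y, "group": np.repeat(np.arange(k), m)})
            msb = m * np.var([y[i * m : (i + 1) * m].mean() for i in range(k)], ddof=1)
            msw = np.mean([np.var(y[i * m : (i + 1) * m], ddof=1) for i in range(k)])
            if msb <= msw:
                continue
            fit = reml_fit(df, ModelSpec(random_terms=("group",)))
            assert fit.variance_components["group"] == pytest.approx((msb - msw) / m, rel=1e-6)
            assert fit.variance_components["residual"] == pytest.approx(msw, rel=1e-6)

    def test_zero_signal_hits_boundary(self):
        df = pd.DataFrame({"value": [1.0, 1, 1, 1, 2, 0, 2, 0], "group": ["a"] * 4 + ["b"] * 4})
        fit = reml_fit(df, ModelSpec(random_terms=("group",)))
        assert "group" in fit.boundary_terms
        assert fit.variance_components["group"] < 1e-8

    def test_loglik_monotone_across_iterations(self):
        table, _ = simulate_trait_table(30, 2, seed=11)
        fit = reml_fit(table, ModelSpec(random_terms=("entry", "block", "plot")))
        trace = np.asarray(fit.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-9)

    def test_deterministic(self):
        table, _ = simulate_trait_table(25, 2, seed=3)
        spec = ModelSpec(random_terms=("entry", "block", "plot"))
        a = reml_fit(table, spec)
        b = reml_fit(table, spec)
        assert a.variance_components == b.variance_components
        assert a.restricted_loglik == b.restricted_loglik

    def test_response_rescaling_scales_components(self):
        """All variance components scale by c^2 under y -> c*y, so H2 is invariant."""
        table, _ = simulate_trait_table(40, 2, seed=5)
        spec = ModelSpec(random_terms=("entry", "block", "plot"), model_tag="II")
        base = reml_fit(table, spec)
        scaled_tab = table.assign(value=3.0 * table.value)
        scaled = reml_fit(scaled_tab, spec)
        for term, v in base.variance_components.items():
            assert scaled.variance_components[term] == pytest.approx(9.0 * v, rel=1e-4)
        inp = HeritabilityInputs(r=2, n=4.0)
        scaled.variance_components = dict(scaled.variance_components)
        base.variance_components["plot"] = base.variance_components["plot"]
        assert heritability(base, inp) == pytest.approx(heritability(scaled, inp), rel=1e-4)

    def test_singular_fixed_design_rejected(self):
        df = BALANCED_ONEWAY.assign(zero=0.0)
        with pytest.raises(ValueError, match="singular"):
            reml_fit(df, ModelSpec(random_terms=("group",), fixed_covariates=("zero",)))

    def test_single_level_factor_rejected(self):
        df = BALANCED_ONEWAY.assign(one="x")
        with pytest.raises(ValueError, match="fewer than 2"):
            reml_fit(df, ModelSpec(random_terms=("one",)))


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_crossed_design_matches_lme4(tmp_path):
    """Independent oracle: lme4 REML on a crossed entry/block/plot design."""
    table, _ = simulate_trait_table(15, 2, subsamples=3, seed=21)
    csv = tmp_path / "d.csv"
    table.to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(
        "suppressMessages(library(lme4))\n"
        f"d <- read.csv('{csv}')\n"
        "d$block <- factor(d$block)\n"
        "f <- lmer(value ~ (1|entry) + (1|block) + (1|plot), data=d, REML=TRUE)\n"
        "vc <- as.data.frame(VarCorr(f))\n"
        "cat(vc$vcov[match(c('entry','block','plot','Residual'), vc$grp)], -0.5*REMLcrit(f), sep='\\n')\n"
    )
    out = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, check=True
    )
    r_entry, r_block, r_plot, r_resid, r_ll = map(float, out.stdout.split())
    fit = reml_fit(table, ModelSpec(random_terms=("entry", "block", "plot")))
    vc = fit.variance_components
    assert vc["entry"] == pytest.approx(r_entry, rel=1e-4, abs=1e-8)
    assert vc["block"] == pytest.approx(r_block, rel=1e-4, abs=1e-8)
    assert vc["plot"] == pytest.approx(r_plot, rel=1e-4, abs=1e-8)
    assert vc["residual"] == pytest.approx(r_resid, rel=1e-4)
    assert fit.restricted_loglik == pytest.approx(r_ll, abs=1e-4)


class TestHarmonicMean:
    def test_constant_counts(self):
        assert harmonic_mean([4, 4, 4]) == pytest.approx(4.0)

    def test_two_counts(self):
        assert harmonic_mean([2, 6]) == pytest.approx(3.0)

    def test_extreme_spread(self):
        # counts at the extremes seen in real campaigns (3 to 49 per plot)
        assert harmonic_mean([3, 49]) == pytest.approx(5.6538, abs=1e-4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            harmonic_mean([])

    def test_never_exceeds_arithmetic_mean(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            c = rng.integers(1, 50, size=12)
            assert harmonic_mean(c) <= c.mean() + 1e-12


class TestHeritability:
    def _fit(self, vc, tag):
        from orthopheno.lmm import FitResult

        return FitResult(
            variance_components=vc,
            fixed_estimates={},
            restricted_loglik=0.0,
            n_obs=10,
            rank_X=1,
            n_vparams=len(vc),
            converged=True,
            boundary_terms=[],
            n_iter=1,
            model_tag=tag,
        )

    def test_single_observation_formula(self):
        fit = self._fit({"entry": 1.0, "residual": 1.0}, "Ia")
        assert heritability(fit, HeritabilityInputs(r=2)) == pytest.approx(2 / 3, abs=1e-4)

    def test_subsample_formula_model_ii(self):
        fit = self._fit({"entry": 1.0, "plot": 0.5, "residual": 1.0}, "II")
        got = heritability(fit, HeritabilityInputs(r=2, n=4))
        assert got == pytest.approx(1 / (1 + 0.25 + 0.125), abs=1e-4)  # 0.7273

    def test_subsample_formula_model_iii(self):
        fit = self._fit({"entry": 2.0, "entry_block": 0.5, "residual": 1.0}, "III")
        got = heritability(fit, HeritabilityInputs(r=2, n=5))
        assert got == pytest.approx(2.0 / (2.0 + 0.25 + 0.1))

    def test_zero_genetic_variance(self):
        fit = self._fit({"entry": 0.0, "residual": 1.0}, "Ia")
        assert heritability(fit, HeritabilityInputs(r=2)) == 0.0

    def test_missing_component_rejected(self):
        fit = self._fit({"entry": 1.0, "residual": 1.0}, "III")
        with pytest.raises(ValueError, match="entry_block"):
            heritability(fit, HeritabilityInputs(r=2, n=4))


class TestBic:
    def test_arithmetic(self):
        fit = TestHeritability()._fit({"a": 1.0, "b": 1.0, "residual": 1.0}, "II")
        fit.restricted_loglik = -100.0
        fit.n_obs, fit.rank_X = 102, 2  # nu = 100, k = 3
        assert bic(fit) == pytest.approx(200 + 3 * np.log(100))

    def test_identical_fits_identical_bic(self):
        table, _ = simulate_trait_table(20, 2, seed=9)
        spec = ModelSpec(random_terms=("entry", "block", "plot"))
        assert bic(reml_fit(table, spec)) == bic(reml_fit(table, spec))

    def test_extra_null_term_increases_bic_on_average(self):
        """A variance term with zero true variance costs BIC in expectation."""
        deltas = []
        for seed in range(8):
            table, _ = simulate_trait_table(
                30, 2, sigma2_block=0.0, subsamples=4, seed=400 + seed
            )
            lean = reml_fit(table, ModelSpec(random_terms=("entry", "plot")))
            full = reml_fit(table, ModelSpec(random_terms=("entry", "block", "plot")))
            deltas.append(bic(full) - bic(lean))
        assert np.mean(deltas) > 0


def _pipeline_table(seed=0, n_entries=24):
    """Small raster-free trait table with MOSAIC + orthorectified rows."""
    from orthopheno import extract_trait_table, render_mosaic, render_orthorectified
    from orthopheno import SimParams, simulate_field, synthetic_layout

    layout = synthetic_layout(n_entries, 2, seed=seed)
    params = SimParams()
    values, truth = simulate_field(layout, params, seed=seed)
    images, truth = render_orthorectified(
        layout, values, params=params, seed=seed, kind="thermal", truth=truth
    )
    mosaic = render_mosaic(images, blend="mean")
    table = extract_trait_table(images, layout, "CT", mosaic=mosaic, date="d0")
    return table, layout.design_frame()


class TestFitTraitModel:
    def test_ia_needs_mosaic_rows(self):
        table, design = _pipeline_table()
        no_mosaic = table[table.source_id != "MOSAIC"]
        with pytest.raises(ValueError, match="MOSAIC"):
            fit_trait_model(no_mosaic, design, "Ia")

    def test_ib_matches_ia_when_single_observation(self):
        """With one orthorectified record per plot, the Ib mean is that record."""
        table, design = _pipeline_table()
        ortho = table[table.source_id != "MOSAIC"]
        singles = ortho.groupby("plot_id", as_index=False).first()
        relabelled = singles.assign(source_id="MOSAIC")
        fit_a, h2_a = fit_trait_model(relabelled, design, "Ia")
        fit_b, h2_b = fit_trait_model(singles, design, "Ib")
        assert h2_a == pytest.approx(h2_b, abs=1e-6)
        for t, v in fit_a.variance_components.items():
            assert fit_b.variance_components[t] == pytest.approx(v, rel=1e-4, abs=1e-9)

    def test_balanced_subsampling_identity_ib_vs_ii(self):
        """sigma2_e(Ib) ~ sigma2_plot(II) + sigma2_eps(II)/n under balance."""
        table, truth = simulate_trait_table(80, 2, subsamples=6, seed=13)
        table = table.rename(columns={"plot": "plot_id"})
        table["source_id"] = [f"S{i}" for i in range(len(table))]
        table["trait"] = "CT"
        table["date"] = "d"
        table["n_pixels"] = 10
        table["azimuth_deg"] = np.nan
        # a design frame in II's row/col vocabulary: one plot per row/col cell
        plots = table[["plot_id", "entry", "block"]].drop_duplicates().reset_index(drop=True)
        plots["row"] = plots.groupby("block").cumcount() // 10 + 1
        plots["col"] = plots.groupby("block").cumcount() % 10 + 1
        design = plots
        fit_ib, _ = fit_trait_model(table, design, "Ib")
        fit_ii, _ = fit_trait_model(table, design, "II")
        lhs = fit_ib.variance_components["residual"]
        rhs = (
            fit_ii.variance_components["plot"]
            + fit_ii.variance_components["residual"] / 6.0
        )
        assert lhs == pytest.approx(rhs, rel=0.10)

    def test_model_iii_zero_image_variance_hits_boundary(self):
        """With no image effects simulated, sigma2_I sits at the boundary mostly."""
        from orthopheno import SimParams, extract_trait_table, render_orthorectified
        from orthopheno import simulate_field, synthetic_layout

        hits = 0
        reps = 10
        for seed in range(reps):
            layout = synthetic_layout(16, 2, n_rows=4, seed=seed)
            params = SimParams(sigma2_image=0.0, drift_per_image=0.0)
            values, truth = simulate_field(layout, params, seed=seed)
            images, _ = render_orthorectified(
                layout, values, params=params, seed=seed, kind="thermal", truth=truth
            )
            table = extract_trait_table(images, layout, "CT", date="d")
            fit, _ = fit_trait_model(table, layout.design_frame(), "III")
            if "image" in fit.boundary_terms:
                hits += 1
        assert hits >= 0.8 * reps

    def test_model_iv_requires_azimuth(self):
        table, design = _pipeline_table()
        broken = table.copy()
        broken.loc[broken.source_id != "MOSAIC", "azimuth_deg"] = np.nan
        with pytest.raises(ValueError, match="azimuth"):
            fit_trait_model(broken, design, "IV")

    def test_model_iv_recovers_azimuth_slope(self):
        from orthopheno import SimParams, extract_trait_table, render_orthorectified
        from orthopheno import simulate_field, synthetic_layout

        seed = 42
        layout = synthetic_layout(40, 2, seed=seed)
        params = SimParams(beta_azimuth=0.01)
        values, truth = simulate_field(layout, params, seed=seed)
        images, _ = render_orthorectified(
            layout, values, params=params, seed=seed, kind="thermal", truth=truth
        )
        table = extract_trait_table(images, layout, "CT", date="d")
        fit, _ = fit_trait_model(table, layout.design_frame(), "IV")
        beta, se = fit.fixed_estimates["azimuth_deg"]
        assert abs(beta - 0.01) < 3 * se


class TestCompareModels:
    def test_report_shape_and_bic_scope(self):
        table, design = _pipeline_table()
        report = compare_models(table, design)
        assert list(report.index) == ["Ia", "Ib", "II", "III", "IV"]
        assert report.loc[["Ia", "Ib"], "BIC"].isna().all()
        assert report.loc[["II", "III", "IV"], "BIC"].notna().all()
        assert report.H2.between(0, 1).all()
        assert report.best_bic.sum() == 1 and report.best_h2.sum() == 1

    def test_single_model_rejected(self):
        table, design = _pipeline_table()
        with pytest.raises(ValueError, match="two models"):
            compare_models(table, design, model_tags=["II"])

    def test_mixed_traits_rejected(self):
        table, design = _pipeline_table()
        mixed = pd.concat([table, table.assign(trait="NDVI")])
        with pytest.raises(ValueError, match="single trait"):
            compare_models(mixed, design)
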