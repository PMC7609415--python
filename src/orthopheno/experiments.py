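"""Canned simulation studies exercising the full pipeline.

Two replication studies are packaged so that tests, scripts and users run
the identical protocol:

* :func:`recovery_study` — can the REML engine recover known variance
  components and entry-mean heritability from subsampled plot data?
* :func:`mosaic_vs_ortho_study` — does modelling image effects on
  orthorectified extractions (Model III) yield higher heritability than a
  mean-blended mosaic analysed with the single-observation model (Ia),
  when image-level offsets dominate the genetic signal?

The second study switches off row/column spatial variance: those are
nuisance terms that Model Ia absorbs explicitly but Model III lumps into
its plot term, so leaving them on confounds the image-offset mechanism
the study isolates.
"""

from __future__ import annotations

import numpy as np

from dataclasses import replace

from .extraction import extract_trait_table
from .lmm import HeritabilityInputs, ModelSpec, fit_trait_model, harmonic_mean, heritability, reml_fit
from .synthfield import (
    FlightPlan,
    SimParams,
    _serpentine_centers,
    render_mosaic,
    render_orthorectified,
    simulate_field,
    simulate_trait_table,
    synthetic_layout,
)

__all__ = ["recovery_study", "mosaic_vs_ortho_study"]


def recovery_study(
    seed: int = 0,
    n_reps: int = 20,
    n_entries: int = 200,
    n_blocks: int = 2,
    truth: tuple[float, float, float, float] = (1.0, 0.2, 0.5, 1.0),
    subsamples=(4, 8),
) -> dict:
    """Fit the subsampling model to simulated tables and summarise recovery.

    Each replicate simulates ``y = mu + entry + block + plot + resid`` with
    the given true variances and a variable subsample count per plot, fits
    the matching mixed model by REML, and computes entry-mean heritability
    with r = ``n_blocks`` and n = the harmonic-mean subsample count.

    Returns mean component estimates, mean estimated and true heritability,
    over ``n_reps`` replicates seeded ``seed .. seed+n_reps-1``.
    """
    s_g, s_b, s_p, s_e = truth
    comps, h2_hat, h2_true = [], [], []
    n_obs = 0
    for i in range(n_reps):
        table, tru = simulate_trait_table(
            n_entries,
            n_blocks,
            sigma2_entry=s_g,
            sigma2_block=s_b,
            sigma2_plot=s_p,
            sigma2_resid=s_e,
            subsamples=subsamples,
            seed=seed + i,
        )
        fit = reml_fit(table, ModelSpec(random_terms=("entry", "block", "plot"), model_tag="II"))
        vc = fit.variance_components
        comps.append([vc["entry"], vc["block"], vc["plot"], vc["residual"]])
        counts = table.groupby("plot").size()
        inputs = HeritabilityInputs(r=n_blocks, n=harmonic_mean(counts))
        h2_hat.append(heritability(fit, inputs))
        h2_true.append(tru["h2_true"])
        n_obs += len(table)
    mean = np.mean(comps, axis=0)
    return {
        "mean_sigma2_entry": float(mean[0]),
        "mean_sigma2_block": float(mean[1]),
        "mean_sigma2_plot": float(mean[2]),
        "mean_sigma2_resid": float(mean[3]),
        "mean_h2": float(np.mean(h2_hat)),
        "mean_h2_true": float(np.mean(h2_true)),
        "truth": {"sigma2_entry": s_g, "sigma2_block": s_b, "sigma2_plot": s_p, "sigma2_resid": s_e},
        "n_reps": n_reps,
        "n_obs_total": n_obs,
    }


def _flight_image_count(layout, plan: FlightPlan) -> int:
    xs, ys = [], []
    for pl in layout.plots:
        b = pl.polygon.bounds
        xs += [b[0], b[2]]
        ys += [b[1], b[3]]
    extent = (
        min(xs) - plan.gsd_m,
        min(ys) - plan.gsd_m,
        max(xs) + plan.gsd_m,
        max(ys) + plan.gsd_m,
    )
    return len(_serpentine_centers(extent, plan))


def mosaic_vs_ortho_study(
    seed: int = 0,
    n_reps: int = 50,
    n_entries: int = 64,
    n_blocks: int = 2,
    n_rows: int = 8,
    params: SimParams | None = None,
    total_drift_c: float = 6.0,
) -> dict:
    """Mean heritability from Model III (orthorectified) vs Ia (mosaic).

    Per replicate: simulate a field with image offsets dominating the
    genetic signal plus capture-order drift, render a serpentine thermal
    flight, mean-blend the mosaic, extract canopy temperature both ways and
    fit both models.  Row/column spatial variance is zero by design (see
    module docstring).

    ``total_drift_c`` fixes the systematic drift accumulated across the
    whole flight: the emulated campaign is a multi-hour midday canopy
    temperature window, over which ambient conditions move by several °C.
    It is converted to a per-capture increment from the flight's image
    count, so the condition is invariant to the desk-scale flight size.
    """
    if params is None:
        params = SimParams(sigma2_row=0.0, sigma2_col=0.0)
    n_images = _flight_image_count(
        synthetic_layout(n_entries, n_blocks, n_rows=n_rows, seed=seed), FlightPlan()
    )
    params = replace(params, drift_per_image=total_drift_c / max(n_images - 1, 1))
    h2_ia, h2_iii = [], []
    n_obs = 0
    for i in range(n_reps):
        rep_seed = seed + i
        layout = synthetic_layout(n_entries, n_blocks, n_rows=n_rows, seed=rep_seed)
        values, truth = simulate_field(layout, params, seed=rep_seed)
        images, truth = render_orthorectified(
            layout, values, params=params, seed=rep_seed, kind="thermal", truth=truth
        )
        mosaic = render_mosaic(images, blend="mean")
        table = extract_trait_table(images, layout, "CT", mosaic=mosaic, date="sim")
        design = layout.design_frame()
        _, h_a = fit_trait_model(table, design, "Ia")
        _, h_3 = fit_trait_model(table, design, "III")
        h2_ia.append(h_a)
        h2_iii.append(h_3)
        n_obs += len(table)
    return {
        "mean_h2_model_Ia": float(np.mean(h2_ia)),
        "mean_h2_model_III": float(np.mean(h2_iii)),
        "mean_paired_gain": float(np.mean(np.asarray(h2_iii) - np.asarray(h2_ia))),
        "n_reps": n_reps,
        "n_obs_total": n_obs,
        "sigma2_image": params.sigma2_image,
        "sigma2_entry": params.sigma2_entry,
    }
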