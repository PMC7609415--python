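"""REML variance components, broad-sense heritability and model comparison.

The response is modelled as a Gaussian linear mixed model

    y = X beta + sum_u Z_u u_u + e,    u_u ~ N(0, sigma2_u I),  e ~ N(0, sigma2_e I)

with independent variance components, one per random factor.  Components
are estimated by residual (restricted) maximum likelihood using
average-information (AI) updates with step-halving and an EM fallback, so
the restricted log-likelihood never decreases across iterations.  The
solver works through the mixed-model equations: for each parameter vector
theta the coefficient matrix

    C = W' W / sigma2_e + diag(0_p, I/sigma2_1, ..., I/sigma2_U),   W = [X | Z_1 ... Z_U]

is factorised once, giving the restricted log-likelihood

    -2 l_R = n log sigma2_e + sum_u q_u log sigma2_u + log|C| + y'Py + (n-p) log 2 pi

with y'Py = (y'y - theta_hat' W'y)/sigma2_e, together with BLUEs, BLUPs,
exact first derivatives and the AI matrix.

Five model variants mirror how plot-level UAS traits are analysed:

========  ==========================================  ========================
tag       response                                    random terms
========  ==========================================  ========================
``Ia``    one mosaic observation per plot             entry, block, row(block), col(block)
``Ib``    per-plot mean of orthorectified obs.        entry, block, row(block), col(block)
``II``    all orthorectified observations             + plot = row x col (block)
``III``   all orthorectified observations             entry, block, image, entry x block
``IV``    as III, camera azimuth as fixed covariate   entry, block, image, entry x block
========  ==========================================  ========================

Broad-sense heritability on an entry-mean basis is computed from the fitted
components: with r blocks (plots per entry) and n the harmonic-mean number
of subsamples per plot,

    Ia/Ib:      H2 = sG2 / (sG2 + se2 / r)
    II:         H2 = sG2 / (sG2 + s_plot2 / r + s_eps2 / (r n))
    III/IV:     H2 = sG2 / (sG2 + s_GxB2 / r + s_eps2 / (r n))

BIC = -2 l_R + k log(n - p) with k the number of freely estimated variance
components; it is comparable only among models fitted to the same response
(II, III, IV).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "FitResult",
    "reml_fit",
    "harmonic_mean",
    "heritability",
    "bic",
    "fit_trait_model",
    "compare_models",
    "MODEL_TAGS",
]

MODEL_TAGS = ("Ia", "Ib", "II", "III", "IV")

#: canonical names of the random terms used by the five model variants
_MODEL_RANDOM = {
    "Ia": ("entry", "block", "row_b", "col_b"),
    "Ib": ("entry", "block", "row_b", "col_b"),
    "II": ("entry", "block", "row_b", "col_b", "plot"),
    "III": ("entry", "block", "image", "entry_block"),
    "IV": ("entry", "block", "image", "entry_block"),
}


@dataclass(frozen=True)
class ModelSpec:
    """Fixed and random structure of one mixed-model fit.

    ``random_terms`` name factor columns of the response table; each
    contributes one iid variance component.  ``fixed_covariates`` are
    numeric columns added to the intercept-only fixed design.
    """

    random_terms: tuple[str, ...]
    fixed_covariates: tuple[str, ...] = ()
    model_tag: str = ""

    def __post_init__(self) -> None:
        if not self.random_terms:
            raise ValueError("at least one random term is required")


@dataclass
class FitResult:
    """REML estimates and fit metadata."""

    variance_components: dict[str, float]
    fixed_estimates: dict[str, tuple[float, float]]  # name -> (estimate, SE)
    restricted_loglik: float
    n_obs: int
    rank_X: int
    n_vparams: int
    converged: bool
    boundary_terms: list[str]
    n_iter: int
    loglik_trace: list[float] = field(default_factory=list)
    model_tag: str = ""

    @property
    def bic(self) -> float:
        return bic(self)


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the log-likelihood trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


# ----------------------------------------------------------------------
# Design construction
# ----------------------------------------------------------------------


def _indicator(codes: np.ndarray, n_levels: int) -> sp.csr_matrix:
    n = codes.shape[0]
    return sp.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, n_levels)
    )


def _build_design(table: pd.DataFrame, spec: ModelSpec):
    y = table["value"].to_numpy(dtype=float)
    n = y.shape[0]
    X_cols = [np.ones(n)]
    names = ["(intercept)"]
    for cov in spec.fixed_covariates:
        v = table[cov].to_numpy(dtype=float)
        if np.isnan(v).any():
            raise ValueError(f"fixed covariate {cov!r} has missing values")
        X_cols.append(v)
        names.append(cov)
    X = np.column_stack(X_cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular fixed-effect design")
    Z_blocks, q_sizes = [], []
    for term in spec.random_terms:
        if term not in table.columns:
            raise ValueError(f"random term {term!r} missing from the table")
        codes, levels = pd.factorize(table[term], sort=True)
        if (codes < 0).any():
            raise ValueError(f"random term {term!r} has missing values")
        if len(levels) < 2:
            raise ValueError(f"random term {term!r} has fewer than 2 levels")
        Z_blocks.append(_indicator(codes, len(levels)))
        q_sizes.append(len(levels))
    return y, X, names, Z_blocks, q_sizes


# ----------------------------------------------------------------------
# REML engine
# ----------------------------------------------------------------------


class _REMLWork:
    """Precomputed cross-products and per-theta factorisations."""

    def __init__(self, y, X, Z_blocks, q_sizes):
        self.n, self.p = X.shape
        self.q_sizes = q_sizes
        self.q = int(sum(q_sizes))
        W = sp.hstack([sp.csr_matrix(X)] + Z_blocks, format="csr")
        self.W = W
        self.WtW = np.asarray((W.T @ W).todense())
        self.Wty = W.T @ y
        self.yty = float(y @ y)
        self.y = y
        # index slices of each random block inside W's columns
        self.slices = []
        start = self.p
        for qu in q_sizes:
            self.slices.append(slice(start, start + qu))
            start += qu

    def factorize(self, sigma2_u: np.ndarray, sigma2_e: float):
        C = self.WtW / sigma2_e
        diag = np.zeros(self.p + self.q)
        for sl, s2 in zip(self.slices, sigma2_u):
            diag[sl] = 1.0 / s2
        C[np.diag_indices_from(C)] += diag
        # degenerate responses (zero residual variance) can cost positive
        # definiteness in floating point; retry with growing jitter
        jitter = 0.0
        for attempt in range(4):
            try:
                cho = sla.cho_factor(C, lower=True, check_finite=False)
                break
            except np.linalg.LinAlgError:
                if attempt == 3:
                    raise
                jitter = max(jitter * 100.0, 1e-12 * float(np.max(np.diag(C))))
                C[np.diag_indices_from(C)] += jitter
        logdetC = 2.0 * np.sum(np.log(np.diag(cho[0])))
        sol = sla.cho_solve(cho, self.Wty / sigma2_e, check_finite=False)
        return cho, logdetC, sol

    def loglik(self, sigma2_u, sigma2_e, cho=None, logdetC=None, sol=None):
        if cho is None:
            cho, logdetC, sol = self.factorize(sigma2_u, sigma2_e)
        n, p = self.n, self.p
        yPy = (self.yty - sol @ self.Wty) / sigma2_e
        ll = -0.5 * (
            n * np.log(sigma2_e)
            + float(np.dot(self.q_sizes, np.log(sigma2_u)))
            + logdetC
            + yPy
            + (n - p) * np.log(2.0 * np.pi)
        )
        return float(ll)


def _gradient_and_ai(work: _REMLWork, sigma2_u, sigma2_e, cho, sol):
    """Exact REML score and average-information matrix at theta."""
    n, p, q = work.n, work.p, work.q
    Cinv = sla.cho_solve(cho, np.eye(p + q), check_finite=False)
    resid = work.y - work.W @ sol
    sse = float(resid @ resid)
    U = len(work.q_sizes)
    grad = np.empty(U + 1)
    trace_terms = 0.0
    f_vectors = []
    for i, sl in enumerate(work.slices):
        s2 = sigma2_u[i]
        qu = work.q_sizes[i]
        u_hat = sol[sl]
        T_u = float(np.trace(Cinv[sl, sl]))
        trace_terms += T_u / s2
        grad[i] = -0.5 * ((qu - T_u / s2) / s2 - float(u_hat @ u_hat) / s2**2)
        f_vectors.append(work.W[:, sl] @ (u_hat / s2))
    grad[U] = -0.5 * ((n - p - q + trace_terms) / sigma2_e - sse / sigma2_e**2)
    f_vectors.append(resid / sigma2_e)

    # AI_{ab} = 0.5 f_a' P f_b with P f = (f - W C^{-1} W' f / sigma2_e)/sigma2_e
    F = np.column_stack(f_vectors)
    WtF = work.W.T @ F
    PF = (F - work.W @ sla.cho_solve(cho, WtF / sigma2_e, check_finite=False)) / sigma2_e
    AI = 0.5 * (F.T @ PF)
    # per-term quantities reused by the EM fallback
    em_info = {
        "traces": [float(np.trace(Cinv[sl, sl])) for sl in work.slices],
        "u_hats": [sol[sl] for sl in work.slices],
        "sse": sse,
    }
    return grad, AI, em_info


def _em_step(work: _REMLWork, sigma2_u, sigma2_e, em_info):
    """EM-REML update (guaranteed ascent, slow near the optimum)."""
    new_u = np.empty_like(sigma2_u)
    trace_terms = 0.0
    for i, qu in enumerate(work.q_sizes):
        T_u = em_info["traces"][i]
        u_hat = em_info["u_hats"][i]
        new_u[i] = (float(u_hat @ u_hat) + T_u) / qu
        trace_terms += T_u / sigma2_u[i]
    denom = work.n - work.p - work.q + trace_terms
    new_e = em_info["sse"] / denom if denom > 0 else sigma2_e
    return new_u, max(new_e, 1e-300)


def reml_fit(
    table: pd.DataFrame,
    spec: ModelSpec,
    max_iter: int = 200,
    tol_loglik: float = 1e-8,
    tol_param: float = 1e-6,
) -> FitResult:
    """Fit the mixed model by AI-REML with EM fallback and step-halving.

    ``table`` must contain a numeric ``value`` column, the factor columns
    named by ``spec.random_terms`` and any fixed covariates.  Components
    that collapse to zero are fixed at 1e-10 x phenotypic variance,
    reported in ``boundary_terms`` and excluded from ``n_vparams``.
    Deterministic: no random initialisation (all components start at
    var(y)/(U+1) for U random terms).
    """
    y, X, fixed_names, Z_blocks, q_sizes = _build_design(table, spec)
    work = _REMLWork(y, X, Z_blocks, q_sizes)
    U = len(q_sizes)
    vary = float(np.var(y, ddof=1)) if work.n > 1 else 1.0
    if vary == 0.0:
        vary = 1.0
    bound = 1e-10 * vary
    sigma2_u = np.full(U, vary / (U + 1))
    sigma2_e = vary / (U + 1)

    cho, logdetC, sol = work.factorize(sigma2_u, sigma2_e)
    ll = work.loglik(sigma2_u, sigma2_e, cho, logdetC, sol)
    trace = [ll]
    converged = False
    it = 0
    grad = np.zeros(U + 1)
    for it in range(1, max_iter + 1):
        grad, AI, em_info = _gradient_and_ai(work, sigma2_u, sigma2_e, cho, sol)
        # a component sitting at the lower bound with a non-positive score
        # stays clamped this iteration; it re-enters if the score turns positive
        pinned = (sigma2_u <= bound * (1 + 1e-6)) & (grad[:U] <= 0)
        free = np.concatenate([~pinned, [True]])
        theta = np.concatenate([sigma2_u, [sigma2_e]])

        step = None
        AI_f = AI[np.ix_(free, free)]
        grad_f = grad[free]
        try:
            delta_f = np.linalg.solve(AI_f, grad_f)
            step = np.zeros(U + 1)
            step[free] = delta_f
            if not np.all(np.isfinite(step)):
                step = None
        except np.linalg.LinAlgError:
            step = None

        new_theta = None
        new_ll = -np.inf
        if step is not None:
            scale = 1.0
            for _ in range(30):
                cand = theta + scale * step
                cand = np.maximum(cand, bound)
                cand[:U][pinned] = bound
                try:
                    cho_c, logdet_c, sol_c = work.factorize(cand[:U], cand[U])
                    cand_ll = work.loglik(cand[:U], cand[U], cho_c, logdet_c, sol_c)
                except (np.linalg.LinAlgError, sla.LinAlgError):
                    cand_ll = -np.inf
                if np.isfinite(cand_ll) and cand_ll >= ll - 1e-12:
                    new_theta, new_ll = cand, cand_ll
                    cho, logdetC, sol = cho_c, logdet_c, sol_c
                    break
                scale *= 0.5
        if new_theta is None:
            # EM fallback, damped: the raw EM map is monotone, but clamping
            # pinned components can break that, so line-search toward it
            em_u, em_e = _em_step(work, sigma2_u, sigma2_e, em_info)
            target = np.concatenate([np.maximum(em_u, bound), [max(em_e, bound)]])
            target[:U][pinned] = bound
            scale = 1.0
            for _ in range(30):
                cand = theta + scale * (target - theta)
                cand = np.maximum(cand, bound)
                try:
                    cho_c, logdet_c, sol_c = work.factorize(cand[:U], cand[U])
                    cand_ll = work.loglik(cand[:U], cand[U], cho_c, logdet_c, sol_c)
                except (np.linalg.LinAlgError, sla.LinAlgError):
                    cand_ll = -np.inf
                if np.isfinite(cand_ll) and cand_ll >= ll - 1e-12:
                    new_theta, new_ll = cand, cand_ll
                    cho, logdetC, sol = cho_c, logdet_c, sol_c
                    break
                scale *= 0.5
        if new_theta is None:
            # neither the AI step nor the damped EM step improves the
            # restricted likelihood: numerically at the constrained optimum
            converged = True
            break

        rel_change = np.max(np.abs(new_theta - theta) / np.maximum(np.abs(theta), bound))
        dll = new_ll - ll
        sigma2_u, sigma2_e = new_theta[:U], new_theta[U]
        ll = new_ll
        trace.append(ll)
        if abs(dll) < tol_loglik and rel_change < tol_param:
            converged = True
            break
    # classification relative to scale: the restricted likelihood is flat
    # near zero, so components under 0.1% of the phenotypic variance are
    # reported as boundary (the hard clamp itself sits at 1e-10 x var(y))
    at_boundary = sigma2_u <= max(bound * (1 + 1e-6), 1e-3 * vary)

    if not converged:
        raise ConvergenceError(
            f"REML did not converge in {max_iter} iterations (last dll={trace[-1] - trace[-2]:.3e})",
            trace,
        )

    # fixed-effect estimates and SEs from the converged factorisation
    Cinv = sla.cho_solve(cho, np.eye(work.p + work.q), check_finite=False)
    beta = sol[: work.p]
    beta_se = np.sqrt(np.maximum(np.diag(Cinv)[: work.p], 0.0))
    varcomps = {t: float(s2) for t, s2 in zip(spec.random_terms, sigma2_u)}
    varcomps["residual"] = float(sigma2_e)
    boundary = [t for t, b in zip(spec.random_terms, at_boundary) if b]
    return FitResult(
        variance_components=varcomps,
        fixed_estimates={nm: (float(b), float(se)) for nm, b, se in zip(fixed_names, beta, beta_se)},
        restricted_loglik=float(ll),
        n_obs=work.n,
        rank_X=work.p,
        n_vparams=int((~at_boundary).sum()) + 1,
        converged=converged,
        boundary_terms=boundary,
        n_iter=it,
        loglik_trace=trace,
        model_tag=spec.model_tag,
    )


# ----------------------------------------------------------------------
# Heritability, BIC, model orchestration
# ----------------------------------------------------------------------


def harmonic_mean(counts) -> float:
    """Harmonic mean of per-plot observation counts: m / sum(1/c_i)."""
    counts = np.asarray(list(counts), dtype=float)
    if counts.size == 0:
        raise ValueError("harmonic_mean of an empty collection")
    if (counts < 1).any():
        raise ValueError("counts must be >= 1")
    return float(counts.size / np.sum(1.0 / counts))


@dataclass(frozen=True)
class HeritabilityInputs:
    """r = plots per entry (number of blocks); n = harmonic-mean subsamples."""

    r: float
    n: float = 1.0

    def __post_init__(self) -> None:
        if self.r < 1 or self.n < 1:
            raise ValueError("r and n must be >= 1")


def heritability(fit: FitResult, inputs: HeritabilityInputs) -> float:
    """Broad-sense heritability on an entry-mean basis, in [0, 1].

    The formula follows the model tag: single-observation models use the
    residual as plot-level error; subsample models additionally separate
    the plot-level variance (row x col within block, or entry x block) from
    the within-plot residual, weighting the latter by the harmonic-mean
    subsample count.
    """
    vc = fit.variance_components
    if "entry" not in vc:
        raise ValueError("fit lacks an 'entry' variance component")
    sG = vc["entry"]
    if sG <= 0 or "entry" in fit.boundary_terms:
        return 0.0
    tag = fit.model_tag
    if tag in ("Ia", "Ib"):
        denom = sG + vc["residual"] / inputs.r
    elif tag == "II":
        if "plot" not in vc:
            raise ValueError("model II fit lacks the 'plot' (row x col within block) component")
        denom = sG + vc["plot"] / inputs.r + vc["residual"] / (inputs.r * inputs.n)
    elif tag in ("III", "IV"):
        if "entry_block" not in vc:
            raise ValueError(f"model {tag} fit lacks the 'entry_block' component")
        denom = sG + vc["entry_block"] / inputs.r + vc["residual"] / (inputs.r * inputs.n)
    else:
        raise ValueError(f"unknown model tag {fit.model_tag!r}")
    return float(sG / denom)


def bic(fit: FitResult) -> float:
    """BIC = -2 l_R + k log(nu), nu = n_obs - rank(X), k = free variance params."""
    if not fit.converged:
        raise ValueError("BIC requires a converged fit")
    nu = fit.n_obs - fit.rank_X
    return float(-2.0 * fit.restricted_loglik + fit.n_vparams * np.log(nu))


def _prepare_response(table: pd.DataFrame, design: pd.DataFrame, model_tag: str) -> pd.DataFrame:
    """Select/aggregate the response rows for a model tag and join design factors."""
    from .extraction import MOSAIC_SOURCE  # local import to avoid a cycle

    cols = [c for c in ("plot_id", "source_id", "value", "azimuth_deg", "n_pixels") if c in table.columns]
    t = table[cols].copy()
    is_mosaic = t["source_id"] == MOSAIC_SOURCE
    if model_tag == "Ia":
        t = t[is_mosaic]
        if t.empty:
            raise ValueError("model Ia needs MOSAIC observations")
    else:
        t = t[~is_mosaic]
        if t.empty:
            raise ValueError(f"model {model_tag} needs orthorectified observations")
    if model_tag == "Ib":
        t = (
            t.groupby("plot_id", as_index=False)
            .agg(value=("value", "mean"))
            .assign(source_id="PLOT_MEAN")
        )
    merged = t.merge(design, on="plot_id", how="left", validate="many_to_one")
    if merged["entry"].isna().any():
        missing = merged.loc[merged["entry"].isna(), "plot_id"].unique()
        raise ValueError(f"plots absent from the design table: {list(missing)[:5]}")
    merged["entry"] = merged["entry"].astype(str)
    merged["block"] = merged["block"].astype(int)
    # factor codings: rows/columns nested within block; plot and entry x block ids
    merged["row_b"] = merged["block"].astype(str) + ":" + merged["row"].astype(str)
    merged["col_b"] = merged["block"].astype(str) + ":" + merged["col"].astype(str)
    merged["plot"] = (
        merged["block"].astype(str)
        + ":"
        + merged["row"].astype(str)
        + ":"
        + merged["col"].astype(str)
    )
    merged["entry_block"] = merged["entry"] + ":" + merged["block"].astype(str)
    if model_tag in ("III", "IV"):
        merged["image"] = merged["source_id"].astype(str)
    if model_tag == "IV":
        if merged["azimuth_deg"].isna().any():
            raise ValueError("model IV needs the azimuth covariate on every observation")
    return merged


def fit_trait_model(
    table: pd.DataFrame,
    design: pd.DataFrame,
    model_tag: str,
    **reml_kwargs,
) -> tuple[FitResult, float]:
    """Fit one model variant to a trait table and return (fit, H2).

    ``table`` is the long trait table from :func:`extraction.extract_trait_table`
    (or equivalent CSV); ``design`` maps plot_id -> entry, block, row, col.
    ``r`` (number of blocks) and the harmonic-mean subsample count ``n`` are
    computed from the data.
    """
    if model_tag not in MODEL_TAGS:
        raise ValueError(f"model_tag must be one of {MODEL_TAGS}")
    resp = _prepare_response(table, design, model_tag)
    spec = ModelSpec(
        random_terms=_MODEL_RANDOM[model_tag],
        fixed_covariates=("azimuth_deg",) if model_tag == "IV" else (),
        model_tag=model_tag,
    )
    fit = reml_fit(resp, spec, **reml_kwargs)
    r = resp["block"].nunique()
    if model_tag in ("Ia", "Ib"):
        inputs = HeritabilityInputs(r=r)
    else:
        counts = resp.groupby("plot_id")["value"].size()
        inputs = HeritabilityInputs(r=r, n=harmonic_mean(counts))
    return fit, heritability(fit, inputs)


def compare_models(
    table: pd.DataFrame,
    design: pd.DataFrame,
    model_tags=MODEL_TAGS,
    **reml_kwargs,
) -> pd.DataFrame:
    """Fit several model variants to one trait/date and tabulate H2 and BIC.

    BIC is reported only for the models sharing the orthorectified response
    (II, III, IV); comparing it across different responses is meaningless.
    Requires a single trait and date in the table.
    """
    if table["trait"].nunique() > 1 or table["date"].nunique() > 1:
        raise ValueError("compare_models needs a single trait and date")
    tags = list(model_tags)
    if len(tags) < 2:
        raise ValueError("need at least two models to compare")
    rows = []
    for tag in tags:
        fit, h2 = fit_trait_model(table, design, tag, **reml_kwargs)
        rows.append(
            {
                "model": tag,
                "H2": h2,
                "BIC": bic(fit) if tag in ("II", "III", "IV") else np.nan,
                "loglik": fit.restricted_loglik,
                "n_obs": fit.n_obs,
                "boundary_terms": ",".join(fit.boundary_terms),
            }
        )
    report = pd.DataFrame(rows).set_index("model")
    with_bic = report["BIC"].dropna()
    report["best_bic"] = False
    if not with_bic.empty:
        report.loc[with_bic.idxmin(), "best_bic"] = True
    report["best_h2"] = False
    report.loc[report["H2"].idxmax(), "best_h2"] = True
    return report
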