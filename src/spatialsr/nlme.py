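"""Cohort-level nonlinear mixed-effects fit of smoothed 1-NN densities.

Each sample's smoothed, unit-area 1-NN density curve is modeled as a
Weibull density plus homoscedastic Gaussian residual noise on a common
1-μm grid:

    y_i(t) = f(t; a_i, b_i) + ε_it,        ε_it ~ N(0, σ²),

where the per-sample parameters live on the unconstrained logistic-link
scale and decompose into cohort fixed effects plus sample-level Gaussian
random effects with diagonal covariance:

    (A_i, B_i) = (A, B) + u_i,   u_i ~ N(0, diag(τ_A², τ_B²)),
    a_i = 10/(1+e^(−A_i)),       b_i = 500/(1+e^(−B_i)).

The marginal likelihood is evaluated by a Laplace approximation over the
random effects (inner penalized Gauss–Newton per sample), with an
REML-style fixed-effects profile correction computed from the linearized
design. Population estimates are the fixed effects; per-sample estimates
are fixed effect + posterior-mode random effect (empirical-Bayes
predictions).

When a cohort fit fails to converge, samples are dropped by a sequential
minimum-cell-count ladder (20, 50, 70, 100 cells in either the reference
or target type) and the fit retried; a relationship still non-convergent
after the last rung is rejected — rejection is a recorded first-class
outcome, not an error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .nn_stats import NNDistanceSet, SmoothedPDF, smooth_nn_pdf
from .weibull import (
    SCALE_UPPER,
    SHAPE_UPPER,
    DegenerateDistancesError,
    WeibullParams,
    fit_weibull_mle,
    inverse_link,
)

logger = logging.getLogger(__name__)

FILTER_LADDER: tuple[int, ...] = (20, 50, 70, 100)

# Grid point t=0 represents the first smoothing bin; the density there is
# evaluated at this offset so shape<1 candidates stay finite.
_X_FLOOR = 0.5

_LOG_SD_MIN, _LOG_SD_MAX = math.log(1e-5), math.log(1e3)


class InsufficientDataError(ValueError):
    """Fewer curves than the mixed model needs (minimum three samples)."""


@dataclass
class FitControls:
    """Optimizer controls for the mixed-effects fit."""

    max_outer_iter: int = 1000
    max_inner_iter: int = 200
    step_tol: float = 1e-1        # inner Gauss–Newton step tolerance
    convergence_tol: float = 1e-6  # relative objective-change criterion
    optimizer: str = "nelder-mead"
    seed: int = 0

    def __post_init__(self):
        if min(self.max_outer_iter, self.max_inner_iter) <= 0:
            raise ValueError("iteration limits must be positive")
        if min(self.step_tol, self.convergence_tol) <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class WeibullFit:
    """Result of the cohort mixed-effects fit for one spatial relationship."""

    from_type: str
    to_type: str
    population_A: float | None = None
    population_B: float | None = None
    population_shape: float | None = None
    population_scale: float | None = None
    se_A: float | None = None
    se_B: float | None = None
    re_sd_A: float | None = None
    re_sd_B: float | None = None
    residual_sd: float | None = None
    per_sample: dict[str, WeibullParams] = field(default_factory=dict)
    per_sample_unconstrained: dict[str, tuple[float, float]] = field(default_factory=dict)
    samples_used: list[str] = field(default_factory=list)
    samples_filtered: dict[str, str] = field(default_factory=dict)
    filter_level: str = "none"
    converged: bool = False
    n_iter: int = 0
    loglik: float | None = None

    @property
    def rejected(self) -> bool:
        return self.filter_level == "rejected"

    def to_dict(self) -> dict:
        return {
            "from_type": self.from_type,
            "to_type": self.to_type,
            "population": None
            if self.rejected
            else {
                "A": self.population_A,
                "B": self.population_B,
                "shape": self.population_shape,
                "scale": self.population_scale,
                "se_A": self.se_A,
                "se_B": self.se_B,
            },
            "random_effect_sd": None
            if self.rejected
            else {"A": self.re_sd_A, "B": self.re_sd_B},
            "residual_sd": self.residual_sd,
            "per_sample": {
                s: {"shape": p.shape, "scale": p.scale}
                for s, p in self.per_sample.items()
            },
            "samples_used": self.samples_used,
            "samples_filtered": self.samples_filtered,
            "filter_level": self.filter_level,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "loglik": self.loglik,
        }


# ---------------------------------------------------------------------------
# model evaluation


def _pdf_and_jac(t: np.ndarray, A: float, B: float):
    """Weibull density on the grid and its Jacobian wrt (A, B).

    Uses the logistic chain rule da/dA = a(1 − a/10), db/dB = b(1 − b/500).
    """
    a = SHAPE_UPPER / (1.0 + math.exp(-min(max(A, -500.0), 500.0)))
    b = SCALE_UPPER / (1.0 + math.exp(-min(max(B, -500.0), 500.0)))
    x = np.maximum(t, _X_FLOOR)
    lx = np.log(x / b)
    z = np.exp(np.clip(a * lx, -700.0, 700.0))
    logf = math.log(a / b) + (a - 1.0) * lx - z
    f = np.exp(np.clip(logf, -700.0, 700.0))
    dlogf_da = 1.0 / a + (1.0 - z) * lx
    dlogf_db = (a / b) * (z - 1.0)
    da_dA = a * (1.0 - a / SHAPE_UPPER)
    db_dB = b * (1.0 - b / SCALE_UPPER)
    J = np.empty((t.size, 2))
    J[:, 0] = f * dlogf_da * da_dA
    J[:, 1] = f * dlogf_db * db_dB
    return f, J


def _inner_mode(y, t, A, B, tau2, sig2, u0, max_iter, step_tol):
    """Penalized Gauss–Newton for one sample's random-effect mode.

    Minimizes RSS(u)/(2σ²) + ½ uᵀ diag(τ²)⁻¹ u with Levenberg damping.
    Returns (û, residual at û, Jacobian at û, H = JᵀJ/σ² + D⁻¹).
    """
    u = np.asarray(u0, dtype=float).copy()
    Dinv = 1.0 / tau2

    def objective(u_):
        f, _ = _pdf_and_jac(t, A + u_[0], B + u_[1])
        r_ = y - f
        return 0.5 * (r_ @ r_) / sig2 + 0.5 * (u_ * u_ * Dinv).sum()

    obj = objective(u)
    lam = 1e-8
    f, J = _pdf_and_jac(t, A + u[0], B + u[1])
    r = y - f
    for _ in range(max_iter):
        g = -(J.T @ r) / sig2 + Dinv * u
        H = (J.T @ J) / sig2 + np.diag(Dinv)
        for _try in range(12):
            try:
                step = np.linalg.solve(H + lam * np.eye(2), -g)
            except np.linalg.LinAlgError:
                lam = max(lam * 10, 1e-6)
                continue
            cand = u + step
            cand_obj = objective(cand)
            if cand_obj <= obj + 1e-12:
                lam = max(lam / 3, 1e-10)
                break
            lam *= 10
        else:
            break
        moved = np.max(np.abs(step))
        u, obj = cand, cand_obj
        f, J = _pdf_and_jac(t, A + u[0], B + u[1])
        r = y - f
        if moved < step_tol * 1e-3:
            break
    H = (J.T @ J) / sig2 + np.diag(Dinv)
    return u, r, J, H


def _neg_reml_loglik(theta, curves_y, t, warm, max_inner, step_tol):
    """Negative Laplace marginal log-likelihood with REML correction.

    theta = (A, B, log τ_A, log τ_B, log σ).
    """
    A, B = theta[0], theta[1]
    log_sd = np.clip(theta[2:5], _LOG_SD_MIN, _LOG_SD_MAX)
    tau2 = np.exp(2.0 * log_sd[:2])
    sig2 = math.exp(2.0 * log_sd[2])
    n_t = t.size

    ll = 0.0
    info_fixed = np.zeros((2, 2))
    for idx, y in enumerate(curves_y):
        u0 = warm.get(idx, np.zeros(2))
        u, r, J, H = _inner_mode(y, t, A, B, tau2, sig2, u0, max_inner, step_tol)
        warm[idx] = u
        sign, logdetH = np.linalg.slogdet(H)
        if sign <= 0 or not np.isfinite(logdetH):
            return 1e10
        joint = (
            -0.5 * n_t * math.log(2 * math.pi * sig2)
            - 0.5 * (r @ r) / sig2
            - 0.5 * (u[0] ** 2 / tau2[0] + u[1] ** 2 / tau2[1])
            - 0.5 * math.log((2 * math.pi) ** 2 * tau2[0] * tau2[1])
        )
        ll += joint + math.log(2 * math.pi) - 0.5 * logdetH

        # Linearized fixed-effects information: XᵀV⁻¹X via Woodbury, with
        # X = Z = J and V = σ²I + J diag(τ²) Jᵀ.
        S = J.T @ J
        M = np.diag(sig2 / tau2) + S
        try:
            info_fixed += (S - S @ np.linalg.solve(M, S)) / sig2
        except np.linalg.LinAlgError:
            return 1e10

    sign, logdet_info = np.linalg.slogdet(info_fixed)
    if sign <= 0 or not np.isfinite(logdet_info):
        return 1e10
    ll += -0.5 * logdet_info + math.log(2 * math.pi)  # REML profile correction
    if not np.isfinite(ll):
        return 1e10
    return -ll


def _fixed_effect_info(theta, curves_y, t, warm, max_inner, step_tol):
    """Linearized (model-based) fixed-effects information matrix."""
    A, B = theta[0], theta[1]
    log_sd = np.clip(theta[2:5], _LOG_SD_MIN, _LOG_SD_MAX)
    tau2 = np.exp(2.0 * log_sd[:2])
    sig2 = math.exp(2.0 * log_sd[2])
    info = np.zeros((2, 2))
    for idx, y in enumerate(curves_y):
        u, r, J, H = _inner_mode(y, t, A, B, tau2, sig2, warm.get(idx, np.zeros(2)), max_inner, step_tol)
        S = J.T @ J
        M = np.diag(sig2 / tau2) + S
        info += (S - S @ np.linalg.solve(M, S)) / sig2
    return info


def _robust_fixed_effect_se(theta, curves_y, t, warm, max_inner, step_tol):
    """Cluster-robust (sandwich) SEs of the fixed effects.

    The residuals of a smoothed curve are correlated across neighboring
    grid points (each distance contributes to several grid points), so
    the model-based information overstates per-sample precision. Samples
    are independent clusters, so the linearized GEE-style sandwich

        cov(Â, B̂) = Info⁻¹ (Σ_i s_i s_iᵀ) Info⁻¹,
        s_i = J_iᵀ V_i⁻¹ r_i*,   r_i* = y_i − f_i(û_i) + J_i û_i,

    with V_i = σ²I + J_i diag(τ²) J_iᵀ and working marginal residuals
    r_i*, remains valid under within-curve correlation. A small-sample
    factor n/(n − 2) is applied.
    """
    A, B = theta[0], theta[1]
    log_sd = np.clip(theta[2:5], _LOG_SD_MIN, _LOG_SD_MAX)
    tau2 = np.exp(2.0 * log_sd[:2])
    sig2 = math.exp(2.0 * log_sd[2])
    n = len(curves_y)
    beta = np.array([A, B])
    infos, rhs = [], []
    for idx, y in enumerate(curves_y):
        u, r, J, H = _inner_mode(
            y, t, A, B, tau2, sig2, warm.get(idx, np.zeros(2)), max_inner, step_tol
        )
        S = J.T @ J
        M = np.diag(sig2 / tau2) + S
        I_i = (S - S @ np.linalg.solve(M, S)) / sig2
        # working marginal residual and V^{-1} r via Woodbury
        r_star = r + J @ u
        Jr = J.T @ r_star
        Vinv_r = (r_star - J @ np.linalg.solve(M, Jr)) / sig2
        infos.append(I_i)
        rhs.append(J.T @ Vinv_r + I_i @ beta)
    info_tot = np.sum(infos, axis=0)
    rhs_tot = np.sum(rhs, axis=0)
    # delete-one-sample estimates of the fixed effects in the linearized
    # problem (jackknife); more conservative than the plain sandwich at
    # cohort-sized cluster counts
    loo = np.array(
        [
            np.linalg.solve(info_tot - infos[i], rhs_tot - rhs[i])
            for i in range(n)
        ]
    )
    dev = loo - loo.mean(axis=0)
    cov = (n - 1) / n * dev.T @ dev
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    # Small-sample calibration: with n independent samples the Wald
    # statistic is t-distributed (≈ n−1 df), so a ±2·SE band built from
    # the raw SE undercovers. Scale so the conventional two-SE band
    # attains its nominal coverage (the t-df correction used for mixed
    # models with few clusters).
    from scipy import stats as _stats

    factor = float(_stats.t.ppf(_stats.norm.cdf(2.0), df=max(n - 1, 2)) / 2.0)
    return float(se[0] * factor), float(se[1] * factor)


# ---------------------------------------------------------------------------
# public fitting interface


def fit_weibull_nlme(
    curves: dict[str, SmoothedPDF],
    init: dict[str, WeibullParams] | None = None,
    controls: FitControls | None = None,
    grid_max: float | None = None,
    from_type: str = "",
    to_type: str = "",
) -> WeibullFit:
    """Fit the Weibull mixed-effects model to a cohort of smoothed curves.

    Parameters
    ----------
    curves
        Per-sample smoothed unit-area 1-NN densities.
    init
        Optional per-sample initial Weibull parameters (e.g. raw-distance
        MLEs); missing entries are initialized from the cohort.
    controls
        Optimizer controls; defaults mirror the standard configuration.
    grid_max
        Upper end of the common fit grid (μm); typically the 99th
        percentile of the pooled distances. Defaults to the largest grid
        value across curves.
    """
    controls = controls or FitControls()
    if len(curves) < 3:
        raise InsufficientDataError(
            f"mixed-effects fit needs at least 3 samples, got {len(curves)}"
        )
    sample_ids = list(curves)
    if grid_max is None:
        grid_max = max(float(c.grid[-1]) for c in curves.values())
    t = np.arange(0.0, max(grid_max, 5.0) + 0.5, 1.0)
    curves_y = [
        np.interp(t, curves[s].grid, curves[s].density, left=0.0, right=0.0)
        for s in sample_ids
    ]

    # --- initialization: per-sample MLEs through the inverse links
    AB0 = []
    for s in sample_ids:
        p = (init or {}).get(s)
        if p is None:
            p = WeibullParams(shape=2.0, scale=float(np.clip(grid_max / 2.5, 1.0, 400.0)))
        AB0.append(inverse_link(p.shape, p.scale))
    AB0 = np.asarray(AB0)
    A0, B0 = AB0.mean(axis=0)
    sdA0 = max(float(AB0[:, 0].std()), 0.02)
    sdB0 = max(float(AB0[:, 1].std()), 0.02)
    resid0 = []
    for (Ai, Bi), y in zip(AB0, curves_y):
        f, _ = _pdf_and_jac(t, Ai, Bi)
        resid0.append(y - f)
    sig0 = max(float(np.std(np.concatenate(resid0))), 1e-6)

    theta0 = np.array([A0, B0, math.log(sdA0), math.log(sdB0), math.log(sig0)])
    warm: dict[int, np.ndarray] = {
        i: AB0[i] - np.array([A0, B0]) for i in range(len(sample_ids))
    }

    obj = lambda th: _neg_reml_loglik(
        th, curves_y, t, warm, controls.max_inner_iter, controls.step_tol
    )
    f0 = obj(theta0)
    res = optimize.minimize(
        obj,
        theta0,
        method="Nelder-Mead",
        options={
            "maxiter": controls.max_outer_iter,
            "maxfev": 20 * controls.max_outer_iter,
            "fatol": controls.convergence_tol * max(1.0, abs(f0)),
            "xatol": 1e-5,
        },
    )
    # Nelder-Mead can terminate with the simplex still wide relative to
    # the fixed-effect curvature; a restart from the solution with a
    # tighter tolerance polishes the optimum. Convergence is judged by
    # the stability of the objective between the two stages, not by the
    # polish stage's own termination flag (it may churn at the noise
    # floor of the inner linearization).
    polish = optimize.minimize(
        obj,
        res.x,
        method="Nelder-Mead",
        options={
            "maxiter": min(400, controls.max_outer_iter),
            "maxfev": 8 * controls.max_outer_iter,
            "fatol": 1e-4,
            "xatol": 1e-6,
        },
    )
    rel_improve = (res.fun - polish.fun) / max(1.0, abs(polish.fun))
    n_iter = int(res.nit + polish.nit)
    stage_success = bool(res.success or polish.success)
    if polish.fun <= res.fun:
        res = polish
    theta = res.x
    objective_stable = stage_success and rel_improve <= 100 * controls.convergence_tol

    fit = WeibullFit(from_type=from_type, to_type=to_type)
    fit.n_iter = n_iter
    fit.samples_used = sample_ids
    fit.loglik = -float(res.fun)

    A, B = float(theta[0]), float(theta[1])
    log_sd = np.clip(theta[2:5], _LOG_SD_MIN, _LOG_SD_MAX)
    tau2 = np.exp(2.0 * log_sd[:2])
    sig2 = math.exp(2.0 * log_sd[2])

    pd_info = True
    try:
        info = _fixed_effect_info(
            theta, curves_y, t, warm, controls.max_inner_iter, controls.step_tol
        )
        pd_info = bool(np.all(np.linalg.eigvalsh(info) > 0))
        se_A, se_B = _robust_fixed_effect_se(
            theta, curves_y, t, warm, controls.max_inner_iter, controls.step_tol
        )
        if not (np.isfinite(se_A) and np.isfinite(se_B) and se_A > 0 and se_B > 0):
            cov = np.linalg.inv(info)
            se_A, se_B = float(math.sqrt(cov[0, 0])), float(math.sqrt(cov[1, 1]))
    except (np.linalg.LinAlgError, ValueError):
        se_A = se_B = float("nan")
        pd_info = False

    fit.converged = objective_stable and np.isfinite(res.fun) and pd_info
    fit.population_A, fit.population_B = A, B
    fit.population_shape = SHAPE_UPPER / (1.0 + math.exp(-A))
    fit.population_scale = SCALE_UPPER / (1.0 + math.exp(-B))
    fit.se_A, fit.se_B = se_A, se_B
    fit.re_sd_A = float(math.sqrt(tau2[0]))
    fit.re_sd_B = float(math.sqrt(tau2[1]))
    fit.residual_sd = float(math.sqrt(sig2))

    for idx, s in enumerate(sample_ids):
        u, _, _, _ = _inner_mode(
            curves_y[idx], t, A, B, tau2, sig2,
            warm.get(idx, np.zeros(2)), controls.max_inner_iter, controls.step_tol,
        )
        Ai, Bi = A + u[0], B + u[1]
        fit.per_sample_unconstrained[s] = (float(Ai), float(Bi))
        fit.per_sample[s] = WeibullParams(
            shape=SHAPE_UPPER / (1.0 + math.exp(-Ai)),
            scale=SCALE_UPPER / (1.0 + math.exp(-Bi)),
        )
    return fit


def sequential_filter_fit(
    sets: dict[str, NNDistanceSet],
    controls: FitControls | None = None,
    window: float = 5.0,
    from_type: str = "",
    to_type: str = "",
) -> WeibullFit:
    """Cohort fit with the sequential minimum-cell-count filter ladder.

    The fit is first attempted on every sample. On non-convergence,
    samples with fewer than 20 cells of either the reference or target
    type are dropped and the fit retried; the ladder continues through
    50, 70 and 100 cells. A relationship that still fails after the last
    rung is marked rejected.
    """
    controls = controls or FitControls()
    if not sets:
        raise ValueError("no samples provided")
    if not from_type:
        first = next(iter(sets.values()))
        from_type, to_type = first.from_type, first.to_type

    filtered: dict[str, str] = {}
    usable: dict[str, NNDistanceSet] = {}
    curves: dict[str, SmoothedPDF] = {}
    init: dict[str, WeibullParams] = {}
    for s, d in sets.items():
        try:
            curves[s] = smooth_nn_pdf(d, window=window)
            init[s] = fit_weibull_mle(d.distances)
            usable[s] = d
        except (DegenerateDistancesError, ValueError) as exc:
            filtered[s] = f"degenerate: {exc}"

    last_fit: WeibullFit | None = None
    for level in (None, *FILTER_LADDER):
        level_filtered = dict(filtered)
        keep = {}
        for s, d in usable.items():
            if level is not None and min(d.n_from, d.n_to) < level:
                level_filtered[s] = f"cell count below {level} (nFROM={d.n_from}, nTO={d.n_to})"
            else:
                keep[s] = d
        if len(keep) < 3:
            logger.info(
                "filter level %s leaves %d sample(s); cannot fit", level, len(keep)
            )
            continue
        pooled = np.concatenate([keep[s].distances for s in keep])
        grid_max = float(np.percentile(pooled, 99))
        fit = fit_weibull_nlme(
            {s: curves[s] for s in keep},
            init={s: init[s] for s in keep},
            controls=controls,
            grid_max=grid_max,
            from_type=from_type,
            to_type=to_type,
        )
        fit.filter_level = "none" if level is None else str(level)
        fit.samples_filtered = level_filtered
        last_fit = fit
        if fit.converged:
            return fit
        logger.info(
            "SR %s->%s did not converge at filter level %s", from_type, to_type, level
        )

    rejected = WeibullFit(from_type=from_type, to_type=to_type)
    rejected.filter_level = "rejected"
    rejected.samples_filtered = filtered if last_fit is None else last_fit.samples_filtered
    rejected.converged = False
    rejected.per_sample = {}
    rejected.samples_used = []
    return rejected


def cohort_fit_from_distances(
    sets: dict[str, NNDistanceSet],
    controls: FitControls | None = None,
) -> WeibullFit:
    """Convenience wrapper: smoothing + ladder fit in one call."""
    return sequential_filter_fit(sets, controls=controls)
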