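"""Nonlinear mixed-effects estimation for the population PK model.

The marginal likelihood is approximated in the FOCE/Laplace family: for
each subject the joint -2 log density of the data and the random effects,

    h_i(eta) = sum_j [ log(2 pi s2_ij) + (y_ij - f_ij(eta))^2 / s2_ij ]
             + eta' Om^{-1} eta + log det(2 pi Om),

with the proportional-error variance s2 = (b f)^2 + floor evaluated at
the individual prediction (the "interaction" part), is minimised over
eta (the subject's MAP / empirical Bayes estimate), and the marginal
contribution is the Laplace approximation

    -2 log L_i ~= h_i(eta_hat) - d log(2 pi) + log det H_i,

where H_i is the Hessian of h_i/2 at the mode and d = 4.  The objective
function value (OFV) is the sum over subjects; its constant convention
(2 pi terms included) is declared here — differences of OFVs, which drive
all model-building decisions, are unaffected by it.

The outer problem maximises the approximate marginal likelihood over the
typical values (log scale, guaranteeing positivity), the log-scale IIV
SDs, the proportional error SD and any covariate coefficients.

All gradients and Hessians are finite differences evaluated through the
batched closed-form concentration kernel, which keeps the inner
optimisation loops inside numpy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .dataset import StudyDataset, SubjectData
from .pk import PKParameters, _conc_matrix
from .population import (
    CovariateEffect,
    PARAM_NAMES,
    PopulationModel,
    scaled_param_array,
)

__all__ = [
    "EstimationConfig",
    "EstimationResult",
    "BootstrapSummary",
    "OutlierReport",
    "CovariateStepResult",
    "marginal_ofv",
    "evaluate",
    "fit",
    "fit_multistart",
    "cwres",
    "exclude_outliers",
    "covariate_step",
    "bootstrap",
    "eta_shrinkage",
    "heuristic_initial_model",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


class ConvergenceError(RuntimeError):
    """Raised when a likelihood evaluation is irrecoverably non-finite."""


@dataclass(frozen=True)
class EstimationConfig:
    """Model-building thresholds and optimiser settings.

    ``ofv_add_threshold`` / ``ofv_remove_threshold`` are the chi-square(1)
    cut-offs used in forward inclusion (p < 0.05) and backward elimination
    (p < 0.01) of covariates; ``cwres_outlier_cut`` flags observations with
    |CWRES| above it as outliers.
    """

    ofv_add_threshold: float = 3.84
    ofv_remove_threshold: float = 6.64
    cwres_outlier_cut: float = 3.0
    inner_gtol: float = 1e-4
    outer_ftol: float = 1e-9
    outer_maxiter: int = 400
    outer_restarts: int = 4
    outer_restart_tol: float = 0.1
    bootstrap_n: int = 1000
    bootstrap_ci: tuple[float, float] = (5.0, 95.0)
    var_floor: float = 1e-6
    compute_rse: bool = True

    def __post_init__(self) -> None:
        if min(self.ofv_add_threshold, self.ofv_remove_threshold,
               self.cwres_outlier_cut) <= 0:
            raise ValueError("thresholds must be > 0")


# ---------------------------------------------------------------------------
# per-subject joint density and inner (MAP) optimisation


def _subject_geometry(subj: SubjectData):
    """Cached dose/observation time geometry for the fast likelihood kernel.

    For each (dose, observation) pair: the post-infusion elapsed time u and
    u + w where w is the within-infusion exposure time, plus the matching
    infusion rate — everything in the closed form that does not depend on
    the parameters.
    """
    geom = getattr(subj, "_geom", None)
    if geom is None:
        tau = subj.obs_times[None, :] - subj.dose_times[:, None]
        w = np.clip(tau, 0.0, subj.dose_durations[:, None])
        u = np.maximum(tau - subj.dose_durations[:, None], 0.0)
        geom = (
            u.ravel(),
            (u + w).ravel(),
            np.repeat(subj.dose_rates, subj.obs_times.size),
            subj.dose_times.size,
        )
        object.__setattr__(subj, "_geom", geom)
    return geom


def _conc_fast(subj: SubjectData, pm: np.ndarray) -> np.ndarray:
    """Batched concentration at the subject's observation times, (m,4)->(m,n).

    Same closed form as :func:`dalbapk.pk._conc_matrix` with the dose loop
    flattened through precomputed geometry; degenerate parameter rows
    propagate as NaN.
    """
    u, uw, rates, n_dose = _subject_geometry(subj)
    from .pk import _hybrid_constants

    cl, v1, q, v2 = pm[:, 0], pm[:, 1], pm[:, 2], pm[:, 3]
    _, _, k21, alpha, beta = _hybrid_constants(cl, v1, q, v2, True)
    denom = alpha - beta
    coef_a = ((alpha - k21) / denom / alpha / v1)[:, None]
    coef_b = ((k21 - beta) / denom / beta / v1)[:, None]
    ea = np.exp(-alpha[:, None] * u[None, :]) - np.exp(-alpha[:, None] * uw[None, :])
    eb = np.exp(-beta[:, None] * u[None, :]) - np.exp(-beta[:, None] * uw[None, :])
    terms = rates[None, :] * (coef_a * ea + coef_b * eb)
    n_obs = subj.obs_times.size
    return terms.reshape(pm.shape[0], n_dose, n_obs).sum(axis=1)


def _h_batch(
    subj: SubjectData,
    base_params: np.ndarray,
    etas: np.ndarray,
    omegas: np.ndarray,
    b: float,
    var_floor: float,
) -> np.ndarray:
    """h_i(eta) for a batch of eta vectors, shape (m, 4) -> (m,)."""
    with np.errstate(all="ignore"):
        pm = base_params[None, :] * np.exp(etas)
        conc = _conc_fast(subj, pm)
        s2 = (b * conc) ** 2 + var_floor
        resid = subj.obs_dv[None, :] - conc
        data_term = np.sum(np.log(s2) + resid * resid / s2, axis=1)
        prior = np.sum(etas * etas / (omegas * omegas)[None, :], axis=1)
        const = subj.n_obs * _LOG_2PI + 4.0 * _LOG_2PI + 2.0 * np.sum(np.log(omegas))
        h = data_term + prior + const
    # degenerate kinetics (alpha ~= beta) propagate as NaN: replace with a
    # large finite penalty so optimisers back away rather than crash
    return np.where(np.isfinite(h), h, 1e10)


_GRAD_STEP = 1e-4
_HESS_STEP = 1e-3


def _h_grad(subj, base, etas0, omegas, b, var_floor) -> np.ndarray:
    """Central-difference gradient of h at eta0 via one batched call."""
    shifts = np.vstack([np.eye(4) * _GRAD_STEP, -np.eye(4) * _GRAD_STEP])
    vals = _h_batch(subj, base, etas0[None, :] + shifts, omegas, b, var_floor)
    return (vals[:4] - vals[4:]) / (2.0 * _GRAD_STEP)


def _h_hessian(subj, base, eta0, omegas, b, var_floor) -> np.ndarray:
    """Central-difference Hessian of h at the mode via one batched call."""
    h = _HESS_STEP
    pts = [eta0]
    for i in range(4):
        e = np.zeros(4)
        e[i] = h
        pts += [eta0 + e, eta0 - e]
    pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
    for i, j in pairs:
        pts += [
            eta0 + _unit(i, h) + _unit(j, h),
            eta0 + _unit(i, h) - _unit(j, h),
            eta0 - _unit(i, h) + _unit(j, h),
            eta0 - _unit(i, h) - _unit(j, h),
        ]
    vals = _h_batch(subj, base, np.vstack(pts), omegas, b, var_floor)
    f0 = vals[0]
    H = np.empty((4, 4))
    for i in range(4):
        fp, fm = vals[1 + 2 * i], vals[2 + 2 * i]
        H[i, i] = (fp - 2.0 * f0 + fm) / (h * h)
    off = 9
    for k, (i, j) in enumerate(pairs):
        fpp, fpm, fmp, fmm = vals[off + 4 * k : off + 4 * k + 4]
        H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h * h)
    return H


def _unit(i: int, h: float) -> np.ndarray:
    e = np.zeros(4)
    e[i] = h
    return e


def _build_fd_shifts(h: float) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Stencil for simultaneous FD gradient and Hessian in one batch.

    Rows 2i / 2i+1 are +-h along axis i; the remaining rows are the four
    corners for each off-diagonal pair.
    """
    rows = []
    for i in range(4):
        rows += [_unit(i, h), _unit(i, -h)]
    pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
    for i, j in pairs:
        rows += [
            _unit(i, h) + _unit(j, h),
            _unit(i, h) + _unit(j, -h),
            _unit(i, -h) + _unit(j, h),
            _unit(i, -h) + _unit(j, -h),
        ]
    return np.vstack(rows), pairs


_FD_SHIFTS, _FD_PAIRS = None, None


def _grad_hess(batch, eta: np.ndarray, f0: float, h: float = _HESS_STEP):
    """FD gradient and Hessian of h at eta from a single 32-row batch."""
    global _FD_SHIFTS, _FD_PAIRS
    if _FD_SHIFTS is None:
        _FD_SHIFTS, _FD_PAIRS = _build_fd_shifts(h)
    vals = batch(eta[None, :] + _FD_SHIFTS)
    g = np.empty(4)
    H = np.empty((4, 4))
    for i in range(4):
        fp, fm = vals[2 * i], vals[2 * i + 1]
        g[i] = (fp - fm) / (2.0 * h)
        H[i, i] = (fp - 2.0 * f0 + fm) / (h * h)
    off = 8
    for k, (i, j) in enumerate(_FD_PAIRS):
        fpp, fpm, fmp, fmm = vals[off + 4 * k : off + 4 * k + 4]
        H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h * h)
    return g, H


_LS_STEPS = 2.0 ** -np.arange(8)  # 1, 1/2, ..., 1/128


def _newton_map(batch, eta0: np.ndarray, f0: float, gtol: float,
                maxiter: int = 20):
    """Damped Newton minimisation of the joint density h over eta.

    Gradient and Hessian come from one batched stencil per iteration and
    the backtracking line search evaluates all candidate steps in a single
    batch.  Returns (eta, h, grad, hess, converged); a stall with a small
    gradient counts as converged (the Laplace value is second-order
    insensitive to the residual mode error).
    """
    eta = np.asarray(eta0, dtype=float).copy()
    f = f0
    g = np.zeros(4)
    H = np.eye(4)
    for it in range(maxiter):
        g, H = _grad_hess(batch, eta, f)
        gmax = np.max(np.abs(g))
        if gmax < gtol:
            return eta, f, g, H, True
        w, V = np.linalg.eigh(H)
        step = -V @ ((V.T @ g) / np.maximum(w, 1e-6))
        trials = eta[None, :] + _LS_STEPS[:, None] * step[None, :]
        fv = batch(trials)
        armijo = fv < f + 1e-4 * _LS_STEPS * float(g @ step)
        if armijo.any():
            k = int(np.argmax(armijo))  # largest step satisfying descent
            eta, f = trials[k], float(fv[k])
        else:
            return eta, f, g, H, gmax < 1e-2
    return eta, f, g, H, np.max(np.abs(g)) < 10.0 * gtol


def _subject_neg2ll(
    subj: SubjectData,
    base: np.ndarray,
    omegas: np.ndarray,
    b: float,
    var_floor: float,
    eta0: np.ndarray,
    gtol: float,
) -> tuple[float, np.ndarray]:
    """Laplace -2 log marginal likelihood contribution and the MAP eta."""
    batch = lambda E: _h_batch(subj, base, E, omegas, b, var_floor)
    zero = np.zeros(4)
    f0, f_zero = batch(np.vstack([eta0, zero]))
    eta_hat, h_min, g, H, ok = _newton_map(batch, eta0, float(f0), gtol)
    if not ok:
        fun = lambda eta: float(batch(eta[None, :])[0])
        jac = lambda eta: _h_grad(subj, base, eta, omegas, b, var_floor)
        res = optimize.minimize(fun, eta_hat, jac=jac, method="BFGS",
                                options={"gtol": gtol, "maxiter": 200})
        if res.fun < h_min:
            eta_hat, h_min = res.x, float(res.fun)
        _, H = _grad_hess(batch, eta_hat, h_min)
    # h can be multimodal in eta; a warm start inherited from a different
    # outer iterate may track the wrong mode.  If even the prior mean beats
    # the warm-started optimum, redo the search from zero.
    if np.any(eta0 != 0.0) and f_zero < h_min:
        eta2, h2, g2, H2, _ = _newton_map(batch, zero, float(f_zero), gtol)
        if h2 < h_min:
            eta_hat, h_min, H = eta2, h2, H2
    if not np.isfinite(h_min):
        raise ConvergenceError(
            f"non-finite joint density for subject {subj.id!r}"
        )
    # Laplace correction from the mode Hessian of h/2; clip tiny/negative
    # curvature for safety
    eigvals = np.linalg.eigvalsh(0.5 * H)
    logdet = float(np.sum(np.log(np.clip(eigvals, 1e-10, None))))
    return h_min - 4.0 * _LOG_2PI + logdet, eta_hat


def _subject_base_params(subj: SubjectData, model: PopulationModel) -> np.ndarray:
    return scaled_param_array(model, subj.weight, subj.covariates or None)


def marginal_ofv(
    dataset: StudyDataset,
    model: PopulationModel,
    config: EstimationConfig | None = None,
    eta_init: dict | None = None,
    return_etas: bool = False,
):
    """Approximate -2 log marginal likelihood (OFV) of the dataset.

    Per subject, the random effects are optimised to their MAP value and the
    contribution is the Laplace approximation around it; the total OFV is the
    sum over subjects.  Deterministic given the inputs.  ``eta_init`` may
    carry warm-start etas keyed by subject id.
    """
    config = config or EstimationConfig()
    omegas = np.maximum(model.omegas, 1e-8)
    total = 0.0
    etas: dict = {}
    for subj in dataset.subjects:
        base = _subject_base_params(subj, model)
        eta0 = np.asarray(
            (eta_init or {}).get(subj.id, np.zeros(4)), dtype=float
        )
        contrib, eta_hat = _subject_neg2ll(
            subj, base, omegas, model.resid_b, config.var_floor, eta0,
            config.inner_gtol,
        )
        total += contrib
        etas[subj.id] = eta_hat
    if return_etas:
        return total, etas
    return total


# ---------------------------------------------------------------------------
# outer optimisation


def _cv_from_omega(omega: np.ndarray, convention: str) -> tuple[float, ...]:
    if convention == "lognormal":
        om = np.minimum(np.asarray(omega, dtype=float), 10.0)
        return tuple(np.sqrt(np.expm1(om * om)))
    return tuple(omega)


def _pack(model: PopulationModel) -> np.ndarray:
    x = np.concatenate(
        [
            np.log(model.theta.as_array()),
            np.log(np.maximum(model.omegas, 1e-8)),
            [np.log(max(model.resid_b, 1e-8))],
            [eff.coef for eff in model.covariate_effects],
        ]
    )
    return x


def _unpack(x: np.ndarray, template: PopulationModel) -> PopulationModel:
    with np.errstate(over="ignore"):
        theta = PKParameters(*np.exp(x[:4]))
        omegas = np.exp(x[4:8])
        b = float(np.exp(x[8]))
    effects = tuple(
        replace(eff, coef=float(c))
        for eff, c in zip(template.covariate_effects, x[9:])
    )
    return replace(
        template,
        theta=theta,
        omega_cv=_cv_from_omega(omegas, template.cv_convention),
        resid_b=b,
        covariate_effects=effects,
    )


@dataclass
class EstimationResult:
    """Outcome of a mixed-effects fit.

    ``residuals`` is the per-observation table (ID, TIME, DV, PRED, IPRED,
    CWRES, row position); ``ebes`` the per-subject MAP etas; ``shrinkage``
    the per-parameter eta shrinkage in percent; ``rse`` approximate relative
    standard errors (%) of the estimated parameters, from the
    finite-difference Hessian of the OFV.
    """

    model: PopulationModel
    ofv: float
    converged: bool
    message: str
    n_evaluations: int
    ebes: pd.DataFrame
    residuals: pd.DataFrame
    shrinkage: np.ndarray
    rse: dict | None = None

    @property
    def theta(self) -> PKParameters:
        return self.model.theta

    @property
    def omega_cv(self) -> tuple[float, ...]:
        return tuple(self.model.omega_cv)

    @property
    def resid_b(self) -> float:
        return self.model.resid_b


def heuristic_initial_model(
    dataset: StudyDataset, template: PopulationModel | None = None
) -> PopulationModel:
    """Label-free initial values from naive pooled summaries.

    Central volume from dose over mean peak concentration, clearance from
    the pooled terminal log-slope of trough-like samples, peripheral volume
    set equal to the central estimate, and moderate starting variabilities.
    """
    peaks, slopes = [], []
    for subj in dataset.subjects:
        dose = subj.dose_rates[0] * subj.dose_durations[0]
        cmax = np.nanmax(subj.obs_dv) if subj.obs_dv.size else np.nan
        if np.isfinite(cmax) and cmax > 0:
            peaks.append(dose / cmax)
        pos = subj.obs_dv > 0
        if pos.sum() >= 2:
            t, y = subj.obs_times[pos], np.log(subj.obs_dv[pos])
            k = -np.polyfit(t, y, 1)[0]
            if 1e-5 < k < 1.0:
                slopes.append(k)
    v1 = float(np.median(peaks)) if peaks else 5.0
    v2 = 1.5 * v1
    beta = float(np.median(slopes)) if slopes else 1e-3
    cl = max(beta * (v1 + v2) * 0.5, 1e-4)
    theta = PKParameters(cl=cl, v1=v1, q=cl, v2=v2)
    template = template or PopulationModel(theta=theta)
    return replace(
        template, theta=theta, omega_cv=(0.3, 0.3, 0.3, 0.3), resid_b=0.2
    )


def evaluate(
    dataset: StudyDataset,
    model: PopulationModel,
    config: EstimationConfig | None = None,
) -> EstimationResult:
    """Evaluate a fixed model on a dataset without optimising it.

    Produces the OFV, empirical Bayes etas, residual table and shrinkage at
    the given parameter values — the building block for diagnostics against
    a known (e.g. generating) model.
    """
    config = config or EstimationConfig()
    ofv, ebes = marginal_ofv(dataset, model, config, return_etas=True)
    ebe_df = pd.DataFrame(
        {"ID": list(ebes.keys())}
        | {f"eta_{p}": [ebes[i][k] for i in ebes] for k, p in enumerate(PARAM_NAMES)}
    )
    residuals = _residual_table(dataset, model, ebes, config)
    shr = eta_shrinkage_from_ebes(
        np.array([ebes[i] for i in ebes]), model.omegas
    )
    return EstimationResult(
        model=model, ofv=float(ofv), converged=True,
        message="evaluation at fixed parameters", n_evaluations=1,
        ebes=ebe_df, residuals=residuals, shrinkage=shr,
    )


def fit(
    dataset: StudyDataset,
    initial: PopulationModel | None = None,
    config: EstimationConfig | None = None,
) -> EstimationResult:
    """Maximum approximate-marginal-likelihood fit of the population model.

    Optimises typical values, IIV SDs and the proportional error SD (all on
    the log scale) plus any covariate coefficients carried by ``initial``.
    Non-convergence is reported on the result, not raised: the last iterate
    is returned flagged.
    """
    config = config or EstimationConfig()
    template = initial if initial is not None else heuristic_initial_model(dataset)
    warm: dict = {}
    n_eval = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval, warm
        n_eval += 1
        try:
            model = _unpack(x, template)
            ofv, etas = marginal_ofv(
                dataset, model, config, eta_init=warm, return_etas=True
            )
        except (ValueError, ArithmeticError, ConvergenceError,
                np.linalg.LinAlgError):
            # overflowing / degenerate parameter excursions are penalised so
            # the line search backs into the feasible region
            return 1e12
        if not np.isfinite(ofv):
            return 1e12
        warm = etas
        return ofv

    # quasi-newton outer runs terminate early now and then on the mildly
    # noisy finite-difference surface; restarting from the incumbent until
    # the OFV stops improving makes convergence reliable
    x0 = _pack(template)
    res = None
    for _ in range(config.outer_restarts):
        prev = res.fun if res is not None else np.inf
        res = optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            jac="2-point",
            options={
                "ftol": config.outer_ftol,
                "gtol": 1e-4,
                "maxiter": config.outer_maxiter,
                "finite_diff_rel_step": 1e-4,
            },
        )
        x0 = res.x
        if prev - res.fun < config.outer_restart_tol:
            break
    final_model = _unpack(res.x, template)
    ofv, ebes = marginal_ofv(
        dataset, final_model, config, eta_init=warm, return_etas=True
    )
    ebe_df = pd.DataFrame(
        {"ID": list(ebes.keys())}
        | {f"eta_{p}": [ebes[i][k] for i in ebes] for k, p in enumerate(PARAM_NAMES)}
    )
    residuals = _residual_table(dataset, final_model, ebes, config)
    shr = eta_shrinkage_from_ebes(
        np.array([ebes[i] for i in ebes]), final_model.omegas
    )
    rse = None
    if config.compute_rse:
        rse = _rse_table(dataset, final_model, config, res.x, template, warm)
    return EstimationResult(
        model=final_model,
        ofv=float(ofv),
        converged=bool(res.success),
        message=str(res.message),
        n_evaluations=n_eval,
        ebes=ebe_df,
        residuals=residuals,
        shrinkage=shr,
        rse=rse,
    )


#: Multiplicative perturbations of (cl, v1, q, v2) used by the multi-start
#: fit.  The inter-compartmental axes (q, v2) are the weakly identified ones
#: in sparse designs, so the starts fan out along them.
DEFAULT_STARTS = (
    (1.0, 1.0, 1.0, 1.0),
    (1.0, 1.0, 0.25, 0.5),
    (1.0, 1.0, 4.0, 2.0),
)


def fit_multistart(
    dataset: StudyDataset,
    initial: PopulationModel | None = None,
    config: EstimationConfig | None = None,
    starts: Sequence[tuple[float, float, float, float]] = DEFAULT_STARTS,
) -> EstimationResult:
    """Run :func:`fit` from several perturbed initial values, keep the best.

    The approximate-likelihood surface can hold local optima along the
    peripheral-compartment axes; fanning the starting point across them and
    keeping the lowest OFV is the standard guard.
    """
    config = config or EstimationConfig()
    template = initial if initial is not None else heuristic_initial_model(dataset)
    best: EstimationResult | None = None
    search_cfg = replace(config, compute_rse=False)
    for k, mult in enumerate(starts):
        start_model = replace(
            template,
            theta=PKParameters(*(template.theta.as_array() * np.asarray(mult))),
        )
        res = fit(dataset, initial=start_model, config=search_cfg)
        if best is None or (np.isfinite(res.ofv) and res.ofv < best.ofv):
            best = res
    if config.compute_rse and best is not None:
        # recompute at the winning optimum with standard errors
        best = fit(dataset, initial=best.model, config=config)
    return best


def _rse_table(dataset, model, config, x_opt, template, warm) -> dict:
    """Approximate RSE% from the finite-difference Hessian of the OFV.

    On the log scale the standard error of log(p) approximates the relative
    standard error of p; covariance is 2 H^{-1} for a -2 log-likelihood.
    """

    def f(x):
        m = _unpack(x, template)
        try:
            return marginal_ofv(dataset, m, config, eta_init=warm)
        except (ConvergenceError, FloatingPointError):
            return np.nan

    H = _fd_hessian(f, x_opt, step=1e-3)
    names = (
        [f"theta_{p}" for p in PARAM_NAMES]
        + [f"omega_{p}" for p in PARAM_NAMES]
        + ["b"]
        + [f"{e.parameter}~{e.covariate}" for e in model.covariate_effects]
    )
    try:
        cov = 2.0 * np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(names), np.nan)
    return {name: 100.0 * s for name, s in zip(names, se)}


def _fd_hessian(f, x0: np.ndarray, step: float = 1e-3) -> np.ndarray:
    """Dense central-difference Hessian of a scalar function."""
    n = x0.size
    H = np.empty((n, n))
    f0 = f(x0)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = step
        fp, fm = f(x0 + ei), f(x0 - ei)
        H[i, i] = (fp - 2.0 * f0 + fm) / step**2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = step
            fpp = f(x0 + ei + ej)
            fpm = f(x0 + ei - ej)
            fmp = f(x0 - ei + ej)
            fmm = f(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * step**2)
    return H


# ---------------------------------------------------------------------------
# residual diagnostics


def _subject_pred(subj, base, eta):
    return _conc_matrix(
        (base * np.exp(eta))[None, :],
        subj.dose_times, subj.dose_rates, subj.dose_durations, subj.obs_times,
    )[0]


def _subject_jacobian(subj, base, eta) -> np.ndarray:
    """d f / d eta at eta, shape (n_obs, 4), by central differences."""
    shifts = np.vstack([np.eye(4) * _GRAD_STEP, -np.eye(4) * _GRAD_STEP])
    pm = base[None, :] * np.exp(eta[None, :] + shifts)
    conc = _conc_matrix(
        pm, subj.dose_times, subj.dose_rates, subj.dose_durations, subj.obs_times
    )
    return ((conc[:4] - conc[4:]) / (2.0 * _GRAD_STEP)).T


def _residual_table(
    dataset: StudyDataset,
    model: PopulationModel,
    ebes: dict,
    config: EstimationConfig,
) -> pd.DataFrame:
    omegas = np.maximum(model.omegas, 1e-8)
    Om = np.diag(omegas**2)
    obs_rows = dataset.observation_index()
    rows = []
    for subj in dataset.subjects:
        base = _subject_base_params(subj, model)
        eta = np.asarray(ebes[subj.id], dtype=float)
        ipred = _subject_pred(subj, base, eta)
        pred = _subject_pred(subj, base, np.zeros(4))
        G = _subject_jacobian(subj, base, eta)
        mean = ipred - G @ eta
        cov = G @ Om @ G.T + np.diag((model.resid_b * ipred) ** 2 + config.var_floor)
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular linearised covariance for subject {subj.id!r}"
            ) from exc
        cw = np.linalg.solve(L, subj.obs_dv - mean)
        first_dose = subj.dose_times.min()
        sub_obs = obs_rows[obs_rows["ID"] == subj.id]
        for k in range(subj.n_obs):
            rows.append(
                {
                    "ID": subj.id,
                    "TIME": subj.obs_times[k],
                    "TAD": subj.obs_times[k]
                    - subj.dose_times[subj.dose_times <= subj.obs_times[k]].max(),
                    "DV": subj.obs_dv[k],
                    "PRED": pred[k],
                    "IPRED": ipred[k],
                    "CWRES": cw[k],
                    "row": int(sub_obs.index[k]),
                }
            )
    return pd.DataFrame(rows)


def cwres(
    dataset: StudyDataset, result: EstimationResult
) -> pd.DataFrame:
    """Conditional weighted residuals of a converged fit.

    FOCE-linearised residuals: observation minus the linearised marginal
    mean, decorrelated by the Cholesky factor of the linearised marginal
    covariance (random-effect part plus residual variance at the individual
    prediction).  Approximately standard normal under a correct model.
    """
    return result.residuals[["ID", "TIME", "DV", "CWRES", "row"]].copy()


def eta_shrinkage_from_ebes(ebes: np.ndarray, omegas: np.ndarray) -> np.ndarray:
    """Per-parameter eta shrinkage % = 100 (1 - SD(EBE)/omega)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = ebes.std(axis=0, ddof=1) if ebes.shape[0] > 1 else np.zeros(4)
        shr = 100.0 * (1.0 - sd / omegas)
    shr[omegas <= 0] = np.nan
    return shr


def eta_shrinkage(result: EstimationResult) -> dict[str, float]:
    """Eta shrinkage (%) per structural parameter for a fit result."""
    return {p: float(s) for p, s in zip(PARAM_NAMES, result.shrinkage)}


# ---------------------------------------------------------------------------
# outlier screening, covariate step, bootstrap


@dataclass
class OutlierReport:
    """Outcome of CWRES-based outlier exclusion and sensitivity refit."""

    removed: pd.DataFrame
    reduced_dataset: StudyDataset
    refit: EstimationResult | None
    delta_ofv: float
    n_removed: int


def exclude_outliers(
    dataset: StudyDataset,
    result: EstimationResult,
    config: EstimationConfig | None = None,
    refit: bool = True,
) -> OutlierReport:
    """Remove observations with |CWRES| above the cut and refit.

    ``delta_ofv`` is the refit OFV on the reduced data minus the original
    OFV — the sensitivity-analysis comparison; large negative values mean
    the flagged points were strongly inconsistent with the model.
    """
    config = config or EstimationConfig()
    flagged = result.residuals[
        result.residuals["CWRES"].abs() > config.cwres_outlier_cut
    ]
    if flagged.empty:
        return OutlierReport(
            removed=flagged, reduced_dataset=dataset, refit=None,
            delta_ofv=0.0, n_removed=0,
        )
    reduced = dataset.drop_rows(flagged["row"].tolist())
    refit_result = None
    delta = np.nan
    if refit:
        refit_result = fit(
            reduced, initial=result.model,
            config=replace(config, compute_rse=False),
        )
        delta = refit_result.ofv - result.ofv
    return OutlierReport(
        removed=flagged,
        reduced_dataset=reduced,
        refit=refit_result,
        delta_ofv=float(delta),
        n_removed=len(flagged),
    )


@dataclass
class CovariateStepResult:
    """Stepwise covariate search outcome with the per-candidate ΔOFV trail."""

    selected_model: PopulationModel
    selected_result: EstimationResult
    table: pd.DataFrame


def _candidate_effect(
    dataset: StudyDataset, parameter: str, covariate: str, form: str
) -> CovariateEffect | None:
    values = np.array(
        [s.covariates.get(covariate, np.nan) for s in dataset.subjects]
    )
    if np.isnan(values).any():
        raise ValueError(f"covariate {covariate!r} missing for some subjects")
    if np.ptp(values) == 0:
        warnings.warn(
            f"covariate {covariate!r} is constant; candidate excluded",
            stacklevel=2,
        )
        return None
    return CovariateEffect(
        parameter=parameter, covariate=covariate, form=form,
        center=float(np.median(values)), coef=0.0,
    )


def covariate_step(
    dataset: StudyDataset,
    base_model: PopulationModel,
    candidates: Sequence[tuple[str, str, str]],
    config: EstimationConfig | None = None,
    base_result: EstimationResult | None = None,
) -> CovariateStepResult:
    """Forward-inclusion / backward-elimination covariate search.

    Each candidate is (parameter, covariate, form) adding exactly one
    coefficient, centred on the dataset median, so the chi-square(1)
    thresholds 3.84 (inclusion) and 6.64 (retention) apply directly.
    """
    config = config or EstimationConfig()
    fit_cfg = replace(config, compute_rse=False)
    effects = [
        e
        for e in (
            _candidate_effect(dataset, p, c, f) for p, c, f in candidates
        )
        if e is not None
    ]
    current = base_result or fit(dataset, initial=base_model, config=fit_cfg)
    current_model = current.model
    included: list[CovariateEffect] = list(current_model.covariate_effects)
    rows = []
    remaining = list(effects)
    step = 0
    while remaining:
        step += 1
        trials = []
        for eff in remaining:
            trial_model = replace(
                current_model, covariate_effects=tuple(included + [eff])
            )
            trial = fit(dataset, initial=trial_model, config=fit_cfg)
            delta = current.ofv - trial.ofv
            rows.append(
                {
                    "step": f"forward-{step}",
                    "parameter": eff.parameter,
                    "covariate": eff.covariate,
                    "form": eff.form,
                    "delta_ofv": float(delta),
                    "included": False,
                }
            )
            trials.append((delta, eff, trial))
        best_delta, best_eff, best_fit = max(trials, key=lambda t: t[0])
        if best_delta > config.ofv_add_threshold:
            rows[-len(trials) + [t[1] for t in trials].index(best_eff)][
                "included"
            ] = True
            included.append(best_eff)
            current, current_model = best_fit, best_fit.model
            remaining = [e for e in remaining if e is not best_eff]
        else:
            break
    # backward elimination
    changed = True
    while changed and included:
        changed = False
        for eff in list(included):
            rest = [e for e in included if e is not eff]
            trial_model = replace(current_model, covariate_effects=tuple(rest))
            trial = fit(dataset, initial=trial_model, config=fit_cfg)
            increase = trial.ofv - current.ofv
            keep = increase > config.ofv_remove_threshold
            rows.append(
                {
                    "step": "backward",
                    "parameter": eff.parameter,
                    "covariate": eff.covariate,
                    "form": eff.form,
                    "delta_ofv": float(increase),
                    "included": keep,
                }
            )
            if not keep:
                included = rest
                current, current_model = trial, trial.model
                changed = True
                break
    return CovariateStepResult(
        selected_model=current_model,
        selected_result=current,
        table=pd.DataFrame(rows),
    )


@dataclass
class BootstrapSummary:
    """Percentile summary of nonparametric bootstrap refits.

    ``table`` has one row per parameter with median and CI bounds;
    ``unreliable`` is set when more than 20 % of replicates failed to
    converge.
    """

    table: pd.DataFrame
    n_requested: int
    n_converged: int
    unreliable: bool


def bootstrap(
    dataset: StudyDataset,
    model: PopulationModel,
    config: EstimationConfig | None = None,
    seed: int = 0,
    n_replicates: int | None = None,
) -> BootstrapSummary:
    """Nonparametric bootstrap: resample subjects, refit, summarise.

    Reports the median and the configured percentile interval (default
    5-95 %) per parameter over converged replicates.
    """
    config = config or EstimationConfig()
    n = n_replicates if n_replicates is not None else config.bootstrap_n
    rng = np.random.default_rng(seed)
    fit_cfg = replace(config, compute_rse=False)
    names = (
        [f"theta_{p}" for p in PARAM_NAMES]
        + [f"omega_cv_{p}" for p in PARAM_NAMES]
        + ["b"]
    )
    draws = []
    n_conv = 0
    for _ in range(n):
        resampled = dataset.resample_subjects(rng)
        try:
            res = fit(resampled, initial=model, config=fit_cfg)
        except Exception:
            continue
        if not np.isfinite(res.ofv):
            continue
        n_conv += 1
        draws.append(
            list(res.model.theta.as_array())
            + list(res.model.omega_cv)
            + [res.model.resid_b]
        )
    lo, hi = config.bootstrap_ci
    if draws:
        arr = np.array(draws)
        table = pd.DataFrame(
            {
                "parameter": names,
                "median": np.median(arr, axis=0),
                "ci_lower": np.percentile(arr, lo, axis=0),
                "ci_upper": np.percentile(arr, hi, axis=0),
            }
        )
    else:
        table = pd.DataFrame(columns=["parameter", "median", "ci_lower", "ci_upper"])
    return BootstrapSummary(
        table=table,
        n_requested=n,
        n_converged=n_conv,
        unreliable=n_conv < 0.8 * n,
    )
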