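"""Staged nonlinear least-squares parameter estimation.

The fitting workflow mirrors the sequential design of the study:

1. ``fit_blood`` — blood concentrations to the biexponential disposition
   model (free: V1, k1, k2, k10; CL_tot = V1·k10 reported);
2. ``fit_stomach`` — lumped stomach concentrations to the three-pool
   tissue model with blood parameters and physiological constants fixed
   (free: V_T, fu_PSeff, k_ass, k_dis);
3. ``fit_pd`` — stomach ACh to the indirect-response model with the full
   PK model fixed (free: k_in, k_out and optionally IC50).

All fits run bounded local least squares in log-parameter space from
multiple seeded restarts; the best converged restart is returned.  The
default residual scale is log-concentration (Gaussian error on the log
scale ≈ proportional error), appropriate for data spanning three
decades.  The Gaussian log-likelihood is evaluated with the error
variance profiled at its maximum-likelihood value σ̂² = RSS/n.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .exceptions import FitFailureError, InvalidArgumentError
from .model import blood_forcing, deep_pool_volume
from .params import BloodPKParams, DoseRegimen, PDParams, StomachParams
from .simulate import simulate_acotiamide, simulate_coupled
from .timeseries import ConcentrationTimeSeries

__all__ = [
    "FitResult",
    "FitOptions",
    "log_likelihood",
    "aic",
    "fit_blood",
    "fit_stomach",
    "fit_pd",
]

ERROR_MODELS = ("additive", "proportional", "log_additive")
_SIGMA_FLOOR = 1e-12


@dataclass
class FitOptions:
    """Optimizer settings shared by the staged fits."""

    error_model: str = "log_additive"
    n_restarts: int = 10
    seed: int = 0
    restart_spread: float = 10.0  # restarts drawn log-uniform within ±spread× of init
    extra_variance_params: int = 1  # profiled error variance counts as a parameter
    xtol: float = 1e-10
    ftol: float = 1e-10
    max_nfev: int = 400
    # Finite-difference step for the Jacobian; must stay well above the ODE
    # solver's relative tolerance or derivative estimates drown in solver noise.
    diff_step: float = 1e-4
    # A restart that drives the cost this low is already at machine-level
    # residuals; further restarts cannot improve it.
    early_stop_cost: float = 1e-14

    def __post_init__(self) -> None:
        if self.error_model not in ERROR_MODELS:
            raise InvalidArgumentError(
                f"error_model must be one of {ERROR_MODELS}, not {self.error_model!r}"
            )


@dataclass
class FitResult:
    """Outcome of one staged fit."""

    estimates: dict[str, float]
    fixed: dict[str, float]
    objective: float  # residual sum of squares on the fitting scale
    loglik: float
    aic: float
    n_obs: int
    n_params: int
    converged: bool
    n_restarts_used: int
    seed: int
    error_model: str
    sensitivity_correlation_max: float | None = None
    data_digest: str | None = None
    diagnostics: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            k: v
            for k, v in self.__dict__.items()
            if k != "diagnostics" or v
        }
        return json.dumps(payload, indent=2, default=float)


def _residuals(observed: np.ndarray, predicted: np.ndarray, error_model: str) -> np.ndarray:
    if error_model == "additive":
        return predicted - observed
    if error_model == "proportional":
        return (predicted - observed) / np.maximum(observed, _SIGMA_FLOOR)
    if error_model == "log_additive":
        if np.any(observed <= 0):
            raise InvalidArgumentError(
                "log_additive error model requires strictly positive observations"
            )
        return np.log(np.maximum(predicted, _SIGMA_FLOOR)) - np.log(observed)
    raise InvalidArgumentError(f"unknown error model {error_model!r}")


def log_likelihood(
    observed: np.ndarray | ConcentrationTimeSeries,
    predicted: np.ndarray,
    error_model: str = "log_additive",
) -> float:
    """Profiled Gaussian log-likelihood of predictions given observations.

    The residual scale is set by ``error_model``; the error variance is
    profiled at σ̂² = RSS/n, giving
    loglik = −n/2·(ln 2π + ln σ̂² + 1).  A σ̂ floor keeps a perfect fit
    finite.
    """
    if isinstance(observed, ConcentrationTimeSeries):
        observed = observed.values
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise InvalidArgumentError("observed and predicted must be aligned")
    r = _residuals(observed, predicted, error_model)
    n = r.size
    sigma2 = max(float(np.mean(r**2)), _SIGMA_FLOOR**2)
    return -0.5 * n * (np.log(2.0 * np.pi) + np.log(sigma2)) - float(
        np.sum(r**2)
    ) / (2.0 * sigma2)


def aic(loglik: float, n_params: int) -> float:
    """Akaike's information criterion, −2·loglik + 2·n_params."""
    if n_params < 1:
        raise InvalidArgumentError("n_params must be >= 1")
    return -2.0 * loglik + 2.0 * n_params


def _max_abs_correlation(jac: np.ndarray) -> float | None:
    """Largest |pairwise correlation| between parameter sensitivity columns."""
    if jac.shape[1] < 2:
        return None
    cols = jac - jac.mean(axis=0)
    norms = np.linalg.norm(cols, axis=0)
    if np.any(norms == 0):
        return 1.0
    corr = (cols.T @ cols) / np.outer(norms, norms)
    off = np.abs(corr - np.eye(corr.shape[0]))
    return float(off.max())


def _multistart_least_squares(
    residual_fn: Callable[[np.ndarray], np.ndarray],
    log_init: np.ndarray,
    options: FitOptions,
) -> tuple[np.ndarray, "least_squares.__class__", int]:
    """Best-of-restarts bounded least squares in log-parameter space."""
    rng = np.random.default_rng(options.seed)
    spread = np.log(options.restart_spread)
    starts = [log_init]
    starts += [
        log_init + rng.uniform(-spread, spread, size=log_init.shape)
        for _ in range(options.n_restarts - 1)
    ]
    best = None
    best_x = None
    n_used = 0
    for x0 in starts:
        n_used += 1
        try:
            res = least_squares(
                residual_fn,
                x0,
                method="trf",
                xtol=options.xtol,
                ftol=options.ftol,
                diff_step=options.diff_step,
                max_nfev=options.max_nfev,
            )
        except Exception:
            continue
        if not res.success or not np.all(np.isfinite(res.x)):
            continue
        if best is None or res.cost < best.cost - 1e-12:
            best, best_x = res, res.x
        if best.cost < options.early_stop_cost:
            break
    if best is None:
        raise FitFailureError("all optimization restarts failed")
    return best_x, best, n_used


def _digest(series: ConcentrationTimeSeries) -> str:
    h = hashlib.sha256()
    h.update(series.times.tobytes())
    h.update(series.values.tobytes())
    return h.hexdigest()[:16]


def _finalize(
    estimates: dict[str, float],
    fixed: dict[str, float],
    res,
    observed: ConcentrationTimeSeries,
    predicted: np.ndarray,
    n_structural: int,
    options: FitOptions,
    n_used: int,
) -> FitResult:
    rss = float(2.0 * res.cost)
    ll = log_likelihood(observed.values, predicted, options.error_model)
    n_params = n_structural + options.extra_variance_params
    corr = _max_abs_correlation(np.atleast_2d(res.jac))
    if corr is not None and corr > 0.999:
        warnings.warn(
            f"parameter sensitivities are nearly collinear (max |r| = {corr:.6f}); "
            "estimates may be ratio-identified only",
            stacklevel=3,
        )
    return FitResult(
        estimates=estimates,
        fixed=fixed,
        objective=rss,
        loglik=ll,
        aic=aic(ll, n_params),
        n_obs=len(observed),
        n_params=n_params,
        converged=bool(res.success),
        n_restarts_used=n_used,
        seed=options.seed,
        error_model=options.error_model,
        sensitivity_correlation_max=corr,
        data_digest=_digest(observed),
        diagnostics={"nfev": int(res.nfev), "optimality": float(res.optimality)},
    )


def fit_blood(
    data: ConcentrationTimeSeries,
    d: DoseRegimen,
    init: BloodPKParams | None = None,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit the biexponential blood disposition model to blood data.

    Free parameters (log scale): V1, k1, k2, k10.  CL_tot = V1·k10 is
    reported alongside.  Requires at least five distinct sampling times
    for the four structural parameters to be identified.
    """
    options = options or FitOptions()
    if data.compartment not in {"blood", "plasma"}:
        raise InvalidArgumentError("fit_blood expects blood (or plasma) data")
    if data.n_timepoints < 5:
        raise FitFailureError(
            f"need >= 5 distinct time points to fit 4 parameters, got {data.n_timepoints}"
        )
    values = data.values
    if data.compartment == "plasma":
        values = values * d.R_bp
    obs = ConcentrationTimeSeries("blood", data.times, values, data.animal_ids)
    init = init or BloodPKParams(V1=300.0, k1=0.1, k2=0.03, CL_tot=50.0)
    log_init = np.log([init.V1, init.k1, init.k2, init.k10])

    def predict(x: np.ndarray) -> np.ndarray:
        V1, k1, k2, k10 = np.exp(x)
        try:
            p = BloodPKParams(V1=V1, k1=k1, k2=k2, CL_tot=V1 * k10)
        except Exception:
            return np.full(len(obs), np.nan)
        return np.asarray(blood_forcing(obs.times, p, d))

    def resid(x: np.ndarray) -> np.ndarray:
        pred = predict(x)
        if np.any(~np.isfinite(pred)):
            return np.full(len(obs), 1e6)
        return _residuals(obs.values, pred, options.error_model)

    x, res, n_used = _multistart_least_squares(resid, log_init, options)
    V1, k1, k2, k10 = np.exp(x)
    estimates = {
        "V1": float(V1),
        "k1": float(k1),
        "k2": float(k2),
        "k10": float(k10),
        "CL_tot": float(V1 * k10),
    }
    return _finalize(
        estimates,
        {"dose": d.dose_per_kg, "Rbp": d.R_bp},
        res,
        obs,
        predict(x),
        n_structural=4,
        options=options,
        n_used=n_used,
    )


def fit_stomach(
    data: ConcentrationTimeSeries,
    blood: BloodPKParams,
    d: DoseRegimen,
    sp_fixed: StomachParams,
    init: dict[str, float] | None = None,
    options: FitOptions | None = None,
    volume_convention: str = "eq_sum",
) -> FitResult:
    """Fit the stomach tissue model to lumped stomach concentrations.

    The blood model and the physiological subset (Q_t, V_e, fb_PSinf)
    are fixed; the free parameters are exactly (V_T, fu_PSeff, k_ass,
    k_dis).  Predictions are lumped stomach concentrations
    (A_T + A_d)/V_stomach.  The default parameter count for AIC is
    4 structural + 1 profiled error variance.
    """
    options = options or FitOptions()
    if data.compartment != "stomach_total":
        raise InvalidArgumentError("fit_stomach expects stomach_total data")
    if data.n_timepoints < 5:
        raise FitFailureError("need >= 5 distinct time points for the stomach fit")
    init = init or {"VT": 0.1, "fu_PSeff": 0.01, "kass": 1e-4, "kdis": 1e-5}
    order = ("VT", "fu_PSeff", "kass", "kdis")
    if set(init) != set(order):
        raise InvalidArgumentError(f"init must provide exactly {order}")
    if any(init[k] <= 0 for k in order):
        raise InvalidArgumentError("initial values must be strictly positive")
    log_init = np.log([init[k] for k in order])
    t_end = max(float(data.times.max()), 1.0)
    t_fit = np.unique(np.concatenate([[0.0], data.times]))

    def build(x: np.ndarray) -> StomachParams | None:
        VT, fu, kass, kdis = np.exp(x)
        try:
            return StomachParams(
                Q_t=sp_fixed.Q_t,
                V_e=sp_fixed.V_e,
                fb_PSinf=sp_fixed.fb_PSinf,
                fu_PSeff=fu,
                V_T=VT,
                k_ass=kass,
                k_dis=kdis,
                V_stomach_literature=sp_fixed.V_stomach_literature,
            )
        except Exception:
            return None

    def predict(x: np.ndarray) -> np.ndarray:
        sp = build(x)
        if sp is None:
            return np.full(len(data), np.nan)
        try:
            sim = simulate_acotiamide(
                d, blood, sp, t_end=t_end, t_eval=t_fit,
                volume_convention=volume_convention,
            )
        except Exception:
            return np.full(len(data), np.nan)
        lookup = dict(zip(sim.time, sim.C_stomach))
        return np.array([lookup[t] for t in data.times])

    def resid(x: np.ndarray) -> np.ndarray:
        pred = predict(x)
        if np.any(~np.isfinite(pred)) or np.any(pred <= 0):
            return np.full(len(data), 1e6)
        return _residuals(data.values, pred, options.error_model)

    x, res, n_used = _multistart_least_squares(resid, log_init, options)
    VT, fu, kass, kdis = np.exp(x)
    estimates = {"VT": float(VT), "fu_PSeff": float(fu), "kass": float(kass),
                 "kdis": float(kdis)}
    fixed = {
        "Qt": sp_fixed.Q_t, "Ve": sp_fixed.V_e, "fb_PSinf": sp_fixed.fb_PSinf,
        "V1": blood.V1, "k1": blood.k1, "k2": blood.k2, "CLtot": blood.CL_tot,
    }
    return _finalize(estimates, fixed, res, data, predict(x), 4, options, n_used)


def fit_pd(
    data: ConcentrationTimeSeries,
    d: DoseRegimen,
    blood: BloodPKParams,
    stomach: StomachParams,
    fix_ic50: float | None = None,
    init: dict[str, float] | None = None,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit the indirect-response ACh model with the PK model fixed.

    Free parameters are (k_in, k_out, IC50), or (k_in, k_out) when
    ``fix_ic50`` is given.  The baseline is constrained to
    R(0) = k_in/k_out.  A design with no post-dose perturbation leaves
    IC50 unidentified and raises a failure.
    """
    options = options or FitOptions()
    if data.compartment != "ach":
        raise InvalidArgumentError("fit_pd expects ach data")
    if data.n_timepoints < 3:
        raise FitFailureError("need >= 3 distinct time points for the PD fit")
    init = init or {"kin": 0.003, "kout": 0.004, "IC50": 2.0}
    names = ["kin", "kout"] if fix_ic50 is not None else ["kin", "kout", "IC50"]
    if any(init[k] <= 0 for k in names):
        raise InvalidArgumentError("initial values must be strictly positive")
    log_init = np.log([init[k] for k in names])
    t_end = max(float(data.times.max()), 1.0)
    t_fit = np.unique(np.concatenate([[0.0], data.times]))

    # Degenerate-design guard: all observations at one concentration level
    # carry no information about IC50.
    if fix_ic50 is None and np.ptp(data.values) == 0:
        raise FitFailureError(
            "ACh data show no perturbation from baseline; IC50 is unidentifiable"
        )

    def predict(x: np.ndarray) -> np.ndarray:
        vals = np.exp(x)
        kin, kout = vals[0], vals[1]
        ic50 = fix_ic50 if fix_ic50 is not None else vals[2]
        try:
            pdp = PDParams(k_in=kin, k_out=kout, IC50=ic50)
            sim = simulate_coupled(d, blood, stomach, pdp, t_end=t_end, t_eval=t_fit)
        except Exception:
            return np.full(len(data), np.nan)
        lookup = dict(zip(sim.time, sim.R))
        return np.array([lookup[t] for t in data.times])

    def resid(x: np.ndarray) -> np.ndarray:
        pred = predict(x)
        if np.any(~np.isfinite(pred)) or np.any(pred <= 0):
            return np.full(len(data), 1e6)
        return _residuals(data.values, pred, options.error_model)

    x, res, n_used = _multistart_least_squares(resid, log_init, options)
    vals = np.exp(x)
    estimates = {"kin": float(vals[0]), "kout": float(vals[1])}
    if fix_ic50 is None:
        estimates["IC50"] = float(vals[2])
    fixed = {
        "dose": d.dose_per_kg, "V1": blood.V1, "CLtot": blood.CL_tot,
        "VT": stomach.V_T, "fu_PSeff": stomach.fu_PSeff,
        "kass": stomach.k_ass, "kdis": stomach.k_dis,
    }
    if fix_ic50 is not None:
        fixed["IC50"] = fix_ic50
    return _finalize(estimates, fixed, res, data, predict(x), len(names), options, n_used)
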