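"""In vitro AChE inhibition: initial velocities and IC50.

Product-formation time courses from the enzyme assay are reduced to
initial hydrolysis velocities by ordinary least-squares over the first
60 seconds, and the velocity–inhibitor relationship is fitted with a
hyperbolic inhibition curve

    v(I) = v0 / (1 + (I/IC50)^h),   h = 1 by default,

the same functional form as the inhibition term of the in vivo
pharmacodynamic model.  The fit is performed in log-IC50 space, which
is scale-free and keeps IC50 positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .exceptions import FitFailureError, InvalidArgumentError

__all__ = ["InhibitionAssay", "IC50Fit", "initial_velocity", "velocities_from_assay", "fit_ic50"]

INITIAL_RATE_WINDOW_S = 60.0


@dataclass
class InhibitionAssay:
    """Product-formation time courses at several inhibitor concentrations.

    ``table`` is tidy with columns (inhibitor_uM, time_s, product_uM,
    replicate); each (inhibitor_uM, replicate) pair is one time course
    within the initial-rate window.
    """

    table: pd.DataFrame

    REQUIRED = ("inhibitor_uM", "time_s", "product_uM", "replicate")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise InvalidArgumentError(f"assay table missing columns {sorted(missing)}")
        if (self.table["inhibitor_uM"] < 0).any():
            raise InvalidArgumentError("inhibitor concentrations must be >= 0")
        if (self.table["time_s"] > INITIAL_RATE_WINDOW_S).any():
            raise InvalidArgumentError(
                f"time points must lie within the {INITIAL_RATE_WINDOW_S:.0f} s initial-rate window"
            )

    @property
    def concentrations(self) -> np.ndarray:
        return np.sort(self.table["inhibitor_uM"].unique())


def initial_velocity(timepoints: np.ndarray, product: np.ndarray) -> float:
    """Initial hydrolysis velocity (μM/s) by linear regression over 0–60 s.

    The slope of product concentration versus time is estimated by
    ordinary least squares with a free intercept.
    """
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(product, dtype=float)
    if t.size < 2 or t.size != y.size:
        raise InvalidArgumentError("need at least 2 aligned (time, product) points")
    if np.any(t > INITIAL_RATE_WINDOW_S) or np.any(t < 0):
        raise InvalidArgumentError(
            f"all time points must lie in [0, {INITIAL_RATE_WINDOW_S:.0f}] s"
        )
    if np.ptp(t) == 0:
        raise InvalidArgumentError("time points must not be all identical")
    res = stats.linregress(t, y)
    return float(res.slope)


def velocities_from_assay(assay: InhibitionAssay) -> pd.DataFrame:
    """Reduce time courses to one velocity per (inhibitor, replicate)."""
    rows = []
    for (conc, rep), grp in assay.table.groupby(["inhibitor_uM", "replicate"]):
        v = initial_velocity(grp["time_s"].to_numpy(), grp["product_uM"].to_numpy())
        rows.append({"inhibitor_uM": conc, "replicate": rep, "velocity_uM_per_s": v})
    return pd.DataFrame(rows)


@dataclass
class IC50Fit:
    ic50: float  # μM
    v0: float  # μM/s, uninhibited velocity
    hill: float
    hill_fixed: bool
    rss: float
    converged: bool
    boundary_warning: bool

    def percent_of_control(self, inhibitor_uM: np.ndarray) -> np.ndarray:
        """Fitted curve expressed as percent of uninhibited velocity."""
        return 100.0 / (1.0 + (np.asarray(inhibitor_uM) / self.ic50) ** self.hill)


def _curve(I: np.ndarray, v0: float, ic50: float, h: float) -> np.ndarray:
    return v0 / (1.0 + (I / ic50) ** h)


def fit_ic50(
    inhibitor_conc: np.ndarray,
    velocities: np.ndarray,
    hill: float | None = None,
    free_hill: bool = False,
) -> IC50Fit:
    """Fit the hyperbolic inhibition curve to (concentration, velocity) data.

    Parameters are (v0, log IC50) — plus log h when ``free_hill`` — and
    the loss is ordinary least squares on absolute velocities.  At least
    four concentrations are required; a zero-inhibitor control pins v0.
    A boundary warning is issued when the fitted IC50 falls outside the
    tested concentration range (no transition observed).
    """
    I = np.asarray(inhibitor_conc, dtype=float)
    v = np.asarray(velocities, dtype=float)
    if I.shape != v.shape:
        raise InvalidArgumentError("concentrations and velocities must be aligned")
    if np.any(I < 0):
        raise InvalidArgumentError("inhibitor concentrations must be >= 0")
    if len(np.unique(I)) < 4:
        raise InvalidArgumentError("need >= 4 distinct concentrations spanning the transition")
    h_fixed = 1.0 if hill is None else float(hill)

    v0_init = float(np.mean(v[I == 0])) if np.any(I == 0) else float(v.max())
    if v0_init <= 0:
        raise FitFailureError("non-positive control velocity; cannot fit inhibition curve")
    pos = I[I > 0]
    ic50_init = float(np.exp(np.mean(np.log(pos)))) if pos.size else 1.0

    if free_hill:
        x0 = np.array([v0_init, np.log(ic50_init), 0.0])

        def resid(x: np.ndarray) -> np.ndarray:
            return _curve(I, x[0], np.exp(x[1]), np.exp(x[2])) - v
    else:
        x0 = np.array([v0_init, np.log(ic50_init)])

        def resid(x: np.ndarray) -> np.ndarray:
            return _curve(I, x[0], np.exp(x[1]), h_fixed) - v

    res = least_squares(resid, x0, method="lm", xtol=1e-12, ftol=1e-12)
    if not res.success:
        raise FitFailureError(f"IC50 fit did not converge: {res.message}")
    v0_hat = float(res.x[0])
    ic50_hat = float(np.exp(res.x[1]))
    h_hat = float(np.exp(res.x[2])) if free_hill else h_fixed
    boundary = bool(pos.size and not (pos.min() <= ic50_hat <= pos.max()))
    if boundary:
        warnings.warn(
            f"fitted IC50 = {ic50_hat:.3g} μM lies outside the tested range "
            f"[{pos.min():.3g}, {pos.max():.3g}] μM; no transition observed",
            stacklevel=2,
        )
    return IC50Fit(
        ic50=ic50_hat,
        v0=v0_hat,
        hill=h_hat,
        hill_fixed=not free_hill,
        rss=float(2.0 * res.cost),
        converged=bool(res.success),
        boundary_warning=boundary,
    )
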