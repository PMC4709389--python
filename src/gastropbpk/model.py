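"""Model equations: closed forms and ODE right-hand sides.

This module contains no solver or optimizer logic.  Conventions:

* blood disposition is biexponential (two-compartment, i.v. bolus) and
  acts as a one-way forcing on the stomach — stomach fluxes do not feed
  back into blood;
* the stomach is three well-stirred pools: vascular space C_e, precursor
  pool C_T (carrier-mediated uptake, site of AChE inhibition), and a
  slowly equilibrating deep pool C_d;
* acetylcholine follows an indirect-response model in which drug in the
  precursor pool inhibits the first-order loss (hydrolysis) term.

The deep-pool mass balance is written with ``k_dis`` as the exit rate
constant (flux V_d·C_d·k_dis), which conserves mass against the
precursor-pool equation and is consistent with the equilibrium volume
V_d = V_T·k_ass/k_dis.  A variant with ``k_ass`` in the exit term is
kept behind ``deep_pool_exit="k_ass"`` for comparison only; it does not
conserve mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np

from .exceptions import DegenerateParameterError, InvalidArgumentError
from .params import BloodPKParams, DoseRegimen, PDParams, StomachParams

__all__ = [
    "StomachState",
    "MacroConstants",
    "plasma_to_blood",
    "macro_constants",
    "blood_forcing",
    "stomach_rhs",
    "deep_pool_volume",
    "stomach_concentration",
    "inhibition_fraction",
    "pd_rhs",
    "stomach_system_matrix",
]


@dataclass(frozen=True)
class StomachState:
    """Stomach pool concentrations (μM) at one time (min)."""

    C_e: float
    C_T: float
    C_d: float
    time: float = 0.0


class MacroConstants(NamedTuple):
    """Hybrid disposition constants of the biexponential blood curve.

    ``A`` and ``B`` are the per-unit-dose coefficients (μM per nmol/kg);
    multiplying by the dose in nmol/kg gives the exponential amplitudes
    in μM.  They satisfy A + B = 1/V1.
    """

    alpha: float  # min⁻¹, fast hybrid exponent
    beta: float  # min⁻¹, slow hybrid exponent
    A: float
    B: float


def plasma_to_blood(C_p: float | np.ndarray, R_bp: float) -> float | np.ndarray:
    """Convert plasma concentration to whole-blood concentration.

    C_blood = C_plasma · R_bp, with R_bp the blood-to-plasma ratio.
    """
    C_p = np.asarray(C_p, dtype=float)
    if np.any(C_p < 0):
        raise InvalidArgumentError("plasma concentration must be >= 0")
    if not R_bp > 0:
        raise InvalidArgumentError("R_bp must be > 0")
    out = C_p * R_bp
    return float(out) if out.ndim == 0 else out


def macro_constants(p: BloodPKParams) -> MacroConstants:
    """Hybrid constants (α, β, A, B) of the two-compartment bolus model.

    α and β are the roots of s² − (k10+k1+k2)·s + k10·k2 = 0 with
    k10 = CL_tot/V1, ordered α > β > 0.  The identities
    α·β = k10·k2 and α+β = k10+k1+k2 hold by construction.
    """
    alpha, beta = p.hybrid_constants()
    denom = p.V1 * (alpha - beta)
    return MacroConstants(
        alpha=alpha,
        beta=beta,
        A=(alpha - p.k2) / denom,
        B=(p.k2 - beta) / denom,
    )


def blood_forcing(
    t: float | np.ndarray, p: BloodPKParams, d: DoseRegimen
) -> float | np.ndarray:
    """Arterial blood concentration C1(t) in μM after an i.v. bolus.

    C1(t) = D·(α−k2)/(V1·(α−β))·e^(−α·t) + D·(k2−β)/(V1·(α−β))·e^(−β·t),
    so C1(0) = D/V1.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidArgumentError("time must be >= 0")
    mc = macro_constants(p)
    D = d.dose_nmol_per_kg
    out = D * (mc.A * np.exp(-mc.alpha * t) + mc.B * np.exp(-mc.beta * t))
    return float(out) if out.ndim == 0 else out


def deep_pool_volume(sp: StomachParams) -> float:
    """Equilibrium deep-pool volume V_d = V_T·k_ass/k_dis, in ml."""
    if sp.k_dis <= 0:
        raise DegenerateParameterError("k_dis must be > 0 to define V_d")
    return sp.V_T * sp.k_ass / sp.k_dis


def stomach_rhs(
    state: StomachState | tuple[float, float, float],
    t: float,
    sp: StomachParams,
    C1_fn: Callable[[float], float],
    deep_pool_exit: str = "k_dis",
) -> tuple[float, float, float]:
    """Time derivatives (dC_e/dt, dC_T/dt, dC_d/dt) in μM/min.

    Mass balances (amounts = volume × concentration):

      V_e·dC_e/dt = Q_t·(C1 − C_e) − fb_PSinf·C_e + fu_PSeff·C_T
      V_T·dC_T/dt = fb_PSinf·C_e + V_d·C_d·k_dis − fu_PSeff·C_T − V_T·C_T·k_ass
      V_d·dC_d/dt = V_T·C_T·k_ass − V_d·C_d·k_exit

    with k_exit = k_dis by default (mass-conserving).  The total stomach
    amount then changes only through the blood exchange term Q_t·(C1 − C_e).
    """
    if isinstance(state, StomachState):
        C_e, C_T, C_d = state.C_e, state.C_T, state.C_d
    else:
        C_e, C_T, C_d = state
    if deep_pool_exit == "k_dis":
        k_exit = sp.k_dis
    elif deep_pool_exit == "k_ass":
        k_exit = sp.k_ass
    else:
        raise InvalidArgumentError(f"unknown deep_pool_exit {deep_pool_exit!r}")
    V_d = deep_pool_volume(sp)
    C1 = C1_fn(t)
    dCe = (sp.Q_t * (C1 - C_e) - sp.fb_PSinf * C_e + sp.fu_PSeff * C_T) / sp.V_e
    dCT = (
        sp.fb_PSinf * C_e
        + V_d * C_d * sp.k_dis
        - sp.fu_PSeff * C_T
        - sp.V_T * C_T * sp.k_ass
    ) / sp.V_T
    dCd = (sp.V_T * C_T * sp.k_ass - V_d * C_d * k_exit) / V_d
    return dCe, dCT, dCd


def stomach_system_matrix(
    sp: StomachParams, deep_pool_exit: str = "k_dis"
) -> tuple[np.ndarray, np.ndarray]:
    """Linear form of the stomach system: d/dt [C_e, C_T, C_d] = M·x + g·C1(t).

    Returns (M, g).  Exposed for analytic work and steady-state algebra;
    the simulation module integrates the same dynamics numerically.
    """
    V_d = deep_pool_volume(sp)
    k_exit = {"k_dis": sp.k_dis, "k_ass": sp.k_ass}.get(deep_pool_exit)
    if k_exit is None:
        raise InvalidArgumentError(f"unknown deep_pool_exit {deep_pool_exit!r}")
    M = np.array(
        [
            [-(sp.Q_t + sp.fb_PSinf) / sp.V_e, sp.fu_PSeff / sp.V_e, 0.0],
            [
                sp.fb_PSinf / sp.V_T,
                -(sp.fu_PSeff + sp.V_T * sp.k_ass) / sp.V_T,
                V_d * sp.k_dis / sp.V_T,
            ],
            [0.0, sp.V_T * sp.k_ass / V_d, -k_exit],
        ]
    )
    g = np.array([sp.Q_t / sp.V_e, 0.0, 0.0])
    return M, g


def stomach_concentration(
    state: StomachState | tuple[float, float, float],
    sp: StomachParams,
    volume_convention: str = "eq_sum",
) -> float:
    """Lumped whole-stomach concentration (A_T + A_d)/V_stomach in μM.

    The vascular space is excluded: measured stomach tissue is rinsed of
    blood, so only the precursor- and deep-pool amounts contribute.
    ``volume_convention`` selects V_stomach = V_T + V_d (``"eq_sum"``) or
    the anatomical literature volume (``"literature"``).
    """
    if isinstance(state, StomachState):
        C_T, C_d = state.C_T, state.C_d
    else:
        _, C_T, C_d = state
    V_d = deep_pool_volume(sp)
    V_stomach = sp.v_stomach(volume_convention)
    return (sp.V_T * C_T + V_d * C_d) / V_stomach


def inhibition_fraction(C_T: float | np.ndarray, IC50: float) -> float | np.ndarray:
    """Fractional AChE inhibition C_T/(IC50 + C_T), in [0, 1).

    Zero with no drug, 0.5 at C_T = IC50, saturating below 1.
    """
    C_T = np.asarray(C_T, dtype=float)
    if np.any(C_T < 0):
        raise InvalidArgumentError("precursor-pool concentration must be >= 0")
    if not IC50 > 0:
        raise InvalidArgumentError("IC50 must be > 0")
    out = C_T / (IC50 + C_T)
    return float(out) if out.ndim == 0 else out


def pd_rhs(R: float, C_T: float, pd: PDParams) -> float:
    """dR/dt for stomach ACh under inhibition of its loss term.

    dR/dt = k_in − k_out·(1 − C_T/(IC50 + C_T))·R

    At C_T = 0 the steady state is the baseline R0 = k_in/k_out.
    """
    return pd.k_in - pd.k_out * (1.0 - inhibition_fraction(C_T, pd.IC50)) * R
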