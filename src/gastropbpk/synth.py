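"""Synthetic datasets replicating the in vivo and in vitro study designs.

The in vivo design: a 1.85 μmol/kg i.v. bolus, destructive (terminal)
sampling of blood and stomach at 5, 10, 15, 30 min and 1, 2, 4, 6, 8,
24, 48 h with n = 6 rats per time point, and stomach ACh determined on
the 5 min–4 h subset.  The in vitro design: acotiamide at a zero
control plus log-spaced concentrations spanning 0.05–25 μM, product
time courses within the 60 s initial-rate window, triplicate.

Noise is multiplicative lognormal with unit mean; each dataset kind
draws from its own deterministic substream of the master seed, so
changing one compartment's draws never perturbs another's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError
from .invitro import InhibitionAssay
from .model import blood_forcing
from .params import BloodPKParams, DoseRegimen, PDParams, StomachParams
from .simulate import DEFAULT_SAMPLING_TIMES_MIN, simulate_acotiamide, simulate_coupled
from .timeseries import ConcentrationTimeSeries

__all__ = [
    "StudyDesign",
    "InVitroDesign",
    "generate_pk_dataset",
    "generate_ach_dataset",
    "generate_invitro_dataset",
]

#: substream labels — one independent random stream per dataset kind
_STREAMS = {"blood": 0, "stomach": 1, "ach": 2, "invitro": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


@dataclass(frozen=True)
class StudyDesign:
    """The in vivo sampling design."""

    seed: int
    dose: DoseRegimen = field(default_factory=lambda: DoseRegimen(dose_per_kg=1.85))
    blood_stomach_times: tuple[float, ...] = tuple(DEFAULT_SAMPLING_TIMES_MIN)
    ach_times: tuple[float, ...] = (5.0, 10.0, 15.0, 30.0, 60.0, 120.0, 240.0)
    n_per_timepoint: int = 6
    noise_cv: float = 0.10

    def __post_init__(self) -> None:
        if self.n_per_timepoint < 1:
            raise InvalidArgumentError("n_per_timepoint must be >= 1")
        if self.noise_cv < 0:
            raise InvalidArgumentError("noise_cv must be >= 0")
        if any(t < 0 for t in self.blood_stomach_times + self.ach_times):
            raise InvalidArgumentError("sampling times must be >= 0")


@dataclass(frozen=True)
class InVitroDesign:
    """The in vitro assay design: concentrations, time points, replicates."""

    seed: int
    concentrations_uM: tuple[float, ...] = (
        0.0, 0.05, 0.15, 0.5, 1.5, 5.0, 15.0, 25.0)
    timepoints_s: tuple[float, ...] = (0.0, 15.0, 30.0, 45.0, 60.0)
    replicates: int = 3
    noise_cv: float = 0.05


def _destructive_draws(
    times: np.ndarray,
    predictions: np.ndarray,
    n: int,
    cv: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One independent animal per (time, replicate) cell."""
    rep_times = np.repeat(times, n)
    rep_pred = np.repeat(predictions, n)
    noise = _lognormal_factor(rng, cv, rep_times.size)
    ids = np.array(
        [f"t{ti}_r{ri + 1}" for ti in range(len(times)) for ri in range(n)], dtype=object
    )
    return rep_times, rep_pred * noise, ids


def generate_pk_dataset(
    d: DoseRegimen | None,
    bp: BloodPKParams,
    sp: StomachParams,
    design: StudyDesign,
    volume_convention: str = "eq_sum",
) -> tuple[ConcentrationTimeSeries, ConcentrationTimeSeries]:
    """Noisy blood and lumped-stomach datasets on the study schedule.

    Every (time, animal) pair is an independent draw around the model
    prediction (destructive sampling); draws are deterministic given the
    design seed, with blood and stomach on separate substreams.
    """
    d = d or design.dose
    times = np.asarray(design.blood_stomach_times, dtype=float)
    blood_pred = np.asarray(blood_forcing(times, bp, d))
    sim = simulate_acotiamide(
        d, bp, sp,
        t_end=max(times.max(), 1.0),
        t_eval=np.unique(np.concatenate([[0.0], times])),
        volume_convention=volume_convention,
    )
    lookup = dict(zip(sim.time, sim.C_stomach))
    stomach_pred = np.array([lookup[t] for t in times])

    bt, bv, bid = _destructive_draws(
        times, blood_pred, design.n_per_timepoint, design.noise_cv, _rng(design.seed, "blood")
    )
    st, sv, sid = _destructive_draws(
        times, stomach_pred, design.n_per_timepoint, design.noise_cv, _rng(design.seed, "stomach")
    )
    return (
        ConcentrationTimeSeries("blood", bt, bv, bid),
        ConcentrationTimeSeries("stomach_total", st, sv, sid),
    )


def generate_ach_dataset(
    d: DoseRegimen | None,
    bp: BloodPKParams,
    sp: StomachParams,
    pd_params: PDParams,
    design: StudyDesign,
) -> ConcentrationTimeSeries:
    """Noisy stomach-ACh dataset on the ACh sub-schedule.

    The truth curve is the coupled PK/PD simulation starting from the
    pre-dose baseline R0 = k_in/k_out; with zero dose every draw
    scatters around R0.
    """
    d = d or design.dose
    times = np.asarray(design.ach_times, dtype=float)
    sim = simulate_coupled(
        d, bp, sp, pd_params,
        t_end=max(times.max(), 1.0),
        t_eval=np.unique(np.concatenate([[0.0], times])),
    )
    lookup = dict(zip(sim.time, sim.R))
    pred = np.array([lookup[t] for t in times])
    at, av, aid = _destructive_draws(
        times, pred, design.n_per_timepoint, design.noise_cv, _rng(design.seed, "ach")
    )
    return ConcentrationTimeSeries("ach", at, av, aid)


def generate_invitro_dataset(
    ic50: float,
    v0: float,
    design: InVitroDesign,
    hill: float = 1.0,
) -> InhibitionAssay:
    """Synthetic product-formation time courses for the inhibition assay.

    Each (concentration, replicate) time course is linear with slope
    v0/(1 + (I/IC50)^h) perturbed by one multiplicative noise factor per
    replicate (the dominant assay error is on the velocity, not on the
    individual readouts).
    """
    if not (ic50 > 0 and v0 > 0):
        raise InvalidArgumentError("ic50 and v0 must be > 0")
    rng = _rng(design.seed, "invitro")
    t = np.asarray(design.timepoints_s, dtype=float)
    rows = []
    for conc in design.concentrations_uM:
        slope_true = v0 / (1.0 + (conc / ic50) ** hill)
        factors = _lognormal_factor(rng, design.noise_cv, design.replicates)
        for rep in range(design.replicates):
            slope = slope_true * factors[rep]
            for ti, prod in zip(t, slope * t):
                rows.append(
                    {
                        "inhibitor_uM": conc,
                        "time_s": ti,
                        "product_uM": prod,
                        "replicate": rep + 1,
                    }
                )
    return InhibitionAssay(pd.DataFrame(rows))
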