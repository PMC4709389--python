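"""Parameter containers for the gastric PBPK/PD model.

Canonical units throughout the package: time in minutes, volume in ml,
mass in g, amount in nmol.  Concentrations are nmol/ml == μM; tissue
acetylcholine is nmol per g wet tissue.  Dose and central-compartment
volume are per kg body weight and only ever enter through the intensive
ratio dose/V1, so body weight itself never appears.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from .exceptions import DegenerateParameterError, InvalidArgumentError

__all__ = [
    "DoseRegimen",
    "BloodPKParams",
    "StomachParams",
    "PDParams",
    "ParameterSet",
    "reference_parameters",
    "load_parameters",
    "dump_parameters",
]


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0) or not math.isfinite(value):
            raise InvalidArgumentError(f"{name} must be finite and > 0, got {value!r}")


@dataclass(frozen=True)
class DoseRegimen:
    """Intravenous bolus dose specification.

    Parameters
    ----------
    dose_per_kg:
        Dose in μmol per kg body weight.
    route:
        Administration route; only ``"iv_bolus"`` is supported.
    R_bp:
        Blood-to-plasma concentration ratio used to convert measured
        plasma concentrations to whole-blood concentrations.
    """

    dose_per_kg: float
    route: str = "iv_bolus"
    R_bp: float = 0.84

    def __post_init__(self) -> None:
        # zero dose is allowed: it is the control condition
        if not (self.dose_per_kg >= 0) or not math.isfinite(self.dose_per_kg):
            raise InvalidArgumentError(
                f"dose_per_kg must be finite and >= 0, got {self.dose_per_kg!r}"
            )
        _require_positive(R_bp=self.R_bp)
        if self.route != "iv_bolus":
            raise InvalidArgumentError(
                f"unsupported route {self.route!r}; only 'iv_bolus' is implemented"
            )

    @property
    def dose_nmol_per_kg(self) -> float:
        """Dose in nmol/kg (μM-compatible when divided by V1 in ml/kg)."""
        return self.dose_per_kg * 1000.0


@dataclass(frozen=True)
class BloodPKParams:
    """Two-compartment blood disposition parameters.

    ``k1`` is the central→peripheral micro rate constant (k12) and ``k2``
    the peripheral→central constant (k21); elimination from the central
    compartment is k10 = CL_tot/V1.  The hybrid exponents α, β of the
    biexponential disposition curve are the characteristic roots

        s² − (k10 + k1 + k2)·s + k10·k2 = 0.
    """

    V1: float  # ml/kg
    k1: float  # min⁻¹, central→peripheral (k12)
    k2: float  # min⁻¹, peripheral→central (k21)
    CL_tot: float  # ml/min/kg

    def __post_init__(self) -> None:
        _require_positive(V1=self.V1, k1=self.k1, k2=self.k2, CL_tot=self.CL_tot)
        # Fails loudly at construction if the exponents would be degenerate.
        alpha, beta = self.hybrid_constants()
        if not (alpha > beta > 0):
            raise DegenerateParameterError(
                f"hybrid exponents must satisfy alpha > beta > 0, got {alpha}, {beta}"
            )

    @property
    def k10(self) -> float:
        """Central elimination rate constant, min⁻¹."""
        return self.CL_tot / self.V1

    def hybrid_constants(self) -> tuple[float, float]:
        """Return (α, β), the macro disposition exponents in min⁻¹."""
        s = self.k10 + self.k1 + self.k2
        p = self.k10 * self.k2
        disc = s * s - 4.0 * p
        if disc <= 0:
            raise DegenerateParameterError(
                f"characteristic roots are not real and distinct (discriminant {disc})"
            )
        root = math.sqrt(disc)
        return (s + root) / 2.0, (s - root) / 2.0


@dataclass(frozen=True)
class StomachParams:
    """Stomach distribution parameters.

    The stomach is modeled as a vascular space (volume ``V_e``) in rapid
    flow-limited exchange with arterial blood, a precursor pool
    (``V_T``) reached by carrier-mediated uptake (influx clearance
    ``fb_PSinf``, efflux clearance ``fu_PSeff``), and a deep pool
    representing slow nonspecific cellular binding with first-order
    association/dissociation constants ``k_ass``/``k_dis``.
    """

    Q_t: float  # ml/min, stomach blood flow
    V_e: float  # ml, vascular space volume
    fb_PSinf: float  # ml/min, influx permeation clearance (blood-unbound)
    fu_PSeff: float  # ml/min, efflux permeation clearance (tissue-unbound)
    V_T: float  # ml, precursor pool volume
    k_ass: float  # min⁻¹, precursor→deep association
    k_dis: float  # min⁻¹, deep→precursor dissociation
    V_i: float | None = None  # ml/g, vascular space per g tissue
    tissue_weight: float | None = None  # g
    V_stomach_literature: float = 1.1  # ml, whole-stomach volume from literature

    def __post_init__(self) -> None:
        _require_positive(
            Q_t=self.Q_t,
            V_e=self.V_e,
            fb_PSinf=self.fb_PSinf,
            fu_PSeff=self.fu_PSeff,
            V_T=self.V_T,
            k_ass=self.k_ass,
            k_dis=self.k_dis,
            V_stomach_literature=self.V_stomach_literature,
        )
        if self.V_i is not None and self.tissue_weight is not None:
            _require_positive(V_i=self.V_i, tissue_weight=self.tissue_weight)
            product = self.V_i * self.tissue_weight
            if abs(product - self.V_e) > 0.005 * max(self.V_e, product):
                raise InvalidArgumentError(
                    f"V_e = {self.V_e} inconsistent with V_i × tissue_weight = {product:.4g}"
                )

    @property
    def V_d(self) -> float:
        """Deep-pool equilibrium volume V_T·k_ass/k_dis, ml."""
        return self.V_T * self.k_ass / self.k_dis

    def v_stomach(self, convention: str = "eq_sum") -> float:
        """Whole-stomach volume under either bookkeeping convention.

        ``"eq_sum"`` returns V_T + V_d (the model's own pools);
        ``"literature"`` returns the fixed anatomical value.
        """
        if convention == "eq_sum":
            return self.V_T + self.V_d
        if convention == "literature":
            return self.V_stomach_literature
        raise InvalidArgumentError(f"unknown volume convention {convention!r}")


@dataclass(frozen=True)
class PDParams:
    """Indirect-response parameters for stomach acetylcholine.

    ACh is produced at a zero-order rate ``k_in`` and hydrolyzed by
    AChE with first-order constant ``k_out``; drug in the precursor
    pool inhibits the hydrolysis term with potency ``IC50``.
    """

    k_in: float  # nmol/g tissue/min
    k_out: float  # min⁻¹
    IC50: float  # μM

    def __post_init__(self) -> None:
        _require_positive(k_in=self.k_in, k_out=self.k_out, IC50=self.IC50)

    @property
    def R0(self) -> float:
        """Pre-dose steady-state ACh level k_in/k_out, nmol/g."""
        return self.k_in / self.k_out


@dataclass(frozen=True)
class ParameterSet:
    """A complete model parameterization (dose + PK + stomach + PD)."""

    dose: DoseRegimen
    blood: BloodPKParams
    stomach: StomachParams
    pd: PDParams | None = None
    extra: dict[str, Any] = field(default_factory=dict)


# Flat config keys, matching the symbol names the parameters are reported
# under. Units are fixed by the package conventions (min, ml, g, nmol, μM).
_FLAT_KEYS = (
    "dose V1 k1 k2 CLtot Rbp Qt Ve Vi tissue_weight "
    "fb_PSinf fu_PSeff VT kass kdis Vstomach kin kout IC50"
).split()


def params_from_dict(cfg: dict[str, Any]) -> ParameterSet:
    """Build a :class:`ParameterSet` from a flat key-value mapping."""
    unknown = set(cfg) - set(_FLAT_KEYS)
    if unknown:
        raise InvalidArgumentError(f"unknown parameter keys: {sorted(unknown)}")
    missing = {"dose", "V1", "k1", "k2", "CLtot", "Qt", "Ve",
               "fb_PSinf", "fu_PSeff", "VT", "kass", "kdis"} - set(cfg)
    if missing:
        raise InvalidArgumentError(f"missing parameter keys: {sorted(missing)}")
    dose = DoseRegimen(dose_per_kg=float(cfg["dose"]), R_bp=float(cfg.get("Rbp", 0.84)))
    blood = BloodPKParams(
        V1=float(cfg["V1"]), k1=float(cfg["k1"]), k2=float(cfg["k2"]),
        CL_tot=float(cfg["CLtot"]),
    )
    stomach = StomachParams(
        Q_t=float(cfg["Qt"]),
        V_e=float(cfg["Ve"]),
        fb_PSinf=float(cfg["fb_PSinf"]),
        fu_PSeff=float(cfg["fu_PSeff"]),
        V_T=float(cfg["VT"]),
        k_ass=float(cfg["kass"]),
        k_dis=float(cfg["kdis"]),
        V_i=float(cfg["Vi"]) if "Vi" in cfg else None,
        tissue_weight=float(cfg["tissue_weight"]) if "tissue_weight" in cfg else None,
        V_stomach_literature=float(cfg.get("Vstomach", 1.1)),
    )
    pd = None
    if {"kin", "kout", "IC50"} <= set(cfg):
        pd = PDParams(k_in=float(cfg["kin"]), k_out=float(cfg["kout"]),
                      IC50=float(cfg["IC50"]))
    return ParameterSet(dose=dose, blood=blood, stomach=stomach, pd=pd)


def params_to_dict(ps: ParameterSet) -> dict[str, float]:
    """Flatten a :class:`ParameterSet` to the on-disk key-value form."""
    out: dict[str, float] = {
        "dose": ps.dose.dose_per_kg,
        "Rbp": ps.dose.R_bp,
        "V1": ps.blood.V1,
        "k1": ps.blood.k1,
        "k2": ps.blood.k2,
        "CLtot": ps.blood.CL_tot,
        "Qt": ps.stomach.Q_t,
        "Ve": ps.stomach.V_e,
        "fb_PSinf": ps.stomach.fb_PSinf,
        "fu_PSeff": ps.stomach.fu_PSeff,
        "VT": ps.stomach.V_T,
        "kass": ps.stomach.k_ass,
        "kdis": ps.stomach.k_dis,
        "Vstomach": ps.stomach.V_stomach_literature,
    }
    if ps.stomach.V_i is not None:
        out["Vi"] = ps.stomach.V_i
    if ps.stomach.tissue_weight is not None:
        out["tissue_weight"] = ps.stomach.tissue_weight
    if ps.pd is not None:
        out.update(kin=ps.pd.k_in, kout=ps.pd.k_out, IC50=ps.pd.IC50)
    return out


def load_parameters(path: str | Path) -> ParameterSet:
    """Read a flat parameter config (JSON or YAML, by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise InvalidArgumentError(f"{path}: expected a flat mapping")
    return params_from_dict(cfg)


def dump_parameters(ps: ParameterSet, path: str | Path) -> None:
    path = Path(path)
    flat = params_to_dict(ps)
    if path.suffix.lower() in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(flat, sort_keys=False))
    else:
        path.write_text(json.dumps(flat, indent=2) + "\n")


def reference_parameters() -> ParameterSet:
    """The packaged reference parameterization of the rat study.

    Blood disposition and stomach transport parameters were estimated
    from concentration-time data after a 1.85 μmol/kg i.v. bolus;
    physiological constants (stomach blood flow, stomach volume,
    vascular space) come from the literature, and the AChE IC50 from
    an in vitro inhibition assay.
    """
    ref = resources.files("gastropbpk.data").joinpath("reference_params.json")
    cfg = json.loads(ref.read_text())
    return params_from_dict(cfg)
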