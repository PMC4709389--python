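"""End-to-end orchestration of the staged analysis workflow.

Stage order mirrors the study: blood fit → stomach fit → in vitro IC50
→ PD fit → coupled simulation and headline summaries.  The config is a
single mapping with sections ``design`` / ``parameters`` / ``stages``;
unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import __version__
from .estimate import FitOptions, fit_blood, fit_pd, fit_stomach
from .exceptions import ConfigurationError
from .invitro import fit_ic50, velocities_from_assay
from .params import (
    BloodPKParams,
    ParameterSet,
    PDParams,
    StomachParams,
    params_from_dict,
    reference_parameters,
)
from .simulate import simulate_coupled, summarize, threshold_crossing_time
from .synth import InVitroDesign, StudyDesign, generate_ach_dataset, generate_invitro_dataset, generate_pk_dataset
from .io import read_observations, write_observations

logger = logging.getLogger("gastropbpk")

_TOP_KEYS = {"design", "parameters", "stages", "inputs", "options"}
_STAGES = {"synth", "fit_blood", "fit_stomach", "fit_ic50", "fit_pd", "simulate"}


def run_pipeline(config: dict, out_dir: str | Path | None = None, seed: int = 0) -> dict:
    """Run the configured stages and return a summary report.

    The report always records parameter provenance (reference fixture vs
    fitted), the seed, solver tolerances, and the package version; when
    ``out_dir`` is given, fit results, simulation exports, and the
    report are written there.
    """
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")
    stages = config.get("stages", ["simulate"])
    bad = set(stages) - _STAGES
    if bad:
        raise ConfigurationError(f"unknown stages: {sorted(bad)}")

    params = (
        params_from_dict(config["parameters"])
        if "parameters" in config
        else reference_parameters()
    )
    provenance = {k: "config" if "parameters" in config else "reference_fixture"
                  for k in ("blood", "stomach", "pd")}
    design_cfg = config.get("design", {})
    design = StudyDesign(
        seed=int(design_cfg.get("seed", seed)),
        n_per_timepoint=int(design_cfg.get("n_per_timepoint", 6)),
        noise_cv=float(design_cfg.get("noise_cv", 0.10)),
    )
    opt_cfg = config.get("options", {})
    options = FitOptions(
        error_model=opt_cfg.get("error_model", "log_additive"),
        n_restarts=int(opt_cfg.get("n_restarts", 10)),
        seed=seed,
    )

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "version": __version__,
        "seed": seed,
        "solver": {"rtol": 1e-8, "atol": 1e-10, "method": "LSODA"},
        "stages": list(stages),
        "provenance": provenance,
        "fits": {},
    }

    data: dict = {}
    if "synth" in stages:
        if params.pd is None:
            raise ConfigurationError("synthesis requires PD parameters in the config")
        blood, stomach = generate_pk_dataset(params.dose, params.blood, params.stomach, design)
        ach = generate_ach_dataset(params.dose, params.blood, params.stomach, params.pd, design)
        data = {"blood": blood, "stomach_total": stomach, "ach": ach}
        data["invitro"] = generate_invitro_dataset(
            params.pd.IC50, 0.05, InVitroDesign(seed=design.seed)
        )
        if out is not None:
            write_observations([blood, stomach, ach], out / "observations.tsv")
            manifest = {"design": asdict(design), "truth": _flatten(params)}
            (out / "synth_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        logger.info("synthesized datasets (seed=%d, cv=%.3g)", design.seed, design.noise_cv)
    elif "inputs" in config:
        tables = read_observations(config["inputs"]["observations"])
        data.update(tables)

    blood_params = params.blood
    stomach_params = params.stomach
    pd_params = params.pd

    if "fit_blood" in stages:
        if "blood" not in data:
            raise ConfigurationError("fit_blood requested but no blood observations available")
        fr = fit_blood(data["blood"], params.dose, init=params.blood, options=options)
        report["fits"]["blood"] = json.loads(fr.to_json())
        blood_params = BloodPKParams(
            V1=fr.estimates["V1"], k1=fr.estimates["k1"],
            k2=fr.estimates["k2"], CL_tot=fr.estimates["CL_tot"],
        )
        provenance["blood"] = "fitted"

    if "fit_stomach" in stages:
        if "stomach_total" not in data:
            raise ConfigurationError("fit_stomach requested but no stomach observations available")
        init = {"VT": params.stomach.V_T, "fu_PSeff": params.stomach.fu_PSeff,
                "kass": params.stomach.k_ass, "kdis": params.stomach.k_dis}
        fr = fit_stomach(data["stomach_total"], blood_params, params.dose,
                         params.stomach, init=init, options=options)
        report["fits"]["stomach"] = json.loads(fr.to_json())
        stomach_params = StomachParams(
            Q_t=params.stomach.Q_t, V_e=params.stomach.V_e,
            fb_PSinf=params.stomach.fb_PSinf,
            fu_PSeff=fr.estimates["fu_PSeff"], V_T=fr.estimates["VT"],
            k_ass=fr.estimates["kass"], k_dis=fr.estimates["kdis"],
            V_stomach_literature=params.stomach.V_stomach_literature,
        )
        provenance["stomach"] = "fitted"

    ic50_invitro = None
    if "fit_ic50" in stages:
        if "invitro" not in data:
            raise ConfigurationError("fit_ic50 requested but no in vitro assay available")
        vel = velocities_from_assay(data["invitro"])
        ic = fit_ic50(vel["inhibitor_uM"].to_numpy(), vel["velocity_uM_per_s"].to_numpy())
        ic50_invitro = ic.ic50
        report["fits"]["ic50"] = {"IC50_uM": ic.ic50, "v0_uM_per_s": ic.v0,
                                  "hill": ic.hill, "converged": ic.converged}

    if "fit_pd" in stages:
        if "ach" not in data:
            raise ConfigurationError("fit_pd requested but no ACh observations available")
        if pd_params is None:
            raise ConfigurationError("fit_pd requires initial PD parameters")
        init = {"kin": pd_params.k_in, "kout": pd_params.k_out, "IC50": pd_params.IC50}
        fix = ic50_invitro if ic50_invitro is not None else None
        fr = fit_pd(data["ach"], params.dose, blood_params, stomach_params,
                    fix_ic50=fix, init=init, options=options)
        report["fits"]["pd"] = json.loads(fr.to_json())
        pd_params = PDParams(
            k_in=fr.estimates["kin"], k_out=fr.estimates["kout"],
            IC50=fr.estimates.get("IC50", fix if fix is not None else pd_params.IC50),
        )
        provenance["pd"] = "fitted"

    if "simulate" in stages:
        if pd_params is None:
            raise ConfigurationError("simulate stage requires PD parameters")
        sim = simulate_coupled(params.dose, blood_params, stomach_params, pd_params)
        summary = summarize(sim)
        i120 = int(np.argmin(np.abs(sim.time - 120.0)))
        headline = {
            "C_T_at_2h_uM": float(sim.dense_state(120.0)[1]),
            "crossing_2uM_min": threshold_crossing_time(sim, "C_T", 2.0, "down"),
            "max_C_d_uM": float(sim.C_d.max()),
            "ach_percent_baseline_at_2h": float(sim.percent_baseline[i120]),
        }
        headline["crossing_2uM_h"] = headline["crossing_2uM_min"] / 60.0
        report["summary"] = summary
        report["headline"] = headline
        if out is not None:
            sim.to_frame().to_csv(out / "simulation.tsv", sep="\t", index=False)

    if out is not None:
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
        logger.info("report written to %s", out / "report.json")
    return report


def _flatten(ps: ParameterSet) -> dict:
    from .params import params_to_dict

    return params_to_dict(ps)
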