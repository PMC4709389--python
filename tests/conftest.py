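"""Shared fixtures: the reference parameterization and expensive shared runs."""

import warnings

import numpy as np
import pytest

import gastropbpk as g


@pytest.fixture(scope="session")
def ref():
    """Reference parameter set (the study's fitted/physiological values)."""
    return g.reference_parameters()


@pytest.fixture(scope="session")
def ref_sim(ref):
    """Coupled PK/PD simulation of the reference parameterization over 48 h."""
    return g.simulate_coupled(ref.dose, ref.blood, ref.stomach, ref.pd)


@pytest.fixture(scope="session")
def zero_noise_data(ref):
    """Noise-free synthetic datasets on the exact study design."""
    design = g.StudyDesign(seed=1, noise_cv=0.0)
    blood, stomach = g.generate_pk_dataset(ref.dose, ref.blood, ref.stomach, design)
    ach = g.generate_ach_dataset(ref.dose, ref.blood, ref.stomach, ref.pd, design)
    return {"blood": blood, "stomach_total": stomach, "ach": ach}


@pytest.fixture(scope="session")
def staged_zero_noise_fits(ref, zero_noise_data):
    """Blood → stomach → PD staged fits on noise-free data (shared: slow)."""
    options = g.FitOptions(seed=1, n_restarts=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fb = g.fit_blood(
            zero_noise_data["blood"], ref.dose,
            init=g.BloodPKParams(V1=200.0, k1=0.2, k2=0.02, CL_tot=40.0),
            options=options,
        )
        blood_hat = g.BloodPKParams(
            V1=fb.estimates["V1"], k1=fb.estimates["k1"],
            k2=fb.estimates["k2"], CL_tot=fb.estimates["CL_tot"],
        )
        fs = g.fit_stomach(
            zero_noise_data["stomach_total"], blood_hat, ref.dose, ref.stomach,
            init={"VT": 0.1, "fu_PSeff": 0.01, "kass": 1e-4, "kdis": 1e-5},
            options=options,
        )
        stomach_hat = g.StomachParams(
            Q_t=ref.stomach.Q_t, V_e=ref.stomach.V_e, fb_PSinf=ref.stomach.fb_PSinf,
            fu_PSeff=fs.estimates["fu_PSeff"], V_T=fs.estimates["VT"],
            k_ass=fs.estimates["kass"], k_dis=fs.estimates["kdis"],
        )
        fp = g.fit_pd(
            zero_noise_data["ach"], ref.dose, blood_hat, stomach_hat,
            fix_ic50=ref.pd.IC50,
            init={"kin": 0.002, "kout": 0.003, "IC50": 2.0},
            options=options,
        )
    return {"blood": fb, "stomach": fs, "pd": fp,
            "blood_params": blood_hat, "stomach_params": stomach_hat}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
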