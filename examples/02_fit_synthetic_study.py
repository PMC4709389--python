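"""Staged parameter estimation on a synthetic replicate of the study.

Generates noisy blood, stomach, and ACh datasets on the exact in vivo
design (11 sampling times over 48 h, 6 rats per time point, destructive
sampling, 10 % lognormal noise), then runs the staged workflow: blood
disposition first, stomach transport with blood fixed, then the ACh
turnover parameters with the full PK model fixed and IC50 held at its
in vitro value.
"""

import warnings

import gastropbpk as g

warnings.filterwarnings("ignore")  # collinearity warnings are expected here

ps = g.reference_parameters()
design = g.StudyDesign(seed=1, noise_cv=0.10)
options = g.FitOptions(seed=1, n_restarts=5)

blood, stomach = g.generate_pk_dataset(ps.dose, ps.blood, ps.stomach, design)
ach = g.generate_ach_dataset(ps.dose, ps.blood, ps.stomach, ps.pd, design)
print(f"synthetic datasets: {len(blood)} blood, {len(stomach)} stomach, "
      f"{len(ach)} ACh observations")

fb = g.fit_blood(blood, ps.dose, options=options)
print("\nblood fit (truth in parentheses):")
print(f"  V1     = {fb.estimates['V1']:7.1f} ml/kg     (302)")
print(f"  CL_tot = {fb.estimates['CL_tot']:7.2f} ml/min/kg (56.9)")
print(f"  loglik = {fb.loglik:.1f}, AIC = {fb.aic:.1f}, n_obs = {fb.n_obs}")

blood_hat = g.BloodPKParams(V1=fb.estimates["V1"], k1=fb.estimates["k1"],
                            k2=fb.estimates["k2"], CL_tot=fb.estimates["CL_tot"])
fs = g.fit_stomach(stomach, blood_hat, ps.dose, ps.stomach,
                   init={"VT": 0.1, "fu_PSeff": 0.01, "kass": 1e-4, "kdis": 1e-5},
                   options=options)
print("\nstomach fit:")
print(f"  VT       = {fs.estimates['VT']:.4f} ml    (0.133)")
print(f"  fu_PSeff = {fs.estimates['fu_PSeff']:.5f} ml/min (0.00600)")
print("  note: VT and fu_PSeff are ratio-identified from stomach data —")
print(f"  their ratio {fs.estimates['VT']/fs.estimates['fu_PSeff']:.1f} "
      f"is stable (truth 22.2) while each alone is noise-sensitive")

fp = g.fit_pd(ach, ps.dose, ps.blood, ps.stomach, fix_ic50=ps.pd.IC50,
              init={"kin": 0.003, "kout": 0.004, "IC50": 2.0}, options=options)
print("\nACh fit (IC50 fixed at the in vitro 1.79 uM):")
print(f"  k_in  = {fp.estimates['kin']:.5f} nmol/g/min (0.00314)")
print(f"  k_out = {fp.estimates['kout']:.5f} 1/min     (0.00415)")
print(f"  baseline k_in/k_out = {fp.estimates['kin']/fp.estimates['kout']:.3f} "
      f"nmol/g (0.757)")
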