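"""Forward-simulate gastric drug distribution and the ACh response.

Uses the packaged reference parameterization (1.85 μmol/kg i.v. bolus in
rat) and prints the quantities that characterize the model's behavior:
when the precursor pool — the site of AChE inhibition — falls back
through 2 μM, how small the deep pool stays, and how far stomach ACh
rises above its pre-dose baseline.
"""

import numpy as np

import gastropbpk as g

ps = g.reference_parameters()
sim = g.simulate_coupled(ps.dose, ps.blood, ps.stomach, ps.pd)

crossing = g.threshold_crossing_time(sim, "C_T", 2.0, direction="down")
summary = g.summarize(sim)
pb_2h = 100.0 * sim.dense_state(120.0)[3] / ps.pd.R0

print(f"blood C(0)                 : {sim.C1[0]:.2f} uM  (dose/V1)")
print(f"peak precursor pool        : {summary['C_T']['c_max']:.1f} uM "
      f"at {summary['C_T']['t_max_min']:.0f} min")
print(f"precursor pool < 2 uM after: {crossing:.0f} min ({crossing/60:.2f} h)")
print(f"max deep pool              : {np.max(sim.C_d):.4f} uM (stays far below 0.01)")
print(f"ACh at 2 h                 : {pb_2h:.1f} % of baseline")
print(f"ACh peak                   : {summary['percent_baseline']['peak']:.1f} % "
      f"at {summary['percent_baseline']['t_peak_h']:.1f} h")
print()
print("The ACh peak lags the drug peak by hours: inhibiting hydrolysis shifts")
print("the production/loss balance slowly, at a rate set by k_out.")
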