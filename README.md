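# gastropbpk

Physiologically-based pharmacokinetic/pharmacodynamic (PBPK/PD) modeling of
acotiamide distribution to rat stomach and its inhibition of
acetylcholinesterase (AChE).

Acotiamide is a gastroprokinetic AChE inhibitor used for functional
dyspepsia. Its pharmacological effect is exerted in stomach tissue, not in
blood, and gastric uptake is carrier-mediated and slow. This package is for
pharmacokineticists and modelers who want to simulate or re-estimate that
system: it links a two-compartment blood disposition model to a
three-pool stomach tissue model and an indirect-response model for stomach
acetylcholine (ACh), and provides staged nonlinear least-squares estimation,
in vitro IC50 analysis, and a synthetic-data generator that replicates the
original study design.

## Model

Blood after an i.v. bolus is biexponential,

    C1(t) = D(α − k21)/(V1(α − β)) e^(−αt) + D(k21 − β)/(V1(α − β)) e^(−βt),

with α, β the roots of s² − (k10 + k12 + k21)s + k10·k21 = 0 and
k10 = CL_tot/V1. Blood drives three well-stirred stomach pools — vascular
space C_e (flow Q_t), a precursor pool C_T reached by carrier-mediated
uptake (influx clearance f_b·PS_inf, efflux f_u·PS_eff), and a deep pool
C_d of slow nonspecific binding (first-order k_ass/k_dis, equilibrium
volume V_d = V_T·k_ass/k_dis):

    V_e dC_e/dt = Q_t(C1 − C_e) − f_b·PS_inf·C_e + f_u·PS_eff·C_T
    V_T dC_T/dt = f_b·PS_inf·C_e + V_d·C_d·k_dis − f_u·PS_eff·C_T − V_T·C_T·k_ass
    V_d dC_d/dt = V_T·C_T·k_ass − V_d·C_d·k_dis

Measured stomach tissue maps to the lumped concentration
C_stomach = (V_T·C_T + V_d·C_d)/V_stomach. Stomach ACh follows an
indirect-response model in which precursor-pool drug inhibits the
hydrolysis (loss) term:

    dR/dt = k_in − k_out·(1 − C_T/(IC50 + C_T))·R,    R(0) = k_in/k_out.

The package ships the study's parameter values as a reference fixture
(`gastropbpk.reference_parameters()`), including the in vitro IC50 of
1.79 μM.

## Worked example

```python
import gastropbpk as g

ps = g.reference_parameters()
sim = g.simulate_coupled(ps.dose, ps.blood, ps.stomach, ps.pd)
print(g.threshold_crossing_time(sim, "C_T", 2.0, direction="down"))
```

Running `python examples/01_simulate_tissue_distribution.py` prints:

```
blood C(0)                 : 6.13 uM  (dose/V1)
peak precursor pool        : 17.0 uM at 9 min
precursor pool < 2 uM after: 112 min (1.87 h)
max deep pool              : 0.0046 uM (stays far below 0.01)
ACh at 2 h                 : 133.6 % of baseline
ACh peak                   : 136.8 % at 2.9 h
```

Read: after a 1.85 μmol/kg bolus the precursor pool — where AChE is
inhibited — stays above the in vitro IC50-scale threshold of 2 μM for
almost two hours; the deep pool never reaches pharmacologically relevant
levels; and ACh rises to about a third above baseline at two hours, peaking
later than the drug itself because an indirect response integrates, rather
than tracks, its driver.

Other examples: `examples/02_fit_synthetic_study.py` (synthetic study +
staged estimation, including the V_T/f_u·PS_eff ratio-identifiability
caveat) and `examples/03_invitro_ic50.py` (initial velocities and the
inhibition curve). A thin CLI mirrors the library:
`gastropbpk synth|simulate|fit-blood|fit-stomach|fit-pd|fit-ic50|run`.

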