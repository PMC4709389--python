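# Methods

## Model structure and assumptions

The system couples three layers, fitted and simulated sequentially the way
the underlying study was analyzed:

1. **Blood disposition.** Two-compartment mammillary model after an i.v.
   bolus, used in closed biexponential form. `k1` is read as the
   central→peripheral micro constant (k12) and `k2` as peripheral→central
   (k21); elimination is k10 = CL_tot/V1. This is the only reading under
   which the published parameter values yield real, distinct, positive
   hybrid exponents (α ≈ 0.328 min⁻¹, β ≈ 0.0180 min⁻¹), and it is asserted
   at construction time. Blood is a one-way forcing: stomach uptake does not
   deplete it. The error of that approximation is bounded by the stomach's
   share of total distribution volume and is far below solver tolerance.

2. **Stomach tissue.** Three well-stirred pools (vascular space, precursor
   pool, deep pool). The vascular space exchanges with arterial blood at the
   tissue blood flow Q_t and feeds the precursor pool through carrier-
   mediated influx (f_b·PS_inf) and passive-like efflux (f_u·PS_eff); the
   deep pool represents slow nonspecific cellular binding. The deep-pool
   balance is written with k_dis as the exit constant,
   V_d·dC_d/dt = V_T·C_T·k_ass − V_d·C_d·k_dis: this is the unique choice
   that conserves mass against the precursor-pool equation and reproduces
   the equilibrium volume V_d = V_T·k_ass/k_dis. The variant with k_ass in
   the exit term is retained behind `deep_pool_exit="k_ass"` for comparison;
   it leaks mass and is never the default. Initial stomach concentrations
   are zero; the vascular space equilibrates with time constant
   (Q_t + f_b·PS_inf)/V_e ≈ 2.9 min⁻¹, so the choice is immaterial after
   ~2 min and is deliberately not configurable.

3. **ACh turnover.** Indirect response with inhibition of the loss term:
   dR/dt = k_in − k_out(1 − C_T/(IC50 + C_T))R, baseline R0 = k_in/k_out.
   The driving concentration is the precursor pool, where the carrier
   delivers drug and AChE acts. The PD state is integrated jointly with the
   PK states in a single state vector (no interpolation error); a sequential
   path on a supplied C_T(t) exists for externally supplied profiles.

**Units.** Minutes, ml, g, nmol throughout; concentrations nmol/ml ≡ μM;
ACh in nmol/g wet tissue. Dose (μmol/kg) and V1 (ml/kg) enter only through
dose/V1, so body weight never appears.

**Whole-stomach lumping.** Two conventions for V_stomach in
C_stomach = (A_T + A_d)/V_stomach coexist: the model's own pool sum
V_T + V_d (≈ 1.01 ml at the reference values; default for lumped
predictions, so that uniform pool concentrations lump to themselves) and
the anatomical literature volume 1.1 ml (default for reporting volume
fractions, e.g. V_T is 12.1 % of stomach volume). Both are exposed via
`volume_convention=`.

## Parameters

| symbol | meaning | unit | reference value |
|---|---|---|---|
| V1 | central volume | ml/kg | 302 |
| k1, k2 | central↔peripheral micro constants | min⁻¹ | 0.126, 0.0313 |
| CL_tot | total clearance | ml/min/kg | 56.9 |
| R_bp | blood/plasma ratio | — | 0.84 |
| Q_t | stomach blood flow | ml/min | 1.1 |
| V_e | vascular space (V_i × tissue weight = 0.401 × 1.1) | ml | 0.441 |
| f_b·PS_inf | influx permeation clearance | ml/min | 0.174 |
| f_u·PS_eff | efflux permeation clearance | ml/min | 0.00600 |
| V_T | precursor pool volume | ml | 0.133 |
| k_ass, k_dis | deep-pool association/dissociation | min⁻¹ | 3.20e−5, 4.85e−6 |
| V_stomach | anatomical stomach volume | ml | 1.1 |
| k_in | ACh production | nmol/g/min | 0.00314 |
| k_out | ACh hydrolysis | min⁻¹ | 0.00415 |
| IC50 | AChE inhibition potency (in vitro) | μM | 1.79 |

The fixture (`data/reference_params.json`) carries exactly these values;
physiological entries (Q_t, V_e, V_stomach, f_b·PS_inf) are fixed inputs in
the staged fits, mirroring their literature provenance.

## Numerics

Rate constants span 2.9 min⁻¹ to 4.9e−6 min⁻¹, so the default solver is
LSODA (stiff-capable) with rtol 1e−8, atol 1e−10 μM, dense output enabled.
The default horizon is 2880 min with an output grid that always contains
the experimental sampling times plus 500 log-spaced points. Threshold
crossings are located on the dense interpolant by bracketing and Brent
refinement to ±0.01 min, never by grid lookup; when a series crosses a
threshold more than once in the same direction, the latest crossing is
returned (the pharmacologically relevant one for "concentration falls
below X"). Verified against two independent oracles in the test suite: the
exact eigen/matrix-exponential solution of the linear stomach system under
biexponential forcing (agreement 1e−6 relative over 48 h) and fixed-step
RK4 at h = 0.01 min (1e−5 over 8 h).

## Estimation

Staged bounded least squares in log-parameter space (positivity by
construction), scipy TRF, 10 seeded multistarts drawn log-uniform within
±10× of the initial values; the best converged restart wins, and a restart
reaching machine-level residuals short-circuits the rest. The
finite-difference step for Jacobians is 1e−4 in log space — far above the
ODE solver's relative tolerance, which would otherwise dominate derivative
estimates. Default residual scale is log-concentration (≈ proportional
error), appropriate for data spanning three decades; additive and
proportional scales are options. The Gaussian log-likelihood profiles the
error variance at σ̂² = RSS/n (σ floor 1e−12 guards perfect fits), and
AIC = −2·loglik + 2·p with p = structural parameters + 1 profiled variance
per dataset; the convention is configurable and always reported, since
published parameter counts for such fits are rarely decomposable.
Replicate animals enter as individual observations (naive pooling —
destructive sampling makes them independent); per-time means are available
upstream. A sensitivity-collinearity report warns (never fails) when the
maximum |pairwise correlation| of Jacobian columns exceeds 0.999.

**Identifiability.** From lumped stomach concentrations alone, V_T and
f_u·PS_eff are ratio-identified: both the quasi-equilibrium amplitude
(f_b·PS_inf/f_u·PS_eff scaled by V_T) and the precursor equilibration time
(≈ V_T/f_u·PS_eff) constrain only their ratio, and the pair is separated
only by the small backflux term f_u·PS_eff·C_T in the vascular balance
(~1.5 % of the blood exchange flux). Likewise k_dis is barely informed
within 48 h (k_dis·t ≤ 0.014), leaving k_ass/k_dis ratio-identified.
Consequently noise-free data recover all parameters exactly (the
information is nonzero), but at realistic noise the marginal uncertainty of
V_T alone is on the order of its magnitude: a Fisher analysis at the
reference values (11 times × 6 rats, 10 % CV) gives SD(ln V_T) ≈ 4. Users
should interpret fitted V_T and f_u·PS_eff jointly, or fix one externally.
k_ass and the well-designed blood/PD parameters do not share this problem.

## Synthetic data

The generator reproduces the study design: 1.85 μmol/kg i.v. bolus;
blood/stomach sampling at 5, 10, 15, 30 min and 1, 2, 4, 6, 8, 24, 48 h;
ACh on the 5 min–4 h subset; 6 rats per time point, each contributing one
terminal sample (no within-animal correlation, matching destructive
sampling). Noise is multiplicative lognormal with unit mean; the default
CV of 10 % reflects standard errors reported as sitting inside the plotted
symbols — small, but the true magnitude is unpublished, so the CV is an
explicit design knob. The absolute ACh baseline is likewise unpublished;
the generator uses k_in/k_out ≈ 0.757 nmol/g and treats percent-of-baseline
as the primary comparison scale. Each dataset kind (blood, stomach, ACh,
in vitro) draws from its own deterministic substream of the master seed, so
regenerating one never perturbs another. The in vitro generator emulates a
zero control plus log-spaced concentrations spanning 0.05–25 μM
(individual levels were not published), linear product formation over
0–60 s, triplicate, one multiplicative noise factor per replicate velocity.

What passing tests on these data do **not** show about real data:
between-animal parameter variability, assay quantification limits and
censoring, model misspecification (the generator and the fitted model share
a structure), and any error-magnitude mismatch with the real assays.

## In vitro analysis

Initial velocities are ordinary least-squares slopes of product vs time
with free intercept, restricted to the 0–60 s initial-rate window. The
inhibition curve is v = v0/(1 + (I/IC50)^h) with h = 1 by default —
the same hyperbolic form as the in vivo inhibition term — fitted in
(v0, log IC50) space; the Hill exponent can be freed. A fitted IC50 outside
the tested concentration range triggers a boundary warning. Absolute
velocities are fitted; percent-of-control is derived output only.

## Design choices that were genuinely open

- Whether V_stomach in the lumping equation is V_T + V_d or the anatomical
  1.1 ml: both implemented (see above); they differ by ~9 %.
- The micro-constant reading of k1/k2 (see Model structure): an inference,
  but the only self-consistent one.
- Error model and naive pooling (see Estimation): the published analysis is
  silent on both.
- The inhibition-curve functional form is not stated in the source
  material; the hyperbola consistent with the in vivo model is the default.
- Parameter-count convention in AIC: structural + 1; configurable because
  published counts cannot be reproduced unambiguously.

## Problem sizes

The default test and acceptance runs use the study-sized designs (66 PK
observations, 42 ACh observations, 24 assay velocity courses), dense output
grids of ~500–1000 points over 48 h, and a 20001-point grid for the
deep-pool maximum; oracle cross-checks use 48 000 RK4 steps over 8 h. These
are the package's working sizes, chosen to resolve all model time scales.

## Known limitations

- No between-animal variability or mixed-effects machinery; naive pooling
  only.
- Only i.v. bolus dosing; no oral/subcutaneous routes, no human scaling.
- No uncertainty quantification beyond the collinearity report (no
  bootstrap or profile likelihood).
- The V_T/f_u·PS_eff and k_ass/k_dis ridges mean point estimates of those
  parameters individually should not be over-interpreted (see
  Identifiability).
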