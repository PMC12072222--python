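# Methods

## Model structure and assumptions

The victim (CP-I or a dosed drug) is a lumped three-compartment linear
system: central plasma, liver extracellular water, liver intracellular
water. CP-I is synthesized entirely in blood (zero-order, k_syn per kg
body weight) and eliminated by renal excretion from plasma and by
sequential hepatic uptake → biliary secretion. Flow terms act on blood
concentrations (C_b = C_p · B/P); renal clearance is plasma-referenced.
Unbound fractions: extracellular liver binding equals plasma binding
(fu_plasma); the intracellular exit terms (biliary efflux and passive
backflux) both act on the same intracellular unbound pool, so the
intracellular binding constant cancels in the net clearance and is set
to 1.

Distribution is deliberately minimal — a 5 L central plasma volume plus
liver water (0.283 L extracellular, 1.04 L intracellular at 70 kg). The
baseline and all steady-state interaction ratios are
distribution-insensitive (they depend only on clearances); what the small
central volume does affect is the *speed* at which the biomarker tracks a
changing inhibitor exposure. With V_c = 5 L and CL ≈ 23 L/h the biomarker
re-equilibrates within ~1 h, i.e. quasi-statically. Trial-design results
are therefore read as orderings and magnitude classes (CmaxR vs AUCR
gaps), not as exact percentages, and the biomarker Tmax in this model is
close to the inlet-exposure Tmax (≈ 1–3 h) rather than the ~5 h seen
clinically. LogP and pKa are carried for provenance only; no
tissue-partition prediction is attempted.

Because every transfer term is linear, the baseline steady state is
solved exactly as a 3×3 linear system; the stiff integrator (LSODA,
rtol 1e-8, atol 1e-10 nmol, output grid ≤ 0.1 h, restarted at inhibitor
dose times) is used only for time-varying exposure. At steady state the
hepatic side is *exactly* the well-stirred model with the
extended-clearance net term CL_int,net = (ΣCL_up + CL_pd)·CL_bile/(CL_bile
+ CL_pd); tests verify ODE/linear agreement to <0.01 % and
dynamic-vs-static agreement to <2 % under constant exposure.

A consequence worth noting: because CL_bile (0.612 µL/min/10⁶ cells) is
far below uptake (~137), passive diffusion is a futile cycle — raising
CL_pd *lowers* net hepatic clearance (more backflux than extra influx)
and raises the baseline. Monotone-decrease of the baseline in a clearance
term holds for the renal, uptake and efflux terms only.

## Parameters

Compound inputs (CP-I): MW 654.71 g/mol, B/P 0.628, fu_plasma 0.069,
CL_R 2.3 L/h (clinically observed weighted mean), k_syn 0.0036 (White /
Asian-Indian male), 0.0032 (female), 0.0024 / 0.0021 (Japanese M/F)
mg/day/kg; per-cell clearances CL_pd 0.76, OATP1B1 106, OATP1B3 31,
MRP2 0.612 µL/min/10⁶ cells (RAF 1).

Physiology (70 kg reference): liver 1650 g, hepatocellularity 99×10⁶
cells/g, hepatic blood flow 87 L/h, portal blood flow 66 L/h, hematocrit
0.45. Allometry: flows and whole-liver intrinsic clearances scale with
(BW/70)^0.75 (implemented by carrying the exponent on the liver-mass
scaling term), volumes with BW^1.0. CL_R is **not** allometrically scaled:
it is treated as the clinically observed per-subject value, with
between-subject variation handled by the population sampler. Scaling it
would move the predicted F:M baseline ratio from 0.845 to ~0.855; the
unscaled convention is the one consistent with treating CL_R as a
clinical input.

The hepatic activity scaler γ multiplies all four hepatocyte-level
intrinsic clearances uniformly. It is the explicit, testable stand-in for
platform-level in-vitro-to-in-vivo reconciliation: calibrated by a
monotone bracketing root-find on log γ against the exact steady state,
with a closed-form well-stirred inversion as independent oracle. The
default target fe = 0.10 at the White-male-TT reference gives γ ≈ 0.802
(target css = 0.685 nM gives γ ≈ 0.828, fe = 9.8 %).

## Covariates

OATP1B1 activity factors: ethnicity — Japanese 0.58 of White (measured
abundance); Asian-Indian kept at the White level (no separate datum;
configurable). Genotype — TT 1.0; CC 0.4409, *calibrated* so the White
mixed-sex CC:TT baseline ratio is 1.4 with hepatic flow limitation
accounted for (a naive uptake-limited back-calculation would suggest
~0.6, but at fu_B·CL_int ≈ 53 L/h against Q_H = 87 L/h the flow term
damps the effect of any uptake change, so a deeper activity reduction is
needed); TC 0.72, the gene-dose midpoint.
`covariates.calibrate_genotype_multiplier` re-derives the factor for
other targets. Demographics: White 70/60 kg (M/F), Japanese and
Asian-Indian 65/52 kg. Reported fT values follow the CL_int ratio
(fT 69/20 % at fe 10 %); per-transporter RAFs allow configuring any other
effective isoform split.

## Interactions and Ki estimation

The inhibition driver is the dynamic unbound liver-inlet concentration,
I_u = fu·(C_sys + ka·A_gut/Q_portal,plasma); inhibitor disposition is an
analytic 1-/2-compartment model with first-order absorption, superposed
across doses (eigendecomposition; dose proportionality and superposition
are exact and tested). IC50 values are used directly as K_i where only
IC50s exist (probe concentration ≪ Km assumed). Interaction windows are
explicit arguments; the convention is the inhibitor dosing day for
single-dose designs and the certified steady-state day (day-over-day AUC
change < 0.5 %) for multiple-dose designs.

K_i estimation matches the simulated AUCR (default) or CmaxR to the
observed ratio by bisection on log K_i over [1e-6, 1e4] µM, scaling both
OATP1B isoform K_i values by one factor (the in vitro OATP1B1:OATP1B3
ratio is preserved — a single interaction ratio cannot identify the
isoforms separately). Observations at or above the blockade ceiling
1/(CL share of non-inhibitable pathways) raise an explicit infeasibility
error naming the ceiling. The profile least-squares estimator minimises
squared log-concentration residuals and reports a curvature-based SE of
log10 K_i; flat objectives (zero-dose) are flagged non-identifiable.

Renal-fraction sensitivity repartitions CL_R vs hepatic clearance at
fixed total clearance (baseline conserved to <0.1 %), re-estimates K_i,
and forward-predicts a downstream victim AUCR. The downstream default is
a synthetic "generic statin-like" victim (combined OATP1B transported
fraction 0.70, fe 0.10), administered as a central bolus — its AUCR is
the informative metric (an instantaneous peak is inhibition-independent).
With the flow-aware static oracle the K_i fold across fe 0→0.15 at an
observed AUCR of 4.6 is ≈ 3.1; the dynamic estimate with a fluctuating
strong inhibitor is larger (≈ 10-fold with the illustrative
rifampicin-like exposure), consistent with the direction that
peaky exposure amplifies the sensitivity.

## Trial design

Virtual inhibitors: 1-compartment, V 115 L, ka 1 h⁻¹, fu 0.1, CL 20 L/h
(t½ ≈ 4 h) or 2.66 L/h (t½ ≈ 30 h), K_i 0.1 µM on both isoforms; the
once-daily dose is solved (exactly, by linearity) so the steady-state
unbound inlet Cmax/K_i hits the class ratio — weak 0.5, moderate 3,
strong 20. Regimens cover ≥ 7 half-lives. Because these disposition
parameters are package choices, the §-level percentages are validated as
orderings and class bounds: CmaxR ≥ AUCR everywhere, the CmaxR–AUCR gap
larger for short than long half-life at matched potency, and the
sparse-sampling deviation 0 % at Tmax, increasing monotonically away from
it. The sparse-sampling deviation is defined on the ratio elevation above
the control baseline, 100·(Cmax − C(t))/(Cmax − css); the alternative
(deviation of the raw ratio) would only shrink the numbers.

## Synthetic data

Generators are pure functions of (configuration, seed). The baseline
panel draws per-subject true baselines as the scenario model prediction
times a median-preserving log-normal between-subject factor (default CV
0.35) and multiplies a residual factor (CV 0.10) onto observations. The
interaction generator simulates paired control/treatment profiles at a
known true K_i with multiplicative residual error (default CV 0.20,
sampling at 0–24 h post-dose), keeping the truth record as a JSON
sidecar. Population variability applies shared log-normal factors to the
OATP1B uptake activities (CV 0.35), k_syn (0.25), CL_R (0.30) and body
weight (0.15) — the standard structure for concentration data; real
datasets additionally carry assay bias, LLOQ censoring and
study-to-study heterogeneity that these fixtures deliberately omit, so
passing recovery tests demonstrate estimator correctness under the
assumed error model, not robustness to real-world artifacts.

## Problem sizes and numerical choices

Test and acceptance runs use a 70-kg representative subject; population
checks use n = 40–1000 subjects; the noisy-recovery study uses 100
replicates of a 12-sample single-subject profile at 20 % residual CV.
Bisection tolerances: calibration to <0.1 % of target (achieved ~1e-10),
ratio matching to 1e-4 relative, profile fit xatol 1e-4 on log10 K_i.
Ties on the exposure grid resolve to the earliest time (argmax). Grids
are ≤ 0.1 h (0.05 h for interaction windows).

## Known limitations

No enterohepatic recirculation, no mechanistic kidney (renal transporter
inhibition, e.g. on OAT1/3, is not represented), no tissue-composition
Kp prediction, no induction or time-dependent inhibition, no
age/ontogeny effects, and genotype effects only on OATP1B1. The shipped
inhibitor configurations are structural placeholders; quantitative
reproduction of a specific clinical study requires that study's inhibitor
PK parameters and demographic details.
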