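# Illustrative strong OATP1B inhibitor, NON-VALIDATED disposition.
# The inhibition constants are published in vitro unbound Ki values for
# rifampicin; the PK parameters are plausible single-compartment values for
# structural and synthetic-data work only.  Supply study-specific PK
# parameters for quantitative reproduction of any clinical trial.
name: rifampicin-like (illustrative)
molecular_weight_g_mol: 822.94
fu_plasma: 0.17
blood_plasma_ratio: 0.9
ka_per_h: 1.15
f_abs: 1.0
cl_over_f_L_h: 12.0
v_central_L: 53.0
q_inter_L_h: 0.0
v_peripheral_L: 0.0
ki_uM:
  OATP1B1: 0.16
  OATP1B3: 0.088
ki_source: in_vitro
regimen:
  dose_mg: 600
  interval_h: 24
  n_doses: 1
  start_time_h: 0
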