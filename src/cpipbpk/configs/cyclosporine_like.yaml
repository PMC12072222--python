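# Illustrative moderate OATP1B inhibitor, NON-VALIDATED disposition.
# Inhibition constants are published in vitro unbound Ki values for
# cyclosporine; PK parameters are plausible placeholders.
name: cyclosporine-like (illustrative)
molecular_weight_g_mol: 1202.6
fu_plasma: 0.066
blood_plasma_ratio: 1.36
ka_per_h: 0.7
f_abs: 1.0
cl_over_f_L_h: 30.0
v_central_L: 100.0
q_inter_L_h: 0.0
v_peripheral_L: 0.0
ki_uM:
  OATP1B1: 0.019
  OATP1B3: 0.032
ki_source: in_vitro
regimen:
  dose_mg: 100
  interval_h: 24
  n_doses: 1
  start_time_h: 0
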