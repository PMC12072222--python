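# Illustrative weak OATP1B inhibitor, NON-VALIDATED disposition.
# Inhibition constants are published in vitro IC50 values for probenecid
# used as Ki (probe concentration well below Km assumed); PK parameters are
# plausible placeholders.
name: probenecid-like (illustrative)
molecular_weight_g_mol: 285.36
fu_plasma: 0.12
blood_plasma_ratio: 0.55
ka_per_h: 1.0
f_abs: 1.0
cl_over_f_L_h: 1.0
v_central_L: 11.0
q_inter_L_h: 0.0
v_peripheral_L: 0.0
ki_uM:
  OATP1B1: 167.0
  OATP1B3: 76.0
ki_source: in_vitro
regimen:
  dose_mg: 1000
  interval_h: 24
  n_doses: 1
  start_time_h: 0
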