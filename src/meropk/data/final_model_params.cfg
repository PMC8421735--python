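# Final population PK parameter estimates: meropenem, septic children on ECLS.
# Units: mg, L, h; eCRCL in ml/min/1.73m2. omega/sigma are SDs on the log scale.
cl_typical = 7.6
v1_typical = 21.4
ecrcl_slope = 0.0035
ecrcl_ref = 150
bw_ref = 12
sc = 0.257
flow_per_kg = 0.045
v2 = 0.025
# Reported between-subject dispersion 0.557 / 0.562 is treated as the
# eta VARIANCE; the values below are the corresponding log-scale SDs.
# (Reading the reported numbers directly as SDs systematically
# over-predicts every published attainment probability; see docs.)
omega_cl = 0.7463243932521    # sqrt(0.557)
omega_v1 = 0.7496665925596    # sqrt(0.562)
sigma_plasma = 0.575
sigma_effluent = 0.284
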