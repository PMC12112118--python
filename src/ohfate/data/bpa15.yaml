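# Bisphenol A anodic oxidation, SnO2-MWCNT@SS anode, 15 mA/cm2, 5 h.
# Concentrations in files are normalised by c0; times are seconds.
name: bpa15
species: [BPA, P_tr, P_or, CO2]
c0_mol_per_L: 1.31e-4
rate_constants_per_M_s: [1.002e10, 3.92e10, 1.387e10]
h2o2_poly:
  b_coeffs: [3.09e-2, 3.39e-4, -3.10e-8, 8.81e-13]
  t_max_s: 18000.0
  fit_r2: 0.977
k_prop: 1.0e-10
current_density_mA_cm2: 15.0
duration_s: 18000.0
sample_interval_s: 3600.0
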