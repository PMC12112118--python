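# Rhodamine B anodic oxidation, same anode, 20 mA/cm2, 3 h, 50 ppm.
# The H2O2 shape is an electrode characteristic; only k scales with j,
# resolved here through the calibrated linear current-density law.
name: rhodamine20
species: [RhB, P1, P2, CO2]
c0_mol_per_L: 1.04e-4
rate_constants_per_M_s: [9.0e9, 1.2e10, 1.2e10]
h2o2_poly:
  b_coeffs: [3.09e-2, 3.39e-4, -3.10e-8, 8.81e-13]
  t_max_s: 18000.0
current_density_mA_cm2: 20.0
current_law:
  slope_cm2_per_mA: 6.48e-12
  intercept: 8.55e-12
duration_s: 10800.0
sample_interval_s: 3600.0
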