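# Digital (dSiPM) camera preset: Philips Vereos-like.
# Rate models: singles in Mcps, activity concentration in kBq/mL.
name: vereos
axial_fov_mm: 164.0
# Symmetric energy acceptance window around 511 keV (width in keV); the
# window width is published, its bounds are not — symmetry is an assumption.
energy_window_kev: 164.0
scatter_fraction: 0.30
prompts_per_single: 0.10
# Scale of the rate-squared randoms model R = k * S^2 (Mcps^-1), chosen so
# that R = T at roughly twice the NECR-peak activity (54 kBq/mL); not a
# published value.
randoms_coeff_per_mcps: 7.264e-4
forward_rate_model:            # S = f(A), Mcps from kBq/mL
  a: 183.6
  b: 0.001547
  c: -183.2
  d: -0.006269
  r_squared: 1.0000
  rmse: 0.07143
  direction: A_to_S
inverse_rate_model:            # A = f(S), kBq/mL from Mcps
  a: -117.9
  b: -0.001315
  c: 117.6
  d: 0.004609
  r_squared: 1.0000
  rmse: 0.06627
  direction: S_to_A
# Timing resolution is rate-independent for the digital camera.
tof_fwhm_ps_vs_mcps:
  - [0.0, 326.0]
energy_res_pct_vs_mcps:
  - [0.0, 11.0]
metadata:
  detector: digital SiPM (dSiPM), one-to-one crystal coupling
  n_photodetectors: 23040
  n_trigger_circuits: 5760
  trigger_domain_cm2: 0.64
  crystal_length_mm: 19
  necr_peak_activity_kbq_ml: 54
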