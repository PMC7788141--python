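# Analog (PMT) camera preset: Philips Ingenuity TF-like.
# Rate models: singles in Mcps, activity concentration in kBq/mL.
name: ingenuity
axial_fov_mm: 180.0
energy_window_kev: 276.0
scatter_fraction: 0.30
prompts_per_single: 0.10
# R = k * S^2 scale chosen so that R = T at roughly twice the NECR-peak
# activity (24 kBq/mL); not a published value.
randoms_coeff_per_mcps: 1.1916e-3
forward_rate_model:            # S = f(A), Mcps from kBq/mL
  a: 76.42
  b: 0.006298
  c: -73.95
  d: -0.020330
  r_squared: 1.0000
  rmse: 0.22910
  direction: A_to_S
inverse_rate_model:            # A = f(S), kBq/mL from Mcps
  a: 368.9
  b: 0.004056
  c: -370.2
  d: 0.002680
  r_squared: 0.9999
  rmse: 0.22390
  direction: S_to_A
# Timing resolution deteriorates with singles rate (dead time / pile-up in
# large trigger domains); anchors are measured (rate, FWHM) pairs.
tof_fwhm_ps_vs_mcps:
  - [5.8, 621.0]
  - [21.7, 732.0]
  - [33.2, 847.0]
  - [39.5, 899.5]
energy_res_pct_vs_mcps:
  - [5.8, 11.3]
  - [39.5, 12.4]
metadata:
  detector: photomultiplier tubes (PMT)
  n_photodetectors: 420
  n_trigger_circuits: 28
  trigger_domain_cm2: 132.48
  crystal_length_mm: 22
  necr_peak_activity_kbq_ml: 24
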