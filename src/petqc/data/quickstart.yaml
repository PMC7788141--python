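# Small end-to-end run: decay series on the digital preset, count rates,
# rate-model refits, resolutions, routine statistics and a light
# kernel-mismatch demo.
seed: 7
preset: vereos
out_dir: results/quickstart
simulate:
  initial_kbq_ml: 45.0
  half_life_s: 6586.2        # F-18
  n_recordings: 10
  events_per_recording: 40000
countrate:
  gate_mm: 20.0
tofres:
  bin_ps: 10.0
routine:
  median_activity_kbq_ml: 2.9
  sigma_log: 0.15
  n_frames: 1853
recon_demo:
  enabled: true
  n_pixels: 64
  pixel_mm: 5.0
  n_angles: 48
  n_subsets: 6
  n_iterations: 2
  true_fwhm_ps: [300.0, 700.0]
  recon_kernel_ps: 300.0
  counts: 2.0e5
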