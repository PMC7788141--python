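# petqc

Count-rate dependence of PET time-of-flight (TOF) resolution and TOF image
quality, as a reproducible analysis pipeline on synthetic list-mode data.

PET timing resolution is certified at ~2 Mcps during daily QC, but routine
exams run far hotter.  On analog (PMT) cameras with large trigger domains,
dead time and pile-up degrade the timing resolution as the singles rate
climbs — and a reconstruction that keeps assuming the calibrated TOF kernel
then *loses* contrast and SNR.  Digital (dSiPM) cameras with tiny trigger
domains are immune across the whole routine range.  This package implements
the analysis chain behind that comparison for physicists doing PET QC:

* **Camera presets** ("vereos" digital / "ingenuity" analog) carrying the
  published double-exponential rate–activity regressions
  `y = a·e^{bx} + c·e^{dx}` in both directions, and the measured
  resolution-vs-rate anchor points.
* **Synthetic list-mode generator** for the NEMA count-rate phantom (line
  source offset 45 mm): true/scatter/random coincidences, Gaussian timing
  and energy blur, 500-ms singles frames, saturating rate response.
* **NEMA count-rate metrics**: 20-mm LOR-distance gating, scatter fraction,
  NECR = T²/(T+S+R), peak interpolation.
* **List-mode resolution estimators**: TOF resolution as the FWHM of the
  Δt histogram (nearest-LOR-point annihilation assumption), energy
  resolution from the pooled photon-energy histogram.
* **Routine count-rate statistics**: Tukey-fenced box-plot limits of pooled
  500-ms frames, converted to phantom-equivalent activity via f_S→A.
* **Dose-scaled / cross-camera rate estimation**:
  `S_est = f_A→S(C·f_S→A(S))`.
* **IEC image-quality metrics** (CRC, sphere SNR, background relative
  noise) with NEMA-convention background ROIs.
* **Toy 2-D TOF-OSEM** demonstrating the TOF SNR gain and the
  kernel-mismatch degradation.

## Worked example

```python
from petqc import load_preset, estimate_scaled_rate, cross_camera_rate, predict

ver, ing = load_preset("vereos"), load_preset("ingenuity")

# routine upper limit observed at 3 MBq/kg -> expected at 5 MBq/kg
estimate_scaled_rate(ver, 13.3, 5/3)     # 21.55 Mcps
estimate_scaled_rate(ing, 21.7, 5/3)     # 33.44 Mcps

# digital-camera Rb-82 upper limit expressed on the analog camera
cross_camera_rate(ver, ing, 29.5)        # 39.45 Mcps

# median FDG rate -> NEMA-phantom-equivalent concentration
predict(ing.inverse_rate_model, 8.1)     # 2.897 kBq/mL
```

The first two numbers say: exams injected at 5 instead of 3 MBq/kg would
push the routine count-rate ceiling to ~21.6 Mcps on the digital camera and
~33.4 Mcps on the analog one — a range where the analog camera's timing
resolution has degraded from 621 ps to ~850 ps while the digital camera
stays at 326 ps.

Simulating and measuring that stability:

```python
from petqc import PhantomSpec, sample_coincidences, estimate_tof_resolution
from petqc.listmode import trues_only_preset

lm = sample_coincidences(trues_only_preset(ver), PhantomSpec(),
                         activity_kbq_ml=2.0, n_events=1_000_000, seed=1)
estimate_tof_resolution(lm).fwhm         # 325.1 ps (generator blur: 326 ps)
```

## Analysis scripts

`analysis/01…07` run the full study on synthetic data, writing tables and
figures under `results/analysis/`:

1. `01_simulate_decay_series.py` — 12 recordings per camera over a 16-h decay
2. `02_count_rates.py` — T/S/R, scatter fraction, NECR per recording
3. `03_fit_rate_models.py` — refit of the double-exponential models
4. `04_resolution_vs_rate.py` — TOF/energy resolution vs singles rate
5. `05_routine_rates.py` — routine-exam box statistics and conversions
6. `06_rate_estimates.py` — dose-scaled and cross-camera estimates
7. `07_kernel_mismatch_demo.py` — toy-recon TOF gain and kernel mismatch

A single-config pipeline (`petqc run config.yaml`, see
`src/petqc/data/quickstart.yaml`) chains the same stages with one seed and
writes a run manifest; `petqc report` renders the figures.  Each stage is
also a standalone subcommand (`petqc simulate|countrate|fit-rates|estimate|
tofres|routine|iq|recon-demo`).

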