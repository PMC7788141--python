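# Methods

This package re-creates, on synthetic data, a quality-control analysis of
how PET count rate affects time-of-flight (TOF) resolution, energy
resolution and TOF image quality, comparing a digital (dSiPM, "vereos"
preset) and an analog (PMT, "ingenuity" preset) camera.  This note records
the models, the assumptions behind the synthetic data, the numerical
choices, and what the tests do and do not demonstrate.

## Rate-activity models

Singles rate S (Mcps) and activity concentration A (kBq/mL) are linked in
both directions by independently fitted double exponentials

    y = a e^{bx} + c e^{dx},

the functional form used for the published regressions, whose coefficients
ship with the presets.  Composing the two directions yields the two
estimators the analysis hinges on:

* dose scaling: `S_est = f_A→S(C · f_S→A(S))` with C = 5/3 for a 3 → 5
  MBq/kg injected-dose change;
* cross-camera transfer: `S_target = f_A→S^target(f_S→A^source(S))`.

Notes on these curves, learned the hard way:

* The two terms of the double exponential are exchangeable, so fits are
  only identified up to curve values; all comparisons are made on curves,
  never on raw coefficients.
* The shipped S→A fits cross zero slightly above S = 0 (the analog
  camera's at about 2 Mcps), so `predict` accepts negative abscissae; the
  round-trip error of forward∘inverse is < 2 % above ~2 Mcps (digital) and
  ~4 Mcps (analog) and grows below that.  The published ≤ 2 % agreement
  claim concerns the upper routine range, where both estimators operate.
* Fitting uses multi-start nonlinear least squares: a log-linear seed for
  the dominant term plus variable-projection seeding (for fixed exponents
  the amplitudes are a linear problem) over an exponent grid scaled to the
  data range; best start by RMSE wins.  A constant series returns a
  flagged degenerate fit (a = ȳ, R² = 0) rather than an error.

## Synthetic list-mode data

The generator emulates the NEMA count-rate setup: a line source parallel to
the axis, offset 45 mm, inside a 101.5-mm-radius cylinder, viewed by a
single cylindrical detector surface of radius 450 mm and axial extent equal
to the preset's axial FOV (164/180 mm).  There is no crystal
discretisation, photon transport, attenuation or dead-time
microsimulation — saturation enters exclusively through the forward rate
model, and resolution degradation through the preset's piecewise-linear
FWHM-vs-rate curves (anchored at the published measurement points;
constant below the first anchor, linear continuation above the last).

Event classes are multinomial with probabilities ((1−SF)(1−RF), SF(1−RF),
RF).  SF defaults to 0.30, a typical 3-D scatter fraction (the study does
not print its measured value).  RF derives from a rate-squared randoms
model R = k·S² with k fixed per preset so that R equals the trues rate at
roughly twice the activity of that camera's NECR peak — a plausible, not
published, calibration.  Coincidences (trues + scatter) are taken as a
fixed fraction (0.10) of singles.

* **Trues** annihilate on the line source; LOR directions have uniform
  azimuth and a small uniform axial tilt (±0.10 rad), with axial positions
  re-drawn when an endpoint leaves the FOV (axial acceptance weighting).
  The measured Δt is the exact geometric TOF difference plus Gaussian
  noise of FWHM `tof_fwhm_at(preset, S)`.
* **Scatter** annihilation points are the source displaced by a transaxial
  Gaussian kick (σ = 40 mm) re-drawn until ≥ 20 mm from the source, with
  the LOR oriented perpendicular to the displacement so that the
  LOR-to-source distance equals the kick length: scatters fail the 20-mm
  true gate by construction.  This is a separability device, not a physical
  scatter model; the analysis only needs the classes to be separable at
  the gate.
* **Randoms** join two independent uniform detector hits with Δt uniform
  in ±3 ns.
* **Energies** are Gaussian around 511 keV with the preset's
  resolution-vs-rate FWHM, rejection-truncated to a symmetric acceptance
  window (164/276 keV full width; the window widths are published, their
  symmetry about 511 keV is an assumption).
* **Frames**: 500-ms singles/prompts/delayeds frames with Poisson counts
  around the model rates.

A decay series spreads recordings uniformly over 16 h, decays the
concentration exponentially, and grows recording durations as the
reciprocal of the coincidence rate (constant expected trues) — the
published schedule states only "increasing recording times", so the
constant-trues rule is this package's choice.

Because trues are proportional to singles here, the synthetic NECR curve is
monotone over the simulated range: the fitted singles curves never turn
over, and the trues rollover that produces a real NECR peak is not modelled.
Peak location (`find_peaks`, quadratic interpolation in log activity
through the three points bracketing the maximum) is therefore validated
against closed-form rate curves with an analytic dead-time rollover, not
against generator output.

## Count-rate analysis

Events are gated by the transaxial distance between the LOR and the line
source (< 20 mm).  The randoms rate uses the noiseless R = k·S² model (the
published analysis used delayeds with variance reduction; the details are
not restated there).  The randoms counts expected inside the gate are
removed using the in-gate fraction of uniform random LORs, a pure geometry
number computed once per geometry by a seeded Monte-Carlo draw (200 000
LORs, cached).  A band-interpolation background estimate was rejected
because the scatter displacement model leaves no scatter under the peak
while filling the band just outside the gate, which would over-subtract.
NECR = T²/(T+S+R); scatter fraction = S/(T+S).

## Resolution estimation

For each gated event the annihilation point is assumed to be the LOR point
transaxially nearest the source line; Δt = measured − geometric time
difference.  TOF resolution is the FWHM of the Δt histogram (10-ps bins),
energy resolution the FWHM of the pooled photon-energy histogram (1-keV
bins) divided by 511 keV.  FWHM is read by linear interpolation of the
half-maximum crossings around the modal bin — no Gaussian fit, so heavy
tails are tolerated.  Known bias: noise in the modal bin raises the
half-maximum level and biases FWHM low, about −0.5 % at 10⁶ events for a
326-ps histogram and −3 % at 2×10⁵ events for an 850-ps one; the optional
3-bin moving average (`smooth=True`) roughly halves it.  Consistency tests
therefore use ≥ 5×10⁵ events and smoothing for the widest histograms, and
the headline recovery checks (10⁶ events, 1.5 % tolerance) hold with the
default estimator.

## Routine statistics

500-ms singles frames are pooled per (tracer, camera) group and summarised
with standard linear-interpolation quartiles.  The published outlier rule
("1.5-fold the upper limit of the 3rd quartile") is ambiguous; the default
is the conventional Tukey reading (Q3 + 1.5·IQR, Q1 − 1.5·IQR), with the
literal quartile-scaled variant (`fence="quartile_scaled"`) also
implemented.  Trimming is single-pass; Tukey fences are only approximately
idempotent under re-application, since trimming moves the quartiles.
Routine exams are emulated by log-normal activity fluctuation around a
group median (σ_log = 0.15, chosen so the trimmed extrema span roughly the
published FDG interval), pushed through the forward rate model with
Poisson frame noise.

## Image quality

CRC_i = ((S_i/B_i − 1)/(a_H/a_c − 1))·100, SNR_i = (S_i − B_i)/σ_i,
RN = σ37/B37·100.  S_i is the mean of a circular 2-D ROI matching the
sphere diameter on the slice through the sphere centre; B_i and σ_i pool
all voxels of the background ROIs of that diameter (12 deterministic
transaxial positions — chosen inside the body ellipse, ≥ 39 mm from every
sphere centre and clear of the lung insert — replicated on five slices at
0, ±10, ±20 mm = 60 ROIs; 12 for single-slice images).  RN uses the pooled
voxels of the 37-mm ROIs.  Voxels belong to an ROI iff their centre is
inside.  A sphere with zero-variance background reports SNR = 0 rather
than infinity.

## Toy TOF reconstruction

A 2-D parallel-beam TOF-OSEM (128² pixels, 2.5 mm; 96 angles; 10
angle-interleaved subsets; relaxation exponent 1.0) exists solely to
demonstrate two effects: the SNR advantage of TOF weighting and the
degradation caused by a mismatched TOF kernel (fixed 300 ps against data
of growing true timing spread).  The TOF axis bins the emission position
along each ray at 25 ps (3.75 mm); kernels are Gaussians truncated at 3σ
and column-normalised.  Projection/backprojection use bilinear image
rotation, which is only approximately adjoint — with noiseless data a
uniform disk reconstructs flat to ~1 % RMS interior at 20 iterations.

The TOF-vs-noTOF SNR comparison depends on convergence: at 1–2 iterations
the under-converged noTOF image is smoother and the ratio can sit below 1;
the informational advantage of TOF data (its ML estimate has lower
variance) expresses near convergence, so the gain experiment runs at 12
iterations, where the mean sphere-SNR gain exceeds 1.  The
kernel-mismatch experiment runs at 2 iterations, matching the published
in-silico protocol, where the effect is large and monotone in the
mismatch.  No quantitative match to the published gain magnitudes is
attempted or claimed.

## What the tests show — and do not

Passing tests show that (i) the printed regression compositions reproduce
the printed estimates, (ii) every estimator recovers the parameters its
own generator injected, within stated statistical tolerances, and
(iii) the reconstruction effects have the published direction and
monotonicity.  They do not validate detector physics: the generator shares
its rate model with the analysis (by design — the published count-rate
figures are likewise descriptive fits), scatter is a separability device,
and the toy reconstructor has no attenuation, scatter or resolution
modelling.  Measured NECR peaks, absolute SNR values and patient-derived
distributions are outside what synthetic data can certify.

## Problem sizes

Default suites use 1.2–3×10⁵ events per recording (10⁶ for the headline
resolution recoveries), 12-recording decay series, and 3–5 seeds × 4
timing levels for the reconstruction experiments — sizes at which every
stochastic tolerance above has comfortable margin on a single CPU.
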