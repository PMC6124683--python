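# Methods

This note documents the models implemented in nirsox, the parameters that
matter, the numerical choices, and what the synthetic data do and do not
establish.

## Photon transport (`nirsox.tissue_mc`)

Standard weighted ("implicit-capture") Monte Carlo in plane-parallel
layers, single-threaded for strict seed determinism:

* **Step sampling.** Dimensionless step s = −ln ξ consumed at the local
  μ_t; a step crossing a layer boundary is continued in the next layer
  with the remaining optical depth (MCML convention).
* **Interaction.** Weight fraction μ_a/μ_t is deposited in a cylindrical
  (r, z) fluence grid (default 0.1 mm voxels, r ≤ 40 mm, z ≤ 20 mm); the
  new direction is drawn from the Henyey–Greenstein phase function with
  the layer's g.
* **Boundaries.** Unpolarised Fresnel reflection/refraction at every
  refractive-index mismatch, including the ambient/tissue surface
  (specular loss at launch). Matched indices short-circuit to zero
  reflection; beyond the critical angle the photon is totally internally
  reflected.
* **Termination.** Russian roulette below weight 10⁻⁴ with survival
  probability 0.1. The roulette is booked exactly: a kill adds the
  remaining weight to the absorbed ledger and a survival boost subtracts
  the injected weight, so reflected + transmitted + absorbed equals the
  launched weight to floating-point accumulation error for *every* run,
  not just in expectation. Photons deeper than 200 mm in the semi-infinite
  layer are scored as transmitted; at 2 cm source–detector separation
  their chance of returning to the detector is negligible.
* **Detection.** Detectors are circular apertures (default radius 1.5 mm)
  on the surface. Because the geometry is rotationally symmetric, an
  escaping photon at exit radius ρ contributes the exact azimuthal
  fraction of its exit circle that overlaps the aperture — the expectation
  of the Bernoulli hit indicator — which reduces detection variance by
  roughly 2πd/(2a) (~40× at 2 cm) without bias. Per detected photon the
  kernel records survival weight, exit radius, maximum depth reached, and
  geometric path per layer; depth statistics are exit-weight-weighted.
  All detectors share one photon stream, so a separation scan is
  bit-identical to dedicated runs at the same seed.

**Optical properties.** The study geometry (0.3 mm dermis, 1 mm
subdermis, semi-infinite muscle; 2 cm separation) does not fix optical
coefficients, so the packaged `tissue_calf.yaml` carries literature
mid-range values for skin, subcutaneous fat and resting skeletal muscle
at 735/805/850 nm (e.g. muscle at 805 nm: μ_a = 0.020 mm⁻¹,
μ_s′ = 0.65 mm⁻¹, g = 0.9, n = 1.4). They are a named, versioned default
(`calf-v1`); every operation accepts overrides. With these values the
weighted median maximum depth of photons detected at 2 cm is ≈ 0.8 cm
(10⁶ photons), consistent with a penetration depth "up to 1 cm", and the
DPF is ≈ 4.7, inside the 3–6 literature band for muscle.

**Photon budget.** Desk default is 10⁶ photons (≈ 2 min on one core for
the layered model), raisable via `--photons`; detection statistics at
2 cm are then a few thousand photons, adequate for median-depth and DPF
estimates.

**Verification.** The transport is checked against an independent
closed-form oracle: steady-state diffusion-dipole reflectance of a
matched-boundary semi-infinite medium (source at one transport mean free
path, image about the extrapolated boundary at 2AD with A = 1). At
μ_a = 0.01 mm⁻¹, μ_s′ = 1.0 mm⁻¹ the simulated reflectance at
r = 20 ± 1 mm agrees with the closed form within a few percent (the test
tolerance is 15%, covering both Monte Carlo noise and the accuracy limit
of the diffusion approximation at μ_eff·r ≈ 3.5).

## Beer–Lambert inversion (`nirsox.mbll`)

* **Log base.** Attenuation is decadic (optical-density convention) and
  paired with decadic molar extinction coefficients; consistency, not the
  base itself, determines the recovered concentrations.
* **Extinction table.** Packaged values are interpolated from the
  standard compiled hemoglobin spectra, in cm⁻¹ mM⁻¹: the construction
  enforces the isosbestic ordering (the Hb/HbO₂ gap at 805 nm is < 10%
  relative and the smallest of the three wavelengths). Replaceable via
  TSV.
* **Reference intensity.** I_o is the mean intensity over the 10-min
  baseline window (configurable), per detector and wavelength.
* **Inversion.** Three equations, two unknowns: ordinary least squares
  via one pseudo-inverse applied to all time points; the per-time-point
  residual norm is exposed for quality control, and a condition number
  above 10⁸ raises an error rather than returning meaningless
  concentrations.
* **Path length.** L(λ) = DPF(λ) × separation, default DPF 4.0 at all
  wavelengths (literature muscle value), overridable per wavelength e.g.
  from `mean_pathlength`. In the synthetic round trip the same L is used
  forward and backward, so the DPF choice cancels exactly.
* **Detectors.** The two detectors are processed independently and their
  attenuations averaged in the log domain (so static gain differences
  cancel); either detector can be selected instead.

## Tilt-table analysis (`nirsox.hut`)

* Segmentation is exact half-open windows from the protocol (1 Hz default:
  [0, 600), [600, 2400), [2400, 3000) samples); the ~5 s posture
  transition belongs to the segment it leads into. Windows partition the
  protocol span by construction.
* Rates of change are OLS slopes over the first 10 min after each posture
  change; AUC is the trapezoid rule over the tilt with time in minutes.
  Signals are already baseline-referenced changes, so no further baseline
  subtraction is applied to the integrand.
* Group comparison: equal-variance two-tailed Student t-test (Welch
  available via `equal_var=False`), fixed α = 0.01 per signal, no
  multiple-testing correction — one test per signal is the study design
  being mirrored. Zero-variance degeneracies are reported explicitly
  (equal means → p = 1, distinct means → p = 0, flagged).
* Group AUC is the per-subject AUC averaged over subjects; by linearity of
  the trapezoid rule this equals the AUC of the group-mean curve on a
  shared grid, and the latter is also reported (`group_mean_curve_auc`).
* Device cross-validation regresses the reference trace on the probe ΔOxy
  over the tilt window after linear-interpolation resampling onto the
  probe grid and a 10 s centred moving average of both series — the
  averaging mirrors the slow display update of clinical reference
  oximeters and keeps R² a measure of trend agreement rather than of
  sample-level sensor noise. The %-vs-μM unit mismatch affects only the
  slope, never R².
* Heart-rate criterion: strict inequality, pediatric threshold 40 bpm
  below age 18, adult threshold 30 bpm otherwise.

## Synthetic cohorts (`nirsox.cohort`)

The generator is the exact forward model of the analysis chain, so with
all dispersions at zero the chain inverts it to machine precision — this
round trip is a structural test, not a statement about real tissue.

* **Templates.** Rise-to-plateau ramps during the tilt with
  group-distinct rise times taken from the study's narrative time
  courses: Hb 4 min (control) vs 30 min (POTS, i.e. rising throughout the
  tilt); HbO₂ 2 min (control) vs 10 min (POTS). Amplitudes are not free:
  a ramp with rise r and plateau A over a 30-min tilt has
  AUC = A(30 − r/2), so A is solved from the published group AUCs
  (Hb 113/52, HbO₂ 42/41 μM·min), giving plateaus of ≈ 7.5/1.9 μM (Hb)
  and 1.68/1.41 μM (HbO₂). Recovery is exponential relaxation to
  baseline, τ = 2 min (control) vs 6 min (POTS), encoding the slower
  recovery of patients; the constants are free parameters of the
  artifact. The templates are constrained by AUCs, rise times and the
  significance pattern, but not uniquely determined by them.
* **Noise.** The study reports no noise model; the artifact uses
  multiplicative Gaussian intensity noise (CV 0.5%), a per-subject,
  per-signal lognormal amplitude factor (σ = 10%), additive reference
  noise (0.2%), and ±2 bpm spread on heart-rate summaries. With n = 6 per
  group these defaults reproduce the study's inference pattern — Hb,
  ΔOxy, ΔBV significant at 0.01 and HbO₂ not — in well over 90% of master
  seeds, and put the group-mean AUC spread at ≈ 4% relative (so a
  randomly seeded cohort occasionally drifts a little past 10% from the
  published AUC; that spread is a property of n = 6 with 10%
  between-subject variability, not of the estimator).
* **Determinism.** Per-subject generators derive from
  `SeedSequence((master, group, index))`; a master seed reproduces every
  file bit for bit, and the cohort manifest (seeds, template version,
  file checksums) is itself reproducible.
* **What is *not* emulated.** Beat-to-beat heart rate (only the two
  printed summary scalars), blood pressure, motion/contact artifacts,
  drift, scattering changes, adipose-thickness variation between
  subjects, and any closed-loop baroreflex physiology. Control subjects'
  ΔOxy excursion is small by construction (their Hb and HbO₂ AUCs nearly
  cancel), so the device-correlation property is stated for a POTS
  subject, whose tilt ΔOxy swing dominates the sensor noise. Passing
  tests therefore demonstrate the correctness and calibration of the
  pipeline, not the physiological validity of the templates.

## Problem sizes

Defaults used throughout tests and the reproduction script: 10⁶ photons
for penetration-depth and diffusion-limit checks, 10⁵–2×10⁵ for transport
invariants, 6 + 6 subjects at 1 Hz for the cohort stage, and 100 master
seeds for the significance-pattern frequency. The whole test suite runs
in a few minutes on one core.

## Known limitations

* The transport model is steady-state CW in flat layers: no time- or
  frequency-domain quantities, curved anatomy, or polarization.
* The inversion is differential only (no absolute StO₂) and carries the
  usual CW assumptions: constant scattering and homogeneous-change
  ("well-mixed") sensitivity; partial-volume effects are folded into the
  single DPF.
* The t-tests treat subjects as exchangeable and independent; no
  repeated-measures or mixed-effects structure.
* Literature optical properties vary several-fold between sources;
  penetration-depth results should be read as order-of-magnitude probe
  design guidance, with the packaged table as one defensible choice.
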