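# nirsox

Continuous-wave near-infrared spectroscopy (NIRS) muscle oximetry toolkit:
photon Monte Carlo for reflectance-probe design in layered tissue, a
three-wavelength modified Beer–Lambert inversion to hemoglobin
concentration changes, and the statistics of a head-up tilt-table (HUT)
study comparing POTS patients with healthy controls.

## Who this is for

Researchers building or analyzing CW reflectance oximeters for skeletal
muscle — in particular anyone studying orthostatic intolerance, where calf
muscle hemodynamics during a tilt-table test (10 min supine baseline,
30 min at 70°, 10 min supine recovery) distinguish postural orthostatic
tachycardia syndrome (POTS) patients from controls.

## The model

**Probe design (photon transport).** Light transport in a layered calf
model (0.3 mm dermis, 1 mm subdermis, semi-infinite muscle) is simulated
with standard weighted Monte Carlo: exponential steps on μ_t = μ_a + μ_s,
fractional absorption μ_a/μ_t per interaction, Henyey–Greenstein
scattering, Fresnel boundaries, and Russian-roulette termination with an
exact weight ledger (reflected + transmitted + absorbed = launched for
every seed). Each detected photon's maximum depth and per-layer path are
recorded, giving the penetration-depth vs. signal trade-off that motivates
the 2 cm source–detector separation, and the differential pathlength
factor DPF = ⟨L⟩/ρ used by the inversion.

**Oximetry (modified Beer–Lambert law).** With baseline intensity I_o and
detected intensity I(t),

    ΔA(λ, t) = −log₁₀ I(t)/I_o = L(λ) [ ε_Hb(λ) ΔC_Hb + ε_HbO₂(λ) ΔC_HbO₂ ],

at λ = 735 nm (Hb-dominated), 805 nm (Hb/HbO₂ isosbestic) and 850 nm
(HbO₂-dominated). The 3-equation, 2-unknown system is solved per time
point by least squares; derived signals are the oxygenation change
ΔOxy = ΔC_HbO₂ − ΔC_Hb and blood-volume surrogate ΔBV = ΔC_HbO₂ + ΔC_Hb.

**Cohort statistics.** Recordings are segmented by the protocol; per
subject the package computes tilt-segment means, first-10-min rates of
change after each posture change, and the trapezoidal area under the
curve (AUC, μM·min) over the 30-min tilt; groups are compared with
equal-variance two-tailed Student t-tests at α = 0.01, and the probe's
ΔOxy is cross-validated against a reference oximeter trace by simple
linear regression (R²). The orthostatic heart-rate criterion (rise
> 40 bpm for children, > 30 bpm for adults) classifies subjects.

**Synthetic cohorts.** No subject recordings are distributed, so a
seeded generator emulates 6 POTS + 6 control subjects: piecewise-linear
concentration templates (rise-to-plateau during the tilt, exponential
recovery) whose amplitudes are solved in closed form from the published
group AUCs, pushed through the Beer–Lambert forward model to raw
intensities with measurement noise, plus heart-rate summaries and a
reference ΔOxy trace.

## Worked example

```python
from nirsox import CohortSpec, run_study

cohort, processed, result = run_study(CohortSpec(seed=42))
print(result.groups.set_index(["group", "signal"])["tilt_auc_um_min"].round(1))
print(result.tests.query("statistic == 'tilt_mean'")[["signal", "p", "significant"]])
```

prints the group-mean tilt AUCs (μM·min)

```
group    signal
POTS     d_bv       153.2
         d_oxy      -67.3
         dc_hb      110.3
         dc_hbo2     42.9
control  d_bv        93.0
         d_oxy      -10.1
         dc_hb       51.5
         dc_hbo2     41.5
```

— deoxyhemoglobin accumulates roughly twice as much in POTS patients as
in controls during the tilt (110 vs 52 μM·min), while oxyhemoglobin is
similar (43 vs 41) — and the t-tests

```
    signal             p  significant
     dc_hb  8.313482e-08         True
   dc_hbo2  6.816618e-01        False
     d_oxy  1.088309e-06         True
      d_bv  6.582839e-07         True
```

show the Hb/ΔOxy/ΔBV differences significant at α = 0.01 with HbO₂ not.

For probe design:

```python
from nirsox import default_tissue_model, simulate, penetration_stats, mean_pathlength

s = simulate(default_tissue_model(), n_photons=1_000_000, wavelength=805.0, seed=7)
print(penetration_stats(s, 0).median_cm)   # 0.81 cm at the 2 cm separation
print(mean_pathlength(s, 0).dpf)           # DPF ~ 4.7
```

The command line mirrors the library: `nirsox simulate-probe`,
`nirsox generate`, `nirsox process`, `nirsox analyze`, `nirsox run-all`,
`nirsox show-config`.

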