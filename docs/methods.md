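# Methods

## Overview

`oispec` analyses two-dimensional optical imaging spectroscopy (2D-OIS)
recordings of the cortical surface: four-wavelength remitted-light image
stacks are converted into movies of oxy-, deoxy- and total hemoglobin
concentration change (ΔHbo, ΔHbr, ΔHbt), from which activated-region and
vessel-compartment response time series and group statistics are derived.
Because no real recordings ship with the package, a forward model
(`oispec.phantom`) generates complete synthetic sessions with known ground
truth; the analysis and the forward model share one optical model, so the
pipeline can be validated end to end.

## Spectroscopic inversion

For each wavelength λ the attenuation change relative to a pre-stimulus
(or pre-switch) baseline window is

    ΔA(λ, t, p) = −ln( I(λ, t, p) / Ī₀(λ, p) ),

with Ī₀ the baseline-window mean of the dark-corrected intensity. The
modified Beer–Lambert model relates it to concentration changes:

    ΔA(λ) = ln(10) · [ ε_HbO(λ) ΔC_HbO + ε_HbR(λ) ΔC_HbR ] · L(λ),

where ε are decadic molar extinction coefficients (cm⁻¹ M⁻¹) and L(λ) is
the mean path length (cm) of remitted photons. With four wavelengths
(495, 559, 575, 587 nm by default) and two unknowns the system is solved
per pixel by ordinary, unweighted least squares; no weighting scheme is
assumed and negative concentration changes are permitted (Hbr washout is
the signal of interest). ΔHbt ≡ ΔHbo + ΔHbr holds element-wise by
construction. Fractional movies are 1 + ΔC/C₀ relative to an assumed
baseline state: 100 μM total hemoglobin at 70% saturation while breathing
100% oxygen. The air-breathing baseline is re-estimated per session from
the oxygen→air transition record: the post-switch settle-window mean shift
in ΔHbt and ΔHbo (over the cranial-window ROI) is added to the oxygen
totals. The settle window defaults to the [0.6, 0.95] fraction of the gas
record (450–712 s of a 750 s record with the switch at 105 s).

Dead pixels (non-positive intensity inside the analysis region) are
flagged, excluded from every ROI average, counted in the log, and never
interpolated. Path lengths are held fixed per breathing condition, not
updated frame by frame.

### Extinction spectra

The bundled table (`data/hb_extinction_synthetic.tsv`) is a **synthetic**
smooth Gaussian-mixture approximation to the canonical visible-band
hemoglobin spectra — HbO₂ Q-band doublet at 542/577 nm, Hb single broad
band at 556 nm, Soret flank below 500 nm, red-window transparency above
600 nm — with the generating formula recorded in the file header. It is
not measured data; any decadic TSV with columns
`wavelength_nm  eps_hbo  eps_hbr` covering 450–650 nm can be supplied
instead. The 4×2 spectral design matrix built from it is well conditioned
(condition number ≈ 4).

## Monte-Carlo path lengths

L(λ) is estimated by photon transport through a homogeneous semi-infinite
slab: pencil beam at normal incidence, exponential step sampling at
μt = μa + μs, Henyey–Greenstein scattering, implicit-capture weighting
(weight × albedo per interaction) with Russian roulette below weight 1e-4
(survival 0.1), and detection of every photon re-crossing the entry
surface regardless of exit angle; Fresnel reflection at the surface is
ignored. The estimate is the weight-weighted mean total geometric path of
detected photons, with a weighted standard error. μa(λ) follows from the
assumed baseline via the extinction table; scattering defaults to a
literature-typical cortical power law μs′(λ) = 20·(λ/500 nm)^−1.2 cm⁻¹
with g = 0.9, n = 1.4, all overridable.

Randomness uses one splitmix64 stream per photon, derived from the master
seed and photon index by a fixed scrambling rule, so results are
bit-reproducible and an independent per-photon reference walker reproduces
the engine exactly (this is tested). Per-wavelength runs use sub-seeds
derived deterministically from the master seed. A hard cap of 10⁶
interactions per photon guarantees termination in the zero-absorption
limit; at physiological absorption it never binds in practice.

At the default oxygen baseline the mean paths are ≈ 0.09–0.16 cm across
the four wavelengths (shortest where absorption is strongest, 559/575 nm),
with SE ∝ n^−1/2.

## Synthetic phantom

The phantom emulates a chronically prepared cranial window: a circular
imaging window (default 184×184 px at 75 μm/px metadata; tests use 32–64
px grids) containing a branching artery, a draining vein, parenchyma, and
an off-centre "activated whisker region" disc through which both vessels
run. The session follows the eight-experiment protocol: two 2 s-stimulation
oxygen records (30 × 25 s trials, stimulus at 5 s, 5 Hz), an oxygen→air
transition (switch at 105 s), a 2 s air record, a 16 s air record
(15 × 70 s trials, stimulus at 10 s), an air→oxygen transition, a 16 s
oxygen record, and a hypercapnia challenge (switch at 250 s, 250 s
duration, 250 s recovery) — 120 stimulation trials per session at an
effective 8 Hz per wavelength. A desk-scale `reduced_protocol()` keeps the
trial geometry but shrinks counts and gas-record lengths for tests.

Evoked responses are gamma-variate impulse kernels (unit area) convolved
with the stimulus boxcar, per compartment: the artery leads the vein in
onset latency, ΔHbr is negative-going with an extra lag, and under air an
additional slow negative lobe creates the post-stimulus arterial Hbt
undershoot that is absent under oxygen. Amplitudes are plateau values for
a sustained stimulus (artery 8 μM Hbt / −4 μM Hbr; vein 5/−5; parenchyma
5/−3), so a 2 s train reaches a fraction of the 16 s response. These
defaults are qualitative shape choices, config-exposed, not fitted
constants.

Gas transitions ramp the baseline state logistically (τ = 10 s) between
the oxygen state (100 μM, 70%) and the air state, which defaults to
(95 μM, 62%). Hypercapnia is a +15% Hbt / +0.08 saturation excursion over
the challenge window. Acute sessions multiply the baseline by a
CSD-like damped oscillation m(t) = 1 − A·cos(2πt/P)·exp(−t/τ) (P = 120 s,
τ = 600 s), with A = 0.10 and evoked scale 0.85 for the WT-like group and
A = 0.20 / 0.55 for the AD-like group; chronic sessions have A = 0 and
full-scale responses in both groups. Camera noise is a signal-scaled
Gaussian approximation to shot noise plus a constant dark offset with
Gaussian dark noise; dark frames are emitted per inter-experiment gap.
Noisy sessions are float32 camera counts; noise-free (verification)
sessions keep float64 so round trips are numerically exact. Every
simulated session carries its injected compartment time courses.

What the phantom does **not** emulate: vascular spatial heterogeneity
within compartments, pixel-wise path-length differences between vessels
and parenchyma, motion, physiological oscillations (heartbeat,
vasomotion), or scattering changes. Passing tests therefore demonstrate
correctness of the inversion and analysis chain under the stated forward
model, not robustness to every artefact of real recordings.

The electrophysiology phantom injects stimulus-locked biphasic field
potentials (negative peak at 8 ms) on 16 channels at 6 kHz with a
mid-channel depth profile and pink-ish noise; evoked amplitudes are equal
across groups by construction, mirroring the neural null result the
hemodynamic deficit is contrasted against.

## Session analysis

Per experiment: dark correction (nearest gap dark frame, clamped at zero
with a count), attenuation against the experiment's baseline window
(pre-stimulus interval for stimulation records, pre-switch interval for
gas records), unmixing, and fractional ROI time series. The whisker ROI is
selected on the trial-averaged fractional Hbt movie of the 16 s oxygen
experiment: a pixel is included iff its stimulation-window mean exceeds
its pre-stimulus mean by 1.5 pre-stimulus SDs; the mask shrinks
monotonically in the threshold. Response magnitude is the mean fractional
deviation from baseline over the stimulation window of the trial-averaged
ROI series. Vessel compartments come from PCA (per-pixel temporal mean
removed, no variance scaling, first singular component, sign fixed to
covary positively with the stimulus regressor): arteries from the Hbt
loading map, veins from the |Hbr| loading map, thresholded at the 0.8
in-ROI quantile, veins excluding artery pixels. Whole-session records are
concatenated on the session clock with NaN-marked gaps, never
interpolated or resampled.

## Statistics

The group stage is a two-way mixed (split-plot) ANOVA — between-subject
factor group, within-subject factor session or experiment — computed from
the explicit sums-of-squares decomposition (SS_total = SS_group +
SS_subject(group) + SS_within + SS_interaction + SS_residual on complete
data), with the group effect tested against the subject(group) stratum.
No sphericity correction is applied. It is implemented directly (the
result type exposes the strata) and cross-checked against
`pingouin.mixed_anova` in the tests. Bonferroni correction is α/m (0.05
over 15 comparisons gives the 0.003 working level). Hypercapnia responses
are the mean fractional deviation over the 250–500 s challenge window,
compared between groups by pooled-variance two-tailed t-tests.

Calibration is validated by simulation: on null phantom cohorts the group
test rejects at ≈ 5% (500 replicates, accepted band [0.02, 0.09]), and an
injected acute-scenario deficit (n = 5+5, effect ≥ 2× residual SD) is
detected in ≥ 80% of 200 replicates.

## Numerical choices and problem sizes

Linear interpolation of spectra; pseudoinverse solve shared across all
pixels of a stack; rank/condition guard (cond < 1e8) on the design matrix;
trial SD uses ddof = 1; zero-variance pixels are excluded from ROI
selection. Tests and the acceptance script run the phantom at 32–64 px
grids with the reduced protocol and 5 000–100 000 photons per wavelength;
these sizes were chosen as the smallest at which every property under
test is comfortably resolved, and the full 184×184 grid and full-length
protocol remain available behind flags.

## Known limitations

* **Fractional-Hbt baseline robustness is approximate, not exact.** With
  path lengths recomputed per assumed baseline, the estimated fractional
  response scales as 1/(L(μa)·Hbt₀); exact invariance would require
  L ∝ 1/μa, but in the scattering-dominated regime the remitted mean path
  scales as ≈ μa^−0.6, leaving a residual ≈ Hbt₀^−0.4 sensitivity. Across
  an 80–120 μM sweep the peak fractional Hbt response varies by ≈ 14%
  ((max−min)/mean); the package's acceptance suite asserts the stricter
  10% bound and that check is expected to fail under the default optics.
* The homogeneous-slab Monte-Carlo geometry ignores the layered cortex,
  vessels as discrete absorbers, and surface index mismatch.
* PCA vessel identification assumes the stimulus-locked component
  dominates; it is validated only against the phantom's vessel geometry.
* The mixed ANOVA expects complete cases; subjects with missing levels
  must be excluded upstream.
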