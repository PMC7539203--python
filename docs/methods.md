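# Methods

## Confined-cell geometry

A non-adherent cell held between two parallel plates is modelled as a
surface of minimal area at constant volume. We use the standard
circular-arc (constant-mean-curvature approximation) profile with a 90°
contact angle at both plates: the meridional profile radius is
`R2 = h/2`, the contact radius `r_con = R1 − h/2`, and

```
V     = π·(2·R2·r_con² + π·r_con·R2² + (4/3)·R2³)
A_lat = 2π·R2·(π·r_con + 2·R2)
A     = A_lat + 2·π·r_con²
```

The exact unduloid solution differs negligibly at these confinement levels
and has no closed form; the circular-arc realisation is exactly testable
against solid-of-revolution quadrature (the suite verifies agreement to
1e-6 relative on a 20×20 grid). Inverting the volume for `r_con` at fixed
`(V, h)` is a quadratic with a single physical root, so per-sample shape
solving is exact and vectorises.

Two deliberate conventions:

* **The cortex covers the contact disks**, so the total area `A` used for
  the strain includes both plate contacts. Strain should reflect the whole
  cortex, which is continuous over the contact zones.
* **Volume is constant within one recording**: a single estimate per cell
  (from the equatorial cross-section at known height, mirroring the
  bright-field measurement) is used for every sample.

Units are µm / nN / mN/m throughout the core (1 nN/µm = 1 mN/m), with
conversions confined to I/O.

## Confinement rheology

Cell height is reconstructed from the recording as
`h(t) = (elevation − lowering(t)) + spike + F(t)/k`: the piezo height
relative to the recorded dish-touch reference, corrected by the wedge
spike height and the force-induced cantilever deflection. The touch
reference is an explicit calibration input; we do not infer it from the
trace.

Analysis is restricted to a steady-state window chosen from whole drive
periods, scanning from the end of the recording: the latest contiguous run
of `W` periods (default 8, clamped to the 5–10-period analysis band) in
which every per-period half peak-to-peak amplitude of force and of height
lies within 5% of the window median (both the length and the threshold are
configurable). If the requested length has no qualifying run, the window
shrinks down to 5 periods before raising an error that reports all
per-period amplitudes.

Amplitude and phase at the drive frequency are extracted by harmonic least
squares (`a + b·sin + c·cos` at the known `f`), not FFT bin-picking: the
fit is exact for non-integer period counts and statistically efficient at
500 samples per period. Results with amplitude below 3·RMS/√n are flagged
low-SNR. The phase shift is wrapped to (−180°, 180°]; values outside
[−5°, 95°] are flagged unphysical, never clipped. The stated ≈0.5 µm
absolute height uncertainty is surfaced as an optional sensitivity report
(re-analysis at h ± 0.5 µm), not folded into the point estimates.

## Synthetic AFM traces

The generator inverts the analysis: `h(t) = h0 + Δh·drive(t)` (drive
rendered as a piecewise-linear sine with 20 knots per period, as a piezo
controller would; the analyser fits the fundamental regardless), geometry
per sample from the constant-volume solver, and a cortex responding
linearly to the *fundamental Fourier component* of the area strain with
modulus `K·e^{iφ}` on top of a resting tension γ0. The geometric
non-linearity of ε_A(t) is preserved in the force signal, so the analyser
is exercised on realistic harmonic distortion; noise-free round trips
recover (γ, K, φ) to ≈0.05%, 0.05%, 0.002° at the default conditions.
Defaults mirror the measurement protocol: free diameter 20 µm, confinement
65%, Δh = 0.25 µm at 1 Hz, 500 Hz sampling, 12 periods after a 2-period
exponential force transient, Gaussian force noise σ_F = 0.1 nN (the order
of an AFM noise floor). The piezo series is constructed so that height
reconstruction returns the true `h(t)` exactly.

What the generator does **not** emulate: cantilever hydrodynamics and
instrument drift, nucleus/cytoplasm contributions, active tension
fluctuations, and adhesion (contact angle ≠ 90°). Passing recovery tests
therefore demonstrates correctness of the inference chain under the
geometric model, not robustness to model violations in real cells.

## Radial-profile quantification

Boundary detection (unspecified in the original workflow, implemented
here as): Gaussian smoothing (σ = 2 px) → Otsu threshold → hole filling →
exactly one sufficiently large component → subpixel contour. A
user-supplied mask always overrides detection. 200 lines normal to the
contour at equidistant arc-length anchors extend ±2 µm; intensity is
sampled bilinearly at half-pixel steps and averaged across lines.

The seven-parameter model uses a *unit-peak* Gaussian, so `I_cort` is an
intensity amplitude comparable to `I_cyt` (a normalised-density Gaussian
would only rescale `I_cort` by σ2√(2π)). The erf arguments use the
standard standardised residual `(r−μ)/(σ√2)` (skew-normal convention).
The cortex integral has the closed form `I_cort·σ2·√(2π)` for any α (the
odd erf term integrates to zero), verified against adaptive quadrature to
1e-8. The ratio divides by the *fitted* `I_cyt`, which is background-free
by construction.

Fitting is bounded nonlinear least squares with deterministic
initialisation (μ from the argmax, background from the outer-10% median,
cytoplasm from the inner-10% median, σ2 from the peak FWHM), a small
deterministic multi-start over σ scalings (the step/peak decomposition has
local minima for wide peaks), and seeded jittered restarts on failure.
`weighting="poisson"` weights residuals by 1/√I — the approximate
maximum-likelihood estimator for photon-limited data and the recommended
setting for noisy profiles. At peak SNR 10 per raw line averaged over 200
lines, recovery medians over seeds are ≲2% for μ, σ2 and the three
intensities and ≈5% for σ1 and α; the skewness α is the weakest-identified
parameter (it trades off against μ and σ2), and its ≈5% median error
matches truth-initialised maximum-likelihood fits, i.e. it is an
information limit of the data, not an optimiser artefact.

Thickness: both channels are registered by the difference of
above-background intensity centroids, profiles are extracted along the
*same* normal lines (so any common boundary bias cancels in the peak
offset), both fits fix α = 0, and the estimate is `2·(μ_mem − μ_act)`.
Synthetic two-channel cells with true thickness 200–500 nm (actin peak
half a thickness inside the membrane peak, 0.05 µm pixels) are recovered
within 10%; negative estimates are returned but flagged.

## Morphometry

Roundness uses the moment-fitted ellipse (`regionprops` axis lengths, full
major axis): `4·Area/(π·major²)`, clipped at 1 against pixelation
overshoot. Digitised ellipses across aspect ratios 1–5 reproduce b/a
within 0.02 and are rotation-invariant within 0.01. Largest cross-section
ties break to the lowest z-index. Mitotic-cell identification is manual
upstream; masks and labels are inputs.

## Cohorts and statistics

Cohort draws are lognormal around group medians with a common coefficient
of variation (default 25%), one synthetic recording per cell. The default
design encodes the EMT shift directions — interphase tension and stiffness
down (γ 1.0→0.6 mN/m, K 20→12 mN/m), mitotic tension and stiffness up
(γ 1.5→2.2 mN/m, K 25→38 mN/m) with phase shift down (30°→22°) — at
n = 25 cells per group. The magnitudes are this package's choices of a
clearly-resolvable effect (the source data are reported only as boxplot
distributions, so no numeric effect size is asserted); `effect=0` gives a
null design for calibration checks.

The Mann–Whitney U test uses midranks for ties; for combined n ≤ 20 the
two-tailed p is exact, from a dynamic-programming enumeration of all rank
assignments (p = min(1, 2·min(P(R ≤ r), P(R ≥ r)))); beyond that, the
tie-corrected normal approximation with continuity correction. Under a
null cohort the empirical type-I rate at α = 0.05 is within 0.05 ± 0.03
over 200 replicates. No multiple-testing correction is applied, matching
the upstream analysis convention. The relative-change test is a one-sided
one-sample t-test against 1.

## Problem sizes used in the validation suite

Recovery grids use 3×3×3×2 parameter combinations (noise-free) and 50
seeded replicates (noisy) for rheology; 50 seeds for Poisson profile
round trips; 20 replicates of 100-cell cohorts for the direction check;
200 replicates for null calibration. These sizes give stable medians and
proportions while keeping the full suite fast.

## Known limitations

* The circular-arc shape is an approximation to the true minimal surface;
  tensions and stiffnesses inherit its (small) geometric bias.
* Single drive frequency only — no frequency sweeps or power-law rheology.
* No 3D cortex reconstruction, chromatic z-shift correction, or PSF
  modelling in the image generator; profiles are rendered directly from
  the radial model.
* The exact placement of the √2 factors inside the erf arguments of the
  profile model is a documented convention (standard skew-normal); a
  different convention rescales α only.
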