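# Methods

This note records the models implemented, the defaults chosen where the
literature conventions are ambiguous, what the synthetic generator does
and does not emulate, and the numerical behavior a user should know
about.

## Quenching models and fitting strategy

All three quenching/binding models are fitted by **unweighted ordinary
least squares on their linearized forms** — the universal practice in
steady-state quenching papers, and deliberately so here: the package aims
to reproduce that workflow, not to improve on it with weighted or
nonlinear refits.

* Stern–Volmer: regression of F0/F on [Q] over the nonzero-concentration
  points; the intercept is reported and should be ≈ 1. The bimolecular
  rate constant k_q = K_SV/τ0 uses τ0 = 1×10⁻⁸ s, the conventional
  fluorescence lifetime of biopolymers; it is a parameter, not a fitted
  quantity.
* Modified Stern–Volmer: regression of F0/(F0−F) on 1/[Q]. Accessible
  fraction f_a = 1/intercept is reported exactly as fitted — values
  slightly above 1 occur in real data and are not clamped.
* Double-log ("Hill-type") fit: regression of log₁₀((F0−F)/F) on
  log₁₀[Q]; base-10 logarithms, as is conventional for these double-log
  plots. The intercept is extrapolated to [Q] = 1 M, far outside the
  titration range — see "Noise sensitivity" below.

Points with F ≥ F0 carry no quenching signal in the latter two
coordinate systems and are dropped with a warning.

**Biphasic detection.** Two site classes with different affinities bend
the modified Stern–Volmer plot concave-down. The test fits a quadratic in
1/[Q] and flags biphasic behavior when the quadratic coefficient is
negative with |t| > 2.0 (configurable). Single-site data are exactly
linear in 1/[Q], so the test has no false-positive pressure at zero
noise. When flagged, window-wise fits default to 1–25 µM (low) and
15–80 µM (high); the windows deliberately overlap, mirroring common
practice of anchoring both fits on the mid-range points.

**Mechanism classification** is rule-based: K_SV strictly decreasing
with temperature together with k_q above the maximal collisional rate
2×10¹⁰ M⁻¹s⁻¹ → static; K_SV strictly increasing with k_q at or below
that limit → dynamic; an upward-curvature flag (set by the caller from
the Stern–Volmer plot) → mixed; anything else → indeterminate. Two
temperatures are the minimum for any call.

## Inner-filter correction

The correction is F_cor = F_obs·10^((A_ex+A_em)/2). The factor-of-½
base-10 form is the standard absorbance-based correction; a natural-
exponent variant is selectable (`convention="exp_sum"`) for comparison
but is not the default. Corrections are monotone in both absorbances and
never reduce the measured intensity.

## Thermodynamics

The van't Hoff fit regresses ln K on 1/T with R = 8.314 J mol⁻¹ K⁻¹;
ΔH° = −R·slope, ΔS° = R·intercept. ΔG° defaults to ΔH° − TΔS°
(consistent with the fitted parameters); ΔG° = −RT ln K is exposed
separately because single-temperature estimates are often quoted that
way, and the two only agree when K lies exactly on the van't Hoff line.
With two temperatures the line is exact and r² is reported as 1; for
constant K the slope is zero (ΔH° = 0) and r² is likewise reported as 1.
Force classification is the standard sign table: (+,+) hydrophobic,
(−,−) hydrogen bond / van der Waals, (−,+) electrostatic; any pattern
involving an exact zero is "mixed".

## FRET

The overlap integral is evaluated by the trapezoidal rule on a common
uniform 0.5 nm grid restricted to the observed overlap window (not
0–∞); with λ in nm and ε in M⁻¹cm⁻¹, J carries units M⁻¹cm⁻¹nm⁴ and
R0(Å) = 0.211·(κ²n⁻⁴φ_D·J)^(1/6), converted to nm. Defaults are
n = 1.336, φ_D = 0.15 (tryptophan in aqueous buffer) and κ² = 0.476
(static orientations), with the free-tumbling preset 2/3 available.
Validity flags accompany every distance: the r⁶ equation is considered
reliable for 0.5·R0 < r < 1.5·R0, and meaningful transfer requires
2 ≤ r ≤ 8 nm.

Note that a published R0 of 2.88 nm quoted alongside J = 2.19×10¹⁴
M⁻¹cm⁻¹nm⁴ and κ² = 0.667 is ~1% below what direct evaluation of the
formula gives (2.91 nm) — consistent with J having been rounded after R0
was computed. The package always reports its own evaluated value.

## Structure probes

Synchronous traces are extracted along λ_em = λ_ex + Δλ by bilinear
interpolation on the EEM grid, indexed by excitation wavelength.
Peak-shift classification uses the most prominent peak of each trace
with a 1 nm tolerance (no-shift band) by default; the threshold is a
parameter because "no significant shift" has no universal definition.

CD helix content uses the raw (uninterpolated if on-grid) 208 nm
ellipticity, converted to mean residue ellipticity by
MRE = θ_obs/(10·C_p·n·l) and then to percent helix via the two-reference
form with −33,000 (pure helix) and −4,000 (β/coil) deg·cm²·dmol⁻¹.
Percentages outside [0, 100] are reported raw with a `clamped` flag
rather than truncated. No smoothing is applied before reading the
208 nm value.

## Synthetic data generator

Defaults encode the study design the package targets: 4 µM protein
titrated with 0–80 µM ligand on the grid
(0, 1, 5, 10, 15, 20, 25, 30, 40, 50, 60, 70, 80) µM at 290/300/310 K,
F0 = 1000 a.u. (arbitrary), two site classes (K = 3.1419×10⁴ M⁻¹ with
f_a = 0.64 and K = 4.5×10³ M⁻¹ with f_a = 0.36) whose constants move
with temperature on a van't Hoff line with ΔH = 43.4 kJ/mol,
ΔS = 222 J/(mol·K), and 1% multiplicative Gaussian intensity noise
(instrument noise magnitudes are rarely published; 1% is an engineering
choice). Free ligand is approximated by total ligand, the assumption all
the linearized models make implicitly (ligand is in large excess over
4 µM protein across most of the grid). Quenching is purely static — no
lifetime term — matching the mechanism the models are designed to
detect; a rising-K_SV series for exercising the dynamic branch is
obtained by configuring a negative ΔH.

Spectral shapes are Gaussian: EEM bands at 280/341 (Trp-like),
275/301 (Tyr-like) and 230/342 nm (backbone) with broad excitation
(σ = 30 nm) and narrow emission (σ = 4–6 nm) profiles; the narrow
emission is narrower than real protein emission (FWHM ~60 nm) and is
chosen so the synchronous Δλ = 15/60 diagonals peak at 301/341 nm as
observed for serum albumin. Absorbance spectra put protein bands at
222/278 nm and ligand bands at 207/244 nm, with complexation emulated by
shifting the 222 nm band +2 nm and amplifying it 15%. CD traces are
double negative bands (208/222 nm) scaled exactly to the requested helix
percentage. Consequently, passing tests demonstrate correctness of the
*arithmetic pipeline* on data satisfying the models' assumptions; they
do not validate baseline drift handling, scatter contamination,
non-Gaussian band shapes, or ligand-depletion effects, none of which the
generator produces.

Noise is applied only to titration intensities; spectra and EEMs are
generated noiseless. All randomness flows through an explicit integer
seed; identical config + seed gives bit-identical output.

## Noise sensitivity of the linearized fits

A finding worth stating plainly: with 1% intensity noise on the default
grid, the Stern–Volmer slope is recovered with ~1% median error over
100 seeds, but the modified Stern–Volmer K_a and double-log K_b are
**not** robust — median relative errors are roughly 100% and 25%
respectively. The cause is structural. At 1 µM with K ≈ 3×10⁴ M⁻¹ the
quenched difference F0 − F is only ~2% of F0, so 1% noise on F becomes
~70% relative noise on F0 − F; the 1/[Q] (resp. log[Q]) coordinate then
hands that point by far the largest leverage in the regression, and the
reciprocal transform makes the estimator biased, not merely noisy. The
double-log intercept additionally extrapolates five decades beyond the
data to [Q] = 1 M. Published fits of this kind with r² > 0.99 therefore
imply effective intensity noise well below 1%, or windowing that
excludes the weakly quenched points. The package keeps the unweighted
linearized fits (that is the method being reproduced) and documents the
sensitivity instead of silently reweighting.

## Numerical choices

* Wavelength grids are stored in nm; derivative and overlap operations
  resample to a uniform 0.5 nm grid first.
* Savitzky–Golay second derivatives default to a 21-point window (the
  nearest odd width to a nominal 20-point smoothing setting) with
  polynomial order 3; edge points come from the first/last full-window
  polynomial and peaks within one grid step of a boundary are discarded
  as edge artifacts.
* Peak finding uses prominence relative to the signal span (default 5%).
* Concentrations are handled in mol/L internally; the CLI-facing
  configs accept µM where noted.
* Energies are stored in J/mol and rendered as kJ/mol to one decimal in
  reports; binding constants render as ×10⁴ M⁻¹ to four significant
  figures; site-marker percent changes round to integers.

## Known limitations

Vendor binary formats, baseline/scatter correction, time-resolved
lifetimes, global multi-temperature fits, heat-capacity-dependent van't
Hoff curvature, CD basis-set deconvolution and docking are out of scope.
The acceptance script's problem sizes (three-temperature fits, single
closed-form distance solves) match the study design itself and run in
well under a second.
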