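# Methods

## Retention model

Each analyte is described by the linear solvent strength (LSS) relation
log₁₀ k = log₁₀ kw − S·φ, with φ the organic fraction (0–1) of the mobile
phase. Gradient elution is modeled by the ideal migration equation: the
solute travels while the inlet composition φ_in(t) — the pump program
delayed by the dwell time t_D = V_D/F and held at its final value after the
program ends — dissolves it, and elutes when

∫₀^{t_e} dt / (t₀·k(φ_in(t))) = 1, t_R = t₀ + t_e.

Two simplifications are inherited from the published LSS closed forms and
documented as such: the solute experiences the dwell-delayed *programmed*
composition (gradient traversal of the column bed is neglected), and
log k is strictly linear in φ (no quadratic term). Because φ_in is piecewise
linear, k(t) is piecewise exponential and the migration integral has an
exact closed form on every segment; the solver accumulates migrated fraction
segment by segment and inverts the closed form analytically inside the
segment where the fraction reaches 1 (`expm1`/`log1p` guard small
exponents). A self-consistency check re-integrates to t_e on every call and
demands 1 within 1e-6. There is no iteration and no convergence tolerance
beyond floating-point rounding; agreement with the independent single-ramp
closed form is at the 1e-13 min level.

Dead time defaults to the geometric estimate t₀ = ε·π·(d/2)²·L/F with total
porosity ε = 0.68 (typical packed silica); a measured t₀ (with its
measurement flow) overrides it. Dwell volume defaults to 1.0 mL. Neither is
printed in most method write-ups, so both are explicit configuration. Plate
count defaults to N = L/(h·d_p) with reduced plate height h = 2.5 (10000
for a 250 mm/10 µm column, 20000 for 5 µm); widths are w = c·4·t₀·(1+k_e)/√N
with the gradient compression factor c = 1.0 (disabled) by default, since
whether commercial simulators apply compression is not documented.

## Calibration over the tG–T–tC cube

The design is fixed at 2 gradient times × 2 temperatures × 3 ternary levels
(12 runs); other level counts are rejected rather than silently generalized.
A warning is issued if the gradient-time ratio falls below the recommended
three-fold spread. At each (T, tC) node, the two gradient times identify
(log kw, S): starting values come from the classical two-run gradient
algebra and are refined against the full forward model (dwell and hold
honored) with `scipy.optimize.least_squares` (bounds log kw ∈ [−2, 12],
S ∈ [0.1, 100]), falling back to a fixed grid of starts; the accepted fit
must reproduce both observations to ≤ 1e-4 min (lowest residual wins, ties
go to the smaller S). A damped Newton iteration would do the same job; the
library routine was preferred for its tested step control. Unretained
solutes and solutes eluting inside the dwell/initial hold in both runs are
reported as unidentifiable, not fitted.

Between nodes, log kw and S are each interpolated linearly in 1/T(K)
(van't Hoff form — the only law identifiable from two temperature levels;
S gets the same treatment rather than a constant-S assumption) and then
quadratically (Lagrange) in the ternary fraction x through the three
levels. Node queries return the fitted coefficients bit-for-bit.
Temperature extrapolation is allowed to ±10 °C with a warning; negative
interpolated S is clipped to 0 with a warning. Coefficients, not retention
times, are interpolated.

## Mapping, MODR and robustness

A virtual chromatogram is one peak per included analyte, sorted by
retention time (elution-order changes across the cube are handled by
re-sorting per cell); adjacent-pair resolution uses the baseline-width form
Rs = 2Δt/(w₁+w₂) and Rs,crit is the minimum, ties resolving to the
earlier-eluting pair. Excluding analytes never changes the remaining peaks,
only the adjacency. The default design-space grid is 21 (tG) × 31 (T) × 11
(tC) points; the MODR is the cell set with Rs,crit ≥ 1.5, and an empty MODR
is a valid, reportable outcome. Rs values are rounded to 2 decimals only in
exports. Robustness scans evaluate a full factorial of ±δ perturbations
(2 or 3 levels, nominal always included) over tG (time-axis stretch of the
whole program), T, x and flow, clipping x into [0, 1] with a warning.

## Peak tracking

Identities come from a three-mixture spiking scheme (a full mixture plus
two partial mixtures). Presence/absence signatures are established by
one-to-one retention-time matching between the full-mixture peaks and each
partial injection (minimum total |Δt_R|, matches beyond the window
forbidden) — one-to-one so that two nearly co-eluted peaks cannot both
claim the same replicate peak. Within a signature group, peaks are assigned
to candidates by matching normalized area shares to normalized nominal
concentration shares (Hungarian assignment); two candidates whose areas and
concentrations are both within 10% are ambiguous unless a user-supplied
expected elution order resolves them. Ambiguous peaks are flagged, never
guessed. The default matching window is 0.1 min; as a rule the window
should be at least five standard deviations of the *difference* between
replicate injections (σ_Δ = √2·σ_tR), i.e. 0.15 min for 0.02-min retention
noise, and the accuracy scans use that value. This evidence-combination
scheme replaces the proprietary composite-chromatogram approach of
commercial software; it behaves identically on resolvable chromatograms
and flags merged peaks instead of resolving them heuristically.

## Synthetic data

The generator emulates the study conditions end to end so every stage is
testable without downloads. Truth for each analyte is a continuous
parametric surface — base log kw ~ U[1.5, 4.5] and S ~ U[3, 8] at 20 °C,
a van't Hoff slope giving a 1–3 % decrease in k per °C, a mild 1/T slope on
S, and quadratic ternary perturbations with amplitude ≤ 0.5 (log kw) and
≤ 1.5 (S) — exactly the family the calibration interpolates, so noiseless
round trips are exact by construction and test the fitting/plumbing, not
the interpolation family. Draws are resampled (bounded attempts) until all
12 corner retention times lie in [15, 80] min: comfortably past the
dwell/initial hold, where both LSS parameters are identifiable, matching
the retention spans of the emulated study (~17–66 min). Elution-order
reversals across the cube are allowed — they occur in practice and the
mapping must handle them.

Noise is additive gaussian on retention times (default SD 0.02 min, which
propagates to setpoint prediction errors of the order seen in real
validation studies, 1–6 %) and multiplicative gaussian on areas (default
CV 3 %). Response factors are drawn from U[0.97, 1.03] (closely related
compounds sharing a chromophore at one wavelength). The nine-compound
roster uses the nominal mixture concentrations of the emulated study; note
those concentrations contain within-signature-group ties (several
impurities at 8 µg/mL), which no area-based tracker can separate — the
`distinct_concentration_scheme` variant (same memberships, ≥1.5× spaced
concentrations) is provided for tracking-accuracy work. Detector-style
traces are sums of gaussians (σ = w/4, integral = area) plus white
baseline noise. Everything is deterministic under a fixed seed.

What passing synthetic tests do *not* show: real chromatograms deviate from
LSS linearity (secondary interactions on some stationary phases produce
retention-time errors of several percent even when selectivity is
predicted well), detectors merge co-eluted peaks instead of reporting two
entries, and widths/plate counts vary with analyte and conditions. The
printed-table fixtures exist precisely to pin the validation arithmetic to
real published measurements.

## Problem sizes and numerical choices

The test suite and the acceptance script use desk-scale problems chosen as
the package's own defaults: 9 analytes, the 12-run design, a 200-point
solver sweep, 200 noise replicates for parameter recovery, 50 off-design
setpoints, a 5×4×3 verification map and 100 tracking replicates. Reported
percentages are rounded half-up to 2 decimals at the reporting layer only;
raw values are kept internally. Validation-table averages use the mean of
absolute signed errors per setpoint and the mean of per-setpoint means per
column — the mixed-sign setpoint in the transcribed tables (signed mean
≈ 0.5 %, printed 4.15 %) confirms the absolute convention, and averaging
setpoint means (not pooling peaks) reproduces both printed overall figures
exactly.

## Known limitations

- No pump mixing dynamics, pressure/viscosity effects, pH or buffer
  dimensions, or temperature gradients along the column.
- Curved (quadratic) log k–φ behavior is out of scope; analytes that
  genuinely curve will calibrate to a compromise slope.
- Flow rescaling changes t₀ and t_D only; plate count and coefficients are
  held (documented simplification).
- Absolute retention predictions for the published study's own corner data
  are not reproducible because its appendix retention tables, dead time,
  dwell volume and plate counts are not available; the validation
  arithmetic on the printed tables and property-based synthetic recovery
  stand in for them.
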