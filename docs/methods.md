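# Methods

## Scope and model

The package covers the data-processing layer of a standardized
physicochemical characterization of particulate TiO₂ food additives by two
complementary techniques: quantitative TEM (particle projections →
Feret-diameter distributions → EC nanomaterial classification) and
single-particle ICP-MS (time-resolved traces → equivalent-spherical-diameter
distributions and concentrations), together with the metrological
uncertainty budget that qualifies both, and a Stokes-law calculator used to
dimension centrifugation-based sample preparation. Instrument control,
dispersion chemistry, real-micrograph preprocessing and electron-diffraction
analysis are out of scope; image segmentation is a simplified
(distance-transform watershed / connected components) re-creation intended
for clean synthetic images, not a replacement for production segmentation of
real micrographs.

## spICP-MS processing

**Event discrimination.** The baseline (dissolved analyte + instrument
background) is separated from particle plumes by iterative outlier trimming:
mean µ and SD σ (n−1 denominator) of the current inlier set define a
threshold µ + kσ (k = 5 by default); readings above it are moved to the
event set and the statistics recomputed until the inlier set is stable
(cap: 1000 iterations, error on non-convergence). Because the threshold is
non-increasing across iterations the procedure converges monotonically. A
trace of identical readings has σ = 0 and yields zero events. Runs of
consecutive above-threshold dwells are ion plumes split across dwell
windows; the default policy **merges** them into one event (summing net
counts conserves particle mass), with `drop` and `keep` available for
sensitivity analysis.

**Calibration.** An ionic standard at concentration c delivers
`W = η · (q/60) · t_dwell · c` analyte mass to the plasma per dwell
(η transport efficiency, q flow in mL/min, t_dwell in s; 1 µg/L = 10⁶
fg/mL), so the sensitivity is S = slope / W_unit in counts per fg. The
transport efficiency itself comes from the particle-frequency method:
detected events divided by the number of reference particles nebulized
during the run, with the reference particle mass (π/6)ρd³. With the
documented acquisition settings (0.47 mL/min, 3 ms, 60 s) and 30 nm gold at
12.5 ng/L, 1033 detected events give η = 4.8 %.

**Sizes, limits, concentrations.** Net counts → analyte mass (÷S) →
particle-compound mass (×1.67 for TiO₂/Ti) → ESD. The size detection limit
is the µ + 3σ background intensity, floored at 4 counts — with very clean
backgrounds the statistical limit drops below what a single plume can
reliably produce, and 4 counts of Ti correspond to a 39 nm TiO₂ particle at
the validated instrument sensitivity (≈50.8 counts/fg). The quantification
limit uses µ + 10σ with the same floor; the 10σ multiplier is a
configurable convention chosen for symmetry with the detection rule, since
no closed-form definition accompanies the sample-dependent quantification
limit. Concentrations divide event counts and summed masses by
V_eff = η·q·t and are then dilution-corrected; normalization per kg of
powder is a separate explicit step given the dispersion's powder loading.
A dilution-series checker flags non-proportional counts (default 20 %
relative tolerance), unstable medians (10 %) and counts outside the
workable 200–2200 range.

## TEM sizing

Feret extents use rotating calipers on the convex hull: the maximum Feret
diameter is the hull diameter, and the minimum is the smallest width over
hull-edge-normal directions (the minimum width of a convex body is attained
flush with an edge). For ellipse-fit mode the full axes of the
moments-equivalent ellipse (4·√eigenvalues of the central second-moment
matrix) estimate Fmax/Fmin, matching the convention of treating the fitted
primary axis as the Fmax estimate. Quantification windows follow the
pixel-based rules LLOD = pixel size, LLOQ = 10·LLOD (Merkus criterion),
ULOD = field width, ULOQ = ULOD/10; values outside [LLOQ, ULOQ] are
excluded strictly and the excluded fractions reported.

Distribution summaries are number-weighted (q₀): linear-interpolation
quantiles, a Gaussian-kernel KDE with Silverman bandwidth on a 512-point
grid spanning the data range ± 3 bandwidths (mode = grid argmax, ties to
the smallest value), 64 equal-width histogram bins normalized to unit
integral, and a strict-inequality convention for the fraction below 100 nm
(a particle at exactly 100 nm is not "below"). The EC classification calls
a material a nanomaterial when the median Fmin is below 100 nm, and
"significantly below" when median × (1 + relU) < 100 with relU the relative
expanded uncertainty (k = 2); the default relU switches at 50 nm between
the small-particle (9.2 %) and ~100 nm (8.5 %) validation estimates.

## Uncertainty budgets

A day × replicate precision design is decomposed by one-way ANOVA:
s_r² is the within-day mean square; the between-day variance component is
(MS_between − MS_within)/n₀ with Searle's n₀ for unbalanced designs,
clamped at zero with a warning when negative (a "conservative" alternative
is to carry the full reproducibility SD as the between-day term, which is
what the concentration-measurand budgets in the validated method use).
Routine-conditions combination (n_rep replicates on n_days days):

    u_c = sqrt(s_r²/n_rep + s_d²/n_days + u_Δ²),   U = k·u_c (k = 2).

The trueness uncertainty u_Δ is an input, not derived here — the validated
method reports the component without its derivation. Display rounding is
half-away-from-zero, one decimal for u_c and integer percent for U; the
displayed U doubles the *displayed* u_c, matching the reporting convention
of the validation table. ± half-widths on reported medians are
median × relU rounded to the median's display precision (integer nm for
sizes, two decimals for aspect ratios).

## Stokes-law protocol design

Constant-field approximation: v = Δρ·g_eff·d²/(18η), distance = v·t. The
default parameter set — density contrast 2.90 g/cm³ (anatase 3.90 minus
water 1.00), viscosity 0.93 mPa·s, RCF 2000 — is a reverse fit: it is the
rounding-consistent mobility that reproduces the published six-entry
sedimentation table (20/40/60 nm × 30 min/2 h) to 0.1 cm, since the source
protocol states neither temperature/viscosity nor the anatase density used.
All four parameters are overridable. The constant-field (fixed effective
radius) choice follows from the published distances scaling exactly
linearly with time. A 60 nm particle clears the 1.75 cm vial column in
about 24 minutes at these settings.

## Synthetic data: what it emulates and what it does not

Trace simulation draws per-dwell baseline counts from Poisson(background
mean), particle arrivals from Poisson(λ) with λ = concentration·η·q·t_dwell
(λ ≥ 0.1 is rejected as coincidence regime), particle sizes from a
lognormal, and plume counts from Poisson(S · analyte mass); an option
splits a fraction of plumes over two dwells to exercise the merge policy.
Defaults: lognormal median 90 nm with GSD 1.3 (right-skewed,
moderately polydisperse, representative of these additives), 2.5 × 10⁷
particles/L (λ ≈ 0.028, ≈560 events/min), background 1 count/dwell,
sensitivity 200 counts/fg. The sensitivity default is deliberately a
high-sensitivity configuration (size detection limit ≈ 25 nm) so that the
whole population is quantifiable and the recovery studies test the
estimator chain rather than detection censoring; at the validated
instrument sensitivity (~51 counts/fg, 39 nm limit) a 60 nm-median
population loses its lower tail below ~45 nm and the recovered median is
biased high by several percent — the known blind spot of the technique near
its detection limit, not an estimator defect. Not modeled: flicker noise,
plume shape within a dwell, ionic background drift, matrix effects.

Image rendering rasterizes equal-projected-area ellipses (axes from ESD and
AR) at random positions/orientations, optionally forcing a fraction to
touch a previously placed particle; it emulates micrograph content
(projections, touching aggregates) but not TEM contrast, noise, or support
artifacts — passing image-pipeline tests therefore validates geometry
measurement, not real-micrograph segmentation. Precision tables add
independent normal day and replicate effects in relative units.

## Problem sizes and numerical choices

Recovery studies use 40,000-dwell (2 min) traces giving ~1100 events per
trace; at that size the per-trace sampling noise on the mass concentration
is ~4 % (single-particle mass CV ≈ 0.9 at GSD 1.3), comfortably inside the
10 % recovery check. ANOVA bias checks average 300–500 simulated 5 × 3
designs; the false-positive check uses 100 pure-Poisson traces of 20,000
dwells (observed event rate ≈ 10⁻⁵ per dwell at 5σ, versus the 10⁻³
acceptance bound). All stochastic paths take explicit integer seeds and use
numpy's default (PCG64) generator.

## Known limitations

- The watershed splitter handles touching convex blobs; heavily aggregated
  small-particle materials (the pearlescent-pigment case) are beyond it, as
  they are partially beyond the production segmentation it simplifies.
- The between-day convention for concentration measurands (reproducibility
  carried whole) and the clamped-ANOVA convention give different budgets
  when MS_between < MS_within; both are exposed, the caller chooses.
- Split plumes longer than two dwells are merged correctly but the
  simulator only generates ≤ 2-dwell plumes.
- `combine_uncertainty` ignores correlation between components (no
  GUM-style covariance propagation).
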