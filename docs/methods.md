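# Methods

## Shape model

The profile of an egg-shaped fruit is modelled by the explicit Preston
equation (EPE): with `u = x/b ∈ [−1, 1]`,

    y(x) = ± a √(1 − u²) · P(u),    P(u) = 1 + c₁u + c₂u² + c₃u³.

`a, b > 0` are in cm; the coefficients are dimensionless. The ± branches
are the upper/lower profile halves, so the closed curve is symmetric about
the long (x) axis — the premise of the solid-of-revolution computation.
A parameter set is *valid* when `P > 0` everywhere on `[−1, 1]` (otherwise
the curve would cross its own axis); validity is checked on a fixed
2001-point grid, which is ample for the coefficient magnitudes real fruit
profiles exhibit (|c| well below 1).

Two conventions worth stating explicitly:

- The polynomial *multiplies* the ellipse term. This is the form whose
  solid-of-revolution volume has the closed form used below (the two are
  algebraically inseparable: π b ∫ a²(1−u²)P(u)² du expands term-for-term
  into that polynomial).
- Length is `L = 2b` by construction. Width `W = 2·max y` is located
  numerically (dense grid + bounded refinement) because the cubic
  modulation moves the widest section off `x = 0`; `W = 2a` holds only in
  the symmetric case. All analysis-level `W` values come from the fitted
  curve; the raw-point maximum is exposed separately as a diagnostic.

## Geometry

Rotating the upper half-profile about the x-axis:

    V = π ∫ y² dx = (4π/315) a² b (105 + 21c₁² + 42c₂ + 9c₂² + 18c₁c₃ + 5c₃²)
    S = 2π ∫ y √(1 + y′²) dx.

The closed-form V is the production path; an adaptive-quadrature oracle of
the first integral is kept in the API and asserted against it (relative
1e-8) so a regression in either path is caught by the other. The surface
integrand is improper at the tips (`y → 0`, `y′ → ∞`); substituting
`x = b sin t` gives the smooth integrand `y·√((dx/dt)² + (dy/dt)²)`,
integrated with fixed tolerances (relative 1e-10, absolute 1e-12 scaled by
`a·b`). Tolerances are deliberately not configurable: the geometry layer
serves as the oracle for the statistics above it.

For any fixed shape scaled isometrically, `log S` vs `log V` has slope
exactly 2/3; this identity links the geometry and regression layers and is
verified to 1e-10 in the tests.

## Digitization chain

Images are binarized at the 50% grey level; the fruit is the phase not
touching the image border. The outer contour of the largest connected
component is traced by marching squares at the 0.5 level (subpixel,
ordered, closed). Scale calibration equates the pixel length of the
boundary's longest chord with the caliper-measured fruit length and
applies that factor isotropically — which is why the pipeline assumes
prolate fruits (length = longest dimension). Standardization rotates the
longest chord onto the x-axis (ties broken toward the smaller angle with
the horizontal), centres its midpoint, starts the traversal at (−L/2, 0),
orients counterclockwise, and resamples to n = 1000 approximately
arc-length-equidistant points by linear interpolation along the polygon.
Standardization is idempotent: a profile already carrying the standardized
flag at the requested n is returned unchanged. No boundary smoothing is
applied by default.

## Fitting

Nelder–Mead minimizes Σ(yᵢ − ŷᵢ)² with branch assignment by the sign of
the observed yᵢ (zero → upper). Initialization is moment-based
(a₀ = max y, b₀ = half x-extent, c = 0) plus 4 restarts with the
coefficients jittered ±0.05 (fixed default seed 20241106); best RSS wins.
Points whose |x| exceeds the current b contribute a continuous overshoot
penalty (10·a per cm of overshoot added to the residual) so the simplex
objective stays smooth. Tolerances: 1e-10 on the objective, 1e-8 on
parameters, 20 000 evaluations; exhaustion returns `converged=False`
rather than failing silently. Fit quality is the adjusted RMSE
`√(RSS/n) / (W/2)` with W from the fitted curve, making the score
dimensionless and unit-invariant; 0.05 is the conventional good-fit
threshold. Noiseless 1000-point profiles are recovered to ~0.1% in a, b
and ~1e-4 absolute in the coefficients, at ~0.15 s per fit.

## Statistics

- `ols_with_ci`: OLS with the 95% t-interval of the slope; r² is the
  squared Pearson correlation of the (possibly log10-transformed)
  variables. Log-base choice does not affect slopes, CIs or r².
- Solid-of-revolution test: linear regression of **V_obs on V_pred**, with
  the strict verdict `1.0 ∈ CI` and a banded verdict `|slope − 1| ≤ 0.1`
  (configurable) for the informal "close to 1" reading used when a tight
  CI narrowly excludes unity. The observed volume is the response because
  it carries the measurement error; regressing the clean predictor on the
  noisy measurement instead would attenuate the slope below 1 (errors in
  variables) and make the test reject unbiased cohorts.
- Allometry: log10–log10 fits of S ~ V_obs, V_pred ~ LW², S ~ LW².
- Group comparisons: one-way ANOVA, Tukey HSD (studentized-range
  adjustment, α = 0.05, no further correction across responses), compact
  letter display computed from the maximal cliques of the
  non-significance graph, and per-group CV (sd/mean, %).

## Synthetic cohorts

The generator emulates a photographed-tomato study; three presets set the
scale of the three cultivars examined in such work:

| preset | n | b (cm) | W/L ratio | c sds | radial noise | ~V median |
|---|---|---|---|---|---|---|
| cherry | 297 | U(1.42, 1.87) | U(0.84, 0.96) | .05/.05/.03 | 3.4% | 15.4 cm³ |
| qianxi | 320 | U(1.44, 1.98) | U(0.83, 0.95) | .05/.05/.03 | 4.8% | 17.0 cm³ |
| truss  | 300 | U(1.08, 1.45) | U(0.94, 1.00) | .03/.03/.02 | 2.6% | 8.1 cm³ |

Half-length b and the width ratio a/b are sampled uniformly (rather than
a and b independently) so that every draw is prolate: oblate draws would
make the longest chord the width axis and silently break caliper-length
calibration. Coefficients are centred Gaussians, resampled (≤100 tries)
until the profile is valid. The radial noise levels reproduce the
fit-quality ordering (truss best, Qianxi worst) observed in real cohorts
of these cultivars.

Digitization error is a **spatially correlated** radial field: a periodic
Gaussian process along the boundary (sd = `radial_noise_frac·a`,
correlation length 0.10 of the perimeter by default) displacing each curve
point along the unit vector from the centroid, followed by
re-standardization. A traced boundary is a connected curve, so its error
is smooth at the point-spacing scale; white per-point noise at these
amplitudes would exceed the 1000-point spacing, produce a self-intersecting
polygon, and — because horizontal displacements near the tips map into
y-residuals amplified by the diverging slope — inflate RMSE_adj to ~4× the
nominal noise level. With the correlated field the propagation is
approximately one-to-one (measured: median RMSE_adj ≈ 0.0095 at 1% noise),
which is the regime real digitized cohorts show.

Observed volume is simulated as `V·(1 + N(0, v_obs_noise_frac))` (default
5%) rounded to `v_obs_resolution` (default 1 cm³ — an optimistic single
graduation of a 250 mL cylinder; the knob exists precisely to study how
cylinder resolution degrades small-fruit accuracy) and floored at one
step. Rendering rasterizes the filled silhouette at 600 dpi equivalent
(2.54/600 cm per pixel) with a ≥10 px margin.

All randomness uses `numpy.random.default_rng` (PCG64); cohorts are
byte-reproducible from their seed.

What the generator does **not** emulate: real surface irregularity
(dents, blemishes — model-error rather than noise), out-of-plane
misalignment of the fruit axis, perspective distortion, and
non-revolution 3D shapes (a cohort whose fruits genuinely violate the
revolution assumption cannot be produced, so passing tests demonstrate
correctness of the machinery, not that any particular real cultivar is a
solid of revolution).

## Problem sizes and numerical choices

The validation suite uses cohorts of up to 300 profiles at 1000 points,
50 noiseless recovery fits, 50 replicate cohorts for CI coverage, and 20
full image round trips at 600 dpi — sizes at which every behaviour of
interest is already stable. CSV output is fixed at 6 significant digits to
make bit-reproducibility checkable. Degenerate inputs (flat profiles,
empty masks, single-phase images, sub-50-pixel components, non-positive
lengths or volumes) raise with specific messages rather than propagating
NaNs.

## Known limitations

- The pipeline assumes prolate fruits photographed with the long axis in
  the image plane; near-spherical fruits (W/L → 1) make the longest-chord
  orientation numerically ill-conditioned, and genuinely oblate fruits
  would be mis-calibrated.
- The fit minimizes vertical residuals only (no orthogonal-distance
  regression), matching field practice for this model family.
- Tukey HSD assumes approximate normality and homoscedasticity of the
  response; the package reports the tests without diagnosing those
  assumptions beyond what the caller inspects.
- Reduced/standardized major-axis regression, common in allometry, is
  deliberately out of scope; all slopes are OLS.
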