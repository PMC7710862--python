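# Methods

This note records the models implemented in `mimicolor`, the conventions
chosen where the problem leaves genuine freedom, and what the synthetic
data can and cannot establish.

## Colour space

Stimulus reflectance is resampled onto a 300–650 nm grid at 10 nm with a
shape-preserving piecewise cubic Hermite interpolant (PCHIP): monotone
input segments stay monotone and the interpolant cannot overshoot local
extrema, which is the right behaviour for smooth floral reflectance
measured on irregular spectrometer grids. Resampling refuses to
extrapolate.

Receptor quantum catches use von Kries adaptation:
`P_i = R_i Σ_λ I_S(λ) S_i(λ) D(λ)` with `R_i = 1 / Σ_λ I_B(λ) S_i(λ) D(λ)`,
where `I_S` is stimulus reflectance, `I_B` the adaptation background, `D`
the illuminant and `S_i` the receptor sensitivity. Sums are left-rectangle
rules on the common 10 nm grid; the constant bin width cancels in the
ratio, and any consistent quadrature rule largely cancels under von Kries
normalisation. Excitation is the saturating transduction `E = P/(P+1)`,
so a background-matching stimulus sits at `E = 0.5` in every receptor and
maps to the hexagon centre for any illuminant. The hexagon projection is
`x = (√3/2)(E_G − E_UV)`, `y = E_B − (E_UV + E_G)/2`; perceptual colour
distance is Euclidean in this plane (hexagon units, Hu).

The default visual system is honeybee-like, built from parts that are not
printed in any single table and therefore synthesised here:

- **Sensitivities**: A1 rhodopsin template curves (Govardovskii-style alpha
  band plus the small beta band) at λmax = 344, 436, 544 nm. CSV-supplied
  curves can replace them.
- **Illuminant**: the CIE D65 daylight distribution converted to relative
  photon flux (energy × λ) and normalised to 1 at 540 nm. The
  normalisation is cosmetic — it cancels in adaptation.
- **Background**: a smooth synthetic green-leaf reflectance (5% UV floor,
  15% peak at 550 nm, width 42 nm). Only its relative shape matters.

Because all downstream analysis runs on colour *distances*, none of the
reported quantities depend on the absolute position of loci, and clouds
given in a translated all-positive x′y′ frame (as the flower PDFs are) are
used as-is: translation leaves every pairwise distance unchanged. The
offset between the native hexagon frame and the x′y′ frame is not
recoverable from the published parameters, so absolute loci of the study
flowers are not reconstructed.

## Discrimination functions

Two psychometric forms, keyed by parameter count (equation numbering in
the source material is inconsistent, so the package never refers to it):

- `logistic3` (successive viewing): `π = Mo·K / (Mo + (K−Mo)·e^(−r·ΔC))`.
  `K` is the upper limit, `Mo` the value at ΔC = 0, `r` the increment rate
  per Hu.
- `logistic4` (absolute conditioning):
  `π = Mo + (K−Mo) / (1 + e^((xmid−ΔC)/scal))`. `K`/`Mo` are upper/lower
  asymptotes, `xmid` the inflection distance, `scal` the rate scale (Hu).
  The rate parameter is named `scal` throughout, following the coefficient
  table it comes from.

Reported probabilities are clamped at the 0.5 chance floor of a
two-alternative task; *fitting* uses the raw curve, because empirical
lower asymptotes (e.g. Mo = 0.441) genuinely fall below chance in the
behavioural data. The π75 threshold distance solves `π(ΔC) = target` by
Brent root finding to 1e-8 Hu; by monotonicity, "fraction of pairs with
π < 0.75" and "fraction of distances below the π75 distance" are the same
number, and the report computes them that way.

Fitting is nonlinear least squares on choice proportions (Gaussian
residuals, as in the original analysis — not a binomial GLMM), with
self-starting values (K from the data maximum, Mo from the minimum, rate
from the steepest rise) and random restarts. The optional per-subject
random effect on one named coefficient (by default the second-listed
parameter, the rate `r`) is marginalised by 21-node Gauss–Hermite
quadrature and maximised with Nelder–Mead; 95% CIs come from the numerical
Hessian. The LRT compares nested fits via `2Δll ~ χ²`; the simpler form is
kept when p ≥ 0.05. The bootstrap equality-of-means test is the
studentised two-sample form with pooled recentring; p is the plain
fraction of resampled |t*| at least as extreme as observed.

## Colour PDFs and copulas

A species' colour cloud is `f(x,y) = f_x(x) f_y(y) c(F_x(x), F_y(y))`,
with normal (mean/std), gamma (shape/rate) or Weibull (shape/scale)
marginals — parameter conventions exactly as the published table prints
them — and a parametric copula. No copula library is a dependency; the
three families are implemented directly:

- **Gumbel** and **Tawn type II** share the extreme-value code path
  `C(u,v) = exp{−(x+y)A(t)}` with `x = −ln u`, `y = −ln v`,
  `t = x/(x+y)`. Gumbel: `A(t) = (t^θ + (1−t)^θ)^{1/θ}`. Tawn II:
  `A(t) = (1−ψ)t + ((1−t)^θ + (ψt)^θ)^{1/θ}`, asymmetry weight ψ ∈ [0,1]
  on the **first** margin (ψ = 1 is Gumbel, ψ = 0 independence). Density
  and conditional CDFs follow from the Pickands derivatives analytically.
- **Joe** is Archimedean, with the standard closed-form density and
  h-function.

Rotations are true rotations of the unit square, the convention of the
vine-copula software the published parameters were fitted with: the
rotated densities are 90°: `c(v, 1−u)`, 180° ("survival"):
`c(1−u, 1−v)`, 270°: `c(1−v, u)`. For exchangeable families this equals
per-axis reflection; for the asymmetric Tawn family it does not, and the
distinction is observable — under reflection conventions the labellum/
pollen confusion percentages drift several points from the published
values, while the rotation convention reproduces all of them. A negative
printed parameter for 90°/270° rotations means |θ| in the base family.
Sampling is by conditional inversion: draw `u, w ~ U(0,1)`, solve
`h(v|u) = w` with 50 vectorised bisection steps (well past the 1e-10
tolerance), then map the pair through the rotation. Kendall's τ is
computed without sampling as `τ = 1 − 4∫∫ ∂_u C ∂_v C du dv` by 200-node
Gauss–Legendre quadrature; for Gumbel it agrees with the closed form
`1 − 1/θ` to 1e-5. Marginal CDF values are clipped to
`[1e-12, 1 − 1e-12]` before copula evaluation to avoid log(0); points
outside a marginal's support have density 0.

`fit_marginal` is ML (closed-form for normal with the 1/n variance;
numeric with location fixed at 0 for gamma/Weibull), with asymptotic SEs
from the observed information. The Anderson–Darling test is against the
*fully specified* fitted CDF with the Marsaglia & Marsaglia (2004)
asymptotic p-value plus finite-n correction. `fit_copula` maximises the
likelihood per candidate (family × rotation, θ re-parameterised as
`1 + e^a`, ψ by logit) and selects by AIC; the default candidate set is
the three families in all four rotations plus independence.

## Monte-Carlo confusion analysis

Within a species, 100,000 loci are sampled from its PDF, their densities
evaluated, and frequency classes assigned from empirical density
quantiles: typical above the 0.9 quantile, less frequent in (0.45, 0.55],
rare in (0.15, 0.25] — each holding ~10% of loci by construction.
Class-pair mean distances use random cross-pairs capped at 100,000 rather
than exhaustive pairing (means agree within MC error at a fraction of the
cost). Cross-species distances pair independent single draws elementwise
(not all-vs-all), keeping cost linear in n. Reports are invariant to any
common translation of both clouds.

Default problem sizes: n = 100,000 samples/pairs everywhere, matching the
published analysis; at this size the Monte-Carlo standard error of the
reported medians is ~1e-4 Hu and of the percentages ~0.15 points, and
repeated seeds move the headline numbers only in the second decimal. The
unit-test suite uses 10,000–50,000 where the check is structural rather
than quantitative.

The simultaneous-viewing condition is supported only as a user-supplied
coefficient set (its published fit belongs to a different source); reports
include a `simul` column only when such a function is passed.

## What the synthetic data shows — and does not

The spectrum generator produces smooth baseline-plus-Gaussians reflectance
with optional noise, emulating the UV-blue profile of the study flowers;
the choice-data generator draws binomial counts from a known psychometric
curve with Gaussian per-subject variation in one coefficient. Passing
tests therefore demonstrate *internal* correctness — projections, fits and
samplers recover what generated the data — and reproduction of the
published quantities from the published parameters. They do not validate
the visual-system templates against measured bee sensitivities, nor the
PDFs against the original reflectance measurements (which the parameter
tables summarise), nor bee behaviour beyond the psychometric model class.

## Known limitations

- Chromatic information only: no achromatic/green-contrast channel, no
  receptor-noise (RNL) model, no alternative colour spaces.
- Single bivariate copulas only; no vines, no nonparametric dependence,
  no trivariate excitation models.
- The mixed-effects machinery supports one scalar random effect; the
  published t-statistics for the function-equality bootstrap are not
  reproduction targets because the distance grid they averaged over is
  unspecified.
- Printed parameters are rounded to 3 significant figures; the residual
  few-percent offsets in the Monte-Carlo quantities (e.g. petal median
  0.050 vs 0.053 Hu) are consistent with that rounding plus parameter
  uncertainty, and stable across seeds.
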