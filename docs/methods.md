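# Methods

This note documents the statistical machinery in `saltol`, the choices
made where the design was genuinely open, and what the synthetic-data
tests do and do not establish about real field data.

## Quantile regression core

**Model and solver.** The conditional quantile Q_y(p | x) = xᵀβ(p) is
estimated by minimising Σᵢ ρ_p(yᵢ − xᵢᵀβ) with ρ_p(u) = u(p − 𝟙[u < 0]).
We solve the *dual* linear program, max yᵀa s.t. Xᵀa = (1 − p)Xᵀ1,
0 ≤ a ≤ 1, with the HiGHS dual simplex; the equality-constraint marginals
recover β exactly and the solution is a vertex, so the usual residual
sign-balance bounds (#{r < 0} ≤ np, #{r > 0} ≤ n(1 − p)) hold.  The dual
variables `a` are the regression rank scores, which the confidence-
interval machinery reuses.  LP optima need not be unique in degenerate
(small-n, tied) configurations; tests compare objectives rather than
coefficients there.

**Rank-score confidence intervals.** A candidate value ξ for coefficient
j is tested by fitting the restricted model with the offset ξx_j removed,
taking the restricted fit's dual scores b = a − (1 − p), and forming
T(ξ) = x̃ᵀb / sqrt(p(1 − p) x̃ᵀx̃), where x̃ is the residual of x_j
projected off the remaining columns.  The 1 − α interval is
{ξ : |T(ξ)| ≤ z_{1−α/2}}.  T is monotone non-increasing in ξ, so the
acceptance boundary is found by bisection, bracketed at ±10 classical
(OLS) standard errors with geometric expansion; if a bracket cannot be
established the interval falls back to an accession-pairs bootstrap
(percentile, B = 1000) and the result is tagged.  Two score variants are
provided: `iid` projects x_j off the nuisance block unweighted;
`nid` (the default, appropriate for heteroscedastic field data) weights
the projection by local conditional-density estimates f̂ᵢ obtained from
the difference quotient of fits at p ± h with the Hall–Sheather
bandwidth.  The bisection tolerance is 1% of the classical standard
error by default (5% in the large replication studies; the interval
endpoints are far less sensitive than their widths).  Coverage of the
nid intervals on the heteroscedastic generator is checked empirically in
the acceptance study (nominal 95%, observed ≈ 0.95 at 100 replicates).

**Mean-regression comparison.** OLS with classical standard errors and
t-tests is reported next to every quantile analysis, mirroring the usual
side-by-side presentation; variance inflation factors (VIF_j =
1/(1 − R²_j)) are available for covariate screening, with `inf` reported
under perfect collinearity rather than an exception.

**Centering.** Covariates are centered to mean 0 (pooled across both
conditions, before interactions are formed) so the intercept is the
fitted response at the trait means.  Slopes are unaffected; centering
within condition instead would change the interaction intercepts, and
users with a preference can center externally and pass covariates
through untouched.  Covariates are deliberately *not* scaled to unit
variance: effects stay in interpretable units (g/m² per cm, per day,
per grain).

## Trait models

The pooled yield model uses covariates {plant height, flowering time,
ripening period, ear number per plant, grain number per ear}; harvest
index, thousand-grain mass and dry mass are excluded by default because
they are partial expressions of yield itself and induce collinearity.
The quantile grid defaults to 0.1, …, 0.9 in steps of 0.1.  The SWP
model uses the saline-condition traits of the same accessions
(n = number of paired accessions).  Significance at each level is strict
exclusion of zero by the rank-score interval.

## Selection rule

Salt tolerance is judged against the no-intercept conditional quantile
line of saline yield on non-saline yield (level p₁), high yield against
the inf-based marginal empirical quantile of saline yield (level p₂).
"Above" is a strict inequality: points on either line are not selected.
The response/covariate orientation (saline conditioned on non-saline) is
the one consistent with the marginal threshold also being on saline
yield; the opposite orientation is available via a flag.  The model is
fit through the origin as specified (y = αx + ε); an intercept can be
enabled.  Both levels are practitioner choices, not estimated.

## Directional quantile envelopes

Directional quantiles use the inf-based (type-1) empirical quantile of
the projections, Q(p, s) = inf{t : F_s(t) ≥ p}, with closed halfspaces
H(s, q) = {y : sᵀy ≥ q} throughout — the discrete set D(p) = ⋂ H(s, Q)
over all directions is then *exactly* the Tukey depth level set
{y : depth(y) ≥ p}, a fact the test suite exploits as an oracle.  With a
finite direction set the envelope can only grow, so discretisation error
is one-sided and O(1/M²) for smooth contours; M defaults to 360 for
static envelopes.

Emptiness is decided by the Chebyshev-center feasibility LP (maximum
inscribed-circle radius r): infeasible or r < −10⁻⁹ ⇒ empty; |r| ≤ 10⁻⁹
⇒ a degenerate envelope represented by the single Chebyshev-center
vertex (this occurs at exactly symmetric configurations, e.g. the level-½
envelope of the four square corners); otherwise vertices are enumerated
by `scipy.spatial.HalfspaceIntersection` around the strictly interior
center, ordered counter-clockwise, and deduplicated at 10⁻⁷.

p* is found by descending grid search over (1/3, 1/2] in steps of 0.005
(deterministic, and finer than any visible effect on the median
envelope); if every level above 1/3 is empty the centerpoint bound 1/3
is returned with a flag, and an empty envelope at 1/3 raises, since the
centerpoint theorem forbids it.  The bivariate median is the vertex
average of the p* envelope.

`tukey_depth` is an exact O(n log n) angular sweep: with data angles θᵢ
about the query point, the minimum closed-halfplane count equals
n′ − maxᵢ #{θ_j ∈ (θᵢ − π, θᵢ]} plus the multiplicity of data coincident
with the query.  It is the package's internal oracle and is never used
to *construct* envelopes.

## Bivariate quantile regression

Per direction s and level p, the projection sᵀy is regressed on the
truncated-power cubic basis [1, x, x², x³, (x − k₁)³₊, …, (x − k_K)³₊]
by the same LP.  K = 3 knots are placed at the 0.25/0.50/0.75 empirical
quantiles of the covariate unless supplied explicitly; knots must lie
strictly inside the observed range, and prediction outside the range
requires an explicit extrapolation flag.  The covariate enters
uncentered (the basis is not interpreted coefficient-wise).  Only one
covariate at a time is modelled.

Envelope prediction re-uses the static halfspace machinery with fitted
offsets Q̂(p, s | x₀).  The level grid pre-fits the band levels {0.1,
0.25} plus the p*-search grid, so the per-x₀ search is a lookup, not a
refit.  The default direction count here is 32: the predicted envelopes
inherit smoothing from the spline fits, and the SWP summaries (vertex
means, vertex min/max) are insensitive to finer direction sets at many
times the cost (M × levels LP fits).

**SWP bands.** The published construction ("bands formed using inner and
outer envelopes") fixes no formula, so two are implemented:
`inner_outer_minmax` (default; lower band = min of y_s/√y_c over
inner-envelope vertices, upper = max over outer-envelope vertices) and
`per_envelope` (min/max over both envelopes, never narrower).  Because
y_s/√y_c is quasiconvex on y_c > 0, its minimum over a polygon need not
sit at a vertex; the band is therefore clamped to include the point
estimate, which keeps lower ≤ ŜWP ≤ upper exactly without visibly
changing the bands.

## Synthetic-data generator

The generator emulates a 404-accession, two-condition barley trial.
Traits are independent truncated normals on positive support (means:
height 70 cm, flowering 65 d, ripening 40 d, 3 ears/plant, 11
grains/ear; sds 10, 7, 5, 1, 3 — chosen as realistic spreads for 2-row
spring barley), drawn independently per condition.  Yield follows the
location-scale model in centered traits

    y = b₀ + bᵀ(x − μ) + (1 + γᵀ(x − μ)) σ ε,

per condition, with the non-saline coefficients shifted by a delta
vector, σ = 30 g/m², and (ε_s, ε_c) drawn from a Gaussian copula with
correlation ρ = 0.5 (Student-t marginals available via the quantile
transform, preserving the analytic marginal quantiles).  Default
coefficient magnitudes track published field-trial estimates (saline
intercept 110 g/m², grain-number slope 6.77, condition effect +27.75,
…), and the default heteroscedasticity is mild (γ = 0.03 on grain
number, −0.008 on flowering time), so upper-quantile slopes genuinely
differ from median slopes.  Under this model the level-p conditional
quantile is linear with slope b_j + γ_j σ F⁻¹(p) and intercept
b₀ + σF⁻¹(p) — the analytic truth used by recovery and coverage tests.

Guard rails: a γ that makes the scale factor non-positive for more than
25% of draws is rejected outright (heavy rejection would truncate the
trait law and silently invalidate the analytic truth); rare violations
are resampled.  Accession error pairs producing a negative yield are
likewise redrawn — with the defaults this affects well under 1% of
accessions and perturbs only the extreme left tail.  Derived traits are
computed consistently with yield (dry mass = yield / harvest index with
harvest index ~ 0.2 + 0.4·Beta(2,2); thousand-grain mass from yield, ear
and grain counts at a fixed stand density of 75 plants/m²), reproducing
the collinearity that motivates their exclusion as covariates.

**What the generator does not emulate:** spatial field structure,
augmented designs and check lines, trait–trait correlations, condition-
specific trait distributions, measurement error in traits, or non-linear
trait effects.  Passing recovery tests therefore demonstrates
correctness of the estimators under the stated location-scale model, not
robustness to these real-data features.

## Problem sizes and numerical tolerances

The replicated validation studies use 100 replicates of the full-size
trial (404 accessions) for bias and coverage, 100 small datasets for the
LP oracle, 20 datasets on 25×25 lattices for the depth-contour oracle,
and n = 800 for SWP-curve shape recovery — sizes at which Monte-Carlo
error is far below the tolerances being checked while a full run stays
in the minutes range on one CPU.  Key tolerances: LP-vs-oracle objective
gap 10⁻⁹; envelope feasibility 10⁻⁹; halfspace membership 10⁻⁸; vertex
deduplication 10⁻⁷; bias within 3 Monte-Carlo standard errors; CI
coverage within [0.92, 0.98] at nominal 0.95.

## Known limitations

* Quantile fits at different levels are independent; crossing of fitted
  quantile surfaces is possible and not repaired.
* Rank-score inversion assumes the score statistic is monotone in ξ;
  pathological small-sample configurations fall back to the bootstrap.
* Envelope prediction can be empty at high levels or extreme covariate
  values; callers must handle `is_empty` (the SWP curve raises if a band
  envelope is empty at a grid point).
* Dimensions above 2 for the envelope machinery, weighted/censored
  regression, and multi-covariate spline surfaces are out of scope.
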