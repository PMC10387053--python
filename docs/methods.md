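# Methods

This note documents the statistical model, the synthetic-data
calibration, the numerical choices, and the limitations of `rootflux`.
Units throughout: fine root production (FRP) as new-root length per
observation-window area per month (m m⁻² mo⁻¹) until the carbon step,
then Mg C ha⁻¹ yr⁻¹; depths in cm below the soil surface.

## Response model

Window-level FRP is non-negative, continuous where positive, and mostly
zero. A Tweedie exponential-dispersion variable with power index
1 < p < 2 has exactly this support: it is a Poisson(λ) sum of
Gamma(α, θ) variates with

    λ = μ^(2−p) / (φ(2−p)),   α = (2−p)/(p−1),   θ = φ(p−1)μ^(p−1),

mean μ, variance φμᵖ, and point mass P(Y=0) = exp(−λ). The regression
puts log μ on ecosystem type (3 levels), season (3 levels), depth window
(5 levels, treated categorically) and their three pairwise interactions,
all under sum-to-zero contrasts — 29 coefficients on the full design.

Estimation is staged, exploiting the exponential-dispersion structure:

1. for each candidate p, the coefficient MLE is the ordinary IRLS/GLM
   solution (it does not involve φ); the numerical solver is
   statsmodels' GLM with the Tweedie family and log link, started from
   the intercept-only solution so that perfectly fitting data (e.g. a
   constant response) does not degenerate the first-step scale estimate;
2. φ is the one-dimensional ML optimum of the full series
   log-likelihood at the fitted means (bounded search over log φ);
3. p is the profile-likelihood argmax over a grid. The default grid is
   1.1–1.9 in steps of 0.05; the source study never reports its fitted
   power, so no finer resolution is warranted. A single-element grid
   fixes p.

The density at positive y uses the standard series expansion in the
Poisson index: log-domain terms, summed with logsumexp over a window
around the dominating index j* ≈ y^(2−p)/((2−p)φ), widened until the
edge terms fall below 1e-10 of the peak. The implementation is
cross-checked in the test-suite against an independent series
implementation (statsmodels' `Tweedie.loglike_obs`) and against
total-probability integration.

**Inference.** Type-III tests are Wald chi-squares of each term's
coefficient block at covariance φ̂(XᵀWX)⁻¹ — with sum-to-zero contrasts
this tests each term in the presence of all others, and is invariant to
factor-level reordering. Estimated marginal means average the linear
predictor with equal weights over the levels of the factors not being
reported, then back-transform through the log link; SEs are delta
method. Note the estimand: a link-scale average back-transforms to a
geometric-type mean of cells, which for skewed rows is smaller than the
arithmetic row average. The published grand depth means are arithmetic
row averages of the measured table, so the reproduction path
(`rootflux.pipeline.grand_depth_means`) uses raw averages; model-based
marginal means are validated on synthetic data only. Tukey comparisons
use the studentised range with k = number of means and residual df
n − k_params. AICc is −2ℓ + 2k + 2k(k+1)/(n−k−1), with k counting β, φ
and (when profiled) p; the correction term's divergence at k ≥ n−1 is
reported as +∞ rather than a negative correction.

**Tube random intercept.** The default model is fixed-effects only: in
the source analysis the tube intercept's contribution was reported as
far from significant, and the fixed-effects likelihood is fully
specifiable. When requested, a shared N(0, σ²) intercept per tube is
marginalised with 21-node Gauss–Hermite quadrature and (β, log σ, log φ)
maximised jointly by L-BFGS from the fixed-effects solution, at the
fixed-effects-selected p. Linear predictors are clipped at ±30 inside
the quadrature to keep extreme trial steps finite. This path is
exercised on reduced designs in the tests; it is an extension, not the
default, and is substantially slower than the fixed-effects fit.

## Synthetic-data generator

The generator emulates the study design: 3 ecosystem types × 16 tubes ×
3 seasons × 5 depth windows, one observation per cell (720 rows).
Defaults, chosen once:

- **Cell means.** The published measured-mean table fixes the
  season-averaged (ecosystem, depth) means. Season structure is added as
  sum-to-zero log-scale main effects (−0.263, 0.062, 0.201 for short
  wet, long wet, long dry — shaped after the published depth-weighted
  season means 3.9, 5.4, 6.2 m m⁻² mo⁻¹) plus a season × depth tilt
  along a centred log-depth score (−0.10, −0.10, +0.20), so the dry
  season allocates relatively more growth deep in the profile, as
  observed. Each depth's three seasonal means are renormalised to
  average exactly to the published value. The construction contains
  only main effects and pairwise interactions, so the generating model
  lies in the span of the analysis model and coefficient recovery is
  well-defined.
- **Power p = 1.6**, mid-range of (1, 2); a default, not a published
  value.
- **Dispersion φ** is solved (scalar root-find) so the design-average
  zero mass equals 0.75, the reported fraction of measurements with no
  new roots; with the default means this gives φ ≈ 16.9.
- **Tube intercepts** N(0, 0.3²) on the log scale, drawn once per tube
  and shared across that tube's seasons and depths (clustering within
  coring locations). No mean correction is applied, so cell expectations
  carry a factor exp(σ²/2) ≈ 1.05 — well inside the published SEs.
- **Randomness**: a single NumPy PCG64 generator seeded from the spec;
  identical spec ⇒ identical data, and seeds are echoed in pipeline
  provenance.

What the generator does *not* emulate: spatial correlation between
tubes, within-month root birth–death dynamics, measurement/tracing
error, and any orientation-level replication (one value per window, as
in the analysed data). Passing tests therefore demonstrate correctness
of the estimation machinery under the assumed model, not robustness to
those real-data features.

## Depth profile and carbon chain

LOESS here is the classic tricube-weighted local polynomial: at each
target the q = ⌊span·n⌋ nearest points are weighted by
(1 − (d/d_q)³)³ and a degree-0/1/2 polynomial solved by weighted least
squares. Defaults span = 1.0, degree = 1: with only five depth means,
smaller spans are ill-posed (the minimum feasible span is reported in
the error) and local quadratics oscillate on sparse monotone profiles.
The published analysis does not state its smoothing settings; these
defaults are this package's choice and are exposed in the config.
Predictions are evaluated at the forty 2.5-cm window midpoints
(1.25 … 98.75 cm); below the deepest measured midpoint (72.25 cm) the
boundary local fit extends linearly. Negative predictions clamp to
zero, consistent with the published 0.00 deep-section entries. Because
the reconstruction differs from the unstated original settings, carbon
totals recomputed from the measured means run ~30–40% above the
published totals while reproducing the profile shape; the published
carbon table itself is shipped as a fixture and all published-value
checks operate on it directly.

Section SEs are produced by passing the five measured SEs through the
identical LOESS → predict → bin path — a documented reconstruction (the
original SE extrapolation is unstated); the total SE is the square root
of the sum of squared section SEs, which reproduces the published totals
(0.13, 0.54) exactly at printed rounding.

Binning averages the four window predictions per 10-cm section; the
carbon step multiplies by the 0.1-m section depth, so this equals
summing the 2.5-cm windows. The conversion constants (depth of field
2 mm, SRL 37.1/45.1/51.6 m g⁻¹ by band looked up by section top —
never interpolated, carbon fraction 0.474, ×12 annualisation) collapse
to carbon = L × 2.844/SRL; the stepwise chain and the closed form agree
to 1e-12 relative tolerance in the tests. Seasonal monthly estimates
are averaged before annualisation: one annual number from three
measured months admits no other reading. The depth-weighted 0–75 cm
mean uses the midpoint-partition weights (4.25, 8, 15, 27.5, 20.25)/75,
a reconstruction validated by matching the published 4.1 (terra firme)
at printed rounding; hardwood reconstructs to 4.63 vs printed 4.7 and
palm to 6.49 vs printed 6.6, gaps attributable to input rounding or to
model-based rather than raw means — not resolvable from the published
material, and asserted at ±0.10 / ±0.15 accordingly.

## Simulation design for estimator validation

Repeated-simulation checks (200 replicates of the 720-observation
design, tube_sd = 0, p fixed at the generating 1.6 to keep each
replicate's fit to a single IRLS pass) are run in two regimes:

- **Information-adequate regime** (φ = 2, ≈16% zeros; regular-suite
  tests): max |bias| of the depth main contrasts ≈ 0.02 on the log
  scale, 95% Wald coverage ≈ 0.94 (within binomial bounds), Type-III
  ecosystem size 0.06 under its null, depth power 1.0, Tukey
  family-wise error near 5%, and AICc drops a spurious term in the
  clear majority of replicates. This validates the estimation and
  inference machinery where ML regularity holds.
- **Study-calibrated regime** (φ ≈ 16.9, 75% zeros; acceptance suite):
  depth-test power remains 1.0, but the deep cells carry only ~1.7
  units of Fisher information for their log means, and in ~7% of
  replicates an entire ecosystem × depth cell draws no positive
  observation, so the log-link MLE for that cell diverges. Measured
  consequences: depth-contrast bias up to ≈0.4 (≈0.2 even excluding
  inestimable replicates), Wald coverage ≈0.86, ecosystem test size
  ≈0.11 (Pearson-scaled covariance is more liberal still). These
  distortions are a property of maximum likelihood at this degree of
  zero inflation on this design — the measured table shows the same
  knife edge, with deep cells whose SE equals their mean (a single
  positive observation) — and are reported as such rather than hidden;
  the corresponding acceptance assertions fail by design of the
  conditions, not of the estimator. Practical implication: inference on
  deep-layer contrasts from designs like this should be treated with
  caution, and Wald p-values near the 0.05 boundary are optimistic.

Problem sizes used in the shipped suites — 200 replicates per
simulation, n = 10⁵ draws for sampler-moment checks, 720-row designs —
were chosen as the smallest sizes at which the binomial/Monte-Carlo
tolerances quoted above are meaningful.

## Degenerate inputs and tie-breaks

- All-zero response: rejected (`FitError`) — the log-link mean model has
  no MLE.
- Factors observed at a single level are dropped from the model (and
  from the ANOVA table) rather than producing zero-width coefficient
  blocks; grouping by such a factor in marginal means is still allowed.
- Rank-deficient designs are rejected with the aliased columns named.
- `d_q = 0` in LOESS (all points at the target) falls back to a plain
  weighted mean.
- AICc ranking uses a stable sort, so exact ties keep input order.
- CSV round-trips preserve values bit-exactly (shortest-repr write,
  round-trip float parsing on read).

## Known limitations

- The tube random intercept is marginalised by quadrature but its
  covariance is a numerical observed-information estimate; no profile
  CIs for σ.
- The SE depth-profile path is a reconstruction (see above); resampling
  based uncertainty bands are out of scope.
- No spatial or temporal correlation beyond the shared tube intercept.
- The carbon chain treats depth of field and SRL as known constants;
  halving the depth of field doubles every flux (tested), so reported
  totals inherit that structural uncertainty unreduced.
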