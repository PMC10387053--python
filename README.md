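# rootflux

Estimation of fine root production (FRP) from minirhizotron depth
profiles, and its conversion to an annual soil carbon flux.

Minirhizotrons are transparent tubes installed in soil; a camera
photographs fixed windows along the tube at repeated visits, and tracing
the roots that appear between visits yields the length of new root per
window area per month (m m⁻² mo⁻¹) at a handful of depths. These data are
awkward: most individual windows record *no* new roots in a given month
(~75% exact zeros), the positive values are strongly right-skewed, and
only five depths of a 1-m profile are observed. `rootflux` is for
ecosystem ecologists who need to go from such a table to (i) defensible
tests of how production varies with depth, season and forest type, and
(ii) a profile-integrated carbon flux in Mg C ha⁻¹ yr⁻¹.

## What it implements

**Zero-inflated response model.** FRP is modelled as Tweedie with
1 < p < 2, i.e. a compound Poisson–gamma: `N ~ Poisson(λ)`,
`Y = Σᵢ₌₁..N Gᵢ`, `Gᵢ ~ Gamma(α, θ)`, with mean μ, variance φμᵖ, and an
exact point mass `P(Y = 0) = exp(−μ^(2−p)/(φ(2−p)))`. The regression

```
log μ = β₀ + ecosystem + season + depth + (all pairwise interactions)
```

uses sum-to-zero contrasts; β is IRLS maximum likelihood, φ is estimated
by maximising the series-expansion log-likelihood, and p is selected on a
grid by profile likelihood. Inference: Type-III Wald χ² per term,
estimated marginal means with delta-method SEs, Tukey-adjusted pairwise
comparisons, and AICc model ranking. An optional tube-level random
intercept is marginalised by Gauss–Hermite quadrature.

**Depth extrapolation.** The five measured depth means are smoothed by
LOESS (tricube weights, local degree 0/1/2), predicted at every 2.5-cm
window midpoint to 1 m, clamped at zero, and binned into ten 10-cm
sections. A depth-weighted 0–75 cm profile mean uses midpoint-partition
weights (4.25, 8, 15, 27.5, 20.25)/75.

**Carbon conversion.** Each section's mean rate L (m m⁻² mo⁻¹) becomes
`L / 0.002 m (depth of field) / SRL × 0.1 m × 12 × 0.01 × 0.474
= L × 2.844 / SRL` Mg C ha⁻¹ yr⁻¹, with specific root length (SRL)
37.1 / 45.1 / 51.6 m g⁻¹ for 0–10 / 10–20 / 20–100 cm; the total SE is
the square root of the summed squared section SEs.

**Synthetic studies.** A generator draws complete factorial designs
(3 ecosystems × 16 tubes × 3 seasons × 5 depths = 720 observations) from
the compound Poisson–gamma model, calibrated so the cell means track the
published measured-mean table and the expected zero fraction is 0.75.
Every analysis stage is testable without any field data.

## Worked example

```python
from rootflux import (ModelSpec, default_generator_spec, fit,
                      generate_study, type3_anova)

obs = generate_study(default_generator_spec(seed=42))
fx = fit(obs, ModelSpec(power_grid=(1.4, 1.5, 1.6, 1.7, 1.8)))
print(f"p = {fx.power_hat:.2f}, phi = {fx.phi_hat:.2f}")
print(type3_anova(fx))
```

prints

```
p = 1.60, phi = 15.41
Variable                Chi-square   df           p
Intercept                   45.785    1     < 0.001
ecosystem                    5.010    2       0.082
season                       0.745    2       0.689
depth                      121.825    4     < 0.001
ecosystem:season             6.316    4       0.177
ecosystem:depth             40.285    8     < 0.001
season:depth                 6.585    8       0.582
```

The profile-likelihood grid recovers the generating power index (1.6);
depth and its interaction with ecosystem dominate — production declines
steeply with depth and the shape of the decline differs between forest
types — while the ecosystem main effect alone is not significant, the
qualitative pattern reported for the real Congo Basin sites.

The `examples/` directory holds one short script per capability:
simulation, model fitting, depth-profile extrapolation and carbon
conversion, reproduction of the published-table arithmetic, and the full
pipeline (also available as the `rootflux` command-line tool with
`simulate`, `fit`, `profile`, `carbon`, `reproduce` and `run`
subcommands).

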