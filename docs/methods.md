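# Methods

This note documents the statistical model, the numerical choices, and the
synthetic-data conditions under which the package is validated — including
what those validations do and do not say about real administrative data.

## Model

For regions `i = 1..n` of one tier, with observed deaths `d_i` and expected
deaths `e_i` from indirect standardization:

```
d_i | θ_i        ~ Poisson(e_i θ_i)
θ_i | α, β       ~ Gamma(shape α, scale β)        (independent across i)
α                ~ Exponential(rate 1)
β                ~ Gamma(shape 0.1, scale 1.0)
```

`θ_i` is the region's relative risk; the reported shrunken SMR is
`100 · E[θ_i | data]`. The prior mean of the risk is `αβ` and the prior
variance `αβ²`, so the fitted `(α, β)` describe the cross-region risk
distribution and the conjugate conditional
`θ_i | α, β, d, e ~ Gamma(α + d_i, rate e_i + 1/β)` makes the shrinkage
mechanics transparent: the posterior mean `(α + d_i)/(1/β + e_i)`
interpolates between the raw ratio `d_i/e_i` (dominant when `e_i` is large)
and the prior mean `αβ` (dominant when `e_i` is small). Because the `β`
hyperprior's second parameter is 1, the shape–rate and shape–scale readings
of Gamma(0.1, 1.0) coincide; nothing hinges on that ambiguity.

The `θ_i` are deliberately exchangeable rather than spatially structured
(no CAR/BYM prior). The point of the downstream Moran test is to ask whether
*the data* carry spatial autocorrelation; a spatial prior would beg that
question.

### Sampler

Metropolis-within-Gibbs:

- every `θ_i` is redrawn exactly from its conjugate Gamma conditional each
  iteration (no rejection, no tuning);
- `α` and `β` take Gaussian random-walk steps on the log scale (the
  log-Jacobian is included in the acceptance ratio), with step sizes adapted
  every 50 warmup iterations toward 35% acceptance and frozen after warmup;
- because the `(α, β)` posterior concentrates along a ridge of near-constant
  `αβ`, a third, anti-correlated joint move (`log α += δ`, `log β -= δ`) is
  taken each iteration; without it the hyperparameters mix an order of
  magnitude more slowly (split-chain rhat ≈ 1.3 at default lengths versus
  ≈ 1.002 with it).

Defaults: 4 chains × 2,000 iterations, first 1,000 discarded, pooled across
chains. Initialization is deterministic — `θ_i = (d_i + 0.5)/(e_i + 1)`,
`α = β = 1` — so runs are reproducible given the seed; chains receive
independent streams spawned from one `SeedSequence`. Convergence is
summarized by split-chain rhat and effective sample size (arviz); a warning
fires if any rhat exceeds 1.05. The point estimate is the posterior mean
(the median and a central 95% interval are emitted alongside). `fixed_alpha`
/ `fixed_beta` switch the sampler into a pure-conjugate oracle mode used by
the tests.

Degenerate inputs: `e_i = 0` is legal (the posterior for that region is the
prior, given `d_i = 0`); `d_i > 0` with `e_i = 0` has zero likelihood
everywhere and is rejected at initialization.

## Standardization

Reference rates are carried per (year, age-stratum) and applied per year,
then summed over the window — not pooled into a single decade rate (a pooled
option exists for sensitivity checks; with populations constant over years
the two coincide). When no external rate table is given, the analyzed slice
is standardized against itself, which enforces the identity
`Σ_i e_i = Σ_i d_i` exactly and makes a region holding the whole population
come out at SMR = 100 by construction. Unknown-age deaths cannot enter
`e_i` and are excluded up front, with the excluded total logged. Coarser
tiers sum `d` and `e` over constituent units and recompute the ratio from
the sums; SMRs are never averaged. Regions with `e = 0` get an undefined
raw SMR (NaN) and are dropped from Moran and Wilcoxon computations with a
logged count, while their Bayesian estimate is still produced.

Gender-specific analyses run the whole pipeline per slice, each slice
standardized by its own rates; the alternative (shared all-gender rates for
every slice) is supported by passing an explicit rate table.

## Spatial autocorrelation

Moran's I uses binary 0/1 contiguity weights with the global `Σw`
normalization (the "B" convention), not row-standardized weights. Queen
contiguity (any shared boundary point) is the default when deriving
adjacency from polygons, with rook as an option; coordinates are snapped to
a 1e-8-degree grid first to absorb digitization slivers. Analytic inference
is the classical randomization test: `E[I] = -1/(n-1)` and the closed-form
variance in `S0, S1, S2` and the sample kurtosis, one-sided "greater" by
default (positive autocorrelation is the substantive alternative). The
variance formula needs `n > 3`. A seeded Monte-Carlo permutation test with
`p = (1 + #{I* ≥ I}) / (1 + n_perm)` is the assumption-free cross-check; the
test suite verifies the analytic moments against 10⁵ permutations and the
5% type-I error rate (measured 4–6% over 1,000 null replicates).

Islands (regions with no neighbors) are retained by default: they
contribute to `n` and the variance denominator but nothing to the
cross-product (their weight rows are zero). A strict mode drops them and
recomputes the mean. Both conventions exist in standard spatial software;
the choice is logged. I is invariant under affine maps of the values, so
computing it on the ×100 SMR scale is immaterial (asserted by a property
test).

## Classification

Low/Middle/High at the first and third quartiles, linear interpolation
between order statistics. Values exactly on a split point go to Middle by
default (`boundary="outer"` closes outward instead); membership near the
boundaries depends on both conventions, which is why they are explicit.
Note these are *quartile split points* producing three classes — not
equal-thirds tertiles, although applied reports sometimes use that word.
The bivariate table pairs each child region's class with its parent tier's
class; `Low(parent)-High(child)` is highlighted red, `High-Low` blue.

The raw-vs-shrunken comparison is the two-sample Wilcoxon rank-sum test
(normal approximation, tie-corrected, no continuity correction), treating
the vectors as independent samples. The data are actually paired per
region, and a signed-rank variant is available behind `paired=True`; the
unpaired rank-sum is the default because it is the conventional summary
comparison for these tables, but it answers a distribution-level question,
not "did region i move".

## Synthetic studies

The generator emulates the *structure* of national small-area suicide data:
a lattice of unit squares nested in rectangular middle and top blocks
(default 400 → 100 → 25, a scaled-down analogue of ~1,887 municipalities /
344 secondary areas / 47 prefectures; exact nesting on a lattice forces the
ratios), ten years of counts (2009–2018 labels), nine 10-year age bands
plus an optional unknown-age stratum, log-normal unit populations (median
≈ 30,000, log-SD 1.0, giving median expected deaths ≈ 60 per decade —
the order of magnitude of the real municipal tables), and an adult suicide
schedule of ≈ 2×10⁻⁴ deaths/person-year. Gender slices share one
population surface (split 50/50) with rate multipliers 1.38/0.62, so men
carry ≈ 69% of deaths and the slices sum exactly to the combined table.

Risks are `θ⁰_i ~ Gamma(α_true, β_true)` (default 10, 0.1 → mean 1,
SD 0.32). Two optional departures from independence:

- **neighbor mixing** `θ_i = (1-ρ)θ⁰_i + ρ·mean(θ⁰ neighbors)` — cheap,
  seedable, keeps marginals near-Gamma, but only correlates regions a step
  or two apart;
- **a regional trend**: multiplication by a half-period sinusoidal hump
  with random phase, normalized to mean 1 (`trend_amplitude`, default 0).
  This exists because block-aggregating a short-range field to 25 top
  regions leaves almost no autocorrelation, whereas real mortality surfaces
  show strong coarse-tier structure; only a field with genuinely long-range
  gradients can reproduce that.

The "strongly clustered" regime used by the spatial tests is defined once
as `ρ = 0.8, trend_amplitude = 0.4`, chosen so the tier-level Moran's I
magnitudes (≈ 0.2–0.6) sit on the scale multi-tier mortality analyses
report. With both knobs at 0 the generator produces exactly the independent
Gamma field the shrinkage model assumes, and the Moran test's null
calibration is verified in that regime.

Deaths are drawn as regional totals `Poisson(e_i θ_i)` and then spread
multinomially across (year, stratum) cells proportionally to `rate × pop`
— the stratified file shape is real, but within-region allocation carries
no extra signal, matching the model's use of regional totals only.

**What passing these tests does not show:** the generator has no migration,
no temporal rate trends, no age-pyramid variation between regions, no
irregular geography (all units are squares with 3–8 neighbors), and its
"unknown age" records are a fixed thinning. Real administrative data can
violate the Poisson assumption (overdispersion beyond the Gamma layer),
have far more skewed adjacency structures, and involve boundary changes
richer than the acyclic ward merges modeled here.

## Validation problem sizes

Test and acceptance runs use desk-scale conditions chosen to keep the full
suite in the low minutes: 400–1,000-region lattices, 2 chains × 1,000–1,500
iterations for replicated fits (the default 4 × 2,000 for single fits),
10⁵ permutations for the variance cross-check, 1,000 replicates for
type-I-error and Wilcoxon calibration, and 20 replicate studies (n = 500)
for the hyperparameter-coverage check (≥ 15/20 nominal-95% intervals must
cover, consistent with binomial noise). Parameter recovery at these sizes
lands within a few percent of truth for `αβ` and within ~10–15% for `α`
itself, whose posterior is intrinsically wide at n = 500.

## Known limitations

- The sampler is single-machine and dense in `n`; at 10⁵ regions a
  collapsed or blocked sampler would be preferable.
- Hyperparameter recovery degrades when all `e_i` are tiny (little
  information about the Gamma shape); the posterior then leans on the
  Exp(1) prior for `α`.
- Queen/rook contiguity from polygons assumes a clean tessellation after
  snapping; genuinely overlapping geometries are treated as adjacent, not
  repaired.
- The bivariate scheme inherits the arbitrariness of Q1/Q3 split points;
  regions near a split can change class under small data perturbations.
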