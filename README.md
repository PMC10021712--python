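# smrmap

Small-area disease mapping of standardized mortality ratios (SMRs) across
nested administrative tiers — municipalities inside secondary (health-policy)
areas inside prefectures — with Bayesian shrinkage, spatial autocorrelation
testing, and bivariate choropleth classification.

## The problem

Rare-event mortality (the motivating case is suicide) is unstable in small
areas: a municipality with two expected deaths and six observed ones shows an
SMR of 300 that is mostly noise. Policy, however, is made at several regional
scales at once, and a prefecture that looks average can hide high-risk
municipalities (and vice versa). `smrmap` implements the standard small-area
workflow for this situation:

1. **Indirect standardization.** Expected deaths
   `e_i = Σ_year Σ_age rate(year, age) · pop_i(year, age)` from national
   age-specific rates applied to each region's age-stratified population,
   summed over a multi-year window. Raw SMR = `100·d_i/e_i`
   (100 = national average risk).
2. **Poisson–Gamma hierarchical shrinkage.** `d_i ~ Poisson(e_i·θ_i)`,
   `θ_i ~ Gamma(α, β)` (shape–scale), with hyperpriors `α ~ Exp(1)` and
   `β ~ Gamma(0.1, 1)`. Fit by Metropolis-within-Gibbs (exact conjugate
   updates for every `θ_i`, adaptive log-scale random walks for `α, β`).
   The shrunken SMR is `100·E[θ_i | data]`: noisy small-`e` regions are
   pulled toward the ensemble mean, informative regions barely move. The
   `θ_i` are a priori independent — no spatial prior — so spatial structure
   found afterwards is in the data, not the smoothing.
3. **Global Moran's I** with binary contiguity weights (queen adjacency from
   polygons, or a supplied edge list), tested analytically under
   randomization and by Monte-Carlo permutation.
4. **Bivariate classification.** Each tier's SMRs are split Low/Middle/High
   at the first and third quartiles; child regions are cross-classified
   against their parent tier into nine classes, flagging `Low-High` (red:
   high-risk pockets invisible at the coarse tier) and `High-Low` (blue)
   discordances. A Wilcoxon rank-sum test compares the raw and shrunken SMR
   distributions.

A synthetic-study generator emulates the real inputs' structure (nested
lattice tiers, a decade of counts, 10-year age strata, an unknown-age
stratum, Gamma risks with optional spatial clustering), so the entire
pipeline is testable from nothing.

## Worked example

```bash
smrmap simulate --grid 20x20 --rho 0.6 --seed 7 --out study/
smrmap standardize --counts study/counts_all.csv --rates study/rates_all.csv \
    --hierarchy study/hierarchy.csv --out unit_table.csv
smrmap fit --table unit_table.csv --seed 1 --out posterior.csv
smrmap moran --table unit_table.csv --adjacency study/adjacency.tsv --estimator raw
```

The `fit` step prints the fitted hyperparameters and convergence check:

```
alpha mean 32.1407, beta mean 0.0295, max rhat 1.014
```

i.e. the fitted risk distribution is Gamma(32.1, 0.0295), with mean
`αβ ≈ 0.95` (the average relative risk) and all split-chain rhat values
below 1.05. The generator drew risks from Gamma(10, 0.1), but `--rho 0.6`
averages each unit with its neighbors, which tightens the cross-region
spread — the model correctly reports the dispersion of the field it was
shown (a larger shape means a tighter Gamma). The `moran` step prints

```
I = 0.1737  E[I] = -0.0025  z = 6.869  p = 3.224e-12  (n = 400, randomization)
```

a clearly positive spatial autocorrelation, as expected for a field
simulated with neighbor mixing (`--rho 0.6`). Running the whole pipeline —
all tiers, gender slices, classifications, and a checksummed manifest — is

```bash
smrmap run --config pipeline.yaml --seed 1
```

Programmatic use mirrors the CLI (`simulate_study`, `make_region_table`,
`sample_posterior` / `PoissonGammaModel`, `moran_test_randomization`,
`classify_q1q3`, `bivariate_classify`, `run_pipeline`).

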