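# spacefortime

Testing the validity of **space-for-time substitution** in community ecology:
do habitat–abundance relationships measured across space explain how
abundance actually changed through time?

The package targets two-period replicated point-count surveys (one count per
site in the historical period, back-to-back replicate counts in the
resurvey) with compositional land cover measured at a ladder of buffer radii
around each point. It provides, end to end:

1. **Synthetic data** with exactly the statistical structure the models
   assume — two-period compositional landscapes, Poisson abundance driven by
   land cover at species-specific scales of effect, Binomial detection.
2. **Scale-of-effect selection** per species × land-cover type, by
   leave-one-out prediction skill of univariate Poisson GLMs (Pearson or
   Spearman correlation) or by boosted-regression-tree relative influence.
3. **Bayesian multispecies N-mixture models** with imperfect detection,
   fitted by MCMC on the marginalized likelihood.
4. A **land-cover-only counterfactual** and a five-way per-species
   classification of whether spatial habitat relationships explain temporal
   change.

## The model

Observed counts are Binomial thinnings of a latent Poisson abundance:

    y_ijkt ~ Binomial(N_ijt, P_i)        N_ijt ~ Poisson(lambda_ijt)

for species *i*, site *j*, within-period replicate *k*, period *t*.
Detection probabilities are shared across periods and partially pooled,
`P_i ~ Beta(a, b)` with centre `psi = a/(a+b) ~ Beta(2, 3)` and
concentration `theta = a+b ~ Gamma(9, 5)`.

Two linear predictors are offered:

* **fixed50** (local scale, Scheffé form — compositions sum to one, so there
  is no intercept and `beta_im` is the expected log abundance were type *m*
  to cover the whole count circle):

      log lambda_ijt = sum_m beta_im E_jmt          (+ phi_i for t = 2)

* **multiscale** (each species sees each land-cover type at its selected
  scale of effect; the design is full rank, so a species intercept enters):

      log lambda_ijt = alpha_i + sum_m beta_im E_ijmt   (+ phi_i for t = 2)

Habitat effects are partially pooled, `beta_im ~ Normal(mu_m, tau_m)`, and
`phi_i ~ Normal(rho, sigma)` is the species-level log change in abundance
**not** attributable to land cover. Setting `phi = 0` in period 2 and
rebuilding abundance from the drawn habitat effects and the period-2 land
cover gives the space-for-time counterfactual: if the substitution is valid,
counterfactual and full-model period-2 abundances should match.

## Worked example

```python
import spacefortime as sft
from spacefortime.nmix import ModelSpec, MCMCSettings, fit_model
from spacefortime.counterfactual import compute_trends

design = sft.SurveyDesign(n_sites=60, n_species=8, n_landcover=7)
grid = sft.build_scale_grid(50, 1500, 50)          # 30 radii

stack = sft.generate_landscape(design, grid, seed=1)
params = sft.generate_community(design, grid, seed=1)
counts, latent_n = sft.simulate_counts(params, stack, design, seed=1)

scale_map = sft.select_scale_correlation(counts, stack, grid, method="pearson")
print("univariate models enumerated:", scale_map.n_models_enumerated)

spec = ModelSpec(variant="multiscale",
                 mcmc=MCMCSettings(chains=2, warmup=1200, samples=600),
                 check_convergence=False)          # short desk-scale chains
posterior = fit_model(counts, stack, scale_map, spec, seed=1)

trends = compute_trends(posterior, stack, scale_map, seed=1)
c = trends.community["true"]
print(f"community change: {c['median']:.1f}% (89% CrI {c['lo']:.1f} to {c['hi']:.1f})")
print(trends.table[["species", "true_median", "cf_median", "category"]]
      .round(1).to_string(index=False))
```

Output:

```
univariate models enumerated: 1680
community change: -14.2% (89% CrI -25.1 to -1.6)
species  true_median  cf_median            category
  sp000        -14.7        1.9 both_nonsignificant
  sp001        -33.6        0.0 both_nonsignificant
  sp002        -59.0        0.6  one_sided_mismatch
  sp003         33.0        2.5  one_sided_mismatch
  sp004        -45.1        1.7  one_sided_mismatch
  sp005         16.8        1.5 both_nonsignificant
  sp006        -27.1        3.2 both_nonsignificant
  sp007        -23.2       -0.2  one_sided_mismatch
```

Here 8 species × 7 types × 30 radii = 1,680 univariate model configurations
were screened. The default synthetic community carries a species-level drift
(`rho = log 0.74`), so the estimated community decline is real but the
land-cover-only counterfactual (`cf_median`) centres near zero — several
species are flagged `one_sided_mismatch`, i.e. their real trend is
significant while the land-cover-only prediction is not: the signature of an
invalid space-for-time substitution.

`compute_trends` classifies each species into one of five categories:
opposite significant trends; exactly one trend significant
(`one_sided_mismatch`); both non-significant; both significant in the same
direction with disjoint CrIs; same direction with overlapping CrIs.

## Command line

```bash
spacefortime simulate      --seed 1 --out-dir run/
spacefortime select-scales --counts run/counts.csv --landcover run/landcover.csv --method pearson --out-dir run/
spacefortime fit           --counts run/counts.csv --landcover run/landcover.csv \
                           --variant multiscale --scales run/optimal_scales.csv --out-dir run/
spacefortime sft-test      --posterior run/posterior --landcover run/landcover.csv \
                           --scales run/optimal_scales.csv --out-dir run/
spacefortime report        --trends run/trends.csv --out-dir run/
```

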