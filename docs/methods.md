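# Methods

This note records the modelling choices behind `spacefortime`: the
generative assumptions of the synthetic data, the estimation machinery, the
numerical decisions, and what the simulation studies do and do not
demonstrate.

## Problem structure

The pipeline targets a two-period multispecies point-count design: J sites
surveyed once in period 1 and with two back-to-back replicates in period 2,
S species, and compositional land cover (M types, proportions summing to
one) measured at C buffer radii (default 50–1500 m in 50 m steps, 30 radii)
around each point. The scientific question is whether the spatial
habitat–abundance relationship, estimated at the scale of effect of each
species × land-cover type, explains the observed temporal change in
abundance — the validity of a space-for-time substitution.

## Synthetic data

The generator produces data with exactly the structure the abundance model
assumes, so that every downstream stage is testable without field data.

**Landscapes.** Per site, the composition at the smallest radius is a
Dirichlet draw around a site-level mean. Moving up the radius ladder, the
log-scale composition drifts toward a site-neighbourhood composition (weight
growing with radius) while a log-scale random walk adds an independent
innovation at every step, mimicking the fresh land that each larger buffer
annexes. This makes adjacent radii strongly correlated (≈0.96 at one step)
yet every radius informative — the feature scale selection needs. The
`spatial_smoothness` parameter divides both the innovation scale and the
drift rate; in the large-smoothness limit all radii at a site are identical.
The period-2 landscape perturbs period 1 by a logistic-normal shock with a
shared (site, type) component plus a radius-smooth component; `shock_sd`
defaults to 0.3, a moderate two-decade land-cover change (the magnitude of
real change is not identified by any source we rely on, so it is exposed in
configuration), and 0 reproduces period 1 exactly.

**Communities.** Species parameters are drawn from the community
distributions the model assumes: `beta_im ~ Normal(mu_m, tau_m)`,
`alpha_i ~ Normal(mu_alpha, tau_alpha)` (multiscale only),
`phi_i ~ Normal(rho, sigma)`, `P_i ~ Beta(psi*theta, (1-psi)*theta)`.
Defaults: `mu` spreads habitat quality from avoided to preferred
(linspace −1 to 1.5 on the log scale), `tau = 0.5`, `mu_alpha = 0.5`,
`tau_alpha = 0.5`, and `rho = log 0.74 ≈ −0.30` with `sigma = 0.4` — a
community whose expected abundance drops ~26% between periods for reasons
unrelated to land cover, the regime the method is designed to expose.
Detection hyperparameters default to the centre of the analysis prior
(`psi = 0.4`, `theta = 1.8`), so simulated communities are self-consistent
with the model fitted to them — the standard device for calibration
studies; the implied Beta(0.72, 1.08) spreads detectability widely, from
skulking to conspicuous species. Detection draws are truncated to
[0.02, 0.98]: below ~2% a species contributes no usable data at realistic
survey sizes. Generating scales of effect are uniform over the radius grid
by default and can be pinned to one radius to create an identifiable target
for recovery experiments.

**Counts.** `N_ijt ~ Poisson(lambda_ijt)` with the variant's linear
predictor (period 2 adds `phi_i`); every within-period replicate is an
independent `Binomial(N_ijt, P_i)` thinning of the *same* latent N — the
correlation between replicates is what identifies detection. The latent N is
always returned: recovery tests need the simulator's ground truth even
though, for real data, "true abundance" is itself a model estimate.

What the generator does **not** emulate: spatially explicit rasters and
spatial autocorrelation between neighbouring sites, interspecific
interactions, irruptive or migratory dynamics, observer- or time-varying
detection. Passing recovery tests therefore show that the machinery is
correct under its own assumptions, not that those assumptions hold for any
particular city's birds.

## Scale-of-effect selection

**Out-of-sample prediction.** For each (species, type, radius), univariate
Poisson GLMs `y ~ exp(zeta + eta E)` are fitted separately per period
(intercepts and slopes carry period subscripts); period-2 responses are
first collapsed to the maximum over replicates, which best reflects the
birds tied to the surrounding land cover. Each observation is predicted by
refitting the period's model without it (leave-one-out); predictions from
both periods are pooled and correlated (Pearson or Spearman) with the
observed responses, and the radius maximizing the correlation wins. At the
full study configuration this screens S × M × C = 61 × 7 × 30 = 12,810
model configurations and emits 61 × 7 = 427 optimal scales.

Decisions the procedure needed that no source fixes: the leave-one-out unit
is one site-within-period observation; ties in the correlation break to the
smallest radius (the most local, most parsimonious scale); undefined
correlations (zero-variance predictions, too few valid folds) are treated as
−∞ so they can never win; a fold whose refit fails (e.g. the remaining
covariate is constant) yields a missing prediction excluded pairwise.

The LOO engine is a vectorized Newton/IRLS solver for the two-parameter
Poisson model, fitting all folds and radii simultaneously; a generic GLM
library refit per fold is infeasible at the enumeration sizes involved
(thousands of refits per configuration). The test suite verifies the engine
against `statsmodels` GLM fold by fold. All-zero responses are guarded
(`zeta = −inf`, `eta = 0`, flagged) rather than iterated to divergence.

**Boosted regression trees.** One gradient-boosted ensemble per species over
all M × C scale-specific proportions (responses from both periods stacked),
Poisson objective, depth-1 trees, bag fraction 0.5, minimum node size 25,
shrinkage 1e-4, 20,000 trees by default (reduced in desk-scale runs — the
influence ranking stabilises long before the full ensemble size matters).
Relative influence is the normalized total split gain per predictor; per
type, the radius with the highest influence wins. Species with fewer than 5
nonzero observations cannot support an ensemble and inherit the map of the
species with the most similar count profile (highest Spearman correlation),
unless a user-supplied donor mapping says otherwise — a reproducible proxy
for "use a closely related species" that needs no taxonomy.

## Abundance model and sampler

Both variants marginalize the discrete latent abundance out of the
likelihood by truncated summation,

    log sum_{N=max(y)}^{Nmax} Poisson(N; lambda) prod_k Binomial(y_k; N, P),

computed in log space with the N-independent binomial terms precomputed.
`Nmax` defaults to the maximum observed count plus 50; a truncation-
stability test verifies that doubling `Nmax` changes the total
log-likelihood by < 1e-6, and the fit warns if imputed abundances touch the
bound. Single-replicate periods use the exact thinning identity
`y ~ Poisson(lambda P)`.

Priors follow the detection hyperprior `psi ~ Beta(2,3)`,
`theta ~ Gamma(9,5)`; location hyperparameters (`mu_m`, `rho`, `mu_alpha`)
get Normal(0, 2) and the positive scales (`tau_m`, `sigma`, `tau_alpha`)
half-Normal(0, 2) — scales must be positive, and 2 on the log-abundance
scale is weakly informative for point-count data. All are configurable.

Sampling is adaptive Metropolis-within-Gibbs, chosen because the
marginalized likelihood is cheap to evaluate per species block and the
hyperparameter layer is conditionally conjugate or low-dimensional:

* species blocks (`beta_im`, `alpha_i`, `phi_i`, logit `P_i`): componentwise
  Gaussian random-walk proposals, vectorized across species, with
  Robbins–Monro adaptation of per-coordinate scales toward 0.44 acceptance
  during warmup only;
* two ridge moves fight the model's known degeneracies: a shift move trading
  the intercept against all habitat effects, and a detection shift moving
  logit `P_i` while compensating the intercept so `lambda * P` is preserved
  (a symmetric, unit-Jacobian map) — without these, the abundance–detection
  ridge mixes very slowly;
* location hyperparameters are conjugate Normal draws; scale
  hyperparameters and (`psi`, `theta`) use univariate slice sampling on the
  log / logit scale.

Latent N is re-imputed per retained draw from its exact conditional
(closed-form thinning for single-replicate periods, truncated categorical
via the Gumbel trick otherwise); posterior communities are per-draw species
and community totals of N over sites. Convergence is monitored by split
R-hat (via `arviz`); `fit_model` fails loudly above 1.01 when the check is
enabled. Desk-scale studies in the tests and the acceptance script use
deliberately short chains (2 chains, 600–1200 warmup, 300–600 draws — sizes
chosen so the full simulation studies complete in minutes) with the check
disabled; at those settings split R-hat is typically 1.1–1.6, which is
sufficient for the interval-coverage and control checks performed but is
*not* a converged production fit. Production settings mirror the
four-chain, 1500-warmup, 500-draw configuration.

Linear predictors are clipped at ±30 on the log scale before
exponentiation. The fixed50 variant refuses an intercept at specification
time: with compositions summing to one the design matrix with an intercept
is rank-deficient, which is the reason the Scheffé form exists.

## Counterfactual and classification

Per posterior draw, the land-cover-only period-2 abundance of species *i* is

    sum_j Poisson(exp(alpha_i + sum_m beta_im E_ijm,t=2)),

with a fresh Poisson realization per (species, site, draw) so the
counterfactual totals carry the same stochastic width as the full model's
posterior communities; an expectation-only variant (no Poisson noise) is
available behind a flag for variance-decomposition use. The fixed50 variant
drops `alpha` and the species dependence of E. `phi` never enters, which a
test asserts directly.

Percent change is computed per draw, `100 (N2 − N1)/N1`, with zeros in the
period-1 draw replaced by 1e-10 (species-level only; community totals are
never zero in practice), then summarized by the median and the equal-tailed
89% credible interval (quantiles 0.055 and 0.945). Species are classified
by comparing the true (full-model) and counterfactual changes: both
significant with opposite signs; exactly one significant; neither
significant; both significant, same direction, disjoint CrIs; both
significant, same direction, overlapping CrIs — significance meaning the
CrI excludes zero, and overlap meaning non-empty interval intersection at
the configured level. Per-draw computation was chosen over
summarize-then-difference because it propagates posterior uncertainty into
the change estimate.

## Simulation studies

The test suite and `scripts/acceptance.py` run the same studies at the same
sizes (chosen to keep each study in the minutes range on one core):

* parameter recovery and interval coverage: S = 8 species, J = 60 sites,
  M = 7 types, default community; coverage of the generating `beta`, `phi`,
  `P` by 89% CrIs, and of true community totals across replicate
  simulations;
* scale recovery: a single generating radius of 500 m, J = 200 sites,
  strong habitat slopes (|eta| ≥ 2 for every type) and high detectability —
  a strong-signal design isolating the selector's ability to find the scale;
  success is the generating or an adjacent radius;
* controls: a positive control (phi = 0, changing land cover), where
  counterfactual and full-model period-2 CrIs must overlap for nearly all
  species, and a negative control (large drift, static land cover), where
  `one_sided_mismatch` must dominate and the counterfactual community
  change must straddle zero.

## Known limitations

* The sampler is a random-walk scheme: effective sample sizes per iteration
  are far below a gradient-based sampler's, and the short desk-scale chains
  trade diagnostic cleanliness for runtime. The ridge moves mitigate, but do
  not remove, the abundance–detection degeneracy at small J.
* Detection is species-level only; no observer, date or effort covariates.
* The landscape generator is not spatially explicit; nothing constrains
  neighbouring sites to share land cover, so spatial pseudo-replication
  cannot be studied with it.
* Scale selection treats (species, type) cells independently; no joint
  multi-type selection is attempted.
* The fallback rule for sparse species in the boosted-tree selector is a
  similarity heuristic, not taxonomy.
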