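"""Shared fixtures: small designs plus session-scoped simulation studies.

The expensive Monte-Carlo studies (parameter recovery, interval coverage,
scale recovery, space-for-time controls) run once per session and are shared
between the unit tests and the acceptance checks.
"""

import numpy as np
import pytest
from hypothesis import settings

import spacefortime as sft
from spacefortime.nmix import MCMCSettings, ModelSpec, fit_model, posterior_true_abundance
from spacefortime.synthetic import CommunityHyperparams

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_grid():
    return sft.build_scale_grid(50, 1500, 50)


@pytest.fixture()
def small_design():
    return sft.SurveyDesign(n_sites=20, n_species=4, n_landcover=3)


@pytest.fixture()
def small_grid():
    return sft.build_scale_grid(50, 300, 50)


def _simulate(design, grid, seed, hyper=None, fixed_scale=None, variant="multiscale",
              shock_sd=0.3):
    stack = sft.generate_landscape(design, grid, seed=seed, shock_sd=shock_sd)
    hp = hyper or CommunityHyperparams()
    params = sft.generate_community(
        design, grid, hp, seed=seed, fixed_scale=fixed_scale,
        include_alpha=variant == "multiscale",
    )
    counts, latent = sft.simulate_counts(params, stack, design, seed=seed,
                                         model_variant=variant)
    return stack, params, counts, latent


@pytest.fixture(scope="session")
def small_dataset(study_grid):
    """A light multiscale dataset for plumbing-level tests."""
    design = sft.SurveyDesign(30, 5, 3)
    grid = sft.build_scale_grid(50, 500, 50)
    stack, params, counts, latent = _simulate(design, grid, seed=77)
    return dict(design=design, grid=grid, stack=stack, params=params,
                counts=counts, latent=latent)


@pytest.fixture(scope="session")
def recovery_run(study_grid):
    """Multiscale fit on simulated data at the recovery study size (S=8, J=60)."""
    design = sft.SurveyDesign(60, 8, 7)
    stack, params, counts, latent = _simulate(design, study_grid, seed=3)
    smap = sft.OptimalScaleMap(
        params.true_scale, list(counts.species), list(stack.types), "truth",
        grid=study_grid,
    )
    spec = ModelSpec(
        variant="multiscale",
        mcmc=MCMCSettings(chains=2, warmup=1200, samples=600),
        check_convergence=False,
    )
    posterior = fit_model(counts, stack, smap, spec, seed=103)
    return dict(design=design, stack=stack, params=params, counts=counts,
                latent=latent, scale_map=smap, posterior=posterior)


@pytest.fixture(scope="session")
def coverage_runs(study_grid):
    """Twenty replicate simulations + short fits; records whether the true
    community totals fall in the 89% CrI of the posterior totals."""
    design = sft.SurveyDesign(60, 8, 7)
    spec = ModelSpec(
        variant="multiscale",
        mcmc=MCMCSettings(chains=2, warmup=600, samples=300),
        check_convergence=False,
    )
    hits = []
    for rep in range(20):
        stack, params, counts, latent = _simulate(design, study_grid, seed=300 + rep)
        smap = sft.OptimalScaleMap(
            params.true_scale, list(counts.species), list(stack.types), "truth",
            grid=study_grid,
        )
        posterior = fit_model(counts, stack, smap, spec, seed=400 + rep)
        comm = posterior_true_abundance(posterior)
        lo, hi = np.quantile(comm.community_totals, [0.055, 0.945], axis=0)
        truth = latent.sum(axis=(0, 1))
        hits.append(bool(np.all((truth >= lo) & (truth <= hi))))
    return hits


@pytest.fixture(scope="session")
def scale_recovery_runs(study_grid):
    """Correlation-based scale selection on strong-signal communities with a
    single generating radius of 500 m; 10 seeds."""
    rates = []
    for seed in range(10):
        design = sft.SurveyDesign(200, 6, 3)
        hp = CommunityHyperparams(
            mu=np.array([2.5, -2.5, 2.0]), tau=0.3, rho=0.0, sigma=0.1,
            psi=0.7, theta=20.0,
        )
        stack, params, counts, _ = _simulate(
            design, study_grid, seed=seed, hyper=hp, fixed_scale=500.0
        )
        smap = sft.select_scale_correlation(counts, stack, study_grid, "pearson")
        rates.append(float((np.abs(smap.radius - 500.0) <= 50.0).mean()))
    return rates


@pytest.fixture(scope="session")
def control_runs(study_grid):
    """Positive (phi = 0, changing land cover) and negative (large phi,
    static land cover) space-for-time control fits."""
    from spacefortime.counterfactual import compute_trends, expected_N_phi0

    design = sft.SurveyDesign(60, 8, 7)
    spec = ModelSpec(
        variant="multiscale",
        mcmc=MCMCSettings(chains=2, warmup=1000, samples=500),
        check_convergence=False,
    )

    hp_pos = CommunityHyperparams(rho=0.0, sigma=1e-3)
    stack_p, params_p, counts_p, _ = _simulate(
        design, study_grid, seed=21, hyper=hp_pos, shock_sd=0.4
    )
    smap_p = sft.OptimalScaleMap(
        params_p.true_scale, list(counts_p.species), list(stack_p.types), "truth",
        grid=study_grid,
    )
    post_p = fit_model(counts_p, stack_p, smap_p, spec, seed=5)
    comm_p = posterior_true_abundance(post_p)
    cf2 = expected_N_phi0(post_p, stack_p, smap_p, seed=5)
    lo_f, hi_f = np.quantile(comm_p.species_totals[:, :, 1], [0.055, 0.945], axis=0)
    lo_c, hi_c = np.quantile(cf2, [0.055, 0.945], axis=0)
    overlap = (lo_f <= hi_c) & (lo_c <= hi_f)

    hp_neg = CommunityHyperparams(rho=-1.2, sigma=0.3)
    stack_n, params_n, counts_n, _ = _simulate(
        design, study_grid, seed=22, hyper=hp_neg, shock_sd=0.0
    )
    smap_n = sft.OptimalScaleMap(
        params_n.true_scale, list(counts_n.species), list(stack_n.types), "truth",
        grid=study_grid,
    )
    post_n = fit_model(counts_n, stack_n, smap_n, spec, seed=6)
    trends_n = compute_trends(post_n, stack_n, smap_n, seed=6)

    return dict(positive_overlap=overlap, negative_trends=trends_n)
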