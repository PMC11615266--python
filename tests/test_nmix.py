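"""N-mixture likelihood, linear predictors, sampler behaviour, posteriors."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import spacefortime as sft
from spacefortime.design import DesignError
from spacefortime.nmix import (
    ConvergenceError,
    MCMCSettings,
    ModelSpec,
    _ModelData,
    cri_bounds,
    fit_model,
    linear_predictor,
    marginal_loglik_site,
    posterior_true_abundance,
    retrodiction_check,
)
from spacefortime.synthetic import CommunityHyperparams


def brute_force_marginal(y_vec, lam, p, nmax):
    """Independent oracle: direct linear-space summation over N."""
    y = np.atleast_1d(y_vec)
    total = 0.0
    for N in range(int(y.max()), nmax + 1):
        term = stats.poisson.pmf(N, lam)
        for yk in y:
            term *= stats.binom.pmf(yk, N, p)
        total += term
    return float(np.log(total))


class TestMarginalLoglik:
    @pytest.mark.parametrize("lam", [0.1, 1.0, 5.0, 20.0])
    @pytest.mark.parametrize("p", [0.1, 0.5, 0.9])
    @pytest.mark.parametrize("y", [(0,), (2,), (10,), (2, 1), (0, 3), (10, 7)])
    def test_matches_brute_force_summation(self, lam, p, y):
        got = marginal_loglik_site(y, lam, p, nmax=200)
        want = brute_force_marginal(y, lam, p, nmax=200)
        assert got == pytest.approx(want, abs=1e-8)

    def test_single_replicate_poisson_thinning_closed_form(self):
        got = marginal_loglik_site([2], 3.0, 0.5, nmax=200)
        assert got == pytest.approx(stats.poisson.logpmf(2, 1.5), abs=1e-10)

    def test_perfect_detection_collapses_to_poisson(self):
        got = marginal_loglik_site([4, 4], 2.5, 1 - 1e-12, nmax=100)
        assert got == pytest.approx(stats.poisson.logpmf(4, 2.5), abs=1e-6)

    def test_nmax_below_observed_rejected(self):
        with pytest.raises(DesignError):
            marginal_loglik_site([5, 2], 1.0, 0.5, nmax=4)

    def test_invalid_rate_rejected(self):
        with pytest.raises(DesignError):
            marginal_loglik_site([1], 0.0, 0.5, nmax=10)


class TestLinearPredictor:
    def test_pure_habitat_composition_reads_beta(self):
        # composition fully on type m: lambda = exp(beta_im)
        spec = ModelSpec(variant="fixed50")
        beta = np.array([0.7, -0.3, 1.1])
        E = np.array([0.0, 1.0, 0.0])
        lam = linear_predictor(spec, beta, 0.0, 0.0, E, period_index=0)
        assert lam == pytest.approx(np.exp(-0.3))

    def test_null_parameters_give_unit_rate(self):
        spec = ModelSpec(variant="multiscale")
        lam1 = linear_predictor(spec, np.zeros(3), 0.0, 0.0, np.array([0.2, 0.3, 0.5]), 0)
        lam2 = linear_predictor(spec, np.zeros(3), 0.0, 0.0, np.array([0.2, 0.3, 0.5]), 1)
        assert lam1 == pytest.approx(1.0) and lam2 == pytest.approx(1.0)

    def test_multiscale_arithmetic(self):
        spec = ModelSpec(variant="multiscale")
        lam = linear_predictor(
            spec, np.array([1.0, -1.0]), 0.5, 0.2, np.array([0.3, 0.7]), 1
        )
        assert lam == pytest.approx(np.exp(0.3))

    def test_fixed50_requires_closed_composition(self):
        spec = ModelSpec(variant="fixed50")
        with pytest.raises(DesignError):
            linear_predictor(spec, np.zeros(3), 0.0, 0.0, np.array([0.2, 0.3, 0.4]), 0)

    def test_scheffe_design_is_full_rank_without_intercept(self):
        rng = np.random.default_rng(0)
        E = rng.dirichlet(np.ones(4), size=50)
        assert np.linalg.matrix_rank(E) == 4
        with_intercept = np.column_stack([np.ones(50), E])
        assert np.linalg.matrix_rank(with_intercept) == 4  # deficient: 5 columns
        with pytest.raises(DesignError, match="rank"):
            ModelSpec(variant="fixed50", include_intercept=True)


@pytest.fixture(scope="module")
def prepared(study_grid):
    design = sft.SurveyDesign(12, 3, 4)
    grid = sft.build_scale_grid(50, 300, 50)
    stack = sft.generate_landscape(design, grid, seed=5)
    params = sft.generate_community(design, grid, seed=5)
    counts, _ = sft.simulate_counts(params, stack, design, seed=5)
    smap = sft.OptimalScaleMap(params.true_scale, list(counts.species),
                               list(stack.types), "t", grid=grid)
    spec = ModelSpec(variant="multiscale", check_convergence=False)
    return _ModelData(counts, stack, smap, spec), params, counts, stack, smap


class TestModelLikelihoodInternals:
    def test_species_loglik_matches_per_site_marginals(self, prepared):
        data, params, *_ = prepared
        got = data.species_loglik(params.beta, params.alpha, params.phi,
                                  params.detect_p)
        want = np.zeros(data.S)
        for i in range(data.S):
            for t in range(2):
                lam = data.lam(params.beta, params.alpha, params.phi, t)
                for j in range(data.J):
                    want[i] += marginal_loglik_site(
                        data.y[t][i, j], lam[i, j], params.detect_p[i], data.nmax
                    )
        assert np.allclose(got, want, atol=1e-10)

    def test_truncation_stability(self, prepared):
        data, params, counts, stack, smap = prepared
        spec2 = ModelSpec(variant="multiscale", nmax=2 * data.nmax,
                          check_convergence=False)
        data2 = _ModelData(counts, stack, smap, spec2)
        ll1 = data.species_loglik(params.beta, params.alpha, params.phi,
                                  params.detect_p).sum()
        ll2 = data2.species_loglik(params.beta, params.alpha, params.phi,
                                   params.detect_p).sum()
        assert abs(ll1 - ll2) < 1e-6

    def test_single_replicate_design_is_thinned_poisson(self, study_grid):
        # both periods with one replicate: the model collapses exactly to
        # independent Poisson(lambda * P) counts
        design = sft.SurveyDesign(10, 2, 3, replicates_per_period={1: 1, 2: 1})
        grid = sft.build_scale_grid(50, 200, 50)
        stack = sft.generate_landscape(design, grid, seed=6)
        params = sft.generate_community(design, grid, seed=6)
        counts, _ = sft.simulate_counts(params, stack, design, seed=6)
        smap = sft.OptimalScaleMap(params.true_scale, list(counts.species),
                                   list(stack.types), "t", grid=grid)
        data = _ModelData(counts, stack, smap,
                          ModelSpec(variant="multiscale", check_convergence=False))
        got = data.species_loglik(params.beta, params.alpha, params.phi,
                                  params.detect_p)
        want = np.zeros(data.S)
        for t in range(2):
            lam = data.lam(params.beta, params.alpha, params.phi, t)
            mu = lam * params.detect_p[:, None]
            want += stats.poisson.logpmf(data.sumy[t], mu).sum(axis=1)
        assert np.allclose(got, want, atol=1e-10)

    def test_nmax_smaller_than_observed_rejected(self, prepared):
        _, _, counts, stack, smap = prepared
        spec = ModelSpec(variant="multiscale", nmax=0, check_convergence=False)
        with pytest.raises(DesignError, match="nmax"):
            _ModelData(counts, stack, smap, spec)


def _tiny_fit(seed=1, chains=1, warmup=60, samples=30, **spec_kw):
    design = sft.SurveyDesign(12, 3, 3)
    grid = sft.build_scale_grid(50, 200, 50)
    stack = sft.generate_landscape(design, grid, seed=seed)
    params = sft.generate_community(design, grid, seed=seed)
    counts, _ = sft.simulate_counts(params, stack, design, seed=seed)
    smap = sft.OptimalScaleMap(params.true_scale, list(counts.species),
                               list(stack.types), "t", grid=grid)
    spec = ModelSpec(
        variant="multiscale",
        mcmc=MCMCSettings(chains=chains, warmup=warmup, samples=samples),
        check_convergence=spec_kw.pop("check_convergence", False),
        **spec_kw,
    )
    return fit_model(counts, stack, smap, spec, seed=99), counts


class TestFitModel:
    def test_deterministic_under_fixed_seed(self):
        post1, _ = _tiny_fit()
        post2, _ = _tiny_fit()
        for k in post1.draws:
            assert np.array_equal(post1.draws[k], post2.draws[k])
        assert np.array_equal(post1.latent_n, post2.latent_n)

    def test_nonconvergence_raises_with_diagnostics(self):
        with pytest.raises(ConvergenceError) as err:
            _tiny_fit(chains=2, check_convergence=True, rhat_max=1.0001)
        assert isinstance(err.value.rhat_table, pd.DataFrame)
        assert "rhat" in err.value.rhat_table.columns

    def test_posterior_shapes_and_supports(self):
        post, _ = _tiny_fit()
        p = post.flat("p")
        assert p.shape == (30, 3)
        assert ((p > 0) & (p < 1)).all()
        for name in ("tau", "sigma", "tau_a", "theta"):
            assert (post.flat(name) > 0).all()

    def test_detection_recovery_at_study_size(self, recovery_run):
        post = recovery_run["posterior"]
        truth = recovery_run["params"]
        p_med = np.median(post.flat("p"), axis=0)
        n_close = int((np.abs(p_med - truth.detect_p) <= 0.15).sum())
        assert n_close >= 6

    def test_hierarchical_pooling_strengthens_with_tighter_prior(self, study_grid):
        from spacefortime.nmix import PriorSettings

        design = sft.SurveyDesign(30, 6, 3)
        grid = sft.build_scale_grid(50, 200, 50)
        stack = sft.generate_landscape(design, grid, seed=14)
        hp = CommunityHyperparams(mu=np.array([0.5, 0.0, 1.0]), tau=0.8)
        params = sft.generate_community(design, grid, hp, seed=14,
                                        include_alpha=False)
        counts, _ = sft.simulate_counts(params, stack, design, seed=14,
                                        model_variant="fixed50")
        spreads = []
        for scale in (1.0, 0.1, 0.01):
            spec = ModelSpec(
                variant="fixed50",
                priors=PriorSettings(scale_scale=scale),
                mcmc=MCMCSettings(chains=1, warmup=400, samples=200),
                check_convergence=False,
            )
            post = fit_model(counts, stack, None, spec, seed=31)
            beta_med = np.median(post.flat("beta"), axis=0)  # (S, M)
            spreads.append(float(beta_med.std(axis=0).mean()))
        assert spreads[0] > spreads[1] > spreads[2]

    def test_species_label_invariance_of_posterior_location(self):
        # permuting the species axis of the data permutes the posterior
        # (up to Monte-Carlo error, since proposal noise is indexed by slot)
        design = sft.SurveyDesign(40, 3, 3)
        grid = sft.build_scale_grid(50, 200, 50)
        stack = sft.generate_landscape(design, grid, seed=15)
        hp = CommunityHyperparams(mu_alpha=1.2, tau_alpha=0.6, psi=0.7, theta=20.0)
        params = sft.generate_community(design, grid, hp, seed=15)
        counts, _ = sft.simulate_counts(params, stack, design, seed=15)
        smap = sft.OptimalScaleMap(params.true_scale, list(counts.species),
                                   list(stack.types), "t", grid=grid)
        spec = ModelSpec(variant="multiscale",
                         mcmc=MCMCSettings(chains=1, warmup=500, samples=300),
                         check_convergence=False)
        post = fit_model(counts, stack, smap, spec, seed=77)

        perm = [2, 0, 1]
        counts_p = sft.CountData(counts.counts[perm],
                                 [counts.species[i] for i in perm],
                                 list(counts.sites), design)
        smap_p = sft.OptimalScaleMap(params.true_scale[perm],
                                     [counts.species[i] for i in perm],
                                     list(stack.types), "t", grid=grid)
        post_p = fit_model(counts_p, stack, smap_p, spec, seed=77)
        a = np.median(post.flat("alpha"), axis=0)
        a_p = np.median(post_p.flat("alpha"), axis=0)
        assert np.allclose(a_p, a[perm], atol=0.35)


class TestPosteriorSummaries:
    def test_totals_are_sums_of_site_draws(self, recovery_run):
        post = recovery_run["posterior"]
        comm = posterior_true_abundance(post)
        assert np.array_equal(comm.species_totals, post.latent_n.sum(axis=2))
        assert np.array_equal(comm.community_totals, comm.species_totals.sum(axis=1))

    def test_summary_intervals_are_ordered_and_monotone_in_level(self, recovery_run):
        comm = posterior_true_abundance(recovery_run["posterior"])
        s89 = comm.summary(0.89)
        s50 = comm.summary(0.50)
        assert (s89["lo"] <= s89["median"]).all() and (s89["median"] <= s89["hi"]).all()
        merged = s89.merge(s50, on=["species", "period"], suffixes=("_89", "_50"))
        assert (merged["lo_89"] <= merged["lo_50"]).all()
        assert (merged["hi_89"] >= merged["hi_50"]).all()

    def test_cri_bounds(self):
        assert cri_bounds(0.89) == pytest.approx((0.055, 0.945))
        with pytest.raises(DesignError):
            cri_bounds(0.0)

    def test_retrodiction_calibrated_on_well_specified_data(self, recovery_run):
        table = retrodiction_check(recovery_run["posterior"],
                                   recovery_run["counts"])
        inside = ((table["observed"] >= table["lo"])
                  & (table["observed"] <= table["hi"]))
        assert inside.mean() >= 0.85

    def test_retrodiction_of_allzero_species_concentrates_near_zero(self):
        post, counts = _tiny_fit(seed=2, warmup=150, samples=80)
        arr = counts.counts.copy()
        arr[0] = 0
        counts0 = sft.CountData(arr, list(counts.species), list(counts.sites),
                                counts.design)
        # refit so the posterior corresponds to the zeroed species
        design = counts.design
        grid = sft.build_scale_grid(50, 200, 50)
        stack = sft.generate_landscape(design, grid, seed=2)
        params = sft.generate_community(design, grid, seed=2)
        smap = sft.OptimalScaleMap(params.true_scale, list(counts.species),
                                   list(stack.types), "t", grid=grid)
        spec = ModelSpec(variant="multiscale",
                         mcmc=MCMCSettings(chains=1, warmup=150, samples=80),
                         check_convergence=False)
        post0 = fit_model(counts0, stack, smap, spec, seed=4)
        table = retrodiction_check(post0, counts0)
        zero_rows = table[table["species"] == counts.species[0]]
        assert (zero_rows["median"] <= 2).all()
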