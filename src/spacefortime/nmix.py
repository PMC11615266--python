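"""Bayesian multispecies N-mixture abundance models.

Counts are Binomial thinnings of a latent Poisson abundance::

    y_ijkt ~ Binomial(N_ijt, P_i)        N_ijt ~ Poisson(lambda_ijt)

with species detection probabilities partially pooled through a Beta
hyperprior (centre psi, concentration theta) and shared across periods.
Two linear predictors are offered:

* ``fixed50`` — the intercept-free compositional (Scheffé) form at the
  smallest radius: log lambda = sum_m beta_im E_jmt. Because the proportions
  sum to one, an intercept would make the design rank-deficient, so beta_im
  reads as the log expected abundance were type m to cover the whole count
  circle.
* ``multiscale`` — species intercept plus covariates at each species' optimal
  scale per type: log lambda = alpha_i + sum_m beta_im E_ijmt (the type
  proportions at different radii no longer sum to one, so the model is full
  rank with an intercept).

Period 2 adds a species drift phi_i ~ Normal(rho, sigma) capturing abundance
change *not* attributable to land cover; habitat effects beta_im are
partially pooled as Normal(mu_m, tau_m).

The discrete latent N is marginalized out of the likelihood by truncated
summation to Nmax and re-imputed per posterior draw from its conditional.
Sampling uses adaptive componentwise Metropolis-within-Gibbs for the species
blocks and conjugate/slice updates for the hyperparameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln, logsumexp

from .config import split_seed
from .containers import CountData, LandCoverStack, OptimalScaleMap
from .design import DesignError

__all__ = [
    "PriorSettings",
    "MCMCSettings",
    "ModelSpec",
    "ModelPosterior",
    "PosteriorCommunity",
    "ConvergenceError",
    "marginal_loglik_site",
    "linear_predictor",
    "fit_model",
    "posterior_true_abundance",
    "retrodiction_check",
    "cri_bounds",
]

_LIN_CLIP = 30.0


class ConvergenceError(RuntimeError):
    """MCMC failed the split-R-hat check; carries the diagnostic table."""

    def __init__(self, message, rhat_table: pd.DataFrame):
        super().__init__(message)
        self.rhat_table = rhat_table


@dataclass(frozen=True)
class PriorSettings:
    """Priors: psi ~ Beta(2, 3), theta ~ Gamma(9, 5) for the detection
    hyperprior; Normal(0, loc_scale) for location hyperparameters (mu_m, rho,
    mu_alpha) and half-Normal(0, scale_scale) for the positive scales
    (tau_m, sigma, tau_alpha)."""

    psi_a: float = 2.0
    psi_b: float = 3.0
    theta_shape: float = 9.0
    theta_rate: float = 5.0
    loc_scale: float = 2.0
    scale_scale: float = 2.0

    def __post_init__(self):
        if self.loc_scale <= 0 or self.scale_scale <= 0:
            raise DesignError("prior scales must be positive")


@dataclass(frozen=True)
class MCMCSettings:
    chains: int = 4
    warmup: int = 1500
    samples: int = 500

    def __post_init__(self):
        if self.chains < 1 or self.warmup < 0 or self.samples < 1:
            raise DesignError("invalid MCMC settings")


@dataclass(frozen=True)
class ModelSpec:
    """Model variant, truncation and sampler settings.

    ``nmax`` of None resolves to (max observed count + ``nmax_extra``).
    ``include_intercept`` is only legal for the multiscale variant: the
    compositional fixed50 design is rank-deficient with an intercept, and the
    build refuses that combination.
    """

    variant: str = "multiscale"
    nmax: int | None = None
    nmax_extra: int = 50
    include_intercept: bool | None = None
    priors: PriorSettings = field(default_factory=PriorSettings)
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    rhat_max: float = 1.01
    check_convergence: bool = True

    def __post_init__(self):
        if self.variant not in ("fixed50", "multiscale"):
            raise DesignError(f"unknown variant {self.variant!r}")
        intercept = self.include_intercept
        if intercept is None:
            intercept = self.variant == "multiscale"
            object.__setattr__(self, "include_intercept", intercept)
        if self.variant == "fixed50" and intercept:
            raise DesignError(
                "fixed50 uses compositional covariates that sum to one; an "
                "intercept makes the design rank-deficient (Scheffé form has "
                "no intercept)"
            )
        if self.variant == "multiscale" and not intercept:
            raise DesignError("the multiscale variant requires the intercept")


# ---------------------------------------------------------------------------
# likelihood primitives


def marginal_loglik_site(y_vec, lam, p, nmax) -> float:
    """Marginal log-likelihood of one (species, site, period) cell.

    log sum_{N=max(y)}^{Nmax} Poisson(N; lam) prod_k Binomial(y_k; N, p),
    computed in log space. For a single replicate this equals the Poisson
    thinning closed form log Poisson(y; lam * p).
    """
    y = np.asarray(y_vec, dtype=np.int64).ravel()
    if lam <= 0:
        raise DesignError("lam must be positive")
    if not 0 < p < 1:
        raise DesignError("p must be in (0,1)")
    ymax = int(y.max())
    if nmax < ymax:
        raise DesignError(f"nmax = {nmax} < max(y) = {ymax}")
    N = np.arange(ymax, nmax + 1)
    logpois = N * np.log(lam) - lam - gammaln(N + 1)
    logbin = np.zeros_like(logpois)
    for yk in y:
        logbin += (
            gammaln(N + 1)
            - gammaln(N - yk + 1)
            - gammaln(yk + 1)
            + yk * np.log(p)
            + (N - yk) * np.log1p(-p)
        )
    return float(logsumexp(logpois + logbin))


def linear_predictor(spec: ModelSpec, beta_i, alpha_i, phi_i, E_i, period_index) -> float:
    """lambda for one (species, site, period) from the variant's linear form.

    ``E_i``: the M land-cover proportions seen by this species at this site
    and period (at the smallest radius for fixed50, at the species' optimal
    scales for multiscale). ``period_index`` 0 or 1; period 2 adds phi.
    """
    E_i = np.asarray(E_i, dtype=float)
    if spec.variant == "fixed50":
        if abs(E_i.sum() - 1.0) > 1e-6:
            raise DesignError(
                "fixed50 requires a closed composition (proportions summing to 1)"
            )
        if alpha_i not in (0, 0.0, None):
            raise DesignError("fixed50 has no intercept")
        lin = float(np.dot(beta_i, E_i))
    else:
        lin = float(alpha_i) + float(np.dot(beta_i, E_i))
    if period_index == 1:
        lin += float(phi_i)
    return float(np.exp(lin))


# ---------------------------------------------------------------------------
# data preparation


class _ModelData:
    """Precomputed arrays for fast repeated likelihood evaluation."""

    def __init__(self, counts: CountData, stack: LandCoverStack,
                 scale_map: OptimalScaleMap | None, spec: ModelSpec):
        design = counts.design
        if design.n_periods != 2:
            raise DesignError("the abundance model is two-period")
        self.design = design
        self.species = list(counts.species)
        self.sites = list(counts.sites)
        S, J = design.n_species, design.n_sites
        self.S, self.J, self.M = S, J, design.n_landcover

        ymax = counts.max_count
        self.nmax = spec.nmax if spec.nmax is not None else ymax + spec.nmax_extra
        if self.nmax < ymax:
            raise DesignError(
                f"nmax = {self.nmax} < max observed count = {ymax}"
            )
        self.Ngrid = np.arange(self.nmax + 1)

        # covariates: (S, J, M) per period for multiscale, (J, M) for fixed50
        if spec.variant == "multiscale":
            if scale_map is None:
                raise DesignError("multiscale fit requires an optimal-scale map")
            E = stack.at_scale_map(scale_map)  # (S, J, M, T)
            self.E = [E[:, :, :, t] for t in range(2)]
        else:
            if scale_map is not None:
                raise DesignError("fixed50 does not take a scale map")
            E = stack.at_radius(stack.grid.min_radius)  # (J, M, T)
            self.E = [E[:, :, t] for t in range(2)]
        self.variant = spec.variant

        # per-period count structures
        self.y = [counts.replicates(t) for t in design.periods]  # (S, J, K_t)
        self.K = [y.shape[2] for y in self.y]
        self.sumy = [y.sum(axis=2) for y in self.y]  # (S, J)
        self.obs_tot = [int(y.sum()) for y in self.y]
        # N-independent binomial coefficient part for replicated periods,
        # -inf where N < y_k so the truncated sum starts at max(y)
        self.pre = []
        for t, y in enumerate(self.y):
            if self.K[t] == 1:
                self.pre.append(None)
                continue
            N = self.Ngrid[None, None, :]
            pre = -gammaln(N + 1)  # Poisson N! term
            with np.errstate(invalid="ignore"):
                for k in range(self.K[t]):
                    yk = y[:, :, k][:, :, None]
                    term = gammaln(N + 1) - gammaln(N - yk + 1) - gammaln(yk + 1)
                    term = np.where(N >= yk, term, -np.inf)
                    pre = pre + term
            self.pre.append(pre)  # (S, J, Nn)

    def lam(self, beta, alpha, phi, t) -> np.ndarray:
        """Expected abundance (S, J) for period index t."""
        if self.variant == "multiscale":
            lin = np.einsum("sjm,sm->sj", self.E[t], beta) + alpha[:, None]
        else:
            lin = beta @ self.E[t].T
        if t == 1:
            lin = lin + phi[:, None]
        return np.exp(np.clip(lin, -_LIN_CLIP, _LIN_CLIP))

    def species_loglik(self, beta, alpha, phi, p) -> np.ndarray:
        """Marginal log-likelihood per species, latent N summed out. (S,)"""
        ll = np.zeros(self.S)
        logp = np.log(p)
        log1mp = np.log1p(-p)
        for t in range(2):
            lam = self.lam(beta, alpha, phi, t)
            if self.K[t] == 1:
                y = self.sumy[t]
                mu = lam * p[:, None]
                ll += (y * np.log(mu) - mu - gammaln(y + 1)).sum(axis=1)
            else:
                base = -lam + self.sumy[t] * (logp - log1mp)[:, None]
                slope = np.log(lam) + self.K[t] * log1mp[:, None]  # (S, J)
                A = self.pre[t] + slope[:, :, None] * self.Ngrid[None, None, :]
                amax = A.max(axis=2)
                s = np.exp(A - amax[:, :, None]).sum(axis=2)
                ll += (base + amax + np.log(s)).sum(axis=1)
        return ll


# ---------------------------------------------------------------------------
# posterior containers


@dataclass
class ModelPosterior:
    """Posterior draws of all model parameters plus imputed latent abundance.

    Parameter arrays are (chains, draws, ...); ``latent_n`` is
    (chains*draws, S, J, T). ``diagnostics`` tabulates split-R-hat per
    parameter block.
    """

    draws: dict
    latent_n: np.ndarray
    species: list
    sites: list
    variant: str
    spec: ModelSpec
    diagnostics: pd.DataFrame
    seed: int

    @property
    def n_draws(self) -> int:
        return self.latent_n.shape[0]

    def flat(self, name) -> np.ndarray:
        """Draws of one parameter with chains stacked: (chains*draws, ...)."""
        a = self.draws[name]
        return a.reshape((-1,) + a.shape[2:])

    @property
    def max_rhat(self) -> float:
        return float(self.diagnostics["rhat"].max())


@dataclass
class PosteriorCommunity:
    """Per-draw totals of true abundance over sites.

    ``species_totals``: (D, S, T); ``community_totals``: (D, T).
    """

    species_totals: np.ndarray
    community_totals: np.ndarray
    species: list
    periods: tuple

    def summary(self, cri_level: float = 0.89) -> pd.DataFrame:
        lo_q, hi_q = cri_bounds(cri_level)
        rows = []
        for t_ix, t in enumerate(self.periods):
            tot = self.community_totals[:, t_ix]
            rows.append(
                {
                    "species": "__community__",
                    "period": t,
                    "median": float(np.median(tot)),
                    "lo": float(np.quantile(tot, lo_q)),
                    "hi": float(np.quantile(tot, hi_q)),
                }
            )
            for i, sp in enumerate(self.species):
                st = self.species_totals[:, i, t_ix]
                rows.append(
                    {
                        "species": sp,
                        "period": t,
                        "median": float(np.median(st)),
                        "lo": float(np.quantile(st, lo_q)),
                        "hi": float(np.quantile(st, hi_q)),
                    }
                )
        return pd.DataFrame(rows)


def cri_bounds(level: float) -> tuple[float, float]:
    """Equal-tailed credible-interval quantiles, e.g. 0.89 -> (0.055, 0.945)."""
    if not 0 < level < 1:
        raise DesignError("CrI level must be in (0,1)")
    return (1 - level) / 2, 1 - (1 - level) / 2


# ---------------------------------------------------------------------------
# sampler internals


def _slice1d(x0, logf, rng, w=1.0, max_steps=50):
    """Univariate slice sampler (stepping out + shrinkage)."""
    f0 = logf(x0)
    if not np.isfinite(f0):
        return x0
    y = f0 - rng.exponential()
    L = x0 - w * rng.uniform()
    R = L + w
    for _ in range(max_steps):
        if logf(L) <= y:
            break
        L -= w
    for _ in range(max_steps):
        if logf(R) <= y:
            break
        R += w
    for _ in range(100):
        x1 = rng.uniform(L, R)
        if logf(x1) > y:
            return x1
        if x1 < x0:
            L = x1
        else:
            R = x1
    return x0


def _normal_conj_mean(values, sd, prior_scale, rng):
    """Gibbs draw of a Normal location with known sd and N(0, prior_scale) prior."""
    n = len(values)
    prec = 1.0 / prior_scale**2 + n / sd**2
    mean = (values.sum() / sd**2) / prec
    return rng.normal(mean, 1.0 / np.sqrt(prec))


def _scale_slice(values, mean, cur, prior_scale, rng):
    """Slice draw of a Normal scale with half-Normal(0, prior_scale) prior."""
    n = len(values)
    ss = float(((values - mean) ** 2).sum())

    def logf(u):
        tau = np.exp(u)
        return -n * u - 0.5 * ss / tau**2 - 0.5 * tau**2 / prior_scale**2 + u

    return float(np.exp(_slice1d(np.log(cur), logf, rng)))


class _ChainState:
    def __init__(self, data: _ModelData, spec: ModelSpec, rng):
        S, M = data.S, data.M
        # data-informed start: species mean response on the log scale
        mean_resp = np.maximum(
            np.mean([data.sumy[t].mean(axis=1) / data.K[t] for t in range(2)], axis=0),
            0.02,
        )
        base = np.log(mean_resp * 2.0)  # crude detection-corrected level
        jit = lambda s, size: rng.normal(0, s, size=size)
        if spec.variant == "multiscale":
            self.alpha = base + jit(0.2, S)
            self.beta = jit(0.3, (S, M))
        else:
            self.alpha = np.zeros(S)
            self.beta = base[:, None] + jit(0.3, (S, M))
        self.phi = jit(0.2, S)
        self.lp = jit(0.3, S)  # logit detection, centred at p = 0.5
        self.mu = self.beta.mean(axis=0) + jit(0.1, M)
        self.tau = np.full(M, 0.5)
        self.rho = 0.0
        self.sigma = 0.5
        self.mu_a = float(self.alpha.mean())
        self.tau_a = 0.5
        self.psi = 0.5
        self.theta = 5.0

    @property
    def p(self):
        return 1.0 / (1.0 + np.exp(-self.lp))


def _run_chain(data: _ModelData, spec: ModelSpec, rng, n_warmup, n_samples):
    S, M = data.S, data.M
    pr = spec.priors
    st = _ChainState(data, spec, rng)
    multiscale = spec.variant == "multiscale"

    groups = [("beta", m) for m in range(M)]
    if multiscale:
        groups += [("alpha", None), ("shift", None)]
    groups += [("phi", None), ("lp", None), ("pshift", None)]
    lscale = {g: np.full(S, np.log(0.4)) for g in groups}

    cur_ll = data.species_loglik(st.beta, st.alpha, st.phi, st.p)

    def beta_ab():
        return st.psi * st.theta, (1 - st.psi) * st.theta

    keep = {
        k: []
        for k in (
            "beta", "alpha", "phi", "p", "psi", "theta",
            "mu", "tau", "rho", "sigma", "mu_a", "tau_a",
        )
    }

    total = n_warmup + n_samples
    for it in range(total):
        adapting = it < n_warmup
        gamma = 1.0 / np.sqrt(1 + it) if adapting else 0.0
        for g in groups:
            name, m = g
            step = np.exp(lscale[g]) * rng.standard_normal(S)
            beta, alpha, phi, lp = st.beta, st.alpha, st.phi, st.lp
            if name == "beta":
                prop = beta.copy()
                prop[:, m] = beta[:, m] + step
                dpri = (
                    (beta[:, m] - st.mu[m]) ** 2 - (prop[:, m] - st.mu[m]) ** 2
                ) / (2 * st.tau[m] ** 2)
                new_ll = data.species_loglik(prop, alpha, phi, st.p)
            elif name == "alpha":
                prop = alpha + step
                dpri = ((alpha - st.mu_a) ** 2 - (prop - st.mu_a) ** 2) / (
                    2 * st.tau_a**2
                )
                new_ll = data.species_loglik(beta, prop, phi, st.p)
            elif name == "shift":
                # ridge move: trade intercept against all habitat effects
                prop_a = alpha + step
                prop_b = beta - step[:, None]
                dpri = ((alpha - st.mu_a) ** 2 - (prop_a - st.mu_a) ** 2) / (
                    2 * st.tau_a**2
                )
                dpri += (
                    ((beta - st.mu[None, :]) ** 2 - (prop_b - st.mu[None, :]) ** 2)
                    / (2 * st.tau[None, :] ** 2)
                ).sum(axis=1)
                new_ll = data.species_loglik(prop_b, prop_a, phi, st.p)
            elif name == "phi":
                prop = phi + step
                dpri = ((phi - st.rho) ** 2 - (prop - st.rho) ** 2) / (
                    2 * st.sigma**2
                )
                new_ll = data.species_loglik(beta, alpha, prop, st.p)
            elif name == "lp":
                prop = lp + step
                a, b = beta_ab()
                p_new = 1.0 / (1.0 + np.exp(-prop))
                p_new = np.clip(p_new, 1e-12, 1 - 1e-12)
                p_old = st.p
                dpri = a * (np.log(p_new) - np.log(p_old)) + b * (
                    np.log1p(-p_new) - np.log1p(-p_old)
                )
                new_ll = data.species_loglik(beta, alpha, phi, p_new)
            else:  # pshift: move detection along the abundance-detection ridge
                # lp' = lp + step; intercept compensated so lambda * p is
                # preserved — a symmetric, unit-Jacobian map
                prop = lp + step
                a, b = beta_ab()
                p_new = np.clip(1.0 / (1.0 + np.exp(-prop)), 1e-12, 1 - 1e-12)
                p_old = st.p
                comp = np.log(p_old) - np.log(p_new)  # added to the intercept
                dpri = a * (np.log(p_new) - np.log(p_old)) + b * (
                    np.log1p(-p_new) - np.log1p(-p_old)
                )
                if multiscale:
                    prop_a = alpha + comp
                    prop_b = beta
                    dpri += ((alpha - st.mu_a) ** 2 - (prop_a - st.mu_a) ** 2) / (
                        2 * st.tau_a**2
                    )
                else:
                    prop_a = alpha
                    prop_b = beta + comp[:, None]
                    dpri += (
                        ((beta - st.mu[None, :]) ** 2
                         - (prop_b - st.mu[None, :]) ** 2)
                        / (2 * st.tau[None, :] ** 2)
                    ).sum(axis=1)
                new_ll = data.species_loglik(prop_b, prop_a, phi, p_new)
            logacc = np.minimum(new_ll - cur_ll + dpri, 0.0)
            acc = np.log(rng.uniform(size=S)) < logacc
            if name == "beta":
                st.beta[acc, m] = prop[acc, m]
            elif name == "alpha":
                st.alpha[acc] = prop[acc]
            elif name == "shift":
                st.alpha[acc] = prop_a[acc]
                st.beta[acc] = prop_b[acc]
            elif name == "phi":
                st.phi[acc] = prop[acc]
            elif name == "lp":
                st.lp[acc] = prop[acc]
            else:  # pshift
                st.lp[acc] = prop[acc]
                st.alpha[acc] = prop_a[acc]
                st.beta[acc] = prop_b[acc]
            cur_ll = np.where(acc, new_ll, cur_ll)
            if adapting:
                lscale[g] += gamma * (np.exp(logacc) - 0.44)

        # hyperparameters (conditionally independent of the data given species params)
        for m in range(M):
            st.mu[m] = _normal_conj_mean(st.beta[:, m], st.tau[m], pr.loc_scale, rng)
            st.tau[m] = _scale_slice(st.beta[:, m], st.mu[m], st.tau[m], pr.scale_scale, rng)
        st.rho = _normal_conj_mean(st.phi, st.sigma, pr.loc_scale, rng)
        st.sigma = _scale_slice(st.phi, st.rho, st.sigma, pr.scale_scale, rng)
        if multiscale:
            st.mu_a = _normal_conj_mean(st.alpha, st.tau_a, pr.loc_scale, rng)
            st.tau_a = _scale_slice(st.alpha, st.mu_a, st.tau_a, pr.scale_scale, rng)

        p = np.clip(st.p, 1e-12, 1 - 1e-12)
        slogp, slog1mp = float(np.log(p).sum()), float(np.log1p(-p).sum())

        def logf_psi(x):
            psi = 1.0 / (1.0 + np.exp(-x))
            a, b = psi * st.theta, (1 - psi) * st.theta
            return (
                (a - 1) * slogp + (b - 1) * slog1mp - S * betaln(a, b)
                + pr.psi_a * np.log(psi) + pr.psi_b * np.log1p(-psi)
            )

        x = _slice1d(np.log(st.psi / (1 - st.psi)), logf_psi, rng)
        st.psi = 1.0 / (1.0 + np.exp(-x))

        def logf_theta(u):
            th = np.exp(u)
            a, b = st.psi * th, (1 - st.psi) * th
            return (
                (a - 1) * slogp + (b - 1) * slog1mp - S * betaln(a, b)
                + pr.theta_shape * u - pr.theta_rate * th
            )

        st.theta = float(np.exp(_slice1d(np.log(st.theta), logf_theta, rng)))

        if not adapting:
            keep["beta"].append(st.beta.copy())
            keep["alpha"].append(st.alpha.copy())
            keep["phi"].append(st.phi.copy())
            keep["p"].append(st.p.copy())
            keep["psi"].append(st.psi)
            keep["theta"].append(st.theta)
            keep["mu"].append(st.mu.copy())
            keep["tau"].append(st.tau.copy())
            keep["rho"].append(st.rho)
            keep["sigma"].append(st.sigma)
            keep["mu_a"].append(st.mu_a)
            keep["tau_a"].append(st.tau_a)

    return {k: np.asarray(v) for k, v in keep.items()}


def _impute_latent_n(data: _ModelData, beta, alpha, phi, p, rng):
    """Draw N from its conditional given parameters and counts, per draw.

    Single-replicate periods use the exact thinning decomposition
    N = y + Poisson(lambda (1-p)); replicated periods sample the truncated
    categorical over the N grid via the Gumbel trick.
    """
    D = beta.shape[0]
    S, J = data.S, data.J
    out = np.zeros((D, S, J, 2), dtype=np.int64)
    for d in range(D):
        pd_ = p[d]
        for t in range(2):
            lam = data.lam(beta[d], alpha[d], phi[d], t)
            if data.K[t] == 1:
                y = data.sumy[t]
                out[d, :, :, t] = y + rng.poisson(lam * (1 - pd_[:, None]))
            else:
                log1mp = np.log1p(-pd_)[:, None]
                slope = np.log(lam) + data.K[t] * log1mp
                logw = data.pre[t] + slope[:, :, None] * data.Ngrid[None, None, :]
                g = rng.gumbel(size=logw.shape)
                out[d, :, :, t] = np.argmax(logw + g, axis=2)
    return out


def _rhat_table(chain_draws: dict, multiscale: bool) -> pd.DataFrame:
    import arviz as az

    rows = []
    names = ["beta", "phi", "p", "psi", "theta", "mu", "tau", "rho", "sigma"]
    if multiscale:
        names += ["alpha", "mu_a", "tau_a"]
    for name in names:
        a = chain_draws[name]  # (chains, draws, ...)
        ds = az.convert_to_dataset({name: a.astype(float)})
        r = az.rhat(ds)[name].to_numpy()
        flat = np.atleast_1d(r).ravel()
        for ix, val in enumerate(flat):
            rows.append({"param": f"{name}[{ix}]" if flat.size > 1 else name,
                         "rhat": float(val)})
    return pd.DataFrame(rows)


def fit_model(
    counts: CountData,
    stack: LandCoverStack,
    scale_map: OptimalScaleMap | None = None,
    spec: ModelSpec | None = None,
    seed: int = 0,
) -> ModelPosterior:
    """Fit a multispecies N-mixture model by MCMC.

    The latent abundances are marginalized out of the likelihood (truncated
    at Nmax) and re-imputed per retained draw. When ``spec.check_convergence``
    is set, the fit fails loudly with a :class:`ConvergenceError` carrying the
    split-R-hat table if any parameter exceeds ``spec.rhat_max``; desk-scale
    runs with deliberately short chains disable the check.
    """
    spec = spec or ModelSpec()
    data = _ModelData(counts, stack, scale_map, spec)
    chains = []
    for c in range(spec.mcmc.chains):
        rng = split_seed(seed, "fit", spec.variant, f"chain{c}")
        chains.append(_run_chain(data, spec, rng, spec.mcmc.warmup, spec.mcmc.samples))
    stacked = {k: np.stack([ch[k] for ch in chains]) for k in chains[0]}

    multiscale = spec.variant == "multiscale"
    rhat = _rhat_table(stacked, multiscale)
    if spec.check_convergence and rhat["rhat"].max() > spec.rhat_max:
        bad = rhat.sort_values("rhat", ascending=False).head(10)
        raise ConvergenceError(
            f"max split-R-hat {rhat['rhat'].max():.3f} exceeds "
            f"{spec.rhat_max}; worst parameters:\n{bad.to_string(index=False)}",
            rhat,
        )

    rng_n = split_seed(seed, "fit", spec.variant, "impute")
    flat = {k: v.reshape((-1,) + v.shape[2:]) for k, v in stacked.items()}
    latent_n = _impute_latent_n(
        data, flat["beta"], flat["alpha"], flat["phi"], flat["p"], rng_n
    )
    boundary = (latent_n == data.nmax).mean()
    if boundary > 1e-3:
        warnings.warn(
            f"{boundary:.1%} of latent-abundance draws sit at the truncation "
            f"bound Nmax = {data.nmax}; raise nmax/nmax_extra",
            stacklevel=2,
        )
    return ModelPosterior(
        draws=stacked,
        latent_n=latent_n,
        species=data.species,
        sites=data.sites,
        variant=spec.variant,
        spec=spec,
        diagnostics=rhat,
        seed=seed,
    )


def posterior_true_abundance(posterior: ModelPosterior, periods=(1, 2)) -> PosteriorCommunity:
    """Posterior communities: per-draw species and community totals of N."""
    n = posterior.latent_n  # (D, S, J, T)
    species_totals = n.sum(axis=2)
    return PosteriorCommunity(
        species_totals=species_totals,
        community_totals=species_totals.sum(axis=1),
        species=posterior.species,
        periods=tuple(periods),
    )


def retrodiction_check(
    posterior: ModelPosterior, counts: CountData, cri_level: float = 0.89
) -> pd.DataFrame:
    """Posterior-predictive totals of detections vs observed, per species x period.

    For each retained draw, replicate counts are re-simulated as Binomial
    thinnings of the imputed latent N and totalled over sites and replicates.
    """
    design = counts.design
    rng = split_seed(posterior.seed, "retrodiction")
    p = posterior.flat("p")  # (D, S)
    n = posterior.latent_n  # (D, S, J, T)
    lo_q, hi_q = cri_bounds(cri_level)
    rows = []
    for t_ix, t in enumerate(design.periods):
        K = design.n_replicates(t)
        obs = counts.replicates(t).sum(axis=(1, 2))  # (S,)
        sim = rng.binomial(
            np.repeat(n[:, :, :, t_ix][:, :, :, None], K, axis=3),
            p[:, :, None, None],
        ).sum(axis=(2, 3))  # (D, S)
        for i, sp in enumerate(posterior.species):
            rows.append(
                {
                    "species": sp,
                    "period": t,
                    "observed": int(obs[i]),
                    "median": float(np.median(sim[:, i])),
                    "lo": float(np.quantile(sim[:, i], lo_q)),
                    "hi": float(np.quantile(sim[:, i], hi_q)),
                }
            )
    return pd.DataFrame(rows)
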