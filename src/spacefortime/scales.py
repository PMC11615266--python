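"""Scale-of-effect selection per species x land-cover type.

Three selectors are provided:

* out-of-sample prediction with Pearson correlation: for every (species,
  type, radius) a univariate Poisson GLM ``y ~ exp(zeta + eta * E)`` is fit
  per period, leave-one-out predictions are generated for every observation,
  and the radius whose predictions correlate best with the observed responses
  (both periods pooled) wins;
* the same with Spearman rank correlation;
* boosted regression trees: one depth-1 Poisson ensemble per species over all
  (type, radius) proportions; per type, the radius with the highest relative
  influence (total split gain) wins.

Period-2 responses are collapsed to the maximum over the within-period
replicates before any selection — the temporal maximum best represents the
number of birds tied to the surrounding land cover.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy import stats

from .config import split_seed
from .containers import CountData, LandCoverStack, OptimalScaleMap
from .design import DesignError, ScaleGrid, SurveyDesign

__all__ = [
    "UnivariateFit",
    "SelectionPlan",
    "BRTSettings",
    "selection_plan",
    "collapse_period2_max",
    "fit_univariate",
    "loo_predictions",
    "select_scale_correlation",
    "select_scale_brt",
]


# ---------------------------------------------------------------------------
# bookkeeping


@dataclass(frozen=True)
class SelectionPlan:
    """Enumeration plan for correlation-based selection.

    ``n_models`` = S x M x C univariate model configurations;
    ``n_entries`` = S x M optimal-scale map entries.
    """

    n_species: int
    n_landcover: int
    n_radii: int

    @property
    def n_models(self) -> int:
        return self.n_species * self.n_landcover * self.n_radii

    @property
    def n_entries(self) -> int:
        return self.n_species * self.n_landcover

    def configurations(self) -> Iterator[tuple[int, int, int]]:
        """Yield every (species, type, radius) model configuration."""
        for i in range(self.n_species):
            for m in range(self.n_landcover):
                for c in range(self.n_radii):
                    yield (i, m, c)


def selection_plan(design: SurveyDesign, grid: ScaleGrid) -> SelectionPlan:
    return SelectionPlan(design.n_species, design.n_landcover, grid.n_radii)


def collapse_period2_max(counts: CountData) -> np.ndarray:
    """Per-(species, site, period) response: max over within-period replicates.

    Period 1 has a single replicate, so its response is the raw count;
    replicated periods collapse to the maximum. Shape (S, J, T).
    """
    d = counts.design
    out = np.zeros((d.n_species, d.n_sites, d.n_periods), dtype=np.int64)
    for t_ix, t in enumerate(d.periods):
        out[:, :, t_ix] = counts.replicates(t).max(axis=2)
    return out


# ---------------------------------------------------------------------------
# univariate Poisson GLM engine (vectorized Newton/IRLS)


@dataclass
class UnivariateFit:
    """MLE of the univariate Poisson log-link model y ~ exp(zeta + eta*E)."""

    zeta: float
    eta: float
    converged: bool = True
    zero_response: bool = False


_LIN_CLIP = 30.0


def _irls(y, x, w, max_iter=80, tol=1e-10):
    """Weighted 2-parameter Poisson IRLS, vectorized over leading axes.

    ``y``, ``x``, ``w`` broadcast with observations on the last axis. Returns
    (zeta, eta, converged, zero_response) with the leading shape. All-zero
    weighted responses are flagged and guarded (zeta = -inf, eta = 0) rather
    than iterated to divergence.
    """
    y, x, w = np.broadcast_arrays(*(np.asarray(a, dtype=float) for a in (y, x, w)))
    wsum = w.sum(-1)
    ysum = (w * y).sum(-1)
    zero = ysum <= 0
    zeta = np.where(zero, -np.inf, np.log(np.clip(ysum, 1e-300, None) / np.clip(wsum, 1e-300, None)))
    eta = np.zeros(zeta.shape)
    active = ~zero
    conv = zero.copy()  # degenerate fits count as resolved
    z_a = np.where(zero, 0.0, zeta)  # keep arithmetic finite for inactive cells
    for _ in range(max_iter):
        if not active.any():
            break
        lin = np.clip(z_a[..., None] + eta[..., None] * x, -_LIN_CLIP, _LIN_CLIP)
        mu = np.exp(lin)
        r = w * (y - mu)
        g0 = r.sum(-1)
        g1 = (r * x).sum(-1)
        wm = w * mu
        h00 = wm.sum(-1)
        h01 = (wm * x).sum(-1)
        h11 = (wm * x * x).sum(-1)
        det = h00 * h11 - h01 * h01
        ok = det > 1e-300
        det = np.where(ok, det, 1.0)
        d0 = np.clip((h11 * g0 - h01 * g1) / det, -5, 5)
        d1 = np.clip((h00 * g1 - h01 * g0) / det, -5, 5)
        step = np.where(active & ok, 1.0, 0.0)
        z_a = z_a + step * d0
        eta = eta + step * d1
        done = (np.abs(d0) < tol) & (np.abs(d1) < tol) & ok
        conv = conv | (active & done)
        active = active & ~done & ok
    finite = np.isfinite(z_a) & np.isfinite(eta)
    conv = conv & (finite | zero)
    zeta = np.where(zero, -np.inf, z_a)
    eta = np.where(zero, 0.0, eta)
    return zeta, eta, conv, zero


def fit_univariate(response, covariate) -> UnivariateFit:
    """Fit one univariate Poisson GLM by maximum likelihood.

    Requires at least two distinct covariate values (otherwise the slope is
    confounded with the intercept). An all-zero response is flagged
    ``zero_response`` with guarded coefficients rather than raising.
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise DesignError("response and covariate must be 1-d and aligned")
    if len(np.unique(x)) < 2:
        raise DesignError("need >= 2 distinct covariate values")
    zeta, eta, conv, zero = _irls(y, x, np.ones_like(y))
    return UnivariateFit(float(zeta), float(eta), bool(conv), bool(zero))


def _loo_engine(y, x):
    """Leave-one-out predictions for one period, vectorized over radii.

    ``y``: (n,) responses; ``x``: (C, n) covariates (one row per radius).
    Returns (C, n) predictions; folds whose refit fails are NaN.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    C, n = x.shape
    w = np.ones((n, n)) - np.eye(n)  # (fold, obs)
    Y = np.broadcast_to(y, (C, n, n))
    X = np.broadcast_to(x[:, None, :], (C, n, n))
    W = np.broadcast_to(w, (C, n, n))
    zeta, eta, conv, zero = _irls(Y, X, W)  # (C, n)
    x_held = x  # covariate of the held-out observation, (C, n)
    lin = np.clip(zeta + eta * x_held, -_LIN_CLIP, _LIN_CLIP)
    with np.errstate(invalid="ignore"):
        pred = np.exp(lin)
    pred = np.where(zero, 0.0, pred)
    pred = np.where(conv, pred, np.nan)
    return pred


def loo_predictions(response_by_period, covariate_by_period):
    """Leave-one-out predictions for one (species, type, radius).

    Parameters
    ----------
    response_by_period, covariate_by_period
        Sequences (one entry per period, in period order) of aligned 1-d
        arrays. Each period's model is refit with one observation held out
        at a time (the equations carry period-specific intercepts and
        slopes), and the held-out value is predicted.

    Returns
    -------
    (observed, predicted): both periods concatenated in period order then
    observation order. Failed refits yield NaN predictions, which downstream
    correlations exclude pairwise.
    """
    obs, pred = [], []
    for y, x in zip(response_by_period, covariate_by_period):
        y = np.asarray(y, dtype=float)
        if len(y) < 3:
            raise DesignError("need >= 3 observations per period for LOO")
        p = _loo_engine(y, np.asarray(x, dtype=float)[None, :])[0]
        obs.append(y)
        pred.append(p)
    return np.concatenate(obs), np.concatenate(pred)


# ---------------------------------------------------------------------------
# correlation-based selection


def _pairwise_corr(obs, pred, method):
    """Correlation with pairwise NaN exclusion; undefined -> -inf."""
    ok = np.isfinite(pred) & np.isfinite(obs)
    if ok.sum() < 3:
        return -np.inf
    o, p = obs[ok], pred[ok]
    if np.std(o) == 0 or np.std(p) == 0:
        return -np.inf
    if method == "pearson":
        return float(np.corrcoef(o, p)[0, 1])
    r = stats.spearmanr(o, p).statistic
    return float(r) if np.isfinite(r) else -np.inf


def select_scale_correlation(
    counts: CountData,
    stack: LandCoverStack,
    grid: ScaleGrid | None = None,
    method: str = "pearson",
) -> OptimalScaleMap:
    """Select the optimal scale per (species, type) by LOO prediction skill.

    For every (species, type, radius) a period-specific univariate Poisson
    GLM is fit; leave-one-out predictions from both periods are pooled and
    correlated with the observed responses; the radius maximizing the
    correlation is selected (ties break to the smallest radius — the most
    local scale). Radii with undefined correlations (zero variance, or too
    few valid folds) never win.
    """
    if method not in ("pearson", "spearman"):
        raise DesignError(f"method must be 'pearson' or 'spearman', got {method!r}")
    grid = grid or stack.grid
    design = counts.design
    resp = collapse_period2_max(counts)  # (S, J, T)
    S, J, T = resp.shape
    M, C = design.n_landcover, grid.n_radii
    radius = np.zeros((S, M))
    score = np.full((S, M), -np.inf)
    n_models = 0
    for m in range(M):
        # per-period LOO predictions for all radii at once
        preds = []  # list over periods of (C, J)
        for t in range(T):
            x = stack.proportions[:, m, :, t].T  # (C, J)
            preds.append(x)
        for i in range(S):
            obs = np.concatenate([resp[i, :, t] for t in range(T)]).astype(float)
            pr = np.concatenate(
                [_loo_engine(resp[i, :, t].astype(float), preds[t]) for t in range(T)],
                axis=1,
            )  # (C, 2J)
            scores_c = np.array(
                [_pairwise_corr(obs, pr[c], method) for c in range(C)]
            )
            n_models += C
            best = int(np.argmax(scores_c))  # argmax takes the first (smallest radius) on ties
            radius[i, m] = grid.radii[best]
            score[i, m] = scores_c[best]
    species = list(counts.species)
    types = list(stack.types)
    return OptimalScaleMap(
        radius, species, types, method, score=score, grid=grid,
        n_models_enumerated=n_models,
    )


# ---------------------------------------------------------------------------
# boosted regression trees


@dataclass(frozen=True)
class BRTSettings:
    """Gradient-boosted tree settings (defaults follow the tuned values:
    20,000 depth-1 trees, shrinkage 1e-4, minimum node size 25, bag fraction
    0.5). ``n_trees`` is the main cost knob and is reduced for desk-scale
    runs."""

    n_trees: int = 20_000
    shrinkage: float = 1e-4
    min_node_obs: int = 25
    bag_fraction: float = 0.5
    interaction_depth: int = 1


def _brt_influence(y, X, settings: BRTSettings, seed: int) -> np.ndarray:
    """Relative influence (normalized total split gain) per predictor column."""
    import xgboost as xgb

    dtrain = xgb.DMatrix(X, label=y)
    params = {
        "objective": "count:poisson",
        "eta": settings.shrinkage,
        "max_depth": settings.interaction_depth,
        "subsample": settings.bag_fraction,
        "min_child_weight": settings.min_node_obs,
        "nthread": 1,
        "seed": int(seed) % (2**31),
        "tree_method": "hist",
        "verbosity": 0,
    }
    booster = xgb.train(params, dtrain, num_boost_round=settings.n_trees)
    gain = booster.get_score(importance_type="total_gain")
    infl = np.zeros(X.shape[1])
    for key, g in gain.items():
        infl[int(key[1:])] = g
    total = infl.sum()
    return infl / total if total > 0 else infl


def select_scale_brt(
    counts: CountData,
    stack: LandCoverStack,
    grid: ScaleGrid | None = None,
    settings: BRTSettings | None = None,
    seed: int = 0,
    min_nonzero: int = 5,
    fallback_map: dict[str, str] | None = None,
) -> OptimalScaleMap:
    """Select optimal scales by boosted-regression-tree relative influence.

    One ensemble per species over all M x C scale-specific proportions
    (responses: period-1 counts and period-2 replicate maxima, stacked);
    per land-cover type, the radius with the highest relative influence
    wins (ties and all-zero influence break to the smallest radius).

    Species with fewer than ``min_nonzero`` nonzero observations cannot
    support an ensemble; they inherit the map of the species with the most
    similar count profile (highest Spearman correlation of pooled site
    responses), unless ``fallback_map`` (sparse species -> donor species)
    says otherwise.
    """
    settings = settings or BRTSettings()
    grid = grid or stack.grid
    design = counts.design
    resp = collapse_period2_max(counts)  # (S, J, T)
    S, J, T = resp.shape
    M, C = design.n_landcover, grid.n_radii
    rng = split_seed(seed, "brt")

    # predictor matrix: for an observation in period t, all M*C proportions of
    # that period; rows = sites x periods stacked in period order
    X = np.concatenate(
        [stack.proportions[:, :, :, t].reshape(J, M * C) for t in range(T)], axis=0
    )
    Y = np.concatenate([resp[:, :, t] for t in range(T)], axis=1)  # (S, 2J)

    radius = np.zeros((S, M))
    score = np.zeros((S, M))
    eligible = (Y > 0).sum(axis=1) >= min_nonzero
    for i in range(S):
        if not eligible[i]:
            continue
        infl = _brt_influence(Y[i].astype(float), X, settings, rng.integers(2**31))
        infl_mc = infl.reshape(M, C)
        best = np.argmax(infl_mc, axis=1)  # first max -> smallest radius on ties
        radius[i] = grid.radii[best]
        score[i] = infl_mc[np.arange(M), best]

    # fallback for sparse species
    species = list(counts.species)
    if (~eligible).any():
        if not eligible.any():
            raise DesignError(
                "no species has enough nonzero observations to fit an ensemble"
            )
        donors = np.flatnonzero(eligible)
        for i in np.flatnonzero(~eligible):
            if fallback_map and species[i] in fallback_map:
                d = species.index(fallback_map[species[i]])
                if not eligible[d]:
                    raise DesignError(
                        f"fallback donor {species[d]!r} is itself too sparse"
                    )
            else:
                with warnings.catch_warnings():
                    # an all-zero profile has no defined rank correlation;
                    # such donors simply never win
                    warnings.simplefilter("ignore", stats.ConstantInputWarning)
                    sims = [
                        stats.spearmanr(Y[i], Y[d]).statistic for d in donors
                    ]
                sims = [s if np.isfinite(s) else -np.inf for s in sims]
                d = donors[int(np.argmax(sims))]
            radius[i] = radius[d]
            score[i] = np.nan
    return OptimalScaleMap(
        radius, species, list(stack.types), "brt", score=score, grid=grid,
        n_models_enumerated=None,
    )
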