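"""Space-for-time counterfactual, percent change and trend classification.

The counterfactual asks what period-2 abundance *would* have been had it
changed only through land cover: per posterior draw, the species drift phi is
set to zero and period-2 expected abundance is rebuilt from the drawn habitat
effects and the period-2 land cover. If space-for-time substitution is valid,
these land-cover-only abundances should match the full model's period-2
abundances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import split_seed
from .containers import LandCoverStack, OptimalScaleMap
from .design import DesignError
from .nmix import ModelPosterior, PosteriorCommunity, cri_bounds, posterior_true_abundance

__all__ = [
    "CATEGORIES",
    "TrendSummary",
    "expected_N_phi0",
    "percent_change",
    "summarize_change",
    "classify_species",
    "compute_trends",
    "sft_validity_report",
]

ZERO_REPLACEMENT = 1e-10

CATEGORIES = (
    "opposite_significant",
    "one_sided_mismatch",
    "both_nonsignificant",
    "same_direction_significant",
    "same_direction_overlapping",
)


def expected_N_phi0(
    posterior: ModelPosterior,
    stack: LandCoverStack,
    scale_map: OptimalScaleMap | None = None,
    seed: int = 0,
    poisson_draws: bool = True,
) -> np.ndarray:
    """Counterfactual period-2 species totals with phi = 0, per draw. (D, S)

    Per draw: sum over sites of Poisson(exp(alpha_i + sum_m beta_im
    E_ijm,t=2)) — a fresh Poisson realization per (species, site, draw), so
    counterfactual totals carry the same stochastic width as the full model's
    posterior communities. For the fixed50 variant the alpha term and the
    species dependence of E drop out. Set ``poisson_draws`` False for the
    expectation-only variant (lambda summed without Poisson noise).
    """
    beta = posterior.flat("beta")  # (D, S, M)
    alpha = posterior.flat("alpha")  # (D, S)
    D, S, M = beta.shape
    if posterior.variant == "multiscale":
        if scale_map is None:
            raise DesignError("multiscale counterfactual requires the scale map")
        E2 = stack.at_scale_map(scale_map)[:, :, :, 1]  # (S, J, M)
        lin = np.einsum("dsm,sjm->dsj", beta, E2) + alpha[:, :, None]
    else:
        if scale_map is not None:
            raise DesignError("fixed50 counterfactual does not take a scale map")
        E2 = stack.at_radius(stack.grid.min_radius)[:, :, 1]  # (J, M)
        lin = np.einsum("dsm,jm->dsj", beta, E2)
    lam = np.exp(np.clip(lin, -30, 30))
    if not poisson_draws:
        return lam.sum(axis=2)
    rng = split_seed(seed, "counterfactual")
    return rng.poisson(lam).sum(axis=2).astype(float)


def percent_change(period1_totals, period2_totals) -> np.ndarray:
    """Per-draw percent change 100 * (N2 - N1) / N1, zeros in N1 replaced by 1e-10."""
    n1 = np.asarray(period1_totals, dtype=float)
    n2 = np.asarray(period2_totals, dtype=float)
    if n1.shape != n2.shape:
        raise DesignError("draw vectors must be aligned")
    n1 = np.where(n1 == 0, ZERO_REPLACEMENT, n1)
    return 100.0 * (n2 - n1) / n1


def summarize_change(changes, cri_level: float = 0.89) -> dict:
    """Median and equal-tailed CrI of a per-draw percent-change vector."""
    lo_q, hi_q = cri_bounds(cri_level)
    c = np.asarray(changes, dtype=float)
    return {
        "median": float(np.median(c)),
        "lo": float(np.quantile(c, lo_q)),
        "hi": float(np.quantile(c, hi_q)),
    }


def _significant(s) -> bool:
    return s["lo"] > 0 or s["hi"] < 0


def classify_species(true_change: dict, counterfactual_change: dict) -> str:
    """Five-way validity category from two trend summaries (median, lo, hi).

    significance = CrI excludes zero; categories: both significant with
    opposite signs; exactly one significant; neither significant; both
    significant same direction with disjoint CrIs; both significant same
    direction with overlapping CrIs.
    """
    t_sig, c_sig = _significant(true_change), _significant(counterfactual_change)
    if t_sig and c_sig:
        same = np.sign(true_change["median"]) == np.sign(counterfactual_change["median"])
        if not same:
            return "opposite_significant"
        overlap = (
            true_change["lo"] <= counterfactual_change["hi"]
            and counterfactual_change["lo"] <= true_change["hi"]
        )
        return "same_direction_overlapping" if overlap else "same_direction_significant"
    if t_sig != c_sig:
        return "one_sided_mismatch"
    return "both_nonsignificant"


@dataclass
class TrendSummary:
    """Per-species true and counterfactual percent-change summaries.

    ``table`` columns: species, true_median/lo/hi, cf_median/lo/hi, category.
    ``community`` holds the community-total change summaries.
    """

    table: pd.DataFrame
    community: dict
    cri_level: float

    def category_shares(self) -> pd.Series:
        counts = self.table["category"].value_counts()
        shares = counts.reindex(CATEGORIES, fill_value=0) / len(self.table) * 100.0
        return shares


def compute_trends(
    posterior: ModelPosterior,
    stack: LandCoverStack,
    scale_map: OptimalScaleMap | None = None,
    cri_level: float = 0.89,
    seed: int = 0,
    poisson_draws: bool = True,
    community: PosteriorCommunity | None = None,
) -> TrendSummary:
    """True vs counterfactual percent change per species, with categories.

    True change uses the full model's posterior communities (periods 1 and
    2); counterfactual change uses the same period-1 draws against the
    land-cover-only period-2 totals. Percent change is computed per draw and
    then summarized, propagating posterior uncertainty.
    """
    community = community or posterior_true_abundance(posterior)
    n1 = community.species_totals[:, :, 0].astype(float)  # (D, S)
    n2 = community.species_totals[:, :, 1].astype(float)
    cf2 = expected_N_phi0(posterior, stack, scale_map, seed=seed,
                          poisson_draws=poisson_draws)
    rows = []
    for i, sp in enumerate(community.species):
        s_true = summarize_change(percent_change(n1[:, i], n2[:, i]), cri_level)
        s_cf = summarize_change(percent_change(n1[:, i], cf2[:, i]), cri_level)
        rows.append(
            {
                "species": sp,
                "true_median": s_true["median"],
                "true_lo": s_true["lo"],
                "true_hi": s_true["hi"],
                "cf_median": s_cf["median"],
                "cf_lo": s_cf["lo"],
                "cf_hi": s_cf["hi"],
                "category": classify_species(
                    {"median": s_true["median"], "lo": s_true["lo"], "hi": s_true["hi"]},
                    {"median": s_cf["median"], "lo": s_cf["lo"], "hi": s_cf["hi"]},
                ),
            }
        )
    comm1 = community.community_totals[:, 0].astype(float)
    comm2 = community.community_totals[:, 1].astype(float)
    comm = {
        "true": summarize_change(percent_change(comm1, comm2), cri_level),
        "counterfactual": summarize_change(
            percent_change(comm1, cf2.sum(axis=1)), cri_level
        ),
    }
    return TrendSummary(pd.DataFrame(rows), comm, cri_level)


def sft_validity_report(
    trends: TrendSummary, external_trends: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-species validity table plus category shares.

    ``external_trends`` (optional): columns species, external_change — a
    pass-through reference column (e.g. a national trend series); no
    modelling of the external series is attempted.
    """
    table = trends.table.copy()
    if external_trends is not None:
        table = table.merge(
            external_trends[["species", "external_change"]], on="species", how="left"
        )
    shares = trends.category_shares()
    share_rows = pd.DataFrame(
        {
            "species": [f"__share__{c}" for c in shares.index],
            "category": shares.index,
            "true_median": shares.to_numpy(),
        }
    )
    return pd.concat([table, share_rows], ignore_index=True)
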