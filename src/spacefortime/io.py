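"""Readers and writers for the canonical tidy text schemas.

Counts: columns ``species, site, period, replicate, count``.
Land cover: columns ``site, type, radius, period, proportion``.
Optimal scales: columns ``species, type, radius, score, method``.

All files are delimited text (comma by default). Datasets that omit rows for
species never seen at a site are handled by the ``absence_implies_zero``
reader flag (default on): raw survey archives often drop zero rows.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    CountData,
    DataValidationError,
    LandCoverStack,
    OptimalScaleMap,
)
from .design import ScaleGrid, SurveyDesign

__all__ = [
    "read_counts",
    "write_counts",
    "read_landcover",
    "write_landcover",
    "read_scale_map",
    "write_scale_map",
]

COUNT_COLUMNS = ["species", "site", "period", "replicate", "count"]
LANDCOVER_COLUMNS = ["site", "type", "radius", "period", "proportion"]


def _check_columns(df: pd.DataFrame, required, path):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing columns {missing}")


def _label_index(values, known: Sequence[str] | None, what: str, path):
    """Map labels to dense indices; unknown labels are a labelled parse error."""
    uniq = pd.unique(values)
    if known is None:
        known = sorted(map(str, uniq))
    lookup = {str(k): i for i, k in enumerate(known)}
    unknown = [u for u in map(str, uniq) if u not in lookup]
    if unknown:
        raise DataValidationError(f"{path}: unknown {what} labels {unknown[:5]}")
    return list(known), np.array([lookup[str(v)] for v in values])


def read_counts(
    path,
    design: SurveyDesign,
    species: Sequence[str] | None = None,
    sites: Sequence[str] | None = None,
    absence_implies_zero: bool = True,
    sep: str = ",",
) -> CountData:
    """Read a tidy count table into dense :class:`CountData`.

    Missing (species, site, period, replicate) combinations are filled with
    zero only when ``absence_implies_zero`` is set; otherwise they raise.
    """
    df = pd.read_csv(path, sep=sep)
    _check_columns(df, COUNT_COLUMNS, path)
    if (df["count"] < 0).any():
        bad = df.loc[df["count"] < 0].iloc[0]
        raise DataValidationError(
            f"{path}: negative count {bad['count']} for species "
            f"{bad['species']!r} at site {bad['site']!r}"
        )
    species, s_ix = _label_index(df["species"], species, "species", path)
    sites, j_ix = _label_index(df["site"], sites, "site", path)
    if len(species) != design.n_species or len(sites) != design.n_sites:
        raise DataValidationError(
            f"{path}: found {len(species)} species / {len(sites)} sites, "
            f"design expects {design.n_species} / {design.n_sites}"
        )
    periods = list(design.periods)
    if not set(df["period"]).issubset(periods):
        raise DataValidationError(
            f"{path}: unknown period labels {sorted(set(df['period']) - set(periods))}"
        )
    t_ix = df["period"].map({t: i for i, t in enumerate(periods)}).to_numpy()
    k = df["replicate"].to_numpy()
    k_max = np.array([design.n_replicates(t) for t in df["period"]])
    if ((k < 1) | (k > k_max)).any():
        bad = df.loc[(k < 1) | (k > k_max)].iloc[0]
        raise DataValidationError(
            f"{path}: replicate {bad['replicate']} is outside the design for "
            f"period {bad['period']} (allows "
            f"{design.n_replicates(bad['period'])} replicate(s))"
        )

    shape = (design.n_species, design.n_sites, design.n_periods, design.max_replicates)
    counts = np.zeros(shape, dtype=np.int64)
    seen = np.zeros(shape, dtype=bool)
    flat = (s_ix, j_ix, t_ix, k - 1)
    if pd.DataFrame({"s": s_ix, "j": j_ix, "t": t_ix, "k": k}).duplicated().any():
        raise DataValidationError(f"{path}: duplicate (species, site, period, replicate) rows")
    counts[flat] = df["count"].to_numpy()
    seen[flat] = True
    if not absence_implies_zero:
        valid = np.zeros(shape, dtype=bool)
        for t_i, t in enumerate(periods):
            valid[:, :, t_i, : design.n_replicates(t)] = True
        if (valid & ~seen).any():
            n = int((valid & ~seen).sum())
            raise DataValidationError(
                f"{path}: {n} (species, site, period, replicate) cells missing "
                "and absence_implies_zero is off"
            )
    return CountData(counts, species, sites, design)


def write_counts(data: CountData, path, sep: str = ","):
    data.to_frame().to_csv(path, sep=sep, index=False)


def read_landcover(
    path,
    grid: ScaleGrid,
    sites: Sequence[str] | None = None,
    types: Sequence[str] | None = None,
    periods: tuple = (1, 2),
    sep: str = ",",
) -> LandCoverStack:
    """Read a tidy land-cover table into a dense :class:`LandCoverStack`.

    Every (site, radius, period) composition must be complete and sum to one;
    radii must lie on ``grid``.
    """
    df = pd.read_csv(path, sep=sep)
    _check_columns(df, LANDCOVER_COLUMNS, path)
    sites, j_ix = _label_index(df["site"], sites, "site", path)
    types, m_ix = _label_index(df["type"], types, "type", path)
    radii = grid.radii
    r_lookup = {float(r): i for i, r in enumerate(radii)}
    try:
        c_ix = np.array([r_lookup[float(r)] for r in df["radius"]])
    except KeyError as e:
        raise DataValidationError(
            f"{path}: radius {e.args[0]} is not on the grid "
            f"({grid.min_radius:g}..{grid.max_radius:g} step {grid.step:g})"
        ) from None
    if not set(df["period"]).issubset(periods):
        raise DataValidationError(f"{path}: unknown period labels")
    t_ix = df["period"].map({t: i for i, t in enumerate(periods)}).to_numpy()

    shape = (len(sites), len(types), len(radii), len(periods))
    props = np.full(shape, np.nan)
    props[j_ix, m_ix, c_ix, t_ix] = df["proportion"].to_numpy()
    if np.isnan(props).any():
        raise DataValidationError(
            f"{path}: incomplete compositions — some (site, type, radius, "
            "period) cells are missing"
        )
    return LandCoverStack(props, sites, types, grid, periods)


def write_landcover(stack: LandCoverStack, path, sep: str = ","):
    stack.to_frame().to_csv(path, sep=sep, index=False)


def read_scale_map(path, species=None, types=None, grid=None, sep=",") -> OptimalScaleMap:
    df = pd.read_csv(path, sep=sep)
    _check_columns(df, ["species", "type", "radius"], path)
    species, s_ix = _label_index(df["species"], species, "species", path)
    types, m_ix = _label_index(df["type"], types, "type", path)
    S, M = len(species), len(types)
    radius = np.full((S, M), np.nan)
    score = np.full((S, M), np.nan)
    radius[s_ix, m_ix] = df["radius"].to_numpy()
    if "score" in df.columns:
        score[s_ix, m_ix] = df["score"].to_numpy()
    if np.isnan(radius).any():
        raise DataValidationError(f"{path}: scale map is missing (species, type) entries")
    method = str(df["method"].iloc[0]) if "method" in df.columns else "unknown"
    return OptimalScaleMap(radius, species, types, method, score=score, grid=grid)


def write_scale_map(scale_map: OptimalScaleMap, path, sep: str = ","):
    scale_map.to_frame().to_csv(path, sep=sep, index=False)
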