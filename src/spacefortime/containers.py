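"""Dense in-memory containers for counts, land cover and optimal scales.

Identifiers for species, sites and land-cover types are opaque strings;
containers hold dense numpy arrays plus the label lists that map axis
positions back to identifiers. Tidy (long) pandas frames are the exchange
format — see :mod:`spacefortime.io` for the on-disk schemas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .design import ScaleGrid, SurveyDesign

__all__ = [
    "CountData",
    "LandCoverStack",
    "OptimalScaleMap",
    "DataValidationError",
    "CompositionError",
]

COMPOSITION_TOL = 1e-6


class DataValidationError(ValueError):
    """An input table violates a container invariant."""


class CompositionError(DataValidationError):
    """Land-cover proportions fail to sum to one for some (site, radius, period)."""


@dataclass
class CountData:
    """Observed counts y indexed by (species i, site j, period t, replicate k).

    ``counts`` has shape (S, J, T, Kmax); replicate slots beyond the design's
    replicate count for a period are structural zeros and must never be read
    directly — use :meth:`replicates`.
    """

    counts: np.ndarray
    species: Sequence[str]
    sites: Sequence[str]
    design: SurveyDesign

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        d = self.design
        expect = (d.n_species, d.n_sites, d.n_periods, d.max_replicates)
        if self.counts.shape != expect:
            raise DataValidationError(
                f"counts shape {self.counts.shape} != design shape {expect}"
            )
        if len(self.species) != d.n_species or len(self.sites) != d.n_sites:
            raise DataValidationError("label lists do not match design sizes")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise DataValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise DataValidationError("counts must be non-negative")

    def replicates(self, period) -> np.ndarray:
        """Counts for one period, shape (S, J, K_t) with only valid replicates."""
        t = self.design.periods.index(period)
        k = self.design.n_replicates(period)
        return self.counts[:, :, t, :k]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t_ix, t in enumerate(self.design.periods):
            for k in range(self.design.n_replicates(t)):
                block = self.counts[:, :, t_ix, k]
                s_ix, j_ix = np.nonzero(np.ones_like(block))
                rows.append(
                    pd.DataFrame(
                        {
                            "species": np.asarray(self.species)[s_ix],
                            "site": np.asarray(self.sites)[j_ix],
                            "period": t,
                            "replicate": k + 1,
                            "count": block[s_ix, j_ix],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    @property
    def max_count(self) -> int:
        m = 0
        for t in self.design.periods:
            m = max(m, int(self.replicates(t).max(initial=0)))
        return m


@dataclass
class LandCoverStack:
    """Compositional land-cover proportions E indexed by (site, type, radius, period).

    ``proportions`` has shape (J, M, C, T). For every (site, radius, period)
    the proportions over types sum to one within ``COMPOSITION_TOL``.
    """

    proportions: np.ndarray
    sites: Sequence[str]
    types: Sequence[str]
    grid: ScaleGrid
    periods: tuple = (1, 2)

    def __post_init__(self):
        self.proportions = np.asarray(self.proportions, dtype=float)
        J, M, C, T = (
            len(self.sites),
            len(self.types),
            self.grid.n_radii,
            len(self.periods),
        )
        if self.proportions.shape != (J, M, C, T):
            raise DataValidationError(
                f"proportions shape {self.proportions.shape} != {(J, M, C, T)}"
            )
        self.validate()

    def validate(self, tol: float = COMPOSITION_TOL):
        p = self.proportions
        if (p < -tol).any() or (p > 1 + tol).any():
            raise CompositionError("proportions must lie in [0, 1]")
        sums = p.sum(axis=1)  # (J, C, T)
        bad = np.abs(sums - 1.0) > tol
        if bad.any():
            j, c, t = map(int, np.argwhere(bad)[0])
            raise CompositionError(
                f"proportions sum to {sums[j, c, t]:.6f} != 1 for site "
                f"{self.sites[j]!r}, radius {self.grid.radii[c]:g}, "
                f"period {self.periods[t]}"
            )

    def at_radius(self, radius) -> np.ndarray:
        """Slice E at a single radius: shape (J, M, T)."""
        return self.proportions[:, :, self.grid.index_of(radius), :]

    def at_scale_map(self, scale_map: "OptimalScaleMap") -> np.ndarray:
        """Species-specific covariates E_ijmt: shape (S, J, M, T).

        Each (species, type) cell is taken at that pair's selected radius.
        """
        c_ix = np.array(
            [
                [self.grid.index_of(r) for r in row]
                for row in np.asarray(scale_map.radius)
            ]
        )  # (S, M)
        # advanced indexing over the radius axis
        S, M = c_ix.shape
        out = np.empty((S, len(self.sites), M, len(self.periods)))
        for m in range(M):
            out[:, :, m, :] = self.proportions[:, m, c_ix[:, m], :].transpose(1, 0, 2)
        return out

    def to_frame(self) -> pd.DataFrame:
        J, M, C, T = self.proportions.shape
        j, m, c, t = np.unravel_index(np.arange(J * M * C * T), (J, M, C, T))
        return pd.DataFrame(
            {
                "site": np.asarray(self.sites)[j],
                "type": np.asarray(self.types)[m],
                "radius": self.grid.radii[c],
                "period": np.asarray(self.periods)[t],
                "proportion": self.proportions[j, m, c, t],
            }
        )


@dataclass
class OptimalScaleMap:
    """Selected scale of effect per (species, land-cover type).

    ``radius``: (S, M) array of radii, each on the generating grid.
    ``score``: (S, M) array — the correlation or relative influence achieved.
    """

    radius: np.ndarray
    species: Sequence[str]
    types: Sequence[str]
    method: str
    score: np.ndarray | None = None
    grid: ScaleGrid | None = None
    n_models_enumerated: int | None = None

    def __post_init__(self):
        self.radius = np.asarray(self.radius, dtype=float)
        S, M = len(self.species), len(self.types)
        if self.radius.shape != (S, M):
            raise DataValidationError(
                f"radius shape {self.radius.shape} != {(S, M)}"
            )
        if self.score is not None:
            self.score = np.asarray(self.score, dtype=float)
            if self.score.shape != (S, M):
                raise DataValidationError("score shape mismatch")
        if self.grid is not None:
            for r in self.radius.ravel():
                self.grid.index_of(r)

    @property
    def n_entries(self) -> int:
        return self.radius.size

    def to_frame(self) -> pd.DataFrame:
        S, M = self.radius.shape
        s, m = np.unravel_index(np.arange(S * M), (S, M))
        return pd.DataFrame(
            {
                "species": np.asarray(self.species)[s],
                "type": np.asarray(self.types)[m],
                "radius": self.radius[s, m],
                "score": (self.score[s, m] if self.score is not None else np.nan),
                "method": self.method,
            }
        )
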