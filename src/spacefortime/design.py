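"""Survey design and spatial-scale grid.

The study design this package targets is a two-period replicated point-count
survey: every site is visited once in period 1 and with back-to-back
within-period replicates in period 2 (the replicates are what make detection
probability estimable). Land cover around each point is summarised as
compositional proportions at a ladder of buffer radii.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = ["SurveyDesign", "ScaleGrid", "build_scale_grid", "DesignError"]


class DesignError(ValueError):
    """Raised when a survey design or scale grid is internally inconsistent."""


@dataclass(frozen=True)
class SurveyDesign:
    """Dimensions and replication structure of a two-period count survey.

    Parameters
    ----------
    n_sites
        Number of sampling locations (J).
    n_species
        Number of species retained for analysis (S).
    n_landcover
        Number of land-cover types in the composition (M).
    periods
        Ordered period labels; the default ``(1, 2)`` denotes the historical
        and the resurvey period.
    replicates_per_period
        Within-period temporal replicates per period. The default
        ``{1: 1, 2: 2}`` matches a design where only the resurvey has
        back-to-back replicate counts.
    """

    n_sites: int
    n_species: int
    n_landcover: int
    periods: tuple = (1, 2)
    replicates_per_period: Mapping[int, int] = field(
        default_factory=lambda: {1: 1, 2: 2}
    )

    def __post_init__(self):
        for name in ("n_sites", "n_species", "n_landcover"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise DesignError(f"{name} must be a positive integer, got {v!r}")
        if len(self.periods) < 1:
            raise DesignError("at least one period is required")
        for t in self.periods:
            k = self.replicates_per_period.get(t)
            if k is None or k < 1:
                raise DesignError(
                    f"replicates_per_period must map period {t} to a positive "
                    f"integer, got {k!r}"
                )

    @property
    def n_periods(self) -> int:
        return len(self.periods)

    @property
    def max_replicates(self) -> int:
        return max(self.replicates_per_period[t] for t in self.periods)

    def n_replicates(self, period) -> int:
        """Replicate count for one period label."""
        try:
            return self.replicates_per_period[period]
        except KeyError:
            raise DesignError(f"unknown period {period!r}") from None


@dataclass(frozen=True)
class ScaleGrid:
    """Ladder of buffer radii (metres) at which land cover is measured.

    Radii run from ``min_radius`` to ``max_radius`` inclusive in steps of
    ``step``; the default study grid (50, 1500, 50) yields 30 radii.
    """

    min_radius: float
    max_radius: float
    step: float

    def __post_init__(self):
        if self.step <= 0:
            raise DesignError(f"step must be positive, got {self.step}")
        if self.min_radius <= 0:
            raise DesignError("min_radius must be positive")
        if self.min_radius > self.max_radius:
            raise DesignError("min_radius must not exceed max_radius")
        span = self.max_radius - self.min_radius
        n, rem = divmod(round(span, 9), self.step)
        if abs(rem) > 1e-9 and abs(rem - self.step) > 1e-9:
            raise DesignError(
                f"(max_radius - min_radius) = {span} is not divisible by "
                f"step = {self.step}"
            )

    @property
    def radii(self) -> np.ndarray:
        """Strictly increasing array of radii, ``min`` to ``max`` inclusive."""
        n = int(round((self.max_radius - self.min_radius) / self.step)) + 1
        return self.min_radius + self.step * np.arange(n)

    @property
    def n_radii(self) -> int:
        return len(self.radii)

    def index_of(self, radius) -> int:
        """Position of ``radius`` in the grid; raises for off-grid values."""
        r = np.asarray(self.radii)
        hits = np.nonzero(np.isclose(r, radius))[0]
        if len(hits) == 0:
            raise DesignError(f"radius {radius} is not on the grid {self}")
        return int(hits[0])


def build_scale_grid(min_radius, max_radius, step) -> ScaleGrid:
    """Construct a :class:`ScaleGrid`, validating divisibility of the range."""
    return ScaleGrid(float(min_radius), float(max_radius), float(step))
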