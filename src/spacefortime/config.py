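"""Pipeline configuration: one structured YAML document, CLI flags override.

Every run resolves to a single :class:`PipelineConfig`; the resolved values
and master seed are logged so any stage can be replayed.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from .design import DesignError

log = logging.getLogger("spacefortime")

SCALE_METHODS = ("brt", "pearson", "spearman", "fixed50")


@dataclass
class PipelineConfig:
    """Resolved settings for a pipeline run.

    ``cri_level`` is the equal-tailed credible-interval mass (default 0.89,
    i.e. quantiles 0.055 and 0.945). ``nmax_extra`` sets the latent-abundance
    truncation as max observed count plus this margin.
    """

    scale_method: str = "pearson"
    chains: int = 4
    warmup: int = 1500
    samples: int = 500
    nmax_extra: int = 50
    seed: int = 0
    cri_level: float = 0.89
    tie_break: str = "smallest"
    counts_path: str | None = None
    landcover_path: str | None = None
    scales_path: str | None = None
    out_dir: str = "out"

    def __post_init__(self):
        if not (0 < self.cri_level < 1):
            raise DesignError(f"cri_level must be in (0,1), got {self.cri_level}")
        if self.chains < 1:
            raise DesignError("chains must be >= 1")
        if self.scale_method not in SCALE_METHODS:
            raise DesignError(
                f"scale_method must be one of {SCALE_METHODS}, got {self.scale_method!r}"
            )
        if self.tie_break != "smallest":
            raise DesignError("only the 'smallest radius' tie-break is provided")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        """Load from a YAML document; keyword overrides win over file values."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise DesignError(f"unknown config keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def log_resolved(self):
        log.info("resolved config: %s", dataclasses.asdict(self))


def split_seed(master_seed: int, *path: str) -> np.random.Generator:
    """Derive an independent generator from the master seed and a stage path.

    All randomness in the pipeline flows from one master seed through
    ``numpy.random.SeedSequence`` spawned with a stable per-stage key, so any
    stage can be replayed in isolation.
    """
    key = [int(master_seed)] + [zlib.crc32(p.encode()) % (2**31) for p in path]
    return np.random.default_rng(np.random.SeedSequence(key))
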