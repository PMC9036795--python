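"""Run configuration.

All defaults mirror the analysis parameters of the study pipeline: the
1 kbp match filter and mapping-quality cutoff for whole-genome alignment
matches, the 10 kbp display filter for synteny plots, Mash-style sketch
parameters (k=21, s=1000), tree search jumbling (10 rounds, seed 23893),
and the Monte-Carlo settings of the flux confidence-interval analysis.
"""

from __future__ import annotations

import dataclasses
import tomllib
from pathlib import Path


@dataclasses.dataclass
class Config:
    min_match_len: int = 1000        # bases; "matches spanning >= 1 kbp"
    display_min_len: int = 10000     # bases; synteny-plot display filter
    min_mapq: int = 1                # "mapping quality > 0"
    kmer_size: int = 21
    sketch_size: int = 1000
    n_jumbles: int = 10
    jumble_seed: int = 23893
    mc_samples: int = 1000
    ci_level: float = 0.95
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for field in ("min_match_len", "display_min_len"):
            if getattr(self, field) < 0:
                raise ValueError(f"{field} must be nonnegative")
        for field in ("kmer_size", "sketch_size", "n_jumbles", "mc_samples"):
            if getattr(self, field) <= 0:
                raise ValueError(f"{field} must be positive")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")

    @classmethod
    def from_toml(cls, path: str | Path) -> "Config":
        """Load a flat TOML key/value file; unknown keys are rejected."""
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def replace(self, **kwargs) -> "Config":
        return dataclasses.replace(self, **kwargs)
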