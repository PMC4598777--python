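"""Relative-abundance profiles shared by all three analyte levels.

A :class:`QuantProfile` is the quantitation currency of the pipeline: per
species, the relative EIC peak area (%) against the total of all observed
species, as mean +/- SD over technical replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["QuantProfile"]


@dataclass
class QuantProfile:
    """Relative abundances (%) per species, mean +/- SD over replicates."""

    means: dict[str, float]
    sds: dict[str, float] = field(default_factory=dict)
    n_replicates: int = 1

    def __post_init__(self) -> None:
        observed = [v for v in self.means.values()]
        total = sum(observed)
        if observed and abs(total - 100.0) > 0.01:
            raise ValueError(f"profile entries must sum to 100%, got {total:.4f}")
        if any(sd < 0 for sd in self.sds.values()):
            raise ValueError("SDs must be non-negative")

    @classmethod
    def from_replicates(cls, replicates: Sequence[Mapping[str, float]]) -> "QuantProfile":
        """Aggregate per-replicate percentage dicts into mean +/- SD.

        Species absent from a replicate count as 0%. Means are renormalized
        to sum to exactly 100% (replicate-mean totals can drift by rounding).
        """
        if not replicates:
            raise ValueError("at least one replicate required")
        species = sorted({s for rep in replicates for s in rep})
        mat = np.array([[rep.get(s, 0.0) for s in species] for rep in replicates])
        means = mat.mean(axis=0)
        total = means.sum()
        if total > 0:
            means = means * (100.0 / total)
        sds = mat.std(axis=0, ddof=1) if len(replicates) > 1 else np.zeros(len(species))
        return cls(
            means=dict(zip(species, means.tolist())),
            sds=dict(zip(species, sds.tolist())),
            n_replicates=len(replicates),
        )

    def __getitem__(self, species: str) -> float:
        return self.means.get(species, 0.0)

    def sd(self, species: str) -> float:
        return self.sds.get(species, 0.0)

    @property
    def species(self) -> list[str]:
        return sorted(self.means, key=self.means.get, reverse=True)

    def top(self) -> str:
        return self.species[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": list(self.means),
                "mean_pct": [self.means[s] for s in self.means],
                "sd_pct": [self.sds.get(s, 0.0) for s in self.means],
            }
        ).sort_values("mean_pct", ascending=False, ignore_index=True)

    def vector(self, universe: Sequence[str]) -> np.ndarray:
        """Abundances over a common species universe (absent species = 0)."""
        return np.array([self.means.get(s, 0.0) for s in universe])
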