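"""Cross-level reconciliation: profile correlation, occupancy consolidation,
contamination diagnosis, and the semi-quantitative site x structure table.

The three analyte levels measure overlapping but differently biased views
of the same glycosylation: the released glycome is site-unspecific and
skewed by contaminant glycoproteins and by PNGase-F-resistant stubs being
invisible; the glycopeptide and intact levels are site-specific and should
agree closely. The reconciliation quantifies that structure as pairwise R2
between profiles over a common species universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .glycans import by_name, pngase_releases
from .profiles import QuantProfile

__all__ = [
    "MAJOR_GLYCOFORMS",
    "correlate",
    "semiquant_table",
    "diagnose_contamination",
    "ReconciliationReport",
]

#: The five major site glycoforms used for cross-level correlation (trace
#: glycoforms are excluded from the quantitative comparison).
MAJOR_GLYCOFORMS = ("GlcNAcb", "Fuca1,6GlcNAcb", "M1", "M1F", "M2")

#: Semi-quantitative bin thresholds (% relative abundance). Reverse-
#: engineered to reproduce the documented nCG semi-quantitative table cells;
#: configurable.
BIN_HIGH = 20.0
BIN_INTERMEDIATE = 2.0
#: Below this the species is considered detected but non-quantifiable.
QUANT_LIMIT = 0.5


def correlate(
    profile_a: QuantProfile | Mapping[str, float],
    profile_b: QuantProfile | Mapping[str, float],
    universe: Sequence[str] = MAJOR_GLYCOFORMS,
) -> float:
    """R2 of the least-squares linear fit between two abundance vectors
    mapped onto a common species universe (absent species count as 0)."""
    if len(universe) < 3:
        raise ValueError("species universe must contain at least 3 species")

    def vec(p) -> np.ndarray:
        if isinstance(p, QuantProfile):
            return p.vector(universe)
        return np.array([p.get(s, 0.0) for s in universe])

    a, b = vec(profile_a), vec(profile_b)
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        raise ValueError("degenerate (constant) profile: R2 undefined")
    res = stats.linregress(a, b)
    return float(res.rvalue**2)


def _bin(mean_pct: float, detected: bool, quant_limit: float) -> str:
    if mean_pct >= BIN_HIGH:
        return "xxxx"
    if mean_pct >= BIN_INTERMEDIATE:
        return "xxx"
    if mean_pct >= quant_limit:
        return "xx"
    return "x" if detected or mean_pct > 0 else ""


def semiquant_table(
    site_profiles: Mapping[tuple[str, int], QuantProfile],
    detections: Mapping[tuple[str, int], Sequence[str]] | None = None,
    quant_limit: float = QUANT_LIMIT,
) -> pd.DataFrame:
    """Site x structure semi-quantitative bins.

    ``xxxx`` >= 20%, ``xxx`` 2-20%, ``xx`` quantifiable below 2%, ``x``
    detected-only (trace, below the quantitation limit). ``detections``
    optionally lists species identified per site (e.g. by MS/MS) without a
    quantifiable EIC. The mapping is monotone in abundance.
    """
    detections = detections or {}
    species = sorted(
        {s for p in site_profiles.values() for s in p.means}
        | {s for d in detections.values() for s in d}
    )
    cols = {}
    for (protein, site), profile in site_profiles.items():
        det = set(detections.get((protein, site), ()))
        cols[f"{protein}:Asn{site}"] = [
            _bin(profile[s], s in det, quant_limit) for s in species
        ]
    return pd.DataFrame(cols, index=species)


def diagnose_contamination(
    glycome_profile: QuantProfile,
    target_site_profiles: Mapping[tuple[str, int], QuantProfile],
    contaminant_site_profiles: Mapping[tuple[str, int], QuantProfile] | None = None,
    residual_threshold: float = 5.0,
) -> dict[str, dict]:
    """Flag glycome species unexplained by the target protein's sites.

    The expected glycome is the target site profile restricted to
    PNGase-F-releasable species and renormalized; any glycome species whose
    abundance exceeds its expectation by more than ``residual_threshold``
    percentage points is flagged, with candidate contaminant attributions
    when contaminant site profiles carrying the species (>= 2%) exist.
    """
    expected: dict[str, float] = {}
    for profile in target_site_profiles.values():
        for s, v in profile.means.items():
            try:
                if not pngase_releases(by_name(s)):
                    continue
            except KeyError:
                pass
            expected[s] = expected.get(s, 0.0) + v / max(len(target_site_profiles), 1)
    tot = sum(expected.values())
    if tot > 0:
        expected = {s: 100.0 * v / tot for s, v in expected.items()}
    flags: dict[str, dict] = {}
    for species, obs in glycome_profile.means.items():
        resid = obs - expected.get(species, 0.0)
        if resid <= residual_threshold:
            continue
        attributions = []
        for (prot, site), profile in (contaminant_site_profiles or {}).items():
            for name, v in profile.means.items():
                if v >= 2.0 and (name == species or name in species.split("|")):
                    attributions.append(f"{prot}:Asn{site}")
                    break
        flags[species] = {
            "observed_pct": obs,
            "expected_pct": expected.get(species, 0.0),
            "residual_pct": resid,
            "candidates": sorted(set(attributions)) or ["unattributed"],
        }
    return flags


@dataclass
class ReconciliationReport:
    """Full cross-level reconciliation output."""

    r2_glycopeptide_intact: float
    r2_glycome_glycopeptide: float
    occupancy: float
    occupancy_sd: float
    site_profile: QuantProfile
    glycome_profile: QuantProfile
    variant_profile: QuantProfile
    glycoform_marginal: QuantProfile
    cterm_peptide_profile: QuantProfile
    semiquant: pd.DataFrame
    contamination_flags: dict[str, dict] = field(default_factory=dict)
    insource_artefact: bool = False

    def to_markdown(self) -> str:
        lines = [
            "# Reconciliation report",
            "",
            f"- R2 (glycopeptide vs intact glycoform profile): "
            f"{self.r2_glycopeptide_intact:.3f}",
            f"- R2 (glycome vs glycopeptide profile): "
            f"{self.r2_glycome_glycopeptide:.3f}",
            f"- Asn71 occupancy: {100 * self.occupancy:.1f}% "
            f"(SD {100 * self.occupancy_sd:.1f})",
            f"- In-source decay artefact flagged: {self.insource_artefact}",
            "",
            "## Site glycoform profile (glycopeptide level)",
            self.site_profile.to_frame().to_string(index=False),
            "",
            "## C-terminal variants (intact level)",
            self.variant_profile.to_frame().to_string(index=False),
            "",
            "## C-terminal reporter peptides",
            self.cterm_peptide_profile.to_frame().to_string(index=False),
            "",
            "## Released glycome",
            self.glycome_profile.to_frame().to_string(index=False),
            "",
            "## Semi-quantitative site x structure table",
            self.semiquant.to_string(),
            "",
            "## Contamination flags",
        ]
        if self.contamination_flags:
            for sp, info in self.contamination_flags.items():
                lines.append(
                    f"- {sp}: observed {info['observed_pct']:.1f}% vs expected "
                    f"{info['expected_pct']:.1f}% -> {', '.join(info['candidates'])}"
                )
        else:
            lines.append("- none")
        return "\n".join(lines) + "\n"
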