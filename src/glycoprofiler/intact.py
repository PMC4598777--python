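"""Intact-glycoprotein level: charge-envelope deconvolution of multi-charge
ESI spectra to neutral masses, matching against the combinatorial proteoform
space, isotopic-envelope fit scoring, and proteoform quantitation.

Deconvolution is a defined charge-envelope clustering (each envelope needs
at least two consecutive charge states agreeing on a common neutral mass)
rather than a vendor maximum-entropy algorithm; the contract — neutral
masses with summed intensities — is the same. Average mass is the matching
currency at this level (deconvoluted apex masses of an unresolved-envelope
QTOF acquisition); monoisotopic masses are carried alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import PROTON
from .glycans import GlycanStructure, full_panel
from .masscalc import (
    IsotopePattern,
    combine,
    composition_mass,
    glycan_composition,
    isotope_pattern,
)
from .profiles import QuantProfile
from .simulate import ProteinSpec, SyntheticRun, intact_proteoform_id

__all__ = [
    "Proteoform",
    "Envelope",
    "ProteoformMatch",
    "enumerate_proteoforms",
    "deconvolute",
    "match_proteoforms",
    "isotope_fit",
    "quantify_proteoforms",
]

#: Average-mass delta of one serine residue (the +87 Da C-terminal pairing).
SERINE_DELTA_AVG = composition_mass({"C": 3, "H": 5, "N": 1, "O": 2}).average
#: Average-mass delta of one oxidation (the +16 Da pairing).
OX_DELTA_AVG = composition_mass({"O": 1}).average


@dataclass(frozen=True)
class Proteoform:
    """One molecular form: C-terminal variant + PTM state + site glycoform."""

    protein: str
    end: int  # last mature residue (C-terminal variant)
    glycan: GlycanStructure | None
    n_oxidations: int
    composition: dict[str, int]
    monoisotopic: float
    average: float

    @property
    def label(self) -> str:
        return intact_proteoform_id(self.protein, self.end, self.glycan.name if self.glycan else None)


def enumerate_proteoforms(
    protein: ProteinSpec,
    panel: Sequence[GlycanStructure] | None = None,
    oxidation_states: Sequence[int] | None = None,
    include_aglycosylated: bool = True,
) -> list[Proteoform]:
    """The combinatorial proteoform space of one protein: C-terminal
    variants x (panel glycoforms + optionally none) x oxidation states.

    By default the oxidation state is the protein's complete fixed
    oxidation; disulfides are native (mass -2 H per bond)."""
    panel = tuple(panel) if panel is not None else full_panel()
    if oxidation_states is None:
        oxidation_states = (len(protein.oxidized_met),)
    out = []
    for end in protein.cterm_variants:
        full_ox = protein.mature_composition(end)
        base = combine(full_ox, {"O": -len(protein.oxidized_met)}) if protein.oxidized_met else full_ox
        glycans: list[GlycanStructure | None] = list(panel)
        if include_aglycosylated:
            glycans.append(None)
        for g in glycans:
            for n_ox in oxidation_states:
                comp = combine(base, {"O": n_ox}) if n_ox else base
                if g is not None:
                    comp = combine(comp, glycan_composition(g.composition))
                mv = composition_mass(comp)
                out.append(
                    Proteoform(
                        protein.name, end, g, n_ox, comp, mv.monoisotopic, mv.average
                    )
                )
    return out


@dataclass
class Envelope:
    """One deconvoluted neutral species."""

    neutral_mass: float
    intensity: float
    charges: tuple[int, ...]
    isotopes: IsotopePattern | None = None


def deconvolute(
    peaks: Sequence[tuple[float, float]] | SyntheticRun,
    charge_range: tuple[int, int] = (8, 30),
    tol_da: float = 0.6,
) -> list[Envelope]:
    """Charge-envelope clustering of a positive-mode multi-charge spectrum.

    Every (peak, candidate charge) hypothesis is converted to a neutral mass
    M = z*(m/z) - z*m_p; hypotheses agreeing within ``tol_da`` are clustered,
    and a cluster is accepted as an envelope only when it contains at least
    two *consecutive* charge states. Each peak contributes to at most one
    envelope (its best-supported one). The envelope mass is the
    intensity-weighted mean over its charge states; the intensity is the sum.
    """
    if isinstance(peaks, SyntheticRun):
        run = peaks
        if run.level != "intact":
            raise ValueError(f"expected an intact-level run, got {run.level!r}")
        peak_list = [(f.mz, f.intensity) for f in run.features]
        iso_by_mz = {round(f.mz, 6): f.isotopes for f in run.features}
    else:
        peak_list = list(peaks)
        iso_by_mz = {}
    if len(peak_list) < 2:
        if peak_list:
            warnings.warn("fewer than 2 peaks: no charge envelope can be formed")
        return []
    zmin, zmax = charge_range
    hyps = []  # (neutral mass, intensity, z, peak index)
    for i, (mz, inten) in enumerate(peak_list):
        for z in range(zmin, zmax + 1):
            hyps.append((mz * z - z * PROTON, inten, z, i))
    hyps.sort()
    # single-linkage clustering along the sorted mass axis
    clusters: list[list[tuple[float, float, int, int]]] = []
    for h in hyps:
        if clusters and h[0] - clusters[-1][-1][0] <= tol_da:
            clusters[-1].append(h)
        else:
            clusters.append([h])

    def _support(cluster: list[tuple[float, float, int, int]]) -> int:
        zs = sorted({z for _, _, z, _ in cluster})
        best = run_len = 1
        for a, b in zip(zs, zs[1:]):
            run_len = run_len + 1 if b == a + 1 else 1
            best = max(best, run_len)
        return best

    # rank clusters by (consecutive-charge support, intensity); greedily
    # claim peaks so each peak explains one envelope only
    ranked = sorted(
        clusters,
        key=lambda c: (_support(c), sum(i for _, i, _, _ in c)),
        reverse=True,
    )
    used: set[int] = set()
    envelopes = []
    for cluster in ranked:
        members = [h for h in cluster if h[3] not in used]
        if not members:
            continue
        # robust trim: drop stray wrong-charge hypotheses that fell into the
        # single-linkage cluster but disagree with the consensus mass
        masses = np.array([m for m, _, _, _ in members])
        med = float(np.median(masses))
        dev = np.abs(masses - med)
        cut = max(5.0 * float(np.median(dev)), 0.05)
        members = [h for h, d in zip(members, dev) if d <= cut]
        if not members:
            continue
        zs = sorted({z for _, _, z, _ in members})
        if _support(members) < 2:
            continue
        masses = np.array([m for m, _, _, _ in members])
        intens = np.array([i for _, i, _, _ in members])
        neutral = float(np.average(masses, weights=intens))
        for h in members:
            used.add(h[3])
        iso = None
        if iso_by_mz:
            # carry the isotope cluster of the most intense member peak
            top = max(members, key=lambda h: h[1])
            mz_top = (top[0] + top[2] * PROTON) / top[2]
            iso = iso_by_mz.get(round(mz_top, 6))
        envelopes.append(
            Envelope(neutral, float(intens.sum()), tuple(zs), iso)
        )
    if not envelopes:
        warnings.warn("no charge envelope found")
    envelopes.sort(key=lambda e: e.neutral_mass)
    return envelopes


@dataclass
class ProteoformMatch:
    """One deconvoluted mass matched to a proteoform (or flagged)."""

    envelope: Envelope
    proteoform: Proteoform | None
    mass_error_ppm: float = float("nan")
    ambiguous: tuple[Proteoform, ...] = ()
    isotope_fit_score: float | None = None
    delta_links: tuple[tuple[str, float], ...] = ()  # ("+87 Da", partner mass)


def match_proteoforms(
    envelopes: Sequence[Envelope],
    space: Sequence[Proteoform],
    tol_ppm: float = 50.0,
) -> list[ProteoformMatch]:
    """Nearest-average-mass matching of deconvoluted masses against the
    proteoform space, with +87 Da (C-terminal Ser) and +16 Da (Met
    oxidation) partner links annotated between matched masses.

    Two proteoforms inside the tolerance yield an ambiguity flag with both
    candidates reported; masses outside the space stay unmatched."""
    matches: list[ProteoformMatch] = []
    for env in envelopes:
        tol = tol_ppm * 1e-6 * env.neutral_mass
        hits = sorted(
            (p for p in space if abs(p.average - env.neutral_mass) <= tol),
            key=lambda p: abs(p.average - env.neutral_mass),
        )
        if not hits:
            matches.append(ProteoformMatch(env, None))
            continue
        best = hits[0]
        err = 1e6 * (env.neutral_mass - best.average) / best.average
        score = None
        if env.isotopes is not None:
            score = isotope_fit(env.isotopes, isotope_pattern(best.composition))
        matches.append(
            ProteoformMatch(
                env, best, err, tuple(hits[1:]) if len(hits) > 1 else (), score
            )
        )
    # annotate symmetric delta-mass pairing links between matched envelopes
    for i, mi in enumerate(matches):
        if mi.proteoform is None:
            continue
        links = list(mi.delta_links)
        for j, mj in enumerate(matches):
            if i == j or mj.proteoform is None:
                continue
            delta = mj.envelope.neutral_mass - mi.envelope.neutral_mass
            if abs(abs(delta) - SERINE_DELTA_AVG) < 0.25:
                links.append(("+87 Da" if delta > 0 else "-87 Da", mj.envelope.neutral_mass))
            elif abs(abs(delta) - OX_DELTA_AVG) < 0.2:
                links.append(("+16 Da" if delta > 0 else "-16 Da", mj.envelope.neutral_mass))
        mi.delta_links = tuple(links)
    return matches


def isotope_fit(
    observed: IsotopePattern, theoretical: IsotopePattern, align_tol: float = 0.5
) -> float:
    """Total-variation similarity between two isotopic envelopes in [0, 1].

    Both patterns are renormalized; observed and theoretical isotopologue
    bins are aligned by nearest mass within ``align_tol`` Da, unaligned
    abundance counts as mismatch. Identical patterns score 1, disjoint 0.
    """
    if len(observed.peaks) < 2:
        raise ValueError("observed isotopic cluster unresolved: fit undefined")
    om, oa = observed.masses, observed.abundances
    tm, ta = theoretical.masses, theoretical.abundances
    oa = oa / oa.sum()
    ta = ta / ta.sum()
    diff = 0.0
    used = np.zeros(len(tm), dtype=bool)
    for m, a in zip(om, oa):
        j = int(np.argmin(np.abs(tm - m)))
        if abs(tm[j] - m) <= align_tol and not used[j]:
            diff += abs(a - ta[j])
            used[j] = True
        else:
            diff += a
    diff += ta[~used].sum()
    return float(1.0 - 0.5 * diff)


def quantify_proteoforms(
    replicate_matches: Sequence[Sequence[ProteoformMatch]],
) -> tuple[QuantProfile, QuantProfile]:
    """Marginal proteoform profiles from matched envelope intensities.

    Returns ``(variant_profile, glycoform_profile)``: the C-terminal variant
    proportions and the site glycoform proportions summed over variants
    (aglycosylated signal keyed ``"aglycosylated"``), each as mean +/- SD
    over replicates."""
    if not replicate_matches:
        raise ValueError("at least one replicate required")
    var_reps, gly_reps = [], []
    for matches in replicate_matches:
        var: dict[str, float] = {}
        gly: dict[str, float] = {}
        for m in matches:
            if m.proteoform is None:
                continue
            p = m.proteoform
            var_key = f"{p.protein}:end={p.end}"
            gly_key = p.glycan.name if p.glycan else "aglycosylated"
            var[var_key] = var.get(var_key, 0.0) + m.envelope.intensity
            gly[gly_key] = gly.get(gly_key, 0.0) + m.envelope.intensity
        vtot, gtot = sum(var.values()), sum(gly.values())
        if vtot == 0:
            raise ValueError("no matched proteoforms to quantify")
        var_reps.append({k: 100.0 * v / vtot for k, v in var.items()})
        gly_reps.append({k: 100.0 * v / gtot for k, v in gly.items()})
    return (
        QuantProfile.from_replicates(var_reps),
        QuantProfile.from_replicates(gly_reps),
    )


def match_table(matches: Sequence[ProteoformMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "neutral_mass": [m.envelope.neutral_mass for m in matches],
            "intensity": [m.envelope.intensity for m in matches],
            "charges": ["-".join(map(str, m.envelope.charges)) for m in matches],
            "proteoform": [m.proteoform.label if m.proteoform else "" for m in matches],
            "mass_error_ppm": [m.mass_error_ppm for m in matches],
            "ambiguous": [bool(m.ambiguous) for m in matches],
            "isotope_fit": [m.isotope_fit_score for m in matches],
            "delta_links": [
                ";".join(f"{lbl}@{mass:.2f}" for lbl, mass in m.delta_links)
                for m in matches
            ],
        }
    )
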