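"""Elemental mass arithmetic, isotopic distributions, and m/z transforms.

This module is the numerical foundation of the pipeline: peptide and glycan
masses, glycopeptide additivity, charge-state arithmetic, and theoretical
isotopic envelopes computed by convolution of per-element natural-abundance
distributions (aggregated at nominal-isotopologue resolution, which is what a
QTOF resolves on an intact ~26 kDa protein).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .constants import (
    ELEMENT_AVG,
    ELEMENT_MONO,
    GLYCAN_FORMULAS,
    ISOTOPES,
    MODIFICATIONS,
    PROTON,
    RESIDUE_FORMULAS,
)

__all__ = [
    "MassValue",
    "IsotopePattern",
    "combine",
    "scale",
    "composition_mass",
    "peptide_composition",
    "peptide_mass",
    "glycan_composition",
    "glycan_mass",
    "to_mz",
    "from_mz",
    "isotope_pattern",
]

# An elemental composition is a plain mapping element symbol -> count.
ElementalComposition = Mapping[str, int]

WATER: dict[str, int] = {"H": 2, "O": 1}
H2: dict[str, int] = {"H": 2}


@dataclass(frozen=True)
class MassValue:
    """Monoisotopic and average mass of one molecular species, in Da."""

    monoisotopic: float
    average: float

    def __post_init__(self) -> None:
        if self.monoisotopic <= 0 or self.average <= 0:
            raise ValueError("masses must be positive")


@dataclass(frozen=True)
class IsotopePattern:
    """Aggregated isotopic envelope: (centroid mass Da, relative abundance).

    Peaks are strictly increasing in mass, abundances sum to 1, and adjacent
    aggregated peaks are spaced by ~1.0034 Da (the average neutron-addition
    mass for CHNOS molecules).
    """

    peaks: tuple[tuple[float, float], ...]

    @property
    def masses(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])

    @property
    def abundances(self) -> np.ndarray:
        return np.array([a for _, a in self.peaks])


def combine(*comps: ElementalComposition) -> dict[str, int]:
    """Sum elemental compositions (negative intermediate counts rejected)."""
    total: Counter[str] = Counter()
    for comp in comps:
        total.update(comp)
    out = {el: n for el, n in total.items() if n != 0}
    if any(n < 0 for n in out.values()):
        raise ValueError(f"negative element count in combined composition: {out}")
    return out


def scale(comp: ElementalComposition, n: int) -> dict[str, int]:
    return {el: c * n for el, c in comp.items() if c * n != 0}


def _validate(comp: ElementalComposition) -> None:
    unknown = set(comp) - set(ELEMENT_MONO)
    if unknown:
        raise ValueError(f"unsupported elements: {sorted(unknown)}")
    if any(n < 0 for n in comp.values()):
        raise ValueError("element counts must be non-negative")
    if sum(comp.values()) == 0:
        raise ValueError("empty elemental composition")


def composition_mass(comp: ElementalComposition) -> MassValue:
    """Monoisotopic and average mass of an elemental composition."""
    _validate(comp)
    mono = sum(ELEMENT_MONO[el] * n for el, n in comp.items())
    avg = sum(ELEMENT_AVG[el] * n for el, n in comp.items())
    return MassValue(mono, avg)


def peptide_composition(
    sequence: str, fixed_mods: Iterable[str] = ()
) -> dict[str, int]:
    """Elemental composition of a linear peptide with named fixed mods.

    Fixed modifications apply to every occurrence of their target residue
    (e.g. ``carboxymethyl`` to every Cys).
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    comps: list[ElementalComposition] = [WATER]
    for i, aa in enumerate(sequence):
        if aa not in RESIDUE_FORMULAS:
            raise ValueError(f"unknown residue {aa!r} at position {i + 1}")
        comps.append(RESIDUE_FORMULAS[aa])
    for mod in fixed_mods:
        if mod not in MODIFICATIONS:
            raise ValueError(f"unknown modification {mod!r}")
        delta, targets = MODIFICATIONS[mod]
        n = sum(sequence.count(t) for t in targets)
        if n:
            comps.append(scale(delta, n))
    return combine(*comps)


def peptide_mass(sequence: str, fixed_mods: Iterable[str] = ()) -> MassValue:
    """Neutral monoisotopic/average mass of a peptide (+ water terminus)."""
    return composition_mass(peptide_composition(sequence, fixed_mods))


def glycan_composition(
    counts: Mapping[str, int], form: str = "glycosidically-bound"
) -> dict[str, int]:
    """Elemental composition of a glycan given monosaccharide counts.

    ``reduced-alditol`` adds water (free reducing end) plus 2 H from
    borohydride reduction; ``glycosidically-bound`` is the dehydrated residue
    sum, to be added onto a carrier (peptide/protein) composition.
    """
    if sum(counts.values()) < 1:
        raise ValueError("glycan composition must contain at least one residue")
    unknown = set(counts) - set(GLYCAN_FORMULAS)
    if unknown:
        raise ValueError(f"unknown monosaccharide types: {sorted(unknown)}")
    comps = [scale(GLYCAN_FORMULAS[res], n) for res, n in counts.items() if n]
    if form == "reduced-alditol":
        comps.append(WATER)
        comps.append(H2)
    elif form != "glycosidically-bound":
        raise ValueError(f"unknown glycan form {form!r}")
    return combine(*comps)


def glycan_mass(counts: Mapping[str, int], form: str = "glycosidically-bound") -> MassValue:
    return composition_mass(glycan_composition(counts, form))


def to_mz(mass: float, charge: int, polarity: str = "+") -> float:
    """m/z of a neutral mass at a given charge (proton adduct/loss)."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    if polarity == "+":
        return (mass + charge * PROTON) / charge
    if polarity == "-":
        return (mass - charge * PROTON) / charge
    raise ValueError("polarity must be '+' or '-'")


def from_mz(mz: float, charge: int, polarity: str = "+") -> float:
    """Neutral mass from an observed m/z and charge (inverse of to_mz)."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    if polarity == "+":
        return mz * charge - charge * PROTON
    if polarity == "-":
        return mz * charge + charge * PROTON
    raise ValueError("polarity must be '+' or '-'")


def _element_distribution(el: str) -> tuple[np.ndarray, np.ndarray]:
    """Single-atom abundance/mass arrays indexed by nominal mass offset."""
    iso = ISOTOPES[el]
    base = round(iso[0][0])
    size = max(round(m) - base for m, _ in iso) + 1
    abund = np.zeros(size)
    mass = np.zeros(size)
    for m, a in iso:
        k = round(m) - base
        abund[k] += a
        mass[k] += a * m
    nz = abund > 0
    mass[nz] /= abund[nz]
    return abund, mass


def _convolve(
    a1: np.ndarray, m1: np.ndarray, a2: np.ndarray, m2: np.ndarray, tail: float
) -> tuple[np.ndarray, np.ndarray]:
    """Convolve two centroided distributions, trimming a negligible tail."""
    abund = np.convolve(a1, a2)
    # centroid masses: intensity-weighted sum of component masses per bin
    mass = np.convolve(a1 * m1, a2) + np.convolve(a1, a2 * m2)
    nz = abund > 0
    mass[nz] /= abund[nz]
    # trim the high-mass tail to keep repeated convolution O(n)
    keep = len(abund)
    cum = np.cumsum(abund)
    above = np.nonzero(cum >= 1.0 - tail)[0]
    if len(above):
        keep = above[0] + 1
    return abund[:keep], mass[:keep]


def isotope_pattern(
    comp: ElementalComposition, coverage: float = 0.9999
) -> IsotopePattern:
    """Theoretical isotopic envelope of an elemental composition.

    Iterated convolution of per-element natural-abundance distributions,
    aggregated in nominal-mass bins with abundance-weighted centroid masses.
    The envelope is truncated once cumulative abundance reaches ``coverage``
    and renormalized to sum to 1.
    """
    _validate(comp)
    tail = min(1e-12, (1.0 - coverage) * 1e-3)
    abund = np.array([1.0])
    mass = np.array([0.0])
    for el, n in sorted(comp.items()):
        e_abund, e_mass = _element_distribution(el)
        # exponentiation by squaring: element distribution to the n-th power
        p_abund, p_mass = np.array([1.0]), np.array([0.0])
        b_abund, b_mass = e_abund, e_mass
        k = n
        while k:
            if k & 1:
                p_abund, p_mass = _convolve(p_abund, p_mass, b_abund, b_mass, tail)
            k >>= 1
            if k:
                b_abund, b_mass = _convolve(b_abund, b_mass, b_abund, b_mass, tail)
        abund, mass = _convolve(abund, mass, p_abund, p_mass, tail)
    nz = abund > 0  # nominal bins are already mass ordered; drop empty ones
    abund, mass = abund[nz], mass[nz]
    cum = np.cumsum(abund)
    cut = int(np.searchsorted(cum, coverage) + 1)
    abund, mass = abund[:cut], mass[:cut]
    abund = abund / abund.sum()
    peaks = tuple((float(m), float(a)) for m, a in zip(mass, abund) if a > 0)
    return IsotopePattern(peaks)
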