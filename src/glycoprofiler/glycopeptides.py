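"""Glycopeptide-level analysis: in-silico chymotryptic digestion, CID/ETD
fragment prediction, spectrum matching, and site-specific EIC quantitation.

Chymotrypsin specificity here is C-terminal to F/Y/W/L/M (never before Pro);
the L/M cleavages are required to produce the peptides this pipeline
quantifies (GSNINVTL at the glycosite, IRTTMR(S) at the C-terminus, the
latter carrying one missed cleavage at its internal Met). Quantitation
follows the EIC model: the relative area summed over all observed charge
states of each glycoform of a site, assuming equal ionization efficiencies
of the related species; site occupancy is the glycosylated fraction of the
total site-peptide signal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
from pyteomics import parser as _pyt_parser

from .constants import MODIFICATIONS, RESIDUE_FORMULAS
from .glycans import GlycanStructure, full_panel
from .masscalc import (
    combine,
    composition_mass,
    glycan_composition,
    peptide_composition,
    to_mz,
)
from .profiles import QuantProfile

if TYPE_CHECKING:
    from .simulate import SyntheticRun

__all__ = [
    "CHYMOTRYPSIN_RULE",
    "PeptideSpecies",
    "Ion",
    "SpectrumMatch",
    "digest",
    "site_peptide",
    "cterm_reporter_peptide",
    "theoretical_fragments",
    "match_spectra",
    "site_profile",
    "cterm_ratio",
]

#: Cleave C-terminal to F, Y, W, L, M, but not before proline.
CHYMOTRYPSIN_RULE = r"[FYWLM](?!P)"

SEQUON = re.compile(r"N(?=[^P][ST])")

# terminal/charge-carrier mass pieces for fragment ions (neutral deltas)
_NH3 = composition_mass({"N": 1, "H": 3}).monoisotopic
_H2O = composition_mass({"H": 2, "O": 1}).monoisotopic
_H = composition_mass({"H": 1}).monoisotopic


@dataclass(frozen=True)
class PeptideSpecies:
    """One (glyco)peptide: protein coordinates, optional glycan, fixed mods.

    Positions are 1-based inclusive in unprocessed-chain numbering. A set
    glycosite must lie within [start, end] and sit in an N-X(!=P)-S/T sequon
    of the parent protein unless ``non_sequon`` is flagged.
    """

    protein: str
    sequence: str
    start: int
    end: int
    glycosite: int | None = None
    glycan: GlycanStructure | None = None
    fixed_mods: tuple[str, ...] = ()
    non_sequon: bool = False
    missed_cleavages: int = 0
    semi_specific: bool = False

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("peptide span inconsistent with sequence length")
        if self.glycosite is not None and not (
            self.start <= self.glycosite <= self.end
        ):
            raise ValueError("glycosite outside peptide span")
        if self.glycan is not None and self.glycosite is None:
            raise ValueError("glycan attached without a glycosite")

    @property
    def site_index(self) -> int | None:
        """0-based index of the glycosite within the peptide sequence."""
        if self.glycosite is None:
            return None
        return self.glycosite - self.start

    def composition(self) -> dict[str, int]:
        comp = peptide_composition(self.sequence, self.fixed_mods)
        if self.glycan is not None:
            comp = combine(comp, glycan_composition(self.glycan.composition))
        return comp

    def neutral_mass(self) -> float:
        return composition_mass(self.composition()).monoisotopic

    def mz(self, charge: int, polarity: str = "+") -> float:
        return to_mz(self.neutral_mass(), charge, polarity)

    @property
    def species_id(self) -> str:
        glycan = self.glycan.name if self.glycan else "peptide"
        site = f"Asn{self.glycosite}" if self.glycosite else f"{self.start}-{self.end}"
        return f"gp|{self.protein}|{site}|{glycan}|{self.sequence}"


def _validate_sequon(sequence: str, site: int) -> bool:
    """Whether 1-based position ``site`` in ``sequence`` starts a sequon."""
    return bool(SEQUON.match(sequence, site - 1))


def digest(
    sequence: str,
    protein: str = "protein",
    specificity: str = "full",
    missed_cleavages: int = 1,
    min_length: int = 4,
    glycosites: Sequence[int] = (),
) -> list[PeptideSpecies]:
    """In-silico chymotryptic digest returning positioned peptide species.

    ``specificity='semi'`` additionally emits peptides with one non-canonical
    terminus (every proper prefix/suffix of a fully specific peptide). The
    protein C-terminus is always a valid peptide terminus. Peptides covering
    a listed glycosite are annotated with the site position (one species per
    covered site; the unglycosylated base species is returned — glycans are
    attached by the caller).
    """
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    if specificity not in ("full", "semi"):
        raise ValueError("specificity must be 'full' or 'semi'")
    spans: set[tuple[int, int, int, bool]] = set()  # (start0, end0, mc, semi)
    for start0, pep in _pyt_parser.icleave(
        sequence, CHYMOTRYPSIN_RULE, missed_cleavages=missed_cleavages, min_length=1
    ):
        end0 = start0 + len(pep)
        mc = len(re.findall(CHYMOTRYPSIN_RULE, pep[:-1]))
        spans.add((start0, end0, mc, False))
        if specificity == "semi":
            for k in range(1, len(pep)):
                spans.add((start0, start0 + k, mc, True))   # keep N-terminus
                spans.add((start0 + k, end0, mc, True))     # keep C-terminus
    out: list[PeptideSpecies] = []
    for start0, end0, mc, semi in sorted(spans):
        pep = sequence[start0:end0]
        if len(pep) < min_length:
            continue
        covered = [s for s in glycosites if start0 + 1 <= s <= end0]
        for site in covered or [None]:
            if site is not None and not _validate_sequon(sequence, site):
                raise ValueError(f"position {site} is not an N-X(!=P)-S/T sequon")
            out.append(
                PeptideSpecies(
                    protein, pep, start0 + 1, end0, glycosite=site,
                    missed_cleavages=mc, semi_specific=semi,
                )
            )
    return out


def site_peptide(
    sequence: str, site: int, protein: str = "protein", missed_cleavages: int = 0
) -> PeptideSpecies:
    """The canonical (fewest missed cleavages, shortest) peptide covering a site."""
    peptides = [
        p
        for p in digest(
            sequence, protein, "full", missed_cleavages, glycosites=[site]
        )
        if p.glycosite == site
    ]
    if not peptides:
        raise ValueError(f"no chymotryptic peptide covers position {site}")
    return min(peptides, key=lambda p: (p.missed_cleavages, len(p.sequence)))


def cterm_reporter_peptide(
    sequence: str, end: int, protein: str = "protein"
) -> PeptideSpecies:
    """The C-terminal reporter peptide of a chain truncated at ``end``.

    Chosen as the shortest C-terminal chymotryptic peptide of length >= 4
    (allowing missed cleavages at internal L/M, as for IRTTMR with its
    internal Met).
    """
    chain = sequence[:end]
    candidates = [
        p
        for p in digest(chain, protein, "full", missed_cleavages=2, min_length=4)
        if p.end == end
    ]
    if not candidates:
        raise ValueError(f"no C-terminal peptide for chain ending at {end}")
    return min(candidates, key=lambda p: len(p.sequence))


@dataclass(frozen=True)
class Ion:
    name: str
    mz: float
    charge: int
    series: str  # "Y" | "B" | "b" | "y" | "c" | "z"


def _residue_masses(sequence: str) -> np.ndarray:
    return np.array(
        [composition_mass(RESIDUE_FORMULAS[aa]).monoisotopic for aa in sequence]
    )


def _glycan_ladder(glycan: GlycanStructure) -> list[tuple[str, float]]:
    """Cumulative glycan masses retained on the peptide for the Y-ion ladder.

    Stripping order from the non-reducing end: NeuAc, then Hex, then antenna
    HexNAc, then core fucose, then the final core HexNAc residues.
    """
    residues: list[str] = (
        ["NeuAc"] * glycan.neuac
        + ["Hex"] * glycan.hex
        + ["HexNAc"] * max(glycan.hexnac - 1, 0)
        + ["dHex"] * glycan.dhex
        + ["HexNAc"]  # reducing-end GlcNAc, lost last
    )
    from .constants import GLYCAN_FORMULAS

    ladder = [("Y0", 0.0)]
    total = 0.0
    for i, res in enumerate(reversed(residues), start=1):
        total += composition_mass(GLYCAN_FORMULAS[res]).monoisotopic
        ladder.append((f"Y{i}", total))
    return ladder


#: Diagnostic oxonium ions (singly protonated B-type fragments), m/z.
OXONIUM = {
    "HexNAc": 204.086649,
    "HexNAc-frag": 138.055,
    "Hex": 163.060101,
    "NeuAc": 292.102693,
    "NeuAc-H2O": 274.092128,
    "HexHexNAc": 366.139472,
}


def theoretical_fragments(
    p: PeptideSpecies, mode: str, max_charge: int = 2
) -> list[Ion]:
    """Theoretical fragment ions of a (glyco)peptide.

    CID fragments the glycosidic bonds: a Y-ion ladder (peptide retaining
    0..n glycan residues), oxonium B ions of the monosaccharides present,
    and weak backbone b/y of the naked peptide. ETD cleaves the backbone
    leaving the glycan intact: c/z ions carry the full glycan mass whenever
    the fragment contains the glycosite.
    """
    if mode not in ("CID", "ETD"):
        raise ValueError("mode must be 'CID' or 'ETD'")
    res = _residue_masses(p.sequence)
    pep_mono = res.sum() + _H2O
    from .constants import ELEMENT_MONO

    for mod in p.fixed_mods:
        delta, targets = MODIFICATIONS[mod]
        n = sum(p.sequence.count(t) for t in targets)
        pep_mono += n * sum(ELEMENT_MONO[el] * c for el, c in delta.items())
    glycan_mono = (
        composition_mass(glycan_composition(p.glycan.composition)).monoisotopic
        if p.glycan
        else 0.0
    )
    site_idx = p.site_index
    ions: list[Ion] = []
    charges = range(1, max(max_charge, 1) + 1)
    if mode == "CID":
        if p.glycan is not None:
            for name, kept in _glycan_ladder(p.glycan):
                for z in charges:
                    ions.append(Ion(name, to_mz(pep_mono + kept, z), z, "Y"))
            comp = p.glycan.composition
            ions.append(Ion("B-HexNAc", OXONIUM["HexNAc"], 1, "B"))
            if comp["Hex"]:
                ions.append(Ion("B-Hex", OXONIUM["Hex"], 1, "B"))
                ions.append(Ion("B-HexHexNAc", OXONIUM["HexHexNAc"], 1, "B"))
            if comp["NeuAc"]:
                ions.append(Ion("B-NeuAc", OXONIUM["NeuAc"], 1, "B"))
                ions.append(Ion("B-NeuAc-H2O", OXONIUM["NeuAc-H2O"], 1, "B"))
        # weak backbone b/y of the naked peptide
        prefix = np.cumsum(res)
        for i in range(1, len(p.sequence)):
            b = prefix[i - 1]
            y = pep_mono - b
            ions.append(Ion(f"b{i}", to_mz(b, 1), 1, "b"))
            ions.append(Ion(f"y{len(p.sequence) - i}", to_mz(y, 1), 1, "y"))
    else:  # ETD: c/z with intact glycan
        prefix = np.cumsum(res)
        n = len(p.sequence)
        for i in range(1, n):
            c_neutral = prefix[i - 1] + _NH3
            z_neutral = pep_mono - prefix[i - 1] - _NH3
            if site_idx is not None and p.glycan is not None:
                if i - 1 >= site_idx:  # c fragment spans residues 0..i-1
                    c_neutral += glycan_mono
                else:
                    z_neutral += glycan_mono
            for z in charges:
                ions.append(Ion(f"c{i}", to_mz(c_neutral, z), z, "c"))
                ions.append(Ion(f"z{n - i}", to_mz(z_neutral, z), z, "z"))
    return ions


@dataclass
class SpectrumMatch:
    """Best candidate explanation of one fragment spectrum."""

    peptide: PeptideSpecies | None
    mode: str
    precursor_mz: float
    precursor_charge: int
    matched_ions: list[Ion] = field(default_factory=list)
    n_theoretical: int = 0
    precursor_error_da: float = float("nan")
    localized_site: int | None = None

    @property
    def n_matched(self) -> int:
        return len(self.matched_ions)


def _match_ions(
    ions: list[Ion], peaks: Sequence[tuple[float, float]], tol: float
) -> list[Ion]:
    if not peaks:
        return []
    mz = np.array(sorted(m for m, _ in peaks))
    out = []
    for ion in ions:
        j = np.searchsorted(mz, ion.mz)
        near = min(
            (abs(mz[k] - ion.mz) for k in (j - 1, j) if 0 <= k < len(mz)),
            default=np.inf,
        )
        if near <= tol:
            out.append(ion)
    return out


def _localization(p: PeptideSpecies, matched: list[Ion]) -> int | None:
    """Claim site localization only when ETD c/z ions bracket the site.

    Requires at least one glycan-shifted fragment containing the site and one
    unshifted fragment excluding it among the matched c/z ions.
    """
    if p.glycan is None or p.site_index is None:
        return None
    n = len(p.sequence)
    shifted = unshifted = False
    for ion in matched:
        if ion.series == "c":
            i = int(ion.name[1:])
            if i - 1 >= p.site_index:
                shifted = True
            else:
                unshifted = True
        elif ion.series == "z":
            j = int(ion.name[1:])
            if n - j <= p.site_index:
                shifted = True
            else:
                unshifted = True
    return p.glycosite if (shifted and unshifted) else None


def match_spectra(
    run: "SyntheticRun",
    candidates: Sequence[PeptideSpecies],
    tol_ms1: float = 0.3,
    tol_ms2: float = 0.5,
) -> list[SpectrumMatch]:
    """Match every fragment spectrum of a run against candidate peptides.

    The best candidate per spectrum maximizes matched-ion count, breaking
    ties by precursor mass error; spectra with no candidate inside the
    precursor tolerance yield an unmatched record. ETD spectra alone support
    a site-localization verdict.
    """
    if tol_ms1 <= 0 or tol_ms2 <= 0:
        raise ValueError("tolerances must be positive")
    results: list[SpectrumMatch] = []
    for spec in run.spectra:
        best: SpectrumMatch | None = None
        for cand in candidates:
            err = cand.mz(spec.precursor_charge) - spec.precursor_mz
            if abs(err) > tol_ms1:
                continue
            ions = theoretical_fragments(
                cand, spec.mode, max_charge=max(spec.precursor_charge - 1, 1)
            )
            matched = _match_ions(ions, spec.peaks, tol_ms2)
            sm = SpectrumMatch(
                cand, spec.mode, spec.precursor_mz, spec.precursor_charge,
                matched, len(ions), err,
            )
            if spec.mode == "ETD":
                sm.localized_site = _localization(cand, matched)
            if (
                best is None
                or best.peptide is None
                or sm.n_matched > best.n_matched
                or (
                    sm.n_matched == best.n_matched
                    and abs(sm.precursor_error_da) < abs(best.precursor_error_da)
                )
            ):
                best = sm
        if best is None:
            best = SpectrumMatch(
                None, spec.mode, spec.precursor_mz, spec.precursor_charge
            )
        results.append(best)
    return results


def _eic_areas(
    run: "SyntheticRun",
    species: Sequence[PeptideSpecies],
    tol: float,
    charges: Iterable[int] = (1, 2, 3),
) -> dict[str, float]:
    """Sum feature intensities matching each species over all charge states."""
    areas = {p.species_id: 0.0 for p in species}
    targets = []
    for p in species:
        for z in charges:
            targets.append((p.mz(z), p.species_id))
    targets.sort()
    tmz = np.array([t[0] for t in targets])
    for feat in run.features:
        j = np.searchsorted(tmz, feat.mz)
        best_k, best_d = None, np.inf
        for k in (j - 1, j):
            if 0 <= k < len(tmz) and abs(tmz[k] - feat.mz) < best_d:
                best_k, best_d = k, abs(tmz[k] - feat.mz)
        if best_k is not None and best_d <= tol:
            areas[targets[best_k][1]] += feat.intensity
    return areas


def site_profile(
    runs: Sequence["SyntheticRun"],
    protein_sequence: str,
    site: int,
    protein: str = "protein",
    panel: Sequence[GlycanStructure] | None = None,
    tol: float = 0.3,
    charges: Iterable[int] = (1, 2, 3),
) -> tuple[QuantProfile, float, float]:
    """Site-specific glycoform distribution and occupancy from EIC areas.

    Returns ``(profile, occupancy_mean, occupancy_sd)`` where the profile is
    the mean +/- SD relative abundance (%) of each glycoform over replicate
    runs and occupancy is glycosylated / (glycosylated + non-glycosylated)
    site-peptide signal, reported as 1.0 when no non-glycosylated form is
    observed. Equal ionization efficiencies of the related species are
    assumed, as is appropriate for the neutral truncated glycoforms.
    """
    if not runs:
        raise ValueError("at least one replicate run is required")
    panel = tuple(panel) if panel is not None else full_panel()
    base = site_peptide(protein_sequence, site, protein)
    from dataclasses import replace

    from .glycans import group_label, isomer_groups

    # glycoforms sharing a composition are isobaric on the same peptide and
    # cannot be separated by EIC m/z: quantify per isomer group
    groups = isomer_groups(panel)
    glyco = [
        (replace(base, glycan=structs[0]), group_label(structs))
        for structs in groups.values()
    ]
    naked = base
    per_rep: list[dict[str, float]] = []
    occs: list[float] = []
    seen_any = False
    for run in runs:
        areas = _eic_areas(run, [p for p, _ in glyco] + [naked], tol, charges)
        gly_total = sum(areas[p.species_id] for p, _ in glyco)
        naked_area = areas[naked.species_id]
        if gly_total + naked_area > 0:
            seen_any = True
        occs.append(
            1.0 if naked_area == 0 else gly_total / (gly_total + naked_area)
        )
        if gly_total > 0:
            per_rep.append(
                {
                    label: 100.0 * areas[p.species_id] / gly_total
                    for p, label in glyco
                }
            )
    if not seen_any:
        raise ValueError(f"glycosite Asn{site} never observed in these runs")
    profile = QuantProfile.from_replicates(per_rep)
    return profile, float(np.mean(occs)), float(np.std(occs, ddof=1)) if len(occs) > 1 else 0.0


def cterm_ratio(
    runs: Sequence["SyntheticRun"],
    protein_sequence: str,
    ends: Sequence[int],
    protein: str = "protein",
    tol: float = 0.3,
    charges: Iterable[int] = (1, 2, 3),
) -> QuantProfile:
    """Relative EIC abundance (%) of the C-terminal truncation reporter
    peptides (e.g. IRTTMR vs IRTTMRS), mean +/- SD over replicates."""
    reporters = [
        cterm_reporter_peptide(protein_sequence, end, protein) for end in ends
    ]
    per_rep = []
    for run in runs:
        areas = _eic_areas(run, reporters, tol, charges)
        total = sum(areas.values())
        if total == 0:
            continue
        per_rep.append(
            {p.sequence: 100.0 * areas[p.species_id] / total for p in reporters}
        )
    if not per_rep:
        raise ValueError("C-terminal reporter peptides not observed")
    return QuantProfile.from_replicates(per_rep)
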