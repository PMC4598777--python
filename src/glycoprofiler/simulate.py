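"""Ground-truth-driven synthetic LC-MS run generation at three analyte
levels: released N-glycan alditols (negative mode), chymotryptic
(glyco)peptides with CID/ETD fragment spectra (positive mode), and intact
multi-charge protein ESI spectra (positive mode).

The generator emulates the acquisition physics that shape such
measurements: PNGase-F resistance of GlcNAc1-2(Fuc0-1) stubs (absent from
the released glycome), positive-mode under-ionization of sialylated
glycopeptides, co-purified contaminant glycoproteins skewing the glycome,
and fragmentor-voltage-dependent in-source glycan loss producing spurious
aglycosylated proteoforms above ~300 V. Chromatographic peaks are single
apex features whose intensity stands for the EIC area — areas are the only
quantity the downstream stages consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .glycans import GlycanStructure, by_name, pngase_releases
from .glycopeptides import (
    PeptideSpecies,
    cterm_reporter_peptide,
    site_peptide,
    theoretical_fragments,
)
from .masscalc import (
    IsotopePattern,
    combine,
    composition_mass,
    glycan_composition,
    glycan_mass,
    isotope_pattern,
    peptide_composition,
    to_mz,
)
from .sequences import AZUROCIDIN, NCG, NE, bundled_sequence

__all__ = [
    "GlycoSite",
    "ProteinSpec",
    "NoiseModel",
    "GroundTruthModel",
    "Feature",
    "FragmentSpectrum",
    "SyntheticRun",
    "default_ncg_model",
    "simulate_run",
    "simulate_replicates",
]

LEVELS = ("glycome", "glycopeptide", "intact")

#: Deterministic charge-state envelopes per level (fixed multinomial splits).
GLYCOME_CHARGES = {1: 0.7, 2: 0.3}
GLYCOPEPTIDE_CHARGES = {1: 0.2, 2: 0.5, 3: 0.3}
INTACT_CHARGES = {z: w for z, w in zip(range(15, 26),
                  (0.02, 0.04, 0.07, 0.10, 0.13, 0.15, 0.14, 0.12, 0.10, 0.08, 0.05))}

#: Surrogate retention times (min): class-based means, Asn71 glycopeptides
#: centred at 39 min.
RT_DEFAULTS = {
    "glycome": 30.0,
    "site-glycopeptide": 39.0,
    "contaminant-glycopeptide": 34.0,
    "cterm-peptide": 22.0,
    "intact": 15.0,
}


def _check_proportions(props: Iterable[float], what: str) -> None:
    total = sum(props)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{what} proportions must sum to 1, got {total!r}")


@dataclass(frozen=True)
class GlycoSite:
    """One N-glycosylation site with its glycoform distribution.

    ``glycoforms`` maps glycan short names to proportions summing to the
    occupancy-independent microheterogeneity (1.0); ``occupancy`` is the
    glycosylated fraction of protein molecules (macroheterogeneity).
    ``zic_hilic_retained`` marks species retained on ZIC-HILIC SPE
    (sialylated glycopeptides are; paucimannosidic/stub ones are not).
    """

    position: int
    glycoforms: dict[str, float]
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        _check_proportions(self.glycoforms.values(), f"site {self.position} glycoform")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")


@dataclass(frozen=True)
class ProteinSpec:
    """One glycoprotein of the preparation, in unprocessed-chain numbering."""

    name: str
    sequence: str
    mature_start: int
    cterm_variants: dict[int, float]  # last mature residue -> proportion
    sites: tuple[GlycoSite, ...]
    abundance: float = 1.0
    oxidized_met: tuple[int, ...] = ()  # complete oxidations (intact level)
    deamidated: tuple[int, ...] = ()  # carried annotations only
    n_disulfides: int = 0
    include_in_intact: bool = True

    def __post_init__(self) -> None:
        _check_proportions(self.cterm_variants.values(), f"{self.name} C-terminal")
        for pos in self.oxidized_met:
            if self.sequence[pos - 1] != "M":
                raise ValueError(f"{self.name}: position {pos} is not Met")
        for site in self.sites:
            if not 1 <= site.position <= len(self.sequence):
                raise ValueError(f"{self.name}: glycosite outside sequence")

    def mature_composition(self, end: int) -> dict[str, int]:
        """Elemental composition of the mature chain ending at ``end``,
        with complete Met oxidations and native disulfides (-2 H each)."""
        comp = peptide_composition(self.sequence[self.mature_start - 1 : end])
        if self.oxidized_met:
            n_ox = sum(1 for p in self.oxidized_met if self.mature_start <= p <= end)
            if n_ox:
                comp = combine(comp, {"O": n_ox})
        if self.n_disulfides:
            comp = combine(comp, {"H": -2 * self.n_disulfides})
        return comp


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal intensity noise + ppm m/z jitter.

    The intensity CV is a calibration chosen so that 3-replicate SDs of
    recovered proportions are of the order of the documented replicate
    SDs (a few percentage points on the major species).
    """

    intensity_cv: float = 0.12
    mz_jitter_ppm: float = 8.0
    mz_jitter_ppm_intact: float = 2.0
    rt_jitter_min: float = 0.8
    baseline: float = 0.0

    def zero(self) -> "NoiseModel":
        return NoiseModel(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class GroundTruthModel:
    """Complete ground truth from which synthetic runs are generated."""

    proteins: tuple[ProteinSpec, ...]
    #: positive-mode ionization response factor per glycan class
    ionization_bias: dict[str, float] = field(
        default_factory=lambda: {"sialylated": 0.5, "neutral": 1.0}
    )
    #: peptide-level response factor per C-terminal variant end (the
    #: ionization-bias reading of the intact-vs-peptide ratio discrepancy)
    cterm_peptide_bias: dict[int, float] = field(default_factory=dict)
    noise: NoiseModel = field(default_factory=NoiseModel)
    #: in-source glycan-loss fraction reaches this value at 400 V; the
    #: fraction is 0 at <=200 V and rises linearly above
    insource_max_fraction: float = 0.35
    base_intensity: float = 1.0e6

    def insource_decay_fraction(self, voltage: float) -> float:
        """Monotone in-source glycan-loss fraction; 0 at <= 200 V."""
        if not 150.0 <= voltage <= 400.0:
            raise ValueError("fragmentor voltage must lie in [150, 400] V")
        if voltage <= 200.0:
            return 0.0
        return self.insource_max_fraction * (voltage - 200.0) / 200.0

    def bias(self, glycan: GlycanStructure | None) -> float:
        if glycan is not None and glycan.neuac > 0:
            return self.ionization_bias.get("sialylated", 1.0)
        return self.ionization_bias.get("neutral", 1.0)

    def zero_noise(self) -> "GroundTruthModel":
        return replace(self, noise=self.noise.zero())


@dataclass(frozen=True)
class Feature:
    """One apex feature of a run; intensity stands for EIC area."""

    mz: float
    charge: int
    rt: float
    intensity: float
    species_id: str  # ground-truth provenance tag
    isotopes: IsotopePattern | None = None
    polarity: str = "+"


@dataclass(frozen=True)
class FragmentSpectrum:
    precursor_species: str
    precursor_mz: float
    precursor_charge: int
    mode: str  # "CID" | "ETD"
    peaks: tuple[tuple[float, float], ...]


@dataclass(frozen=True)
class SyntheticRun:
    level: str
    voltage: float
    seed: int
    features: tuple[Feature, ...]
    spectra: tuple[FragmentSpectrum, ...] = ()

    def feature_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mz": [f.mz for f in self.features],
                "charge": [f.charge for f in self.features],
                "rt_min": [f.rt for f in self.features],
                "intensity": [f.intensity for f in self.features],
                "polarity": [f.polarity for f in self.features],
                "species_id": [f.species_id for f in self.features],
            }
        )

    def write_features_csv(self, path: str | Path) -> None:
        self.feature_table().to_csv(path, index=False)

    def write_mgf(self, path: str | Path) -> None:
        """Write fragment spectra as MGF (via pyteomics)."""
        from pyteomics import mgf as _mgf

        entries = []
        for i, spec in enumerate(self.spectra):
            mz = np.array([m for m, _ in spec.peaks])
            inten = np.array([a for _, a in spec.peaks])
            entries.append(
                {
                    "m/z array": mz,
                    "intensity array": inten,
                    "params": {
                        "title": f"{spec.mode}.{i}.{spec.precursor_species}",
                        "pepmass": spec.precursor_mz,
                        "charge": spec.precursor_charge,
                    },
                }
            )
        _mgf.write(entries, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# default ground truth: the documented nCG profiles

#: Asn71 glycoform ground truth: the five major species at their printed
#: relative abundances plus trace species (normalized internally).
NCG_ASN71_RAW = {
    "GlcNAcb": 55.2,
    "Fuca1,6GlcNAcb": 22.7,
    "M1": 10.6,
    "M1F": 7.9,
    "M2": 3.7,
    "M2F": 0.1,
    "tri-mono-F-a2,6-SA": 0.04,
    "tri-mono-F-a2,3-SA": 0.04,
    "tri-mono-a2,6-SA": 0.04,
    "bi-mono-F-a2,6-SA": 0.04,
    "bi-mono-F-a2,3-SA": 0.04,
}

#: M2F-dominated contaminant site distributions. The released glycome is
#: site-unspecific, so the minor glycome-only species (M0F, M3F, sialylated)
#: are attributed to the highly accessible contaminant sites.
AZUROCIDIN_SITE_RAW = {
    "M2F": 70.0, "M1F": 10.0, "M3F": 6.0, "M0F": 6.0,
    "tri-mono-F-a2,6-SA": 2.0, "tri-mono-F-a2,3-SA": 2.0,
    "tri-mono-a2,6-SA": 2.0, "bi-mono-F-a2,6-SA": 1.0, "bi-mono-F-a2,3-SA": 1.0,
}
NE_SITE_RAW = {
    "M2F": 78.0, "M1F": 6.0, "M3F": 4.0, "M0F": 4.0,
    "tri-mono-F-a2,6-SA": 2.0, "tri-mono-F-a2,3-SA": 2.0,
    "tri-mono-a2,6-SA": 2.0, "bi-mono-F-a2,6-SA": 1.0, "bi-mono-F-a2,3-SA": 1.0,
}


def _normalized(raw: dict[str, float]) -> dict[str, float]:
    total = sum(raw.values())
    return {k: v / total for k, v in raw.items()}


def default_ncg_model(
    occupancy: float = 1.0,
    include_contaminants: bool = True,
    noise: NoiseModel | None = None,
) -> GroundTruthModel:
    """The default ground truth: the documented nCG profiles.

    Cathepsin G carries the Asn71 five-major-glycoform distribution
    (GlcNAcβ 55.2 : Fucα1,6GlcNAcβ 22.7 : M1 10.6 : M1F 7.9 : M2 3.7 plus
    traces), fully occupied Asn71, complete Met152 oxidation, three
    disulfides, and C-terminal variants Arg243/Ser244 at the intact-level
    61.9/38.1 ratio; the default peptide-level response factors reproduce
    the observed 57.8/42.2 reporter-peptide ratio. Azurocidin and NE
    contaminants carry M2F-dominant glycoforms on their two sites each.
    """
    ncg = ProteinSpec(
        name="NCG",
        sequence=bundled_sequence(NCG),
        mature_start=21,
        cterm_variants={243: 0.619, 244: 0.381},
        sites=(GlycoSite(71, _normalized(NCG_ASN71_RAW), occupancy=occupancy),),
        abundance=0.5 if include_contaminants else 1.0,
        oxidized_met=(152,),
        deamidated=(163, 208),
        n_disulfides=3,
    )
    proteins = [ncg]
    if include_contaminants:
        azu = ProteinSpec(
            name="AZU",
            sequence=bundled_sequence(AZUROCIDIN),
            mature_start=27,
            cterm_variants={251: 1.0},
            sites=(
                GlycoSite(126, _normalized(AZUROCIDIN_SITE_RAW)),
                GlycoSite(171, _normalized(AZUROCIDIN_SITE_RAW)),
            ),
            abundance=0.3,
            include_in_intact=False,
        )
        ne = ProteinSpec(
            name="NE",
            sequence=bundled_sequence(NE),
            mature_start=30,
            cterm_variants={267: 1.0},
            sites=(
                GlycoSite(124, _normalized(NE_SITE_RAW)),
                GlycoSite(173, _normalized(NE_SITE_RAW)),
            ),
            abundance=0.3,
            include_in_intact=False,
        )
        proteins += [azu, ne]
    # peptide-level reporter response factors chosen so that the observed
    # IRTTMR:IRTTMRS EIC ratio is 57.8:42.2 given the 61.9:38.1 molecular
    # ratio (the ionization-bias reading of the level discrepancy)
    bias_244 = (42.2 / 57.8) / (0.381 / 0.619)
    return GroundTruthModel(
        proteins=tuple(proteins),
        cterm_peptide_bias={243: 1.0, 244: bias_244},
        noise=noise if noise is not None else NoiseModel(),
    )


# ---------------------------------------------------------------------------
# simulation


def _noisy_intensity(rng: np.random.Generator, base: float, cv: float) -> float:
    if cv <= 0:
        return base
    sigma = np.sqrt(np.log(1.0 + cv * cv))
    return float(base * rng.lognormal(-0.5 * sigma * sigma, sigma))


def _jitter_mz(rng: np.random.Generator, mz: float, ppm: float) -> float:
    if ppm <= 0:
        return mz
    return float(mz * (1.0 + rng.normal(0.0, ppm * 1e-6)))


def _emit(
    rng: np.random.Generator,
    model: GroundTruthModel,
    mass: float,
    charges: dict[int, float],
    polarity: str,
    rt_mean: float,
    weight: float,
    species_id: str,
    jitter_ppm: float,
    isotopes: IsotopePattern | None = None,
) -> list[Feature]:
    rt = rt_mean + (
        rng.normal(0.0, model.noise.rt_jitter_min) if model.noise.rt_jitter_min else 0.0
    )
    feats = []
    for z, frac in charges.items():
        inten = _noisy_intensity(
            rng, model.base_intensity * weight * frac, model.noise.intensity_cv
        )
        if inten <= 0:
            continue
        feats.append(
            Feature(
                mz=_jitter_mz(rng, to_mz(mass, z, polarity), jitter_ppm),
                charge=z,
                rt=float(rt),
                intensity=inten,
                species_id=species_id,
                isotopes=isotopes,
                polarity=polarity,
            )
        )
    return feats


def _glycome_features(
    rng: np.random.Generator, model: GroundTruthModel
) -> list[Feature]:
    """Released-glycan alditol features: PNGase-F-releasable species only."""
    weights: dict[str, float] = {}
    for prot in model.proteins:
        for site in prot.sites:
            for gname, prop in site.glycoforms.items():
                g = by_name(gname)
                if not pngase_releases(g):
                    continue
                w = prot.abundance * site.occupancy * prop
                weights[gname] = weights.get(gname, 0.0) + w
    feats: list[Feature] = []
    for gname, w in sorted(weights.items()):
        g = by_name(gname)
        mass = glycan_mass(g.composition, "reduced-alditol").monoisotopic
        feats.extend(
            _emit(
                rng, model, mass, GLYCOME_CHARGES, "-",
                RT_DEFAULTS["glycome"], w, f"glycome|{gname}",
                model.noise.mz_jitter_ppm,
            )
        )
    return feats


def _glycopeptide_species(
    model: GroundTruthModel,
) -> list[tuple[PeptideSpecies, float, str, float]]:
    """(species, weight, kind, rt_mean) tuples for the glycopeptide level."""
    out = []
    for prot in model.proteins:
        kind = "site-glycopeptide" if prot.name == "NCG" else "contaminant-glycopeptide"
        for site in prot.sites:
            base = site_peptide(prot.sequence, site.position, prot.name)
            for gname, prop in site.glycoforms.items():
                g = by_name(gname)
                w = prot.abundance * site.occupancy * prop * model.bias(g)
                out.append((replace(base, glycan=g), w, kind, RT_DEFAULTS[kind]))
            if site.occupancy < 1.0:
                w = prot.abundance * (1.0 - site.occupancy)
                out.append((base, w, kind, RT_DEFAULTS[kind]))
        if len(prot.cterm_variants) > 1:
            for end, prop in prot.cterm_variants.items():
                rep = cterm_reporter_peptide(prot.sequence, end, prot.name)
                w = (
                    prot.abundance
                    * prop
                    * model.cterm_peptide_bias.get(end, 1.0)
                )
                out.append((rep, w, "cterm-peptide", RT_DEFAULTS["cterm-peptide"]))
    return out


def _fragment_spectra(
    rng: np.random.Generator,
    model: GroundTruthModel,
    species: list[tuple[PeptideSpecies, float, str, float]],
) -> list[FragmentSpectrum]:
    """CID + ETD spectra for each glycopeptide precursor (z=2)."""
    spectra = []
    for pep, w, kind, _rt in species:
        if pep.glycan is None:
            continue
        z = 2
        pre_mz = pep.mz(z)
        for mode in ("CID", "ETD"):
            ions = theoretical_fragments(pep, mode, max_charge=max(z - 1, 1))
            peaks = tuple(
                sorted(
                    (
                        _jitter_mz(rng, ion.mz, model.noise.mz_jitter_ppm),
                        _noisy_intensity(rng, 100.0, model.noise.intensity_cv),
                    )
                    for ion in ions
                )
            )
            spectra.append(
                FragmentSpectrum(pep.species_id, pre_mz, z, mode, peaks)
            )
    return spectra


def _glycopeptide_features(
    rng: np.random.Generator, model: GroundTruthModel
) -> tuple[list[Feature], list[FragmentSpectrum]]:
    species = _glycopeptide_species(model)
    feats: list[Feature] = []
    for pep, w, kind, rt_mean in species:
        feats.extend(
            _emit(
                rng, model, pep.neutral_mass(), GLYCOPEPTIDE_CHARGES, "+",
                rt_mean, w, pep.species_id, model.noise.mz_jitter_ppm,
            )
        )
    spectra = _fragment_spectra(rng, model, species)
    return feats, spectra


def intact_proteoform_id(
    protein: str, end: int, glycan: str | None, insource: bool = False
) -> str:
    tag = glycan if glycan else "aglycosylated"
    src = "insource|" if insource else ""
    return f"intact|{src}{protein}|end={end}|{tag}"


def _intact_features(
    rng: np.random.Generator,
    model: GroundTruthModel,
    voltage: float,
    with_isotopes: bool = True,
) -> list[Feature]:
    decay = model.insource_decay_fraction(voltage)
    feats: list[Feature] = []
    for prot in model.proteins:
        if not prot.include_in_intact:
            continue
        site = prot.sites[0] if prot.sites else None
        for end, vprop in prot.cterm_variants.items():
            base_comp = prot.mature_composition(end)
            glycoforms: list[tuple[str | None, float, bool]] = []
            if site is not None:
                for gname, gprop in site.glycoforms.items():
                    g = by_name(gname)
                    w = vprop * site.occupancy * gprop * model.bias(g)
                    glycoforms.append((gname, w * (1.0 - decay), False))
                if site.occupancy < 1.0:
                    glycoforms.append((None, vprop * (1.0 - site.occupancy), False))
                lost = vprop * site.occupancy * decay
                if lost > 0:
                    glycoforms.append((None, lost, True))
            else:
                glycoforms.append((None, vprop, False))
            # merge aglycosylated contributions by provenance tag
            for gname, w, insource in glycoforms:
                if w <= 0:
                    continue
                comp = (
                    combine(base_comp, glycan_composition(by_name(gname).composition))
                    if gname
                    else base_comp
                )
                mass = composition_mass(comp).average
                iso = isotope_pattern(comp) if with_isotopes else None
                feats.extend(
                    _emit(
                        rng, model, mass, INTACT_CHARGES, "+",
                        RT_DEFAULTS["intact"],
                        prot.abundance * w,
                        intact_proteoform_id(prot.name, end, gname, insource),
                        model.noise.mz_jitter_ppm_intact,
                        isotopes=iso,
                    )
                )
    return feats


def simulate_run(
    model: GroundTruthModel,
    level: str,
    seed: int,
    fragmentor_voltage: float = 200.0,
    with_isotopes: bool = True,
) -> SyntheticRun:
    """Generate one synthetic LC-MS run at the requested analyte level.

    The same seed yields a byte-identical run. The fragmentor voltage
    controls in-source glycan loss at the intact level (none at <= 200 V);
    voltages outside the instrument's 150-400 V range are rejected.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    model.insource_decay_fraction(fragmentor_voltage)  # validates range
    rng = np.random.default_rng(seed)
    spectra: tuple[FragmentSpectrum, ...] = ()
    if level == "glycome":
        feats = _glycome_features(rng, model)
    elif level == "glycopeptide":
        flist, slist = _glycopeptide_features(rng, model)
        feats, spectra = flist, tuple(slist)
    else:
        feats = _intact_features(rng, model, fragmentor_voltage, with_isotopes)
    return SyntheticRun(
        level=level,
        voltage=fragmentor_voltage,
        seed=seed,
        features=tuple(feats),
        spectra=spectra,
    )


def digest_model(model: GroundTruthModel, rule) -> GroundTruthModel:
    """Ground truth after an in-silico exoglycosidase digest of the released
    glycans: every site glycoform is replaced by its digestion product.

    Products falling outside the default panel (e.g. desialylated
    monoantennary species) keep their transformed structure name; paired
    untreated/treated glycome runs simulated from the original and digested
    models drive the differential re-assignment used to resolve linkage
    isomers.
    """
    from .glycans import apply_exoglycosidase

    new_proteins = []
    for prot in model.proteins:
        new_sites = []
        for site in prot.sites:
            merged: dict[str, float] = {}
            for gname, prop in site.glycoforms.items():
                product = apply_exoglycosidase(by_name(gname), rule)
                merged[product.name] = merged.get(product.name, 0.0) + prop
            new_sites.append(
                GlycoSite(site.position, merged, occupancy=site.occupancy)
            )
        new_proteins.append(replace(prot, sites=tuple(new_sites)))
    return replace(model, proteins=tuple(new_proteins))


def simulate_replicates(
    model: GroundTruthModel,
    level: str,
    seeds: Sequence[int],
    fragmentor_voltage: float = 200.0,
    with_isotopes: bool = True,
) -> list[SyntheticRun]:
    """Technical replicates: one run per seed."""
    return [
        simulate_run(model, level, s, fragmentor_voltage, with_isotopes)
        for s in seeds
    ]
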