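"""The constrained truncated N-glycan structure space of human neutrophil
azurophilic-granule glycoproteins, and its enzymatic transformation rules.

The space covers three classes observed on these proteins:

* chitobiose stubs — GlcNAc1-2(Fuc0-1) remnants on Asn (GlcNAcβ,
  Fucα1,6GlcNAcβ, M0F);
* paucimannose — GlcNAc2 Man1-3 Fuc0-1 (M1, M1F, M2, M2F, M3F, short-name
  grammar M{0-3}{F?}, M = mannosylated chitobiose core, F = α1,6 core
  fucose);
* monoantennary complex — a single GlcNAc antenna on a bi- or trimannosyl
  chitobiose core, optionally core-fucosylated and α2,3- or α2,6-sialylated.

Structures are modelled as monosaccharide composition plus flat linkage
annotations (core fucose, mannose arms, sialyl linkage) — the discriminating
evidence at every stage (mass, retention class, exoglycosidase response)
never requires deeper topology.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .masscalc import MassValue, glycan_mass

__all__ = [
    "GlycanStructure",
    "EnzymeRule",
    "BROAD_SIALIDASE",
    "A23_SIALIDASE",
    "JBM_MANNOSIDASE",
    "ENZYMES",
    "enumerate_panel",
    "stub_panel",
    "full_panel",
    "apply_exoglycosidase",
    "pngase_releases",
    "isomer_groups",
    "zic_hilic_retained",
    "import_panel_csv",
    "export_panel_csv",
]

CLASSES = ("chitobiose-stub", "paucimannose", "monoantennary-complex")


@dataclass(frozen=True)
class GlycanStructure:
    """One N-glycan: composition + class + flat linkage annotations."""

    name: str
    hex: int
    hexnac: int
    dhex: int
    neuac: int
    cls: str
    core_fucose: bool = False
    #: mannose arm linkages beyond the β-Man core, e.g. ("a1,6",)
    arms: tuple[str, ...] = ()
    #: "a2,3" | "a2,6" | None
    sialyl_linkage: str | None = None

    def __post_init__(self) -> None:
        if self.cls not in CLASSES:
            raise ValueError(f"unknown glycan class {self.cls!r}")
        if not 0 <= self.dhex <= 1:
            raise ValueError("dHex count must be 0 or 1")
        if self.cls == "chitobiose-stub" and not (
            self.hexnac in (1, 2) and self.hex == 0 and self.neuac == 0
        ):
            raise ValueError(f"invalid chitobiose stub composition: {self.name}")
        if self.cls == "paucimannose" and not (
            self.hexnac == 2 and 1 <= self.hex <= 3 and self.neuac == 0
        ):
            raise ValueError(f"invalid paucimannose composition: {self.name}")
        if self.cls == "monoantennary-complex" and not (
            self.hexnac == 3 and self.hex in (3, 4) and self.neuac in (0, 1)
        ):
            raise ValueError(f"invalid monoantennary composition: {self.name}")
        if self.core_fucose != (self.dhex == 1):
            raise ValueError("core_fucose flag must mirror the dHex count")

    @property
    def composition(self) -> dict[str, int]:
        return {
            "Hex": self.hex,
            "HexNAc": self.hexnac,
            "dHex": self.dhex,
            "NeuAc": self.neuac,
        }

    @property
    def composition_key(self) -> tuple[int, int, int, int]:
        return (self.hex, self.hexnac, self.dhex, self.neuac)

    def mass(self, form: str = "glycosidically-bound") -> MassValue:
        return glycan_mass(self.composition, form)


@dataclass(frozen=True)
class EnzymeRule:
    """Exoglycosidase specificity: which terminal linkages are cleaved.

    ``preference`` orders linkages from most to least preferred; cleavage is
    exhaustive within the digest but honours the ordering when only a subset
    of residues is removable.
    """

    name: str
    residue: str  # "NeuAc" | "Hex"
    linkages: tuple[str, ...]
    preference: tuple[str, ...] = ()


BROAD_SIALIDASE = EnzymeRule(
    "a2-3/6/8-sialidase", "NeuAc", ("a2,3", "a2,6", "a2,8")
)
A23_SIALIDASE = EnzymeRule("a2,3-sialidase", "NeuAc", ("a2,3",))
JBM_MANNOSIDASE = EnzymeRule(
    "jack-bean-a-mannosidase",
    "Hex",
    ("a1,2", "a1,3", "a1,6"),
    preference=("a1,2", "a1,3", "a1,6"),
)
ENZYMES = {e.name: e for e in (BROAD_SIALIDASE, A23_SIALIDASE, JBM_MANNOSIDASE)}


def _stub(name: str, hexnac: int, dhex: int) -> GlycanStructure:
    return GlycanStructure(
        name, 0, hexnac, dhex, 0, "chitobiose-stub", core_fucose=bool(dhex)
    )


def _pauci(name: str, hexn: int, dhex: int, arms: tuple[str, ...]) -> GlycanStructure:
    return GlycanStructure(
        name, hexn, 2, dhex, 0, "paucimannose", core_fucose=bool(dhex), arms=arms
    )


def _mono(name: str, hexn: int, dhex: int, sialyl: str | None) -> GlycanStructure:
    arms = ("a1,3", "a1,6") if hexn == 4 else ("a1,3",)
    return GlycanStructure(
        name,
        hexn,
        3,
        dhex,
        1 if sialyl else 0,
        "monoantennary-complex",
        core_fucose=bool(dhex),
        arms=arms,
        sialyl_linkage=sialyl,
    )


#: PNGase-F-resistant Asn-linked stubs, seen only at the (glyco)peptide and
#: intact levels.
GLCNAC = _stub("GlcNAcb", 1, 0)
FUC_GLCNAC = _stub("Fuca1,6GlcNAcb", 1, 1)

#: The 11-structure released-glycome panel: M0F, five paucimannose
#: structures (the a1,3-arm isomers of M2/M2F are absent from the human
#: neutrophil panel), and five monoantennary sialylated variants.
_GLYCOME_PANEL: tuple[GlycanStructure, ...] = (
    _stub("M0F", 2, 1),
    _pauci("M1", 1, 0, ()),
    _pauci("M1F", 1, 1, ()),
    _pauci("M2", 2, 0, ("a1,6",)),
    _pauci("M2F", 2, 1, ("a1,6",)),
    _pauci("M3F", 3, 1, ("a1,3", "a1,6")),
    _mono("tri-mono-F-a2,6-SA", 4, 1, "a2,6"),
    _mono("tri-mono-F-a2,3-SA", 4, 1, "a2,3"),
    _mono("tri-mono-a2,6-SA", 4, 0, "a2,6"),
    _mono("bi-mono-F-a2,6-SA", 3, 1, "a2,6"),
    _mono("bi-mono-F-a2,3-SA", 3, 1, "a2,3"),
)


def enumerate_panel(
    include_stubs: bool = False,
    classes: Iterable[str] = CLASSES,
) -> tuple[GlycanStructure, ...]:
    """The default glycan panel, deterministically ordered by (class, mass).

    With the default configuration this is exactly the 11-structure released
    glycome; ``include_stubs`` adds the two PNGase-F-resistant Asn-linked
    stubs (GlcNAcβ, Fucα1,6GlcNAcβ) needed for peptide-level work.
    """
    classes = set(classes)
    panel = [g for g in _GLYCOME_PANEL if g.cls in classes]
    if include_stubs and "chitobiose-stub" in classes:
        panel += [GLCNAC, FUC_GLCNAC]
    order = {c: i for i, c in enumerate(CLASSES)}
    panel.sort(key=lambda g: (order[g.cls], g.mass().monoisotopic, g.name))
    return tuple(panel)


def stub_panel() -> tuple[GlycanStructure, ...]:
    return (GLCNAC, FUC_GLCNAC)


def full_panel() -> tuple[GlycanStructure, ...]:
    """Glycome panel plus Asn-linked stubs (13 structures)."""
    return enumerate_panel(include_stubs=True)


#: Structures produced by in-silico digestion, registered on creation so
#: they stay resolvable by name alongside the fixed panel.
_DERIVED: dict[str, GlycanStructure] = {}


def by_name(name: str) -> GlycanStructure:
    for g in full_panel():
        if g.name == name:
            return g
    if name in _DERIVED:
        return _DERIVED[name]
    raise KeyError(name)


def apply_exoglycosidase(g: GlycanStructure, rule: EnzymeRule) -> GlycanStructure:
    """Exhaustive in-silico exoglycosidase digest of one structure.

    Sialidases remove NeuAc whose annotated linkage the enzyme cleaves;
    α-mannosidase removes terminal α-linked Man (arm annotations), honouring
    its preference ordering, but never the β-Man core. Applying the rule to
    its own product is a no-op (fixed point).
    """
    if rule.residue == "NeuAc":
        if g.neuac and g.sialyl_linkage in rule.linkages:
            # desialylated monoantennary keeps its composition class
            product = replace(g, neuac=0, sialyl_linkage=None, name=g.name + "-deSA")
            _DERIVED[product.name] = product
            return product
        return g
    if rule.residue == "Hex":
        if g.neuac:
            return g  # capped antenna: no terminal Man exposed beyond arms
        removable = tuple(a for a in g.arms if a in rule.linkages)
        if not removable or g.cls != "paucimannose":
            return g
        new_hex = g.hex - len(removable)
        if new_hex < 1:
            return g  # β-Man core is never removed
        return replace(
            g, hex=new_hex, arms=(), name=f"M{new_hex}{'F' if g.dhex else ''}"
        )
    return g


def pngase_releases(g: GlycanStructure) -> bool:
    """Whether PNGase F releases this Asn-linked glycan from its peptide.

    Truncated chitobiose stubs with a single core GlcNAc (GlcNAcβ,
    Fucα1,6GlcNAcβ) resist PNGase F; anything with an intact chitobiose
    (HexNAc >= 2 at the core) is released.
    """
    return g.hexnac >= 2


def isomer_groups(
    panel: Sequence[GlycanStructure],
) -> dict[tuple[int, int, int, int], tuple[GlycanStructure, ...]]:
    """Group panel structures sharing a monosaccharide composition.

    Mass alone cannot distinguish members of a group (α2,3/α2,6 sialyl and
    arm isomers), so assignment reports isomer groups, not single structures.
    """
    groups: dict[tuple[int, int, int, int], list[GlycanStructure]] = {}
    for g in panel:
        groups.setdefault(g.composition_key, []).append(g)
    return {k: tuple(v) for k, v in groups.items()}


def group_label(structures: Sequence[GlycanStructure]) -> str:
    return "|".join(g.name for g in structures)


def zic_hilic_retained(g: GlycanStructure) -> bool:
    """Whether a glycopeptide carrying this glycan is retained on ZIC-HILIC
    SPE. Sialylated complex glycopeptides are retained; the lowly
    hydrophilic stub and paucimannosidic species elute in the non-retained
    fraction (an empirical label, not a retention model)."""
    return g.neuac > 0


def import_panel_csv(path: str | Path) -> tuple[GlycanStructure, ...]:
    """Read a glycan panel from the CSV layout written by export_panel_csv."""
    with Path(path).open() as fh:
        rows = list(csv.DictReader(fh))
    panel = []
    for row in rows:
        panel.append(
            GlycanStructure(
                name=row["name"],
                hex=int(row["Hex"]),
                hexnac=int(row["HexNAc"]),
                dhex=int(row["dHex"]),
                neuac=int(row["NeuAc"]),
                cls=row["class"],
                core_fucose=bool(int(row["core_fucose"])),
                arms=tuple(a for a in row["arms"].split(";") if a),
                sialyl_linkage=row["sialyl_linkage"] or None,
            )
        )
    return tuple(panel)


def export_panel_csv(panel: Sequence[GlycanStructure], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["name", "Hex", "HexNAc", "dHex", "NeuAc", "class", "core_fucose",
             "arms", "sialyl_linkage", "monoisotopic_da", "average_da"]
        )
        for g in panel:
            mv = g.mass()
            writer.writerow(
                [g.name, g.hex, g.hexnac, g.dhex, g.neuac, g.cls,
                 int(g.core_fucose), ";".join(g.arms), g.sialyl_linkage or "",
                 f"{mv.monoisotopic:.6f}", f"{mv.average:.6f}"]
            )
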