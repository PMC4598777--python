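"""Physical constants for mass spectrometry arithmetic.

All monoisotopic element masses and isotope abundances follow the IUPAC 2013
atomic-weight evaluation; the proton mass is the CODATA value. These are the
single source of truth for every mass computed in the package and can be
exported as a CSV table for audit (:func:`export_constants_csv`).
"""

from __future__ import annotations

import csv
from pathlib import Path

#: Proton mass in Da (charge carrier for ESI protonation/deprotonation).
PROTON = 1.007276467

#: Mass of a water molecule (monoisotopic), Da.
WATER_MONO = 18.0105646863

#: Mass of H2 (glycan reducing-end borohydride reduction adds 2 H), Da.
H2_MONO = 2.0156500638

#: Per-element isotope tables: symbol -> list of (mass Da, abundance).
#: The first entry is the lightest (monoisotopic) isotope.
ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "H": [(1.0078250319, 0.999885), (2.0141017780, 0.000115)],
    "C": [(12.0, 0.9893), (13.0033548378, 0.0107)],
    "N": [(14.0030740052, 0.99636), (15.0001088984, 0.00364)],
    "O": [(15.9949146221, 0.99757), (16.9991315, 0.00038), (17.9991604, 0.00205)],
    "S": [
        (31.97207069, 0.9499),
        (32.97145850, 0.0075),
        (33.96786683, 0.0425),
        (35.96708088, 0.0001),
    ],
}

#: Monoisotopic element masses, Da.
ELEMENT_MONO: dict[str, float] = {el: iso[0][0] for el, iso in ISOTOPES.items()}

#: Average (abundance-weighted) element masses, Da.
ELEMENT_AVG: dict[str, float] = {
    el: sum(m * a for m, a in iso) / sum(a for _, a in iso)
    for el, iso in ISOTOPES.items()
}

#: Amino-acid residue elemental compositions (residue = amino acid - water).
RESIDUE_FORMULAS: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

#: Monosaccharide residue elemental compositions (glycosidically bound,
#: i.e. dehydrated) for the four residue types used throughout.
GLYCAN_FORMULAS: dict[str, dict[str, int]] = {
    "Hex": {"C": 6, "H": 10, "O": 5},
    "HexNAc": {"C": 8, "H": 13, "N": 1, "O": 5},
    "dHex": {"C": 6, "H": 10, "O": 4},
    "NeuAc": {"C": 11, "H": 17, "N": 1, "O": 8},
}

#: Named fixed modifications: name -> (elemental delta, target residues).
#: carboxymethyl = iodoacetic-acid alkylation of Cys; oxidation targets Met;
#: deamidation converts Asn/Gln amides to the acid.
MODIFICATIONS: dict[str, tuple[dict[str, int], str]] = {
    "carboxymethyl": ({"C": 2, "H": 2, "O": 2}, "C"),
    "oxidation": ({"O": 1}, "M"),
    "deamidation": ({"H": -1, "N": -1, "O": 1}, "NQ"),
}


def export_constants_csv(path: str | Path) -> None:
    """Write the element/residue/monosaccharide constants to a CSV table."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["kind", "name", "monoisotopic_da", "average_da", "formula"])
        writer.writerow(["constant", "proton", f"{PROTON:.9f}", f"{PROTON:.9f}", ""])
        for el, iso in ISOTOPES.items():
            writer.writerow(
                ["element", el, f"{ELEMENT_MONO[el]:.9f}", f"{ELEMENT_AVG[el]:.9f}", ""]
            )
            for m, a in iso:
                writer.writerow(["isotope", el, f"{m:.9f}", f"{a:.6f}", ""])
        from .masscalc import composition_mass  # local import avoids a cycle

        for name, formula in {**RESIDUE_FORMULAS, **GLYCAN_FORMULAS}.items():
            mv = composition_mass(formula)
            formula_str = "".join(f"{el}{n}" for el, n in sorted(formula.items()))
            writer.writerow(
                ["residue", name, f"{mv.monoisotopic:.6f}", f"{mv.average:.6f}", formula_str]
            )
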