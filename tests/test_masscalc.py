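"""Mass arithmetic: residue sums, charge-state transforms, isotope patterns.

The isotope-pattern convolution is checked against an exhaustive
isotopologue enumeration oracle; peptide masses are cross-checked against
an independent implementation (pyteomics).
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pyt_mass

from glycoprofiler.constants import ISOTOPES, PROTON
from glycoprofiler.masscalc import (
    composition_mass,
    from_mz,
    glycan_composition,
    glycan_mass,
    isotope_pattern,
    peptide_composition,
    peptide_mass,
    to_mz,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestPeptideMass:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("IRTTMR", 776.4327),   # C-terminal reporter of the Arg243 variant
            ("GSNINVTL", 816.4341),  # the Asn71 glycosite peptide
        ],
    )
    def test_monoisotopic_values(self, seq, expected):
        assert peptide_mass(seq).monoisotopic == pytest.approx(expected, abs=1e-4)

    def test_serine_delta_rounds_to_87(self):
        delta = peptide_mass("IRTTMRS").monoisotopic - peptide_mass("IRTTMR").monoisotopic
        assert delta == pytest.approx(87.0320, abs=1e-4)
        assert round(delta) == 87

    def test_oxidation_delta_rounds_to_16(self):
        plain = peptide_mass("IRTTMR")
        ox = peptide_mass("IRTTMR", fixed_mods=["oxidation"])
        delta = ox.monoisotopic - plain.monoisotopic
        assert delta == pytest.approx(15.9949, abs=1e-4)
        assert round(delta) == 16

    def test_carboxymethyl_applies_per_cysteine(self):
        delta = (
            peptide_mass("ACDC", ["carboxymethyl"]).monoisotopic
            - peptide_mass("ACDC").monoisotopic
        )
        assert delta == pytest.approx(2 * 58.005479, abs=1e-4)

    def test_unknown_residue_reports_position(self):
        with pytest.raises(ValueError, match="position 3"):
            peptide_mass("GSXNV")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            peptide_mass("")

    @given(st.text(alphabet=AA, min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_agrees_with_independent_calculator(self, seq):
        ours = peptide_mass(seq).monoisotopic
        theirs = pyt_mass.fast_mass(seq)
        assert ours == pytest.approx(theirs, abs=5e-3)

    @given(st.text(alphabet=AA, min_size=1, max_size=25))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_average_at_least_monoisotopic(self, seq):
        mv = peptide_mass(seq)
        assert mv.average >= mv.monoisotopic


class TestGlycanMass:
    def test_hexnac_alditol(self):
        mv = glycan_mass({"HexNAc": 1}, "reduced-alditol")
        assert mv.monoisotopic == pytest.approx(223.1056, abs=1e-4)

    def test_m2f_alditol(self):
        mv = glycan_mass({"Hex": 2, "HexNAc": 2, "dHex": 1}, "reduced-alditol")
        assert mv.monoisotopic == pytest.approx(896.3485, abs=1e-4)

    def test_bound_glycan_additivity_exact(self):
        pep = peptide_composition("GSNINVTL")
        gly = glycan_composition({"HexNAc": 1})
        combined = composition_mass({el: pep.get(el, 0) + gly.get(el, 0) for el in set(pep) | set(gly)})
        expected = peptide_mass("GSNINVTL").monoisotopic + glycan_mass({"HexNAc": 1}).monoisotopic
        assert combined.monoisotopic == pytest.approx(expected, abs=1e-9)
        assert combined.monoisotopic == pytest.approx(1019.5135, abs=1e-4)

    def test_empty_composition_rejected(self):
        with pytest.raises(ValueError):
            glycan_mass({"Hex": 0})


class TestMz:
    def test_single_proton_adduct(self):
        assert to_mz(1000.0, 1, "+") == pytest.approx(1001.0073, abs=1e-4)

    def test_glycopeptide_doubly_charged(self):
        assert to_mz(1019.5135, 2, "+") == pytest.approx(510.7640, abs=1e-4)

    def test_deprotonated_alditol(self):
        assert to_mz(896.3485, 1, "-") == pytest.approx(895.3412, abs=1e-4)

    def test_zero_charge_rejected(self):
        with pytest.raises(ValueError):
            to_mz(1000.0, 0)

    @given(
        st.floats(min_value=100.0, max_value=50000.0),
        st.integers(min_value=1, max_value=30),
        st.sampled_from(["+", "-"]),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_round_trip_identity(self, mass, z, pol):
        assert from_mz(to_mz(mass, z, pol), z, pol) == pytest.approx(mass, abs=1e-9)


def enumerate_isotopologues(comp):
    """Brute-force oracle: exact nominal-bin isotope distribution by
    enumerating per-element isotope count vectors (multinomial weights)."""

    def element_vectors(el, n):
        iso = ISOTOPES[el]
        out = {}
        for counts in itertools.product(range(n + 1), repeat=len(iso) - 1):
            rest = n - sum(counts)
            if rest < 0:
                continue
            vec = (rest,) + counts
            weight = math.factorial(n)
            prob = 1.0
            for k, (m, a) in zip(vec, iso):
                weight //= math.factorial(k)
                prob *= a**k
            mass = sum(k * m for k, (m, _) in zip(vec, iso))
            out[vec] = (weight * prob, mass)
        return list(out.values())

    dists = [element_vectors(el, n) for el, n in comp.items()]
    bins = {}
    base = sum(ISOTOPES[el][0][0] * n for el, n in comp.items())
    for combo in itertools.product(*dists):
        prob = math.prod(p for p, _ in combo)
        mass = sum(m for _, m in combo)
        k = round(mass - base)
        a, msum = bins.get(k, (0.0, 0.0))
        bins[k] = (a + prob, msum + prob * mass)
    return {k: (a, msum / a) for k, (a, msum) in sorted(bins.items()) if a > 0}


class TestIsotopePattern:
    def test_methane_carbon13_ratio(self):
        pat = isotope_pattern({"C": 1, "H": 4})
        ratio = pat.abundances[1] / pat.abundances[0]
        # dominated by natural 13C/12C (~1.08%), slightly raised by 2H
        assert ratio == pytest.approx(0.0107 / 0.9893, rel=0.05)

    def test_abundances_sum_to_one(self):
        pat = isotope_pattern({"C": 50, "H": 80, "N": 10, "O": 20, "S": 2})
        assert pat.abundances.sum() == pytest.approx(1.0, abs=1e-9)

    def test_peak_spacing_near_neutron_mass(self):
        pat = isotope_pattern({"C": 100, "H": 160, "N": 20, "O": 40})
        spacings = np.diff(pat.masses)
        assert np.all(np.abs(spacings - 1.0034) < 0.01)

    @pytest.mark.parametrize(
        "comp",
        [
            {"C": 1, "H": 4},
            {"C": 6, "H": 12, "O": 6},
            {"C": 10, "H": 15, "N": 3, "O": 4, "S": 1},
        ],
    )
    def test_convolution_matches_enumeration_oracle(self, comp):
        pat = isotope_pattern(comp, coverage=1.0 - 1e-12)
        oracle = enumerate_isotopologues(comp)
        total = sum(a for a, _ in oracle.values())
        for (mass, abund), (k, (oa, om)) in zip(pat.peaks, oracle.items()):
            assert abund == pytest.approx(oa / total, abs=1e-10)
            assert mass == pytest.approx(om, abs=1e-6)

    def test_masses_strictly_increasing(self):
        pat = isotope_pattern({"C": 30, "H": 50, "N": 5, "O": 10, "S": 1})
        assert np.all(np.diff(pat.masses) > 0)


def test_constants_export_table(tmp_path):
    """The audit CSV carries every element, isotope, and residue constant."""
    import csv

    from glycoprofiler.constants import export_constants_csv

    path = tmp_path / "constants.csv"
    export_constants_csv(path)
    with path.open() as fh:
        rows = list(csv.DictReader(fh))
    kinds = {r["kind"] for r in rows}
    assert kinds == {"constant", "element", "isotope", "residue"}
    residues = {r["name"] for r in rows if r["kind"] == "residue"}
    assert len(residues) == 24  # 20 amino acids + 4 monosaccharides
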