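"""Chymotryptic digestion, CID/ETD fragments, spectrum matching, and
site-specific EIC quantitation."""

import random
from dataclasses import replace

import numpy as np
import pytest
from pyteomics import mass as pyt_mass

from glycoprofiler import simulate
from glycoprofiler.glycans import by_name, full_panel
from glycoprofiler.glycopeptides import (
    PeptideSpecies,
    cterm_ratio,
    cterm_reporter_peptide,
    digest,
    match_spectra,
    site_peptide,
    site_profile,
    theoretical_fragments,
)
from glycoprofiler.sequences import NCG, bundled_sequence


@pytest.fixture(scope="module")
def ncg_seq():
    return bundled_sequence(NCG)


class TestDigest:
    def test_full_digest_contains_site_peptide(self, ncg_seq):
        peps = {p.sequence for p in digest(ncg_seq, "NCG", "full")}
        assert "GSNINVTL" in peps

    def test_site_peptide_covers_asn71(self, ncg_seq):
        p = site_peptide(ncg_seq, 71, "NCG")
        assert p.sequence == "GSNINVTL"
        assert (p.start, p.end) == (67, 74)
        assert p.site_index == 4  # the second Asn of GSNINVTL

    def test_cterminal_reporters(self, ncg_seq):
        assert cterm_reporter_peptide(ncg_seq, 243).sequence == "IRTTMR"
        assert cterm_reporter_peptide(ncg_seq, 244).sequence == "IRTTMRS"

    def test_semi_specific_yields_gsninv(self, ncg_seq):
        peps = {p.sequence for p in digest(ncg_seq, "NCG", "semi")}
        assert "GSNINV" in peps

    def test_full_zero_missed_cleavage_tiles_protein(self, ncg_seq):
        peps = [
            p
            for p in digest(ncg_seq, "NCG", "full", missed_cleavages=0, min_length=1)
            if p.glycosite in (None, 71)
        ]
        seen = sorted(peps, key=lambda p: p.start)
        assert seen[0].start == 1 and seen[-1].end == len(ncg_seq)
        for a, b in zip(seen, seen[1:]):
            assert b.start == a.end + 1  # contiguous, no overlap

    def test_no_cleavage_before_proline(self, ncg_seq):
        for p in digest(ncg_seq, "NCG", "full", missed_cleavages=0, min_length=1):
            if p.end < len(ncg_seq):
                assert ncg_seq[p.end] != "P"

    def test_negative_missed_cleavages_rejected(self, ncg_seq):
        with pytest.raises(ValueError):
            digest(ncg_seq, missed_cleavages=-1)

    def test_glycosite_outside_span_rejected(self):
        with pytest.raises(ValueError):
            PeptideSpecies("x", "GSNINVTL", 67, 74, glycosite=80)


class TestFragments:
    def test_cid_y_ladder_of_glcnac_glycopeptide(self, ncg_seq):
        p = replace(site_peptide(ncg_seq, 71, "NCG"), glycan=by_name("GlcNAcb"))
        ions = {i.name: i for i in theoretical_fragments(p, "CID", max_charge=1)}
        assert ions["Y0"].mz == pytest.approx(817.441, abs=1e-3)
        assert ions["Y1"].mz == pytest.approx(1020.521, abs=1e-3)

    def test_plain_peptide_has_no_glycan_ladder(self, ncg_seq):
        p = site_peptide(ncg_seq, 71, "NCG")
        series = {i.series for i in theoretical_fragments(p, "CID")}
        assert series == {"b", "y"}

    def test_etd_fragments_shift_by_glycan_when_spanning_site(self, ncg_seq):
        base = site_peptide(ncg_seq, 71, "NCG")
        glyco = replace(base, glycan=by_name("GlcNAcb"))
        plain = {
            (i.name, i.charge): i.mz for i in theoretical_fragments(base, "ETD")
        }
        shift = 203.079373
        for ion in theoretical_fragments(glyco, "ETD", max_charge=1):
            i = int(ion.name[1:])
            contains_site = (
                i - 1 >= glyco.site_index
                if ion.series == "c"
                else len(glyco.sequence) - i <= glyco.site_index
            )
            expected = plain[(ion.name, 1)] + (shift if contains_site else 0.0)
            assert ion.mz == pytest.approx(expected, abs=1e-6)

    def test_etd_complementarity(self, ncg_seq):
        """Every c_i / z_(n-i) pair sums to precursor neutral + 2 protons."""
        p = replace(site_peptide(ncg_seq, 71, "NCG"), glycan=by_name("M2F"))
        precursor = p.neutral_mass()
        ions = {
            (i.name, i.charge): i.mz
            for i in theoretical_fragments(p, "ETD", max_charge=1)
        }
        n = len(p.sequence)
        for i in range(1, n):
            total = ions[(f"c{i}", 1)] + ions[(f"z{n - i}", 1)]
            assert total == pytest.approx(precursor + 2 * 1.007276467, abs=1e-6)

    def test_backbone_ions_match_independent_calculator(self, ncg_seq):
        p = site_peptide(ncg_seq, 71, "NCG")
        seq = p.sequence
        ours = {
            (i.name): i.mz
            for i in theoretical_fragments(p, "CID", max_charge=1)
            if i.series in "by"
        }
        for i in range(1, len(seq)):
            assert ours[f"b{i}"] == pytest.approx(
                pyt_mass.fast_mass(seq[:i], ion_type="b", charge=1), abs=5e-3
            )
            assert ours[f"y{len(seq) - i}"] == pytest.approx(
                pyt_mass.fast_mass(seq[i:], ion_type="y", charge=1), abs=5e-3
            )


@pytest.fixture(scope="module")
def run(zero_noise_model):
    return simulate.simulate_run(zero_noise_model, "glycopeptide", seed=5)


@pytest.fixture(scope="module")
def candidates(zero_noise_model):
    out = []
    for prot in zero_noise_model.proteins:
        for site in prot.sites:
            base = site_peptide(prot.sequence, site.position, prot.name)
            out.extend(replace(base, glycan=g) for g in full_panel())
    return out


class TestSpectrumMatching:
    def test_generator_round_trip_identifies_true_species(self, run, candidates):
        """Composition-level identification: sialyl-linkage isomers are
        isobaric with identical fragments and cannot be told apart."""
        matches = match_spectra(run, candidates)
        assert len(matches) == len(run.spectra)
        n_matched = n_correct = 0
        by_id = {c.species_id: c for c in candidates}
        for spec, m in zip(run.spectra, matches):
            if m.peptide is None:
                continue
            n_matched += 1
            true = by_id.get(spec.precursor_species)
            if (
                true is not None
                and m.peptide.sequence == true.sequence
                and m.peptide.glycan.composition_key == true.glycan.composition_key
            ):
                n_correct += 1
        assert n_matched > 0
        assert n_correct == n_matched

    def test_cid_spectrum_matches_y_ions(self, run, candidates):
        matches = match_spectra(run, candidates)
        cid = [m for m in matches if m.mode == "CID" and m.peptide is not None]
        assert any(
            {"Y0", "Y1"} <= {i.name for i in m.matched_ions} for m in cid
        )

    def test_etd_localizes_glycosite(self, run, candidates):
        matches = match_spectra(run, candidates)
        etd = [m for m in matches if m.mode == "ETD" and m.peptide is not None]
        ncg_etd = [m for m in etd if m.peptide.protein == "NCG"]
        assert ncg_etd
        assert all(m.localized_site == 71 for m in ncg_etd)

    def test_decoy_scores_fewer_ions_than_true_candidate(self, run, candidates):
        spec = next(s for s in run.spectra if "GlcNAcb|GSNINVTL" in s.precursor_species)
        true_cand = next(
            c
            for c in candidates
            if c.sequence == "GSNINVTL" and c.glycan and c.glycan.name == "GlcNAcb"
        )
        rng = random.Random(0)
        shuffled = "".join(rng.sample("GSNINVTL", 8))
        decoy = PeptideSpecies(
            "decoy", shuffled, 67, 74,
            glycosite=67 + shuffled.index("N"),
            glycan=by_name("GlcNAcb"), non_sequon=True,
        )
        sub = simulate.SyntheticRun("glycopeptide", 200.0, 0, (), (spec,))
        best_true = match_spectra(sub, [true_cand])[0]
        best_decoy = match_spectra(sub, [decoy], tol_ms1=5.0)[0]
        assert best_true.n_matched > best_decoy.n_matched


class TestSiteQuantitation:
    def test_zero_noise_profile_recovers_model_exactly(self, zero_noise_model):
        runs = simulate.simulate_replicates(zero_noise_model, "glycopeptide", [1])
        ncg = zero_noise_model.proteins[0]
        prof, occ, _ = site_profile(runs, ncg.sequence, 71, "NCG")
        site = ncg.sites[0]
        # expected = model proportions re-weighted by ionization bias,
        # aggregated over isobaric isomer groups (profile reporting unit)
        biased = {
            name: p * zero_noise_model.bias(by_name(name))
            for name, p in site.glycoforms.items()
        }
        total = sum(biased.values())
        for label in prof.means:
            expected = sum(biased.get(n, 0.0) for n in label.split("|"))
            assert prof[label] == pytest.approx(100.0 * expected / total, abs=1e-6)
        assert occ == 1.0

    def test_full_occupancy_reported_as_one_when_no_naked_peptide(self, default_model):
        runs = simulate.simulate_replicates(default_model, "glycopeptide", [11, 12, 13])
        ncg = default_model.proteins[0]
        naked = site_peptide(ncg.sequence, 71, "NCG")
        naked_ids = {naked.species_id}
        assert not any(f.species_id in naked_ids for r in runs for f in r.features)
        _, occ, _ = site_profile(runs, ncg.sequence, 71, "NCG")
        assert occ == 1.0

    def test_partial_occupancy_recovered(self):
        model = simulate.default_ncg_model(occupancy=0.8)
        runs = simulate.simulate_replicates(model, "glycopeptide", [21, 22, 23])
        ncg = model.proteins[0]
        _, occ, occ_sd = site_profile(runs, ncg.sequence, 71, "NCG")
        assert occ == pytest.approx(0.8, abs=max(2 * occ_sd, 0.04))

    def test_single_glycoform_model_gives_100_percent(self):
        model = simulate.default_ncg_model()
        ncg = model.proteins[0]
        single = replace(
            ncg, sites=(simulate.GlycoSite(71, {"GlcNAcb": 1.0}),)
        )
        m = replace(model, proteins=(single,))
        runs = simulate.simulate_replicates(m, "glycopeptide", [3])
        prof, _, _ = site_profile(runs, single.sequence, 71, "NCG")
        assert prof["GlcNAcb"] == pytest.approx(100.0)

    def test_unobserved_site_rejected(self, default_model):
        runs = simulate.simulate_replicates(default_model, "glycopeptide", [1])
        ncg = default_model.proteins[0]
        empty = simulate.SyntheticRun("glycopeptide", 200.0, 0, ())
        with pytest.raises(ValueError, match="Asn71"):
            site_profile([empty], ncg.sequence, 71, "NCG")

    def test_cterm_ratio_recovers_peptide_level_ground_truth(self, zero_noise_model):
        runs = simulate.simulate_replicates(zero_noise_model, "glycopeptide", [1])
        ncg = zero_noise_model.proteins[0]
        prof = cterm_ratio(runs, ncg.sequence, [243, 244], "NCG")
        assert prof["IRTTMR"] == pytest.approx(57.8, abs=1e-6)
        assert prof["IRTTMRS"] == pytest.approx(42.2, abs=1e-6)
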