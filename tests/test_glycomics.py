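"""Released-glycan assignment and EIC quantitation."""

import pytest

from glycoprofiler import glycomics, simulate
from glycoprofiler.glycans import enumerate_panel
from glycoprofiler.glycomics import (
    assign_glycome,
    count_assigned_structures,
    quantify,
)
from glycoprofiler.simulate import Feature


def _feature(mz, charge=1, intensity=1000.0, rt=30.0, sid=""):
    return Feature(mz=mz, charge=charge, rt=rt, intensity=intensity,
                   species_id=sid, polarity="-")


class TestAssignment:
    def test_m2f_deprotonated_ion_assigned(self):
        assignments = assign_glycome([_feature(895.3412)])
        (a,) = assignments
        assert a.assigned
        assert a.structures[0].name == "M2F"
        assert abs(a.mass_error_da) < 1e-3

    def test_doubly_deprotonated_matches_same_species(self):
        a1 = assign_glycome([_feature(895.3412, 1)])[0]
        a2 = assign_glycome([_feature(447.1670, 2)])[0]
        assert a1.group == a2.group == "M2F"

    def test_off_panel_mz_left_unassigned(self):
        (a,) = assign_glycome([_feature(1234.5678)])
        assert not a.assigned and a.structures == ()

    def test_sialyl_isomers_reported_as_group(self):
        # tri-mono-F sialylated isomer pair shares one alditol mass
        from glycoprofiler.masscalc import glycan_mass, to_mz

        mass = glycan_mass(
            {"Hex": 4, "HexNAc": 3, "dHex": 1, "NeuAc": 1}, "reduced-alditol"
        ).monoisotopic
        (a,) = assign_glycome([_feature(to_mz(mass, 2, "-"), 2)])
        assert a.assigned
        assert len(a.structures) == 2

    def test_ambiguous_match_flagged_not_chosen(self):
        # a panel with two compositions closer than the tolerance
        panel = enumerate_panel()
        (a,) = assign_glycome([_feature(895.3412)], panel=panel, tol_da=700.0)
        assert a.ambiguous and not a.assigned and len(a.structures) > 2

    def test_bad_tolerance_rejected(self):
        with pytest.raises(ValueError):
            assign_glycome([_feature(895.3412)], tol_da=0.0)

    def test_wrong_run_level_rejected(self, default_model):
        run = simulate.simulate_run(default_model, "glycopeptide", 1)
        with pytest.raises(ValueError, match="glycome"):
            assign_glycome(run)


class TestQuantify:
    def test_single_species_is_100_percent(self):
        prof = quantify([assign_glycome([_feature(895.3412)])])
        assert prof["M2F"] == pytest.approx(100.0)

    def test_empty_assignments_rejected(self):
        with pytest.raises(ValueError):
            quantify([assign_glycome([_feature(1234.5678)])])

    def test_zero_noise_recovery_matches_ground_truth(self, zero_noise_model):
        run = simulate.simulate_run(zero_noise_model, "glycome", 1)
        prof = quantify([assign_glycome(run)])
        # ground truth per released species, renormalized
        from glycoprofiler.glycans import by_name, pngase_releases

        truth: dict[str, float] = {}
        for prot in zero_noise_model.proteins:
            for site in prot.sites:
                for name, p in site.glycoforms.items():
                    if pngase_releases(by_name(name)):
                        truth[name] = truth.get(name, 0.0) + prot.abundance * p
        total = sum(truth.values())
        for label, mean in prof.means.items():
            expected = sum(truth.get(n, 0.0) for n in label.split("|"))
            assert mean == pytest.approx(100.0 * expected / total, abs=1e-6)

    def test_profile_invariant_under_uniform_rescaling(self, zero_noise_model):
        run = simulate.simulate_run(zero_noise_model, "glycome", 1)
        scaled = [
            _feature(f.mz, f.charge, f.intensity * 37.5, f.rt, f.species_id)
            for f in run.features
        ]
        p1 = quantify([assign_glycome(run)])
        p2 = quantify([assign_glycome(scaled)])
        for k in p1.means:
            assert p1[k] == pytest.approx(p2[k], abs=1e-9)

    def test_charge_states_merge_into_one_entry(self, zero_noise_model):
        run = simulate.simulate_run(zero_noise_model, "glycome", 1)
        assignments = assign_glycome(run)
        m2f = [a for a in assignments if a.group == "M2F"]
        assert len({a.feature.charge for a in m2f}) == 2  # z=1 and z=2
        prof = quantify([assignments])
        assert "M2F" in prof.means


@pytest.fixture(scope="module")
def assignments(default_model):
    run = simulate.simulate_run(default_model, "glycome", 17)
    return assign_glycome(run)


class TestDefaultGlycomeRun:

    def test_eleven_distinct_structures_assigned(self, assignments):
        assert count_assigned_structures(assignments) == 11

    def test_m2f_most_abundant(self, assignments):
        prof = quantify([assignments])
        assert prof.top() == "M2F"

    def test_exoglycosidase_differential_resolves_sialyl_linkage(self):
        """A paired untreated vs α2,3-sialidase-treated run reveals the
        α2,6-linked share of each sialylated isomer group; the broad
        sialidase removes the whole group."""
        from glycoprofiler.glycans import A23_SIALIDASE, BROAD_SIALIDASE
        from glycoprofiler.glycomics import exoglycosidase_differential
        from glycoprofiler.simulate import digest_model

        model = simulate.default_ncg_model().zero_noise()
        untreated = simulate.simulate_run(model, "glycome", 1)
        label = "tri-mono-F-a2,3-SA|tri-mono-F-a2,6-SA"
        for rule, expected in [(A23_SIALIDASE, 0.5), (BROAD_SIALIDASE, 0.0)]:
            treated = simulate.simulate_run(digest_model(model, rule), "glycome", 1)
            report = exoglycosidase_differential(untreated, treated, rule)
            # the a2,6/a2,3 pair is planted at equal ground-truth proportions
            assert report[label]["persisted_fraction"] == pytest.approx(
                expected, abs=1e-6
            )
        assert set(report[label]["susceptible_members"]) == {
            "tri-mono-F-a2,6-SA", "tri-mono-F-a2,3-SA",
        }

    def test_mannosidase_differential_collapses_arm_isomers(self):
        from glycoprofiler.glycans import JBM_MANNOSIDASE
        from glycoprofiler.glycomics import exoglycosidase_differential
        from glycoprofiler.simulate import digest_model

        model = simulate.default_ncg_model().zero_noise()
        untreated = simulate.simulate_run(model, "glycome", 1)
        treated = simulate.simulate_run(
            digest_model(model, JBM_MANNOSIDASE), "glycome", 1
        )
        report = exoglycosidase_differential(untreated, treated, JBM_MANNOSIDASE)
        assert report["M2"]["persisted_fraction"] == pytest.approx(0.0, abs=1e-9)
        # M1 gains the trimmed M2 signal: persistence ratio above 1 clips to 1
        assert report["M1"]["persisted_fraction"] == pytest.approx(1.0)

    def test_zic_hilic_retention_labels(self):
        from glycoprofiler.glycans import by_name, full_panel, zic_hilic_retained

        retained = {g.name for g in full_panel() if zic_hilic_retained(g)}
        assert all("SA" in name for name in retained)
        assert not zic_hilic_retained(by_name("M2F"))
        assert not zic_hilic_retained(by_name("GlcNAcb"))

    def test_panel_csv_import_round_trip(self, tmp_path):
        from glycoprofiler.glycans import export_panel_csv, full_panel, import_panel_csv

        path = tmp_path / "panel.csv"
        export_panel_csv(full_panel(), path)
        assert import_panel_csv(path) == full_panel()

    def test_removing_contaminants_shifts_profile_toward_site(self):
        """Contaminants drive the glycome away from the Asn71 profile:
        dropping them strictly increases the correlation with it."""
        from glycoprofiler import glycopeptides, reconcile

        contaminated = simulate.default_ncg_model().zero_noise()
        clean = simulate.default_ncg_model(include_contaminants=False).zero_noise()
        ncg = contaminated.proteins[0]
        runs_gp = simulate.simulate_replicates(contaminated, "glycopeptide", [1])
        site, _, _ = glycopeptides.site_profile(runs_gp, ncg.sequence, 71, "NCG")
        universe = [s for s in reconcile.MAJOR_GLYCOFORMS]
        r2 = {}
        for tag, model in [("contaminated", contaminated), ("clean", clean)]:
            run = simulate.simulate_run(model, "glycome", 2)
            prof = quantify([assign_glycome(run)])
            r2[tag] = reconcile.correlate(prof, site, universe)
        assert r2["clean"] > r2["contaminated"]
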