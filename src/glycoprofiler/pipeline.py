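"""End-to-end replay of the three-level profiling experiment on synthetic
data: simulate all three acquisition levels from the default ground-truth
model, run every stage, and assemble the reconciliation report."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from . import glycomics, glycopeptides, intact, reconcile, simulate
from .profiles import QuantProfile

__all__ = ["PipelineConfig", "run_replay"]


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline replay.

    Seeds are explicit per replicate; level-specific run seeds are derived
    deterministically from them. Three technical replicates per level by
    default, matching the triplicate acquisition design.
    """

    seeds: tuple[int, ...] = (11, 12, 13)
    voltage: float = 200.0
    occupancy: float = 1.0
    include_contaminants: bool = True
    zero_noise: bool = False
    tol_glycome_da: float = 0.15
    tol_peptide_da: float = 0.3
    tol_intact_ppm: float = 50.0
    with_isotopes: bool = False
    outdir: Path | None = None

    def level_seeds(self, level: str) -> list[int]:
        offset = {"glycome": 1, "glycopeptide": 2, "intact": 3}[level]
        return [(s * 8 + offset) % (2**31) for s in self.seeds]

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        if "seeds" in raw:
            raw["seeds"] = tuple(raw["seeds"])
        if raw.get("outdir"):
            raw["outdir"] = Path(raw["outdir"])
        return cls(**raw)


def run_replay(config: PipelineConfig | None = None) -> reconcile.ReconciliationReport:
    """Simulate all three levels, run every stage, and reconcile.

    Writes profiles, match tables, the semi-quantitative table, and a
    Markdown report to ``config.outdir`` when set.
    """
    config = config or PipelineConfig()
    noise = simulate.NoiseModel().zero() if config.zero_noise else None
    model = simulate.default_ncg_model(
        occupancy=config.occupancy,
        include_contaminants=config.include_contaminants,
        noise=noise,
    )
    ncg = model.proteins[0]

    # --- released glycome ---------------------------------------------
    glycome_runs = simulate.simulate_replicates(
        model, "glycome", config.level_seeds("glycome"), config.voltage
    )
    assignments = [
        glycomics.assign_glycome(run, tol_da=config.tol_glycome_da)
        for run in glycome_runs
    ]
    glycome_profile = glycomics.quantify(assignments)

    # --- glycopeptides -------------------------------------------------
    gp_runs = simulate.simulate_replicates(
        model, "glycopeptide", config.level_seeds("glycopeptide"), config.voltage
    )
    site_prof, occ, occ_sd = glycopeptides.site_profile(
        gp_runs, ncg.sequence, 71, ncg.name, tol=config.tol_peptide_da
    )
    cterm_prof = glycopeptides.cterm_ratio(
        gp_runs, ncg.sequence, sorted(ncg.cterm_variants), ncg.name,
        tol=config.tol_peptide_da,
    )
    contaminant_profiles: dict[tuple[str, int], QuantProfile] = {}
    for prot in model.proteins[1:]:
        for site in prot.sites:
            prof, _, _ = glycopeptides.site_profile(
                gp_runs, prot.sequence, site.position, prot.name,
                tol=config.tol_peptide_da,
            )
            contaminant_profiles[(prot.name, site.position)] = prof

    # --- intact protein -------------------------------------------------
    intact_runs = simulate.simulate_replicates(
        model, "intact", config.level_seeds("intact"), config.voltage,
        with_isotopes=config.with_isotopes,
    )
    space = intact.enumerate_proteoforms(ncg)
    matches = [
        intact.match_proteoforms(
            intact.deconvolute(run), space, tol_ppm=config.tol_intact_ppm
        )
        for run in intact_runs
    ]
    variant_prof, glycoform_marginal = intact.quantify_proteoforms(matches)

    # --- reconciliation -------------------------------------------------
    r2_gi = reconcile.correlate(site_prof, glycoform_marginal)
    r2_gg = reconcile.correlate(glycome_profile, site_prof)
    semiquant = reconcile.semiquant_table(
        {("NCG", 71): site_prof, **contaminant_profiles}
    )
    flags = reconcile.diagnose_contamination(
        glycome_profile, {("NCG", 71): site_prof}, contaminant_profiles
    )
    aglyco = glycoform_marginal["aglycosylated"]
    report = reconcile.ReconciliationReport(
        r2_glycopeptide_intact=r2_gi,
        r2_glycome_glycopeptide=r2_gg,
        occupancy=occ,
        occupancy_sd=occ_sd,
        site_profile=site_prof,
        glycome_profile=glycome_profile,
        variant_profile=variant_prof,
        glycoform_marginal=glycoform_marginal,
        cterm_peptide_profile=cterm_prof,
        semiquant=semiquant,
        contamination_flags=flags,
        insource_artefact=bool(occ >= 0.999 and aglyco > 0.01),
    )

    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.md").write_text(report.to_markdown())
        site_prof.to_frame().to_csv(out / "site_profile.csv", index=False)
        glycome_profile.to_frame().to_csv(out / "glycome_profile.csv", index=False)
        variant_prof.to_frame().to_csv(out / "variant_profile.csv", index=False)
        glycoform_marginal.to_frame().to_csv(out / "glycoform_marginal.csv", index=False)
        cterm_prof.to_frame().to_csv(out / "cterm_peptides.csv", index=False)
        semiquant.to_csv(out / "semiquant_table.csv")
        intact.match_table(matches[0]).to_csv(out / "proteoform_matches.csv", index=False)
        summary = {
            "r2_glycopeptide_intact": r2_gi,
            "r2_glycome_glycopeptide": r2_gg,
            "occupancy": occ,
            "insource_artefact": report.insource_artefact,
            "contamination_flags": flags,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return report
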