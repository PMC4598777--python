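# Methods

## The measurement model

The package treats a glycoprotein preparation as a mixture of molecular
species defined by a ground-truth model: proteins with abundances,
C-terminal truncation variants with proportions, glycosylation sites with a
glycoform distribution (microheterogeneity) and an occupancy
(macroheterogeneity), and fixed PTMs (complete Met oxidations, native
disulfides at −2 H each, deamidations carried as annotations only — they
are sub-stoichiometric and localized at the peptide level, so they do not
enter intact-level masses). Three acquisition levels observe this mixture:

1. **Released glycome** (negative mode): PNGase F releases every glycan
   with an intact chitobiose core (HexNAc ≥ 2 at the reducing end);
   Asn-linked GlcNAc₁(Fuc₀₋₁) stubs resist the enzyme and are invisible at
   this level. Released glycans are reduced to alditols (+H₂O +2 H) and
   observed as [M−H]⁻ / [M−2H]²⁻.
2. **Glycopeptides** (positive mode): chymotryptic peptides (cleavage
   C-terminal to F/Y/W/L/M, never before Pro) carry the site's glycans
   intact. CID fragments glycosidic bonds (Y-ion ladder, oxonium B ions,
   weak backbone b/y); ETD fragments the backbone (c/z) leaving the glycan
   in place, which is what licenses a site-localization claim.
3. **Intact protein** (positive mode): multi-charge ESI envelopes of whole
   proteoforms, resolved to neutral average masses.

All quantitation is relative EIC area summed over observed charge states,
with equal ionization efficiency assumed for related species (an optional
per-class bias hook exists and is off by default, except for the
generator's own sialylated-species bias below).

## The glycan structure space

Structures are compositions (Hex, HexNAc, dHex, NeuAc) plus flat linkage
annotations (core α1,6-fucose, mannose arms, sialyl linkage α2,3/α2,6) in
three classes: chitobiose stubs (GlcNAcβ, Fucα1,6GlcNAcβ, M0F),
paucimannose M1–M3F (α1,3-arm M2/M2F isomers excluded from the default
human-neutrophil panel), and monoantennary sialylated complex structures on
bi-/trimannosyl cores. The default released-glycome panel has 11
structures; the full panel adds the two stubs. Composition isomers
(α2,3/α2,6 sialyl pairs) share a mass, so every mass-based assignment
reports *isomer groups*; distinguishing them requires orthogonal evidence,
modelled here as in-silico exoglycosidase rules (broad sialidase, α2,3-
specific sialidase, α1,2/3 > α1,6-preferring α-mannosidase that never
touches the β-Man core). Linkage resolution is implemented as differential
re-assignment across a paired untreated vs in-silico-digested run: the
fraction of an isomer group's signal persisting after the digest,
normalized to an enzyme-inert reference group that receives no digestion
products, estimates the share of members the enzyme cannot cleave.

## The synthetic-data generator

The generator's defaults are the documented profiling conditions for
human neutrophil cathepsin G: a fully occupied
glycosite carrying GlcNAcβ 55.2 : Fucα1,6GlcNAcβ 22.7 : M1 10.6 : M1F 7.9 :
M2 3.7 plus trace M2F and five trace sialylated species (proportions
normalized internally); C-terminal variants Arg243/Ser244 at 61.9 : 38.1;
complete Met152 oxidation; three disulfides; and two contaminant
glycoproteins (azurocidin- and elastase-like, two sites each) at 0.3
abundance apiece with M2F-dominant site distributions. Because released-
glycan data are site-unspecific, the minor glycome-only species (M0F, M3F,
sialylated) are attributed to the highly solvent-accessible contaminant
sites; this reproduces the 11-species released glycome and its M2F-
dominated skew without asserting anything about the target protein's site.

Modelling choices a user should know:

* **Two C-terminal ratios.** The intact level reports 61.9 : 38.1 while the
  peptide level reports 57.8 : 42.2. The generator encodes the molecular
  truth as the intact ratio and applies a configurable per-variant
  ionization response factor to the C-terminal reporter peptides whose
  default reproduces the peptide-level ratio — i.e. the discrepancy is
  modelled as peptide-level ionization bias. Both hypotheses (bias vs
  biology) are expressible through the model config.
* **Ionization bias.** Sialylated glycopeptides/glycoforms receive a 0.5
  response factor in positive mode (configurable; the under-representation
  is documented qualitatively, not numerically, so this is an assumption).
* **Charge envelopes** are fixed multinomial splits: released glycans
  z = 1–2 (0.7/0.3), glycopeptides z = 1–3 (0.2/0.5/0.3), intact protein
  z = 15–25 with a bell-shaped weight profile.
* **Chromatography** is a surrogate: each species is a single apex feature
  whose intensity stands for its EIC area, at a class-based retention time
  (site glycopeptides 39 min, contaminant glycopeptides 34 min, C-terminal
  peptides 22 min) with Gaussian jitter. Elution profiles, ZIC-HILIC
  physics, and ion mobility are not modelled; ZIC-HILIC enrichment exists
  only as a retained/non-retained label (sialylated retained, stub and
  paucimannosidic species not).
* **Noise** is mean-one lognormal intensity noise (CV 0.12) plus ppm-scale
  m/z jitter (8 ppm at the ion-trap levels, 2 ppm at the QTOF intact
  level). The CV is a calibration: it makes 3-replicate SDs of recovered
  proportions land at the order of the documented replicate SDs (a few
  points on major species). It is not inferred from data.
* **In-source glycan loss** at the intact level is zero at ≤ 200 V and
  rises linearly to a maximum fraction (default 0.35) at 400 V. The lost
  fraction appears as a spurious aglycosylated proteoform tagged as
  in-source in its provenance — reproducing the artefact that mimics
  partial site occupancy at high fragmentor potential.
* **Determinism.** All randomness flows through one seeded generator per
  run; the same seed yields a byte-identical run.

What passing tests on this generator do *not* show: robustness to real
chromatographic peak shape, co-elution, missing values, charge-state
distributions that vary by species, adducts (flagged, not modelled), or
FDR-controlled identification at proteome scale. The generator exists to
verify the analysis logic against a known truth, not to certify
instrument-grade performance.

## Stage numerics

* **Glycome assignment** uses a 0.15 Da absolute tolerance by default
  (unit-resolution ion trap); features matching more than one panel
  composition are flagged ambiguous rather than silently resolved.
  Assignment is charge-state consistent: features of one species at
  different z merge into one quantitative entry.
* **Glycopeptide matching** defaults to 0.3 Da MS1 / 0.5 Da MS2 tolerances
  (configurable assumptions; the instrument's tolerances are not
  documented). Spectrum matching scores matched-ion counts with precursor-
  error tie-break; site localization is claimed only when matched ETD c/z
  ions bracket the site with the expected glycan mass shift. EIC
  quantitation reports isomer groups for isobaric glycoforms.
* **Deconvolution** clusters charge hypotheses by single linkage along the
  neutral-mass axis (0.6 Da), requires ≥ 2 consecutive charge states,
  assigns each peak to its best-supported envelope (support first,
  intensity second — which also defuses the M/2 harmonic, whose support is
  always lower than the true envelope's), and trims stray members that
  disagree with the cluster's median mass by > max(5·MAD, 0.05 Da).
  Proteoform matching uses average mass at 50 ppm (conservative relative
  to calibrant-level accuracy, configurable). The isotope-fit score is
  undefined (and reported as such) for unresolved clusters.
* **Isotope patterns** are computed by per-element convolution aggregated
  in nominal-mass bins (fine structure is not resolved at the modelled
  resolution), truncated at 99.99% cumulative abundance and renormalized;
  element masses and abundances are pinned to the IUPAC 2013 evaluation in
  one exportable constants table, with the CODATA proton mass (not the
  H-atom mass) as the ESI charge carrier.
* **Reconciliation** computes R² of a least-squares fit between profiles
  over a common species universe — by default the five major glycoforms,
  excluding traces, on raw proportions (not logits). Semi-quantitative
  bins: ≥ 20% → `xxxx`, 2–20% → `xxx`, quantifiable < 2% → `xx`,
  detected-only → `x`; thresholds are reverse-engineered from the
  documented table's populated cells and configurable. Contamination diagnosis flags
  glycome species exceeding their expectation (from the target protein's
  releasable site profile) by > 5 percentage points and attributes them to
  contaminant sites carrying the species at ≥ 2%.
* **Structure module.** SASA is Shrake–Rupley on a deterministic Fibonacci
  sphere lattice (960 points by default; converges to < 1% change at
  3840), with Bondi van der Waals radii and a 5 Å probe by default —
  scores are accessibility rankings in arbitrary absolute units, not
  water-probe SASA. Distances default to minimum side-chain-heavy-atom
  convention, and the convention is always reported alongside the value
  because published site-to-site distances rarely state theirs. PDB input
  is parsed with gemmi (first model, waters out, highest-occupancy
  altloc). The crystal-structure workflow (`fetch_pdb` +
  `methionine_accessibility_ranking` + `site_distance`) requires a
  downloaded structure; the test suite runs entirely on synthetic
  coordinate fixtures with analytic expectations (isolated atom =
  4π(r+p)²).

## Sequence fixtures

The bundled FASTA files are synthetic stand-ins (see each file's header and
`sequences.py`). The cathepsin-G stand-in encodes every documented anchor
in unprocessed-chain numbering: signal+pro 1–20, His64/Asp108/Ser201
triad, the single sequon at Asn71 inside chymotryptic GSNINVTL (67–74),
Met35/110/152/242, deamidation-prone Gln163/Asn208, six mature-chain
cysteines, and the W237 | IRTTMR(238–243) | S244 | F245 C-terminal region
that yields the two truncation-variant reporter peptides. The contaminant
stand-ins plant their documented glycosites (Asn126/171 and Asn124/173)
inside 18-mer chymotryptic peptides chosen to be mass-separated (≥ 0.6 Da
at z = 1–3) from every target-protein species, so EIC quantitation is not
confounded by accidental isobars that real sequences would not exhibit at
these exact masses. Every pipeline function accepts real UniProt sequences
in their place.

## Problem sizes

Default analyses run triplicate simulations per level (~20–50 features per
run, tens of fragment spectra, 22 intact proteoform species over 11 charge
states), which completes in seconds on one CPU; the full replay including
report assembly stays well under a minute. Intact isotope-cluster
generation is optional (off in the default replay) since proteoform-level
quantitation needs only envelope areas.

## Known limitations

* Identification is matched-ion counting against a closed candidate space;
  no target-decoy FDR, no open search.
* Glycan topology is composition + flat annotations; no tree encoding
  (GlycoCT/WURCS) and no de-novo topology from fragments.
* The released-glycome attribution of minor species to contaminant sites is
  a modelling convention, not an inference — real site-unspecific data
  cannot distinguish the sources without the glycopeptide evidence.
* Maximum-entropy deconvolution is deliberately replaced by the defined
  charge-envelope clustering above; results agree on the contract (neutral
  masses + intensities) but not necessarily on artifact behaviour.
* Glycan 3D conformers and their heights above the protein surface are out
  of scope; the structure module ranks residue exposure and measures
  residue–residue distances only.
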