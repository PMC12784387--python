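# Methods

## Mass arithmetic

All mass computation reduces to integer element counts over a pinned table
of monoisotopic atomic masses (`heritagems/data/isotope_masses.tsv`,
version `2020.1`, AME2020/CODATA-2018 values to ≥ 8 decimals; C, H, N, O,
S, P, Cu). Reproducing sub-ppm mass errors requires fixing these constants:
a change in the fifth decimal of an atomic mass moves a 600 Th ion by more
than 0.01 ppm, which is visible at the precision of published
interpretation tables. Reports record the constants version.

Two conventions are worth stating explicitly:

* **Electron correction.** The m/z of a singly charged cation is the
  monoisotopic mass of its full atom inventory minus one electron mass.
  At m/z 300 the electron is ≈ 1.8 ppm; omitting it shifts every computed
  error by that amount and visibly breaks agreement with measured values.
* **Proton mass.** The proton constant is defined as m(H atom) − m(e⁻),
  the universal mass-spectrometry convention. This ignores the 13.6 eV
  hydrogen binding energy (≈ 1.5 × 10⁻⁸ Da, < 10⁻⁴ ppm at any m/z in
  range), so "add a proton" and "add H, subtract an electron" are
  numerically interchangeable.

ppm errors are signed, `(measured − theoretical)/theoretical × 10⁶`, kept
at full precision internally and rounded to two decimals only for display.
Recomputed errors for reference resin-varnish peaks occasionally differ
from published cells by 0.01–0.02 ppm; this is consistent with rounding of
the printed measured m/z values to five decimals and is why agreement is
asserted at ±0.03 ppm rather than exactly.

## Component tables

Building blocks live in a human-editable TSV with name, abbreviation,
class, Hill formula and material families. Classes drive the assembly
rules; families scope which components each material contributes. Two
taxonomy decisions:

* Oleanonic/ursonic acid is stored as a single isobaric entry (C30H46O3):
  spectra cannot distinguish the oleanane and ursane skeletons, and the
  assignments treat them jointly.
* Triterpenoids are split into *dammarane* (tetracyclic: dammaradienol,
  dammaradienone, hydroxydammarenone, dammarenolic acid) and *pentacyclic*
  (oleanonic/ursonic acid, nor-amyrone) classes. Only the dammarane cores
  participate in dammar's polycadinene fraction, so cadinene combinations
  are built on them alone. This keeps the combination clusters where aged
  dammar spectra actually show them (second cluster ≈ 610–665, third
  ≈ 815–880); a C29 pentacyclic core extended by two cadinene units would
  land at m/z ≈ 784, in a region observed to be empty.
* "Decadienoic acid (C10:2)" is encoded as C10H16O2 by Cn:k arithmetic;
  only the shorthand is attested.

## Candidate generation

Neutral parents are enumerated per family: acylglycerols as combinations
with repetition of the acid pool on glycerol (each ester bond −H₂O; sn
positions are not distinguished — assignment is compositional), wax mono-
and diesters, abietane resin acids with pairwise combination products
(plain formula sums, no atom loss, colophony only), dammarane cores with
one or two cadinene units, sterols and PAH markers. Free fatty acids are
emitted only for families with a glycerolipid backbone, where they are
hydrolysis products; wax-bound acids stay esterified.

Cadinene attachment emits both the 0- and 1-water-loss variants per
attachment set: the attested combination ions imply exactly one water lost
in total whether one or two units attach, which no fixed per-bond rule
expresses, so the generator enumerates and lets ppm matching decide.

Each parent is expanded into protonated variants [M+H]⁺ with up to two
water losses, one combined (H₂O+CO) loss, up to three oxygen gains and one
−2H dehydrogenation (all bounds configurable). These bounds cover every
attested assignment without combinatorial explosion. Variants that would
require atoms the parent lacks are skipped. Candidates sharing a cation
formula merge with concatenated provenances — one peak frequently admits
several isomeric parent routes — and the library is sorted by (m/z, Hill
string) for reproducible diffs.

Polymerized C34–C39 oil/resin species beyond these mechanisms are excluded
by default: they are reported qualitatively in aged films but without
formulas to encode.

## Annotation and clustering

Peak matching is a binary search over the m/z-sorted library with a
relative window: candidate *t* matches peak *m* iff
|(m − t)/t| ≤ tol × 10⁻⁶. The default tolerance is 2 ppm, the accuracy
contract of an externally calibrated FT-ICR instrument; ~5 ppm is
recommended for uncalibrated data. Matches are ranked by |Δppm|, ties
broken by fewer modifications, then lexicographic formula — reports are
deterministic. Cluster detection is a greedy scan splitting at m/z gaps
above `min_gap` (default 50 Th) and discarding clusters below `min_peaks`
(default 3); both defaults are qualitative choices matching how broad peak
groups are described in practice.

## Classification

Material calls use weighted marker coverage with required-marker gating
(AND of OR-groups). Scores are (matched weight)/(total weight) ∈ [0, 1]
and monotone in the matched marker set. The rule file is data, not code.
Weights formalize presence/absence reasoning, not measured likelihoods:
e.g. pine tar requires retene AND simonellite (weight 2 each) with
abietanes as support (weight 1), so a colophony spectrum without the PAH
markers scores 0 for pine tar while a pine-tar spectrum without aging
dimers scores only 0.75 for colophony. Ties rank by absolute matched
weight, which puts dammar above beeswax on the matte-varnish mixture where
both reach full coverage. Triterpenoid evidence without a cadinene
combination yields an "ambiguous" flag rather than a call — several
materials (mastic, myrrh, birch bark tar) share the C30 skeletons.

## Simulator

The simulator is the package's test bed; its defaults are the study
conditions and are not tuned per test.

* **Sampling.** Candidate inclusion probability is proportional to a
  plausibility weight: family abundance × assembly-group share ×
  modification penalties. Group shares divide a family's signal across
  comparable species (all TAGs of a pool, all free acids, all sterols…),
  so a single named compound such as cholesterol or retene is not swamped
  by the combinatorial multiplicity of acylglycerol isomers — mirroring
  real spectra, where the named markers are individually detectable while
  the TAG envelope is spread over many peaks. Hydrolysis (default 0.5)
  moves acylglycerol weight from TAGs to DAG/MAG/free acids; oxidation
  (default 0.3) scales each +O gain; fragmentation (default 0.3, 0.2 for
  dammar/beeswax recipes, which fragment less) scales each loss step.
* **Calibration error.** Measured m/z = theoretical × (1 + ε),
  ε ~ N(0, sd × 10⁻⁶) with sd = 1 ppm by default — matching instruments
  whose errors are mostly below ±1 ppm with a tail toward ±2 ppm. At this
  setting ≈ 4.6 % of peaks fall outside a 2 ppm annotation window (the 2σ
  tail), which is why rank-1 recovery sits near 95 %, its theoretical
  ceiling.
* **Intensities** are log-normal (log-sd 0.7) around the plausibility
  weight. This is explicitly *not* an ionization-physics model — none is
  available for laser ablation of aged films; it suffices to exercise
  matching, clustering and classification. Consequently, passing tests
  demonstrate correctness of the interpretation machinery, not predictive
  intensity accuracy on real spectra.
* **Noise** peaks are uniform in m/z over the acquisition window
  (100–1000 Th) at 0.2 peaks/100 Th, with intensities from the lowest
  decile of the signal. Real chemical noise is neither uniform nor
  independent of the matrix; a mid-gap noise peak occasionally (a few % of
  seeds) bridges two peak clusters, which is why cluster-structure checks
  use the modal count over a block of seeds rather than a single run.
* One global seed governs all randomness and is recorded in the spectrum
  metadata; identical inputs are bit-reproducible.

Simulated family recipes use 80–150 signal peaks, sized so that the full
statistical test battery (hundreds of simulate–annotate–classify runs)
completes in well under a minute while keeping per-spectrum peak counts in
the range of real centroided spectra.

Laser dose: fluence = pulse energy / (π (d/2)²) in J/cm², reported to two
significant figures; the closed form is cross-checked against numeric area
integration.

## I/O

Peak lists: CSV/TSV (header `mz,intensity`, m/z printed to five decimals),
MGF via pyteomics, and centroided mzML via pyteomics where its psims
backend is installed (otherwise a clear error advises exporting CSV/MGF;
profile-mode mzML is always rejected). Malformed numeric fields raise with
the line number; duplicate m/z values merge by intensity sum, logged.
Reports are deterministic TSV + JSON with package version, constants
version, config hash and seed.

## Known limitations

* No isotope-pattern scoring, no multiply charged ions, no negative mode.
* Copper is in the constants table but no Cu adducts are generated: none
  are observed for resinate varnishes under APCI.
* Phospholipids are absent by design (they do not survive to the detector
  under these conditions), as are MS/MS fragmentation prediction and any
  kinetic model of aging.
* The classifier reports scores for both pine tar and colophony rather
  than forcing a choice when PAH markers are weak — the two materials are
  genuinely hard to distinguish.
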