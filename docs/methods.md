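# Methods

## Mass model

All masses are monoisotopic, computed from NIST atomic masses over
elemental compositions. Amino acids use standard peptide-residue
compositions (peptide mass = Σ residues + H₂O). Ribonucleotide residues
follow the 3′-phosphate convention — residue = nucleoside 3′-monophosphate
− H₂O — which matches the chemistry of RNase T1/A products: an
oligonucleotide in the default 5′-OH/3′-phosphate state weighs
Σ residues + H₂O, so a mononucleotide adduct equals the free NMP
(U → 324.0359 Da). A 5′-phosphate terminal state adds one HPO₃
(79.9663 Da); a 2′,3′-cyclic phosphate is expressible as the default state
− H₂O but is off by default to keep the standard model simple. All residue
tables and atomic masses can be overridden from a YAML file
(`chem.load_table`).

Two isotope-labeling schemes generate the light/heavy doublet shift Δm:

* **full_13C15N** — uniformly ¹³C/¹⁵N-labeled RNA. Every C and N of the
  adduct is heavy, so Δm is additive over the composition: per-nucleotide
  increments are U 11.0243, C 12.0213, A/G 15.0187 Da (A and G share C/N
  counts, so Δm alone cannot distinguish them; the light precursor mass
  can, since G = A + O).
* **post_digest_18O** — an ¹⁸O-phosphate transferred enzymatically from
  γ-labeled ATP onto the oligonucleotide 5′-OH after digestion.
  Δm = k × 2.0042464 Da independent of composition, with k = 3 by default:
  the transferred γ-phosphate retains its three nonbridging heavy oxygens
  while the bridging oxygen comes from the acceptor 5′-OH. k is
  configurable for variant chemistries. Under this scheme candidate
  oligonucleotides default to the 5′-phosphate terminal state (the
  transferred group is part of the observed mass).

Cross-link formation itself is assumed mass-additive (peptide + adduct);
a configurable constant `xlink_offset` is provided for chemistries where
bond formation loses e.g. H₂, defaulting to 0.

## Digestion and search space

Trypsin cleaves C-terminal of K/R, suppressed before proline; up to 2
missed cleavages and peptide lengths 1–60 by default. RNase T1 cleaves 3′
of G, RNase A 3′ of pyrimidines. Benzonase, being nonspecific, is modeled
exhaustively as every substring up to the adduct-length cap rather than
stochastically: the search operates on nucleotide *compositions*
(multisets), so completeness of the hypothesis space is what matters, not
a kinetic product distribution. The composition space is all multisets
over {A,C,G,U} up to length 4 by default (69 hypotheses; counts per length
follow C(k+3,3)); the cap of 4 reflects that mono- to tetranucleotide
adducts dominate after exhaustive nuclease digestion, and it is
configurable. Neutral losses on the precursor default to
{none, −H₂O, −HPO₃}. Candidate precursors are the Cartesian product
peptides × compositions × losses; each carries light mass, heavy mass, and
Δm, with heavy − light ≡ Δm by construction. Coordinates are 1-based
inclusive throughout.

## Doublet detection and identification

Spectra are centroided MS2 peak lists (MGF); a doublet is two same-charge
precursors whose neutral-mass difference matches some composition's Δm
within 2× the precursor tolerance (both members contribute measurement
error; default precursor tolerance 10 ppm). A candidate matches a doublet
when its light mass agrees with the light member at the precursor
tolerance *and* its Δm agrees with the observed spacing. Localization
scores every site hypothesis 1..len(peptide) against both spectra of the
pair: the theoretical b/y ladder places the adduct mass on every fragment
containing the hypothesized site (light adduct against the light spectrum,
heavy against the heavy), and each matched fragment (20 ppm default)
contributes `1 + log10(1 + intensity)`. The two per-site profiles are
summed, so a site must be supported by both doublet members. The argmax
site is reported; ties are broken deterministically toward the lowest
position and the full tie set is emitted as the ambiguity set. The score
is deliberately a simple, documented surrogate for unpublished commercial
or in-house engine scores; it is pluggable (`peak_weight`).

## Target–decoy FDR

Decoys are reversed peptide sequences with the C-terminal K/R fixed.
Reversal preserves the residue multiset, so each decoy has exactly its
target's precursor mass and competes for the same doublets, differing only
in fragmentation — a conservative competition model. Peptides invariant
under the rule are excluded with a warning. Identifications are collapsed
to their best score per unique (peptide sequence, adduct mass rounded to
1 mDa, residue site) combination; the estimated FDR at score s is
#decoys(≥s)/#targets(≥s), q-values are the running minimum from the bottom
of the ranked list (monotone nonincreasing in score), and targets with
q ≤ 0.01 are accepted by default. Spectral counts are taken over all
accepted spectrum matches *before* the uniqueness collapse, supporting
"most abundant site by spectral count" summaries. `filter_fdr` refuses to
run without decoys (the estimate would be undefined).

## Mapping and phase comparison

Per-residue maps count accepted identifications at each localized residue
with a per-composition breakdown. Because MS determines only the adduct's
multiset, mapping onto the RNA enumerates every sequence window whose
content matches the composition; all candidate windows are reported
(overlaps allowed) in coordinates shifted by a configurable offset so that
subcloned elements can be labeled in their native numbering. Motif
scanning accepts IUPAC degenerate codes and reports overlapping matches.
The two-phase comparison partitions identification keys
(protein, site, composition) into shared and phase-specific sets and
pairs spectral counts only for shared keys: counts from different samples
are not placed on a common scale, so the output is qualitative by design
and no statistical test is attached.

## Simulator

The simulator is the package's ground-truth generator, emulating the
study conditions of an equimolar heavy/light RNA pool: each cross-link
site emits one light and one heavy MS2 spectrum whose precursor
intensities split exactly as `heavy_fraction` (default 0.5, i.e. 50%/50%
mixing) and whose spacing is Δm/z; fragment peaks are the complete
theoretical ladder. Optional imperfections: uniform random noise peaks
with exponential intensities, log-normal fragment-intensity jitter, and
Gaussian ppm-scale m/z jitter — all drawn from a seeded generator, so a
fixed seed gives byte-identical files. Precursor charges cycle through
{2,3}; fragment charge is 1. The built-in scenario pairs a synthetic
88-residue RNA-binding protein (tryptic peptides of 2–12 residues with
aromatic/His residues at the cross-link positions) with a
pyrimidine-repeat RNA (three UCUCU motifs separated by adenosines); the 12
ground-truth sites carry U-rich mono- to trinucleotide adducts, all
realizable as contiguous windows of that RNA. Not emulated: retention
time, isotope envelopes beyond the light/heavy pair, chimeric spectra,
enrichment losses — so green tests validate the identification logic, not
instrument effects.

## Numerical and design choices

* Tolerances: precursor 10 ppm, fragment 20 ppm, doublet-spacing 2× the
  precursor tolerance; all configurable. Localization ties use an absolute
  tie tolerance of 1e-9 on the score.
* Doublet pairing is deliberately permissive (a spectrum may join several
  pairs); disambiguation is delegated to candidate matching and FDR.
* Composition keys serialize alphabetically (e.g. `C1U1`) to make
  uniqueness collapsing deterministic; TSV floats are written at fixed
  precision so reruns are byte-identical.
* The pipeline aborts a failing stage with a stage-named error and removes
  partial outputs; the manifest records config hash, seed, version, and a
  SHA-256 per output file.
* Problem sizes in the test and acceptance runs (tens to hundreds of
  simulated doublet pairs over 12 sites) were chosen so the entire
  validation executes in seconds on one CPU while exercising every code
  path: recovery and FDR behavior are governed by the per-site score
  separation, which does not change at larger spectrum counts.

## Known limitations

Semi-tryptic and nonspecific protease search, modified nucleotides/amino
acids, DNA, open modification search, isotope-envelope modeling, and
statistical differential-binding tests between phases are out of scope.
Residue-level aggregation uses the exact localized residue (window 0);
"sites surrounding residue X" summaries can be produced downstream from
the TSV output.
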