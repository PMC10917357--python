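# clirms

Identification of protein–RNA cross-links from isotope-doublet mass
spectrometry data.

## The problem

UV irradiation covalently freezes direct contacts between RNA nucleobases
and nearby amino-acid side chains. After digesting the protein with trypsin
and trimming the RNA with nucleases (RNase T1, RNase A, benzonase), each
contact survives as a *peptide–oligonucleotide adduct*. When the RNA pool
is an equimolar mixture of unlabeled ("light") and stable-isotope-labeled
("heavy") molecules, every genuine adduct appears in the precursor (MS1)
domain as a **doublet**: two co-eluting species separated by a mass shift

&nbsp;&nbsp;&nbsp;&nbsp;Δm = Σ<sub>nucleotides</sub> (n<sub>C</sub> · 1.0033548 + n<sub>N</sub> · 0.9970349) Da

for uniform ¹³C/¹⁵N labeling, or a constant Δm ≈ 3 × 2.0042 Da when a heavy
¹⁸O-phosphate is enzymatically transferred onto the oligonucleotide 5′-OH
after digestion. Fragmentation (b/y ladders, with the RNA adduct riding on
every fragment that contains the cross-linked residue) then localizes the
contact to a single residue and determines the *composition* — but not the
sequence — of the attached oligonucleotide.

`clirms` implements this computational pipeline end to end for
two-sample designs (e.g. the dispersed and condensed fractions of a
phase-separated protein–RNA mixture, analyzed independently and compared
only on identical cross-link sites):

* exact monoisotopic mass model for peptides, oligonucleotides, and both
  labeling schemes (`clirms.chem`);
* in-silico protease/nuclease digestion and enumeration of the
  nucleotide-multiset search space (`clirms.digest`);
* MGF peak-list I/O, theoretical fragment ladders, and a seeded
  ground-truth simulator for validation (`clirms.spectra`,
  `clirms.simulate`);
* doublet detection, precursor matching, residue-level site localization,
  reversed-sequence decoys, and FDR filtering at 1% on unique
  (peptide, adduct mass, site) combinations (`clirms.search`);
* residue maps by spectral count, ambiguous composition-to-RNA window
  mapping, IUPAC motif scanning, and the qualitative two-phase comparison
  (`clirms.mapping`), with optional plots (`clirms.plotting`).

The scoring function is a documented surrogate (matched fragment count
weighted by `1 + log10(1 + intensity)`), not a re-implementation of any
proprietary engine; see `docs/methods.md`.

## Worked example

Simulate a 40-doublet dataset for the built-in toy RNA-binding protein
bound to a pyrimidine-repeat RNA, then search it:

```sh
clirms simulate --out sim --seed 7 --n-pairs 40 --noise-peaks 10
cat > config.yaml <<'YAML'
protein_fasta: sim/proteins.fasta
rna_fasta: sim/rna.fasta
mgf: [sim/dispersed.mgf]
phase_labels: [dispersed]
out_dir: out
motif: YCUNN
YAML
clirms search --config config.yaml
```

which prints

```
dispersed: 72 identifications, estimated FDR 0.00%
```

i.e. 72 spectrum matches survived 1% FDR filtering, and at the selected
score threshold no decoy outscored a target (decoy-estimated FDR 0%). The
per-residue map `out/residue_map.tsv` recovers every simulated cross-link
site with its composition, e.g.:

```
    phase protein_id  position  spectral_count compositions
dispersed     TOYRBP         5               8         U1:8
dispersed     TOYRBP        18               8       C1U1:8
dispersed     TOYRBP        25               8       C2U1:8
dispersed     TOYRBP        55               5         U1:5
```

(`position` is the 1-based protein residue; `U1`/`C1U1` are canonical
adduct-composition keys; `spectral_count` is the number of FDR-passing
identifications supporting the residue.) `out/rna_intervals.tsv` lists all
RNA windows compatible with each identified composition, and
`out/motif_matches.tsv` the 5′-YCUNN-3′ consensus positions. With two MGF
inputs the pipeline additionally writes `comparison_shared.tsv` /
`comparison_only_*.tsv`, partitioning cross-link keys into shared and
phase-specific sets. Use `clirms simulate --two-phase` to generate such a
dataset, and `clirms config --defaults` to see every tunable.

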